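import numpy as np
import pytest

from padma import SimConfig, fit_mfa, generate_multiomic, prepare_pathway


def make_assembled(seed=0, **overrides):
    """A small prepared (assembled/filtered/imputed) synthetic pathway."""
    cfg = SimConfig(
        n_individuals=overrides.pop("n_individuals", 20),
        n_genes=overrides.pop("n_genes", 4),
        aberrant_fraction=overrides.pop("aberrant_fraction", 0.1),
        effect_size=overrides.pop("effect_size", 2.0),
        seed=seed,
        **overrides,
    )
    ds = generate_multiomic(cfg)
    return prepare_pathway(ds.pathway, ds.omics, ds.mti), ds


@pytest.fixture
def assembled():
    return make_assembled(seed=1)[0]


@pytest.fixture
def model(assembled):
    return fit_mfa(assembled)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
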