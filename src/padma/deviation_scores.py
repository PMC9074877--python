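"""Individualized pathway deviation scores and their decomposition.

In the consensus space of a fitted MFA, the origin is the "average"
multi-omic pathway profile.  The deviation score of individual i is the
Euclidean distance of their factor-score vector from that origin,

    d_i = sqrt( sum_l f_{i,l}^2 ),

optionally restricted to a subset of components, and normalized by the
number of retained genes p so scores are comparable across pathways of
different sizes.  With all components, d_i equals the Euclidean norm of
the individual's row of the centered weighted concatenated matrix: no
information is lost to dimension reduction.

The score decomposes into signed per-gene contributions

    d_{i,g} = sum_l f_{i,l} (f_{i,l,g} - f_{i,l}) / sum_l f_{i,l}^2,

which sum to zero over genes: positive values mark genes pulling the
individual away from the average, negative values genes closest to it.
Scaled contributions divide by d_i to compare individuals on a common
footing.  The same construction extends additively to any grouping of
variables (single assays, omics, gene families).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import PadmaError
from .mfa_core import MFAModel


@dataclass
class DeviationResult:
    """Per-individual deviation scores and per-gene contributions."""

    pathway_name: str
    individual_ids: list[str]
    gene_names: list[str]
    raw_score: np.ndarray
    normalized_score: np.ndarray
    gene_contributions: np.ndarray
    scaled_gene_contributions: np.ndarray
    components_used: tuple[int, ...]
    zero_deviation: np.ndarray

    @property
    def p(self) -> int:
        return len(self.gene_names)


def _component_index(model: MFAModel, components: Sequence[int] | None) -> np.ndarray:
    if components is None:
        return np.arange(model.rank)
    comps = sorted(set(int(c) for c in components))
    if not comps:
        raise PadmaError("component subset must be non-empty")
    if comps[0] < 1 or comps[-1] > model.rank:
        raise PadmaError(
            f"components must lie in 1..{model.rank}; got {comps}"
        )
    return np.asarray(comps) - 1


def pathway_deviation(
    model: MFAModel, components: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual deviation scores (raw and gene-count-normalized).

    ``components`` selects 1-based consensus axes; the default uses all of
    them, in which case the score is exactly the distance of the
    individual's weighted standardized data row to the origin.
    """
    idx = _component_index(model, components)
    raw = np.sqrt((model.factor_scores[:, idx] ** 2).sum(axis=1))
    return raw, raw / model.p


def gene_contributions(
    model: MFAModel, components: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Signed per-gene contributions d_{i,g} (n x p) and a zero-score flag.

    For an individual sitting exactly at the origin the ratio is 0/0;
    such rows are set to zero and flagged rather than propagating NaN.
    Uses the same component subset as the deviation score so the
    sum-to-zero identity holds.
    """
    idx = _component_index(model, components)
    f = model.factor_scores[:, idx]  # n x L'
    d2 = (f**2).sum(axis=1)
    zero = d2 == 0.0
    contrib = np.zeros((model.n, model.p))
    for g in range(model.p):
        fg = model.partial_factor_scores[:, idx, g]
        num = (f * (fg - f)).sum(axis=1)
        contrib[~zero, g] = num[~zero] / d2[~zero]
    return contrib, zero


def scale_gene_contributions(
    contribs: np.ndarray, raw_scores: np.ndarray
) -> np.ndarray:
    """Scale contributions by the inverse overall score: d_{i,g} / d_i.

    Rows with d_i = 0 become all-zero.  Highlights genes that are atypical
    both within the pathway and relative to the population.
    """
    contribs = np.asarray(contribs, dtype=float)
    raw = np.asarray(raw_scores, dtype=float)
    if contribs.shape[0] != raw.shape[0]:
        raise PadmaError(
            f"dimension mismatch: {contribs.shape[0]} contribution rows, "
            f"{raw.shape[0]} scores"
        )
    safe = np.where(raw > 0, raw, 1.0)
    return np.where(raw[:, None] > 0, contribs / safe[:, None], 0.0)


def compute_deviation(
    model: MFAModel, components: Sequence[int] | None = None
) -> DeviationResult:
    """Bundle scores, contributions and scaled contributions for a model."""
    idx = _component_index(model, components)
    raw, norm = pathway_deviation(model, components)
    contrib, zero = gene_contributions(model, components)
    scaled = scale_gene_contributions(contrib, raw)
    return DeviationResult(
        pathway_name=model.assembled.pathway.name,
        individual_ids=list(model.individual_ids),
        gene_names=list(model.gene_names),
        raw_score=raw,
        normalized_score=norm,
        gene_contributions=contrib,
        scaled_gene_contributions=scaled,
        components_used=tuple(int(k) + 1 for k in idx),
        zero_deviation=zero,
    )


def _resolve_columns(
    model: MFAModel, feature_group: Iterable[str | tuple[str, str]]
) -> list[int]:
    cols: list[int] = []
    for feat in feature_group:
        if isinstance(feat, tuple):
            matches = [
                j
                for j, (f, o) in enumerate(zip(model.column_feature, model.column_omic))
                if (f, o) == feat
            ]
        else:
            matches = [
                j for j, f in enumerate(model.column_feature) if f == feat
            ]
        if not matches:
            raise PadmaError(f"unknown feature {feat!r} in group")
        cols.extend(matches)
    return sorted(set(cols))


def group_contribution(
    model: MFAModel,
    feature_group: Iterable[str | tuple[str, str]],
    components: Sequence[int] | None = None,
) -> np.ndarray:
    """Contribution of an arbitrary variable group to each deviation score.

    Group members are feature IDs, or (feature_id, omic) pairs when an ID
    is ambiguous across omics (gene-indexed assays share the gene symbol).
    A bare feature ID selects every column carrying it, including a miRNA
    column replicated across its target genes' tables.

    The construction is additive over columns: each gene carries mass 1/p
    shared equally by its columns, and a column's contribution is its
    share of sum_l f_{i,l}^2 through the partial projection, minus its
    mass.  Consequences: the group of all of gene g's features equals
    d_{i,g}; any partition of all features sums to 0 per individual; and
    singleton groups add up to their gene's contribution.  Zero-deviation
    individuals contribute 0.
    """
    cols = _resolve_columns(model, feature_group)
    idx = _component_index(model, components)
    f = model.factor_scores[:, idx]
    d2 = (f**2).sum(axis=1)
    zero = d2 == 0.0

    # per-column gene mass: 1 / (p * j_g) for a column of gene g
    j_per_gene = {
        g: sl.stop - sl.start for g, sl in zip(model.gene_names, model.block_slices)
    }
    mass = sum(1.0 / (model.p * j_per_gene[model.column_gene[j]]) for j in cols)

    # a_{i,j} summed over the group: sum_l f_{i,l} X*_{i,j} V_{j,l}
    x = model.weighted[:, cols]  # n x |S|
    v = model.loadings[np.ix_(cols, idx)]  # |S| x L'
    a = (f * np.einsum("nj,jl->nl", x, v)).sum(axis=1)

    out = np.zeros(model.n)
    out[~zero] = model.p * a[~zero] / d2[~zero] - model.p * mass
    return out


def omic_contributions(
    model: MFAModel, components: Sequence[int] | None = None
) -> dict[str, np.ndarray]:
    """Per-individual contribution of each omic (a partition: sums to 0)."""
    out: dict[str, np.ndarray] = {}
    for omic in sorted(set(model.column_omic)):
        group = [
            (f, o)
            for f, o in zip(model.column_feature, model.column_omic)
            if o == omic
        ]
        out[omic] = group_contribution(model, set(group), components)
    return out
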