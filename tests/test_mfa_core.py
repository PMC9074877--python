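"""MFA core checked against independent brute-force linear algebra.

The oracle used throughout standardizes with explicit loops, weights by
the largest eigenvalue of the per-table covariance (dense eigendecomposition,
no SVD), and diagonalizes the covariance of the concatenation — a fully
separate code path from the fitted model.
"""

import numpy as np
import pytest

from padma import (
    PadmaError,
    first_eigenvalue,
    fit_mfa,
    inertia_decomposition,
    project_supplementary,
    standardize_table,
)
from padma.pathway_assembly import GeneTable


def brute_force_mfa(tables, ddof=0):
    """Covariance-eigendecomposition pipeline, independent of the package SVD."""
    blocks = []
    for values in tables:
        n = values.shape[0]
        std = np.empty_like(values, dtype=float)
        for j in range(values.shape[1]):
            col = values[:, j]
            std[:, j] = (col - col.mean()) / col.std(ddof=ddof)
        cov = std.T @ std / (n - ddof)
        lam1 = max(np.linalg.eigvalsh(cov))
        blocks.append(std / np.sqrt(lam1))
    concat = np.concatenate(blocks, axis=1)
    n = concat.shape[0]
    cov = concat.T @ concat / (n - ddof)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(evals) * 1e-9
    scores = concat @ evecs[:, keep]
    return evals[keep], scores, concat


def random_tables(rng, n=8, p=3, max_j=3):
    return [
        rng.standard_normal((n, rng.integers(1, max_j + 1)))
        for _ in range(p)
    ]


def as_assembled(tables):
    from padma import PathwayDefinition
    from padma.pathway_assembly import AssembledPathway

    n = tables[0].shape[0]
    inds = [f"S{k}" for k in range(n)]
    gene_tables = [
        GeneTable(
            f"G{g}",
            inds,
            [f"G{g}_f{j}" for j in range(t.shape[1])],
            ["expression"] * t.shape[1],
            t,
        )
        for g, t in enumerate(tables)
    ]
    pw = PathwayDefinition("PW", "d", tuple(t.gene for t in gene_tables))
    return AssembledPathway(pw, gene_tables, inds)


class TestStandardize:
    @pytest.mark.parametrize("ddof", [0, 1])
    def test_zero_mean_unit_scale(self, rng, ddof):
        t = GeneTable("G", ["a", "b", "c", "d"], ["f1", "f2"], ["expression"] * 2,
                      rng.standard_normal((4, 2)) * 5 + 3)
        std, params = standardize_table(t, ddof=ddof)
        np.testing.assert_allclose(std.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(std.std(axis=0, ddof=ddof), 1, atol=1e-12)
        np.testing.assert_allclose(params.apply(t.values), std)

    def test_zero_variance_column_is_error(self):
        t = GeneTable("G", ["a", "b", "c"], ["f1"], ["cna"], [[2.0], [2.0], [2.0]])
        with pytest.raises(PadmaError, match="zero"):
            standardize_table(t)


class TestFirstEigenvalue:
    def test_single_standardized_column_gives_one(self, rng):
        col = rng.standard_normal((10, 1))
        std = (col - col.mean()) / col.std()
        assert first_eigenvalue(std) == pytest.approx(1.0)

    def test_two_identical_columns_give_two(self, rng):
        col = rng.standard_normal(10)
        std = (col - col.mean()) / col.std()
        assert first_eigenvalue(np.column_stack([std, std])) == pytest.approx(2.0)

    def test_matches_dense_eigensolver(self, rng):
        x = rng.standard_normal((10, 3))
        std = (x - x.mean(0)) / x.std(0)
        expected = max(np.linalg.eigvalsh(std.T @ std / 10))
        assert first_eigenvalue(std) == pytest.approx(expected, abs=1e-10)

    def test_requires_two_individuals(self):
        with pytest.raises(PadmaError):
            first_eigenvalue(np.zeros((1, 2)))


class TestFitMfa:
    def test_single_table_reduces_to_pca(self, rng):
        tables = [rng.standard_normal((12, 4))]
        model = fit_mfa(as_assembled(tables))
        evals, scores, _ = brute_force_mfa(tables)
        np.testing.assert_allclose(model.eigenvalues, evals, atol=1e-8)
        np.testing.assert_allclose(
            np.abs(model.factor_scores), np.abs(scores), atol=1e-8
        )

    def test_weighted_tables_have_unit_first_eigenvalue(self, model):
        for sl in model.block_slices:
            assert first_eigenvalue(model.weighted[:, sl]) == pytest.approx(
                1.0, abs=1e-10
            )

    def test_partial_scores_average_to_factor_scores(self, model):
        np.testing.assert_allclose(
            model.partial_factor_scores.mean(axis=2),
            model.factor_scores,
            atol=1e-10,
        )

    def test_eigenvalues_positive_descending_rank_bounded(self, model):
        ev = model.eigenvalues
        assert (ev > 0).all() and (np.diff(ev) <= 1e-12).all()
        total_j = model.weighted.shape[1]
        assert model.rank <= min(model.n - 1, total_j)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tables = random_tables(rng)
        model = fit_mfa(as_assembled(tables))
        evals, scores, _ = brute_force_mfa(tables)
        np.testing.assert_allclose(model.eigenvalues, evals[: model.rank], atol=1e-8)
        np.testing.assert_allclose(
            np.abs(model.factor_scores), np.abs(scores[:, : model.rank]), atol=1e-8
        )

    def test_isometry_of_score_space(self, model):
        row_norms2 = (model.weighted**2).sum(axis=1)
        np.testing.assert_allclose(
            (model.factor_scores**2).sum(axis=1), row_norms2, atol=1e-8
        )

    def test_affine_transform_of_raw_feature_leaves_scores_unchanged(self, rng):
        tables = random_tables(rng, n=10)
        model0 = fit_mfa(as_assembled(tables))
        tables[1] = tables[1].copy()
        tables[1][:, 0] = 3.5 * tables[1][:, 0] + 7.0
        model1 = fit_mfa(as_assembled(tables))
        np.testing.assert_allclose(
            model0.factor_scores, model1.factor_scores, atol=1e-8
        )
        # a negative multiplier flips the standardized column, which may
        # flip a component's deterministic orientation; scores agree up to
        # sign and every derived quantity is sign-invariant
        tables[1][:, 0] *= -1
        model2 = fit_mfa(as_assembled(tables))
        np.testing.assert_allclose(
            np.abs(model0.factor_scores), np.abs(model2.factor_scores), atol=1e-8
        )
        np.testing.assert_allclose(
            (model0.factor_scores**2).sum(axis=1),
            (model2.factor_scores**2).sum(axis=1),
            atol=1e-8,
        )

    def test_duplicating_features_doubles_lambda_keeps_invariant(self, rng):
        tables = random_tables(rng, n=10, p=2)
        model0 = fit_mfa(as_assembled(tables))
        dup = [np.hstack([tables[0], tables[0]]), tables[1]]
        model1 = fit_mfa(as_assembled(dup))
        assert model1.table_first_eigenvalue[0] == pytest.approx(
            2 * model0.table_first_eigenvalue[0], rel=1e-10
        )
        for sl in model1.block_slices:
            assert first_eigenvalue(model1.weighted[:, sl]) == pytest.approx(1.0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(PadmaError):
            fit_mfa(as_assembled([np.zeros((4, 2))]))


class TestSupplementaryProjection:
    def test_reference_individuals_reproduce_their_scores(self, model):
        new = {t.gene: t.values for t in model.assembled.tables}
        np.testing.assert_allclose(
            project_supplementary(model, new), model.factor_scores, atol=1e-8
        )

    def test_feature_mean_profile_projects_to_origin(self, model):
        means = {
            t.gene: t.values.mean(axis=0, keepdims=True)
            for t in model.assembled.tables
        }
        np.testing.assert_allclose(
            project_supplementary(model, means), 0, atol=1e-10
        )

    def test_held_out_individual_matches_column_by_column_formula(self, rng):
        tables = random_tables(rng, n=12, p=3)
        train = [t[:10] for t in tables]
        test = [t[10:] for t in tables]
        model = fit_mfa(as_assembled(train))
        scores = project_supplementary(
            model, {f"G{g}": test[g] for g in range(3)}
        )
        # hand-rolled projection, column by column
        expected = np.zeros((2, model.rank))
        col = 0
        for g, t in enumerate(train):
            prm = model.standardization[g]
            lam = model.table_first_eigenvalue[g]
            for j in range(t.shape[1]):
                z = (test[g][:, j] - prm.center[j]) / prm.scale[j] / np.sqrt(lam)
                expected += z[:, None] * model.loadings[col, :][None, :]
                col += 1
        np.testing.assert_allclose(scores, expected, atol=1e-8)

    def test_missing_feature_listed_in_error(self, model):
        t0 = model.assembled.tables[0]
        short = GeneTable(
            t0.gene,
            t0.individual_ids,
            t0.feature_ids[:-1],
            t0.feature_omics[:-1],
            t0.values[:, :-1],
        )
        with pytest.raises(PadmaError, match="lacks features"):
            project_supplementary(model, [short] + model.assembled.tables[1:])


class TestInertia:
    def test_single_omic_contributes_everything(self, rng):
        model = fit_mfa(as_assembled(random_tables(rng, n=10)))
        dec = inertia_decomposition(model)
        np.testing.assert_allclose(dec.omic_contribution.loc["expression"], 100.0)
        assert dec.weighted_omic_contribution["expression"] == pytest.approx(100.0)

    def test_percent_variances_and_contributions_sum_to_100(self, model):
        dec = inertia_decomposition(model)
        assert dec.axis_percent_variance.sum() == pytest.approx(100.0)
        np.testing.assert_allclose(dec.omic_contribution.sum(axis=0), 100.0)
        np.testing.assert_allclose(dec.gene_contribution.sum(axis=0), 100.0)
        np.testing.assert_allclose(dec.individual_contribution.sum(axis=0), 100.0)

    def test_weighted_omic_contribution_matches_direct_resummation(self, model):
        dec = inertia_decomposition(model)
        ev = model.eigenvalues
        for omic in dec.omic_contribution.index:
            expected = float(
                np.sum(dec.omic_contribution.loc[omic].to_numpy() * ev) / ev.sum()
            )
            assert dec.weighted_omic_contribution[omic] == pytest.approx(expected)
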