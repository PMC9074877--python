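"""Multiple factor analysis (MFA) over per-gene multi-omic tables.

MFA extends PCA to several data tables sharing the same observations.
Each gene table is standardized column-wise, then every feature in table
g is divided by sqrt(lambda_g1), where lambda_g1 is the variance of the
table's first principal component.  After this weighting the first
eigenvalue of a PCA of each table equals 1, so no single gene — however
many or however redundant its assays — dominates the global analysis.
A single SVD of the column-concatenated weighted matrix X* then yields
the consensus space: eigenvalues, per-individual factor scores, per-gene
partial factor scores, and loadings onto which supplementary individuals
can be projected without refitting.

Conventions
-----------
* Variances (standardization scale, lambda_g1, eigenvalues) use the
  population denominator ``n`` by default; set ``ddof=1`` for the
  unbiased convention.  All structural identities hold under either.
* Factor scores are the SVD coordinates ``U @ diag(s)``, so the factor
  space is an isometry of the rows of the centered weighted matrix:
  sum_l f_{i,l}^2 equals the squared Euclidean norm of row i of X*.
* Component signs are fixed by making the largest-magnitude loading of
  each component positive, for reproducibility across backends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PadmaError
from .pathway_assembly import AssembledPathway, GeneTable

#: Relative singular-value cutoff defining the numeric rank of X*.
RANK_RTOL = 1e-10


@dataclass
class StandardizationParams:
    """Per-feature centering and scaling constants of one gene table."""

    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.scale <= 0):
            raise PadmaError("standardization scale must be positive for every feature")

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.center) / self.scale


def standardize_table(
    table: GeneTable, ddof: int = 0
) -> tuple[np.ndarray, StandardizationParams]:
    """Center and scale each column of a gene table to mean 0, variance 1.

    The scale is the standard deviation with ``ddof`` delta degrees of
    freedom.  Zero-variance columns are an error: the variance filter is
    expected to have removed them upstream.
    """
    values = np.asarray(table.values, dtype=float)
    if np.isnan(values).any():
        raise PadmaError(f"gene {table.gene}: missing values; impute first")
    center = values.mean(axis=0)
    scale = values.std(axis=0, ddof=ddof)
    if np.any(scale == 0):
        j = int(np.argmax(scale == 0))
        raise PadmaError(
            f"gene {table.gene}, feature {table.feature_ids[j]!r} has zero "
            "variance; apply the variance filter before standardizing"
        )
    params = StandardizationParams(center, scale)
    return params.apply(values), params


def first_eigenvalue(std_table: np.ndarray, ddof: int = 0) -> float:
    """Variance of the first principal component of a standardized table.

    Computed from the largest singular value s1 of the (already centered)
    table as ``s1**2 / (n - ddof)``.  This is the per-table MFA weight
    constant: redundant columns inflate it, complementary columns do not.
    """
    std_table = np.asarray(std_table, dtype=float)
    n = std_table.shape[0]
    if n - ddof < 2:
        raise PadmaError("first_eigenvalue requires at least 2 individuals")
    s1 = np.linalg.svd(std_table, compute_uv=False)[0]
    return float(s1**2 / (n - ddof))


@dataclass
class MFAModel:
    """A fitted multiple factor analysis of one assembled pathway.

    Attributes
    ----------
    eigenvalues
        Variances of the ``rank`` global components, descending.
    factor_scores
        n x L matrix of consensus coordinates f_{i,l}.
    partial_factor_scores
        n x L x p array; ``mean(axis=2)`` reproduces ``factor_scores``.
    loadings
        J x L orthonormal right singular vectors of X*; projection axes.
    weighted
        The centered, weighted, concatenated matrix X* (n x J).
    """

    assembled: AssembledPathway
    standardization: list[StandardizationParams]
    table_first_eigenvalue: np.ndarray
    weighted: np.ndarray
    singular_values: np.ndarray
    eigenvalues: np.ndarray
    factor_scores: np.ndarray
    partial_factor_scores: np.ndarray
    loadings: np.ndarray
    rank: int
    ddof: int = 0
    column_gene: list[str] = field(default_factory=list)
    column_feature: list[str] = field(default_factory=list)
    column_omic: list[str] = field(default_factory=list)
    block_slices: list[slice] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.factor_scores.shape[0]

    @property
    def p(self) -> int:
        return self.assembled.p

    @property
    def gene_names(self) -> list[str]:
        return self.assembled.gene_names

    @property
    def individual_ids(self) -> list[str]:
        return self.assembled.individual_ids


def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Deterministic orientation: largest-|loading| entry of each component > 0.
    for ell in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, ell])))
        if v[j, ell] < 0:
            v[:, ell] = -v[:, ell]
            u[:, ell] = -u[:, ell]
    return u, v


def fit_mfa(assembled: AssembledPathway, ddof: int = 0) -> MFAModel:
    """Fit the multiple factor analysis of an assembled pathway.

    Requires filtered, imputed tables with at least 3 individuals.  Raises
    on rank-0 input (all individuals identical after standardization is
    impossible here since columns have unit variance, but a degenerate
    all-zero concatenation is still guarded against).
    """
    if assembled.n < 3:
        raise PadmaError("MFA requires at least 3 individuals")
    blocks: list[np.ndarray] = []
    params: list[StandardizationParams] = []
    lambdas: list[float] = []
    col_gene: list[str] = []
    col_feature: list[str] = []
    col_omic: list[str] = []
    slices: list[slice] = []
    start = 0
    for t in assembled.tables:
        std, prm = standardize_table(t, ddof=ddof)
        lam = first_eigenvalue(std, ddof=ddof)
        blocks.append(std / np.sqrt(lam))
        params.append(prm)
        lambdas.append(lam)
        col_gene.extend([t.gene] * t.n_features)
        col_feature.extend(t.feature_ids)
        col_omic.extend(t.feature_omics)
        slices.append(slice(start, start + t.n_features))
        start += t.n_features

    weighted = np.concatenate(blocks, axis=1)
    u, s, vt = np.linalg.svd(weighted, full_matrices=False)
    rank = int(np.sum(s > s[0] * RANK_RTOL)) if s.size else 0
    if rank == 0:
        raise PadmaError("degenerate input: weighted matrix has rank 0")
    u, s, v = u[:, :rank], s[:rank], vt[:rank].T
    u, v = _fix_signs(u, v)

    n = assembled.n
    eigenvalues = s**2 / (n - ddof)
    factor_scores = u * s
    p = assembled.p
    partial = np.empty((n, rank, p))
    for g, sl in enumerate(slices):
        partial[:, :, g] = p * (weighted[:, sl] @ v[sl, :])

    return MFAModel(
        assembled=assembled,
        standardization=params,
        table_first_eigenvalue=np.asarray(lambdas),
        weighted=weighted,
        singular_values=s,
        eigenvalues=eigenvalues,
        factor_scores=factor_scores,
        partial_factor_scores=partial,
        loadings=v,
        rank=rank,
        ddof=ddof,
        column_gene=col_gene,
        column_feature=col_feature,
        column_omic=col_omic,
        block_slices=slices,
    )


def project_supplementary(
    model: MFAModel, new_tables: dict[str, np.ndarray] | list[GeneTable]
) -> np.ndarray:
    """Project supplementary individuals into a fitted consensus space.

    ``new_tables`` maps gene name to an m x j_g array whose columns follow
    the reference feature order for that gene (or is a list of
    :class:`~padma.pathway_assembly.GeneTable` with matching features).
    New individuals are centered and scaled with the *stored* reference
    parameters, weighted with the stored per-table eigenvalues, and
    multiplied by the stored loadings; the reference model is not refit.

    Returns an m x L factor-score matrix.
    """
    if isinstance(new_tables, list):
        supplied = {t.gene: t for t in new_tables}
        arrays: dict[str, np.ndarray] = {}
        for t0 in model.assembled.tables:
            t = supplied.get(t0.gene)
            if t is None:
                continue
            ref = list(zip(t0.feature_ids, t0.feature_omics))
            new = list(zip(t.feature_ids, t.feature_omics))
            if set(ref) - set(new):
                missing = sorted(set(ref) - set(new))
                raise PadmaError(
                    f"gene {t0.gene}: supplementary table lacks features {missing}"
                )
            order = [new.index(f) for f in ref]
            arrays[t0.gene] = t.values[:, order]
        new_tables = arrays
    missing_genes = [g for g in model.gene_names if g not in new_tables]
    if missing_genes:
        raise PadmaError(f"supplementary data lacks gene tables: {missing_genes}")

    blocks = []
    m = None
    for g, (t0, prm, lam) in enumerate(
        zip(model.assembled.tables, model.standardization, model.table_first_eigenvalue)
    ):
        arr = np.atleast_2d(np.asarray(new_tables[t0.gene], dtype=float))
        if arr.shape[1] != t0.n_features:
            raise PadmaError(
                f"gene {t0.gene}: expected {t0.n_features} features, "
                f"got {arr.shape[1]}"
            )
        if m is None:
            m = arr.shape[0]
        elif arr.shape[0] != m:
            raise PadmaError("supplementary tables disagree on individual count")
        blocks.append(prm.apply(arr) / np.sqrt(lam))
    return np.concatenate(blocks, axis=1) @ model.loadings


@dataclass
class InertiaDecomposition:
    """Percent-of-inertia decompositions of a fitted MFA.

    Per axis, contributions over omics (genes, individuals) each sum to
    100; ``axis_percent_variance`` sums to 100 over all retained axes.
    """

    axis_percent_variance: pd.Series
    omic_contribution: pd.DataFrame
    gene_contribution: pd.DataFrame
    individual_contribution: pd.DataFrame
    weighted_omic_contribution: pd.Series


def inertia_decomposition(
    model: MFAModel, omic_of: dict[str, str] | None = None
) -> InertiaDecomposition:
    """Decompose the total variance of a fitted MFA by axis, omic, gene
    and individual.

    The contribution of a variable to an axis is the squared loading (the
    share of that axis's inertia carried by the variable's partial
    projection); omic and gene contributions aggregate variables.  The
    per-individual contribution on axis l is f_{i,l}^2 over the axis's
    total squared score.  The eigenvalue-weighted overall omic
    contribution averages per-axis contributions with eigenvalue weights —
    the single-number summary of how much each omic shapes the consensus.

    ``omic_of`` optionally remaps column feature IDs to omic labels;
    by default the labels recorded at assembly are used.
    """
    axes = [f"axis{k+1}" for k in range(model.rank)]
    ev = model.eigenvalues
    axis_pct = pd.Series(100.0 * ev / ev.sum(), index=axes, name="percent_variance")

    v2 = model.loadings**2  # J x L, columns sum to 1
    if omic_of is not None:
        omics = [omic_of.get(f, o) for f, o in zip(model.column_feature, model.column_omic)]
    else:
        omics = model.column_omic
    omic_labels = sorted(set(omics))
    omic_ctr = pd.DataFrame(
        [100.0 * v2[[o == lbl for o in omics], :].sum(axis=0) for lbl in omic_labels],
        index=omic_labels,
        columns=axes,
    )
    gene_ctr = pd.DataFrame(
        [100.0 * v2[sl, :].sum(axis=0) for sl in model.block_slices],
        index=model.gene_names,
        columns=axes,
    )
    f2 = model.factor_scores**2
    ind_ctr = pd.DataFrame(
        100.0 * f2 / f2.sum(axis=0), index=model.individual_ids, columns=axes
    )
    weighted = pd.Series(
        (omic_ctr.to_numpy() * ev).sum(axis=1) / ev.sum(),
        index=omic_labels,
        name="weighted_percent_contribution",
    )
    return InertiaDecomposition(axis_pct, omic_ctr, gene_ctr, ind_ctr, weighted)
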