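"""Assembly of per-gene multi-omic data tables for one pathway.

For each gene in a pathway, measurements from the gene-indexed omics
(expression, promoter methylation, copy number) become columns of that
gene's table, and any miRNA predicted to target the gene contributes its
abundance profile as an additional column.  Tables share the same matched
individuals (rows, the intersection across omics) but may have different
column sets — a gene measured by a single assay is a one-column table.

Feature filtering and imputation follow the preprocessing the deviation
method assumes: columns missing for every individual or with raw variance
below a threshold are removed, and remaining missing cells are replaced by
the feature mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import (
    GENE_INDEXED_OMICS,
    MiRnaTargetMap,
    OmicMatrix,
    PadmaError,
    PathwayDefinition,
)

logger = logging.getLogger(__name__)


@dataclass
class GeneTable:
    """All omic measurements for one gene across matched individuals.

    ``values`` is individuals x features; ``feature_ids`` and
    ``feature_omics`` are parallel per-column annotations.
    """

    gene: str
    individual_ids: list[str]
    feature_ids: list[str]
    feature_omics: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, j = self.values.shape
        if n != len(self.individual_ids):
            raise PadmaError(f"gene {self.gene}: row count mismatch")
        if j != len(self.feature_ids) or j != len(self.feature_omics):
            raise PadmaError(f"gene {self.gene}: column annotation mismatch")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, keep: list[int]) -> "GeneTable":
        return GeneTable(
            self.gene,
            self.individual_ids,
            [self.feature_ids[k] for k in keep],
            [self.feature_omics[k] for k in keep],
            self.values[:, keep],
        )


@dataclass
class AssembledPathway:
    """The per-gene tables of one pathway over a shared individual order."""

    pathway: PathwayDefinition
    tables: list[GeneTable]
    individual_ids: list[str]
    dropped_genes: list[tuple[str, str]] = field(default_factory=list)
    dropped_features: list[tuple[str, str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.tables:
            if t.individual_ids != self.individual_ids:
                raise PadmaError(
                    f"gene {t.gene}: individual order differs from pathway order"
                )
        if not self.tables:
            raise PadmaError(
                f"pathway {self.pathway.name!r} has no genes with any omic data"
            )

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def p(self) -> int:
        return len(self.tables)

    @property
    def gene_names(self) -> list[str]:
        return [t.gene for t in self.tables]


def assemble_pathway(
    pathway: PathwayDefinition,
    omics: list[OmicMatrix],
    mti: MiRnaTargetMap | None = None,
) -> AssembledPathway:
    """Build one table per pathway gene from the omic matrices.

    Individuals are matched across omics by exact ID equality; the
    intersection (in the order of the first matrix) defines the shared row
    order.  A miRNA targeting several pathway genes appears as a column in
    each target's table.  Genes absent from every omic are dropped and
    recorded with a reason.
    """
    if not omics:
        raise PadmaError("at least one omic matrix is required")
    shared = [str(i) for i in omics[0].individual_ids]
    for om in omics[1:]:
        ids = set(om.individual_ids)
        shared = [i for i in shared if i in ids]
    if not shared:
        raise PadmaError("no individuals are shared across all omic matrices")
    n_excluded = sum(len(om.individual_ids) for om in omics) - len(shared) * len(omics)
    if n_excluded:
        logger.info(
            "restricting to %d matched individuals (%d unmatched entries excluded)",
            len(shared),
            n_excluded,
        )

    gene_indexed = [om for om in omics if om.omic in GENE_INDEXED_OMICS]
    mirna_mats = [om for om in omics if om.omic == "mirna"]

    tables: list[GeneTable] = []
    dropped: list[tuple[str, str]] = []
    for gene in pathway.genes:
        ids: list[str] = []
        labels: list[str] = []
        cols: list[np.ndarray] = []
        for om in gene_indexed:
            if gene in om.data.index:
                ids.append(gene)
                labels.append(om.omic)
                cols.append(om.data.loc[gene, shared].to_numpy(dtype=float))
        if mti is not None:
            for om in mirna_mats:
                for mirna in mti.mirnas_targeting(gene):
                    if mirna in om.data.index:
                        ids.append(mirna)
                        labels.append("mirna")
                        cols.append(om.data.loc[mirna, shared].to_numpy(dtype=float))
        if not cols:
            dropped.append((gene, "no data in any omic"))
            continue
        tables.append(GeneTable(gene, shared, ids, labels, np.column_stack(cols)))
    if not tables:
        raise PadmaError(
            f"pathway {pathway.name!r}: none of its {len(pathway)} genes "
            "have data in any omic"
        )
    return AssembledPathway(pathway, tables, shared, dropped)


def filter_features(
    assembled: AssembledPathway, var_threshold: float = 1e-5
) -> AssembledPathway:
    """Drop all-missing and near-constant feature columns.

    A column is removed when it is missing for every individual, or when
    the variance of its non-missing raw (unscaled) values — unbiased, n-1
    denominator — is strictly below ``var_threshold``.  Genes left with no
    columns are dropped and recorded.
    """
    tables: list[GeneTable] = []
    dropped_genes = list(assembled.dropped_genes)
    dropped_features = list(assembled.dropped_features)
    for t in assembled.tables:
        keep: list[int] = []
        for j in range(t.n_features):
            col = t.values[:, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                dropped_features.append(
                    (t.gene, t.feature_ids[j], t.feature_omics[j], "all missing")
                )
            elif obs.size < 2 or np.var(obs, ddof=1) < var_threshold:
                dropped_features.append(
                    (t.gene, t.feature_ids[j], t.feature_omics[j], "minimal variance")
                )
            else:
                keep.append(j)
        if keep:
            tables.append(t.select_columns(keep))
        else:
            dropped_genes.append((t.gene, "all features filtered"))
    if not tables:
        raise PadmaError(
            f"pathway {assembled.pathway.name!r}: every feature was filtered out"
        )
    return AssembledPathway(
        assembled.pathway,
        tables,
        assembled.individual_ids,
        dropped_genes,
        dropped_features,
    )


def impute_missing(assembled: AssembledPathway) -> AssembledPathway:
    """Mean-impute remaining missing cells, column by column.

    Requires :func:`filter_features` to have run first so that no column is
    entirely missing.  The imputed column keeps its pre-imputation mean.
    """
    tables: list[GeneTable] = []
    for t in assembled.tables:
        values = t.values.copy()
        for j in range(values.shape[1]):
            col = values[:, j]
            miss = np.isnan(col)
            if miss.all():
                raise PadmaError(
                    f"gene {t.gene}, feature {t.feature_ids[j]!r}: all values "
                    "missing; run filter_features before impute_missing"
                )
            if miss.any():
                col[miss] = col[~miss].mean()
        tables.append(replace(t, values=values))
    return AssembledPathway(
        assembled.pathway,
        tables,
        assembled.individual_ids,
        list(assembled.dropped_genes),
        list(assembled.dropped_features),
    )


def prepare_pathway(
    pathway: PathwayDefinition,
    omics: list[OmicMatrix],
    mti: MiRnaTargetMap | None = None,
    var_threshold: float = 1e-5,
) -> AssembledPathway:
    """Assemble, filter and impute in one call (the standard preprocessing)."""
    return impute_missing(filter_features(assemble_pathway(pathway, omics, mti), var_threshold))
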