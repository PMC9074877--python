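"""Readers and writers for the delimited formats the tool touches.

Covers GMT gene-set collections, feature-by-individual omic matrices,
miRTarBase-style miRNA-target interaction tables, and the per-pathway
deviation-score tables the pipeline emits.  All formats are plain
delimited text; delimiters are auto-detected from {tab, comma} unless
given explicitly, and readers are insensitive to OS line endings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .deviation_scores import DeviationResult

logger = logging.getLogger(__name__)

#: Recognised omic labels, in canonical display order.
OMIC_LABELS = ("expression", "methylation", "cna", "mirna")

#: Omics whose features are indexed by gene symbol (as opposed to miRNA ID).
GENE_INDEXED_OMICS = ("expression", "methylation", "cna")


class PadmaError(Exception):
    """Base class for errors raised by this package."""


class ParseError(PadmaError):
    """A file could not be parsed; the message locates the offending record."""


@dataclass(frozen=True)
class PathwayDefinition:
    """A named gene set, as read from one GMT line."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise PadmaError(f"pathway {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise PadmaError(f"pathway {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class OmicMatrix:
    """One omic's feature-by-individual measurements.

    Parameters
    ----------
    omic
        One of :data:`OMIC_LABELS`.
    data
        Features in rows, individuals in columns, float dtype.  NaN marks
        a missing measurement.
    """

    omic: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.omic not in OMIC_LABELS:
            raise PadmaError(
                f"unknown omic label {self.omic!r}; expected one of {OMIC_LABELS}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise PadmaError(f"duplicated feature IDs in {self.omic} matrix: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise PadmaError(f"duplicated individual IDs in {self.omic} matrix: {dups}")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.index]

    @property
    def individual_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class MiRnaTargetMap:
    """Retained miRNA-to-target-gene interaction pairs (exact-string IDs)."""

    pairs: frozenset[tuple[str, str]]
    support_type: str = "Functional MTI"

    def mirnas_targeting(self, gene: str) -> list[str]:
        """miRNA IDs predicted to target *gene*, sorted for determinism."""
        return sorted(m for m, g in self.pairs if g == gene)

    def __len__(self) -> int:
        return len(self.pairs)


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_gmt(path: str | Path) -> list[PathwayDefinition]:
    """Read a GMT file: one tab-delimited gene set per line.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Duplicate
    gene symbols within a line are collapsed (first occurrence kept) with a
    logged warning; duplicate pathway names across lines are an error.
    """
    path = Path(path)
    pathways: list[PathwayDefinition] = []
    seen: set[str] = set()
    with path.open("r", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "%s:%d: pathway %s contains duplicate gene symbols; collapsed",
                    path,
                    lineno,
                    name,
                )
            if not deduped:
                raise ParseError(f"{path}:{lineno}: pathway {name!r} lists no genes")
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            seen.add(name)
            pathways.append(PathwayDefinition(name, description, tuple(deduped)))
    return pathways


def write_gmt(pathways: Iterable[PathwayDefinition], path: str | Path) -> None:
    """Write pathway definitions in GMT format (inverse of :func:`read_gmt`)."""
    with Path(path).open("w") as fh:
        for pw in pathways:
            fh.write("\t".join([pw.name, pw.description, *pw.genes]) + "\n")


def read_omic_matrix(
    path: str | Path,
    omic: str,
    *,
    missing_token: str = "NA",
    delimiter: str | None = None,
) -> OmicMatrix:
    """Read a feature-by-individual matrix from delimited text.

    The header row holds individual IDs; the first column holds feature IDs.
    ``missing_token`` (and the empty string) map to missing values.  Any
    other non-numeric cell is a :class:`ParseError` that names its
    coordinates.
    """
    path = Path(path)
    with path.open("r", newline=None) as fh:
        header = fh.readline()
    if delimiter is None:
        delimiter = _sniff_delimiter(header.rstrip("\r\n"))
    df = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        na_values=[missing_token, ""],
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] == 0:
        logger.warning("%s: matrix has a header but no feature rows", path)
        return OmicMatrix(omic, df.astype(float))
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = rows[0], cols[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at feature "
            f"{df.index[r]!r}, individual {df.columns[c]!r}"
        )
    return OmicMatrix(omic, numeric)


def write_omic_matrix(
    matrix: OmicMatrix,
    path: str | Path,
    *,
    missing_token: str = "NA",
    delimiter: str = "\t",
) -> None:
    """Write an omic matrix in the dialect :func:`read_omic_matrix` reads."""
    matrix.data.to_csv(path, sep=delimiter, na_rep=missing_token, float_format="%.12g")


# Default miRTarBase-style column headers; matching is case-insensitive.
_MTI_COLUMNS = {
    "mirna": ("mirna",),
    "target": ("target gene", "target_gene", "target"),
    "support": ("support type", "support_type", "support"),
}


def read_mirna_target_table(
    path: str | Path,
    support_type: str = "Functional MTI",
    *,
    delimiter: str | None = None,
) -> MiRnaTargetMap:
    """Read a miRNA-target interaction table, keeping one support type.

    Only rows whose support-type field is *exactly* equal to
    ``support_type`` are retained (the curated-interaction filter);
    duplicate (miRNA, gene) pairs are collapsed.  IDs are matched as exact
    strings, with no version normalization.
    """
    path = Path(path)
    with path.open("r", newline=None) as fh:
        header = fh.readline().rstrip("\r\n")
    if delimiter is None:
        delimiter = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    lower = {c.lower().strip(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for key, aliases in _MTI_COLUMNS.items():
        for alias in aliases:
            if alias in lower:
                resolved[key] = lower[alias]
                break
        else:
            raise ParseError(
                f"{path}: missing required column for {key!r} "
                f"(accepted headers: {', '.join(aliases)})"
            )
    kept = df[df[resolved["support"]] == support_type]
    pairs = frozenset(
        (str(m), str(g))
        for m, g in zip(kept[resolved["mirna"]], kept[resolved["target"]])
    )
    return MiRnaTargetMap(pairs, support_type=support_type)


def deviation_frame(result: "DeviationResult") -> pd.DataFrame:
    """Tabulate a deviation result: one row per individual.

    Columns are the individual ID, pathway name, normalized deviation score,
    and one scaled per-gene contribution column per retained gene.
    """
    df = pd.DataFrame(
        {
            "individual_id": result.individual_ids,
            "pathway": result.pathway_name,
            "deviation_score": result.normalized_score,
        }
    )
    for g, gene in enumerate(result.gene_names):
        df[gene] = result.scaled_gene_contributions[:, g]
    return df


def write_deviation_table(
    result: "DeviationResult", path: str | Path, *, delimiter: str = "\t"
) -> None:
    """Write per-individual deviation scores and scaled gene contributions.

    The file round-trips through :func:`read_deviation_table` with no loss
    beyond the printed precision (12 significant digits).
    """
    deviation_frame(result).to_csv(
        path, sep=delimiter, index=False, float_format="%.12g"
    )


def read_deviation_table(
    path: str | Path, *, delimiter: str | None = None
) -> pd.DataFrame:
    """Read a table written by :func:`write_deviation_table`."""
    path = Path(path)
    with path.open("r", newline=None) as fh:
        header = fh.readline().rstrip("\r\n")
    if delimiter is None:
        delimiter = _sniff_delimiter(header)
    return pd.read_csv(path, sep=delimiter)
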