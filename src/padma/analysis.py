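"""Batch execution over pathway collections and score-based screening.

Runs the assemble -> filter -> impute -> MFA -> deviation pipeline over a
gene-set collection, tabulates normalized scores in long format, and
prioritizes pathways whose score distributions are heavily right-skewed
— the signature of a few strongly aberrant individuals against a quiet
background.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deviation_scores import DeviationResult, compute_deviation
from .io_formats import (
    MiRnaTargetMap,
    OmicMatrix,
    PadmaError,
    PathwayDefinition,
    write_deviation_table,
)
from .mfa_core import MFAModel, fit_mfa
from .pathway_assembly import prepare_pathway

logger = logging.getLogger(__name__)


def run_pathway(
    pathway: PathwayDefinition,
    omics: list[OmicMatrix],
    mti: MiRnaTargetMap | None = None,
    *,
    var_threshold: float = 1e-5,
    components: Sequence[int] | None = None,
    ddof: int = 0,
) -> tuple[MFAModel, DeviationResult]:
    """Full single-pathway pipeline: preprocessing, MFA, deviation scores."""
    assembled = prepare_pathway(pathway, omics, mti, var_threshold)
    model = fit_mfa(assembled, ddof=ddof)
    return model, compute_deviation(model, components)


@dataclass
class PathwayScoreTable:
    """Normalized deviation scores across a pathway collection.

    ``scores`` is long-format with one row per (pathway, individual);
    ``summary`` holds one row per pathway (skewness of its score
    distribution, genes retained, total features).
    """

    scores: pd.DataFrame
    summary: pd.DataFrame


def moment_skewness(values: Sequence[float]) -> float:
    """Pearson's moment coefficient of skewness g1 = m3 / m2^(3/2).

    Central moments use the n denominator (no bias correction).  Constant
    input, or fewer than 3 values, is an error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise PadmaError("skewness requires at least 3 values")
    if np.var(arr) == 0:
        raise PadmaError("skewness undefined for constant input")
    return float(stats.skew(arr, bias=True))


def rank_by_skewness(
    table: PathwayScoreTable | pd.DataFrame, top_fraction: float = 0.05
) -> pd.DataFrame:
    """Top pathways by descending skewness of their normalized scores.

    Returns ceil(top_fraction x N) pathways; ties are broken by pathway
    name so the subset is deterministic.  Skewness is scale-invariant, so
    the per-pathway gene-count normalization does not affect the ranking.
    """
    scores = table.scores if isinstance(table, PathwayScoreTable) else table
    if not 0.0 < top_fraction <= 1.0:
        raise PadmaError("top_fraction must be in (0, 1]")
    skew = (
        scores.groupby("pathway")["normalized_score"]
        .apply(lambda s: moment_skewness(s.to_numpy()))
        .rename("skewness")
        .reset_index()
    )
    skew = skew.sort_values(
        ["skewness", "pathway"], ascending=[False, True]
    ).reset_index(drop=True)
    k = math.ceil(top_fraction * len(skew))
    return skew.head(k)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_collection(
    pathways: list[PathwayDefinition],
    omics: list[OmicMatrix],
    mti: MiRnaTargetMap | None = None,
    *,
    var_threshold: float = 1e-5,
    components: Sequence[int] | None = None,
    ddof: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[PathwayScoreTable, dict[str, DeviationResult], dict]:
    """Score every pathway in a collection against the same cohort.

    Pathways that fail assembly (no measurable genes, everything
    filtered) are skipped with the reason logged and recorded in the run
    log; at least one pathway must succeed.  With ``out_dir`` set, writes
    one deviation table per pathway, the combined long-format score
    table, and a machine-readable run log.
    """
    config = {
        "var_threshold": var_threshold,
        "components": list(components) if components is not None else "all",
        "ddof": ddof,
        "n_pathways": len(pathways),
        "omics": sorted(om.omic for om in omics),
    }
    rows = []
    summaries = []
    results: dict[str, DeviationResult] = {}
    skipped: dict[str, str] = {}
    for pw in sorted(pathways, key=lambda p: p.name):
        try:
            model, result = run_pathway(
                pw,
                omics,
                mti,
                var_threshold=var_threshold,
                components=components,
                ddof=ddof,
            )
        except PadmaError as exc:
            skipped[pw.name] = str(exc)
            logger.warning("skipping pathway %s: %s", pw.name, exc)
            continue
        results[pw.name] = result
        for ind, score in zip(result.individual_ids, result.normalized_score):
            rows.append({"pathway": pw.name, "individual": ind, "normalized_score": score})
        summaries.append(
            {
                "pathway": pw.name,
                "n_genes_retained": result.p,
                "n_features": model.weighted.shape[1],
                "skewness": (
                    moment_skewness(result.normalized_score)
                    if np.var(result.normalized_score) > 0
                    else float("nan")
                ),
            }
        )
    if not results:
        raise PadmaError("no pathway in the collection could be scored")
    table = PathwayScoreTable(
        scores=pd.DataFrame(rows), summary=pd.DataFrame(summaries)
    )
    run_log = {
        "config": config,
        "config_hash": _config_hash(config),
        "n_scored": len(results),
        "skipped": skipped,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, result in results.items():
            write_deviation_table(result, out / f"{name}_deviation.tsv")
        table.scores.to_csv(out / "pathway_scores_long.tsv", sep="\t", index=False)
        table.summary.to_csv(out / "pathway_summary.tsv", sep="\t", index=False)
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return table, results, run_log
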