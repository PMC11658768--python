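"""Filtering, gene/cell-type aggregation, FDR control and helpers.

Per-cell scores X_1..X_k of one gene across the k cells of a cell-type
are independent but not identically distributed: each carries its own
exact null variance (a function of that cell's spot counts).  The
Lyapunov central limit theorem therefore gives the aggregate statistic

    z = sum_i X_i / sqrt(sum_i sigma_i^2)  ->  N(0, 1)

under the null of within-cell gene-label exchangeability.  Two-sided
p-values come from the standard normal CDF and are Benjamini-Hochberg
corrected per metric across all gene/cell-type pairs of a run (alpha
0.05 by default).  The effect size Y is the plain mean of the cell
scores; cells with sigma_i^2 = 0 (every spot is the gene of interest, or
a degenerate permutation null) carry no information about localization
and contribute to Y but not to z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geometry import Dataset

logger = logging.getLogger("spotloc")

__all__ = [
    "FilterConfig",
    "filter_dataset",
    "scores_to_frame",
    "aggregate_celltype",
    "aggregate_scores",
    "bh_correct",
    "classify_directionality",
    "correlate_with_covariate",
]


@dataclass
class FilterConfig:
    """Cell- and group-level filters applied before aggregation.

    Defaults: drop cells with fewer than 10 unique genes and/or fewer
    than 200 spots; drop gene/cell-type groups with fewer than 20 cells;
    the median-spot-count filter (>= 5 spots of the gene per cell at the
    median) is off by default and only applied when set.
    """

    min_unique_genes: int = 10
    min_total_spots: int = 200
    min_cells_per_group: int = 20
    min_median_spots: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("min_unique_genes", "min_total_spots", "min_cells_per_group"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def filter_dataset(ds: Dataset, cfg: FilterConfig = FilterConfig()) -> Tuple[Dataset, Dict[str, int]]:
    """Remove sparse cells (too few unique genes or total spots)."""
    kept, removed = [], 0
    for c in ds.cells:
        if c.n_spots < cfg.min_total_spots or len(c.unique_genes()) < cfg.min_unique_genes:
            removed += 1
        else:
            kept.append(c)
    if not kept:
        raise ValueError(
            "all cells removed by filtering; relax min_unique_genes/min_total_spots"
        )
    report = {"n_cells_in": ds.n_cells, "n_cells_removed": removed, "n_cells_kept": len(kept)}
    if removed:
        logger.info("filtered out %d of %d cells", removed, ds.n_cells)
    out = Dataset(
        cells=kept,
        gene_panel=set(ds.gene_panel),
        blank_codes=set(ds.blank_codes),
        name=ds.name,
    )
    return out, report


def scores_to_frame(scores: Iterable) -> pd.DataFrame:
    """Flatten CellScore records into a tidy per-cell score table."""
    rows = [
        {
            "cell_id": s.cell_id,
            "cell_type": s.cell_type,
            "gene": s.gene,
            "metric": s.metric,
            "m": s.m,
            "n": s.n,
            "score": s.score,
            "null_variance": s.null_variance,
            "exact_pvalue": s.exact_pvalue,
        }
        for s in scores
    ]
    cols = [
        "cell_id", "cell_type", "gene", "metric",
        "m", "n", "score", "null_variance", "exact_pvalue",
    ]
    return pd.DataFrame(rows, columns=cols)


def aggregate_celltype(
    scores: np.ndarray, variances: np.ndarray
) -> Tuple[float, float, float]:
    """Lyapunov-CLT aggregation of one gene/cell-type group.

    Returns (effect_size, z, p).  Cells with zero null variance are
    excluded from both CLT sums; if no variance remains the group is
    untestable and z, p are NaN.
    """
    scores = np.asarray(scores, dtype=float)
    variances = np.asarray(variances, dtype=float)
    effect = float(scores.mean())
    informative = variances > 0
    denom = float(variances[informative].sum())
    if denom == 0.0:
        return effect, float("nan"), float("nan")
    z = float(scores[informative].sum() / np.sqrt(denom))
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))
    return effect, z, p


def bh_correct(pvalues: Sequence[float], alpha: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (q_values, significant); NaN p-values propagate to NaN q and
    are never significant.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        rej, qv, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = qv
        sig[ok] = rej
    return q, sig


def aggregate_scores(
    cell_scores: pd.DataFrame,
    min_cells: int = 20,
    alpha: float = 0.05,
    min_median_spots: Optional[int] = None,
) -> pd.DataFrame:
    """Aggregate a per-cell score table into a gene/cell-type summary.

    One row per (gene, cell_type, metric): number of cells k, effect size
    (mean score), median score, z, p, BH q (corrected per metric across
    all gene/cell-type pairs of the run) and a significance flag at
    ``alpha``.  Groups with fewer than ``min_cells`` cells — and, if
    ``min_median_spots`` is set, groups whose median per-cell spot count
    of the gene is below it — are excluded.
    """
    required = {"cell_id", "cell_type", "gene", "metric", "score", "null_variance", "m"}
    if not required.issubset(cell_scores.columns):
        raise ValueError(f"cell score table must have columns {sorted(required)}")
    rows = []
    for (gene, cell_type, metric), grp in cell_scores.groupby(
        ["gene", "cell_type", "metric"], sort=True
    ):
        k = len(grp)
        if k < min_cells:
            continue
        if min_median_spots is not None and np.median(grp["m"]) < min_median_spots:
            continue
        effect, z, p = aggregate_celltype(
            grp["score"].to_numpy(), grp["null_variance"].to_numpy()
        )
        rows.append(
            {
                "gene": gene,
                "cell_type": cell_type,
                "metric": metric,
                "k": k,
                "effect_size": effect,
                "median_score": float(grp["score"].median()),
                "z": z,
                "p": p,
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=["gene", "cell_type", "metric", "k", "effect_size", "median_score", "z", "p"],
    )
    summary["q"] = np.nan
    summary["significant"] = False
    for metric in summary["metric"].unique():
        mask = summary["metric"] == metric
        q, sig = bh_correct(summary.loc[mask, "p"].to_numpy(), alpha=alpha)
        summary.loc[mask, "q"] = q
        summary.loc[mask, "significant"] = sig
    return summary


def classify_directionality(summary: pd.DataFrame) -> pd.DataFrame:
    """Classify each gene/metric by the pattern of its cell-type calls.

    opposite            significantly positive in one cell-type and
                        significantly negative in another;
    cell_type_dependent significant somewhere, insignificant elsewhere
                        (and not opposite);
    uniform             significant in every scored cell-type, same sign;
    none                no significant cell-type (also returned when only
                        one cell-type was scored).
    """
    rows = []
    for (gene, metric), grp in summary.groupby(["gene", "metric"], sort=True):
        sig = grp["significant"].to_numpy(dtype=bool)
        eff = grp["effect_size"].to_numpy(dtype=float)
        if len(grp) < 2 or not sig.any():
            cls = "none"
        elif (sig & (eff > 0)).any() and (sig & (eff < 0)).any():
            cls = "opposite"
        elif (~sig).any():
            cls = "cell_type_dependent"
        else:
            cls = "uniform"
        rows.append(
            {"gene": gene, "metric": metric, "n_celltypes": len(grp), "directionality": cls}
        )
    return pd.DataFrame(rows, columns=["gene", "metric", "n_celltypes", "directionality"])


def correlate_with_covariate(
    summary: pd.DataFrame,
    covariate: pd.DataFrame,
    value_col: str = "median_score",
    alpha: float = 0.05,
    min_celltypes: int = 3,
) -> pd.DataFrame:
    """Pearson-correlate per-cell-type scores against a per-cell-type covariate.

    ``covariate`` has columns (gene, cell_type, value) — e.g. a per-type
    3' UTR length proxy.  For every gene/metric pair with at least
    ``min_celltypes`` matched cell-types, the score column is correlated
    against the covariate; p-values come from the standard correlation
    test and are BH-corrected across all gene/metric pairs tested.
    Constant covariates (undefined r) are skipped.
    """
    need = {"gene", "cell_type", "value"}
    if not need.issubset(covariate.columns):
        raise ValueError("covariate table must have columns gene, cell_type, value")
    rows = []
    for (gene, metric), grp in summary.groupby(["gene", "metric"], sort=True):
        cov = covariate[covariate["gene"] == gene]
        merged = grp.merge(cov, on="cell_type", how="inner")
        if len(merged) < min_celltypes:
            continue
        x = merged[value_col].to_numpy(dtype=float)
        y = merged["value"].to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            logger.warning("constant values for %s/%s; correlation skipped", gene, metric)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(
            {"gene": gene, "metric": metric, "n_celltypes": len(merged),
             "r": float(r), "p": float(p)}
        )
    out = pd.DataFrame(rows, columns=["gene", "metric", "n_celltypes", "r", "p"])
    if len(out):
        q, sig = bh_correct(out["p"].to_numpy(), alpha=alpha)
        out["q"] = q
        out["significant"] = sig
    else:
        out["q"] = []
        out["significant"] = []
    return out
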