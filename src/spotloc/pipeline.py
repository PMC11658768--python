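"""End-to-end scoring: filters -> per-cell scores -> gene/cell-type summary."""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd

from .aggregate import FilterConfig, aggregate_scores, filter_dataset, scores_to_frame
from .geometry import Dataset
from .permutation import (
    DEFAULT_PAIR_DRAWS,
    DEFAULT_PERMUTATIONS,
    PERMUTATION_METRICS,
    score_cell_permutation_metric,
)
from .ranks import RANK_METRICS, score_cell_rank_metric

logger = logging.getLogger("spotloc")

ALL_METRICS = RANK_METRICS + PERMUTATION_METRICS

__all__ = ["ALL_METRICS", "score_dataset", "run"]


def score_dataset(
    ds: Dataset,
    metrics: Sequence[str] = ALL_METRICS,
    seed: int = 0,
    permutations: int = DEFAULT_PERMUTATIONS,
    pair_draws: int = DEFAULT_PAIR_DRAWS,
    min_spots_punctate: int = 2,
    min_spots_radial: int = 3,
    filter_config: Optional[FilterConfig] = FilterConfig(),
) -> pd.DataFrame:
    """Per-cell scores for every requested metric, as a tidy table.

    Cell-level filters are applied first (pass ``filter_config=None`` to
    score unfiltered data).  The seed drives both rank tie-breaking and
    the permutation nulls; per-cell streams are derived from
    (seed, cell_id) so results do not depend on cell order.
    """
    for metric in metrics:
        if metric not in ALL_METRICS:
            raise ValueError(f"unknown metric {metric!r}; choose from {ALL_METRICS}")
    if filter_config is not None:
        ds, _ = filter_dataset(ds, filter_config)
    all_scores = []
    for cell in ds.cells:
        for metric in metrics:
            if metric in RANK_METRICS:
                all_scores.extend(score_cell_rank_metric(cell, metric, tie_seed=seed))
            else:
                min_spots = min_spots_punctate if metric == "punctate" else min_spots_radial
                all_scores.extend(
                    score_cell_permutation_metric(
                        cell, metric, B=permutations, P=pair_draws,
                        seed=seed, min_spots=min_spots,
                    )
                )
    return scores_to_frame(all_scores)


def run(
    ds: Dataset,
    metrics: Sequence[str] = ALL_METRICS,
    seed: int = 0,
    alpha: float = 0.05,
    permutations: int = DEFAULT_PERMUTATIONS,
    pair_draws: int = DEFAULT_PAIR_DRAWS,
    filter_config: Optional[FilterConfig] = FilterConfig(),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Score a dataset and aggregate to gene/cell-type summaries.

    Returns (per-cell score table, gene/cell-type summary with BH q and
    significance flags at ``alpha``).
    """
    cfg = filter_config if filter_config is not None else FilterConfig(0, 0, 0)
    cell_scores = score_dataset(
        ds, metrics=metrics, seed=seed,
        permutations=permutations, pair_draws=pair_draws,
        filter_config=filter_config,
    )
    summary = aggregate_scores(
        cell_scores,
        min_cells=cfg.min_cells_per_group,
        alpha=alpha,
        min_median_spots=cfg.min_median_spots,
    )
    return cell_scores, summary
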