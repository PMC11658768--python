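"""Punctate and radial per-cell scores via gene-label permutation nulls.

The punctate statistic for a gene with m spots in a cell is the mean
Euclidean distance over P randomly drawn pairs of its spots (z dropped,
i.e. all slices projected onto one plane).  The radial statistic is the
mean over P pairs of the angle the two spots subtend at the cell's
vertex-mean boundary centroid (the whole-cell mean centroid for
multi-slice cells), each angle in [0, pi].

The null is built by B within-cell gene-label permutations: labels are
shuffled across the cell's spots (one shared shuffle per iteration serves
all genes of the cell), the statistic is re-evaluated with fresh pair
draws, and the observed statistic is placed on the resulting empirical
distribution.  The mid-rank quantile q = (r + 0.5)/(B + 1), with
r = #{null means <= observed}, maps to the score

    X = 1 - 2 q,

so spots closer together (smaller distance / smaller angle) than the
null give positive scores.  Under the null r is uniform on {0..B}, hence
E[X] = 0 and Var[X] = B(B+2) / (3 (B+1)^2)  (~1/3 for large B), which is
the per-cell variance the CLT aggregation consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._util import derive_rng
from .geometry import Cell, boundary_centroid
from .ranks import CellScore

logger = logging.getLogger("spotloc")

__all__ = [
    "PermutationNull",
    "mean_pair_distance",
    "mean_pair_angle",
    "permutation_null",
    "quantile_score",
    "quantile_null_variance",
    "score_cell_permutation_metric",
]

PERMUTATION_METRICS = ("punctate", "radial")
DEFAULT_PERMUTATIONS = 1000
DEFAULT_PAIR_DRAWS = 10
MIN_SPOTS_PUNCTATE = 2
MIN_SPOTS_RADIAL = 3


@dataclass
class PermutationNull:
    """Observed statistic plus its permutation null for one gene/cell."""

    statistic: str  # "distance" or "angle"
    observed_mean: float
    null_means: np.ndarray  # (B,)
    B: int
    P: int
    degenerate: bool = False


def _pair_indices(m: int, shape, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform unordered pairs of distinct indices in 0..m-1, with replacement
    across draws (for m = 2 every draw is the single existing pair)."""
    i = rng.integers(0, m, size=shape)
    j = rng.integers(0, m - 1, size=shape)
    j = np.where(j >= i, j + 1, j)
    return i, j


def mean_pair_distance(xy: np.ndarray, P: int, rng: np.random.Generator) -> float:
    """Mean 2D Euclidean distance over P random spot pairs of one gene."""
    xy = np.asarray(xy, dtype=float)
    m = len(xy)
    if m < 2:
        raise ValueError("mean pair distance needs at least 2 spots")
    i, j = _pair_indices(m, P, rng)
    return float(np.mean(np.linalg.norm(xy[i] - xy[j], axis=-1)))


def _angles(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle in [0, pi] between direction vectors about the centroid."""
    dot = np.sum(v1 * v2, axis=-1)
    norm = np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    return np.arccos(np.clip(dot / norm, -1.0, 1.0))


def mean_pair_angle(
    xy: np.ndarray, centroid: np.ndarray, P: int, rng: np.random.Generator
) -> float:
    """Mean angle (radians, [0, pi]) subtended at the centroid by P spot pairs.

    Spots exactly at the centroid have no direction and are excluded;
    if fewer than 2 usable spots remain a ValueError is raised (the
    caller skips the gene with a warning).
    """
    xy = np.asarray(xy, dtype=float)
    v = xy - np.asarray(centroid, dtype=float)
    usable = np.linalg.norm(v, axis=1) > 0
    if not usable.all():
        v = v[usable]
    if len(v) < 2:
        raise ValueError("mean pair angle needs >= 2 spots away from the centroid")
    i, j = _pair_indices(len(v), P, rng)
    return float(np.mean(_angles(v[i], v[j])))


def quantile_null_variance(B: int) -> float:
    """Exact variance of X = 1 - 2(r+0.5)/(B+1) for r uniform on {0..B}."""
    B = int(B)
    return B * (B + 2) / (3.0 * (B + 1) ** 2)


def quantile_score(null: PermutationNull) -> Tuple[float, float]:
    """Map an observed statistic onto its permutation null.

    Returns (score, null_variance).  Degenerate nulls (label permutation
    is the identity, or every permuted mean equals the observed mean)
    score 0 with variance 0 so they carry no weight in the aggregation z
    while remaining real observations of score 0.
    """
    nm = np.asarray(null.null_means, dtype=float)
    B = len(nm)
    if null.degenerate or bool(np.all(nm == null.observed_mean)):
        return 0.0, 0.0
    r = int(np.count_nonzero(nm <= null.observed_mean))
    q = (r + 0.5) / (B + 1.0)
    return 1.0 - 2.0 * q, quantile_null_variance(B)


def _label_permutations(n: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """B independent uniform permutations of 0..n-1 (one per null iteration)."""
    return np.argsort(rng.random((B, n)), axis=1)


def permutation_null(
    cell: Cell,
    gene: str,
    statistic: str = "distance",
    B: int = DEFAULT_PERMUTATIONS,
    P: int = DEFAULT_PAIR_DRAWS,
    seed: int = 0,
) -> PermutationNull:
    """Build the permutation null for one gene of one cell.

    Convenience wrapper over the shared-shuffle machinery used by
    :func:`score_cell_permutation_metric`; a standalone call derives its
    own per-cell RNG from (seed, cell_id, statistic).
    """
    if statistic not in ("distance", "angle"):
        raise ValueError("statistic must be 'distance' or 'angle'")
    rng = derive_rng(seed, cell.cell_id, statistic)
    genes = cell.spot_genes.astype(str)
    pos = np.flatnonzero(genes == gene)
    if len(pos) < 2:
        raise ValueError(f"gene {gene!r} has fewer than 2 spots in cell {cell.cell_id!r}")
    xy = cell.spot_xy
    centroid = boundary_centroid(cell)
    obs = _observed_stat(xy[pos], centroid, statistic, P, rng)
    degenerate = len(np.unique(genes)) < 2
    perms = _label_permutations(len(genes), B, rng)
    null_means = _null_means(xy, centroid, perms[:, pos], statistic, P, rng)
    return PermutationNull(
        statistic=statistic,
        observed_mean=obs,
        null_means=null_means,
        B=B,
        P=P,
        degenerate=degenerate,
    )


def _observed_stat(
    gene_xy: np.ndarray, centroid: np.ndarray, statistic: str, P: int, rng
) -> float:
    if statistic == "distance":
        return mean_pair_distance(gene_xy, P, rng)
    return mean_pair_angle(gene_xy, centroid, P, rng)


def _null_means(
    xy: np.ndarray,
    centroid: np.ndarray,
    idx: np.ndarray,  # (B, m) spot indices the gene occupies per permutation
    statistic: str,
    P: int,
    rng: np.random.Generator,
) -> np.ndarray:
    B, m = idx.shape
    i, j = _pair_indices(m, (B, P), rng)
    rows = np.arange(B)[:, None]
    a = xy[idx[rows, i]]
    b = xy[idx[rows, j]]
    if statistic == "distance":
        vals = np.linalg.norm(a - b, axis=-1)
    else:
        vals = _angles(a - centroid, b - centroid)
    return vals.mean(axis=1)


def score_cell_permutation_metric(
    cell: Cell,
    metric: str = "punctate",
    B: int = DEFAULT_PERMUTATIONS,
    P: int = DEFAULT_PAIR_DRAWS,
    seed: int = 0,
    min_spots: Optional[int] = None,
) -> List[CellScore]:
    """Score every eligible gene of one cell with a permutation metric.

    Spots of single-spot genes are removed up front (they carry no
    pairwise information) and the remaining spots are scored.  Genes with
    fewer than ``min_spots`` spots (default 2 punctate, 3 radial) are not
    scored but their spots still participate in the label permutations.
    One label shuffle per iteration is shared by all genes of the cell.
    """
    if metric not in PERMUTATION_METRICS:
        raise ValueError(f"metric must be one of {PERMUTATION_METRICS}")
    statistic = "distance" if metric == "punctate" else "angle"
    if min_spots is None:
        min_spots = MIN_SPOTS_PUNCTATE if metric == "punctate" else MIN_SPOTS_RADIAL
    genes_all = cell.spot_genes.astype(str)
    uniq, counts = np.unique(genes_all, return_counts=True)
    multi = set(uniq[counts >= 2])
    keep = np.isin(genes_all, list(multi))
    xy = cell.spot_xy[keep]
    genes = genes_all[keep]
    n = len(genes)
    centroid = boundary_centroid(cell)
    if statistic == "angle":
        off = np.linalg.norm(xy - centroid, axis=1) > 0
        if not off.all():
            logger.warning(
                "cell %s: %d spot(s) exactly at the centroid excluded from the radial metric",
                cell.cell_id,
                int((~off).sum()),
            )
            xy, genes = xy[off], genes[off]
            n = len(genes)
    uniq, counts = np.unique(genes, return_counts=True)
    eligible = [(g, c) for g, c in zip(uniq, counts) if c >= max(min_spots, 2)]
    if not eligible:
        return []
    rng = derive_rng(seed, cell.cell_id, metric)
    degenerate = len(uniq) < 2
    observed = {
        g: _observed_stat(xy[genes == g], centroid, statistic, P, rng)
        for g, _ in eligible
    }
    perms = _label_permutations(n, B, rng)
    scores = []
    for g, m in eligible:
        pos = np.flatnonzero(genes == g)
        null_means = _null_means(xy, centroid, perms[:, pos], statistic, P, rng)
        null = PermutationNull(
            statistic=statistic,
            observed_mean=observed[g],
            null_means=null_means,
            B=B,
            P=P,
            degenerate=degenerate,
        )
        x, var = quantile_score(null)
        scores.append(
            CellScore(
                cell_id=cell.cell_id,
                cell_type=cell.cell_type,
                gene=str(g),
                metric=metric,
                m=int(m),
                n=n,
                score=x,
                null_variance=var,
                exact_pvalue=None,
            )
        )
    return scores
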