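"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths:
distances use a hand-written point-to-segment routine, PMFs come from
exhaustive enumeration of rank subsets, and containment uses a ray-cast
point-in-polygon test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
import pytest

from spotloc import Cell, SimulationConfig, generate_dataset

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def unit_square_cell():
    """Factory: a one-slice unit-square cell with the given spots."""

    def make(spot_xy, genes=None, cell_id="cell0", cell_type="typeA"):
        spot_xy = np.asarray(spot_xy, dtype=float)
        n = len(spot_xy)
        if genes is None:
            genes = ["geneA"] * n
        return Cell(
            cell_id,
            cell_type,
            rings={0: UNIT_SQUARE},
            spot_xy=spot_xy,
            spot_z=np.zeros(n, dtype=int),
            spot_genes=np.asarray(genes, dtype=object),
        )

    return make


@pytest.fixture(scope="session")
def uniform_dataset():
    """Small all-null dataset shared by read-only tests."""
    cfg = SimulationConfig(n_cells=40, n_celltypes=2, n_genes=12,
                           spots_per_cell=250.0, seed=42)
    ds, truth = generate_dataset(cfg)
    return ds, truth


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def point_segment_distance(p, a, b) -> float:
    """Plain point-to-segment Euclidean distance."""
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def boundary_distance_oracle(p, vertices) -> float:
    """Min distance from a point to a closed polygon boundary."""
    vertices = np.asarray(vertices, dtype=float)
    return min(
        point_segment_distance(p, vertices[i], vertices[(i + 1) % len(vertices)])
        for i in range(len(vertices))
    )


def point_in_polygon_oracle(p, vertices) -> bool:
    """Ray-cast containment test, boundary-inclusive."""
    vertices = np.asarray(vertices, dtype=float)
    if boundary_distance_oracle(p, vertices) < 1e-12:
        return True
    x, y = p
    inside = False
    n = len(vertices)
    for i in range(n):
        (x1, y1), (x2, y2) = vertices[i], vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xcross:
                inside = not inside
    return inside


def median_rank_pmf_enumeration(n: int, m: int):
    """Exhaustive PMF over all C(n, m) rank subsets, exact rationals."""
    total = 0
    tally = {}
    for subset in itertools.combinations(range(1, n + 1), m):
        k = len(subset)
        if k % 2 == 1:
            t = Fraction(subset[k // 2])
        else:
            t = Fraction(subset[k // 2 - 1] + subset[k // 2], 2)
        tally[t] = tally.get(t, 0) + 1
        total += 1
    return {t: Fraction(c, total) for t, c in tally.items()}
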