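"""Synthetic multiplexed-FISH datasets with known ground truth.

Emulates the essential structure of MERFISH/SeqFISH-style single-cell
spot data: convex (regular-polygon) cell boundaries in micron
coordinates, negative-binomial per-cell spot counts, multinomial gene
assignment, and spot placement that is either uniform inside the cell
(the null) or biased by one of four planted pattern types matching the
metrics:

* ``peripheral``  — uniform draws restricted to boundary distances below
  the rho-quantile of the uniform boundary-distance distribution;
* ``central``     — the complementary restriction (boundary distance
  above the (1 - rho)-quantile), i.e. the innermost uniform mass;
* ``punctate``    — isotropic Gaussian (spread s, microns) around a
  uniformly placed focus, truncated to the cell;
* ``radial``      — uniform draws restricted to an angular sector of
  width w about the vertex-mean centroid.

All samplers are restrictions/truncations of the uniform law, so each
pattern has an exact neutral limit that reduces to uniform placement:
rho = 1, w = 2*pi, or s -> infinity.  The within-cell gene-label
permutation used as the negative control preserves all geometry and
per-gene counts while destroying any spatial pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from ._util import derive_rng
from .geometry import Cell, Dataset, boundary_distances, ring_centroid

__all__ = [
    "SimulationConfig",
    "sample_uniform_in_polygon",
    "sample_pattern",
    "generate_dataset",
    "permute_gene_labels",
]

PATTERNS = ("null", "peripheral", "central", "punctate", "radial")


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic dataset.

    ``patterns`` maps gene name -> (pattern, strength); genes not listed
    are null (uniform placement).  Strengths: retained uniform mass
    rho in (0, 1] for peripheral/central, Gaussian spread s > 0 microns
    for punctate, sector width w in (0, 2*pi] for radial.
    ``pattern_celltypes`` optionally restricts a gene's pattern to a
    subset of cell-types (it is null elsewhere).
    """

    n_cells: int = 100
    n_celltypes: int = 2
    n_genes: int = 20
    gene_names: Optional[Sequence[str]] = None
    gene_weights: Optional[Sequence[float]] = None
    spots_per_cell: float = 300.0
    spots_dispersion: float = 50.0
    n_vertices: int = 12
    radius_range: Tuple[float, float] = (8.0, 12.0)
    z_slices: int = 1
    patterns: Mapping[str, Tuple[str, float]] = field(default_factory=dict)
    pattern_celltypes: Optional[Mapping[str, Sequence[str]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_names is None:
            width = max(2, len(str(self.n_genes - 1)))
            self.gene_names = [f"g{str(i).zfill(width)}" for i in range(self.n_genes)]
        self.gene_names = list(self.gene_names)
        self.n_genes = len(self.gene_names)
        if self.gene_weights is None:
            self.gene_weights = [1.0 / self.n_genes] * self.n_genes
        w = np.asarray(self.gene_weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("gene weights must be positive")
        self.gene_weights = (w / w.sum()).tolist()
        for gene, (pattern, strength) in self.patterns.items():
            if gene not in self.gene_names:
                raise ValueError(f"pattern assigned to unknown gene {gene!r}")
            _check_strength(pattern, strength)
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must be 0 < lo <= hi")
        if self.n_vertices < 3 or self.z_slices < 1 or self.n_cells < 1:
            raise ValueError("need n_vertices >= 3, z_slices >= 1, n_cells >= 1")

    def celltype_names(self) -> List[str]:
        return [f"type{chr(ord('A') + i)}" for i in range(self.n_celltypes)]


def _check_strength(pattern: str, strength: float) -> None:
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {PATTERNS}")
    if pattern in ("peripheral", "central") and not (0.0 < strength <= 1.0):
        raise ValueError("peripheral/central strength rho must be in (0, 1]")
    if pattern == "punctate" and not strength > 0.0:
        raise ValueError("punctate spread s must be > 0")
    if pattern == "radial" and not (0.0 < strength <= 2.0 * math.pi + 1e-12):
        raise ValueError("radial sector width w must be in (0, 2*pi]")


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

_MAX_BATCHES = 200


def _rejection_sample(count, propose, accept) -> np.ndarray:
    """Draw ``count`` points from ``propose`` batches passing ``accept``."""
    if count == 0:
        return np.zeros((0, 2), dtype=float)
    out: List[np.ndarray] = []
    got, proposed = 0, 0
    for _ in range(_MAX_BATCHES):
        cand = propose(max(4 * count, 256))
        ok = accept(cand)
        pts = cand[ok]
        out.append(pts)
        got += len(pts)
        proposed += len(cand)
        if got >= count:
            return np.concatenate(out)[:count]
        if proposed >= 25_600 and got < 0.01 * proposed:
            break
    raise RuntimeError(
        f"rejection sampling acceptance rate below 1% ({got}/{proposed}); "
        "pathological region"
    )


def sample_uniform_in_polygon(
    ring_vertices: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside a polygon via bounding-box rejection sampling."""
    verts = np.asarray(ring_vertices, dtype=float)
    poly = Polygon(verts)
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)

    def propose(k: int) -> np.ndarray:
        return rng.uniform(lo, hi, size=(k, 2))

    def accept(pts: np.ndarray) -> np.ndarray:
        return shapely.covers(poly, shapely.points(pts))

    return _rejection_sample(count, propose, accept)


_CALIBRATION_DRAWS = 2000


def sample_pattern(
    ring_vertices: np.ndarray,
    count: int,
    pattern: str,
    strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``count`` spots inside the ring under a planted pattern."""
    _check_strength(pattern if pattern != "null" else "peripheral", 1.0 if pattern == "null" else strength)
    verts = np.asarray(ring_vertices, dtype=float)
    if pattern == "null":
        return sample_uniform_in_polygon(verts, count, rng)
    if count == 0:
        return np.zeros((0, 2), dtype=float)
    poly = Polygon(verts)

    if pattern in ("peripheral", "central"):
        rho = float(strength)
        if rho >= 1.0:
            return sample_uniform_in_polygon(verts, count, rng)
        calib = sample_uniform_in_polygon(verts, _CALIBRATION_DRAWS, rng)
        d = boundary_distances(calib, verts)
        if pattern == "peripheral":
            thr = np.quantile(d, rho)

            def keep(pts):
                return boundary_distances(pts, verts) <= thr

        else:
            thr = np.quantile(d, 1.0 - rho)

            def keep(pts):
                return boundary_distances(pts, verts) >= thr

        def propose(k: int) -> np.ndarray:
            return sample_uniform_in_polygon(verts, k, rng)

        return _rejection_sample(count, propose, keep)

    if pattern == "punctate":
        s = float(strength)
        focus = sample_uniform_in_polygon(verts, 1, rng)[0]
        if 2.0 * math.pi * s * s <= poly.area:
            # tight focus: propose from the Gaussian, keep in-polygon points
            def propose(k: int) -> np.ndarray:
                return focus + rng.normal(scale=s, size=(k, 2))

            def accept(pts: np.ndarray) -> np.ndarray:
                return shapely.covers(poly, shapely.points(pts))

        else:
            # wide focus: propose uniform, thin by the Gaussian density
            # ratio (max density inside the polygon is at the focus);
            # exact truncated-Gaussian law, tends to uniform as s grows
            def propose(k: int) -> np.ndarray:
                return sample_uniform_in_polygon(verts, k, rng)

            def accept(pts: np.ndarray) -> np.ndarray:
                d2 = np.sum((pts - focus) ** 2, axis=1)
                return rng.random(len(pts)) < np.exp(-d2 / (2.0 * s * s))

        return _rejection_sample(count, propose, accept)

    # radial: uniform restricted to a sector of width w about the centroid
    w = float(strength)
    if w >= 2.0 * math.pi:
        return sample_uniform_in_polygon(verts, count, rng)
    c = ring_centroid(verts)
    phi0 = rng.uniform(0.0, 2.0 * math.pi)

    def propose(k: int) -> np.ndarray:
        return sample_uniform_in_polygon(verts, k, rng)

    def keep(pts: np.ndarray) -> np.ndarray:
        ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
        return ((ang - phi0) % (2.0 * math.pi)) < w

    return _rejection_sample(count, propose, keep)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def _regular_polygon(center: np.ndarray, radius: float, V: int, rotation: float) -> np.ndarray:
    theta = rotation + 2.0 * math.pi * np.arange(V) / V
    return center + radius * np.column_stack([np.cos(theta), np.sin(theta)])


def generate_dataset(cfg: SimulationConfig) -> Tuple[Dataset, pd.DataFrame]:
    """Generate a synthetic dataset and its ground-truth pattern table.

    Cells are regular polygons laid out on a disjoint grid, cell-types
    assigned round-robin.  Per cell, the spot count is negative-binomial
    (mean ``spots_per_cell``, dispersion ``spots_dispersion``), gene
    identities are multinomial by weight, and each gene's positions are
    drawn from its pattern sampler (uniform for null genes).  Fully
    deterministic given ``cfg.seed``.
    """
    types = cfg.celltype_names()
    weights = np.asarray(cfg.gene_weights, dtype=float)
    genes = np.asarray(cfg.gene_names, dtype=object)
    r_hi = cfg.radius_range[1]
    spacing = 2.0 * r_hi + 4.0
    ncols = int(math.ceil(math.sqrt(cfg.n_cells)))
    cells: List[Cell] = []
    for i in range(cfg.n_cells):
        cell_id = f"c{i:05d}"
        cell_type = types[i % cfg.n_celltypes]
        rng = derive_rng(cfg.seed, "cell", cell_id)
        center = np.array([(i % ncols) * spacing, (i // ncols) * spacing])
        rings = {}
        for z in range(cfg.z_slices):
            radius = rng.uniform(*cfg.radius_range)
            rings[z] = _regular_polygon(
                center, radius, cfg.n_vertices, rng.uniform(0.0, 2.0 * math.pi)
            )
        p_nb = cfg.spots_dispersion / (cfg.spots_dispersion + cfg.spots_per_cell)
        total = int(rng.negative_binomial(cfg.spots_dispersion, p_nb))
        gene_counts = rng.multinomial(total, weights)
        xy_parts, z_parts, g_parts = [], [], []
        for g, cnt in zip(genes, gene_counts):
            if cnt == 0:
                continue
            pattern, strength = cfg.patterns.get(str(g), ("null", 1.0))
            if cfg.pattern_celltypes is not None:
                allowed = cfg.pattern_celltypes.get(str(g))
                if allowed is not None and cell_type not in allowed:
                    pattern, strength = "null", 1.0
            per_z = rng.multinomial(cnt, np.full(cfg.z_slices, 1.0 / cfg.z_slices))
            for z, cz in enumerate(per_z):
                if cz == 0:
                    continue
                pts = sample_pattern(rings[z], int(cz), pattern, strength, rng)
                xy_parts.append(pts)
                z_parts.append(np.full(int(cz), z, dtype=int))
                g_parts.append(np.full(int(cz), g, dtype=object))
        if xy_parts:
            xy = np.concatenate(xy_parts)
            zz = np.concatenate(z_parts)
            gg = np.concatenate(g_parts)
            order = rng.permutation(len(xy))
            xy, zz, gg = xy[order], zz[order], gg[order]
        else:
            xy = np.zeros((0, 2))
            zz = np.zeros(0, dtype=int)
            gg = np.zeros(0, dtype=object)
        cells.append(
            Cell(cell_id, cell_type, rings, spot_xy=xy, spot_z=zz, spot_genes=gg)
        )
    ds = Dataset(cells=cells, gene_panel=set(map(str, genes)), name="synthetic")
    truth_rows = []
    for g in genes:
        pattern, strength = cfg.patterns.get(str(g), ("null", 1.0))
        for ct in types:
            p, s = pattern, strength
            if cfg.pattern_celltypes is not None:
                allowed = cfg.pattern_celltypes.get(str(g))
                if allowed is not None and ct not in allowed:
                    p, s = "null", 1.0
            truth_rows.append({"gene": str(g), "cell_type": ct, "pattern": p, "strength": s})
    truth = pd.DataFrame(truth_rows, columns=["gene", "cell_type", "pattern", "strength"])
    return ds, truth


def permute_gene_labels(ds: Dataset, seed: int = 0) -> Dataset:
    """Within-cell gene-label permutation (the negative control).

    Per cell, gene labels are uniformly permuted across that cell's
    spots; boundaries, spot counts and coordinates are untouched, and
    per-gene within-cell counts are preserved as multisets.
    """
    cells = []
    for c in ds.cells:
        rng = derive_rng(seed, "permute", c.cell_id)
        cells.append(c.replace(spot_genes=c.spot_genes[rng.permutation(c.n_spots)]))
    return Dataset(
        cells=cells,
        gene_panel=set(ds.gene_panel),
        blank_codes=set(ds.blank_codes),
        name=f"{ds.name}-permuted",
    )
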