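"""Cell/spot data model and geometric primitives.

Cells are the unit of scoring: each carries one boundary polygon per
z-slice (micron coordinates, stored *unclosed* — the first vertex is not
repeated at the end), the RNA spots detected inside it, and a cell-type
label.  The primitives here — minimum distance to the boundary, the
vertex-mean centroid, spot-to-cell assignment and boundary shrinking —
are the geometry every localization metric consumes.

Conventions:

* coordinates are microns in 2D per z-slice; ``z`` is an integer slice
  label, not a physical coordinate;
* containment is boundary-inclusive: a spot exactly on a ring edge is
  inside (distance 0, rank-eligible);
* the cell centroid is the arithmetic mean of the boundary vertices
  (mean of per-ring vertex means for multi-slice cells), which is why a
  duplicated closing vertex must be dropped — it would bias the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LinearRing, Polygon
from shapely.strtree import STRtree

logger = logging.getLogger("spotloc")

__all__ = [
    "Spot",
    "Cell",
    "Dataset",
    "dedup_closing_vertex",
    "min_distance_to_boundary",
    "boundary_distances",
    "ring_centroid",
    "boundary_centroid",
    "assign_spots_to_cells",
    "shrink_boundary",
    "shrink_dataset",
]


@dataclass(frozen=True)
class Spot:
    """A single detected RNA molecule."""

    x: float
    y: float
    z_index: int
    gene: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("spot coordinates must be finite")
        if not self.gene:
            raise ValueError("spot gene label must be non-empty")


def dedup_closing_vertex(vertices: np.ndarray) -> np.ndarray:
    """Drop a repeated closing vertex so rings are stored unclosed."""
    vertices = np.asarray(vertices, dtype=float)
    if len(vertices) >= 2 and np.allclose(vertices[0], vertices[-1]):
        vertices = vertices[:-1]
    return vertices


def _validate_ring(vertices: np.ndarray, where: str = "ring") -> np.ndarray:
    vertices = dedup_closing_vertex(vertices)
    if vertices.ndim != 2 or vertices.shape[1] != 2:
        raise ValueError(f"{where}: vertices must be an (V, 2) array")
    if len(vertices) < 3:
        raise ValueError(f"{where}: a boundary needs at least 3 vertices")
    if not np.isfinite(vertices).all():
        raise ValueError(f"{where}: vertices must be finite")
    ring = LinearRing(vertices)
    if not ring.is_valid or Polygon(vertices).area == 0.0:
        raise ValueError(f"{where}: boundary must be a simple polygon with area")
    return vertices


class Cell:
    """One cell: boundary ring(s) per z-slice, spots, and a type label.

    Spots are stored as parallel arrays (``spot_xy`` (n, 2), ``spot_z``
    (n,), ``spot_genes`` (n,)) for vectorized scoring; :meth:`iter_spots`
    yields :class:`Spot` records.
    """

    def __init__(
        self,
        cell_id: str,
        cell_type: str,
        rings: Mapping[int, np.ndarray],
        spot_xy: Optional[np.ndarray] = None,
        spot_z: Optional[np.ndarray] = None,
        spot_genes: Optional[Sequence[str]] = None,
    ) -> None:
        if not rings:
            raise ValueError(f"cell {cell_id!r}: at least one boundary ring required")
        self.cell_id = str(cell_id)
        self.cell_type = str(cell_type)
        self.rings: Dict[int, np.ndarray] = {
            int(z): _validate_ring(v, where=f"cell {cell_id!r} z={z}")
            for z, v in rings.items()
        }
        n = 0 if spot_xy is None else len(spot_xy)
        self.spot_xy = (
            np.zeros((0, 2), dtype=float)
            if spot_xy is None
            else np.asarray(spot_xy, dtype=float).reshape(n, 2)
        )
        self.spot_z = (
            np.zeros(0, dtype=int) if spot_z is None else np.asarray(spot_z, dtype=int)
        )
        self.spot_genes = (
            np.zeros(0, dtype=object)
            if spot_genes is None
            else np.asarray(spot_genes, dtype=object)
        )
        if not (len(self.spot_xy) == len(self.spot_z) == len(self.spot_genes)):
            raise ValueError(f"cell {cell_id!r}: spot arrays must have equal length")
        if not np.isfinite(self.spot_xy).all():
            raise ValueError(f"cell {cell_id!r}: spot coordinates must be finite")
        missing = set(np.unique(self.spot_z)) - set(self.rings)
        if missing:
            raise ValueError(
                f"cell {cell_id!r}: spots on z-slices {sorted(missing)} have no boundary"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_spots(self) -> int:
        return len(self.spot_xy)

    @property
    def z_indices(self) -> List[int]:
        return sorted(self.rings)

    def unique_genes(self) -> np.ndarray:
        return np.unique(self.spot_genes.astype(str))

    def gene_counts(self) -> Dict[str, int]:
        genes, counts = np.unique(self.spot_genes.astype(str), return_counts=True)
        return dict(zip(genes, counts.tolist()))

    def iter_spots(self) -> Iterator[Spot]:
        for (x, y), z, g in zip(self.spot_xy, self.spot_z, self.spot_genes):
            yield Spot(float(x), float(y), int(z), str(g))

    def polygon(self, z_index: int) -> Polygon:
        return Polygon(self.rings[z_index])

    def validate_containment(self) -> None:
        """Check every spot lies inside (or on) its slice's ring."""
        for z in self.z_indices:
            mask = self.spot_z == z
            if not mask.any():
                continue
            pts = shapely.points(self.spot_xy[mask])
            inside = shapely.covers(self.polygon(z), pts)
            if not inside.all():
                bad = int((~inside).sum())
                raise ValueError(
                    f"cell {self.cell_id!r}: {bad} spot(s) outside the z={z} boundary"
                )

    def replace(self, **kwargs) -> "Cell":
        args = dict(
            cell_id=self.cell_id,
            cell_type=self.cell_type,
            rings=self.rings,
            spot_xy=self.spot_xy,
            spot_z=self.spot_z,
            spot_genes=self.spot_genes,
        )
        args.update(kwargs)
        return Cell(**args)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"Cell({self.cell_id!r}, type={self.cell_type!r}, "
            f"slices={len(self.rings)}, spots={self.n_spots})"
        )


@dataclass
class Dataset:
    """A collection of cells plus the imaged gene panel.

    ``blank_codes`` are decoding barcodes that correspond to no real gene;
    they are scored like genes and serve as negative controls.
    """

    cells: List[Cell] = field(default_factory=list)
    gene_panel: set = field(default_factory=set)
    blank_codes: set = field(default_factory=set)
    name: str = "dataset"

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell_ids must be unique")
        if not self.gene_panel:
            self.gene_panel = set()
            for c in self.cells:
                self.gene_panel.update(map(str, c.unique_genes()))
        else:
            for c in self.cells:
                extra = set(map(str, c.unique_genes())) - self.gene_panel
                if extra:
                    raise ValueError(
                        f"cell {c.cell_id!r} has genes outside the panel: {sorted(extra)[:5]}"
                    )
        if self.blank_codes - self.gene_panel:
            raise ValueError("blank_codes must be a subset of the gene panel")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_types(self) -> List[str]:
        return sorted({c.cell_type for c in self.cells})

    def spots_frame(self) -> pd.DataFrame:
        """Flat per-spot table (cell_id, cell_type, x, y, z_index, gene)."""
        frames = []
        for c in self.cells:
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": c.cell_id,
                        "cell_type": c.cell_type,
                        "x": c.spot_xy[:, 0],
                        "y": c.spot_xy[:, 1],
                        "z_index": c.spot_z,
                        "gene": c.spot_genes.astype(str),
                    }
                )
            )
        if not frames:
            return pd.DataFrame(
                columns=["cell_id", "cell_type", "x", "y", "z_index", "gene"]
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------


def boundary_distances(xy: np.ndarray, ring_vertices: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance from each point to the boundary polyline."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    ring = LinearRing(dedup_closing_vertex(np.asarray(ring_vertices, dtype=float)))
    return shapely.distance(shapely.points(xy), ring)


def min_distance_to_boundary(spot: Spot, ring_vertices: np.ndarray, z_index: int) -> float:
    """Distance from one spot to its own slice's boundary.

    Raises if the spot's z-slice does not match the ring's — that always
    indicates a slice-pairing bug upstream.
    """
    if int(spot.z_index) != int(z_index):
        raise ValueError(
            f"slice mismatch: spot z={spot.z_index} vs boundary z={z_index}"
        )
    return float(boundary_distances([[spot.x, spot.y]], ring_vertices)[0])


def ring_centroid(ring_vertices: np.ndarray) -> np.ndarray:
    """Vertex-mean centroid of one (unclosed) ring."""
    return dedup_closing_vertex(np.asarray(ring_vertices, dtype=float)).mean(axis=0)


def boundary_centroid(cell: Cell) -> np.ndarray:
    """Cell centroid: mean of per-ring vertex-mean centroids."""
    return np.mean([ring_centroid(cell.rings[z]) for z in cell.z_indices], axis=0)


def assign_spots_to_cells(
    spots: pd.DataFrame, cells: Sequence[Cell], name: str = "dataset"
) -> Tuple[Dataset, Dict[str, int]]:
    """Assign a flat spot table (x, y, z_index, gene) to cells by containment.

    Uses an STRtree bounding-box index per z-slice before the exact
    boundary-inclusive point-in-polygon test.  Spots inside no cell are
    dropped (counted in the report); a spot inside more than one cell at
    the same z goes to the cell with the nearest centroid (warned).
    """
    required = {"x", "y", "z_index", "gene"}
    if not required.issubset(spots.columns):
        raise ValueError(f"spot table must have columns {sorted(required)}")
    owner = np.full(len(spots), -1, dtype=int)
    n_ambiguous = 0
    centroids = np.array([boundary_centroid(c) for c in cells]) if cells else np.zeros((0, 2))
    z_values = spots["z_index"].to_numpy(dtype=int)
    xy = spots[["x", "y"]].to_numpy(dtype=float)
    for z in np.unique(z_values):
        cell_idx = [i for i, c in enumerate(cells) if int(z) in c.rings]
        if not cell_idx:
            continue
        polys = [cells[i].polygon(int(z)) for i in cell_idx]
        tree = STRtree(polys)
        rows = np.flatnonzero(z_values == z)
        pts = shapely.points(xy[rows])
        pairs = tree.query(pts, predicate="covered_by")
        if pairs.size == 0:
            continue
        spot_pos, poly_pos = pairs
        for s in np.unique(spot_pos):
            hits = poly_pos[spot_pos == s]
            row = rows[s]
            if len(hits) == 1:
                owner[row] = cell_idx[hits[0]]
            else:
                n_ambiguous += 1
                cand = [cell_idx[h] for h in hits]
                d = np.linalg.norm(centroids[cand] - xy[row], axis=1)
                owner[row] = cand[int(np.argmin(d))]
    if n_ambiguous:
        logger.warning(
            "%d spot(s) fell inside multiple cell boundaries; "
            "assigned to the nearest-centroid cell",
            n_ambiguous,
        )
    n_dropped = int((owner == -1).sum())
    out_cells = []
    genes = spots["gene"].to_numpy(dtype=object)
    for i, c in enumerate(cells):
        rows = np.flatnonzero(owner == i)
        out_cells.append(
            c.replace(spot_xy=xy[rows], spot_z=z_values[rows], spot_genes=genes[rows])
        )
    ds = Dataset(cells=out_cells, name=name)
    report = {
        "n_spots": len(spots),
        "n_assigned": len(spots) - n_dropped,
        "n_dropped": n_dropped,
        "n_ambiguous": n_ambiguous,
    }
    if n_dropped:
        logger.info("dropped %d spot(s) outside all cell boundaries", n_dropped)
    return ds, report


def shrink_boundary(cell: Cell, factor: float) -> Cell:
    """Shrink each ring toward its own vertex-mean centroid by ``factor``.

    Vertex offsets from the centroid are divided by ``factor`` (so 1.25
    shrinks the boundary 1.25-fold in x and y); spots falling outside the
    shrunk ring of their slice are discarded.  ``factor`` must be >= 1;
    factor 1 is the identity.
    """
    factor = float(factor)
    if factor < 1.0:
        raise ValueError("shrink factor must be >= 1 (enlarging is out of contract)")
    new_rings = {}
    for z, verts in cell.rings.items():
        c = ring_centroid(verts)
        new_rings[z] = c + (verts - c) / factor
    keep = np.ones(cell.n_spots, dtype=bool)
    for z in cell.z_indices:
        mask = cell.spot_z == z
        if not mask.any():
            continue
        pts = shapely.points(cell.spot_xy[mask])
        inside = shapely.covers(Polygon(new_rings[z]), pts)
        keep[np.flatnonzero(mask)[~inside]] = False
    return cell.replace(
        rings=new_rings,
        spot_xy=cell.spot_xy[keep],
        spot_z=cell.spot_z[keep],
        spot_genes=cell.spot_genes[keep],
    )


def shrink_dataset(ds: Dataset, factor: float) -> Dataset:
    """Apply :func:`shrink_boundary` to every cell of a dataset."""
    return Dataset(
        cells=[shrink_boundary(c, factor) for c in ds.cells],
        gene_panel=set(ds.gene_panel),
        blank_codes=set(ds.blank_codes),
        name=ds.name,
    )
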