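"""Cell-centric HDF5 storage and flat-table converters.

The native format consolidates boundaries and spots per cell:

    /                       attrs: format_version, dataset_name
    /gene_panel             (G,) UTF-8 strings          [optional]
    /blank_codes            (B,) UTF-8 strings          [optional]
    /cells/<cell_id>        attrs: cell_type
        boundary_z<k>       (V_k, 2) float64 microns
        spots_z<k>          (S_k, 2) float64 microns    [if slice has spots]
        genes_z<k>          (S_k,)   UTF-8 strings

A z-slice with spots must have a boundary; round-trips are lossless.
Converters accept the flat CSV/TSV shape of MERFISH/Vizgen/SeqFISH+
exports (a spot table, a boundary vertex table, and a cell-type table),
assigning spots to cells by containment when the spot table carries no
cell ids.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import h5py
import numpy as np
import pandas as pd

from .geometry import Cell, Dataset, assign_spots_to_cells, dedup_closing_vertex

logger = logging.getLogger("spotloc")

FORMAT_VERSION = "1.0"

__all__ = ["read_dataset", "write_dataset", "convert_tables", "read_table"]

_STR = h5py.string_dtype(encoding="utf-8")


def write_dataset(ds: Dataset, path: Union[str, Path]) -> None:
    """Write a dataset to the cell-centric HDF5 format."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["dataset_name"] = ds.name
        f.create_dataset("gene_panel", data=sorted(ds.gene_panel), dtype=_STR)
        f.create_dataset("blank_codes", data=sorted(ds.blank_codes), dtype=_STR)
        root = f.create_group("cells")
        for c in ds.cells:
            g = root.create_group(c.cell_id)
            g.attrs["cell_type"] = c.cell_type
            for z in c.z_indices:
                g.create_dataset(f"boundary_z{z}", data=c.rings[z], dtype="f8")
                mask = c.spot_z == z
                if mask.any():
                    g.create_dataset(f"spots_z{z}", data=c.spot_xy[mask], dtype="f8")
                    g.create_dataset(
                        f"genes_z{z}",
                        data=[str(x) for x in c.spot_genes[mask]],
                        dtype=_STR,
                    )


def read_dataset(path: Union[str, Path], validate: bool = True) -> Dataset:
    """Read a dataset, checking format version and per-slice invariants."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(f"unknown format_version {version!r}; expected {FORMAT_VERSION!r}")
        name = str(f.attrs.get("dataset_name", "dataset"))
        gene_panel = set(np.asarray(f["gene_panel"], dtype=str)) if "gene_panel" in f else set()
        blank_codes = set(np.asarray(f["blank_codes"], dtype=str)) if "blank_codes" in f else set()
        cells = []
        for cell_id, g in f.get("cells", {}).items():
            rings: Dict[int, np.ndarray] = {}
            spot_parts = []
            for key in g:
                if key.startswith("boundary_z"):
                    rings[int(key[len("boundary_z"):])] = np.asarray(g[key], dtype=float)
            for key in sorted(g):
                if not key.startswith("spots_z"):
                    continue
                z = int(key[len("spots_z"):])
                xy = np.asarray(g[key], dtype=float)
                genes = np.asarray(g[f"genes_z{z}"], dtype=str)
                if len(xy) != len(genes):
                    raise ValueError(f"cell {cell_id!r} z={z}: spot/gene length mismatch")
                if z not in rings:
                    raise ValueError(
                        f"cell {cell_id!r}: spots at z={z} but no boundary for that slice"
                    )
                spot_parts.append((xy, np.full(len(xy), z, dtype=int), genes))
            if spot_parts:
                xy = np.concatenate([p[0] for p in spot_parts])
                zz = np.concatenate([p[1] for p in spot_parts])
                gg = np.concatenate([p[2] for p in spot_parts]).astype(object)
            else:
                xy, zz, gg = None, None, None
            cell = Cell(
                cell_id,
                str(g.attrs["cell_type"]),
                rings,
                spot_xy=xy,
                spot_z=zz,
                spot_genes=gg,
            )
            if validate:
                cell.validate_containment()
            cells.append(cell)
    return Dataset(
        cells=cells,
        gene_panel=gene_panel or set(),
        blank_codes=blank_codes,
        name=name,
    )


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a CSV/TSV table, sniffing the delimiter and skipping # comments."""
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def convert_tables(
    spots: Union[pd.DataFrame, str, Path],
    boundaries: Union[pd.DataFrame, str, Path],
    celltypes: Union[pd.DataFrame, str, Path],
    name: str = "dataset",
) -> Tuple[Dataset, Dict[str, int]]:
    """Build a Dataset from flat spot / boundary-vertex / cell-type tables.

    ``spots``:      x, y, z_index, gene [, cell_id]
    ``boundaries``: cell_id, z_index, vertex_order, x, y
    ``celltypes``:  cell_id, cell_type

    A duplicated closing vertex is dropped.  When the spot table has no
    ``cell_id`` column, spots are assigned by boundary-inclusive
    containment; unassigned spots are dropped and counted in the report.
    Cells whose boundary is degenerate, or referenced cell ids without a
    boundary, are skipped with a warning.
    """
    if not isinstance(spots, pd.DataFrame):
        spots = read_table(spots)
    if not isinstance(boundaries, pd.DataFrame):
        boundaries = read_table(boundaries)
    if not isinstance(celltypes, pd.DataFrame):
        celltypes = read_table(celltypes)
    type_map = dict(zip(celltypes["cell_id"].astype(str), celltypes["cell_type"].astype(str)))
    shells: Dict[str, Dict[int, np.ndarray]] = {}
    for (cell_id, z), grp in boundaries.groupby(["cell_id", "z_index"], sort=True):
        verts = (
            grp.sort_values("vertex_order")[["x", "y"]].to_numpy(dtype=float)
        )
        shells.setdefault(str(cell_id), {})[int(z)] = dedup_closing_vertex(verts)
    cells = []
    n_bad_cells = 0
    for cell_id, rings in sorted(shells.items()):
        try:
            cells.append(Cell(cell_id, type_map.get(cell_id, "unknown"), rings))
        except ValueError as exc:
            n_bad_cells += 1
            logger.warning("skipping cell %s: %s", cell_id, exc)
    report: Dict[str, int] = {"n_cells_skipped": n_bad_cells}
    if "cell_id" in spots.columns:
        by_id: Dict[str, list] = {c.cell_id: [] for c in cells}
        n_missing = 0
        for row, cid in enumerate(spots["cell_id"].astype(str)):
            if cid in by_id:
                by_id[cid].append(row)
            else:
                n_missing += 1
        if n_missing:
            logger.warning("%d spot(s) reference cell ids without a boundary", n_missing)
        out = []
        for c in cells:
            rows = np.asarray(by_id[c.cell_id], dtype=int)
            out.append(
                c.replace(
                    spot_xy=spots[["x", "y"]].to_numpy(dtype=float)[rows],
                    spot_z=spots["z_index"].to_numpy(dtype=int)[rows],
                    spot_genes=spots["gene"].to_numpy(dtype=object)[rows],
                )
            )
        ds = Dataset(cells=out, name=name)
        report.update({"n_spots": len(spots), "n_dropped": n_missing})
        for c in ds.cells:
            c.validate_containment()
    else:
        ds, assign_report = assign_spots_to_cells(spots, cells, name=name)
        report.update(assign_report)
    return ds, report
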