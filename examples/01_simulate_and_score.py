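"""Simulate a small dataset with one planted peripheral gene and score it.

Builds 60 cells of two types with ~300 spots each, plants gene g00 near
the boundary (keeping only the outermost 40% of the uniform mass), runs
the peripheral and central rank metrics, and prints the gene/cell-type
summary.  Expect g00 strongly significant: positive peripheral effect
around +0.55 with its anti-central mirror image.  Note the null genes:
their effects are small (|Y| ~ 0.1) but many reach significance with
the opposite sign, because ranks are relative within a cell — a gene
that hogs the boundary-proximal ranks pushes everything else slightly
outward.  This compositionality is intrinsic to rank-based scores and
worth remembering when one gene dominates a panel; on fully null or
label-permuted data (example 03) no calls survive FDR control.
"""

import spotloc as sl

cfg = sl.SimulationConfig(
    n_cells=60, n_celltypes=2, n_genes=12, spots_per_cell=300.0,
    patterns={"g00": ("peripheral", 0.4)}, seed=1,
)
dataset, truth = sl.generate_dataset(cfg)
print(f"{dataset.n_cells} cells, {len(dataset.gene_panel)} genes")

cell_scores, summary = sl.run(dataset, metrics=["peripheral", "central"], seed=1)
cols = ["gene", "cell_type", "metric", "k", "effect_size", "z", "q", "significant"]
print("\nplanted gene g00:")
print(summary.loc[summary.gene == "g00", cols].to_string(index=False))
null_part = summary[summary.gene != "g00"]
print(
    f"\nnull genes: {int(null_part['significant'].sum())} of {len(null_part)} "
    f"gene/cell-type pairs significant, max |effect| = "
    f"{null_part['effect_size'].abs().max():.3f}"
)
print(
    "\neffect_size is the mean per-cell score in [-1, 1] "
    "(+1 = on the boundary / at the centroid); q is the BH-corrected p-value."
)
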