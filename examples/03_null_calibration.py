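"""Negative control: gene-label permutation kills every pattern.

Generates a dataset with two strongly planted genes, scores it before
and after permuting gene labels within each cell, and prints the number
of significant gene/cell-type calls in each condition plus a
Kolmogorov-Smirnov check that permuted-data p-values are uniform.
Expect many discoveries before permutation and zero after, with KS
p-value well above 0.05.
"""

from scipy import stats

import spotloc as sl

cfg = sl.SimulationConfig(
    n_cells=80, n_celltypes=2, n_genes=15, spots_per_cell=300.0,
    patterns={"g00": ("peripheral", 0.4), "g01": ("punctate", 1.0)}, seed=2,
)
dataset, _ = sl.generate_dataset(cfg)

_, before = sl.run(dataset, seed=2)
permuted = sl.permute_gene_labels(dataset, seed=3)
_, after = sl.run(permuted, seed=2)

print(f"significant gene/cell-type pairs before permutation: {int(before['significant'].sum())}")
print(f"significant gene/cell-type pairs after  permutation: {int(after['significant'].sum())}")
ks = stats.kstest(after["p"].dropna(), "uniform")
print(f"KS test of permuted-data p-values against U(0,1): p = {ks.pvalue:.3f}")
print(
    "\nPermuting labels within each cell preserves geometry and per-gene "
    "counts but destroys localization, so a calibrated method must report "
    "uniform p-values and no BH discoveries here."
)
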