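# spotloc

Statistics for subcellular RNA localization from multiplexed FISH spot
data.

Imaging technologies such as MERFISH, Vizgen and SeqFISH+ resolve
individual RNA molecules ("spots") inside single cells, each spot
carrying (x, y, z-slice) coordinates and a decoded gene label, together
with a segmented cell boundary. `spotloc` asks, gene by gene and cell by
cell: are this gene's molecules unusually close to the cell boundary
(*peripheral*), to the centroid (*central*), to each other (*punctate*),
or concentrated in one angular sector (*radial*) — beyond what the
cell's own spot geometry would produce by chance?

It is aimed at computational biologists analysing spatial
transcriptomics experiments who want per-cell effect sizes with honest
statistics rather than hard thresholds: every score comes with an exact
or permutation null, and gene/cell-type calls carry FDR control.

## The statistics

**Peripheral / central (exact rank nulls).** In a cell with `n` spots,
all spots are ranked 1..n by distance to the boundary (peripheral) or to
the vertex-mean centroid (central), ties broken at random. The median
rank `t` of a gene's `m` spots is normalized to

```
x = (t_e - t) / (t_e - 1),     t_e = (n + 1) / 2,
```

so `x ∈ [-1, 1]` with `E[x] = 0` under the null that gene labels are
exchangeable within the cell. The null PMF of the median rank is exactly
computable (an order-statistic formula for odd `m`, a sum over
consecutive order-statistic pairs for even `m`), giving an exact
variance `Var[x | n, m]` and an exact two-sided per-cell p-value. When
`m = n` the median is pinned at `t_e` and the variance is 0.

**Punctate / radial (permutation nulls).** The punctate statistic is the
mean distance over `P = 10` random pairs of the gene's spots; the radial
statistic is the mean angle those pairs subtend at the cell centroid.
`B = 1000` within-cell gene-label permutations build the null; the
mid-rank quantile `q` of the observed statistic maps to
`x = 1 - 2q ∈ (-1, 1)` (positive = more aggregated than chance), with
closed-form null variance `B(B+2)/(3(B+1)^2) ≈ 1/3`.

**Aggregation.** Per gene, cell-type and metric, the cell scores
`x_1..x_k` have known, unequal null variances, so the Lyapunov CLT gives

```
z = Σ x_i / sqrt(Σ σ_i²)  →  N(0, 1),
```

a two-sided normal p-value, and the effect size `Y = mean(x_i)`.
P-values are Benjamini–Hochberg corrected per metric at α = 0.05.
Default filters: cells need ≥10 unique genes and ≥200 spots; groups need
≥20 cells.

A synthetic-data generator with planted peripheral / central / punctate
/ radial patterns (and the gene-label permutation negative control)
makes the whole machinery testable without any external download.

## Worked example

```python
import spotloc as sl

# 100 cells, 2 cell-types, 20 genes; g00 is planted peripheral
cfg = sl.SimulationConfig(
    n_cells=100, n_celltypes=2, n_genes=20,
    patterns={"g00": ("peripheral", 0.4)}, seed=5,
)
ds, truth = sl.generate_dataset(cfg)
cell_scores, summary = sl.run(ds, seed=5)
hit = summary[(summary.gene == "g00") & (summary.metric == "peripheral")]
print(hit[["cell_type", "k", "effect_size", "z", "q", "significant"]].to_string(index=False))
```

prints

```
cell_type  k  effect_size         z            q  significant
    typeA 50     0.567425 16.694989 2.850901e-61         True
    typeB 50     0.599931 17.114346 4.640455e-64         True
```

i.e. in both cell-types the planted gene's mean per-cell peripheral
score is ≈ +0.6 (strongly boundary-proximal on the [-1, 1] scale), the
Lyapunov z of ~17 leaves no doubt, and the BH-corrected q-value is far
below α = 0.05. A couple of null genes in the same run pick up small
opposite-signed calls (effect ≈ −0.12): ranks are relative within a
cell, so a gene that hogs the boundary-proximal ranks pushes everything
else slightly outward — a compositional property of rank scores to keep
in mind when one gene dominates. On fully null or label-permuted data
there are no significant calls at all.

The same pipeline is available from the shell:

```sh
spotloc simulate --out toy.h5 --pattern g00:peripheral:0.4 --seed 5
spotloc score toy.h5 --out scores.tsv --seed 5
spotloc aggregate scores.tsv --out summary.tsv
```

See `examples/` for short narrative scripts covering each capability
(scoring, permutation nulls, boundary-shrink robustness, covariate
correlation).

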