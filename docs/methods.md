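# Methods

## Data model and geometry

A *cell* is the unit of scoring: one simple boundary polygon per
z-slice (micron coordinates, vertices stored unclosed), the RNA spots
detected in it (x, y, integer z-slice, gene label), and a cell-type
label. z is a slice index, not a physical coordinate: distances are
always 2D within a slice, and the punctate metric projects all slices
onto one plane.

The cell centroid is the arithmetic mean of boundary vertices (mean of
per-ring means for multi-slice cells). This vertex-mean convention — not
the area centroid — is used everywhere a centroid is needed (central
ranking, radial angles, boundary shrinking), so a duplicated closing
vertex must be dropped on input or it would bias the mean. Containment
is boundary-inclusive: segmentation pipelines snap spots onto
boundaries, and such spots are legitimate rank-1 candidates (distance
0). Spot-to-cell assignment uses an STRtree bounding-box prefilter
before the exact test; a spot covered by more than one cell polygon at
the same z (the upstream segmentation never promises disjointness) is
given to the nearest-centroid cell with a warning. Degenerate rings
(<3 vertices or zero area) reject the cell at load time.

`shrink_boundary(cell, f)` divides each vertex's offset from its ring
centroid by `f ≥ 1` and discards spots that fall outside, matching the
boundary-perturbation robustness experiment (`f = 1.25` by default).
Enlarging is out of contract.

## Rank metrics and their exact null

All `n` spots of a cell are ranked by distance to the reference
(boundary or per-slice centroid), jointly across slices, ties broken
uniformly at random from a per-cell stream derived from
`(seed, cell_id)` — reproducible and independent of cell iteration
order. The gene's median rank `t` maps to
`x = (t_e - t)/(t_e - 1)`, `t_e = (n+1)/2`. A 1-spot cell has `t_e = 1`
and cannot be scored (division by zero); the default cell filters
remove such cells long before this matters.

Under within-cell label exchangeability the gene's ranks are a uniform
`m`-subset of 1..n. For odd `m` the median is the `r`-th order statistic
(`r = (m+1)/2`):
`P(T=t) = C(t-1, r-1) C(n-t, m-r) / C(n, m)`.
For even `m` it is the average of the `m/2`-th and `(m/2+1)`-th order
statistics `L < R`, and with `k = m/2`:
`P(L=l, R=r) = C(l-1, k-1) C(n-r, k-1) / C(n, m)`,
summed over pairs with `l + r = 2t`. This is algebraically the same
computation as conditioning `R` on `L` and walking the pair outward from
`t`; the pair form vectorizes better. The PMF is symmetric about `t_e`,
so `E[x] = 0` exactly; `Var[x]` follows by summation and is 0 iff
`m = n`.

Two code paths exist deliberately:

* an exact rational path (`fractions.Fraction`) used by the theory
  tests and the acceptance targets — exhaustive-enumeration oracles
  confirm it for all `n ≤ 12`;
* a float path on log-gamma binomials, cached per `(n, m)`, used at
  dataset scale: the even-`m` computation is O(n²) and big-integer
  binomials at n ≈ 300 would dominate the runtime. The two agree to
  ~1e-12, which is far below any decision threshold downstream.

Per-cell exact two-sided p-values (`P(|X| ≥ |x_obs|)`) are attached to
every rank score for inspection, but inference runs only through the
CLT aggregation below — the per-cell p-values are descriptive.

## Permutation metrics

The punctate statistic of a gene with `m ≥ 2` spots is the mean 2D
distance over `P` uniformly drawn unordered pairs of distinct spots
(with replacement across draws; for `m = 2` every draw is the one
existing pair). The radial statistic (default `m ≥ 3`) is the mean
angle in [0, π] subtended at the whole-cell centroid. Spots exactly at
the centroid have no direction and are excluded from the radial
statistic; a gene left with fewer than two usable spots is skipped with
a warning. Single-spot genes are removed from the cell before either
metric (no pairwise information), and the remaining spots are still
scored; both minimum-spot thresholds are configurable.

The null is built from `B` label permutations; one shared shuffle per
iteration serves all genes of the cell (statistically valid, and B-fold
cheaper than per-gene shuffles). With `r = #{null means ≤ observed}`,
the mid-rank quantile `q = (r + 0.5)/(B + 1)` gives `x = 1 - 2q`. The
scale of the score was a genuinely open design choice; the mid-rank
quantile mapping was chosen because it is bounded in (−1, 1), exactly
mean-zero under the null (where `r` is uniform on {0..B}), and has the
closed-form variance `B(B+2)/(3(B+1)²)` that the CLT stage needs.
Degenerate nulls — a single-gene cell, where label permutation is the
identity, or every permuted mean exactly equal to the observed mean —
score 0 *with null variance 0*, mirroring the `m = n` convention of the
rank metrics: such cells stay in the effect size but carry no weight in
`z`. Defaults `B = 1000`, `P = 10`.

## Aggregation, FDR, and helpers

For one gene/cell-type/metric with `k ≥ 20` cells,
`z = Σ x_i / sqrt(Σ σ_i²)` over cells with `σ_i² > 0`; `p = 2(1−Φ(|z|))`
clipped into (0, 1]; effect size `Y = mean(x_i)` over all cells. A group
whose every cell has zero variance is flagged untestable (`p = NaN`,
never significant). BH correction is applied per metric across all
gene/cell-type pairs of one run — cross-metric or cross-replicate
pooling is not done; running replicates separately and correlating their
summaries is the supported comparison route.

Cell filters (≥10 unique genes, ≥200 spots) and the group filter
(≥20 cells) are strict "fewer than" thresholds. The optional
median-spot filter (group median `m ≥ 5`) is off by default because it
belongs to specific dataset analyses, not the core method.

`classify_directionality` labels each gene/metric across cell-types:
*opposite* (significant positive and significant negative coexist),
*cell_type_dependent* (significant somewhere, insignificant elsewhere),
*uniform*, or *none*. `correlate_with_covariate` Pearson-correlates
per-cell-type median scores against any per-cell-type covariate (e.g. a
3' UTR-length proxy) with BH correction across gene/metric pairs,
requiring ≥3 matched cell-types and skipping constant inputs.

## Synthetic data

The generator emulates what the statistics actually consume: convex
regular-polygon cells (default 12-gon, radius 8–12 µm) on a disjoint
grid, round-robin cell-types, negative-binomial spot counts (default
mean 300, dispersion 50), multinomial gene identities, and per-gene
placement laws. All pattern samplers are restrictions/truncations of
the uniform-in-polygon law, so correctness is provable and each
pattern has an exact neutral limit equal to uniform placement:

* peripheral: keep uniform draws with boundary distance ≤ the
  ρ-quantile of uniform boundary distances (ρ = 1 neutral);
* central: the complementary restriction (distance ≥ the
  (1−ρ)-quantile);
* punctate: isotropic Gaussian of spread `s` around a uniform focus,
  truncated to the cell (s → ∞ neutral). Two exact samplers are
  switched on `2πs² ≤ area`: Gaussian proposals filtered by
  containment when the focus is tight, uniform proposals thinned by the
  Gaussian density ratio when it is wide;
* radial: uniform restricted to a sector of width `w` about the
  centroid (w = 2π neutral).

The quantile thresholds for peripheral/central are estimated from 2000
uniform calibration draws per ring; the ~1% quantile-estimation noise
only perturbs the *strength* of a planted pattern, never the null.

What the generator does **not** model: optical crowding and duplicate
spot calls, nuclei, irregular/concave boundaries, segmentation errors,
spatially correlated expression between neighbouring cells, or
z-dependent boundary changes beyond radius jitter. Passing tests
therefore demonstrate the statistics are correct and calibrated under
the stated null, not that real segmentation or imaging artifacts are
harmless; the boundary-shrink experiment probes the segmentation axis
specifically.

`permute_gene_labels` shuffles labels within each cell, preserving
geometry and per-gene counts — the negative control under which every
metric must be calibrated.

## Numerical and reproducibility choices

* All randomness flows from one integer seed through per-cell
  `SeedSequence`s keyed by `(seed, cell_id, purpose)`, so results are
  identical regardless of iteration order or parallel scheduling.
* Rank ties are broken by a random key appended to a stable lexsort —
  uniform over tied orderings, deterministic per seed.
* Rank scores are exactly invariant under rigid motion and uniform
  scaling of a cell (ranks depend only on distance order); permutation
  scores are invariant given the same seed (angles are invariant,
  distances scale jointly with their null).
* `p = 2(1−Φ(|z|))` is clipped away from exact 0 so BH never sees a
  literal zero.
* The float PMF path normalizes by its own sum (residual error ≤ 1e-12)
  to keep p-values exactly summable.

## Problem sizes used in checks

Theory checks run the exact PMF against exhaustive enumeration for all
`n ≤ 12` and use `n ≤ 50` for the `m = n` variance scan. Calibration
and specificity checks use 100–600 cells with ~300 spots each;
the permuted-null sign-balance report uses 6 cell-types × 100 cells and
100 genes so that the percentage of positive gene/cell-type pairs is
estimated with a Monte-Carlo sd of about 2 percentage points (with only
40 pairs the estimator's own noise would swamp the quantity). The
boundary-shrink comparison plants six peripheral and six central genes
across a strength range (ρ 0.3–0.8) among 18 null genes in 150 cells
with ~450 spots each — enough spots that cells still pass the 200-spot
filter after 1.25× shrinking removes ~36% of them, mirroring how
spot-dense imaging datasets behave under the same operation.

## Known limitations

* The even-`m` PMF is O(n²); per-(n, m) caching makes a full run cheap,
  but pathological inputs with thousands of distinct (n, m) pairs and
  huge n would feel it.
* The CLT z is asymptotic in the number of cells; at the minimum group
  size (20 cells) p-values are mildly approximate, which the
  permuted-null KS checks bound in practice.
* Scores of different genes within one cell are not independent (shared
  ranking, shared permutations); aggregation assumes independence only
  across cells, as the theory requires, but cross-gene correlations can
  make the *joint* BH family slightly conservative or liberal in edge
  cases. Rank scores are also compositional: a gene that strongly
  occupies boundary-proximal ranks pushes every other gene's ranks
  outward, so a dominant true pattern can induce small opposite-signed
  calls on otherwise null genes. The permuted-label null is immune (no
  gene has a pattern), but interpretation of real data should keep this
  relativity in mind.
* Blank codes are scored like genes and flagged downstream; no special
  calibration is applied to them.
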