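"""Synthetic-data generator: samplers, planted patterns, label permutation."""

import numpy as np
import pytest
from scipy import stats

from spotloc import (
    SimulationConfig,
    boundary_distances,
    generate_dataset,
    permute_gene_labels,
    sample_pattern,
    sample_uniform_in_polygon,
)
from conftest import UNIT_SQUARE, point_in_polygon_oracle

HEXAGON = 10.0 * np.column_stack(
    [np.cos(2 * np.pi * np.arange(6) / 6), np.sin(2 * np.pi * np.arange(6) / 6)]
)


class TestUniformSampler:
    def test_count_zero(self):
        assert sample_uniform_in_polygon(UNIT_SQUARE, 0, np.random.default_rng(0)).shape == (0, 2)

    def test_points_inside_and_mean_centered(self):
        pts = sample_uniform_in_polygon(UNIT_SQUARE, 10_000, np.random.default_rng(1))
        assert all(point_in_polygon_oracle(p, UNIT_SQUARE) for p in pts[:200])
        se = np.sqrt(1 / 12 / len(pts))
        np.testing.assert_allclose(pts.mean(axis=0), [0.5, 0.5], atol=3 * se)

    def test_grid_uniformity(self):
        pts = sample_uniform_in_polygon(UNIT_SQUARE, 8000, np.random.default_rng(2))
        counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=4, range=[[0, 1], [0, 1]])
        chi2 = ((counts - 500.0) ** 2 / 500.0).sum()
        assert stats.chi2.sf(chi2, df=15) > 0.01

    def test_seed_determinism(self):
        a = sample_uniform_in_polygon(HEXAGON, 100, np.random.default_rng(3))
        b = sample_uniform_in_polygon(HEXAGON, 100, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


class TestPatternSamplers:
    def test_all_patterns_stay_inside(self):
        rng = np.random.default_rng(4)
        for pattern, strength in [("peripheral", 0.3), ("central", 0.3),
                                  ("punctate", 0.5), ("radial", np.pi / 4)]:
            pts = sample_pattern(HEXAGON, 300, pattern, strength, rng)
            assert pts.shape == (300, 2)
            assert all(point_in_polygon_oracle(p, HEXAGON) for p in pts[:100])

    def test_peripheral_bias_shrinks_boundary_distance(self):
        rng = np.random.default_rng(5)
        per = sample_pattern(HEXAGON, 1500, "peripheral", 0.3, rng)
        uni = sample_uniform_in_polygon(HEXAGON, 1500, rng)
        t = stats.mannwhitneyu(
            boundary_distances(per, HEXAGON), boundary_distances(uni, HEXAGON),
            alternative="less",
        )
        assert t.pvalue < 1e-10

    def test_central_bias_grows_boundary_distance(self):
        rng = np.random.default_rng(6)
        cen = sample_pattern(HEXAGON, 1500, "central", 0.3, rng)
        uni = sample_uniform_in_polygon(HEXAGON, 1500, rng)
        t = stats.mannwhitneyu(
            boundary_distances(cen, HEXAGON), boundary_distances(uni, HEXAGON),
            alternative="greater",
        )
        assert t.pvalue < 1e-10

    def test_punctate_spread_controls_pair_distance(self):
        rng = np.random.default_rng(7)
        tight = sample_pattern(HEXAGON, 400, "punctate", 0.1, rng)
        uni = sample_uniform_in_polygon(HEXAGON, 400, rng)

        def mean_pd(pts):
            i, j = rng.integers(0, len(pts), (2, 2000))
            return np.linalg.norm(pts[i] - pts[j], axis=1).mean()

        assert mean_pd(tight) < 0.2 * mean_pd(uni)

    def test_radial_sector_width_respected(self):
        rng = np.random.default_rng(8)
        w = np.pi / 3
        pts = sample_pattern(HEXAGON, 600, "radial", w, rng)
        ang = np.sort(np.arctan2(pts[:, 1], pts[:, 0]))  # hexagon centroid is the origin
        gaps = np.diff(np.append(ang, ang[0] + 2 * np.pi))
        # all angles inside one arc of width w <=> an empty arc of 2*pi - w
        assert gaps.max() >= 2 * np.pi - w - 1e-9

    def test_neutral_strengths_reduce_to_uniform(self):
        rng = np.random.default_rng(9)
        for pattern, neutral in [("peripheral", 1.0), ("central", 1.0),
                                 ("radial", 2 * np.pi)]:
            pts = sample_pattern(HEXAGON, 2000, pattern, neutral, rng)
            uni = sample_uniform_in_polygon(HEXAGON, 2000, rng)
            ks = stats.ks_2samp(boundary_distances(pts, HEXAGON),
                                boundary_distances(uni, HEXAGON))
            assert ks.pvalue > 0.01
        # punctate becomes uniform as the spread dwarfs the cell
        pts = sample_pattern(HEXAGON, 2000, "punctate", 1e4, rng)
        uni = sample_uniform_in_polygon(HEXAGON, 2000, rng)
        ks = stats.ks_2samp(boundary_distances(pts, HEXAGON),
                            boundary_distances(uni, HEXAGON))
        assert ks.pvalue > 0.01

    def test_strength_ranges_validated(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_pattern(HEXAGON, 5, "peripheral", 1.5, rng)
        with pytest.raises(ValueError):
            sample_pattern(HEXAGON, 5, "radial", 7.0, rng)
        with pytest.raises(ValueError):
            sample_pattern(HEXAGON, 5, "vortex", 0.5, rng)


class TestGenerateDataset:
    def test_shapes_types_and_truth_table(self):
        cfg = SimulationConfig(n_cells=10, n_celltypes=3, n_genes=5,
                               spots_per_cell=50.0, seed=1,
                               patterns={"g00": ("peripheral", 0.5)})
        ds, truth = generate_dataset(cfg)
        assert ds.n_cells == 10
        assert set(ds.cell_types()) == {"typeA", "typeB", "typeC"}
        assert len(truth) == 5 * 3
        assert (truth.loc[truth.gene == "g00", "pattern"] == "peripheral").all()
        assert (truth.loc[truth.gene == "g01", "pattern"] == "null").all()
        for c in ds.cells:
            c.validate_containment()

    def test_deterministic(self):
        cfg = SimulationConfig(n_cells=6, n_genes=4, spots_per_cell=40.0, seed=5)
        a, _ = generate_dataset(cfg)
        b, _ = generate_dataset(cfg)
        for ca, cb in zip(a.cells, b.cells):
            np.testing.assert_array_equal(ca.spot_xy, cb.spot_xy)
            np.testing.assert_array_equal(ca.spot_genes, cb.spot_genes)

    def test_pattern_celltype_restriction(self):
        cfg = SimulationConfig(n_cells=4, n_celltypes=2, n_genes=3, spots_per_cell=30.0,
                               patterns={"g0": ("punctate", 0.5)},
                               gene_names=["g0", "g1", "g2"],
                               pattern_celltypes={"g0": ["typeA"]}, seed=2)
        _, truth = generate_dataset(cfg)
        assert (truth.loc[(truth.gene == "g0") & (truth.cell_type == "typeA"),
                          "pattern"] == "punctate").all()
        assert (truth.loc[(truth.gene == "g0") & (truth.cell_type == "typeB"),
                          "pattern"] == "null").all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(patterns={"nope": ("peripheral", 0.5)})
        with pytest.raises(ValueError):
            SimulationConfig(gene_weights=[1.0, -1.0], n_genes=2)
        with pytest.raises(ValueError):
            SimulationConfig(radius_range=(5.0, 2.0))


class TestPermuteLabels:
    def test_counts_preserved_geometry_untouched(self, uniform_dataset):
        ds, _ = uniform_dataset
        perm = permute_gene_labels(ds, seed=1)
        for a, b in zip(ds.cells, perm.cells):
            np.testing.assert_array_equal(a.spot_xy, b.spot_xy)
            np.testing.assert_array_equal(a.spot_z, b.spot_z)
            assert a.gene_counts() == b.gene_counts()

    def test_single_gene_cell_identical(self, unit_square_cell):
        from spotloc import Dataset

        cell = unit_square_cell([[0.2, 0.2], [0.6, 0.7]], genes=["g", "g"])
        ds = Dataset(cells=[cell])
        perm = permute_gene_labels(ds, seed=3)
        np.testing.assert_array_equal(perm.cells[0].spot_genes, cell.spot_genes)

    def test_deterministic(self, uniform_dataset):
        ds, _ = uniform_dataset
        a = permute_gene_labels(ds, seed=9)
        b = permute_gene_labels(ds, seed=9)
        for ca, cb in zip(a.cells, b.cells):
            np.testing.assert_array_equal(ca.spot_genes, cb.spot_genes)
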