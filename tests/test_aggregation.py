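"""Filtering, CLT aggregation, BH correction, directionality, correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spotloc import (
    FilterConfig,
    SimulationConfig,
    aggregate_celltype,
    aggregate_scores,
    bh_correct,
    classify_directionality,
    correlate_with_covariate,
    filter_dataset,
    generate_dataset,
    permute_gene_labels,
    run,
)


def _synthetic_cell(n_genes, n_spots, seed=0):
    from conftest import UNIT_SQUARE
    from spotloc import Cell

    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i % n_genes}" for i in range(n_spots)], dtype=object)
    return Cell(f"cell{seed}", "A", rings={0: UNIT_SQUARE},
                spot_xy=rng.uniform(0, 1, (n_spots, 2)),
                spot_z=np.zeros(n_spots, dtype=int), spot_genes=genes)


class TestFiltering:
    def test_cell_thresholds_are_strict_fewer_than(self):
        from spotloc import Dataset

        sparse = _synthetic_cell(n_genes=9, n_spots=500, seed=1)
        dense = _synthetic_cell(n_genes=10, n_spots=200, seed=2)
        ds = Dataset(cells=[sparse, dense])
        kept, report = filter_dataset(ds, FilterConfig())
        assert [c.cell_id for c in kept.cells] == [dense.cell_id]
        assert report["n_cells_removed"] == 1

    def test_all_removed_raises(self):
        from spotloc import Dataset

        ds = Dataset(cells=[_synthetic_cell(n_genes=3, n_spots=50)])
        with pytest.raises(ValueError, match="relax"):
            filter_dataset(ds, FilterConfig())

    def test_small_groups_excluded_from_aggregation(self):
        rows = [
            {"cell_id": f"c{i}", "cell_type": "A", "gene": "g", "metric": "peripheral",
             "m": 5, "n": 50, "score": 0.1, "null_variance": 0.2}
            for i in range(19)
        ]
        summary = aggregate_scores(pd.DataFrame(rows), min_cells=20)
        assert summary.empty
        summary = aggregate_scores(pd.DataFrame(rows), min_cells=19)
        assert len(summary) == 1 and summary.iloc[0]["k"] == 19


class TestLyapunovAggregation:
    def test_single_cell_example(self):
        effect, z, p = aggregate_celltype([0.75], [0.25])
        assert z == pytest.approx(1.5)
        assert p == pytest.approx(2 * (1 - stats.norm.cdf(1.5)), abs=1e-6)
        assert p == pytest.approx(0.1336, abs=2e-4)
        assert effect == pytest.approx(0.75)

    def test_all_zero_scores(self):
        effect, z, p = aggregate_celltype([0.0] * 10, [0.3] * 10)
        assert (effect, z, p) == (0.0, 0.0, 1.0)

    def test_zero_variance_cells_excluded_from_z_kept_in_effect(self):
        effect, z, p = aggregate_celltype([0.75, 0.5], [0.25, 0.0])
        assert z == pytest.approx(1.5)  # the m = n cell is uninformative
        assert effect == pytest.approx(0.625)

    def test_untestable_group(self):
        effect, z, p = aggregate_celltype([0.0, 0.0], [0.0, 0.0])
        assert np.isnan(z) and np.isnan(p)


class TestBH:
    def test_step_up_by_hand(self):
        q, sig = bh_correct([0.005, 0.01, 0.03, 0.04], alpha=0.05)
        assert sig.all()  # thresholds 0.0125, 0.025, 0.0375, 0.05
        q2, sig2 = bh_correct([0.5, 0.6, 0.9])
        assert not sig2.any()

    def test_invariant_under_permutation_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 50)
        q, _ = bh_correct(p)
        perm = rng.permutation(50)
        q_perm, _ = bh_correct(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_nan_propagates(self):
        q, sig = bh_correct([0.01, np.nan, 0.02])
        assert np.isnan(q[1]) and not sig[1]


class TestDirectionality:
    def _summary(self, rows):
        df = pd.DataFrame(rows)
        df["metric"] = "peripheral"
        df["gene"] = "g"
        return df

    @pytest.mark.parametrize(
        "effects,sigs,expected",
        [
            ([0.3, -0.2], [True, True], "opposite"),
            ([0.3, 0.1], [True, False], "cell_type_dependent"),
            ([0.3, 0.2], [True, True], "uniform"),
            ([0.3, 0.2], [False, False], "none"),
        ],
    )
    def test_classes(self, effects, sigs, expected):
        df = self._summary(
            [{"cell_type": f"T{i}", "effect_size": e, "significant": s}
             for i, (e, s) in enumerate(zip(effects, sigs))]
        )
        out = classify_directionality(df)
        assert out.iloc[0]["directionality"] == expected

    def test_single_celltype_is_none(self):
        df = self._summary([{"cell_type": "T0", "effect_size": 0.5, "significant": True}])
        assert classify_directionality(df).iloc[0]["directionality"] == "none"


class TestCovariateCorrelation:
    def _summary(self):
        return pd.DataFrame(
            {"gene": "g", "metric": "peripheral",
             "cell_type": ["A", "B", "C", "D"],
             "median_score": [0.1, 0.2, 0.3, 0.4],
             "effect_size": [0.1, 0.2, 0.3, 0.4]}
        )

    def test_perfect_correlations(self):
        s = self._summary()
        cov = pd.DataFrame({"gene": "g", "cell_type": list("ABCD"),
                            "value": [0.1, 0.2, 0.3, 0.4]})
        out = correlate_with_covariate(s, cov)
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        cov["value"] = -cov["value"]
        out = correlate_with_covariate(s, cov)
        assert out.iloc[0]["r"] == pytest.approx(-1.0)

    def test_constant_covariate_skipped(self):
        cov = pd.DataFrame({"gene": "g", "cell_type": list("ABCD"), "value": 1.0})
        out = correlate_with_covariate(self._summary(), cov)
        assert out.empty

    def test_too_few_celltypes_skipped(self):
        cov = pd.DataFrame({"gene": "g", "cell_type": ["A", "B"], "value": [1.0, 2.0]})
        assert correlate_with_covariate(self._summary(), cov).empty

    def test_noisy_linear_relation_recovered(self):
        rng = np.random.default_rng(8)
        types = [f"T{i}" for i in range(12)]
        eff = np.linspace(-0.5, 0.5, 12)
        s = pd.DataFrame({"gene": "g", "metric": "punctate", "cell_type": types,
                          "median_score": eff, "effect_size": eff})
        cov = pd.DataFrame({"gene": "g", "cell_type": types,
                            "value": 2.0 * eff + rng.normal(0, 0.05, 12)})
        out = correlate_with_covariate(s, cov)
        assert out.iloc[0]["r"] > 0.9 and out.iloc[0]["significant"]


class TestTypeIControl:
    def test_bh_families_control_false_positives_across_permuted_runs(self):
        """Over 20 permuted-null runs (all four metrics, BH at 0.05), the
        per-family any-discovery rate stays at or below the nominal level.

        Under the global null, BH makes at least one false call in a
        family with probability alpha, so across 20 runs x 4 metric
        families = 80 families the number with any discovery is
        Binomial(80, 0.05): <= 9 at the 99.4th percentile, and most runs
        (clean probability 0.95^4 ~ 0.81) have zero discoveries anywhere.
        """
        clean_runs = 0
        dirty_families = 0
        for rep in range(20):
            cfg = SimulationConfig(n_cells=44, n_celltypes=2, n_genes=12,
                                   spots_per_cell=250.0, seed=100 + rep)
            ds, _ = generate_dataset(cfg)
            perm = permute_gene_labels(ds, seed=rep)
            _, summary = run(
                perm, seed=rep, permutations=200,
                filter_config=FilterConfig(min_cells_per_group=20),
            )
            per_metric = summary.groupby("metric")["significant"].sum()
            dirty_families += int((per_metric > 0).sum())
            if int(summary["significant"].sum()) == 0:
                clean_runs += 1
        assert dirty_families <= 9
        assert clean_runs >= 12
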