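import numpy as np
import pandas as pd
import pytest

from rapidwashout.benchmarks import icc2k_oracle, pearson_oracle
from rapidwashout.stats import (RatingTable, compare_volumes, icc, icc2k,
                                likert_agreement_summary, pearson, tukey_hsd)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


class TestICC:
    def test_perfect_agreement_is_one(self):
        vals = np.arange(10.0).reshape(-1, 1) * 100
        table = np.hstack([vals, vals])
        res = icc2k(table)
        assert res.value == pytest.approx(1.0, abs=1e-12)
        assert res.interpretation == "excellent"

    def test_constant_offset_absolute_vs_consistency(self):
        r1 = np.arange(8.0) * 50
        table = np.column_stack([r1, r1 + 200.0])
        assert icc(table, form="2k").value < 1.0
        assert icc(table, form="3k").value == pytest.approx(1.0, abs=1e-12)

    def test_fixed_table_matches_oracle(self):
        table = np.array([[1200.0, 1310.0], [640.0, 700.0], [2480.0, 2300.0],
                          [150.0, 180.0], [3620.0, 3500.0], [940.0, 1010.0]])
        assert icc2k(table).value == pytest.approx(icc2k_oracle(table), abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = int(rng.integers(3, 12)), int(rng.integers(2, 5))
        x = rng.normal(1000, 300, (n, 1)) + rng.normal(0, 100, (n, k))
        assert icc2k(x).value == pytest.approx(icc2k_oracle(x), abs=1e-10)

    def test_matches_pingouin_estimate_and_ci(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(1000, 400, (9, 1)) + rng.normal(0, 120, (9, 3))
        res = icc2k(x)
        long = pd.DataFrame({
            "target": np.repeat(np.arange(9), 3),
            "rater": np.tile(np.arange(3), 9),
            "value": x.ravel(),
        })
        pg = pingouin.intraclass_corr(long, targets="target", raters="rater",
                                      ratings="value")
        row = pg[pg.Type == "ICC(A,k)"].iloc[0]
        assert res.value == pytest.approx(row.ICC, abs=1e-8)
        # pingouin rounds the reported CI to 2 decimals
        assert res.ci95[0] == pytest.approx(row.CI95[0], abs=6e-3)
        assert res.ci95[1] == pytest.approx(row.CI95[1], abs=6e-3)

    def test_rescaling_invariance_mm3_vs_cm3(self, rng):
        x = rng.normal(2000, 500, (8, 2))
        assert icc2k(x).value == pytest.approx(icc2k(x / 1000.0).value, abs=1e-12)

    def test_incomplete_or_tiny_tables_rejected(self):
        with pytest.raises(ValueError):
            icc2k(np.array([[1.0, 2.0]]))
        bad = np.array([[1.0, 2.0], [3.0, np.nan]])
        with pytest.raises(ValueError):
            icc2k(bad)

    def test_zero_between_target_variance_flagged(self):
        table = np.array([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        res = icc2k(table)
        assert res.degenerate
        assert np.isnan(res.value)


class TestPearson:
    def test_perfect_correlations(self, rng):
        x = rng.normal(size=10)
        r, r2, _ = pearson(x, x)
        assert r == pytest.approx(1.0)
        r, _, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_fixed_table_matches_covariance_definition(self):
        x = [1.0, 2.0, 4.0, 7.0, 11.0]
        y = [2.0, 3.0, 3.5, 8.0, 12.0]
        r, r2, p = pearson(x, y)
        assert r == pytest.approx(pearson_oracle(x, y), abs=1e-12)
        assert r2 == pytest.approx(r * r, abs=1e-15)
        assert 0 < p < 1

    @pytest.mark.parametrize("seed", range(5))
    def test_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r0 = pearson(x, y)[0]
        r1 = pearson(3.0 * x + 7.0, y)[0]
        r2 = pearson(x, 0.25 * y - 2.0)[0]
        assert r0 == pytest.approx(r1, abs=1e-12)
        assert r0 == pytest.approx(r2, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTukey:
    def test_identical_groups_not_significant(self):
        g = np.arange(10.0)
        table = tukey_hsd([g, g.copy(), g.copy()])
        assert (table.p_adj > 0.99).all()
        assert len(table) == 3  # 3 choose 2 comparisons

    def test_far_separated_groups_significant(self, rng):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(10.0, 1.0, 10)  # 10 sigma shift
        table = tukey_hsd({"ctrl": a, "treat": b})
        assert table.p_adj.iloc[0] < 0.001
        assert table.group_a.iloc[0] == "ctrl"

    def test_adjusted_p_never_below_unadjusted(self, rng):
        from rapidwashout.benchmarks import pooled_pairwise_p
        groups = [rng.normal(m, 1.0, 8) for m in (0.0, 0.4, 1.0, 2.0)]
        table = tukey_hsd(groups)
        for _, row in table.iterrows():
            ia = int(row.group_a.replace("group", "")) - 1
            ib = int(row.group_b.replace("group", "")) - 1
            assert row.p_adj >= pooled_pairwise_p(groups, ia, ib) - 1e-12

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd([np.arange(5.0)])


class TestCompareVolumes:
    def test_identical_lists(self):
        v = [100.0, 250.0, 300.0, 80.0]
        res = compare_volumes(v, v, paired=True)
        assert res.t.iloc[0] == 0.0
        assert res.p.iloc[0] == 1.0

    def test_large_shift_significant(self, rng):
        a = rng.normal(100.0, 1.0, 10)
        res = compare_volumes(a, a + 10.0, paired=True)
        assert res.p.iloc[0] < 0.001

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            compare_volumes([1.0], [2.0])

    def test_subgroup_descriptives_shape(self, rng):
        perf = rng.normal(1000, 100, 8)
        wash = rng.normal(1000, 100, 8)
        sub = ["gb"] * 4 + ["met"] * 4
        res = compare_volumes(perf, wash, paired=True, subgroup=sub)
        assert set(res.subgroup) == {"gb", "met"}
        assert {"perfusion_mean_mm3", "washout_sd_mm3", "t", "p"} <= set(res.columns)


class TestLikert:
    def test_full_agreement(self):
        table = RatingTable(np.full((3, 2), 10.0), subgroup=["a", "a", "a"])
        res = likert_agreement_summary(table)
        assert res.mean_pct.iloc[0] == 100.0
        assert res.sd_pct.iloc[0] == 0.0

    def test_two_identical_scores(self):
        table = RatingTable(np.array([[4.0, 4.0]]))
        res = likert_agreement_summary(table)
        assert res.mean_pct.iloc[0] == 40.0
        assert res.sd_pct.iloc[0] == 0.0

    def test_sd_conventions(self):
        table = RatingTable(np.array([[3.0], [7.0]]))
        sample = likert_agreement_summary(table, ddof=1)
        population = likert_agreement_summary(table, ddof=0)
        assert sample.mean_pct.iloc[0] == 50.0
        assert sample.sd_pct.iloc[0] == pytest.approx(28.284271, abs=1e-5)
        assert population.sd_pct.iloc[0] == pytest.approx(20.0)

    def test_single_row_subgroup_flagged(self):
        table = RatingTable(np.array([[7.0]]), subgroup=["lymphoma"])
        res = likert_agreement_summary(table)
        assert res.sd_pct.iloc[0] == 0.0
        assert bool(res.sd_flagged.iloc[0])

    def test_non_integer_scores_rejected(self):
        with pytest.raises(ValueError):
            likert_agreement_summary(RatingTable(np.array([[3.5, 4.0]])))
        with pytest.raises(ValueError):
            likert_agreement_summary(RatingTable(np.array([[11.0, 4.0]])))
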