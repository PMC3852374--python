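import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oracles import naive_pearson, naive_spearman, naive_welch
from noiseplast import coupling as cp
from noiseplast import io_formats as io


class TestSpearman:
    def test_perfect_monotone(self):
        assert cp.spearman([1, 2, 3], [10, 20, 30])[0] == 1.0
        assert cp.spearman([1, 2, 3], [30, 20, 10])[0] == -1.0

    def test_extreme_rho_reports_smallest_positive_p(self):
        _, p = cp.spearman([1, 2, 3], [10, 20, 30])
        assert p == np.finfo(float).tiny

    def test_hand_computed_tie_example(self):
        rho, _ = cp.spearman([1, 2, 2, 3], [1, 3, 2, 4])
        assert rho == pytest.approx(4.5 / np.sqrt(22.5), abs=1e-12)
        assert rho == pytest.approx(0.94868, abs=1e-5)

    def test_constant_vector_raises(self):
        with pytest.raises(cp.UndefinedCorrelationError):
            cp.spearman([1, 1, 1], [1, 2, 3])

    def test_agrees_with_scipy(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 200))
            x = rng.normal(size=n).round(1)
            y = rng.normal(size=n).round(1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = cp.spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            if abs(rho) < 0.999:
                assert p == pytest.approx(ref.pvalue, rel=1e-8)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 100))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        rho0, p0 = cp.spearman(x, y)
        rho1, p1 = cp.spearman(np.exp(3 * x), y ** 3 + 5 * y)  # strictly increasing
        assert rho1 == pytest.approx(rho0, abs=1e-12)
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_permutation_p_close_to_t_approximation(self, rng):
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        _, p_t = cp.spearman(x, y)
        _, p_perm = cp.spearman(x, y, permutations=2000, rng=rng)
        assert p_perm == pytest.approx(p_t, abs=0.02)


class TestPearson:
    def test_exact_linear(self):
        x = np.array([0.0, 1, 2, 5])
        assert cp.pearson(x, 2 * x + 1)[0] == 1.0

    def test_orthogonalized_residual_uncorrelated(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        fit = stats.linregress(x, y)
        resid = y - fit.intercept - fit.slope * x
        r, _ = cp.pearson(x, resid)
        assert abs(r) < 1e-10

    def test_hand_computed_example(self):
        r, _ = cp.pearson([1, 2, 3], [1, 1, 4])
        assert r == pytest.approx(3 / np.sqrt(12), abs=1e-12)
        assert r == pytest.approx(0.866025, abs=1e-6)


class TestWelch:
    def test_identical_samples(self):
        t, p = cp.welch_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_separated_samples_drive_p_to_zero(self, rng):
        a = rng.normal(0, 1e-6, size=4)
        b = 1.0 + rng.normal(0, 1e-6, size=4)
        _, p = cp.welch_t_test(a, b)
        assert p < 1e-10

    def test_hand_computed_example(self):
        t, p = cp.welch_t_test([1.0, 2, 3, 4], [3.0, 4, 5, 6])
        assert t == pytest.approx(-2.19089, abs=1e-5)
        assert p == pytest.approx(0.0712, abs=5e-4)

    def test_degenerate_equal_constants_give_p_one(self):
        assert cp.welch_t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)


class TestOracleEquivalence:
    """The statistics match literal brute-force formulations, ties included."""

    def test_spearman_and_pearson_match_naive(self, rng):
        for _ in range(250):
            n = int(rng.integers(3, 1000))
            x = rng.normal(size=n).round(int(rng.integers(0, 3)))
            y = rng.normal(size=n).round(int(rng.integers(0, 3)))
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = cp.spearman(x, y)
            rho_o, p_o = naive_spearman(x, y)
            assert abs(rho - rho_o) <= 1e-12 and abs(p - p_o) <= 1e-12
            r, pp = cp.pearson(x, y)
            r_o, pp_o = naive_pearson(x, y)
            assert abs(r - r_o) <= 1e-12 and abs(pp - pp_o) <= 1e-12

    def test_welch_matches_naive(self, rng):
        for _ in range(250):
            na, nb = int(rng.integers(2, 500)), int(rng.integers(2, 500))
            a = rng.normal(size=na)
            b = rng.normal(loc=rng.normal(), size=nb)
            t, p = cp.welch_t_test(a, b)
            t_o, p_o = naive_welch(a, b)
            assert abs(t - t_o) <= 1e-12 and abs(p - p_o) <= 1e-12


def _metrics_frame(n, rng, rho=0.0):
    z = rng.normal(size=n)
    w = rho * z + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
    return pd.DataFrame({
        "gene_id": [f"g{i:04d}" for i in range(n)],
        "mean_expr": rng.uniform(6, 13, size=n),
        "sd_expr": np.abs(rng.normal(size=n)),
        "noise": z, "plasticity_resid": w, "plasticity_rm": w,
    })


class TestBinning:
    def test_even_split_and_lowest_bin_contains_lowest_means(self, rng):
        m = _metrics_frame(10, rng)
        bins = cp.bin_by_expression(m, 5)
        assert bins["n"].tolist() == [2, 2, 2, 2, 2]
        two_lowest = set(m.nsmallest(2, "mean_expr")["gene_id"])
        assert bins.loc[0, "expr_hi"] == m.loc[m["gene_id"].isin(two_lowest), "mean_expr"].max()

    def test_remainder_genes_go_to_lowest_bins(self, rng):
        bins = cp.bin_by_expression(_metrics_frame(11, rng), 5)
        assert bins["n"].tolist() == [3, 2, 2, 2, 2]

    def test_bins_partition_the_gene_set(self, rng):
        for n in (37, 100, 101, 104):
            m = _metrics_frame(n, rng)
            bins = cp.bin_by_expression(m, 5)
            assert bins["n"].sum() == n
            assert bins["n"].max() - bins["n"].min() <= 1

    def test_constant_bin_flagged_undefined(self, rng):
        m = _metrics_frame(15, rng)
        m["noise"] = 1.0
        bins = cp.bin_by_expression(m, 5)
        assert bins["undefined"].all() and not bins["significant"].any()


class TestSlowGrowth:
    def _annot(self, growth, essential=None):
        n = len(growth)
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                             "essential": essential or [False] * n,
                             "growth_rate": growth,
                             "dosage_sensitive": [False] * n,
                             "stress_response": [False] * n})

    def test_slowest_of_ten_flagged(self):
        a = cp.derive_slow_growth(self._annot(list(np.linspace(0.5, 1.4, 10))), 0.10)
        assert a["slow_growth"].sum() == 1
        assert a.loc[a["slow_growth"], "gene_id"].tolist() == ["g0"]

    def test_essential_gene_never_flagged(self):
        growth = [0.1] + list(np.linspace(0.5, 1.4, 10))
        ess = [True] + [False] * 10
        a = cp.derive_slow_growth(self._annot(growth, ess), 0.10)
        assert not a.loc[a["essential"], "slow_growth"].any()
        assert a["slow_growth"].sum() == 1 and a.loc[1, "slow_growth"]

    def test_boundary_ties_all_included(self):
        # 20 genes, fraction 0.10 -> k = 2; two genes tied at the boundary value
        growth = [0.5, 0.6, 0.6] + list(np.linspace(0.8, 1.4, 17))
        a = cp.derive_slow_growth(self._annot(growth), 0.10)
        assert a["slow_growth"].sum() == 3  # not 2: boundary ties included

    def test_no_growth_data_is_hard_error(self):
        with pytest.raises(io.InputError):
            cp.derive_slow_growth(self._annot([np.nan, np.nan]), 0.10)


class TestRegulonsAndClasses:
    def test_regulator_threshold(self):
        genes = [f"g{i}" for i in range(60)]
        reg_map = {"A": set(genes[:29]), "B": set(genes[:30])}
        kept = cp.filter_regulons(reg_map, genes, 30)
        assert "A" not in kept and "B" in kept

    def test_targets_counted_after_join(self):
        reg_map = {"A": {f"g{i}" for i in range(40)}}
        analyzed = [f"g{i}" for i in range(25)]  # only 25 of 40 targets analyzed
        assert cp.filter_regulons(reg_map, analyzed, 30) == {}

    def test_all_class_equals_global_spearman(self, rng):
        m = _metrics_frame(200, rng, rho=0.3)
        cfg = io.AnalysisConfig()
        res = cp.coupling_by_class(m, [cp.ClassSpec("all", set(m["gene_id"]))], cfg)
        rho, p = cp.spearman(m["noise"], m["plasticity_resid"])
        assert res.loc[0, "rho"] == rho and res.loc[0, "p_value"] == p

    def test_set_algebra_class_matches_naive_oracle(self, small_dataset):
        d = small_dataset
        cfg = io.AnalysisConfig()
        stress = d["truth"].memberships["stress"]
        s38 = d["truth"].memberships["Sigma38"]
        m = _metrics_frame(300, np.random.default_rng(0))
        m["gene_id"] = list(d["truth"].genes["gene_id"])
        spec = cp.ClassSpec("stress_minus_Sigma38", stress - s38)
        res = cp.coupling_by_class(m, [spec], cfg)
        assert res.loc[0, "n"] == len(stress - s38)

    def test_small_class_flagged_underpowered_not_dropped(self, rng):
        m = _metrics_frame(100, rng)
        spec = cp.ClassSpec("tiny", set(m["gene_id"].iloc[:5]))
        res = cp.coupling_by_class(m, [spec], io.AnalysisConfig())
        assert len(res) == 1
        assert res.loc[0, "underpowered"] and not res.loc[0, "significant"]

    def test_build_class_specs_covers_expected_labels(self, small_dataset):
        d = small_dataset
        cfg = io.AnalysisConfig(min_regulon_targets=20)
        m = _metrics_frame(300, np.random.default_rng(0))
        m["gene_id"] = list(d["truth"].genes["gene_id"])
        annot = cp.derive_slow_growth(d["annot"], 0.10)
        specs = cp.build_class_specs(m, annot, d["regulons"], cfg)
        labels = {s.label for s in specs}
        for expected in ["all", "highly_expressed", "essential", "slow_growth",
                         "dosage_sensitive", "other", "highly_expressed_other",
                         "CRP", "Sigma38", "stress", "stress_minus_Sigma38",
                         "Sigma38_minus_stress"]:
            assert expected in labels
        assert any(lbl.startswith("CRP:") for lbl in labels)  # mode slices


class TestExpressionMatching:
    def _means(self, values):
        return pd.Series(values, index=[f"g{i}" for i in range(len(values))])

    def test_already_matched_class_is_unchanged(self, rng):
        vals = rng.normal(10, 1, size=60)
        means = self._means(vals)
        focal = list(means.index[:20])
        background = list(means.index[20:])
        trimmed, removed, p = cp.expression_matched_subset(
            focal, background, means, side="low")
        assert removed == 0 and sorted(trimmed) == sorted(focal) and p >= 0.05

    def test_single_outlier_is_the_only_removal(self):
        # slightly low focal class whose significance hinges on one extreme
        # gene: brute force over removal counts shows k = 1 is minimal
        r = np.random.default_rng(4)
        bg_vals = r.normal(10, 1, 200)
        focal_vals = np.concatenate([r.normal(9.7, 1, 40), [5.0]])
        means = self._means(np.concatenate([focal_vals, bg_vals]))
        focal = list(means.index[:41])
        background = list(means.index[41:])
        _, p0 = cp.welch_t_test(focal_vals, bg_vals)
        assert p0 < 0.05  # fixture precondition
        trimmed, removed, p = cp.expression_matched_subset(
            focal, background, means, side="low")
        assert removed == 1 and p >= 0.05
        assert means.index[40] not in trimmed  # the planted outlier went first

    def test_removals_only_from_declared_extreme_and_final_p_ok(self, rng):
        means = self._means(np.concatenate([rng.normal(9.5, 1, size=50),
                                            rng.normal(10, 1, size=150)]))
        focal = list(means.index[:50])
        background = list(means.index[50:])
        trimmed, removed, p = cp.expression_matched_subset(
            focal, background, means, side="low")
        assert p >= 0.05 and removed > 0
        kept_min = means.loc[trimmed].min()
        removed_genes = set(focal) - set(trimmed)
        assert all(means[g] < kept_min for g in removed_genes)

    def test_unmatchable_classes_raise(self, rng):
        means = self._means(np.concatenate([rng.normal(0, 0.1, size=30),
                                            rng.normal(10, 0.1, size=30)]))
        with pytest.raises(cp.NotMatchableError):
            cp.expression_matched_subset(list(means.index[:30]),
                                         list(means.index[30:]), means, side="low")
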