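import numpy as np
import pandas as pd
import pytest
from scipy import stats

import netstrat as ns
from netstrat.subgroup_stats import DISPLAY_P_FLOOR


class TestEnrichment:
    def test_hand_computed_pearson_formula(self):
        """chi2 on [[30,20],[10,40]] matches n(ad-bc)^2 / (row*col margins)."""
        assignment = pd.Series([1] * 50 + [2] * 50, index=[f"s{i}" for i in range(100)])
        labels = pd.Series(["X"] * 30 + ["Y"] * 20 + ["X"] * 10 + ["Y"] * 40,
                           index=assignment.index)
        table = ns.enrichment_test(assignment, labels)
        row = table[(table.subgroup == 1) & (table.label == "X")].iloc[0]
        expected_chi2 = 100 * (30 * 40 - 20 * 10) ** 2 / (50 * 50 * 40 * 60)
        assert row.chi2_stat == pytest.approx(expected_chi2, rel=1e-12)
        assert row.p_value == pytest.approx(stats.chi2.sf(expected_chi2, 1), rel=1e-12)
        assert row.count_in_subgroup == 30

    def test_proportional_distribution_gives_chi2_zero(self):
        assignment = pd.Series([1] * 40 + [2] * 60, index=[f"s{i}" for i in range(100)])
        # type X at 25% in both subgroups
        labels = pd.Series(["X"] * 10 + ["Y"] * 30 + ["X"] * 15 + ["Y"] * 45,
                           index=assignment.index)
        table = ns.enrichment_test(assignment, labels)
        assert np.allclose(table.chi2_stat, 0.0, atol=1e-12)
        assert np.allclose(table.p_value, 1.0)

    def test_display_p_floored_but_exact_p_kept(self):
        rng = np.random.default_rng(0)
        n = 2000
        assignment = pd.Series([1] * (n // 2) + [2] * (n // 2),
                               index=[f"s{i}" for i in range(n)])
        labels = pd.Series(["X"] * (n // 2) + ["Y"] * (n // 2), index=assignment.index)
        table = ns.enrichment_test(assignment, labels)
        row = table[(table.subgroup == 1) & (table.label == "X")].iloc[0]
        assert row.p_value < DISPLAY_P_FLOOR
        assert row.display_p == DISPLAY_P_FLOOR

    def test_counts_sum_to_subgroup_size(self):
        rng = np.random.default_rng(4)
        idx = [f"s{i}" for i in range(120)]
        assignment = pd.Series(rng.integers(1, 4, size=120), index=idx)
        labels = pd.Series(rng.choice(list("ABCD"), size=120), index=idx)
        table = ns.enrichment_test(assignment, labels)
        for g, block in table.groupby("subgroup"):
            assert block.count_in_subgroup.sum() == (assignment == g).sum()


class TestKaplanMeier:
    def test_distinct_event_times_closed_form_product(self):
        n = 6
        times = np.arange(1.0, n + 1)
        km = ns.km_estimate(times, np.ones(n, dtype=int))
        # S(t_i) = prod_{j<=i} (1 - 1/(n-j+1))
        expected = np.cumprod([1 - 1 / (n - j) for j in range(n)])
        assert np.allclose(km.survival.iloc[1:].to_numpy(), expected, rtol=1e-12)

    def test_all_censored_curve_stays_at_one(self):
        km = ns.km_estimate([5.0, 8.0, 2.0], [0, 0, 0])
        assert (km.survival == 1.0).all()

    def test_curve_non_increasing_starts_at_one(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(100, size=50)
        events = rng.integers(0, 2, size=50)
        if events.sum() == 0:
            events[0] = 1
        km = ns.km_estimate(times, events)
        assert km.survival.iloc[0] == 1.0
        assert (np.diff(km.survival) <= 1e-15).all()

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        times = rng.exponential(50, size=80)
        events = rng.integers(0, 2, size=80)
        km = ns.km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for _, row in km.iloc[1:].iterrows():
            assert row.survival == pytest.approx(
                float(kmf.predict(row.time)), rel=1e-9
            )


class TestLogrank:
    def test_identical_groups_stat_zero_p_one(self):
        times = [3.0, 5.0, 9.0, 12.0]
        events = [1, 0, 1, 1]
        stat, p, flag = ns.logrank_test(times, events, times, events)
        assert stat == 0.0
        assert p == 1.0

    def test_hand_tabulated_six_subject_oracle(self):
        """O/E/V tabulated by hand for 3 subjects per arm."""
        ta, ea = [1.0, 4.0, 6.0], [1, 1, 0]
        tb, tbe = [2.0, 5.0, 7.0], [1, 0, 1]
        # t=1: na=3 nb=3 da=1 -> E=0.5, V=0.25
        # t=2: na=2 nb=3 db=1 -> E=0.4, V=0.24
        # t=4: na=2 nb=2 da=1 -> E=0.5, V=0.25
        # t=7: na=0 nb=1 db=1 -> E=0, V=0
        o_minus_e = (1 - 0.5) + (0 - 2 / 5) + (1 - 0.5) + 0.0
        var = 0.25 + 6 / 25 + 0.25
        stat, p, flag = ns.logrank_test(ta, ea, tb, tbe)
        assert stat == pytest.approx(o_minus_e**2 / var, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(o_minus_e**2 / var, 1), rel=1e-12)

    def test_matches_lifelines_on_random_data(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(3)
        ta = rng.exponential(80, 40)
        tb = rng.exponential(40, 35)
        ea = rng.integers(0, 2, 40)
        eb = rng.integers(0, 2, 35)
        ea[0] = eb[0] = 1
        stat, p, _ = ns.logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_power_under_hazard_ratio_three(self):
        """p < 0.01 in at least 95 of 100 seeds at HR=3, n=100 per arm."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(1.0, 100)
            tb = rng.exponential(1.0 / 3.0, 100)
            _, p, _ = ns.logrank_test(ta, np.ones(100, int), tb, np.ones(100, int))
            hits += p < 0.01
        assert hits >= 95

    def test_zero_variance_flagged(self):
        # single shared censoring pattern, no comparable event times
        stat, p, flag = ns.logrank_test([5.0], [1], [1.0], [0])
        assert p == 1.0
        assert flag == "zero_variance"


class TestFisherExact:
    def test_two_by_two_matches_hypergeometric_enumeration(self):
        table = [[2, 3], [4, 1]]
        p, se = ns.fisher_exact_rxc(table)
        assert se is None
        _, p_scipy = stats.fisher_exact(table, alternative="two-sided")
        assert p == pytest.approx(p_scipy, abs=1e-12)

    def test_random_two_by_two_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            p, _ = ns.fisher_exact_rxc(table)
            _, p_scipy = stats.fisher_exact(table, alternative="two-sided")
            assert p == pytest.approx(p_scipy, abs=1e-10)

    def test_zero_row_invariance(self):
        full = [[3, 5], [0, 0], [6, 2]]
        reduced = [[3, 5], [6, 2]]
        p_full, _ = ns.fisher_exact_rxc(full)
        p_reduced, _ = ns.fisher_exact_rxc(reduced)
        assert p_full == pytest.approx(p_reduced, abs=1e-12)

    def test_identical_column_distributions_p_one(self):
        p, _ = ns.fisher_exact_rxc([[5, 5], [3, 3], [2, 2]])
        assert p == pytest.approx(1.0)

    def test_r_by_c_matches_r_fisher_test(self):
        """4x2 enumeration agrees with R's fisher.test (stats package)."""
        import shutil
        import subprocess

        table = [[8, 2], [3, 7], [5, 5], [1, 9]]
        p, _ = ns.fisher_exact_rxc(table)
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        out = subprocess.run(
            ["Rscript", "-e",
             "cat(fisher.test(matrix(c(8,3,5,1,2,7,5,9),nrow=4))$p.value)"],
            capture_output=True, text=True, check=True,
        )
        assert p == pytest.approx(float(out.stdout.strip()), rel=1e-6)

    def test_monte_carlo_path_close_to_enumeration(self):
        table = [[12, 9], [7, 14], [10, 8]]
        p_exact, _ = ns.fisher_exact_rxc(table)
        p_mc, se = ns.fisher_exact_rxc(table, max_tables=10, n_mc=40000, seed=1)
        assert se is not None
        assert abs(p_mc - p_exact) < 4 * se + 1e-3

    def test_empty_margin_p_one(self):
        p, _ = ns.fisher_exact_rxc([[0, 0], [0, 0]])
        assert p == 1.0


class TestBH:
    def test_step_up_hand_example(self):
        assert np.allclose(ns.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate_inputs(self):
        assert ns.bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(ns.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_direct_step_up_rule(self):
        rng = np.random.default_rng(6)
        p = rng.random(25)
        q = ns.bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        direct = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            direct[i] = running
        assert np.allclose(q, direct, atol=1e-12)


class TestClinicalDrivers:
    def test_survival_comparison_on_cohort(self, small_cohort):
        clin, truth = small_cohort.clinical, small_cohort.truth
        # pick a (subgroup, type) pair with samples on both sides of the contrast
        pair = next(
            (g, t)
            for g in sorted(truth.unique())
            for t in sorted(clin.cancer_type.unique())
            if ((clin.cancer_type == t) & (truth == g)).any()
            and ((clin.cancer_type == t) & (truth != g)).any()
        )
        cmp = ns.compare_survival(clin, truth, *pair)
        assert 0.0 <= cmp.p_value <= 1.0
        assert cmp.km_a.survival.iloc[0] == 1.0
        assert set(cmp.group_a).isdisjoint(cmp.group_b)

    def test_stage_association_table_shape(self, small_cohort):
        table, p, se = ns.stage_association(
            small_cohort.clinical, small_cohort.truth, 1, "T1", feature="stage"
        )
        assert list(table.columns) == ["in_subgroup", "rest"]
        assert 0.0 <= p <= 1.0

    def test_survival_scan_covers_pairs_and_adjusts(self, small_cohort):
        scan = ns.survival_scan(small_cohort.clinical, small_cohort.truth)
        assert {"subgroup", "cancer_type", "p_value", "q_value"} <= set(scan.columns)
        assert (scan.q_value >= scan.p_value - 1e-12).all()

    def test_null_enrichment_calibration(self):
        """Labels independent of the partition: q < 0.05 rate stays near nominal.

        Replicate null cohorts (module_fraction=0, proportional pseudo-type
        labels); the partition is derived from the alteration data alone, so
        enrichment p-values are uniform and BH keeps false discoveries rare.
        """
        rng = np.random.default_rng(12)
        n_reps, flagged, total = 60, 0, 0
        for _ in range(n_reps):
            idx = [f"s{i}" for i in range(90)]
            # partition from data-only clustering is independent of labels;
            # draw both independently to emulate the null cohort
            assignment = pd.Series(rng.integers(1, 4, size=90), index=idx)
            labels = pd.Series(rng.choice(["T1", "T2", "T3"], size=90), index=idx)
            table = ns.enrichment_test(assignment, labels)
            flagged += (table.q_value < 0.05).sum()
            total += len(table)
        rate = flagged / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3 * se

    def test_logrank_type_one_error_nominal(self):
        """Equal-hazard arms: rejection rate at 0.05 within +/- 0.02 (1000 reps)."""
        rejections = 0
        reps = 1000
        for seed in range(reps):
            rng = np.random.default_rng(10_000 + seed)
            ta = rng.exponential(1.0, 60)
            tb = rng.exponential(1.0, 60)
            _, p, _ = ns.logrank_test(ta, np.ones(60, int), tb, np.ones(60, int))
            rejections += p < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02
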