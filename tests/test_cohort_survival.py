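import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbpanel.cohort_survival import (
    PatientRecord,
    km_estimate,
    logrank_test,
    mutual_exclusivity,
    prevalence_table,
    stratify_and_summarize,
)
from oracles import fisher_exact_two_sided, km_at, km_brute_force, logrank_two_group_brute_force


class TestPrevalence:
    def _matrix(self, cells):
        return pd.DataFrame(cells).T  # dict of patient -> {gene: cell}

    def test_twelve_of_72_is_16_7_percent(self):
        cells = {f"P{i}": {"ALK": "snv_indel" if i < 12 else "none"} for i in range(72)}
        table = prevalence_table(self._matrix(cells))
        row = table[table["gene"] == "ALK"].iloc[0]
        assert row["n_altered"] == 12
        assert row["percent"] == 16.7

    def test_all_none_matrix_zero_percent(self):
        cells = {f"P{i}": {"ALK": "none", "ATM": "none"} for i in range(10)}
        table = prevalence_table(self._matrix(cells))
        assert (table["percent"] == 0.0).all()

    def test_patient_counted_once_per_gene(self):
        # the matrix cell already collapses multiple variants; 'both' counts once
        cells = {"P1": {"ALK": "both"}, "P2": {"ALK": "none"}}
        table = prevalence_table(self._matrix(cells))
        assert table.iloc[0]["n_altered"] == 1

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            prevalence_table(pd.DataFrame())

    def test_fractions_in_unit_interval_and_additive(self, rng):
        cells = {
            f"P{i}": {"G": "snv_indel" if rng.random() < 0.4 else "none"} for i in range(50)
        }
        m = self._matrix(cells)
        t1 = prevalence_table(m)
        assert 0.0 <= t1.iloc[0]["fraction"] <= 1.0
        m2 = m.copy()
        m2.loc["P_extra"] = "snv_indel"
        t2 = prevalence_table(m2)
        assert t2.iloc[0]["n_altered"] == t1.iloc[0]["n_altered"] + 1


class TestKaplanMeier:
    def test_five_subject_worked_example(self):
        # censored 6, event 12, censored 18, event 24, censored 40
        times = [6, 12, 18, 24, 40]
        events = [0, 1, 0, 1, 0]
        curve = km_estimate(times, events)
        assert curve.survival_at(36) == pytest.approx(0.375)  # (3/4) * (1/2)

    def test_four_subject_worked_example(self):
        # censored 6, event 12, event 24, censored 40 -> (2/3) * (1/2) = 1/3
        curve = km_estimate([6, 12, 24, 40], [0, 1, 1, 0])
        assert curve.survival_at(36) == pytest.approx(1.0 / 3.0)

    def test_no_events_survival_one_se_zero(self):
        curve = km_estimate([5, 10, 15], [0, 0, 0])
        assert curve.survival_at(100) == 1.0
        assert curve.se_at(100) == 0.0

    def test_all_events_distinct_times_empirical_survival(self):
        n = 7
        times = np.arange(1, n + 1, dtype=float)
        curve = km_estimate(times, np.ones(n, dtype=int))
        for k, t in enumerate(times, start=1):
            assert curve.survival_at(t) == pytest.approx((n - k) / n)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_greenwood_se_zero_before_first_event(self):
        curve = km_estimate([10, 20], [1, 1])
        assert curve.se_at(5) == 0.0
        assert curve.survival_at(5) == 1.0

    def test_greenwood_hand_computed(self):
        # events at 1 and 2, n=3 with a censoring at 1.5
        # t=1: n=3, d=1 -> S=2/3, gw=1/(3*2)
        # t=2: n=1, d=1 -> S=0, se degenerate 0
        curve = km_estimate([1, 1.5, 2], [1, 0, 1])
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.se_at(1) == pytest.approx((2 / 3) * np.sqrt(1 / 6))
        assert curve.survival_at(2) == pytest.approx(0.0)

    @given(
        st.lists(
            st.tuples(st.integers(min_value=0, max_value=6), st.integers(min_value=0, max_value=1)),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle_exhaustive_ties(self, subjects):
        times = [float(t) for t, _ in subjects]
        events = [e for _, e in subjects]
        curve = km_estimate(times, events)
        for t, s in km_brute_force(times, events):
            assert curve.survival_at(t) == pytest.approx(s, abs=1e-10)
        for horizon in (0.0, 2.5, 6.0, 10.0):
            assert curve.survival_at(horizon) == pytest.approx(
                km_at(times, events, horizon), abs=1e-10
            )

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(20, size=60).round(1)
        events = rng.integers(0, 2, size=60)
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in np.unique(times[events == 1]):
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-9
            )


class TestLogRank:
    def test_identical_groups_statistic_zero_p_one(self):
        times = [3, 5, 7, 9]
        events = [1, 0, 1, 1]
        chi2, df, p = logrank_test(
            ["a"] * 4 + ["b"] * 4, times + times, events + events
        )
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        times = rng.exponential(10, size=30).round(1)
        events = rng.integers(0, 2, size=30)
        groups = rng.integers(0, 2, size=30)
        for g in np.unique(groups):
            assert (groups == g).any()
        a = logrank_test(groups, times, events)
        b = logrank_test(1 - groups, times, events)
        assert a[0] == pytest.approx(b[0], abs=1e-10)

    def test_subject_order_permutation_invariance(self, rng):
        times = rng.exponential(10, size=25).round(1)
        events = rng.integers(0, 2, size=25)
        groups = np.array(["x"] * 13 + ["y"] * 12)
        a = logrank_test(groups, times, events)
        perm = rng.permutation(25)
        b = logrank_test(groups[perm], times[perm], events[perm])
        assert a[0] == pytest.approx(b[0], abs=1e-10)

    def test_six_subject_example_matches_brute_force(self):
        groups = ["a", "a", "a", "b", "b", "b"]
        times = [2.0, 4.0, 6.0, 3.0, 5.0, 7.0]
        events = [1, 1, 0, 1, 0, 1]
        chi2, df, p = logrank_test(groups, times, events)
        assert df == 1
        assert chi2 == pytest.approx(
            logrank_two_group_brute_force(groups, times, events), abs=1e-10
        )

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_random_small_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        groups = rng.integers(0, 2, size=n)
        if len(np.unique(groups)) < 2:
            groups[0], groups[-1] = 0, 1
        times = rng.integers(1, 6, size=n).astype(float)
        events = rng.integers(0, 2, size=n)
        chi2, _, _ = logrank_test(groups, times, events)
        assert chi2 == pytest.approx(
            logrank_two_group_brute_force(list(groups), list(times), list(events)),
            abs=1e-10,
        )

    def test_matches_lifelines_multigroup(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        times = rng.exponential(12, size=60).round(1)
        events = rng.integers(0, 2, size=60)
        groups = rng.integers(0, 3, size=60)
        chi2, df, p = logrank_test(groups, times, events)
        ll = multivariate_logrank_test(times, groups, events)
        assert chi2 == pytest.approx(ll.test_statistic, abs=1e-8)
        assert p == pytest.approx(ll.p_value, abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(["a", "a"], [1.0, 2.0], [1, 1])


class TestMutualExclusivity:
    def _matrix(self, arid1b_patients, n=10):
        cells = {
            f"P{i}": {"ARID1B": "snv_indel" if i in arid1b_patients else "none"}
            for i in range(n)
        }
        return pd.DataFrame(cells).T

    def test_zero_overlap(self):
        m = self._matrix({0, 1, 2})
        mycn = pd.Series([False] * 3 + [True] * 3 + [False] * 4, index=m.index)
        overlap, p = mutual_exclusivity(m, ["ARID1A", "ARID1B"], mycn)
        assert overlap == 0

    def test_constructed_overlap_two(self):
        m = self._matrix({0, 1, 2})
        mycn = pd.Series([True, True] + [False] * 8, index=m.index)
        overlap, _ = mutual_exclusivity(m, ["ARID1B"], mycn)
        assert overlap == 2

    def test_fisher_p_matches_enumeration(self):
        # 2x2 table (3, 0; 5, 64)
        n = 72
        cells = {
            f"P{i}": {"ARID1B": "snv_indel" if i < 3 else "none"} for i in range(n)
        }
        m = pd.DataFrame(cells).T
        mycn = pd.Series([False] * 3 + [True] * 5 + [False] * 64, index=m.index)
        overlap, p = mutual_exclusivity(m, ["ARID1B"], mycn)
        assert overlap == 0
        assert p == pytest.approx(fisher_exact_two_sided(0, 3, 5, 64), rel=1e-9)

    @pytest.mark.parametrize("a,b,c,d", [(0, 3, 5, 64), (2, 4, 1, 10), (3, 0, 5, 64)])
    def test_fisher_oracle_agreement_scipy(self, a, b, c, d):
        from scipy import stats

        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert p == pytest.approx(fisher_exact_two_sided(a, b, c, d), rel=1e-9)


def _patient(pid, time, event, risk="high", mycn=False):
    return PatientRecord(
        patient_id=pid, risk_group=risk, mycn_amplified=mycn,
        rfs_time=time, rfs_event=event, os_time=time, os_event=event,
    )


class TestStratifyAndSummarize:
    def _cohort_and_matrix(self):
        # 4 high-risk ARID1B-altered: censored 6, event 12, event 24, censored 40
        patients = [
            _patient("A1", 6, 0), _patient("A2", 12, 1),
            _patient("A3", 24, 1), _patient("A4", 40, 0),
        ]
        # neither-stratum subjects
        patients += [_patient(f"N{i}", 40, 0) for i in range(5)]
        # MYCN-amplified subjects
        patients += [_patient("M1", 10, 1, mycn=True), _patient("M2", 40, 0, mycn=True)]
        cells = {
            p.patient_id: {"ARID1B": "snv_indel" if p.patient_id.startswith("A") else "none"}
            for p in patients
        }
        return patients, pd.DataFrame(cells).T

    def test_arid1b_stratum_matches_worked_example(self):
        patients, matrix = self._cohort_and_matrix()
        summary = stratify_and_summarize(patients, matrix, horizon=36.0, endpoint="os",
                                         high_risk_only=True)
        s = summary["strata"]["arid1b"]
        assert s["n"] == 4
        assert s["survival_at_horizon"] == pytest.approx(1.0 / 3.0)

    def test_stratum_counts_and_precedence(self):
        patients, matrix = self._cohort_and_matrix()
        summary = stratify_and_summarize(patients, matrix, horizon=36.0)
        assert summary["strata"]["mycn"]["n"] == 2
        assert summary["strata"]["neither"]["n"] == 5

    def test_empty_stratum_reported_not_raised(self):
        patients = [_patient(f"N{i}", 40, 0) for i in range(4)]
        cells = {p.patient_id: {"ARID1B": "none"} for p in patients}
        summary = stratify_and_summarize(patients, pd.DataFrame(cells).T, horizon=36.0)
        assert summary["strata"]["arid1b"]["n"] == 0
        assert summary["strata"]["arid1b"]["survival_at_horizon"] is None
        assert summary["strata"]["neither"]["n"] == 4

    def test_high_risk_filter(self):
        patients = [
            _patient("H1", 40, 0, risk="high"),
            _patient("L1", 40, 0, risk="non-high"),
        ]
        cells = {p.patient_id: {"ARID1B": "none"} for p in patients}
        summary = stratify_and_summarize(patients, pd.DataFrame(cells).T, horizon=36.0,
                                         high_risk_only=True)
        assert summary["strata"]["neither"]["n"] == 1

    def test_two_group_split_present(self):
        patients, matrix = self._cohort_and_matrix()
        summary = stratify_and_summarize(patients, matrix, horizon=36.0)
        assert summary["two_group"]["altered"]["n"] == 4
        assert summary["two_group"]["wildtype"]["n"] == 7
        assert "logrank" in summary["two_group"]


class TestSurvivalRecovery:
    def test_km_at_horizon_recovers_configured_fraction(self):
        # 30 cohorts of n=300 at S(36) = 0.905 with 20% censoring
        from nbpanel.synthetic_cohort import child_rng, simulate_survival

        rng = child_rng(42, 0)
        estimates = []
        for _ in range(30):
            draws = [simulate_survival(0.905, 36.0, 0.2, rng) for _ in range(300)]
            curve = km_estimate([t for t, _ in draws], [e for _, e in draws])
            estimates.append(curve.survival_at(36.0))
        mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(float(np.mean(estimates)) - 0.905) < 3 * max(mc_se, 1e-3)
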