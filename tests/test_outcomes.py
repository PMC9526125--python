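"""Person-time, exact Poisson CIs, rate comparison, stratification."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from cmrextract.outcomes import (
    compare_rates,
    incidence_rate,
    person_time,
    select_report,
    simulate_cohort,
    stratify,
    threshold_rule,
    DAYS_PER_YEAR,
)


def _cohort_row(pid, cmr, event=None, death=None, censor=None):
    return {
        "person_id": pid,
        "cmr_date": cmr,
        "event_date": event,
        "death_date": death,
        "last_encounter_date": censor,
    }


class TestPersonTime:
    def test_event_counted_with_its_time(self):
        df = pd.DataFrame(
            [_cohort_row("p1", date(2010, 1, 1), event=date(2012, 1, 1),
                         censor=date(2015, 1, 1))]
        )
        pt = person_time(df)
        assert pt.loc[0, "events"] == 1
        assert pt.loc[0, "person_years"] == pytest.approx(730 / DAYS_PER_YEAR)

    def test_censored_person_contributes_time_only(self):
        df = pd.DataFrame(
            [_cohort_row("p1", date(2010, 1, 1), censor=date(2013, 1, 1))]
        )
        pt = person_time(df)
        assert pt.loc[0, "events"] == 0
        assert pt.loc[0, "person_years"] == pytest.approx(1096 / DAYS_PER_YEAR)

    def test_death_before_event_censors_it(self):
        df = pd.DataFrame(
            [_cohort_row("p1", date(2010, 1, 1), event=date(2014, 1, 1),
                         death=date(2012, 1, 1), censor=date(2015, 1, 1))]
        )
        pt = person_time(df)
        assert pt.loc[0, "events"] == 0

    def test_three_person_hand_summed(self):
        df = pd.DataFrame(
            [
                _cohort_row("p1", date(2010, 1, 1), event=date(2011, 1, 1),
                            censor=date(2015, 1, 1)),
                _cohort_row("p2", date(2010, 1, 1), censor=date(2012, 1, 1)),
                _cohort_row("p3", date(2010, 1, 1), event=date(2013, 1, 1),
                            censor=date(2013, 6, 1)),
            ]
        )
        pt = person_time(df)
        expect_days = 365 + 730 + 1096
        assert pt.loc[0, "events"] == 2
        assert pt.loc[0, "person_years"] == pytest.approx(expect_days / DAYS_PER_YEAR)

    def test_negative_followup_names_person(self):
        df = pd.DataFrame(
            [_cohort_row("bad_person", date(2015, 1, 1), censor=date(2010, 1, 1))]
        )
        with pytest.raises(ValueError, match="bad_person"):
            person_time(df)

    def test_stratified_person_years_conserved(self):
        cohort = simulate_cohort(400, seed=1, stratum_rates={"a": 0.05, "b": 0.10})
        total = person_time(cohort).loc[0, "person_years"]
        per = person_time(cohort, by="stratum")["person_years"].sum()
        assert per == pytest.approx(total)


class TestIncidenceRate:
    def test_rate_arithmetic(self):
        rr = incidence_rate(10, 500.0)
        assert rr.rate == pytest.approx(2.0)

    def test_zero_events_lower_bound_zero(self):
        rr = incidence_rate(0, 100.0)
        assert rr.lo == 0.0 and rr.hi > 0.0

    def test_bounds_bracket_rate(self):
        rr = incidence_rate(17, 812.0)
        assert rr.lo <= rr.rate <= rr.hi

    def test_exact_ci_matches_chi_square_closed_form(self):
        rr = incidence_rate(10, 500.0)
        assert rr.lo == pytest.approx(100 * stats.chi2.ppf(0.025, 20) / 2 / 500)
        assert rr.hi == pytest.approx(100 * stats.chi2.ppf(0.975, 22) / 2 / 500)

    @pytest.mark.parametrize("k,py", [(1, 50.0), (10, 500.0), (40, 123.4)])
    def test_exact_ci_matches_poisson_inversion_oracle(self, k, py):
        """Bounds solve P(X>=k)=alpha/2 (lower) and P(X<=k)=alpha/2 (upper)."""
        rr = incidence_rate(k, py)
        lo_mu = optimize.brentq(lambda m: stats.poisson.sf(k - 1, m) - 0.025, 1e-9, 1e4)
        hi_mu = optimize.brentq(lambda m: stats.poisson.cdf(k, m) - 0.025, 1e-9, 1e4)
        assert rr.lo == pytest.approx(100 * lo_mu / py, rel=1e-6)
        assert rr.hi == pytest.approx(100 * hi_mu / py, rel=1e-6)

    def test_nonpositive_person_time_rejected(self):
        with pytest.raises(ValueError):
            incidence_rate(3, 0.0)

    def test_simulated_coverage_at_least_93_percent(self):
        """Exact CIs cover the true rate in >=93% of 2000 Poisson draws."""
        true_rate = 2.0  # per 100 PY
        py = 500.0
        rng = np.random.default_rng(0)
        draws = rng.poisson(true_rate / 100 * py, size=2000)
        covered = 0
        for k in draws:
            rr = incidence_rate(int(k), py)
            covered += rr.lo <= true_rate <= rr.hi
        assert covered / 2000 >= 0.93


class TestCompareRates:
    def test_identical_groups_p_one(self):
        a = incidence_rate(10, 500.0)
        z, p = compare_rates(a, a)
        assert z == 0.0 and p == 1.0

    def test_symmetry(self):
        a = incidence_rate(20, 1000.0)
        b = incidence_rate(60, 1000.0)
        za, pa = compare_rates(a, b)
        zb, pb = compare_rates(b, a)
        assert za == -zb and pa == pb

    def test_closed_form_oracle(self):
        a = incidence_rate(20, 1000.0)
        b = incidence_rate(60, 1000.0)
        z, p = compare_rates(a, b)
        pooled = 80 / 2000
        z_expect = (0.02 - 0.06) / np.sqrt(pooled * (1 / 1000 + 1 / 1000))
        assert z == pytest.approx(z_expect)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z_expect)))

    def test_against_statsmodels_score_test(self):
        from statsmodels.stats.rates import test_poisson_2indep

        a = incidence_rate(20, 1000.0)
        b = incidence_rate(60, 1000.0)
        z, p = compare_rates(a, b)
        res = test_poisson_2indep(20, 1000.0, 60, 1000.0, method="score",
                                  compare="diff")
        assert abs(z) == pytest.approx(abs(res.statistic), rel=1e-6)
        assert p == pytest.approx(res.pvalue, rel=1e-6)


class TestStratify:
    def test_eight_values_equal_quartiles(self):
        strata = stratify(np.arange(1, 9), "quartiles")
        assert list(strata) == ["q1", "q1", "q2", "q2", "q3", "q3", "q4", "q4"]

    def test_tie_goes_to_lower_stratum(self):
        values = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        cuts = np.quantile(values, [0.25, 0.5, 0.75])
        strata = stratify(values, "quartiles")
        for v, s in zip(values, strata):
            below = int(np.sum(cuts < v))
            assert s == f"q{below + 1}"

    def test_lvef_threshold_strict(self):
        assert list(stratify([49.9, 50.0], "lvef")) == ["abnormal", "normal"]

    def test_rvef_threshold(self):
        assert list(stratify([44.9, 45.0], "rvef")) == ["abnormal", "normal"]

    def test_named_threshold_helper(self):
        assert list(threshold_rule([10, 20], 15.0)) == ["abnormal", "normal"]

    def test_degenerate_all_equal_warns(self):
        with pytest.warns(UserWarning, match="identical"):
            strata = stratify(np.ones(8), "quartiles")
        assert set(strata) == {"q1"}

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            stratify([1, 2], "deciles")


class TestSelectReport:
    def _table(self):
        return pd.DataFrame(
            [
                {"person_id": "p1", "report_id": "r1",
                 "report_date": date(2010, 1, 1), "value": 55.0},
                {"person_id": "p1", "report_id": "r2",
                 "report_date": date(2012, 6, 1), "value": 48.0},
                {"person_id": "p2", "report_id": "r3",
                 "report_date": date(2011, 1, 1), "value": None},
            ]
        )

    def test_first_and_last(self):
        sel_first, _ = select_report(self._table(), "first")
        sel_last, _ = select_report(self._table(), "last")
        assert sel_first.loc[0, "value"] == 55.0
        assert sel_last.loc[0, "value"] == 48.0

    def test_single_report_same_both_ways(self):
        df = self._table().iloc[:1]
        f, _ = select_report(df, "first")
        l, _ = select_report(df, "last")
        assert f.loc[0, "report_id"] == l.loc[0, "report_id"] == "r1"

    def test_missing_feature_excluded_with_reason(self):
        _, excluded = select_report(self._table(), "first")
        assert list(excluded["person_id"]) == ["p2"]
        assert "not extracted" in excluded.loc[0, "reason"]

    def test_date_tie_broken_by_report_id(self):
        df = pd.DataFrame(
            [
                {"person_id": "p", "report_id": "rB",
                 "report_date": date(2010, 1, 1), "value": 1.0},
                {"person_id": "p", "report_id": "rA",
                 "report_date": date(2010, 1, 1), "value": 2.0},
            ]
        )
        sel, _ = select_report(df, "first")
        assert sel.loc[0, "report_id"] == "rA"

    def test_invalid_which(self):
        with pytest.raises(ValueError):
            select_report(self._table(), "middle")


class TestSimulateCohort:
    def test_seeded_determinism(self):
        a = simulate_cohort(50, seed=4, stratum_rates={"a": 0.1})
        b = simulate_cohort(50, seed=4, stratum_rates={"a": 0.1})
        pd.testing.assert_frame_equal(a, b)

    def test_rate_estimator_recovers_hazard_ratio(self):
        cohort = simulate_cohort(
            5000, seed=7, stratum_rates={"lo": 0.05, "hi": 0.10}, death_rate=0.005
        )
        pt = person_time(cohort, by="stratum").set_index("stratum")
        r_lo = pt.loc["lo", "events"] / pt.loc["lo", "person_years"]
        r_hi = pt.loc["hi", "events"] / pt.loc["hi", "person_years"]
        assert r_hi / r_lo == pytest.approx(2.0, abs=0.2)

    def test_monotone_hazards_give_monotone_rates(self):
        cohort = simulate_cohort(
            6000, seed=8, stratum_rates={"s1": 0.02, "s2": 0.05, "s3": 0.10},
            death_rate=0.005,
        )
        pt = person_time(cohort, by="stratum").set_index("stratum")
        rates = [pt.loc[s, "events"] / pt.loc[s, "person_years"] for s in ["s1", "s2", "s3"]]
        assert rates[0] < rates[1] < rates[2]

    def test_degenerate_followup_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(10, seed=0, stratum_rates={"a": 0.1}, max_followup_years=0.0)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(10, seed=0, stratum_rates={"a": -1.0})
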