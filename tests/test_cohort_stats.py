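"""Group tests, deletion counts, survival machinery, frequency table."""

import numpy as np
import pandas as pd
import pytest

from oligofish.cohort_stats import (chi_square_test, cox_fit, cox_workflow,
                                    deletion_count_summary,
                                    group_frequency_table, km_estimate,
                                    logrank_test, univariate_screen)
from oligofish.simulate import simulate_survival


class TestChiSquare:
    def test_independent_table_gives_zero(self):
        stat, p = chi_square_test([[5, 5], [5, 5]])
        assert stat == 0 and p == 1

    def test_9p_oii_vs_oiii_comparison(self):
        # 0/13 OII vs 7/10 OIII deleted; Yates-corrected p prints as 0.002
        stat, p = chi_square_test([[0, 13], [7, 3]])
        assert p == pytest.approx(0.00158, abs=2e-4)
        assert round(p, 3) == 0.002

    def test_doubling_counts_increases_statistic(self):
        t = np.array([[2, 8], [7, 3]])
        s1, _ = chi_square_test(t)
        s2, _ = chi_square_test(2 * t)
        assert s2 > s1

    def test_yates_is_conservative_for_2x2(self):
        from scipy.stats import chi2_contingency
        t = [[2, 8], [7, 3]]
        stat, _ = chi_square_test(t)
        uncorrected = chi2_contingency(t, correction=False).statistic
        assert stat <= uncorrected

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [5, 5]])
        with pytest.raises(ValueError):
            chi_square_test([[1, -2], [3, 4]])


class TestDeletionCounts:
    def test_fixture_group_means(self, cohort):
        d = deletion_count_summary(cohort)
        assert d.group_means["OII"] == pytest.approx(2.0)
        assert d.group_means["OIII"] == pytest.approx(2.7)
        assert d.group_means["AII"] == pytest.approx(1 / 3, abs=1e-9)
        assert d.group_means["AIII"] == pytest.approx(1 / 3, abs=1e-9)
        assert d.group_means["GBM"] == pytest.approx(1.75)
        assert d.total_mean == pytest.approx(62 / 33)

    def test_whole_chromosome_9_counts_once(self, cohort):
        # the two whole-chromosome-9 OIII cases have 9q flagged but only
        # 9p in the deleted-arm count: 1p + 19q + 9p = 3
        d = deletion_count_summary(cohort)
        whole9 = cohort["control_9q_deleted"]
        assert whole9.sum() == 2
        counted = d.per_case.loc[whole9.values, "n_deleted"]
        assert (counted == 3).all()

    def test_all_normal_case_counts_zero(self):
        df = pd.DataFrame([{
            "case_id": "x", "group": "AII",
            "status_1p": "NORMAL", "status_19q": "NORMAL",
            "status_9p": "NORMAL", "status_10q": "NORMAL",
        }])
        d = deletion_count_summary(df)
        assert d.per_case["n_deleted"].iloc[0] == 0

    def test_altered_adds_imbalances(self, cohort):
        d = deletion_count_summary(cohort)
        assert (d.per_case["n_altered"] >= d.per_case["n_deleted"]).all()
        # AII: 1 deletion + 7 imbalances over 3 cases
        assert d.group_means_altered["AII"] == pytest.approx(8 / 3)

    def test_missing_status_column_rejected(self):
        with pytest.raises(ValueError):
            deletion_count_summary(pd.DataFrame({"case_id": [], "group": []}))


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        km = km_estimate(t, np.ones(4, dtype=bool))
        sf = km.survival_function
        assert sf.loc[2.0].iloc[0] == pytest.approx(0.5)
        assert sf.loc[4.0].iloc[0] == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([5.0, 8.0, 12.0], [False] * 3)
        assert (km.survival_function.values == 1).all()
        assert km.median_months is None

    def test_curve_is_monotone_from_one(self, rng):
        t, e = simulate_survival(0.02, 0.3, 300, rng)
        sf = km_estimate(t, e).survival_function.values.ravel()
        assert sf[0] == 1.0
        assert (np.diff(sf) <= 1e-12).all()

    def test_exponential_median_matches_closed_form(self, rng):
        lam = 1 / 90
        t, e = simulate_survival(lam, 0.0, 2000, rng)
        km = km_estimate(t, e)
        theory = np.log(2) / lam
        # SE of the sample median of an exponential ~ median / sqrt(n)
        assert km.median_months == pytest.approx(theory,
                                                 abs=3 * theory / np.sqrt(2000))


def test_km_plot_written(tmp_path, rng):
    from oligofish.cohort_stats import save_km_plot
    t, e = simulate_survival(0.02, 0.2, 60, rng)
    out = tmp_path / "km.png"
    save_km_plot([km_estimate(t, e, label="all")], out, title="synthetic")
    assert out.stat().st_size > 0


class TestLogRank:
    def test_single_group_rejected(self, rng):
        t, e = simulate_survival(0.02, 0.1, 20, rng)
        with pytest.raises(ValueError):
            logrank_test(t, e, np.zeros(20))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2, 3, 4], [False] * 4, [0, 0, 1, 1])

    def test_power_under_threefold_hazard(self, rng):
        rejections = 0
        for _ in range(40):
            t1, e1 = simulate_survival(0.03, 0.1, 200, rng)
            t2, e2 = simulate_survival(0.01, 0.1, 200, rng)
            _, p = logrank_test(np.r_[t1, t2], np.r_[e1, e2],
                                np.r_[np.zeros(200), np.ones(200)])
            rejections += p < 0.05
        assert rejections / 40 > 0.9

    def test_invariant_under_time_rescaling(self, rng):
        t, e = simulate_survival(0.02, 0.2, 120, rng)
        g = rng.integers(0, 2, 120)
        s1, p1 = logrank_test(t, e, g)
        s2, p2 = logrank_test(10 * t, e, g)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)


class TestCox:
    def _frame(self, rng, hr, n=600):
        x = rng.integers(0, 2, n)
        base = 0.02
        t = np.where(x == 1, rng.exponential(1 / (base * hr), n),
                     rng.exponential(1 / base, n))
        cens = rng.exponential(200, n)
        return pd.DataFrame({"time_months": np.minimum(t, cens),
                             "event": (t <= cens).astype(float),
                             "x": x.astype(float)})

    def test_null_covariate_hr_near_one(self, rng):
        res = cox_fit(self._frame(rng, hr=1.0), ["x"])
        assert res.converged
        assert res.ci_lower["x"] < 1.0 < res.ci_upper["x"]

    def test_recovers_twofold_hazard(self, rng):
        res = cox_fit(self._frame(rng, hr=2.0), ["x"])
        assert res.converged
        assert res.ci_lower["x"] < 2.0 < res.ci_upper["x"]
        assert res.hazard_ratios["x"] == pytest.approx(2.0, rel=0.25)

    def test_separated_covariate_flagged(self, rng):
        # covariate perfectly orders survival -> partial likelihood
        # diverges; must come back flagged, not as a silent estimate
        n = 40
        t = np.r_[np.arange(1, n // 2 + 1), 100 + np.arange(1, n // 2 + 1)]
        df = pd.DataFrame({
            "time_months": t.astype(float),
            "event": np.ones(n),
            "x": np.r_[np.zeros(n // 2), np.ones(n // 2)],
        })
        res = cox_fit(df, ["x"])
        assert not res.converged
        assert res.flag

    def test_few_events_warns(self, rng):
        df = self._frame(rng, hr=1.0, n=30)
        df.loc[5:, "event"] = 0.0
        with pytest.warns(UserWarning):
            cox_fit(df, ["x"])

    def test_workflow_screens_then_fits(self, rng):
        df = self._frame(rng, hr=3.0)
        df["noise"] = rng.integers(0, 2, len(df)).astype(float)
        screen, res = cox_workflow(df, ["x", "noise"])
        assert screen.loc[screen.covariate == "x", "selected"].item()
        assert res is not None and res.converged
        assert "x" in res.hazard_ratios.index

    def test_workflow_with_nothing_significant(self, rng):
        df = self._frame(rng, hr=1.0)
        df["x"] = 0.0  # constant -> not testable, not selected
        screen, res = cox_workflow(df, ["x"])
        assert res is None


class TestFrequencyTable:
    def test_key_molecular_cells(self, cohort):
        table = group_frequency_table(cohort)
        assert table.loc["Chr 9p loss", "Total"] == "11 (33)"
        assert table.loc["Chr 9p loss", "OIII"] == "7 (70)"
        assert table.loc["Chr 9p loss", "GBM"] == "4 (100)"
        assert table.loc["Chr 10q loss", "GBM"] == "2 (50)"
        assert table.loc["Chr 1p loss", "Total"] == "26 (79)"
        assert table.loc["INA positive", "OII"] == "11 (85)"

    def test_histology_rows(self, cohort):
        table = group_frequency_table(cohort)
        assert table.loc["MVP glomeruloid", "OIII"] == "10 (100)"
        assert table.loc["Mitoses/10HPF mean", "OIII"] == "7"
        assert table.loc["Mitoses/10HPF mean", "Total"] == "3.6"
        assert table.loc["Chr arm deletion mean", "GBM"] == "1.75"

    def test_subset_without_groups_has_no_division_error(self, cohort):
        sub = cohort[cohort["group"] == "OII"]
        table = group_frequency_table(sub)
        assert table.loc["Chr 9p loss", "OII"] == "0 (0)"
        assert "GBM" not in table.columns
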