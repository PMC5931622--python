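import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from grschd.cohort_sim import SimConfig, simulate_covariates, simulate_outcomes
from grschd.survival_eval import (
    FitError,
    ModelSpec,
    age_adjusted_rates,
    fit_cox,
    fit_cox_design,
    harrells_c,
    hosmer_lemeshow,
    km_survival,
    ph_check,
)


def brute_force_cox_beta(x, time, event):
    """Maximize the (Breslow) partial likelihood by direct 1-D search."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)

    def neg_pl(beta):
        ll = 0.0
        for i in np.where(event == 1)[0]:
            risk_set = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk_set])))
        return -ll

    res = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


class TestFitCox:
    def test_two_group_toy_matches_brute_force_partial_likelihood(self, rng):
        # distinct event times -> Efron and Breslow coincide
        n = 18
        x = np.array([0.0, 1.0] * (n // 2))
        time = rng.permutation(np.linspace(1, 10, n))
        event = np.ones(n, dtype=int)
        X = pd.DataFrame({"x": x})
        fit = fit_cox_design(X, pd.Series(time), pd.Series(event))
        beta_star = brute_force_cox_beta(x, time, event)
        assert fit.params["x"] == pytest.approx(beta_star, abs=1e-6)

    def test_duplicating_subjects_near_preserves_hazard_ratio(self, rng):
        # exact invariance holds under Breslow ties; Efron's tie correction
        # (the default here) perturbs the estimate slightly because
        # duplication creates tied event times
        n = 30
        x = rng.normal(size=n)
        time = rng.exponential(5, n).round(3) + 0.01
        event = rng.integers(0, 2, n)
        event[0] = 1
        X = pd.DataFrame({"x": x})
        fit1 = fit_cox_design(X, pd.Series(time), pd.Series(event))
        X2 = pd.concat([X, X], ignore_index=True)
        fit2 = fit_cox_design(
            X2,
            pd.Series(np.concatenate([time, time])),
            pd.Series(np.concatenate([event, event])),
        )
        assert fit2.params["x"] == pytest.approx(fit1.params["x"], abs=0.06)
        # the duplicated fit must not gain spurious precision beyond 1/sqrt(2)
        assert fit2.ses["x"] == pytest.approx(
            fit1.ses["x"] / np.sqrt(2), rel=0.15
        )

    def test_time_unit_invariance(self, rng):
        n = 60
        x = rng.normal(size=n)
        time = rng.exponential(5, n) + 0.01
        event = rng.integers(0, 2, n)
        event[:5] = 1
        X = pd.DataFrame({"x": x})
        fit_years = fit_cox_design(X, pd.Series(time), pd.Series(event))
        fit_days = fit_cox_design(
            X, pd.Series(time * 365.25), pd.Series(event)
        )
        assert fit_days.params["x"] == pytest.approx(
            fit_years.params["x"], rel=1e-6
        )

    def test_no_events_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        with pytest.raises(FitError, match="no events"):
            fit_cox_design(X, pd.Series([1.0, 2.0, 3.0]), pd.Series([0, 0, 0]))

    def test_constant_score_rejected(self, small_study):
        cohort = small_study["cohort"]
        sub = cohort[cohort["ancestry"] == "LAT"]
        const = pd.Series(1.0, index=sub.index)
        with pytest.raises(FitError, match="constant"):
            fit_cox(sub, ModelSpec("1a"), const)


class TestPhCheck:
    def test_nominal_rejection_rate_under_proportional_hazards(self):
        rejections = 0
        reps = 100
        for s in range(reps):
            cfg = SimConfig(
                n=400, seed=1000 + s, covariate_loghrs={},
                grs_loghr_per_sd=np.log(1.3), dropout_rate=0.0,
            )
            cov = simulate_covariates(cfg)
            g = pd.Series(
                np.random.default_rng(s).normal(size=len(cov)),
                index=cov.index,
            )
            cohort = simulate_outcomes(cov, g, cfg)
            X = pd.DataFrame({"grs": g})
            fit = fit_cox_design(X, cohort["followup_time"], cohort["event"])
            if ph_check(fit, "grs") < 0.05:
                rejections += 1
        assert rejections / reps < 0.13  # ~ nominal 5%, binomial slack

    def test_power_against_reversing_effect(self, rng):
        """A score whose effect flips sign mid-follow-up must be flagged."""
        rejections = 0
        reps = 40
        for s in range(reps):
            r = np.random.default_rng(3000 + s)
            n = 600
            g = r.normal(size=n)
            # piecewise hazard: strong positive effect before t=2,
            # strong negative after
            t1 = r.exponential(1 / (0.25 * np.exp(1.2 * g)))
            t2 = 2.0 + r.exponential(1 / (0.25 * np.exp(-1.2 * g)))
            time = np.where(t1 < 2.0, t1, t2)
            event = np.ones(n, int)
            cens = r.uniform(3, 8, n)
            event[time > cens] = 0
            time = np.minimum(time, cens)
            X = pd.DataFrame({"grs": g})
            fit = fit_cox_design(X, pd.Series(time), pd.Series(event))
            if ph_check(fit, "grs") < 0.05:
                rejections += 1
        assert rejections / reps > 0.5

    def test_unknown_term_rejected(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=50)})
        fit = fit_cox_design(
            X, pd.Series(rng.exponential(5, 50) + 0.01),
            pd.Series(np.ones(50, int)),
        )
        with pytest.raises(FitError):
            ph_check(fit, "absent")


def oracle_concordance(risk, time, event):
    """Exhaustive O(n^2) pair enumeration with Harrell's comparability rule."""
    conc = ties = comp = 0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must have the earlier observed event
            if event[i] != 1 or time[i] >= time[j]:
                continue
            comp += 1
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] == risk[j]:
                ties += 1
    return (conc + 0.5 * ties) / comp


class TestHarrellsC:
    def test_perfect_ranking_gives_one(self):
        time = np.array([1.0, 2, 3, 4, 5])
        risk = -time  # earliest event has highest risk
        assert harrells_c(risk, time, np.ones(5, int)) == 1.0

    def test_all_tied_risks_give_half(self):
        time = np.array([1.0, 2, 3, 4, 5])
        assert harrells_c(np.ones(5), time, np.ones(5, int)) == 0.5

    def test_matches_exhaustive_pair_oracle_with_censoring(self, rng):
        n = 15
        for _ in range(5):
            time = rng.exponential(5, n).round(2) + 0.1
            event = rng.integers(0, 2, n)
            event[rng.integers(0, n)] = 1
            risk = rng.normal(size=n).round(2)  # rounded -> some ties
            expected = oracle_concordance(risk, time, event)
            assert harrells_c(risk, time, event) == pytest.approx(
                expected, abs=1e-12
            )

    def test_reversing_risk_complements_c(self, rng):
        n = 40
        time = rng.exponential(5, n) + 0.01
        event = np.ones(n, int)
        risk = rng.normal(size=n)
        c = harrells_c(risk, time, event)
        assert harrells_c(-risk, time, event) == pytest.approx(1 - c)


class TestKmSurvival:
    def test_censoring_free_fraction(self):
        time = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], float)
        event = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        # treat the zero rows as followed past t: censor at 10 means no
        # event observed by then only for t <= 10
        assert km_survival(time, event, 2.5) == pytest.approx(0.2)

    def test_matches_empirical_cdf_without_censoring(self, rng):
        time = rng.exponential(5, 50) + 0.01
        event = np.ones(50, int)
        for t in (1.0, 3.0, 6.0):
            assert km_survival(time, event, t) == pytest.approx(
                np.mean(time <= t)
            )

    def test_staggered_censoring_hand_computed_product_limit(self):
        # times:   1  2  3  4  5  6  7  8
        # status:  E  C  E  C  E  E  C  C
        time = np.array([1, 2, 3, 4, 5, 6, 7, 8], float)
        event = np.array([1, 0, 1, 0, 1, 1, 0, 0])
        # S(6) = (7/8)(5/6)(3/4)(2/3) = 0.364583...
        s6 = (7 / 8) * (5 / 6) * (3 / 4) * (2 / 3)
        assert km_survival(time, event, 6.5) == pytest.approx(1 - s6)

    def test_extrapolation_uses_final_year_hazard(self):
        # events at a constant exponential rate; extrapolated 10-year risk
        # should continue that rate rather than freeze
        rng = np.random.default_rng(5)
        time = rng.exponential(10, 4000)
        event = np.ones(4000, int)
        cens = 6.0
        event[time > cens] = 0
        time = np.minimum(time, cens)
        p10 = km_survival(time, event, 10.0)
        assert p10 == pytest.approx(1 - np.exp(-1.0), abs=0.05)
        p6 = km_survival(time, event, 6.0)
        assert p10 > p6

    def test_all_censored_without_extrapolation_rejected(self):
        with pytest.raises(FitError):
            km_survival([1.0, 2.0], [0, 0], 10.0, extrapolate=False)


class TestHosmerLemeshow:
    def test_identical_risks_with_matching_events_near_zero(self, rng):
        n = 1000
        p = 0.2
        event = (rng.uniform(size=n) < p).astype(int)
        time = np.where(event == 1, rng.uniform(0.5, 9.5, n), 11.0)
        chi2, df, _ = hosmer_lemeshow(np.full(n, event.mean()), time, event,
                                      t_star=10)
        assert chi2 == pytest.approx(0.0, abs=1e-6)

    def test_gross_miscalibration_detected(self, rng):
        n = 2000
        true_p = rng.uniform(0.05, 0.4, n)
        event = (rng.uniform(size=n) < true_p).astype(int)
        time = np.where(event == 1, rng.uniform(0.5, 9.5, n), 11.0)
        chi2, df, p = hosmer_lemeshow(true_p / 2, time, event, t_star=10)
        assert p < 1e-4

    def test_df_is_bins_minus_one(self, rng):
        n = 500
        risks = rng.uniform(0.01, 0.5, n)
        event = (rng.uniform(size=n) < risks).astype(int)
        time = np.where(event == 1, rng.uniform(0.5, 9.5, n), 11.0)
        _, df, _ = hosmer_lemeshow(risks, time, event, bins=10, t_star=10)
        assert df == 9


class TestAgeAdjustedRates:
    def test_symmetric_tertiles_get_equal_rates(self):
        n = 300
        cohort = pd.DataFrame(
            {
                "age": np.tile(np.linspace(40, 70, 100), 3),
                "followup_time": 8.0,
                "event": np.tile([1] + [0] * 49, 6),
            }
        )
        tert = pd.Series(np.repeat([1, 2, 3], 100))
        rates = age_adjusted_rates(cohort, tert)
        assert rates.loc[1, "rate"] == pytest.approx(rates.loc[2, "rate"],
                                                     rel=1e-6)
        assert rates.loc[2, "rate"] == pytest.approx(rates.loc[3, "rate"],
                                                     rel=1e-6)

    def test_rate_ratio_recovered(self, rng):
        n = 3000
        tert = pd.Series(rng.integers(1, 4, n))
        rate = np.where(tert == 3, 0.02, 0.01)
        fu = np.full(n, 8.0)
        events = rng.poisson(rate * fu)
        cohort = pd.DataFrame(
            {
                "age": rng.uniform(40, 70, n),
                "followup_time": fu,
                "event": np.minimum(events, 1),
            }
        )
        rates = age_adjusted_rates(cohort, tert)
        ratio = rates.loc[3, "rate"] / rates.loc[1, "rate"]
        assert 1.5 < ratio < 2.6

    def test_age_null_adjusted_equals_crude(self, rng):
        n = 2000
        tert = pd.Series(rng.integers(1, 4, n))
        fu = rng.uniform(5, 10, n)
        event = (rng.uniform(size=n) < 0.05).astype(int)
        cohort = pd.DataFrame(
            {"age": rng.uniform(40, 70, n), "followup_time": fu,
             "event": event}
        )
        rates = age_adjusted_rates(cohort, tert)
        for t in (1, 2, 3):
            mask = tert == t
            crude = event[mask].sum() / fu[mask].sum()
            assert rates.loc[t, "rate"] == pytest.approx(crude, rel=0.15)
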