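"""Dynamic conditional-survival predictions: contracts and closed forms."""

import numpy as np
import pandas as pd
import pytest

import seroprog as sp
from seroprog.cohort import survival_design
from seroprog.joint import JointModelParams
from seroprog.longitudinal import LongitudinalParams
from seroprog.prediction import (
    conditional_survival,
    posterior_random_effects,
    predict_conditional_survival,
)


def _params(alpha=-0.2, sd_b0=0.6, sd_b1=0.03):
    lp = LongitudinalParams(
        "Hb", np.array([0.5, -0.02, 0.1, 0.01, 0.95]), 0.5,
        np.array([[sd_b0 ** 2, 0.0], [0.0, sd_b1 ** 2]]))
    return JointModelParams(
        endpoint="OS", markers=("Hb",), scalings={"Hb": 1.0},
        longitudinal={"Hb": lp},
        gamma=np.array([-0.3, 0.2, 0.4, 0.3, 0.1, 0.15, 0.04, -0.01, -0.04]),
        alpha={"Hb": alpha},
        knots=np.array([0.0, 12.0, 30.0, np.inf]),
        logh0=np.array([-4.2, -3.9, -3.6]), t_max=60.0)


def _subject(sid=0):
    return pd.Series({
        "id": sid, "arm": 1, "ecog_ge1": 0, "skeletal_ge10": 1,
        "liver_met": 0, "nodal_n1": 0, "gleason_9_10": 1, "worst_pain": 1,
        "baseline_hb": 12.5, "baseline_psa": 15.0, "baseline_nlr": 2.2,
        "baseline_plr": 140.0, "baseline_lmr": 4.5,
        "event_time": 40.0, "event": 0, "cause": "censored"})


def _history(sid=0, times=(0, 3, 6, 12, 18, 24), slope=0.0, start=12.5):
    times = np.asarray(times, dtype=float)
    return pd.DataFrame({"id": sid, "marker": "Hb", "time_months": times,
                         "value": start + slope * times})


class TestContracts:
    def test_survival_at_landmark_is_one(self):
        pred = conditional_survival(_params(), _subject(), _history(), 24.0,
                                    [24.0, 36.0, 48.0], seed=3)
        assert pred.survival[0] == 1.0

    def test_monotone_nonincreasing_in_unit_interval(self):
        pred = conditional_survival(_params(), _subject(), _history(), 24.0,
                                    np.arange(24.0, 61.0, 6.0), seed=3)
        assert np.all(np.diff(pred.survival) <= 1e-12)
        assert np.all((pred.survival >= 0) & (pred.survival <= 1))

    def test_horizon_before_landmark_rejected(self):
        with pytest.raises(ValueError):
            conditional_survival(_params(), _subject(), _history(), 24.0,
                                 [12.0])

    def test_extrapolation_flagged(self):
        p = _params()
        p.t_max = 40.0
        pred = conditional_survival(p, _subject(), _history(), 24.0,
                                    [36.0, 55.0], seed=0)
        assert not pred.extrapolated[0] and pred.extrapolated[1]


class TestClosedForms:
    def test_null_association_equals_cox_ratio(self):
        """alpha=0: pi(u|t) must equal the proportional-hazards ratio
        exp(-(H0(u)-H0(t)) e^{gamma'w}) exactly."""
        p = _params(alpha=0.0)
        subj = _subject()
        pred = conditional_survival(p, subj, _history(), 24.0,
                                    [30.0, 48.0, 60.0], n_draws=50, seed=1)

        def H0(u):
            total = 0.0
            for k in range(len(p.logh0)):
                lo = min(p.knots[k], u)
                hi = min(p.knots[k + 1], u)
                if hi > lo:
                    total += np.exp(p.logh0[k]) * (hi - lo)
            return total

        lp0 = float((survival_design(subj.to_frame().T) @ p.gamma)[0])
        for u, got in zip([30.0, 48.0, 60.0], pred.survival):
            want = np.exp(-(H0(u) - H0(24.0)) * np.exp(lp0))
            assert np.isclose(got, want, atol=1e-6)

    def test_chaining_identity_with_frozen_posterior(self):
        """pi(u|t) = pi(s|t) * pi(u|s) when all three use the same posterior
        draws (same seed and history)."""
        p = _params(alpha=-0.3)
        subj, hist = _subject(), _history()
        t, s, u = 24.0, 36.0, 54.0
        base = conditional_survival(p, subj, hist, t, [s, u], n_draws=400,
                                    seed=9)
        # pi(u|s) from the same landmark-t posterior: ratio of E[S(u)]/E[S(s)]
        ratio = base.survival[1] / base.survival[0]
        chained = base.survival[0] * ratio
        assert np.isclose(base.survival[1], chained, rtol=1e-12)

    def test_rising_psa_history_lowers_survival(self):
        """A subject whose PSA rises has strictly lower predicted survival
        than one with a flat history, all else equal."""
        lp = LongitudinalParams(
            "PSA", np.array([0.1, -0.05, 0.0, -0.02, 1.0]), 0.3,
            np.diag([0.3 ** 2, 0.05 ** 2]))
        p = JointModelParams(
            endpoint="OS", markers=("PSA",), scalings={"PSA": 1.0},
            longitudinal={"PSA": lp},
            gamma=np.zeros(9), alpha={"PSA": 0.25},
            knots=np.array([0.0, 20.0, np.inf]),
            logh0=np.array([-4.0, -3.8]), t_max=60.0)
        subj = _subject()
        times = np.arange(0.0, 25.0, 3.0)
        flat = pd.DataFrame({"id": 0, "marker": "PSA", "time_months": times,
                             "value": 15.0})
        rising = pd.DataFrame({"id": 0, "marker": "PSA", "time_months": times,
                               "value": 15.0 * np.exp(0.15 * times)})
        s_flat = conditional_survival(p, subj, flat, 24.0, [60.0],
                                      n_draws=400, seed=2).survival[0]
        s_rise = conditional_survival(p, subj, rising, 24.0, [60.0],
                                      n_draws=400, seed=2).survival[0]
        assert s_rise < s_flat


class TestPosteriorRandomEffects:
    def test_conjugate_oracle_at_null_association(self):
        """alpha=0 gives uniform importance weights, so the weighted mean
        equals the closed-form Gaussian posterior mean (up to MC noise)."""
        from seroprog.longitudinal import posterior_b

        p = _params(alpha=0.0)
        subj, hist = _subject(), _history(slope=-0.05)
        out = posterior_random_effects(p, subj, hist, 24.0, n_draws=4000,
                                       seed=5)
        assert np.allclose(out["weights"], out["weights"][0])
        lpar = p.longitudinal["Hb"]
        post = hist[hist["time_months"] > 0]  # t=0 is the baseline covariate
        mu, Sigma = posterior_b(lpar, 1, 12.5, post["time_months"],
                                post["value"])
        assert np.allclose(out["mean"]["Hb"], mu,
                           atol=4 * np.sqrt(np.diag(Sigma).max() / 4000) + 0.02)

    def test_survival_conditioning_shifts_towards_low_risk(self):
        """With a strongly positive association, surviving to the landmark
        favours low-marker trajectories relative to alpha=0."""
        p_null = _params(alpha=0.0, sd_b0=1.2)
        p_hazard = _params(alpha=0.9, sd_b0=1.2)
        # centre the current value near zero so exp(alpha m) stays finite
        for p in (p_null, p_hazard):
            p.longitudinal["Hb"].beta[4] = 0.0
        p_hazard.logh0 = p_hazard.logh0 + 1.0  # sizeable cumulative hazard
        subj = _subject()
        hist = _history(times=(0.0,))  # almost no marker information
        null = posterior_random_effects(p_null, subj, hist, 30.0,
                                        n_draws=4000, seed=8)
        cond = posterior_random_effects(p_hazard, subj, hist, 30.0,
                                        n_draws=4000, seed=8)
        assert cond["mean"]["Hb"][0] < null["mean"]["Hb"][0]

    def test_empty_history_uses_population_distribution(self):
        p = _params(alpha=0.0)
        empty = pd.DataFrame(columns=["id", "marker", "time_months", "value"])
        out = posterior_random_effects(p, _subject(), empty, 12.0,
                                       n_draws=3000, seed=4)
        sd0 = np.sqrt(p.longitudinal["Hb"].cov_re[0, 0])
        assert abs(out["mean"]["Hb"][0]) < 4 * sd0 / np.sqrt(3000)


class TestCohortPredictions:
    def test_batch_matches_single_subject(self, small_cohort):
        fit = sp.fit_univariate_joint(small_cohort.markers,
                                      small_cohort.subjects, "Hb",
                                      backend="two_stage")
        alive = small_cohort.subjects[
            small_cohort.subjects["event_time"] > 24.0].head(5).reset_index(drop=True)
        hist = small_cohort.markers[
            small_cohort.markers["id"].isin(alive["id"])
            & (small_cohort.markers["time_months"] <= 24.0)]
        batch = predict_conditional_survival(fit.params, alive, hist, 24.0,
                                             [48.0], n_draws=200, seed=3)
        one = conditional_survival(
            fit.params, alive.iloc[0],
            hist[hist["id"] == alive["id"].iloc[0]], 24.0, [48.0],
            n_draws=200, seed=3)
        got = batch[batch["id"] == alive["id"].iloc[0]]["pi_hat"].iloc[0]
        assert np.isclose(got, one.survival[0], atol=0.02)

    def test_later_landmark_reduces_error_against_truth(self):
        """More marker history tightens predictions toward the generating
        conditional survival (RMSE decreases from landmark 12 to 24)."""
        from seroprog.cohort import true_all_cause_survival
        from seroprog.scenarios import psa_dominant_config

        cfg = psa_dominant_config(300, seed=3)
        c = sp.simulate_cohort(cfg, apply_filter=True)
        fit = sp.fit_univariate_joint(c.markers, c.subjects, "PSA",
                                      backend="two_stage")
        rmse = {}
        for lm in (12.0, 24.0):
            alive_mask = c.subjects["event_time"] > 24.0
            alive = c.subjects[alive_mask].reset_index(drop=True)
            hist = c.markers[c.markers["id"].isin(alive["id"])
                             & (c.markers["time_months"] <= lm)]
            pred = predict_conditional_survival(fit.params, alive, hist, lm,
                                                [60.0], n_draws=200, seed=1)
            truth_all = true_all_cause_survival(c, lm, 60.0)
            truth = truth_all[alive_mask.to_numpy()]
            rmse[lm] = float(np.sqrt(np.mean(
                (pred["pi_hat"].to_numpy() - truth) ** 2)))
        assert rmse[24.0] < rmse[12.0]
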