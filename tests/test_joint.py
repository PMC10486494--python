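"""Joint likelihood correctness, backend agreement, and reporting rules."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

import seroprog as sp
from seroprog.joint import (
    JointModel,
    JointModelParams,
    JointModelResults,
    JointModelSpec,
    joint_log_likelihood,
    survival_loglik_nodes,
)
from seroprog.longitudinal import LongitudinalParams


def _tiny_dataset():
    subjects = pd.DataFrame({
        "id": [0, 1], "arm": [0, 1], "ecog_ge1": [0, 1],
        "skeletal_ge10": [1, 0], "liver_met": [0, 0], "nodal_n1": [1, 0],
        "gleason_9_10": [0, 1], "worst_pain": [2, 0],
        "baseline_hb": [13.0, 11.5], "baseline_psa": [20.0, 5.0],
        "baseline_nlr": [2.0, 2.0], "baseline_plr": [100.0, 100.0],
        "baseline_lmr": [4.0, 4.0],
        "event_time": [14.0, 30.0], "event": [1, 0],
        "cause": ["prostate_cancer", "censored"]})
    markers = pd.DataFrame({
        "id": [0, 0, 0, 1, 1, 1], "marker": "Hb",
        "time_months": [0.0, 2.0, 6.0, 0.0, 3.0, 12.0],
        "value": [13.0, 12.4, 12.9, 11.5, 11.8, 12.3]})
    return subjects, markers


def _tiny_params(alpha=-0.25):
    beta = np.array([1.0, 0.03, -0.2, 0.02, 0.92])
    lp = LongitudinalParams("Hb", beta, 0.5,
                            np.array([[0.49, -0.02], [-0.02, 0.001]]))
    return JointModelParams(
        endpoint="OS", markers=("Hb",), scalings={"Hb": 1.0},
        longitudinal={"Hb": lp},
        gamma=np.array([-0.4, 0.3, 0.5, 0.4, 0.1, 0.2, 0.05, -0.01, -0.05]),
        alpha={"Hb": alpha},
        knots=np.array([0.0, 10.0, 20.0, np.inf]),
        logh0=np.array([-4.5, -4.0, -3.8]), t_max=60.0)


def _brute_force_loglik(params, markers, subjects, grid_pts=401):
    """Dense 2-D grid integration oracle over the random effects."""
    from seroprog.cohort import survival_design

    beta = params.longitudinal["Hb"].beta
    sd = params.longitudinal["Hb"].sd_resid
    D = params.longitudinal["Hb"].cov_re
    knots, logh0 = params.knots, params.logh0
    lp0 = survival_design(subjects) @ params.gamma
    alpha = params.alpha["Hb"]
    total = 0.0
    for i in range(len(subjects)):
        sub = markers[(markers["id"] == subjects["id"].iloc[i])
                      & (markers["time_months"] > 0)]
        ti, yi = sub["time_months"].to_numpy(), sub["value"].to_numpy()
        arm = subjects["arm"].iloc[i]
        base = subjects["baseline_hb"].iloc[i]
        T, d = subjects["event_time"].iloc[i], subjects["event"].iloc[i]
        g = np.linspace(-4, 4, grid_pts)
        b0g, b1g = np.meshgrid(g * np.sqrt(D[0, 0]) * 1.5,
                               g * np.sqrt(D[1, 1]) * 1.5, indexing="ij")
        db0 = b0g[1, 0] - b0g[0, 0]
        db1 = b1g[0, 1] - b1g[0, 0]
        dens = multivariate_normal(np.zeros(2), D).pdf(np.dstack([b0g, b1g]))
        fa = beta[0] + beta[2] * arm + beta[4] * base + b0g
        fc = beta[1] + beta[3] * arm + b1g
        for t, y in zip(ti, yi):
            dens = dens * norm.pdf(y, fa + fc * t, sd)
        A, C = alpha * fa, alpha * fc
        H = np.zeros_like(A)
        for k in range(len(logh0)):
            lo, hi = min(knots[k], T), min(knots[k + 1], T)
            if hi > lo:
                H += np.where(
                    np.abs(C) > 1e-12,
                    np.exp(logh0[k] + A) * (np.exp(C * hi) - np.exp(C * lo))
                    / np.where(np.abs(C) > 1e-12, C, 1.0),
                    np.exp(logh0[k] + A) * (hi - lo))
        H *= np.exp(lp0[i])
        seg = np.searchsorted(knots, T, side="right") - 1
        loghaz = logh0[seg] + lp0[i] + A + C * T
        surv = np.exp(d * loghaz - H)
        total += np.log((dens * surv).sum() * db0 * db1)
    return total


class TestJointLogLikelihood:
    def test_matches_brute_force_grid(self):
        subjects, markers = _tiny_dataset()
        params = _tiny_params()
        mine = joint_log_likelihood(params, markers, subjects, quad_order=9)
        brute = _brute_force_loglik(params, markers, subjects)
        assert np.isclose(mine, brute, atol=1e-4)

    def test_quadrature_order_converged(self):
        subjects, markers = _tiny_dataset()
        params = _tiny_params()
        l5 = joint_log_likelihood(params, markers, subjects, quad_order=5)
        l15 = joint_log_likelihood(params, markers, subjects, quad_order=15)
        assert abs(l5 - l15) < 1e-4

    def test_separates_at_null_association(self):
        """alpha=0: joint loglik = marginal LMM loglik + parametric PH
        loglik, each computed independently."""
        subjects, markers = _tiny_dataset()
        params = _tiny_params(alpha=0.0)
        joint = joint_log_likelihood(params, markers, subjects)

        from seroprog._lmm import build_marker_data, marginal_and_posterior
        from seroprog.cohort import survival_design

        md = build_marker_data(markers, subjects, "Hb")
        p = params.longitudinal["Hb"]
        lmm = marginal_and_posterior(md, p.beta, p.sigma2, p.cov_re)[0].sum()
        lp0 = survival_design(subjects) @ params.gamma
        ph = 0.0
        for i in range(2):
            T, d = subjects["event_time"].iloc[i], subjects["event"].iloc[i]
            H = 0.0
            for k in range(3):
                lo = min(params.knots[k], T)
                hi = min(params.knots[k + 1], T)
                if hi > lo:
                    H += math.exp(params.logh0[k] + lp0[i]) * (hi - lo)
            seg = np.searchsorted(params.knots, T, side="right") - 1
            ph += d * (params.logh0[seg] + lp0[i]) - H
        assert np.isclose(joint, lmm + ph, atol=1e-8)

    def test_piecewise_segment_integrals_closed_form(self):
        """Cumulative hazard over two segments matches the hand-computed
        sum of closed-form exponential-in-t integrals."""
        lp0 = np.array([0.3])
        A = np.array([[0.2]])
        C = np.array([[0.05]])
        T = np.array([15.0])
        delta = np.array([0])
        logh0 = np.array([-3.0, -2.5])
        lo = np.array([[0.0, 10.0]])
        hi = np.array([[10.0, 15.0]])
        seg_idx = np.array([1])
        g = survival_loglik_nodes(lp0, A, C, T, delta, logh0, lo, hi, seg_idx)
        seg1 = math.exp(-3.0 + 0.3 + 0.2) * (math.exp(0.05 * 10) - 1) / 0.05
        seg2 = math.exp(-2.5 + 0.3 + 0.2) * (math.exp(0.05 * 15)
                                             - math.exp(0.05 * 10)) / 0.05
        assert np.isclose(g[0, 0], -(seg1 + seg2), rtol=1e-12)


@pytest.fixture(scope="module")
def hb_cohort():
    from seroprog.scenarios import univariate_recovery_config

    cfg = univariate_recovery_config("Hb", n_subjects=250, seed=6)
    return sp.simulate_cohort(cfg, apply_filter=True)


class TestBackends:
    def test_two_stage_and_full_agree_in_sign(self, hb_cohort):
        ts = sp.fit_univariate_joint(hb_cohort.markers, hb_cohort.subjects,
                                     "Hb", backend="two_stage")
        fl = sp.fit_univariate_joint(hb_cohort.markers, hb_cohort.subjects,
                                     "Hb", backend="full_likelihood",
                                     compute_se=False)
        assert np.sign(ts.params.alpha["Hb"]) == np.sign(fl.params.alpha["Hb"])
        assert ts.hazard_ratio("Hb") < 1.0 and fl.hazard_ratio("Hb") < 1.0

    def test_full_likelihood_trace_monotone(self, hb_cohort):
        fl = sp.fit_univariate_joint(hb_cohort.markers, hb_cohort.subjects,
                                     "Hb", backend="full_likelihood",
                                     compute_se=False)
        trace = fl.diagnostics["nll_trace"]
        assert len(trace) > 3
        assert np.all(np.diff(trace) <= 1e-6)

    def test_time_unit_reparameterisation_invariance(self, hb_cohort):
        """Measuring time in years instead of months leaves the reported
        association HR (per marker unit) unchanged."""
        fl = sp.fit_univariate_joint(hb_cohort.markers, hb_cohort.subjects,
                                     "Hb", backend="full_likelihood",
                                     compute_se=False)
        markers_y = hb_cohort.markers.assign(
            time_months=hb_cohort.markers["time_months"] / 12.0)
        subjects_y = hb_cohort.subjects.assign(
            event_time=hb_cohort.subjects["event_time"] / 12.0)
        fl_y = sp.fit_univariate_joint(markers_y, subjects_y, "Hb",
                                       backend="full_likelihood",
                                       compute_se=False)
        assert np.isclose(fl.hazard_ratio("Hb"), fl_y.hazard_ratio("Hb"),
                          atol=0.02)

    def test_single_marker_multivariate_degeneracy(self, hb_cohort):
        """A one-marker 'multivariate' survival-block fit agrees with the
        univariate full fit to reasonable tolerance."""
        spec = JointModelSpec(endpoint="OS", markers=("Hb",),
                              backend="full_likelihood")
        uni = JointModel(hb_cohort.markers, hb_cohort.subjects, spec).fit(
            compute_se=False)
        mcmc = sp.fit_univariate_joint(
            hb_cohort.markers, hb_cohort.subjects, "Hb",
            backend="bayesian_mcmc", seed=1, n_steps=400, n_burn=200)
        assert np.isclose(uni.params.alpha["Hb"], mcmc.params.alpha["Hb"],
                          atol=0.12)

    def test_horseshoe_requires_mcmc_backend(self):
        with pytest.raises(ValueError, match="horseshoe"):
            JointModelSpec(shrinkage="horseshoe",
                           backend="full_likelihood").validate()


class TestHazardRatioTable:
    def _results_with(self, alpha, se=0.1, draws=None):
        params = _tiny_params(alpha=alpha)
        model = object.__new__(JointModel)
        model.spec = JointModelSpec(endpoint="OS", markers=("Hb",))
        diag = {"backend": "full_likelihood"}
        if draws is not None:
            diag["draws"] = {"alpha:Hb": draws}
        ses = {f"gamma:{c}": 0.2 for c in sp.config.SURVIVAL_COVARIATES}
        ses["alpha:Hb"] = se
        return JointModelResults(model, params, ses, diag)

    def test_null_association_prints_unit_hr(self):
        table = self._results_with(0.0).hazard_ratio_table()
        row = table[table["parameter"].str.startswith("current Hb")].iloc[0]
        assert f"{row['hazard_ratio']:.2f}" == "1.00"

    def test_scale_arithmetic(self):
        table = self._results_with(math.log(1.24)).hazard_ratio_table()
        row = table[table["parameter"].str.startswith("current Hb")].iloc[0]
        assert np.isclose(row["hazard_ratio"], 1.24)

    def test_boundary_p_value_not_significant(self):
        """p exactly 0.004 fails the strict p < 0.004 rule."""
        draws = np.concatenate([np.full(998, -1.0), [0.5, 0.5]])  # tail 2/1000
        res = self._results_with(-1.0, draws=draws)
        res.diagnostics["backend"] = "bayesian_mcmc"
        table = res.hazard_ratio_table()
        row = table[table["parameter"].str.startswith("current Hb")].iloc[0]
        assert np.isclose(row["p_value"], 0.004)
        assert not row["significant"]

    def test_summary_mentions_backend_and_intervals(self):
        res = self._results_with(0.1)
        text = res.summary()
        assert "full_likelihood" in text and "Wald" in text
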