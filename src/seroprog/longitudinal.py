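"""Per-marker linear mixed-effects trajectory models.

Fixed effects: intercept, time (months), treatment arm, arm x time, and the
subject's baseline marker value. Random effects: subject-level intercept
and slope on time with unstructured 2x2 covariance. PSA is modelled on the
log(x+1) scale; all other markers on their native scale.

Two routes are provided: a statsmodels ``MixedLM`` wrapper (REML by
default) for standalone trajectory analysis, and a fast closed-form
maximum-likelihood fitter used internally by the joint model (full
likelihood, so that the joint fit's longitudinal block is not confounded
by REML/ML differences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._lmm import (
    MarkerData,
    build_marker_data,
    cov_from_unconstrained,
    design_row,
    marginal_and_posterior,
)
from .cohort import modelling_scale

FIXED_EFFECT_NAMES = ("intercept", "time", "arm", "arm_time", "baseline")


class RankDeficientDesignError(ValueError):
    """The fixed-effect design has no unique least-squares solution."""


@dataclass
class LongitudinalParams:
    """Estimated longitudinal sub-model for one marker."""

    marker: str
    beta: np.ndarray                 # (5,) fixed effects
    sd_resid: float
    cov_re: np.ndarray               # (2, 2) random intercept/slope covariance
    loglik: float = np.nan
    converged: bool = True
    method: str = "ml"
    beta_se: np.ndarray | None = None

    @property
    def sigma2(self) -> float:
        return self.sd_resid ** 2

    def fixed_prediction(self, t, arm, baseline):
        """Population (fixed-effects-only) current value at ``t``."""
        return design_row(t, arm, baseline) @ self.beta


def _pack(beta, sd_resid, cov_re):
    sd0 = np.sqrt(cov_re[0, 0])
    sd1 = np.sqrt(cov_re[1, 1])
    rho = np.clip(cov_re[0, 1] / max(sd0 * sd1, 1e-12), -0.999, 0.999)
    return np.concatenate([beta, [np.log(max(sd_resid, 1e-8)),
                                  np.log(max(sd0, 1e-8)),
                                  np.log(max(sd1, 1e-8)),
                                  np.arctanh(rho)]])


def unpack_longitudinal(theta, marker="marker") -> LongitudinalParams:
    beta = np.asarray(theta[:5], dtype=float)
    sd_resid = float(np.exp(theta[5]))
    cov_re = cov_from_unconstrained(theta[6], theta[7], theta[8])
    return LongitudinalParams(marker=marker, beta=beta, sd_resid=sd_resid,
                              cov_re=cov_re)


def _check_rank(data: MarkerData):
    XX = data.XX.sum(axis=0)
    if np.linalg.matrix_rank(XX) < XX.shape[0]:
        raise RankDeficientDesignError(
            f"{data.marker}: fixed-effect design is rank deficient "
            "(e.g. a single treatment arm with 'arm' among the fixed effects)")


def _ols_start(data: MarkerData):
    XX = data.XX.sum(axis=0)
    Xy = data.Xy.sum(axis=0)
    beta = np.linalg.solve(XX, Xy)
    rss = data.yy.sum() - beta @ Xy
    s = np.sqrt(max(rss / max(data.n_obs.sum() - 5, 1), 1e-6))
    return beta, s


def fit_lmm_ml(data: MarkerData, start: np.ndarray | None = None) -> LongitudinalParams:
    """Full-likelihood fit via the closed-form marginal (internal route)."""
    if data.n_subjects < 2 or data.total_obs < 4:
        raise ValueError("need >= 2 observations on >= 2 subjects")
    _check_rank(data)
    if start is None:
        beta, s = _ols_start(data)
        start = _pack(beta, 0.8 * s,
                      np.diag([max(0.25 * s ** 2, 1e-6), max(0.003 * s, 1e-8) ** 2]))

    def nll(theta):
        p = unpack_longitudinal(theta)
        ll, _, _ = marginal_and_posterior(data, p.beta, p.sigma2, p.cov_re)
        return -ll.sum()

    res = minimize(nll, start, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-10})
    params = unpack_longitudinal(res.x, data.marker)
    params.loglik = -res.fun
    params.converged = bool(res.success)
    params.method = "ml"
    if not res.success:
        warnings.warn(f"{data.marker}: longitudinal ML did not converge: {res.message}")
    return params


def posterior_b(params: LongitudinalParams, arm, baseline, times, values_model):
    """Closed-form Gaussian posterior of (b0, b1) given a subject history.

    ``values_model`` must be on the modelling scale. Empty histories return
    the prior. Returns (mu (2,), Sigma (2, 2)).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.zeros(2), params.cov_re.copy()
    X = design_row(times, arm, baseline)
    Z = np.stack([np.ones_like(times), times], axis=-1)
    r = np.asarray(values_model, dtype=float) - X @ params.beta
    A = params.sigma2 * np.linalg.inv(params.cov_re) + Z.T @ Z
    mu = np.linalg.solve(A, Z.T @ r)
    Sigma = params.sigma2 * np.linalg.inv(A)
    return mu, Sigma


def predict_current_value(params: LongitudinalParams, arm, baseline_native,
                          history_times, history_values, t_query):
    """Model-implied current value m(t_query) on the modelling scale.

    Empirical-Bayes (posterior-mean, = posterior-mode) random effects given
    the history are plugged into the linear predictor; an empty history
    yields the population prediction.
    """
    baseline = float(modelling_scale(params.marker, baseline_native))
    values_model = modelling_scale(params.marker, np.asarray(history_values, float))
    mu, _ = posterior_b(params, arm, baseline, history_times, values_model)
    t_query = np.asarray(t_query, dtype=float)
    fixed = params.fixed_prediction(t_query, arm, baseline)
    return fixed + mu[0] + mu[1] * t_query


class MarkerTrajectoryModel:
    """statsmodels-style model object for one marker's trajectories."""

    def __init__(self, markers: pd.DataFrame, subjects: pd.DataFrame, marker: str):
        self.marker = marker
        self.subjects = subjects
        self.data = build_marker_data(markers, subjects, marker)
        # response rows: post-baseline only (t=0 is the baseline covariate)
        self._long = markers[(markers["marker"] == marker)
                             & (markers["time_months"] > 0)]

    def fit(self, reml: bool = True) -> "MarkerTrajectoryResults":
        """Fit by REML (default) or ML with statsmodels MixedLM."""
        import statsmodels.api as sm

        _check_rank(self.data)
        sub = self._long.merge(self.subjects[["id", "arm"]], on="id")
        base_map = dict(zip(self.data.ids, self.data.baseline))
        t = sub["time_months"].to_numpy(float)
        arm = sub["arm"].to_numpy(float)
        baseline = np.array([base_map[s] for s in sub["id"]])
        y = modelling_scale(self.marker, sub["value"].to_numpy())
        X = pd.DataFrame(design_row(t, arm, baseline), columns=FIXED_EFFECT_NAMES)
        exog_re = np.stack([np.ones_like(t), t], axis=-1)
        model = sm.MixedLM(y, X, groups=sub["id"].to_numpy(), exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            smfit = model.fit(reml=reml, method="lbfgs", maxiter=500)
        params = LongitudinalParams(
            marker=self.marker,
            beta=smfit.fe_params.to_numpy(),
            sd_resid=float(np.sqrt(smfit.scale)),
            cov_re=smfit.cov_re.to_numpy() * 1.0,
            loglik=float(smfit.llf),
            converged=bool(smfit.converged),
            method="reml" if reml else "ml",
            beta_se=smfit.bse_fe.to_numpy(),
        )
        return MarkerTrajectoryResults(self, params)


class MarkerTrajectoryResults:
    """Fitted trajectory model: estimates, uncertainty and predictions."""

    def __init__(self, model: MarkerTrajectoryModel, params: LongitudinalParams):
        self.model = model
        self.params = params

    def predict_current_value(self, arm, baseline_native, history_times,
                              history_values, t_query):
        return predict_current_value(self.params, arm, baseline_native,
                                     history_times, history_values, t_query)

    def summary(self) -> pd.DataFrame:
        p = self.params
        rows = [{"parameter": n, "estimate": b,
                 "se": (p.beta_se[i] if p.beta_se is not None else np.nan)}
                for i, (n, b) in enumerate(zip(FIXED_EFFECT_NAMES, p.beta))]
        rows += [
            {"parameter": "sd_resid", "estimate": p.sd_resid, "se": np.nan},
            {"parameter": "sd_b0", "estimate": np.sqrt(p.cov_re[0, 0]), "se": np.nan},
            {"parameter": "sd_b1", "estimate": np.sqrt(p.cov_re[1, 1]), "se": np.nan},
            {"parameter": "corr_b0b1",
             "estimate": p.cov_re[0, 1] / max(np.sqrt(p.cov_re[0, 0] * p.cov_re[1, 1]), 1e-12),
             "se": np.nan},
        ]
        return pd.DataFrame(rows)
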