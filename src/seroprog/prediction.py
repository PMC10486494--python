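"""Dynamic (landmark) predictions from a fitted joint model.

Given a subject's marker history up to a landmark time t, the conditional
survival to a horizon u > t is

    pi(u | t) = E_b[ S(u | b, w) ] / E_b[ S(t | b, w) ],

the expectation running over the subject's random-effect posterior given
the history; the ratio form conditions on survival to the landmark. The
expectation is taken by seeded Monte-Carlo draws from the closed-form
longitudinal Gaussian posterior (the survival tilt enters through the
ratio). The marker trajectory beyond t extrapolates the subject's fitted
linear predictor — no post-landmark measurements are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from ._lmm import chol2, marginal_and_posterior
from .cohort import survival_design
from .joint import JointModelParams, _phi

logger = logging.getLogger(__name__)


@dataclass
class DynamicPrediction:
    """Conditional survival curve for one subject beyond a landmark."""

    subject_id: object
    landmark: float
    horizons: np.ndarray
    survival: np.ndarray          # pi_hat(u | t)
    extrapolated: np.ndarray      # True where u exceeds baseline support

    @property
    def event_probability(self) -> np.ndarray:
        return 1.0 - self.survival


def _cumhaz_at(params: JointModelParams, lp0, A, C, u: float) -> np.ndarray:
    """H(u) for node arrays A, C of shape (n, Q)."""
    lo = np.minimum(params.knots[:-1], u)
    hi = np.minimum(params.knots[1:], u)
    cum = np.zeros_like(A)
    for seg in range(len(params.logh0)):
        width = hi[seg] - lo[seg]
        if width <= 0:
            continue
        x = C * width
        expo = np.clip(params.logh0[seg] + lp0[:, None] + A + C * lo[seg],
                       -745.0, 700.0)
        cum += np.exp(expo) * width * _phi(x)
    return cum


def _node_lines(params: JointModelParams, subjects: pd.DataFrame,
                history: pd.DataFrame, n_draws: int, seed: int):
    """Association line nodes (A, C) of shape (n, n_draws) plus lp0."""
    from ._lmm import build_marker_data

    rng = np.random.default_rng(seed)
    k = len(params.markers)
    z = rng.standard_normal((n_draws, 2 * k))
    lp0 = survival_design(subjects) @ params.gamma
    A = np.zeros((len(subjects), n_draws))
    C = np.zeros_like(A)
    for j, marker in enumerate(params.markers):
        p = params.longitudinal[marker]
        md = build_marker_data(history, subjects, marker)
        _, mu, Sigma = marginal_and_posterior(md, p.beta, p.sigma2, p.cov_re)
        L = chol2(Sigma)
        zz = z[:, 2 * j:2 * j + 2]
        b = mu[:, None, :] + np.einsum("nij,qj->nqi", L, zz)
        coef = params.alpha[marker] / params.scalings[marker]
        fix_a = p.beta[0] + p.beta[2] * md.arm + p.beta[4] * md.baseline
        fix_c = p.beta[1] + p.beta[3] * md.arm
        A += coef * (fix_a[:, None] + b[..., 0])
        C += coef * (fix_c[:, None] + b[..., 1])
    return lp0, A, C


def predict_conditional_survival(params: JointModelParams,
                                 subjects: pd.DataFrame,
                                 markers: pd.DataFrame,
                                 landmark: float,
                                 horizons,
                                 n_draws: int = 500,
                                 seed: int = 0) -> pd.DataFrame:
    """Cohort-level dynamic predictions.

    Uses only marker measurements at or before the landmark. Returns a long
    table (id, landmark, horizon, pi_hat). Horizons beyond the fitted
    baseline-hazard support are flagged in an ``extrapolated`` column.
    """
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    if np.any(horizons < landmark):
        raise ValueError("horizons must be >= landmark")
    history = markers[markers["time_months"] <= landmark]
    n_empty = len(set(subjects["id"]) - set(history["id"]))
    if n_empty:
        logger.info("%d subjects have no history by the landmark; "
                    "population prediction used", n_empty)
    lp0, A, C = _node_lines(params, subjects, history, n_draws, seed)
    S_t = np.exp(-_cumhaz_at(params, lp0, A, C, landmark)).mean(axis=1)
    rows = []
    for u in horizons:
        S_u = np.exp(-_cumhaz_at(params, lp0, A, C, float(u))).mean(axis=1)
        pi = np.clip(S_u / np.maximum(S_t, 1e-300), 0.0, 1.0)
        flagged = bool(u > params.t_max)
        if flagged:
            logger.warning("horizon %.1f beyond baseline-hazard support %.1f; "
                           "extrapolating the last segment", u, params.t_max)
        rows.append(pd.DataFrame({
            "id": subjects["id"].to_numpy(), "landmark": landmark,
            "horizon": u, "pi_hat": pi, "extrapolated": flagged}))
    return pd.concat(rows, ignore_index=True)


def conditional_survival(params: JointModelParams, subject: pd.Series,
                         history: pd.DataFrame, landmark: float, horizons,
                         n_draws: int = 500, seed: int = 0) -> DynamicPrediction:
    """Dynamic prediction for a single subject (see module docstring)."""
    subjects = subject.to_frame().T if isinstance(subject, pd.Series) else subject
    subjects = subjects.reset_index(drop=True)
    df = predict_conditional_survival(params, subjects, history, landmark,
                                      horizons, n_draws=n_draws, seed=seed)
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    return DynamicPrediction(
        subject_id=subjects["id"].iloc[0], landmark=landmark,
        horizons=horizons, survival=df["pi_hat"].to_numpy(),
        extrapolated=df["extrapolated"].to_numpy())


def posterior_random_effects(params: JointModelParams, subject: pd.Series,
                             history: pd.DataFrame, landmark: float,
                             n_draws: int = 500, seed: int = 0) -> dict:
    """Random-effect posterior given history *and* survival to the landmark.

    Returns per-marker draws with importance weights proportional to
    S(landmark | b); the weighted mean shifts toward low-risk trajectories
    whenever the association is nonzero. An empty history falls back to the
    population (prior) distribution, which is logged.
    """
    subjects = (subject.to_frame().T if isinstance(subject, pd.Series)
                else subject).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    hist = history[history["time_months"] <= landmark]
    if hist.empty:
        logger.info("empty history: population random-effect distribution used")
    draws = {}
    k = len(params.markers)
    z = rng.standard_normal((n_draws, 2 * k))
    lp0 = survival_design(subjects) @ params.gamma
    A = np.zeros((1, n_draws))
    C = np.zeros_like(A)
    from ._lmm import build_marker_data

    for j, marker in enumerate(params.markers):
        p = params.longitudinal[marker]
        md = build_marker_data(hist, subjects, marker)
        _, mu, Sigma = marginal_and_posterior(md, p.beta, p.sigma2, p.cov_re)
        b = mu[:, None, :] + np.einsum(
            "nij,qj->nqi", chol2(Sigma), z[:, 2 * j:2 * j + 2])
        draws[marker] = b[0]
        coef = params.alpha[marker] / params.scalings[marker]
        fix_a = p.beta[0] + p.beta[2] * md.arm + p.beta[4] * md.baseline
        fix_c = p.beta[1] + p.beta[3] * md.arm
        A += coef * (fix_a[:, None] + b[..., 0])
        C += coef * (fix_c[:, None] + b[..., 1])
    w = np.exp(-_cumhaz_at(params, lp0, A, C, landmark))[0]
    if w.sum() <= 0.0:
        logger.warning("survival weights vanished at the landmark; "
                       "falling back to unweighted draws")
        w = np.full_like(w, 1.0 / len(w))
    else:
        w = w / w.sum()
    return {
        "draws": draws,
        "weights": w,
        "mean": {m: w @ draws[m] for m in params.markers},
    }
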