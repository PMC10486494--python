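"""Joint models linking marker trajectories to survival.

The longitudinal sub-model for each marker is the linear mixed model of
:mod:`seroprog.longitudinal`; the time-to-event sub-model is proportional
hazards on the nine baseline covariates with a piecewise-constant baseline
hazard on event-time quantile knots. The two are linked through the shared
random effects via a *current value* association: the log hazard at time t
adds ``sum_k alpha_k m_k(t) / scale_k`` where ``m_k(t)`` is the full linear
predictor (fixed + random parts) of marker k at t, and ``scale_k`` the
reporting scale (1 g/dL Hb, 1 NLR point, 100 PLR points, 5 LMR points, 1
log-PSA unit), so exp(alpha_k) is directly the reported hazard ratio.

Because the longitudinal sub-model is Gaussian, the random effects can be
integrated out in two exact steps: the marginal Gaussian likelihood of the
marker series times the expectation of the survival factor under the
closed-form longitudinal posterior of b_i. That expectation is approximated
by pseudo-adaptive Gauss-Hermite quadrature (single marker) or quasi-Monte
Carlo draws (several markers); with the current-value line linear in t and
a piecewise-constant baseline, each subject's cumulative hazard is a sum of
closed-form segment integrals.

Backends
--------
``two_stage``
    Empirical-Bayes current values plugged into a time-varying Cox fit —
    fast, approximate, used for smoke tests and cross-validation loops.
``full_likelihood``
    Maximises the marginalised joint likelihood (all parameters jointly for
    a single marker; the survival block given stage-1 longitudinal ML
    estimates for several markers). Wald intervals.
``bayesian_mcmc``
    Ensemble MCMC (emcee) over the survival block with an optional
    horseshoe prior on the association coefficients; required for
    ``shrinkage="horseshoe"``. Equal-tailed posterior intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm, qmc

from ._lmm import MarkerData, build_marker_data, chol2, marginal_and_posterior
from .cohort import survival_design
from .config import MARKER_SCALES, MARKERS, SURVIVAL_COVARIATES
from .longitudinal import (
    LongitudinalParams,
    fit_lmm_ml,
    unpack_longitudinal,
)
from .survival import endpoint_indicator

logger = logging.getLogger(__name__)

SIGNIFICANCE_THRESHOLD = 0.004  # two-sided, strict inequality

_N_LONG = 9  # packed longitudinal parameters per marker


@dataclass
class JointModelSpec:
    """What to fit: endpoint, marker set, shrinkage, backend, and knobs."""

    endpoint: str = "OS"
    markers: tuple = MARKERS
    shrinkage: str = "none"              # "none" | "horseshoe"
    backend: str = "full_likelihood"     # two_stage | full_likelihood | bayesian_mcmc
    scalings: dict = field(default_factory=lambda: dict(MARKER_SCALES))
    n_baseline_segments: int = 6
    quad_order: int = 5                  # per-dimension GH order (univariate)
    qmc_draws: int = 32                  # QMC draws (multivariate)
    tau0: float = 1.0                    # horseshoe global scale
    n_walkers: int = 48
    n_steps: int = 900
    n_burn: int = 400
    seed: int = 0

    def validate(self):
        if not self.markers:
            raise ValueError("marker set must be nonempty")
        if self.shrinkage not in ("none", "horseshoe"):
            raise ValueError(f"unknown shrinkage {self.shrinkage!r}")
        if self.backend not in ("two_stage", "full_likelihood", "bayesian_mcmc"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.shrinkage == "horseshoe" and self.backend != "bayesian_mcmc":
            raise ValueError("horseshoe shrinkage requires the bayesian_mcmc backend")
        if any(self.scalings[m] <= 0 for m in self.markers):
            raise ValueError("association scalings must be positive")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")


@dataclass
class JointModelParams:
    """Everything needed to evaluate hazards and survival for any subject."""

    endpoint: str
    markers: tuple
    scalings: dict
    longitudinal: dict                    # marker -> LongitudinalParams
    gamma: np.ndarray                     # (9,) baseline-covariate log HRs
    alpha: dict                           # marker -> log HR per reporting scale
    knots: np.ndarray                     # (K+1,) segment bounds, last = inf
    logh0: np.ndarray                     # (K,) log piecewise hazards
    t_max: float = np.inf                 # support of the baseline estimate


class JointModelData:
    """Aligned arrays for one cohort and one endpoint."""

    def __init__(self, markers_df: pd.DataFrame, subjects: pd.DataFrame,
                 spec: JointModelSpec):
        self.subjects = subjects.reset_index(drop=True)
        self.w = survival_design(self.subjects)
        self.T = self.subjects["event_time"].to_numpy(dtype=float)
        self.delta = endpoint_indicator(self.subjects, spec.endpoint)
        if self.delta.sum() == 0:
            raise ValueError(f"no events for endpoint {spec.endpoint}")
        self.marker_data = {m: build_marker_data(markers_df, self.subjects, m)
                            for m in spec.markers}
        self.knots = _quantile_knots(self.T[self.delta == 1],
                                     spec.n_baseline_segments)
        self.lo = np.minimum(self.knots[:-1][None, :], self.T[:, None])
        self.hi = np.minimum(self.knots[1:][None, :], self.T[:, None])
        self.seg_idx = np.clip(np.searchsorted(self.knots, self.T, side="right") - 1,
                               0, len(self.knots) - 2)

    @property
    def n(self):
        return len(self.T)


def _quantile_knots(event_times: np.ndarray, n_segments: int) -> np.ndarray:
    qs = np.quantile(event_times, np.linspace(0, 1, n_segments + 1)[1:-1])
    inner = np.unique(qs)
    return np.concatenate([[0.0], inner, [np.inf]])


def _phi(x):
    """expm1(x)/x, stable near zero."""
    small = np.abs(x) < 1e-8
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 + x / 2.0, np.expm1(safe) / safe)


def survival_loglik_nodes(lp0, A, C, T, delta, logh0, lo, hi, seg_idx):
    """log f(T, delta | b) at each random-effect node.

    ``A``, ``C`` are the (n, Q) association intercepts/slopes already summed
    over markers and multiplied by their coefficients; the hazard is
    h(t) = exp(logh0_seg + lp0 + A + C t).
    """
    K = len(logh0)
    cum = np.zeros_like(A)
    for seg in range(K):
        width = (hi[:, seg] - lo[:, seg])[:, None]
        x = C * width
        expo = np.clip(logh0[seg] + lp0[:, None] + A + C * lo[:, seg][:, None],
                       -745.0, 700.0)
        cum += np.exp(expo) * width * _phi(x)
    death = delta[:, None] * (logh0[seg_idx][:, None] + lp0[:, None]
                              + A + C * T[:, None])
    return death - cum


def _gh_nodes(order: int):
    z, w = np.polynomial.hermite.hermgauss(order)
    z2 = np.stack(np.meshgrid(z, z, indexing="ij"), axis=-1).reshape(-1, 2)
    w2 = np.outer(w, w).reshape(-1)
    return z2, np.log(w2 / np.pi)


def _qmc_normal_nodes(dim: int, n_draws: int, seed: int):
    sob = qmc.Sobol(d=dim, scramble=True, seed=seed)
    u = sob.random(n_draws)
    z = norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    return z, np.full(n_draws, -np.log(n_draws))


class _REIntegrator:
    """Random-effect nodes per marker from the longitudinal posteriors."""

    def __init__(self, data: JointModelData, spec: JointModelSpec):
        self.data = data
        self.spec = spec
        k = len(spec.markers)
        if k == 1:
            self.z, self.logw = _gh_nodes(spec.quad_order)
            self.z_scale = np.sqrt(2.0)
        else:
            self.z, self.logw = _qmc_normal_nodes(2 * k, spec.qmc_draws,
                                                  seed=spec.seed + 7919)
            self.z_scale = 1.0

    def nodes(self, marker_idx: int, mu, Sigma):
        """(b0, b1) node arrays (n, Q) for one marker."""
        L = chol2(Sigma)
        z = self.z[:, 2 * marker_idx: 2 * marker_idx + 2] \
            if self.z.shape[1] > 2 else self.z
        b = mu[:, None, :] + self.z_scale * np.einsum("nij,qj->nqi", L, z)
        return b[..., 0], b[..., 1]


def _association_lines(md: MarkerData, lp: LongitudinalParams):
    """Fixed parts of the current-value line: a_i (less b0) and c_i (less b1)."""
    beta = lp.beta
    fix_a = beta[0] + beta[2] * md.arm + beta[4] * md.baseline
    fix_c = beta[1] + beta[3] * md.arm
    return fix_a, fix_c


def _marginalised_loglik(data: JointModelData, spec: JointModelSpec,
                         long_params: dict, gamma, alpha: dict, logh0,
                         integrator: _REIntegrator,
                         include_longitudinal: bool = True) -> float:
    """Exact-in-form joint log-likelihood with the RE integral approximated."""
    lp0 = data.w @ np.asarray(gamma, dtype=float)
    A = 0.0
    C = 0.0
    total = 0.0
    for k, marker in enumerate(spec.markers):
        md = data.marker_data[marker]
        p = long_params[marker]
        ll_marg, mu, Sigma = marginal_and_posterior(md, p.beta, p.sigma2, p.cov_re)
        if include_longitudinal:
            total += ll_marg.sum()
        b0, b1 = integrator.nodes(k, mu, Sigma)
        coef = alpha[marker] / spec.scalings[marker]
        fix_a, fix_c = _association_lines(md, p)
        A = A + coef * (fix_a[:, None] + b0)
        C = C + coef * (fix_c[:, None] + b1)
    if np.isscalar(A):  # no markers contributed (cannot happen post-validate)
        raise ValueError("empty marker set")
    g = survival_loglik_nodes(lp0, A, C, data.T, data.delta, logh0,
                              data.lo, data.hi, data.seg_idx)
    total += logsumexp(g + integrator.logw[None, :], axis=1).sum()
    return float(total)


def _precomputed_lines(data: JointModelData, spec: JointModelSpec,
                       long_params: dict, integrator: _REIntegrator) -> dict:
    """Per-marker current-value node lines (a, c), fixed given stage-1 fits."""
    lines = {}
    for k, marker in enumerate(spec.markers):
        md = data.marker_data[marker]
        p = long_params[marker]
        _, mu, Sigma = marginal_and_posterior(md, p.beta, p.sigma2, p.cov_re)
        b0, b1 = integrator.nodes(k, mu, Sigma)
        fix_a, fix_c = _association_lines(md, p)
        lines[marker] = (fix_a[:, None] + b0, fix_c[:, None] + b1)
    return lines


def _survival_block_loglik(data: JointModelData, spec: JointModelSpec,
                           lines: dict, gamma, alpha: dict, logh0,
                           integrator: _REIntegrator) -> float:
    """Survival part of the marginalised likelihood with frozen node lines."""
    lp0 = data.w @ np.asarray(gamma, dtype=float)
    A = 0.0
    C = 0.0
    for marker in spec.markers:
        coef = alpha[marker] / spec.scalings[marker]
        A = A + coef * lines[marker][0]
        C = C + coef * lines[marker][1]
    g = survival_loglik_nodes(lp0, A, C, data.T, data.delta, logh0,
                              data.lo, data.hi, data.seg_idx)
    return float(logsumexp(g + integrator.logw[None, :], axis=1).sum())


def joint_log_likelihood(params: JointModelParams, markers_df: pd.DataFrame,
                         subjects: pd.DataFrame, quad_order: int = 5,
                         qmc_draws: int = 256, seed: int = 0) -> float:
    """Joint log-likelihood of a cohort under fully specified parameters."""
    spec = JointModelSpec(endpoint=params.endpoint, markers=tuple(params.markers),
                          scalings=dict(params.scalings), quad_order=quad_order,
                          qmc_draws=qmc_draws, seed=seed,
                          n_baseline_segments=len(params.logh0))
    data = JointModelData(markers_df, subjects, spec)
    data.knots = params.knots
    data.lo = np.minimum(params.knots[:-1][None, :], data.T[:, None])
    data.hi = np.minimum(params.knots[1:][None, :], data.T[:, None])
    data.seg_idx = np.clip(np.searchsorted(params.knots, data.T, side="right") - 1,
                           0, len(params.knots) - 2)
    integrator = _REIntegrator(data, spec)
    return _marginalised_loglik(data, spec, params.longitudinal, params.gamma,
                                params.alpha, params.logh0, integrator)


# ---------------------------------------------------------------------------
# two-stage backend


def _episode_table(data: JointModelData, spec: JointModelSpec,
                   blups: dict) -> pd.DataFrame:
    """Counting-process table with BLUP current values at episode midpoints."""
    T = data.T
    n = data.n
    rows_start, rows_stop, rows_id = [], [], []
    for i in range(n):
        bounds = np.arange(0.0, T[i], 1.0)
        bounds = np.append(bounds, T[i])
        rows_start.append(bounds[:-1])
        rows_stop.append(bounds[1:])
        rows_id.append(np.full(len(bounds) - 1, i))
    start = np.concatenate(rows_start)
    stop = np.concatenate(rows_stop)
    idx = np.concatenate(rows_id).astype(int)
    mid = (start + stop) / 2.0
    event = np.zeros(len(start), dtype=int)
    last = np.concatenate([np.where(np.diff(idx))[0], [len(idx) - 1]])
    event[last] = data.delta[idx[last]]
    df = pd.DataFrame({"sid": idx, "start": start, "stop": stop, "event": event})
    for j, cov in enumerate(SURVIVAL_COVARIATES):
        df[cov] = data.w[idx, j]
    for marker in spec.markers:
        a, c = blups[marker]
        df[f"cur_{marker}"] = (a[idx] + c[idx] * mid) / spec.scalings[marker]
    return df


def _profile_logh0(data: JointModelData, spec: JointModelSpec, gamma,
                   alpha: dict, blups: dict) -> np.ndarray:
    """Piecewise-constant baseline MLE given coefficients and BLUP lines."""
    lp0 = data.w @ gamma
    A = np.zeros(data.n)
    C = np.zeros(data.n)
    for marker in spec.markers:
        a, c = blups[marker]
        coef = alpha[marker] / spec.scalings[marker]
        A += coef * a
        C += coef * c
    K = len(data.knots) - 1
    logh0 = np.empty(K)
    for seg in range(K):
        width = data.hi[:, seg] - data.lo[:, seg]
        x = C * width
        integral = np.exp(lp0 + A + C * data.lo[:, seg]) * width * _phi(x)
        d = np.sum(data.delta[data.seg_idx == seg])
        logh0[seg] = np.log(max(d, 0.5)) - np.log(max(integral.sum(), 1e-300))
    return logh0


def _fit_two_stage(data: JointModelData, spec: JointModelSpec):
    from lifelines import CoxTimeVaryingFitter

    long_params = {m: fit_lmm_ml(data.marker_data[m]) for m in spec.markers}
    blups = {}
    for marker in spec.markers:
        md = data.marker_data[marker]
        p = long_params[marker]
        _, mu, _ = marginal_and_posterior(md, p.beta, p.sigma2, p.cov_re)
        fix_a, fix_c = _association_lines(md, p)
        blups[marker] = (fix_a + mu[:, 0], fix_c + mu[:, 1])

    df = _episode_table(data, spec, blups)
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(df, id_col="sid", start_col="start", stop_col="stop",
                event_col="event")
    est = ctv.params_
    gamma = np.array([est[c] for c in SURVIVAL_COVARIATES])
    alpha = {m: float(est[f"cur_{m}"]) for m in spec.markers}
    logh0 = _profile_logh0(data, spec, gamma, alpha, blups)

    se = {f"gamma:{c}": float(ctv.standard_errors_[c]) for c in SURVIVAL_COVARIATES}
    se.update({f"alpha:{m}": float(ctv.standard_errors_[f"cur_{m}"])
               for m in spec.markers})
    diagnostics = {"backend": "two_stage", "converged": True,
                   "log_partial_likelihood": float(ctv.log_likelihood_)}
    return long_params, gamma, alpha, logh0, se, diagnostics, blups


# ---------------------------------------------------------------------------
# full-likelihood backend


def _pack_long(p: LongitudinalParams) -> np.ndarray:
    sd0 = np.sqrt(p.cov_re[0, 0])
    sd1 = np.sqrt(p.cov_re[1, 1])
    rho = np.clip(p.cov_re[0, 1] / max(sd0 * sd1, 1e-12), -0.999, 0.999)
    return np.concatenate([p.beta, [np.log(max(p.sd_resid, 1e-8)),
                                    np.log(max(sd0, 1e-8)),
                                    np.log(max(sd1, 1e-10)),
                                    np.arctanh(rho)]])


def _fit_full_likelihood(data: JointModelData, spec: JointModelSpec,
                         compute_se: bool = True):
    warm = _fit_two_stage(data, spec)
    long_params, gamma0, alpha0, logh0_0 = warm[0], warm[1], warm[2], warm[3]
    integrator = _REIntegrator(data, spec)
    K = len(data.knots) - 1
    n_mark = len(spec.markers)
    univariate = n_mark == 1
    trace: list = []

    if univariate:
        marker = spec.markers[0]
        theta0 = np.concatenate([_pack_long(long_params[marker]), gamma0,
                                 [alpha0[marker]], logh0_0])

        def unpack(theta):
            lp = {marker: unpack_longitudinal(theta[:_N_LONG], marker)}
            g = theta[_N_LONG:_N_LONG + 9]
            a = {marker: float(theta[_N_LONG + 9])}
            lh = theta[_N_LONG + 10:_N_LONG + 10 + K]
            return lp, g, a, lh
    else:
        theta0 = np.concatenate([gamma0, [alpha0[m] for m in spec.markers],
                                 logh0_0])
        frozen_lines = _precomputed_lines(data, spec, long_params, integrator)

        def unpack(theta):
            g = theta[:9]
            a = {m: float(theta[9 + j]) for j, m in enumerate(spec.markers)}
            lh = theta[9 + n_mark:9 + n_mark + K]
            return long_params, g, a, lh

    def nll(theta):
        lp, g, a, lh = unpack(theta)
        try:
            if univariate:
                val = -_marginalised_loglik(data, spec, lp, g, a, lh, integrator)
            else:
                val = -_survival_block_loglik(data, spec, frozen_lines, g, a,
                                              lh, integrator)
        except FloatingPointError:
            return 1e10
        if not np.isfinite(val):
            return 1e10
        return val

    def record(xk):  # accepted L-BFGS iterates only
        trace.append(nll(xk))

    res = minimize(nll, theta0, method="L-BFGS-B", callback=record,
                   options={"maxiter": 400, "ftol": 1e-9})
    lp, g, a, lh = unpack(res.x)
    diagnostics = {"backend": "full_likelihood", "converged": bool(res.success),
                   "iterations": int(res.nit), "loglik": float(-res.fun),
                   "nll_trace": np.array(trace)}
    if not res.success:
        logger.warning("full-likelihood optimiser flagged non-convergence: %s",
                       res.message)

    se = {}
    if compute_se:
        from ._numdiff import numerical_hessian

        H = numerical_hessian(nll, res.x)
        cov = _safe_inverse(H)
        names = ([f"long:{marker}:{j}" for j in range(_N_LONG)] if univariate else [])
        names += [f"gamma:{c}" for c in SURVIVAL_COVARIATES]
        names += [f"alpha:{m}" for m in spec.markers]
        names += [f"logh0:{seg}" for seg in range(K)]
        sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se = dict(zip(names, sd))
    return lp, np.asarray(g), a, np.asarray(lh), se, diagnostics


def _safe_inverse(H):
    try:
        eigval, eigvec = np.linalg.eigh(H)
        eigval = np.clip(eigval, 1e-10, None)
        return (eigvec / eigval) @ eigvec.T
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# Bayesian (horseshoe) backend


def _fit_bayesian(data: JointModelData, spec: JointModelSpec):
    import emcee

    warm = _fit_two_stage(data, spec)
    long_params, gamma0, alpha0, logh0_0 = warm[0], warm[1], warm[2], warm[3]
    integrator = _REIntegrator(data, spec)
    K = len(data.knots) - 1
    n_mark = len(spec.markers)
    horseshoe = spec.shrinkage == "horseshoe"
    ndim = 9 + n_mark + K + (n_mark + 1 if horseshoe else 0)
    lines = _precomputed_lines(data, spec, long_params, integrator)

    def split(theta):
        g = theta[:9]
        a = theta[9:9 + n_mark]
        lh = theta[9 + n_mark:9 + n_mark + K]
        rest = theta[9 + n_mark + K:]
        return g, a, lh, rest

    def log_prob(theta):
        g, a, lh, rest = split(theta)
        lp = 0.0
        lp += -0.5 * np.sum((g / 2.5) ** 2)
        lp += -0.5 * np.sum(((lh + 4.0) / 3.0) ** 2)
        if horseshoe:
            log_lam, log_tau = rest[:n_mark], rest[n_mark]
            lam, tau = np.exp(log_lam), np.exp(log_tau)
            if np.any(lam > 1e6) or tau > 1e6:
                return -np.inf
            # half-Cauchy priors on lambda_k and tau (scale tau0), log-space
            lp += np.sum(np.log(2.0 / np.pi) - np.log1p(lam ** 2) + log_lam)
            lp += (np.log(2.0 / (np.pi * spec.tau0))
                   - np.log1p((tau / spec.tau0) ** 2) + log_tau)
            scale = np.maximum(tau * lam, 1e-12)
            lp += np.sum(-0.5 * (a / scale) ** 2 - np.log(scale))
        else:
            lp += -0.5 * np.sum((a / 2.5) ** 2)
        alpha = {m: float(a[j]) for j, m in enumerate(spec.markers)}
        try:
            ll = _survival_block_loglik(data, spec, lines, g, alpha, lh,
                                        integrator)
        except FloatingPointError:
            return -np.inf
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll

    rng = np.random.default_rng(spec.seed + 424243)
    center = np.concatenate([
        gamma0, [alpha0[m] for m in spec.markers], logh0_0,
        np.zeros(n_mark + 1) - 0.5 if horseshoe else np.zeros(0)])
    n_walkers = max(spec.n_walkers, 2 * ndim + 4)
    p0 = center[None, :] + 0.02 * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    sampler.random_state = np.random.RandomState(spec.seed + 11).get_state()
    sampler.run_mcmc(p0, spec.n_steps, progress=False,
                     skip_initial_state_check=True)
    chain = sampler.get_chain(discard=spec.n_burn, flat=True)
    acc = float(np.mean(sampler.acceptance_fraction))
    if acc < 0.05:
        warnings.warn(f"MCMC acceptance fraction low ({acc:.3f}); "
                      "treat posterior summaries with caution")

    med = np.median(chain, axis=0)
    g, a, lh, _ = split(med)
    alpha = {m: float(a[j]) for j, m in enumerate(spec.markers)}
    gamma = np.asarray(g)
    # recompute the baseline profile at the posterior-median coefficients so
    # absolute predictions stay internally consistent
    blups = warm[6]
    logh0 = _profile_logh0(data, spec, gamma, alpha, blups)

    names = [f"gamma:{c}" for c in SURVIVAL_COVARIATES] \
        + [f"alpha:{m}" for m in spec.markers] \
        + [f"logh0:{seg}" for seg in range(K)]
    draws = {name: chain[:, j] for j, name in enumerate(names)}
    se = {name: float(np.std(draws[name])) for name in names}
    diagnostics = {"backend": "bayesian_mcmc", "converged": acc > 0.05,
                   "acceptance_fraction": acc,
                   "n_samples": int(chain.shape[0]),
                   "draws": draws}
    return long_params, gamma, alpha, logh0, se, diagnostics


# ---------------------------------------------------------------------------
# model / results


class JointModel:
    """Joint longitudinal-survival model for a cohort.

    Parameters
    ----------
    markers : long-format marker table (id, marker, time_months, value).
    subjects : one-row-per-subject table with baseline covariates and
        (event_time, event, cause).
    spec : which endpoint, markers, backend and shrinkage to use.
    """

    def __init__(self, markers: pd.DataFrame, subjects: pd.DataFrame,
                 spec: JointModelSpec):
        spec.validate()
        self.spec = spec
        self.data = JointModelData(markers, subjects, spec)

    def fit(self, compute_se: bool = True) -> "JointModelResults":
        spec = self.spec
        if spec.backend == "two_stage":
            lp, g, a, lh, se, diag, _ = _fit_two_stage(self.data, spec)
        elif spec.backend == "full_likelihood":
            lp, g, a, lh, se, diag = _fit_full_likelihood(self.data, spec,
                                                          compute_se=compute_se)
        else:
            lp, g, a, lh, se, diag = _fit_bayesian(self.data, spec)
        params = JointModelParams(
            endpoint=spec.endpoint, markers=tuple(spec.markers),
            scalings=dict(spec.scalings), longitudinal=lp,
            gamma=np.asarray(g), alpha=dict(a),
            knots=self.data.knots, logh0=np.asarray(lh),
            t_max=float(self.data.T.max()))
        return JointModelResults(self, params, se, diag)


class JointModelResults:
    """Fitted joint model: estimates, intervals, and reporting tables."""

    def __init__(self, model: JointModel, params: JointModelParams,
                 se: dict, diagnostics: dict):
        self.model = model
        self.spec = model.spec
        self.params = params
        self.se = se
        self.diagnostics = diagnostics

    @property
    def interval_type(self) -> str:
        return ("equal-tailed posterior"
                if self.diagnostics.get("backend") == "bayesian_mcmc" else "Wald")

    def hazard_ratio(self, marker: str) -> float:
        """Reported HR for a marker association on its reporting scale."""
        return float(np.exp(self.params.alpha[marker]))

    def _row(self, name: str, label: str, est: float) -> dict:
        draws = self.diagnostics.get("draws", {})
        if name in draws:
            d = draws[name]
            lo, hi = np.quantile(d, [0.025, 0.975])
            tail = min(np.mean(d > 0.0), np.mean(d < 0.0))
            p = float(min(1.0, 2.0 * max(tail, 1.0 / len(d))))
        else:
            s = self.se.get(name, np.nan)
            lo, hi = est - 1.959964 * s, est + 1.959964 * s
            p = float(2.0 * norm.sf(abs(est) / s)) if s and np.isfinite(s) and s > 0 \
                else np.nan
        return {"parameter": label, "hazard_ratio": float(np.exp(est)),
                "lower_ci": float(np.exp(lo)), "upper_ci": float(np.exp(hi)),
                "p_value": p,
                "significant": bool(p < SIGNIFICANCE_THRESHOLD)
                if np.isfinite(p) else False}

    def hazard_ratio_table(self) -> pd.DataFrame:
        """One row per survival covariate and association, reporting scales."""
        rows = []
        for j, cov in enumerate(SURVIVAL_COVARIATES):
            rows.append(self._row(f"gamma:{cov}", cov, float(self.params.gamma[j])))
        unit = {"Hb": "1 g/dL", "NLR": "1 point", "PLR": "100 points",
                "LMR": "5 points", "PSA": "1 log-unit"}
        for marker in self.params.markers:
            rows.append(self._row(
                f"alpha:{marker}",
                f"current {marker} (per {unit.get(marker, 'unit')})",
                float(self.params.alpha[marker])))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        t = self.hazard_ratio_table()
        lines = [
            f"Joint model [{self.params.endpoint}] markers={list(self.params.markers)}",
            f"backend={self.diagnostics.get('backend')} "
            f"shrinkage={self.spec.shrinkage} intervals={self.interval_type}",
            t.to_string(index=False, float_format=lambda v: f"{v:0.4f}"),
        ]
        return "\n".join(lines)


def fit_univariate_joint(markers: pd.DataFrame, subjects: pd.DataFrame,
                         marker: str, endpoint: str = "OS",
                         backend: str = "full_likelihood",
                         compute_se: bool = True, seed: int = 0,
                         **kwargs) -> JointModelResults:
    """Univariate joint model for one marker (association HR on its scale)."""
    spec = JointModelSpec(endpoint=endpoint, markers=(marker,), backend=backend,
                          seed=seed, **kwargs)
    return JointModel(markers, subjects, spec).fit(compute_se=compute_se)


def fit_multivariate_joint(markers_df: pd.DataFrame, subjects: pd.DataFrame,
                           markers: tuple = MARKERS, endpoint: str = "OS",
                           shrinkage: str = "horseshoe",
                           backend: str = "bayesian_mcmc", seed: int = 0,
                           **kwargs) -> JointModelResults:
    """Multivariate joint model, horseshoe-regularised by default."""
    if len(markers) < 2:
        raise ValueError("multivariate joint model needs >= 2 markers")
    spec = JointModelSpec(endpoint=endpoint, markers=tuple(markers),
                          shrinkage=shrinkage, backend=backend, seed=seed,
                          **kwargs)
    return JointModel(markers_df, subjects, spec).fit()
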