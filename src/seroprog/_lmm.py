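"""Vectorised linear-mixed-model kernels.

For one marker the observation model is

    y_ij = x_ij' beta + z_ij' b_i + eps_ij,
    b_i ~ N(0, D),  eps_ij ~ N(0, sigma^2),

with x = [1, t, arm, arm*t, baseline] and z = [1, t]. Because everything
is Gaussian, the marginal likelihood of each subject's data and the
posterior of b_i are available in closed form from per-subject sufficient
statistics; all formulas below are vectorised over subjects with 2x2
linear algebra written out explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import modelling_scale

N_FIXED = 5  # intercept, time, arm, arm*time, baseline

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MarkerData:
    """Sufficient statistics of one marker's series, aligned to a subject order."""

    marker: str
    ids: np.ndarray          # (n,) subject ids in canonical order
    n_obs: np.ndarray        # (n,)
    XX: np.ndarray           # (n, 5, 5)
    Xy: np.ndarray           # (n, 5)
    yy: np.ndarray           # (n,)
    ZX: np.ndarray           # (n, 2, 5)
    Zy: np.ndarray           # (n, 2)
    ZZ: np.ndarray           # (n, 2, 2)
    arm: np.ndarray          # (n,)
    baseline: np.ndarray     # (n,) modelling scale

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def total_obs(self) -> int:
        return int(self.n_obs.sum())


def design_row(t, arm, baseline):
    """Fixed-effect design [1, t, arm, arm*t, baseline] (vectorised in t)."""
    t = np.asarray(t, dtype=float)
    one = np.ones_like(t)
    return np.stack([one, t, arm * one, arm * t, baseline * one], axis=-1)


def build_marker_data(markers: pd.DataFrame, subjects: pd.DataFrame,
                      marker: str) -> "MarkerData":
    """Accumulate per-subject sufficient statistics for one marker.

    The response is on the modelling scale (log(x+1) for PSA) and consists
    of the post-baseline measurements only: the t=0 measurement *is* the
    baseline covariate, so it enters every fixed-effect row rather than the
    response (modelling it twice would make its residual degenerate).
    """
    sub = markers[(markers["marker"] == marker) & (markers["time_months"] > 0)]
    order_set = set(subjects["id"])
    sub = sub[sub["id"].isin(order_set)]
    order = subjects["id"].to_numpy()
    pos = {sid: k for k, sid in enumerate(order)}
    n = len(order)
    arm = subjects["arm"].to_numpy(dtype=float)
    baseline = modelling_scale(
        marker, subjects[f"baseline_{marker.lower()}"].to_numpy())

    idx = np.fromiter((pos[s] for s in sub["id"]), count=len(sub), dtype=int)
    t = sub["time_months"].to_numpy(dtype=float)
    y = modelling_scale(marker, sub["value"].to_numpy())
    X = design_row(t, arm[idx], baseline[idx])          # (m, 5)
    Z = np.stack([np.ones_like(t), t], axis=-1)          # (m, 2)

    def acc(prod, shape):
        out = np.zeros((n,) + shape)
        np.add.at(out, idx, prod)
        return out

    return MarkerData(
        marker=marker, ids=order,
        n_obs=np.bincount(idx, minlength=n).astype(float),
        XX=acc(X[:, :, None] * X[:, None, :], (N_FIXED, N_FIXED)),
        Xy=acc(X * y[:, None], (N_FIXED,)),
        yy=acc(y * y, ()),
        ZX=acc(Z[:, :, None] * X[:, None, :], (2, N_FIXED)),
        Zy=acc(Z * y[:, None], (2,)),
        ZZ=acc(Z[:, :, None] * Z[:, None, :], (2, 2)),
        arm=arm, baseline=baseline,
    )


def cov_from_unconstrained(log_sd0, log_sd1, atanh_rho):
    sd0, sd1 = np.exp(log_sd0), np.exp(log_sd1)
    rho = np.tanh(atanh_rho)
    return np.array([[sd0 ** 2, rho * sd0 * sd1],
                     [rho * sd0 * sd1, sd1 ** 2]])


def _inv2(M):
    """Inverse and determinant of stacked 2x2 matrices."""
    a, b, c, d = M[..., 0, 0], M[..., 0, 1], M[..., 1, 0], M[..., 1, 1]
    det = a * d - b * c
    inv = np.empty_like(M)
    inv[..., 0, 0] = d
    inv[..., 0, 1] = -b
    inv[..., 1, 0] = -c
    inv[..., 1, 1] = a
    return inv / det[..., None, None], det


def chol2(S):
    """Cholesky factors of stacked SPD 2x2 matrices."""
    l11 = np.sqrt(np.maximum(S[..., 0, 0], 1e-300))
    l21 = S[..., 1, 0] / l11
    l22 = np.sqrt(np.maximum(S[..., 1, 1] - l21 ** 2, 1e-300))
    L = np.zeros_like(S)
    L[..., 0, 0] = l11
    L[..., 1, 0] = l21
    L[..., 1, 1] = l22
    return L


def marginal_and_posterior(data: MarkerData, beta, sigma2, D):
    """Per-subject marginal Gaussian log-likelihood and posterior of b_i.

    Returns (loglik (n,), mu (n, 2), Sigma (n, 2, 2)). Subjects with no
    observations get loglik 0 and the prior as posterior.
    """
    beta = np.asarray(beta, dtype=float)
    Zr = data.Zy - data.ZX @ beta                                   # (n, 2)
    rr = (data.yy - 2.0 * data.Xy @ beta
          + np.einsum("i,nij,j->n", beta, data.XX, beta))           # (n,)
    Dinv, detD = _inv2(np.asarray(D)[None, :, :])
    A = sigma2 * Dinv + data.ZZ                                     # (n, 2, 2)
    Ainv, detA = _inv2(A)
    quad = (rr - np.einsum("ni,nij,nj->n", Zr, Ainv, Zr)) / sigma2
    logdetV = data.n_obs * np.log(sigma2) + np.log(detD * detA) - 2.0 * np.log(sigma2)
    loglik = -0.5 * (data.n_obs * _LOG2PI + logdetV + quad)
    mu = np.einsum("nij,nj->ni", Ainv, Zr)
    Sigma = sigma2 * Ainv
    empty = data.n_obs == 0
    if np.any(empty):
        loglik = np.where(empty, 0.0, loglik)
        mu[empty] = 0.0
        Sigma[empty] = np.asarray(D)
    return loglik, mu, Sigma
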