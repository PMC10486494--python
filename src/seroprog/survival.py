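"""Cox proportional-hazards sub-model on the nine baseline covariates.

Endpoints: overall survival (OS; any death) and prostate-cancer-specific
survival (PCSS; other-cause deaths censored). Coefficient estimation goes
through lifelines; the Breslow cumulative baseline hazard needed for
absolute risk predictions is computed here as an explicit step function.
Simulated event times are continuous, so tie conventions only matter for
rounded inputs (lifelines applies Efron's correction when ties occur).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .cohort import CAUSE_CANCER, survival_design
from .config import SURVIVAL_COVARIATES

ENDPOINTS = ("OS", "PCSS")


class NoEventsError(ValueError):
    """The requested endpoint has zero events."""


def endpoint_indicator(subjects: pd.DataFrame, endpoint: str) -> np.ndarray:
    """Event indicator for OS (any death) or PCSS (cancer death only)."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")
    if endpoint == "OS":
        return subjects["event"].to_numpy(dtype=int)
    return ((subjects["event"] == 1)
            & (subjects["cause"] == CAUSE_CANCER)).to_numpy(dtype=int)


class BreslowBaseline:
    """Nondecreasing step-function estimate of the cumulative baseline hazard.

    Jumps only at observed event times: dH0(t_j) = d_j / sum_{i at risk}
    exp(lp_i). H0(t) = 0 before the first event.
    """

    def __init__(self, times, events, linear_predictors):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        lp = np.asarray(linear_predictors, dtype=float)
        order = np.argsort(times, kind="mergesort")
        t_sorted, e_sorted, risk = times[order], events[order], np.exp(lp[order])
        # risk-set sums via reverse cumulative sum
        rev_cum = np.cumsum(risk[::-1])[::-1]
        event_times = np.unique(t_sorted[e_sorted == 1])
        jumps = []
        for et in event_times:
            at = t_sorted == et
            d = int(e_sorted[at].sum())
            denom = rev_cum[np.searchsorted(t_sorted, et, side="left")]
            jumps.append(d / denom)
        self.event_times = event_times
        self.cumhaz = np.cumsum(jumps) if len(jumps) else np.array([])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.cumhaz.size == 0:
            return np.zeros_like(t)
        idx = np.searchsorted(self.event_times, t, side="right")
        padded = np.concatenate([[0.0], self.cumhaz])
        return padded[idx]


def breslow_baseline(times, events, linear_predictors=None) -> BreslowBaseline:
    """Breslow estimator; a null model corresponds to all-zero predictors."""
    if linear_predictors is None:
        linear_predictors = np.zeros(len(np.asarray(times)))
    return BreslowBaseline(times, events, linear_predictors)


class CoxBaselineModel:
    """statsmodels-style model: Cox PH on the nine baseline covariates."""

    def __init__(self, subjects: pd.DataFrame, endpoint: str = "OS"):
        self.subjects = subjects
        self.endpoint = endpoint
        self.event = endpoint_indicator(subjects, endpoint)
        if self.event.sum() == 0:
            raise NoEventsError(f"no events for endpoint {endpoint}")
        self.design = pd.DataFrame(survival_design(subjects),
                                   columns=list(SURVIVAL_COVARIATES))

    def fit(self) -> "CoxResults":
        df = self.design.copy()
        df["event_time"] = self.subjects["event_time"].to_numpy()
        df["event"] = self.event
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="event_time", event_col="event")
        coef = cph.params_.to_numpy()
        lp = self.design.to_numpy() @ coef
        baseline = BreslowBaseline(df["event_time"], df["event"], lp)
        return CoxResults(self, cph, baseline)


class CoxResults:
    """Fitted Cox sub-model with Breslow baseline and a Table-style summary."""

    def __init__(self, model: CoxBaselineModel, cph: CoxPHFitter,
                 baseline: BreslowBaseline):
        self.model = model
        self._cph = cph
        self.baseline_cumhaz = baseline
        self.ties = "efron-if-tied"
        self.params = cph.params_.copy()
        self.log_partial_likelihood = float(cph.log_likelihood_)

    def linear_predictor(self, subjects: pd.DataFrame | None = None) -> np.ndarray:
        design = (self.model.design.to_numpy() if subjects is None
                  else survival_design(subjects))
        return design @ self.params.to_numpy()

    def predict_survival(self, subjects: pd.DataFrame | None, times) -> np.ndarray:
        """S(t | w) = exp(-H0(t) exp(gamma' w)); rows subjects, cols times."""
        lp = self.linear_predictor(subjects)
        H0 = self.baseline_cumhaz(np.asarray(times, dtype=float))
        return np.exp(-np.outer(np.exp(lp), H0))

    def summary(self) -> pd.DataFrame:
        s = self._cph.summary
        out = pd.DataFrame({
            "parameter": s.index,
            "coef": s["coef"].to_numpy(),
            "hazard_ratio": s["exp(coef)"].to_numpy(),
            "lower_ci": s["exp(coef) lower 95%"].to_numpy(),
            "upper_ci": s["exp(coef) upper 95%"].to_numpy(),
            "p_value": s["p"].to_numpy(),
        }).reset_index(drop=True)
        return out


def fit_cox(subjects: pd.DataFrame, endpoint: str = "OS") -> CoxResults:
    """Convenience wrapper: build and fit the baseline Cox sub-model."""
    return CoxBaselineModel(subjects, endpoint).fit()
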