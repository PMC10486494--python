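"""Decision curve analysis of dynamic predictions.

Net benefit at a risk threshold p compares the policy "treat every subject
whose predicted event risk is >= p" against treating everyone or no one:

    NB_model(p) = TP/n - p/(1-p) * FP/n
    NB_all(p)   = prev - p/(1-p) * (1 - prev)
    NB_none     = 0

where TP and FP are IPCW-weighted counts of flagged subjects with and
without an event by the horizon, and prev the IPCW event prevalence —
the same censoring adjustment as the Brier module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import horizon_status, ipcw_weights


@dataclass
class NetBenefitCurve:
    """Net benefit of model, treat-all and treat-none over a threshold grid."""

    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    horizon: float
    prevalence: float

    @property
    def nb_none(self) -> np.ndarray:
        return np.zeros_like(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "nb_model": self.nb_model,
            "nb_all": self.nb_all, "nb_none": self.nb_none})

    def superior_interval(self) -> tuple | None:
        """Widest contiguous threshold run where NB_model > max(NB_all, 0)."""
        better = self.nb_model > np.maximum(self.nb_all, 0.0)
        best = None
        start = None
        for i, flag in enumerate(better):
            if flag and start is None:
                start = i
            if (not flag or i == len(better) - 1) and start is not None:
                end = i if flag else i - 1
                if best is None or end - start > best[1] - best[0]:
                    best = (start, end)
                start = None
        if best is None:
            return None
        return float(self.thresholds[best[0]]), float(self.thresholds[best[1]])


def default_thresholds():
    return np.round(np.arange(0.01, 0.601, 0.01), 10)


def net_benefit_curve(pred_event_prob, outcomes: pd.DataFrame, u: float,
                      thresholds=None) -> NetBenefitCurve:
    """Net-benefit curve of predicted event probabilities at horizon ``u``."""
    risk = np.asarray(pred_event_prob, dtype=float)
    if len(risk) != len(outcomes):
        raise ValueError("predictions and outcomes refer to different subject sets")
    thresholds = (default_thresholds() if thresholds is None
                  else np.atleast_1d(np.asarray(thresholds, dtype=float)))
    if np.any(thresholds <= 0.0):
        raise ValueError("thresholds must be strictly positive")
    if np.any(thresholds >= 1.0):
        warnings.warn("thresholds at or above 1 capped at 0.99")
        thresholds = np.minimum(thresholds, 0.99)
    w = ipcw_weights(outcomes, u)
    n = len(outcomes)
    event_by_u, at_risk = horizon_status(outcomes, u)
    prev = float(np.sum(w[event_by_u]) / n)
    nb_model = np.empty(len(thresholds))
    for j, p in enumerate(thresholds):
        flag = risk >= p
        tp = np.sum(w[flag & event_by_u]) / n
        fp = np.sum(w[flag & at_risk]) / n
        nb_model[j] = tp - p / (1.0 - p) * fp
    odds = thresholds / (1.0 - thresholds)
    nb_all = prev - odds * (1.0 - prev)
    return NetBenefitCurve(thresholds=thresholds, nb_model=nb_model,
                           nb_all=nb_all, horizon=u, prevalence=prev)
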