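"""Canned generating scenarios for recovery studies.

These encode the effect sizes the package treats as ground truth when
benchmarking its estimators on synthetic cohorts: the published univariate
overall-survival associations of each marker's current value, and the
published five-marker multivariate association/covariate set. Other-cause
mortality is set negligibly small in recovery scenarios so the generating
OS hazard is exactly the proportional-hazards form the estimators assume
(with a material competing hazard, the OS association is no longer the
clean generating estimand).
"""

from __future__ import annotations

import math

from .config import MARKERS, SimulationConfig

#: univariate OS hazard ratios of the current marker value, on the
#: reporting scales (Hb per g/dL, NLR per point, PLR per 100, LMR per 5)
UNIVARIATE_OS_HR = {"Hb": 0.77, "NLR": 1.29, "PLR": 1.60, "LMR": 0.53}

#: five-marker multivariate OS model: association HRs per reporting scale
MULTIVARIATE_OS_HR = {"Hb": 0.88, "NLR": 1.26, "PLR": 0.97, "LMR": 1.02,
                      "PSA": 1.24}

#: five-marker multivariate OS model: baseline-covariate HRs (arm expressed
#: for the experimental arm, i.e. inverted from control-vs-experimental)
MULTIVARIATE_OS_GAMMA_HR = {
    "arm": 1.0 / 0.87,
    "skeletal_ge10": 1.34,
    "ecog_ge1": 1.33,
    "nodal_n1": 1.14,
    "liver_met": 1.78,
    "gleason_9_10": 1.17,
    "worst_pain": 1.04,
    "baseline_hb": 0.99,
    "log_baseline_psa": 0.92,
}

_NEGLIGIBLE_HAZARD = 1e-8


def univariate_recovery_config(marker: str, n_subjects: int = 600,
                               seed: int = 1) -> SimulationConfig:
    """Cohort whose OS hazard depends on one marker's current value only.

    The generating association is the published univariate OS hazard ratio
    for that marker; all other associations are zero and every other
    generator default is untouched.
    """
    cfg = SimulationConfig(n_subjects=n_subjects, seed=seed)
    cfg.survival_params.alpha = {m: 0.0 for m in MARKERS}
    cfg.survival_params.alpha[marker] = math.log(UNIVARIATE_OS_HR[marker])
    cfg.survival_params.othercause_hazard = _NEGLIGIBLE_HAZARD
    return cfg


def null_association_config(n_subjects: int = 200, seed: int = 1) -> SimulationConfig:
    """Cohort with every marker association set to zero (calibration runs)."""
    cfg = SimulationConfig(n_subjects=n_subjects, seed=seed)
    cfg.survival_params.alpha = {m: 0.0 for m in MARKERS}
    cfg.survival_params.othercause_hazard = _NEGLIGIBLE_HAZARD
    return cfg


def multivariate_recovery_config(n_subjects: int = 600,
                                 seed: int = 42) -> SimulationConfig:
    """Cohort generated from the five-marker multivariate OS effect sizes."""
    cfg = SimulationConfig(n_subjects=n_subjects, seed=seed)
    cfg.survival_params.alpha = {m: math.log(MULTIVARIATE_OS_HR[m])
                                 for m in MARKERS}
    cfg.survival_params.gamma = {c: math.log(h)
                                 for c, h in MULTIVARIATE_OS_GAMMA_HR.items()}
    cfg.survival_params.othercause_hazard = _NEGLIGIBLE_HAZARD
    return cfg


def psa_dominant_config(n_subjects: int = 500, seed: int = 1) -> SimulationConfig:
    """Cohort where the PSA trajectory carries the only marker association.

    Used for decision-curve contrasts: a model without the PSA trajectory
    retains only baseline-covariate discrimination.
    """
    cfg = SimulationConfig(n_subjects=n_subjects, seed=seed)
    cfg.survival_params.alpha = {m: 0.0 for m in MARKERS}
    cfg.survival_params.alpha["PSA"] = math.log(MULTIVARIATE_OS_HR["PSA"])
    cfg.survival_params.othercause_hazard = _NEGLIGIBLE_HAZARD
    return cfg
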