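"""Configuration objects for the synthetic mHSPC trial generator.

Defaults emulate a two-arm randomised trial of abiraterone + ADT versus ADT
alone in high-risk de novo metastatic hormone-sensitive prostate cancer:
1138 subjects (563 experimental / 575 control), laboratory visits monthly in
the first year and every other month thereafter, five serological markers
(Hb, NLR, PLR, LMR, PSA) evolving as linear mixed trajectories, and death
times whose log hazard depends on the markers' current model-implied values.
Time is measured in months from randomisation throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

MARKERS = ("Hb", "NLR", "PLR", "LMR", "PSA")

#: reporting scale of the association coefficient for each marker:
#: Hb per 1 g/dL, NLR per 1 point, PLR per 100 points, LMR per 5 points,
#: PSA per 1 unit of log(PSA + 1).
MARKER_SCALES = {"Hb": 1.0, "NLR": 1.0, "PLR": 100.0, "LMR": 5.0, "PSA": 1.0}

#: markers modelled after a log(x + 1) transform
LOG1P_MARKERS = ("PSA",)

#: baseline covariates of the time-to-event sub-model, in canonical order
SURVIVAL_COVARIATES = (
    "arm",
    "ecog_ge1",
    "skeletal_ge10",
    "liver_met",
    "nodal_n1",
    "gleason_9_10",
    "worst_pain",
    "baseline_hb",
    "log_baseline_psa",
)


class ConfigError(ValueError):
    """Raised when a simulation configuration fails validation."""


@dataclass
class TrajectoryParams:
    """Linear mixed trajectory for one marker (modelling scale).

    The subject-level current value is

        m_i(t) = beta0 + b0_i + (beta_t + b1_i) t
                 + beta_arm * arm_i + beta_arm_t * arm_i * t
                 + beta_base * baseline_i

    with (b0, b1) bivariate normal and i.i.d. Gaussian residuals on the
    observations. Slopes are per month.
    """

    beta0: float = 0.0
    beta_t: float = 0.0
    beta_arm: float = 0.0
    beta_arm_t: float = 0.0
    beta_base: float = 1.0
    sd_b0: float = 0.5
    sd_b1: float = 0.03
    corr_b0b1: float = 0.0
    sd_resid: float = 0.5

    def validate(self, name: str = "marker") -> None:
        if min(self.sd_b0, self.sd_b1, self.sd_resid) < 0:
            raise ConfigError(f"{name}: standard deviations must be >= 0")
        if abs(self.corr_b0b1) > 1:
            raise ConfigError(f"{name}: |corr_b0b1| must be <= 1")


@dataclass
class BaselineParams:
    """Marginal distributions of the baseline covariates.

    Continuous markers use a normal (Hb) or log-normal (PSA and the three
    blood-count ratios) marginal matched to the trial's published medians
    and interquartile ranges; binary covariates use published prevalences.
    Baseline covariates are drawn independently (only marginals are known).
    """

    hb_mean: float = 13.2
    hb_sd: float = 1.7
    psa_log_mu: float = 2.80  # log ng/mL
    psa_log_sd: float = 2.30
    nlr_log_mu: float = math.log(2.2)
    nlr_log_sd: float = 0.47
    plr_log_mu: float = math.log(138.0)
    plr_log_sd: float = 0.39
    lmr_log_mu: float = math.log(4.75)
    lmr_log_sd: float = 0.38
    p_ecog_ge1: float = 0.448
    p_skeletal_ge10: float = 0.654
    p_liver_met: float = 0.051
    p_nodal_n1: float = 0.466
    p_gleason_9_10: float = 0.519
    # worst pain 0-10: decaying mass with median 1, Q3 = 4
    pain_probs: tuple = (0.35, 0.17, 0.12, 0.09, 0.08, 0.06, 0.05, 0.04, 0.02, 0.01, 0.01)

    def validate(self) -> None:
        probs = (self.p_ecog_ge1, self.p_skeletal_ge10, self.p_liver_met,
                 self.p_nodal_n1, self.p_gleason_9_10)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("binary covariate prevalences must lie in [0, 1]")
        if abs(sum(self.pain_probs) - 1.0) > 1e-9 or len(self.pain_probs) != 11:
            raise ConfigError("pain_probs must be 11 probabilities summing to 1")


def _default_marker_params() -> dict:
    return {
        "Hb": TrajectoryParams(beta_t=0.020, beta_arm_t=0.015,
                               sd_b0=0.70, sd_b1=0.035, corr_b0b1=-0.2, sd_resid=0.70),
        "NLR": TrajectoryParams(beta_t=0.012, beta_arm_t=-0.012,
                                sd_b0=0.55, sd_b1=0.030, corr_b0b1=-0.1, sd_resid=0.60),
        "PLR": TrajectoryParams(beta_t=0.60, beta_arm_t=-0.50,
                                sd_b0=30.0, sd_b1=1.50, corr_b0b1=-0.1, sd_resid=28.0),
        "LMR": TrajectoryParams(beta_t=-0.015, beta_arm_t=0.015,
                                sd_b0=1.00, sd_b1=0.035, corr_b0b1=-0.1, sd_resid=0.90),
        # PSA trajectory on the log(x+1) scale; ADT drives PSA down, more so
        # in the experimental arm.
        "PSA": TrajectoryParams(beta_t=-0.060, beta_arm_t=-0.030,
                                sd_b0=0.30, sd_b1=0.055, corr_b0b1=0.1, sd_resid=0.30),
    }


def _default_gamma() -> dict:
    # log hazard ratios for the nine baseline covariates (arm coded 1 for
    # the experimental arm, hence negative = protective)
    return {
        "arm": -0.45,
        "ecog_ge1": 0.27,
        "skeletal_ge10": 0.50,
        "liver_met": 0.45,
        "nodal_n1": 0.08,
        "gleason_9_10": 0.18,
        "worst_pain": 0.05,
        "baseline_hb": -0.01,
        "log_baseline_psa": -0.05,
    }


def _default_alpha() -> dict:
    # association log hazard ratios on the reporting scales (per 1 g/dL Hb,
    # per NLR point, per 100 PLR points, per 5 LMR points, per log-PSA unit)
    return {
        "Hb": math.log(0.88),
        "NLR": math.log(1.26),
        "PLR": math.log(0.97),
        "LMR": math.log(1.02),
        "PSA": math.log(1.24),
    }


def _default_marker_ref() -> dict:
    # cohort-typical current values on the modelling scale; the association
    # is centred here so the Weibull baseline is the hazard of a typical
    # trajectory and event rates stay realistic across alpha scenarios
    return {"Hb": 13.2, "NLR": 2.3, "PLR": 140.0, "LMR": 4.75,
            "PSA": math.log(16.0 + 1.0)}


@dataclass
class SurvivalParams:
    """Cause-specific hazard structure of the generator.

    Prostate-cancer death: Weibull baseline hazard (months) times
    exp(gamma' w + sum_k alpha_k (m_k(t) - ref_k) / scale_k). Other-cause
    death: constant competing hazard. ``alpha`` is stored on the reporting
    scales (see :data:`MARKER_SCALES`); ``marker_ref`` centres the
    association at cohort-typical values (a constant absorbed by the
    baseline hazard of any fitted model, so estimands are unchanged).
    """

    weibull_shape: float = 1.3
    weibull_scale: float = 80.0
    gamma: dict = field(default_factory=_default_gamma)
    alpha: dict = field(default_factory=_default_alpha)
    marker_ref: dict = field(default_factory=_default_marker_ref)
    othercause_hazard: float = 0.0015  # per month

    def validate(self) -> None:
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ConfigError("Weibull shape and scale must be > 0")
        if self.othercause_hazard <= 0:
            raise ConfigError("othercause_hazard must be > 0")
        missing = set(SURVIVAL_COVARIATES) - set(self.gamma)
        if missing:
            raise ConfigError(f"gamma missing covariates: {sorted(missing)}")
        missing = set(MARKERS) - set(self.alpha)
        if missing:
            raise ConfigError(f"alpha missing markers: {sorted(missing)}")


@dataclass
class SimulationConfig:
    """Full description of one synthetic trial cohort."""

    n_subjects: int = 1138
    arm_allocation: float = 563 / 1138
    followup_max: float = 60.0
    marker_params: dict = field(default_factory=_default_marker_params)
    baseline_params: BaselineParams = field(default_factory=BaselineParams)
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    censoring_rate: float = 0.003  # per-month exponential random censoring
    missing_visit_prob: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if not 0.0 <= self.arm_allocation <= 1.0:
            raise ConfigError("arm_allocation must lie in [0, 1]")
        if self.followup_max <= 0:
            raise ConfigError("followup_max must be > 0")
        if not 0.0 <= self.missing_visit_prob <= 1.0:
            raise ConfigError("missing_visit_prob must lie in [0, 1]")
        if self.censoring_rate < 0:
            raise ConfigError("censoring_rate must be >= 0")
        missing = set(MARKERS) - set(self.marker_params)
        if missing:
            raise ConfigError(f"marker_params missing markers: {sorted(missing)}")
        for name, tp in self.marker_params.items():
            tp.validate(name)
        self.baseline_params.validate()
        self.survival_params.validate()

    def to_dict(self) -> dict:
        return asdict(self)
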