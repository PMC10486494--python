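"""Synthetic trial cohorts with joint longitudinal-survival structure.

Generates subjects tables (one row per subject: baseline covariates, arm,
event time/indicator/cause) and long-format marker tables (subject, marker,
time in months, observed value on the marker's native scale), plus a truth
echo of every generating parameter so downstream estimators can be tested
for parameter recovery without any external data.

Event times are drawn by inverting each subject's cumulative cause-specific
hazard: the prostate-cancer hazard is a Weibull baseline times
exp(gamma' w + sum_k alpha_k m_k(t) / scale_k) with m_k the subject's
current (model-implied) marker value; other-cause death is a constant
competing hazard; random censoring is exponential; administrative censoring
applies at the end of follow-up. The earliest of the four wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    LOG1P_MARKERS,
    MARKER_SCALES,
    MARKERS,
    SURVIVAL_COVARIATES,
    ConfigError,
    SimulationConfig,
    SurvivalParams,
    TrajectoryParams,
)

logger = logging.getLogger(__name__)

_VALUE_FLOOR = 0.01  # native-scale floor for simulated marker values
_TIME_GRID_STEP = 0.05  # months; hazard-integration grid resolution

CAUSE_CANCER = "prostate_cancer"
CAUSE_OTHER = "other"
CAUSE_CENSORED = "censored"

SUBJECT_COLUMNS = [
    "id", "arm", "ecog_ge1", "skeletal_ge10", "liver_met", "nodal_n1",
    "gleason_9_10", "worst_pain", "baseline_hb", "baseline_psa",
    "baseline_nlr", "baseline_plr", "baseline_lmr",
    "event_time", "event", "cause",
]

MARKER_COLUMNS = ["id", "marker", "time_months", "value"]


class HazardOverflowError(FloatingPointError):
    """A subject's simulated hazard left the finite range."""


@dataclass
class SyntheticCohort:
    """Container for one simulated cohort.

    ``truth`` echoes the generating configuration; ``latent`` holds the
    realised per-subject current-value lines (intercept ``a`` and slope
    ``c`` on the modelling scale, per marker) so tests can score estimators
    against the exact generating trajectories.
    """

    subjects: pd.DataFrame
    markers: pd.DataFrame
    truth: dict
    latent: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def modelling_scale(marker: str, values):
    """Native -> modelling scale (log(x+1) for PSA, identity otherwise)."""
    values = np.asarray(values, dtype=float)
    return np.log1p(values) if marker in LOG1P_MARKERS else values


def native_scale(marker: str, values):
    """Modelling -> native scale (inverse of :func:`modelling_scale`)."""
    values = np.asarray(values, dtype=float)
    return np.expm1(values) if marker in LOG1P_MARKERS else values


def visit_grid(followup_max: float) -> np.ndarray:
    """Scheduled visit times: monthly through month 12, bimonthly after."""
    monthly = np.arange(0.0, min(12.0, followup_max) + 1e-9)
    bimonthly = np.arange(14.0, followup_max + 1e-9, 2.0)
    return np.concatenate([monthly, bimonthly[bimonthly > 12.0]])


def true_marker_value(params: TrajectoryParams, arm, baseline, random_effects, t):
    """Current model-implied marker value on the modelling scale.

    ``baseline`` is the subject's baseline value on the modelling scale and
    ``random_effects = (b0, b1)``. Linear in ``t`` for a fixed subject.
    """
    b0, b1 = random_effects
    t = np.asarray(t, dtype=float)
    return (params.beta0 + b0 + (params.beta_t + b1) * t
            + params.beta_arm * arm + params.beta_arm_t * arm * t
            + params.beta_base * baseline)


def _draw_baselines(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    bp = cfg.baseline_params
    n = cfg.n_subjects
    n_exp = int(round(cfg.arm_allocation * n))
    arm = np.zeros(n, dtype=int)
    arm[rng.permutation(n)[:n_exp]] = 1
    hb = np.clip(rng.normal(bp.hb_mean, bp.hb_sd, n), 5.0, None)
    return pd.DataFrame({
        "id": np.arange(n),
        "arm": arm,
        "ecog_ge1": (rng.random(n) < bp.p_ecog_ge1).astype(int),
        "skeletal_ge10": (rng.random(n) < bp.p_skeletal_ge10).astype(int),
        "liver_met": (rng.random(n) < bp.p_liver_met).astype(int),
        "nodal_n1": (rng.random(n) < bp.p_nodal_n1).astype(int),
        "gleason_9_10": (rng.random(n) < bp.p_gleason_9_10).astype(int),
        "worst_pain": rng.choice(11, size=n, p=bp.pain_probs),
        "baseline_hb": hb,
        "baseline_psa": rng.lognormal(bp.psa_log_mu, bp.psa_log_sd, n),
        "baseline_nlr": rng.lognormal(bp.nlr_log_mu, bp.nlr_log_sd, n),
        "baseline_plr": rng.lognormal(bp.plr_log_mu, bp.plr_log_sd, n),
        "baseline_lmr": rng.lognormal(bp.lmr_log_mu, bp.lmr_log_sd, n),
    })


def survival_design(subjects: pd.DataFrame) -> np.ndarray:
    """Design matrix of the nine baseline survival covariates.

    log(PSA+1) is computed internally from the native baseline PSA.
    """
    cols = {
        "arm": subjects["arm"],
        "ecog_ge1": subjects["ecog_ge1"],
        "skeletal_ge10": subjects["skeletal_ge10"],
        "liver_met": subjects["liver_met"],
        "nodal_n1": subjects["nodal_n1"],
        "gleason_9_10": subjects["gleason_9_10"],
        "worst_pain": subjects["worst_pain"],
        "baseline_hb": subjects["baseline_hb"],
        "log_baseline_psa": np.log1p(subjects["baseline_psa"].to_numpy(dtype=float)),
    }
    return np.column_stack([np.asarray(cols[c], dtype=float) for c in SURVIVAL_COVARIATES])


def simulate_event_times(params: SurvivalParams, subjects: pd.DataFrame,
                         trajectories: dict, followup_max: float,
                         censoring_rate: float, rng: np.random.Generator):
    """Draw (event_time, event, cause) for every subject.

    ``trajectories`` maps marker -> (a, c) arrays: per-subject intercept and
    slope of the current value on the modelling scale. The prostate-cancer
    cumulative hazard is integrated on a dense grid and inverted against
    -log(U); subjects whose -log(U) exceeds H(followup_max) cannot die of
    prostate cancer inside the window.
    """
    n = len(subjects)
    w = survival_design(subjects)
    gamma = np.array([params.gamma[c] for c in SURVIVAL_COVARIATES])
    lp0 = w @ gamma

    a_tot = np.zeros(n)
    c_tot = np.zeros(n)
    for marker in MARKERS:
        if marker not in trajectories:
            continue
        a_k, c_k = trajectories[marker]
        coef = params.alpha[marker] / MARKER_SCALES[marker]
        ref = params.marker_ref.get(marker, 0.0)
        a_tot = a_tot + coef * (np.asarray(a_k) - ref)
        c_tot = c_tot + coef * np.asarray(c_k)

    grid = np.arange(0.0, followup_max + _TIME_GRID_STEP / 2, _TIME_GRID_STEP)
    shape, scale = params.weibull_shape, params.weibull_scale
    h0 = (shape / scale) * (grid / scale) ** (shape - 1.0) if shape != 1.0 \
        else np.full_like(grid, 1.0 / scale)
    log_rel = lp0[:, None] + a_tot[:, None] + c_tot[:, None] * grid[None, :]
    if not np.all(np.isfinite(log_rel)) or np.max(log_rel) > 50.0:
        bad = int(np.argmax(np.max(log_rel, axis=1)))
        raise HazardOverflowError(
            f"non-finite or overflowing hazard for subject id={subjects['id'].iloc[bad]}"
        )
    haz = h0[None, :] * np.exp(log_rel)
    cumhaz = np.concatenate(
        [np.zeros((n, 1)),
         np.cumsum((haz[:, 1:] + haz[:, :-1]) * (_TIME_GRID_STEP / 2), axis=1)],
        axis=1)

    target = -np.log(rng.uniform(size=n))
    reached = cumhaz[:, -1] >= target
    idx = np.minimum((cumhaz >= target[:, None]).argmax(axis=1), len(grid) - 1)
    idx = np.maximum(idx, 1)
    h_lo = cumhaz[np.arange(n), idx - 1]
    h_hi = cumhaz[np.arange(n), idx]
    frac = np.where(h_hi > h_lo, (target - h_lo) / np.maximum(h_hi - h_lo, 1e-300), 1.0)
    t_cancer = np.where(reached, grid[idx - 1] + np.clip(frac, 0, 1) * _TIME_GRID_STEP,
                        np.inf)
    t_cancer = np.maximum(t_cancer, 1e-6)

    t_other = rng.exponential(1.0 / params.othercause_hazard, size=n)
    t_censor = (rng.exponential(1.0 / censoring_rate, size=n)
                if censoring_rate > 0 else np.full(n, np.inf))

    event_time = np.minimum.reduce([t_cancer, t_other, t_censor,
                                    np.full(n, followup_max)])
    cause = np.where(t_cancer <= event_time, CAUSE_CANCER,
                     np.where(t_other <= event_time, CAUSE_OTHER, CAUSE_CENSORED))
    event = (cause != CAUSE_CENSORED).astype(int)
    return event_time, event, cause


def apply_visit_schedule(config: SimulationConfig, event_time: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Scheduled visits intersected with [0, event_time), with MCAR skips.

    The baseline visit is never dropped; each later visit is independently
    skipped with ``missing_visit_prob``.
    """
    grid = visit_grid(config.followup_max)
    times = grid[grid < event_time]
    if config.missing_visit_prob > 0 and len(times) > 1:
        keep = rng.random(len(times)) >= config.missing_visit_prob
        keep[0] = True
        times = times[keep]
    return times


def apply_inclusion_filter(subjects: pd.DataFrame, markers: pd.DataFrame):
    """Keep subjects with a baseline and >= 2 post-baseline values per marker.

    Returns (subjects, markers, excluded_ids); the exclusion list is also
    logged, mirroring an eligibility screen applied to every one of the
    five markers.
    """
    counts = (markers.assign(post=markers["time_months"] > 0,
                             base=markers["time_months"] == 0)
              .groupby(["id", "marker"])[["post", "base"]].sum())
    ok_pair = (counts["base"] >= 1) & (counts["post"] >= 2)
    ok_by_id = ok_pair.groupby(level="id").agg(lambda s: bool(s.all()))
    n_markers = counts.groupby(level="id").size()
    ok_by_id &= n_markers == len(MARKERS)
    eligible = set(ok_by_id[ok_by_id].index)
    excluded = sorted(set(subjects["id"]) - eligible)
    if excluded:
        logger.info("inclusion filter excluded %d subjects: %s",
                    len(excluded), excluded[:20])
    keep_subj = subjects[subjects["id"].isin(eligible)].reset_index(drop=True)
    keep_mark = markers[markers["id"].isin(eligible)].reset_index(drop=True)
    return keep_subj, keep_mark, excluded


def simulate_cohort(config: SimulationConfig, apply_filter: bool = False) -> SyntheticCohort:
    """Generate one cohort. Reproducible given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = _draw_baselines(config, rng)
    n = config.n_subjects

    # realised current-value lines m_i(t) = a_i + c_i t (modelling scale)
    latent = {}
    re_draws = {}
    for marker in MARKERS:
        tp = config.marker_params[marker]
        cov = np.array([
            [tp.sd_b0 ** 2, tp.corr_b0b1 * tp.sd_b0 * tp.sd_b1],
            [tp.corr_b0b1 * tp.sd_b0 * tp.sd_b1, tp.sd_b1 ** 2]])
        b = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
        base = modelling_scale(marker, subjects[f"baseline_{marker.lower()}"].to_numpy())
        arm = subjects["arm"].to_numpy()
        a = tp.beta0 + b[:, 0] + tp.beta_arm * arm + tp.beta_base * base
        c = tp.beta_t + b[:, 1] + tp.beta_arm_t * arm
        latent[marker] = (a, c)
        re_draws[marker] = b

    event_time, event, cause = simulate_event_times(
        config.survival_params, subjects, latent, config.followup_max,
        config.censoring_rate, rng)
    subjects = subjects.assign(event_time=event_time, event=event, cause=cause)

    # observed marker series on the shared visit grid
    grid = visit_grid(config.followup_max)
    in_window = grid[None, :] < event_time[:, None]
    keep = in_window & ((rng.random((n, len(grid))) >= config.missing_visit_prob)
                        | (grid[None, :] == 0.0))
    rows = []
    n_floored = 0
    for marker in MARKERS:
        tp = config.marker_params[marker]
        a, c = latent[marker]
        values = a[:, None] + c[:, None] * grid[None, :] \
            + rng.normal(0.0, tp.sd_resid, size=(n, len(grid)))
        values = native_scale(marker, values)
        # the baseline visit records the baseline measurement itself
        values[:, 0] = subjects[f"baseline_{marker.lower()}"].to_numpy()
        n_floored += int(np.sum(values[keep] < _VALUE_FLOOR))
        values = np.maximum(values, _VALUE_FLOOR)
        sid, vid = np.nonzero(keep)
        rows.append(pd.DataFrame({
            "id": subjects["id"].to_numpy()[sid],
            "marker": marker,
            "time_months": grid[vid],
            "value": values[sid, vid],
        }))
    if n_floored:
        logger.warning("floored %d simulated marker values at %g",
                       n_floored, _VALUE_FLOOR)
    markers = pd.concat(rows, ignore_index=True)
    markers = markers.sort_values(["id", "marker", "time_months"],
                                  kind="mergesort").reset_index(drop=True)

    truth = {"config": config.to_dict()}
    cohort = SyntheticCohort(subjects=subjects, markers=markers, truth=truth,
                             latent={"lines": latent, "random_effects": re_draws})
    if apply_filter:
        subj_f, mark_f, excluded = apply_inclusion_filter(subjects, markers)
        keep = subjects["id"].isin(subj_f["id"]).to_numpy()
        latent_f = {
            "lines": {m: (a[keep], c[keep]) for m, (a, c) in latent.items()},
            "random_effects": {m: b[keep] for m, b in re_draws.items()},
        }
        cohort = SyntheticCohort(subjects=subj_f, markers=mark_f,
                                 truth={**truth, "excluded_ids": excluded},
                                 latent=latent_f)
    return cohort


def true_all_cause_survival(cohort: SyntheticCohort, t: float, u: float) -> np.ndarray:
    """Generator-truth P(T > u | T > t, subject's latent trajectory).

    Oracle conditional survival used to benchmark fitted dynamic
    predictions; integrates each subject's realised total hazard.
    """
    cfg = cohort.truth["config"]
    sp = cfg["survival_params"]
    subjects = cohort.subjects
    n = len(subjects)
    w = survival_design(subjects)
    gamma = np.array([sp["gamma"][c] for c in SURVIVAL_COVARIATES])
    lp0 = w @ gamma
    a_tot = np.zeros(n)
    c_tot = np.zeros(n)
    for marker in MARKERS:
        a_k, c_k = cohort.latent["lines"][marker]
        coef = sp["alpha"][marker] / MARKER_SCALES[marker]
        a_tot += coef * (a_k - sp["marker_ref"].get(marker, 0.0))
        c_tot += coef * c_k
    grid = np.linspace(t, u, 241)
    shape, scale = sp["weibull_shape"], sp["weibull_scale"]
    h0 = (shape / scale) * (grid / scale) ** (shape - 1.0)
    haz = h0[None, :] * np.exp(lp0[:, None] + a_tot[:, None]
                               + c_tot[:, None] * grid[None, :])
    H = np.trapezoid(haz, grid, axis=1) + sp["othercause_hazard"] * (u - t)
    return np.exp(-H)
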