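"""End-to-end pipeline: simulate -> filter -> fit -> evaluate -> decision curves.

Every run writes its artifact directory with delimited-text tables, a run
log and a machine-readable manifest (full configuration + seeds + package
versions), so any output table can be regenerated bit-identically from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import apply_inclusion_filter, simulate_cohort
from .config import MARKERS, ConfigError, SimulationConfig
from .dca import net_benefit_curve
from .evaluation import cross_validate
from .io import params_to_dict, write_cohort
from .joint import JointModel, JointModelSpec
from .prediction import predict_conditional_survival
from .reporting import baseline_table
from .survival import endpoint_indicator

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serialisable)."""

    output_dir: str = "seroprog_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    markers: tuple = MARKERS
    endpoint: str = "OS"
    backend: str = "two_stage"
    k_folds: int = 5
    landmarks: tuple = (12.0, 24.0)
    dca_horizon: float = 60.0
    n_draws: int = 200
    seed: int = 0
    run_univariate: bool = True
    run_multivariate: bool = True
    log_level: str = "INFO"

    def validate(self):
        self.simulation.validate()
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        unknown = set(self.markers) - set(MARKERS)
        if unknown:
            raise ConfigError(f"unknown markers: {sorted(unknown)}")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        sim = d.pop("simulation", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if sim is not None:
            from .config import BaselineParams, SurvivalParams, TrajectoryParams

            marker_params = {m: TrajectoryParams(**p)
                             for m, p in sim.pop("marker_params", {}).items()}
            baseline = sim.pop("baseline_params", {})
            survival = sim.pop("survival_params", {})
            cfg.simulation = SimulationConfig(**sim)
            if marker_params:
                cfg.simulation.marker_params = marker_params
            if baseline:
                if "pain_probs" in baseline:
                    baseline["pain_probs"] = tuple(baseline["pain_probs"])
                cfg.simulation.baseline_params = BaselineParams(**baseline)
            if survival:
                cfg.simulation.survival_params = SurvivalParams(**survival)
        cfg.markers = tuple(cfg.markers)
        cfg.landmarks = tuple(cfg.landmarks)
        return cfg


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and return the artifact directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("seroprog")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> Path:
    manifest = {
        "config": yaml.safe_load(config.to_yaml()),
        "seed": config.seed,
        "versions": _versions(),
        "fits": {},
    }

    @_stage("simulate")
    def stage_simulate():
        cohort = simulate_cohort(config.simulation)
        write_cohort(cohort, outdir)
        return cohort

    cohort = stage_simulate()

    @_stage("filter")
    def stage_filter():
        subj, mark, excluded = apply_inclusion_filter(cohort.subjects,
                                                      cohort.markers)
        manifest["n_excluded"] = len(excluded)
        return subj, mark

    subjects, markers = stage_filter()

    @_stage("baseline_table")
    def stage_table():
        baseline_table(subjects).to_csv(outdir / "baseline_table.csv", index=False)

    stage_table()

    fitted = {}

    @_stage("fit")
    def stage_fit():
        if config.run_univariate:
            for marker in config.markers:
                spec = JointModelSpec(endpoint=config.endpoint, markers=(marker,),
                                      backend=config.backend, seed=config.seed)
                res = JointModel(markers, subjects, spec).fit(compute_se=True)
                res.hazard_ratio_table().to_csv(
                    outdir / f"univariate_{marker}.csv", index=False)
                manifest["fits"][f"univariate_{marker}"] = params_to_dict(res.params)
        if config.run_multivariate and len(config.markers) >= 2:
            sets = {"multivariate": tuple(config.markers)}
            no_psa = tuple(m for m in config.markers if m != "PSA")
            if "PSA" in config.markers and len(no_psa) >= 2:
                sets["multivariate_nopsa"] = no_psa
            for name, mset in sets.items():
                spec = JointModelSpec(
                    endpoint=config.endpoint, markers=mset,
                    backend=config.backend,
                    shrinkage="horseshoe" if config.backend == "bayesian_mcmc"
                    else "none",
                    seed=config.seed)
                res = JointModel(markers, subjects, spec).fit(compute_se=True)
                res.hazard_ratio_table().to_csv(outdir / f"{name}.csv", index=False)
                manifest["fits"][name] = params_to_dict(res.params)
                fitted[name] = res

    stage_fit()

    @_stage("evaluate")
    def stage_evaluate():
        spec = JointModelSpec(endpoint=config.endpoint,
                              markers=tuple(config.markers),
                              backend=config.backend, seed=config.seed)
        for lm in config.landmarks:
            report = cross_validate(markers, subjects, spec, k=config.k_folds,
                                    landmark=lm, seed=config.seed,
                                    n_draws=config.n_draws)
            report.metrics.to_csv(outdir / f"cv_metrics_lm{int(lm)}.csv",
                                  index=False)
            report.folds.to_csv(outdir / f"cv_folds_lm{int(lm)}.csv", index=False)

    stage_evaluate()

    @_stage("dca")
    def stage_dca():
        lm = config.landmarks[-1]
        u = config.dca_horizon
        for name, res in fitted.items():
            alive = subjects[subjects["event_time"] > lm].reset_index(drop=True)
            hist = markers[(markers["id"].isin(alive["id"]))
                           & (markers["time_months"] <= lm)]
            pred = predict_conditional_survival(res.params, alive, hist, lm, [u],
                                                n_draws=config.n_draws,
                                                seed=config.seed)
            outcomes = pd.DataFrame({
                "event_time": alive["event_time"],
                "event": endpoint_indicator(alive, config.endpoint)})
            curve = net_benefit_curve(1.0 - pred["pi_hat"].to_numpy(),
                                      outcomes, u)
            curve.to_frame().to_csv(outdir / f"dca_{name}.csv", index=False)

    if fitted:
        stage_dca()

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=float, sort_keys=True))
    return outdir


def _versions() -> dict:
    import lifelines
    import scipy
    import sklearn
    import statsmodels

    return {
        "seroprog": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "lifelines": lifelines.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
    }
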