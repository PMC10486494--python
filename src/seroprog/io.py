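"""Delimited-text and structured-text I/O for cohorts and fitted models."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MARKER_COLUMNS, SUBJECT_COLUMNS, SyntheticCohort
from .joint import JointModelParams
from .longitudinal import LongitudinalParams


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write subjects.csv, markers.csv and truth.json; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": outdir / "subjects.csv",
        "markers": outdir / "markers.csv",
        "truth": outdir / "truth.json",
    }
    cohort.subjects[SUBJECT_COLUMNS].to_csv(paths["subjects"], index=False)
    cohort.markers[MARKER_COLUMNS].to_csv(paths["markers"], index=False)
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2, default=float))
    return paths


def read_subjects(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_markers(path) -> pd.DataFrame:
    return pd.read_csv(path)


def params_to_dict(params: JointModelParams) -> dict:
    return {
        "endpoint": params.endpoint,
        "markers": list(params.markers),
        "scalings": {k: float(v) for k, v in params.scalings.items()},
        "gamma": params.gamma.tolist(),
        "alpha": {k: float(v) for k, v in params.alpha.items()},
        "knots": [None if not np.isfinite(k) else float(k) for k in params.knots],
        "logh0": params.logh0.tolist(),
        "t_max": float(params.t_max),
        "longitudinal": {
            m: {"beta": p.beta.tolist(), "sd_resid": float(p.sd_resid),
                "cov_re": p.cov_re.tolist(), "method": p.method}
            for m, p in params.longitudinal.items()
        },
    }


def params_from_dict(d: dict) -> JointModelParams:
    longitudinal = {
        m: LongitudinalParams(marker=m, beta=np.array(v["beta"]),
                              sd_resid=v["sd_resid"],
                              cov_re=np.array(v["cov_re"]),
                              method=v.get("method", "ml"))
        for m, v in d["longitudinal"].items()
    }
    return JointModelParams(
        endpoint=d["endpoint"], markers=tuple(d["markers"]),
        scalings=d["scalings"], longitudinal=longitudinal,
        gamma=np.array(d["gamma"]), alpha=d["alpha"],
        knots=np.array([np.inf if k is None else k for k in d["knots"]]),
        logh0=np.array(d["logh0"]), t_max=d["t_max"])


def write_params(params: JointModelParams, path) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params), indent=2))


def read_params(path) -> JointModelParams:
    return params_from_dict(json.loads(Path(path).read_text()))
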