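"""Baseline characteristics tables in the style of trial Table 1."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

CONTINUOUS_ROWS = [
    ("Worst pain score", "worst_pain"),
    ("Baseline PSA (ng/mL)", "baseline_psa"),
    ("Baseline Hb (g/dL)", "baseline_hb"),
    ("Baseline NLR", "baseline_nlr"),
    ("Baseline PLR", "baseline_plr"),
    ("Baseline LMR", "baseline_lmr"),
]

CATEGORICAL_ROWS = [
    ("ECOG >= 1", "ecog_ge1"),
    ("Skeletal lesions >= 10", "skeletal_ge10"),
    ("Liver metastasis", "liver_met"),
    ("Nodal stage N1", "nodal_n1"),
    ("Gleason 9-10", "gleason_9_10"),
]


def _median_iqr(x) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}, {q3:.1f})"


def _count_pct(x) -> str:
    n = int(np.sum(x))
    return f"{n} ({100.0 * n / len(x):.1f}%)"


def baseline_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) / counts (%) per arm with chi-square and rank-sum p-values.

    Chi-square tests are uncorrected (no continuity correction); continuous
    rows use the Wilcoxon rank-sum test. With a single arm present the table
    is descriptive only (p-values NaN) and a warning is raised.
    """
    arms = sorted(subjects["arm"].unique())
    two_arms = len(arms) == 2
    if not two_arms:
        warnings.warn("single treatment arm: descriptive table only")
    groups = [subjects[subjects["arm"] == a] for a in arms]
    rows = [{"variable": "n",
             **{f"arm_{a}": str(len(g)) for a, g in zip(arms, groups)},
             "p_value": np.nan}]
    for label, col in CONTINUOUS_ROWS:
        if col not in subjects:
            continue
        row = {"variable": f"{label} (median (IQR))"}
        for a, g in zip(arms, groups):
            row[f"arm_{a}"] = _median_iqr(g[col])
        row["p_value"] = (stats.ranksums(groups[0][col], groups[1][col]).pvalue
                          if two_arms else np.nan)
        rows.append(row)
    for label, col in CATEGORICAL_ROWS:
        if col not in subjects:
            continue
        row = {"variable": f"{label} (n (%))"}
        for a, g in zip(arms, groups):
            row[f"arm_{a}"] = _count_pct(g[col])
        if two_arms:
            table = np.array([[np.sum(g[col] == v) for v in (0, 1)] for g in groups])
            if np.all(table.sum(axis=0) > 0):
                row["p_value"] = stats.chi2_contingency(table, correction=False)[1]
            else:
                row["p_value"] = np.nan
        else:
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
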