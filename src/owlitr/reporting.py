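"""Descriptive study-characteristics table (by-arm means, frequencies, tests).

Continuous variables get mean/SD overall and by arm with a Welch two-sample
t-test; binary variables get counts/percentages with a chi-square test of
independence.  Percent missing is reported per variable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

_CONTINUOUS = [("age", "Age"), ("pcl_baseline", "Baseline PCL-5"),
               ("pcl_6month", "6-month PCL-5")]
_BINARY = [("white", "White"), ("disability", "Disability status"),
           ("rural", "Rural status"), ("low_income", "Low income")]


def _ttest_p(x0: np.ndarray, x1: np.ndarray) -> float:
    if len(x0) < 2 or len(x1) < 2:
        return np.nan
    return float(stats.ttest_ind(x1, x0, equal_var=False).pvalue)


def _chi2_p(x: pd.Series, arm: pd.Series) -> float:
    tab = pd.crosstab(x, arm)
    if tab.shape != (2, 2) or (tab.values == 0).any():
        # fall back to Fisher when a cell is empty
        if tab.shape == (2, 2):
            return float(stats.fisher_exact(tab.values).pvalue)
        return np.nan
    return float(stats.chi2_contingency(tab.values, correction=False).pvalue)


def descriptive_table(trial: pd.DataFrame) -> pd.DataFrame:
    """Table of study characteristics, overall and by randomized arm.

    Expects the canonical trial table (arm: 1 = telehealth, 0 = in-person;
    missing outcomes as NaN).  Returns one row per variable with columns
    for the overall and per-arm summaries, the between-arm test p-value,
    and percent missing.
    """
    arm = trial["arm"].astype(int)
    rows = []
    for col, label in _CONTINUOUS:
        if col not in trial.columns:
            continue
        x = trial[col].astype(float)
        pct_miss = 100.0 * x.isna().mean()
        x0, x1 = x[(arm == 0) & x.notna()], x[(arm == 1) & x.notna()]
        rows.append({
            "variable": label, "type": "continuous",
            "overall": f"{x.mean():.2f} ({x.std(ddof=1):.2f})",
            "telehealth": f"{x1.mean():.2f} ({x1.std(ddof=1):.2f})",
            "in_person": f"{x0.mean():.2f} ({x0.std(ddof=1):.2f})",
            "p_value": _ttest_p(x0.to_numpy(), x1.to_numpy()),
            "pct_missing": round(pct_miss, 2),
        })
    for col, label in _BINARY:
        if col not in trial.columns:
            continue
        x = trial[col].astype(int)
        def _fmt(mask):
            k, m = int(x[mask].sum()), int(mask.sum())
            return f"{k} ({100.0 * k / m:.2f}%)" if m else "0 (0%)"
        rows.append({
            "variable": label, "type": "binary",
            "overall": _fmt(np.ones(len(x), bool)),
            "telehealth": _fmt((arm == 1).to_numpy()),
            "in_person": _fmt((arm == 0).to_numpy()),
            "p_value": _chi2_p(x, arm),
            "pct_missing": 0.0,
        })
    return pd.DataFrame(rows)
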