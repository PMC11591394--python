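"""Raw trial tables -> analysis-ready standardized intention-to-treat dataset.

Handles the study's covariate recoding: race collapsed to a White indicator
(all other races, including Black, coded 0) and annual household income
collapsed to a low-income indicator at the <USD 35,000 threshold (the five
brackets below it).  All six prescriptive factors — binaries included — are
then standardized to mean 0, SD 1 (n - 1 denominator), and every randomized
participant is retained regardless of outcome missingness or treatment
completion (intention to treat).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .rules import COLUMNS, StandardizationParams

logger = logging.getLogger(__name__)

#: Income bracket labels mapping to the low-income indicator (upper bound
#: <= USD 35,000 -> 1).  Labels are whitespace/dash-normalized before lookup.
INCOME_BRACKETS = {
    "USD 0-<USD 10,000": 1,
    "USD 10,000-<USD 15,000": 1,
    "USD 15,000-<USD 20,000": 1,
    "USD 20,000-<USD 25,000": 1,
    "USD 25,000-<USD 35,000": 1,
    "USD 35,000-<USD 50,000": 0,
    "USD 50,000-<USD 75,000": 0,
    "USD 75,000 or more": 0,
}

RACE_LABELS = ("White", "Black", "Other race")

_BINARY_COLUMNS = ("white", "disability", "rural", "low_income")


def _normalize_label(label: str) -> str:
    s = re.sub(r"[–—−]", "-", str(label))   # en/em dash, minus
    s = re.sub(r"\s*-\s*", "-", s)
    s = re.sub(r"-<\s*", "-<", s)
    return re.sub(r"\s+", " ", s).strip()


def binarize_demographics(raw: pd.DataFrame) -> pd.DataFrame:
    """Recode categorical ``race`` and ``income`` columns to 0/1 indicators.

    ``white`` = 1 iff race is White; ``low_income`` = 1 iff the income
    bracket's upper bound is at most USD 35,000.  Unrecognized labels raise,
    naming the offending value.
    """
    out = raw.copy()
    if "race" in out.columns:
        known = {_normalize_label(r): r for r in RACE_LABELS}
        vals = out["race"].map(lambda v: _normalize_label(v))
        bad = set(vals) - set(known)
        if bad:
            raise ValueError(f"unrecognized race label(s): {sorted(bad)}; "
                             f"expected one of {RACE_LABELS}")
        out["white"] = (vals == "White").astype(int)
        out = out.drop(columns=["race"])
    if "income" in out.columns:
        table = {_normalize_label(k): v for k, v in INCOME_BRACKETS.items()}
        vals = out["income"].map(_normalize_label)
        bad = set(vals) - set(table)
        if bad:
            raise ValueError(f"unrecognized income bracket(s): {sorted(bad)}; "
                             f"expected one of {list(INCOME_BRACKETS)}")
        out["low_income"] = vals.map(table).astype(int)
        out = out.drop(columns=["income"])
    return out


def impute_covariates(raw: pd.DataFrame) -> pd.DataFrame:
    """Single deterministic imputation: binaries to the mode, continuous to the mean.

    Intended for the trace amounts of covariate missingness seen in practice
    (a few percent); counts are logged per column.
    """
    out = raw.copy()
    for col in COLUMNS:
        if col not in out.columns:
            continue
        miss = out[col].isna()
        if not miss.any():
            continue
        if miss.all():
            raise ValueError(f"column {col!r} is entirely missing")
        if col in _BINARY_COLUMNS:
            # mode; 1 wins a tie to keep the choice deterministic
            observed = out.loc[~miss, col].astype(float)
            fill = 1.0 if observed.mean() >= 0.5 else 0.0
        else:
            fill = float(out.loc[~miss, col].mean())
        out.loc[miss, col] = fill
        logger.info("imputed %d missing value(s) in %r with %s",
                    int(miss.sum()), col, fill)
    return out


def standardize(table: pd.DataFrame):
    """Center and scale the six covariate columns; returns (Z, params).

    Every column — including binary indicators — ends up with mean 0 and
    sample SD 1 (n - 1 denominator).  A zero-variance column raises, since
    the decision rule would be unidentifiable in that coordinate.
    """
    X = table[list(COLUMNS)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values; impute first")
    params = StandardizationParams(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=1))
    return params.transform(X), params


def apply_standardization(params: StandardizationParams, row: np.ndarray) -> np.ndarray:
    """Standardize a raw covariate row (or matrix) with stored training params."""
    return params.transform(row)


@dataclass(frozen=True)
class TrialDataset:
    """Analysis-ready intention-to-treat dataset.

    Z is the n x 6 standardized prescriptive-factor matrix in the frozen
    column order (age, white, disability, rural, low_income, pcl_baseline);
    A is the arm indicator (1 = telehealth); Y holds the 6-month outcome
    with NaN marking missingness; ``raw`` retains original-scale covariates
    for descriptive reporting.
    """

    ids: np.ndarray
    Z: np.ndarray
    A: np.ndarray
    Y: np.ndarray
    standardization: StandardizationParams
    raw: Optional[pd.DataFrame] = None

    def __post_init__(self):
        n = len(self.ids)
        if self.Z.shape != (n, len(COLUMNS)) or len(self.A) != n or len(self.Y) != n:
            raise ValueError("inconsistent component lengths")
        if np.isnan(self.Z).any() or np.isnan(np.asarray(self.A, float)).any():
            raise ValueError("Z and A must be complete after preprocessing")
        obs = self.Y[~np.isnan(self.Y)]
        if obs.size and (obs.min() < 0 or obs.max() > 80):
            raise ValueError("observed outcomes must lie in [0, 80]")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of rows with an observed outcome."""
        return ~np.isnan(self.Y)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def subset(self, idx) -> "TrialDataset":
        """Row subset / resample; standardization params are kept as fitted."""
        idx = np.asarray(idx)
        return TrialDataset(ids=self.ids[idx], Z=self.Z[idx], A=self.A[idx],
                            Y=self.Y[idx], standardization=self.standardization,
                            raw=(self.raw.iloc[idx].reset_index(drop=True)
                                 if self.raw is not None else None))


def assemble_analysis_dataset(raw: pd.DataFrame) -> TrialDataset:
    """Binarize, impute, standardize and wrap a raw trial table.

    Accepts either the canonical generated dialect (0/1 ``white`` and
    ``low_income`` already present) or a raw export with categorical
    ``race``/``income`` labels.  All randomized rows are retained; a
    ``completed`` column, if present, is ignored (intention to treat).
    """
    if "arm" not in raw.columns or raw["arm"].isna().any():
        raise ValueError("every row must carry an arm assignment")
    df = binarize_demographics(raw)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing covariate column(s): {missing_cols}")
    df = impute_covariates(df)
    Z, params = standardize(df)
    ids = (df["id"].to_numpy() if "id" in df.columns
           else np.arange(1, len(df) + 1))
    y = (df["pcl_6month"].to_numpy(dtype=float) if "pcl_6month" in df.columns
         else np.full(len(df), np.nan))
    return TrialDataset(ids=ids, Z=Z,
                        A=df["arm"].to_numpy(dtype=int),
                        Y=y, standardization=params,
                        raw=df[[c for c in df.columns if c != "pcl_6month"]])


def read_trial_csv(path) -> pd.DataFrame:
    """Read the canonical trial CSV (empty outcome field = missing)."""
    return pd.read_csv(path)
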