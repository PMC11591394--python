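"""Linear decision rules and covariate standardization.

A decision rule maps a standardized baseline-covariate vector z to one of
two treatment arms via the indicator

    d(z) = 1{ b0 + b' z >= 0 }

with 1 = telehealth and 0 = in-person.  Ties (score exactly zero) go to
telehealth, matching the indicator convention ``score >= 0``.

The six prescriptive factors appear in a frozen order so serialized rules
are unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Frozen column order of the prescriptive-factor matrix.
COLUMNS = ("age", "white", "disability", "rural", "low_income", "pcl_baseline")

#: Arm coding used throughout: 1 = telehealth, 0 = in-person.
TELEHEALTH, IN_PERSON = 1, 0


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column location/scale used to put covariates on the z-scale.

    ``mean`` and ``sd`` are length-6 arrays in :data:`COLUMNS` order.  The
    sample SD uses the n - 1 denominator.  Binary indicators are
    standardized along with continuous columns.
    """

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if mean.shape != (len(COLUMNS),) or sd.shape != (len(COLUMNS),):
            raise ValueError(f"expected {len(COLUMNS)} means and SDs")
        if np.any(sd <= 0):
            bad = [COLUMNS[i] for i in np.flatnonzero(sd <= 0)]
            raise ValueError(f"non-positive SD for column(s) {bad}: "
                             "rule would be unidentifiable in that coordinate")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean) / self.sd

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        return Z * self.sd + self.mean

    def to_dict(self) -> dict:
        return {"mean": dict(zip(COLUMNS, self.mean.tolist())),
                "sd": dict(zip(COLUMNS, self.sd.tolist()))}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(mean=np.array([d["mean"][c] for c in COLUMNS]),
                   sd=np.array([d["sd"][c] for c in COLUMNS]))


@dataclass(frozen=True)
class DecisionRule:
    """Linear treatment-assignment rule on the standardized scale.

    Parameters
    ----------
    intercept : float
        Decision-score offset b0.
    slopes : ndarray of shape (6,)
        Coefficients in :data:`COLUMNS` order.
    standardization : StandardizationParams, optional
        Training-data location/scale; when present, raw covariate rows can
        be scored directly via :meth:`assign_raw`.
    """

    intercept: float
    slopes: np.ndarray
    standardization: Optional[StandardizationParams] = field(default=None)

    def __post_init__(self):
        slopes = np.asarray(self.slopes, dtype=float)
        if slopes.shape != (len(COLUMNS),):
            raise ValueError(f"expected exactly {len(COLUMNS)} slopes, "
                             f"got shape {slopes.shape}")
        object.__setattr__(self, "slopes", slopes)
        object.__setattr__(self, "intercept", float(self.intercept))

    def score(self, z: np.ndarray) -> np.ndarray:
        """Decision score b0 + b'z for one row or a matrix of rows."""
        z = np.asarray(z, dtype=float)
        if z.shape[-1] != len(COLUMNS):
            raise ValueError(f"covariate row(s) must have {len(COLUMNS)} "
                             f"entries, got {z.shape[-1]}")
        return self.intercept + z @ self.slopes

    def assign(self, z: np.ndarray) -> np.ndarray:
        """Arm assignment: 1 (telehealth) iff score >= 0, else 0."""
        return (self.score(z) >= 0).astype(int)

    def assign_raw(self, x: np.ndarray) -> np.ndarray:
        if self.standardization is None:
            raise ValueError("rule carries no standardization parameters; "
                             "standardize inputs explicitly")
        return self.assign(self.standardization.transform(x))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {"intercept": self.intercept,
             "slopes": dict(zip(COLUMNS, self.slopes.tolist())),
             "tie_rule": "telehealth",
             "arm_coding": {"1": "telehealth", "0": "in-person"}}
        if self.standardization is not None:
            d["standardization"] = self.standardization.to_dict()
        return d

    def to_json(self, path, extra: Optional[dict] = None) -> None:
        d = self.to_dict()
        if extra:
            d["provenance"] = extra
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionRule":
        std = d.get("standardization")
        return cls(intercept=d["intercept"],
                   slopes=np.array([d["slopes"][c] for c in COLUMNS]),
                   standardization=(StandardizationParams.from_dict(std)
                                    if std else None))

    @classmethod
    def from_json(cls, path) -> "DecisionRule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def indicator_notation(self) -> str:
        """Render the rule in the indicator notation d(X) = I(... >= 0)."""
        terms = [f"{self.intercept:+.2f}"]
        for name, b in zip(COLUMNS, self.slopes):
            terms.append(f"{b:+.2f} x {name}")
        return "d(X) = I(" + " ".join(terms) + " >= 0)"


def fixed_rule(arm) -> DecisionRule:
    """One-size-fits-all rule assigning every subject to ``arm``.

    ``arm`` may be 1/0 or the strings "telehealth"/"in-person".  Implemented
    as zero slopes with intercept +1 (telehealth) or -1 (in-person).
    """
    if isinstance(arm, str):
        key = arm.strip().lower().replace("_", "-")
        if key in ("telehealth", "tele"):
            arm = TELEHEALTH
        elif key in ("in-person", "inperson"):
            arm = IN_PERSON
        else:
            raise ValueError(f"unrecognized arm {arm!r}")
    if arm not in (TELEHEALTH, IN_PERSON):
        raise ValueError(f"arm must be 0 or 1, got {arm!r}")
    return DecisionRule(intercept=1.0 if arm == TELEHEALTH else -1.0,
                        slopes=np.zeros(len(COLUMNS)))
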