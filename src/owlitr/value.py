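"""Policy-value estimation, contrasts, and bootstrap inference.

The value V(d) of a decision rule d is the mean outcome if the whole
population were treated according to d (lower 6-month symptom score =
better).  It is estimated by the normalized (Hajek) inverse-probability
estimator over participants whose randomized arm agrees with the rule's
assignment:

    V_hat(d) = [ sum_i r_i Y_i 1{A_i = d(z_i)} / pi_i ]
             / [ sum_i r_i 1{A_i = d(z_i)} / pi_i ]

with r_i the observation weight (0 when Y_i is missing) and pi_i the
empirical propensity of the arm received.  The Hajek form is invariant to
outcome location shifts and reduces exactly to an arm's sample mean for a
fixed-arm rule on fully observed data.

Uncertainty comes from a nonparametric bootstrap stratified by arm: within
each replicate the observation model, weights and the statistic are
recomputed with the decision rule held fixed; the reported interval is the
Wald form, estimate +- 1.96 x bootstrap SE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .missingness import ObservationWeights, fit_observation_weights
from .owl import empirical_propensities
from .preprocessing import TrialDataset
from .rules import DecisionRule, fixed_rule

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054       # 97.5% standard-normal quantile


def estimate_value(rule, dataset: TrialDataset,
                   r: ObservationWeights,
                   propensities: Optional[np.ndarray] = None) -> float:
    """Hajek IPW estimate of the mean outcome under ``rule`` (PCL points)."""
    pi = empirical_propensities(dataset.A) if propensities is None \
        else np.asarray(propensities, float)
    match = (rule.assign(dataset.Z) == dataset.A) & dataset.observed
    den = float(np.sum(r.weights[match] / pi[match]))
    if den <= 0:
        raise ValueError("no observed subject matches the rule's assignment; "
                         "value is undefined")
    num = float(np.sum(r.weights[match] * dataset.Y[match] / pi[match]))
    return num / den


def n_matched(rule, dataset: TrialDataset) -> int:
    """Observed subjects whose randomized arm equals the rule's assignment."""
    return int(np.sum((rule.assign(dataset.Z) == dataset.A) & dataset.observed))


def contrast_values(rule_a, rule_b, dataset: TrialDataset,
                    r: ObservationWeights,
                    propensities: Optional[np.ndarray] = None) -> float:
    """V_hat(rule_a) - V_hat(rule_b) on the same data and weights."""
    return (estimate_value(rule_a, dataset, r, propensities)
            - estimate_value(rule_b, dataset, r, propensities))


@dataclass(frozen=True)
class ValueEstimate:
    """Point estimate with bootstrap SE and symmetric Wald 95% CI."""

    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    n_matched: Optional[int] = None
    n_replicates: int = 0

    def __str__(self):
        return f"{self.estimate:.2f} ({self.ci_lower:.2f}, {self.ci_upper:.2f})"


def bootstrap_inference(statistic: Callable[[TrialDataset], float],
                        dataset: TrialDataset,
                        B: int = 1000,
                        rng: Union[int, np.random.Generator, None] = None,
                        max_failure_rate: float = 0.10,
                        point: Optional[float] = None) -> ValueEstimate:
    """Stratified nonparametric bootstrap of a dataset-level statistic.

    Resamples participants with replacement within each arm (conditioning on
    the realized randomization ratio) and re-evaluates ``statistic`` on each
    replicate; the statistic is expected to redo any internal estimation
    (observation model, weights) itself.  Replicates on which the statistic
    raises are dropped and logged; more than ``max_failure_rate`` failures
    aborts.  SE is the SD of replicate values; CI is estimate +- 1.96 SE.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    if point is None:
        point = float(statistic(dataset))
    arm_idx = [np.flatnonzero(dataset.A == a) for a in (0, 1)]
    values, failures = [], 0
    for _ in range(B):
        idx = np.concatenate([g[rng.integers(0, len(g), len(g))]
                              for g in arm_idx if len(g)])
        try:
            values.append(float(statistic(dataset.subset(idx))))
        except Exception as exc:
            failures += 1
            logger.debug("bootstrap replicate failed: %s", exc)
    if failures > max_failure_rate * B:
        raise RuntimeError(f"statistic failed on {failures}/{B} bootstrap "
                           "replicates")
    if failures:
        logger.warning("dropped %d failed bootstrap replicate(s)", failures)
    se = float(np.std(values, ddof=1))
    return ValueEstimate(estimate=point, se=se,
                         ci_lower=point - Z975 * se,
                         ci_upper=point + Z975 * se,
                         n_replicates=len(values))


def value_statistic(rule, clip_floor: float = 0.05) -> Callable[[TrialDataset], float]:
    """Statistic closure: refit observation weights, then the Hajek value."""
    def stat(ds: TrialDataset) -> float:
        return estimate_value(rule, ds, fit_observation_weights(ds, clip_floor))
    return stat


def contrast_statistic(rule_a, rule_b,
                       clip_floor: float = 0.05) -> Callable[[TrialDataset], float]:
    """Statistic closure for the value contrast of two fixed rules."""
    def stat(ds: TrialDataset) -> float:
        r = fit_observation_weights(ds, clip_floor)
        return contrast_values(rule_a, rule_b, ds, r)
    return stat


def performance_table(dataset: TrialDataset,
                      r: ObservationWeights,
                      fitted_rule: DecisionRule,
                      B: int = 1000,
                      rng=None,
                      clip_floor: float = 0.05) -> pd.DataFrame:
    """The rule-performance report: values, contrasts, and assignment counts.

    Three inference rows — V(d_opt), V(d_opt) - V(telehealth) and
    V(d_opt) - V(in-person), each "estimate (lower, upper)" — followed by
    the counts the fitted rule assigns to each arm.
    """
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    tele, inp = fixed_rule(1), fixed_rule(0)
    specs = [
        ("V(d_opt)",
         value_statistic(fitted_rule, clip_floor),
         estimate_value(fitted_rule, dataset, r)),
        ("V(d_opt) - V(telehealth)",
         contrast_statistic(fitted_rule, tele, clip_floor),
         contrast_values(fitted_rule, tele, dataset, r)),
        ("V(d_opt) - V(in-person)",
         contrast_statistic(fitted_rule, inp, clip_floor),
         contrast_values(fitted_rule, inp, dataset, r)),
    ]
    rows = []
    for label, stat, center in specs:
        est = bootstrap_inference(stat, dataset, B=B, rng=rng, point=center)
        rows.append({"quantity": label, "estimate": est.estimate,
                     "se": est.se, "ci_lower": est.ci_lower,
                     "ci_upper": est.ci_upper,
                     "formatted": str(est)})
    d = fitted_rule.assign(dataset.Z)
    rows.append({"quantity": "n assigned telehealth",
                 "estimate": float(np.sum(d == 1)), "se": np.nan,
                 "ci_lower": np.nan, "ci_upper": np.nan,
                 "formatted": str(int(np.sum(d == 1)))})
    rows.append({"quantity": "n assigned in-person",
                 "estimate": float(np.sum(d == 0)), "se": np.nan,
                 "ci_lower": np.nan, "ci_upper": np.nan,
                 "formatted": str(int(np.sum(d == 0)))})
    return pd.DataFrame(rows)
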