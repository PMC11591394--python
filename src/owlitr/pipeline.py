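"""End-to-end estimation pipeline: preprocess -> weights -> tune -> fit.

The single entry point library users need: feed a raw trial table, get back
the fitted decision rule (with embedded standardization so new individuals
can be scored on the raw scale), the jackknife tuning trace, and the fitted
observation weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .missingness import ObservationWeights, fit_observation_weights
from .owl import (DEFAULT_LAMBDA_GRID, TuningResult, compute_rewards,
                  empirical_propensities, fit_owl, loocv_select_lambda,
                  normalize_weights, owl_weights)
from .preprocessing import TrialDataset, assemble_analysis_dataset
from .rules import DecisionRule


@dataclass(frozen=True)
class FitResult:
    rule: DecisionRule
    tuning: TuningResult
    dataset: TrialDataset
    observation: ObservationWeights


def fit_pipeline(raw: pd.DataFrame,
                 grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                 clip_floor: float = 0.05,
                 max_folds: Optional[int] = None,
                 rng=None,
                 lam: Optional[float] = None) -> FitResult:
    """Estimate the optimal individualized treatment rule from a raw table.

    Stages: intention-to-treat preprocessing (binarize, impute,
    standardize), logistic observation model and IPW weights for missing
    outcomes, jackknife selection of the ridge penalty over ``grid`` (or a
    fixed penalty ``lam``, skipping tuning), and a final weighted-SVM fit on
    the full data at the selected penalty.
    """
    dataset = assemble_analysis_dataset(raw)
    r = fit_observation_weights(dataset, clip_floor=clip_floor)
    pi = empirical_propensities(dataset.A)
    if lam is None:
        tuning = loocv_select_lambda(dataset, r, grid=grid,
                                     propensities=pi,
                                     max_folds=max_folds, rng=rng)
        lam = tuning.selected_lambda
    else:
        import numpy as np
        tuning = TuningResult(grid=np.array([lam]),
                              cv_values=np.array([float("nan")]),
                              selected_lambda=float(lam), assignments={},
                              fold_indices=np.array([], dtype=int))
    w = owl_weights(compute_rewards(dataset.Y), r, dataset.A, propensities=pi)
    rule = fit_owl(dataset.Z, dataset.A, normalize_weights(w.weights), lam)
    rule = DecisionRule(rule.intercept, rule.slopes,
                        standardization=dataset.standardization)
    return FitResult(rule=rule, tuning=tuning, dataset=dataset, observation=r)
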