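"""Observation model and inverse-probability weights for missing outcomes.

Outcome missingness is handled by modelling the probability that a
participant's 6-month outcome was observed — a main-effects logistic
regression on the six standardized prescriptive factors plus the treatment
arm — and weighting each observed participant by the reciprocal of their
fitted observation probability.  Weights are unstabilized; the normalized
(Hajek) value estimator downstream absorbs the difference a stabilizing
numerator would make.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from .preprocessing import TrialDataset

logger = logging.getLogger(__name__)

#: Largest |coefficient| on the standardized scale we accept as a converged
#: ML fit; beyond this the likelihood is effectively flat (separation).
_SEPARATION_BOUND = 15.0


def _design(dataset: TrialDataset) -> np.ndarray:
    """Intercept + 6 standardized covariates + arm indicator."""
    return np.column_stack([np.ones(dataset.n), dataset.Z,
                            dataset.A.astype(float)])


def fit_observation_model(dataset: TrialDataset) -> np.ndarray:
    """ML logistic fit of the observed-outcome indicator; returns coefficients.

    Coefficient order: intercept, the six covariates, arm.  Fitting uses
    iteratively reweighted least squares (statsmodels GLM, binomial family).
    Degenerate inputs (all observed / all missing) return the constant model
    on the logit scale; separation falls back to a ridge-regularized fit
    with a logged warning.
    """
    obs = dataset.observed.astype(float)
    k = _design(dataset).shape[1]
    if obs.all() or not obs.any():
        # constant probability; +-inf logit represented by a large finite value
        const = 30.0 if obs.all() else -30.0
        return np.array([const] + [0.0] * (k - 1))
    X = _design(dataset)
    try:
        res = sm.GLM(obs, X, family=sm.families.Binomial()).fit(
            maxiter=100, tol=1e-10)
        coefs = np.asarray(res.params)
        converged = getattr(res, "converged", True)
    except Exception:   # pragma: no cover - statsmodels raises on perfect fits
        coefs, converged = None, False
    if coefs is None or not converged or np.any(np.abs(coefs) > _SEPARATION_BOUND):
        logger.warning("observation model separated or failed to converge; "
                       "falling back to a ridge-regularized fit")
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=1.0, max_iter=1000)
        lr.fit(X[:, 1:], obs)
        coefs = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    return coefs


@dataclass(frozen=True)
class ObservationWeights:
    """Fitted observation probabilities and inverse-probability weights.

    ``weights[i]`` is 1 / p_hat_i for participants with an observed outcome
    and exactly 0 for missing ones, so downstream weighted sums silently
    drop the missing.  Probabilities are floored at ``clip_floor`` before
    inversion (positivity safeguard).
    """

    probabilities: np.ndarray
    weights: np.ndarray
    coefficients: np.ndarray
    clip_floor: float

    @property
    def n_clipped(self) -> int:
        return int((self.probabilities <= self.clip_floor).sum())


def observation_weights(coefficients: np.ndarray, dataset: TrialDataset,
                        clip_floor: float = 0.05) -> ObservationWeights:
    """Turn fitted coefficients into per-participant IPW weights."""
    if not 0.0 < clip_floor <= 0.5:
        raise ValueError(f"clip_floor {clip_floor} outside (0, 0.5]")
    X = _design(dataset)
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (X.shape[1],):
        raise ValueError(f"expected {X.shape[1]} coefficients, "
                         f"got {coefficients.shape}")
    p = expit(X @ coefficients)
    n_below = int((p < clip_floor).sum())
    if n_below:
        logger.info("floored %d observation probabilit(ies) at %.3g",
                    n_below, clip_floor)
    p = np.maximum(p, clip_floor)
    w = np.where(dataset.observed, 1.0 / p, 0.0)
    return ObservationWeights(probabilities=p, weights=w,
                              coefficients=coefficients, clip_floor=clip_floor)


def fit_observation_weights(dataset: TrialDataset,
                            clip_floor: float = 0.05) -> ObservationWeights:
    """Convenience: fit the model and compute weights in one step."""
    return observation_weights(fit_observation_model(dataset), dataset,
                               clip_floor=clip_floor)
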