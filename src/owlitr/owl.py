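"""Outcome Weighted Learning: weighted SVM estimation of the optimal rule.

OWL recasts value maximization as weighted classification: each participant
votes for the arm they actually received, with a nonnegative weight

    w_i = B_i * r_i / pi_i

where B_i = 80 - Y_i is the reward transform of the 0-80 symptom outcome
(larger = better, so maximizing weighted agreement minimizes expected
symptoms), r_i the inverse-probability-of-observation weight (0 for missing
outcomes), and pi_i the empirical probability of the arm received.  The
estimated rule minimizes the penalized weighted hinge loss

    (1/n) sum_i w_i max(0, 1 - a_i (b0 + b'z_i)) + lambda ||b||^2

with a_i = +1 for telehealth, -1 for in-person, and the intercept b0
unpenalized.  This is exactly a weighted soft-margin linear SVM; the fit is
delegated to libsvm (scikit-learn SVC, linear kernel) after reparameterizing
C = 1 / (2 lambda n).  The objective is invariant to jointly scaling the
weights and lambda by a positive constant, which is used internally to
normalize the weight scale before solving.

The penalty is selected by the jackknife: leave-one-out cross-validation
over a log-spaced grid, scoring each candidate by the Hajek inverse-
probability-weighted value (on the symptom scale, lower = better) of the
left-out assignments.

Two deliberately independent optimizers are included for verification: a
projected-subgradient minimizer of the same objective and a brute-force
search over linear dichotomies for tiny low-dimensional instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import warnings as _warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from .missingness import ObservationWeights
from .preprocessing import TrialDataset
from .rules import COLUMNS, DecisionRule

logger = logging.getLogger(__name__)

#: 13 penalty candidates log-spaced from 2^-8 to 2^4: spans near-unregularized
#: fits through collapse to a single fixed arm.
DEFAULT_LAMBDA_GRID = tuple(float(2.0 ** k) for k in range(-8, 5))

_MIN_LAMBDA = 1e-9      # internal floor so C = 1/(2 lambda n) stays finite


def compute_rewards(Y: np.ndarray) -> np.ndarray:
    """Reward transform B = 80 - Y, anchored at the instrument's maximum.

    Missing outcomes (NaN) map to NaN; they carry zero weight downstream.
    """
    Y = np.asarray(Y, dtype=float)
    obs = Y[~np.isnan(Y)]
    if obs.size and (obs.min() < 0 or obs.max() > 80):
        raise ValueError("outcomes must lie in [0, 80]")
    return 80.0 - Y


def empirical_propensities(A: np.ndarray) -> np.ndarray:
    """pi_i = empirical frequency of the arm participant i received."""
    A = np.asarray(A)
    p1 = A.mean()
    if p1 in (0.0, 1.0):
        raise ValueError("both arms must be present to estimate propensities")
    return np.where(A == 1, p1, 1.0 - p1)


@dataclass(frozen=True)
class OwlWeights:
    """Per-subject classification weights w = B * r / pi and their parts."""

    weights: np.ndarray
    rewards: np.ndarray
    observation: np.ndarray
    propensities: np.ndarray


def owl_weights(B: np.ndarray,
                r: Union[ObservationWeights, np.ndarray],
                A: np.ndarray,
                propensities: Optional[np.ndarray] = None) -> OwlWeights:
    """Assemble OWL weights; exactly zero wherever the outcome is missing."""
    B = np.asarray(B, dtype=float)
    rw = r.weights if isinstance(r, ObservationWeights) else np.asarray(r, float)
    A = np.asarray(A)
    pi = empirical_propensities(A) if propensities is None \
        else np.asarray(propensities, float)
    if np.any(pi <= 0) or np.any(pi >= 1):
        raise ValueError("propensities must lie strictly in (0, 1)")
    w = np.where(rw > 0, np.nan_to_num(B) * rw / pi, 0.0)
    if np.any(w < 0):
        raise ValueError("negative OWL weight; check the reward transform")
    return OwlWeights(weights=w, rewards=B, observation=rw, propensities=pi)


def normalize_weights(w: np.ndarray) -> np.ndarray:
    """Rescale weights to unit mean over their positive entries.

    The OWL objective is invariant to jointly scaling (w, lambda), so this
    fixes the scale on which a penalty grid is interpreted.
    """
    w = np.asarray(w, dtype=float)
    pos = w > 0
    return w / w[pos].mean() if pos.any() else w


@dataclass(frozen=True)
class GenericLinearRule:
    """Linear rule over an arbitrary number of covariates (test instances)."""

    intercept: float
    slopes: np.ndarray

    def score(self, z: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(z, float) @ self.slopes

    def assign(self, z: np.ndarray) -> np.ndarray:
        return (self.score(z) >= 0).astype(int)


def owl_objective(Z, A, w, lam, intercept, slopes) -> float:
    """The penalized weighted hinge loss at the given coefficients."""
    Z = np.asarray(Z, float)
    a = 2.0 * np.asarray(A) - 1.0
    margins = a * (intercept + Z @ np.asarray(slopes, float))
    hinge = np.maximum(0.0, 1.0 - margins)
    return float(np.mean(np.asarray(w, float) * hinge)
                 + lam * np.dot(slopes, slopes))


def _make_rule(intercept: float, slopes: np.ndarray):
    if slopes.shape == (len(COLUMNS),):
        return DecisionRule(intercept=intercept, slopes=slopes)
    return GenericLinearRule(intercept=float(intercept), slopes=slopes)


def fit_owl(Z: np.ndarray, A: np.ndarray, w, lam: float,
            tol: float = 1e-7, gap_tol: float = 1e-4,
            max_iter: int = 100_000):
    """Minimize the penalized weighted hinge loss; returns the fitted rule.

    Deterministic convex fit via libsvm, verified post hoc: libsvm's own
    stopping test can fail to trigger with fractional per-sample weights
    even when the solution is converged, so optimality is certified by the
    relative primal-dual gap (must be below ``gap_tol``), escalating the
    iteration cap once before raising.

    Degenerate inputs are handled explicitly: with no positive weights the
    zero rule is returned (all telehealth by the tie convention, with a
    logged warning); with positive weight confined to a single arm the fit
    collapses to that fixed arm, which is the objective's minimizer among
    intercept-only rules.
    """
    Z = np.asarray(Z, dtype=float)
    A = np.asarray(A)
    w = w.weights if isinstance(w, OwlWeights) else np.asarray(w, dtype=float)
    n, p = Z.shape
    if len(A) != n or len(w) != n:
        raise ValueError("Z, A and w differ in length")
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    pos = w > 0
    if not pos.any():
        logger.warning("all OWL weights are zero; returning the zero rule")
        return _make_rule(0.0, np.zeros(p))
    arms_with_weight = np.unique(A[pos])
    if arms_with_weight.size == 1:
        arm = int(arms_with_weight[0])
        return _make_rule(1.0 if arm == 1 else -1.0, np.zeros(p))
    # joint rescaling of (w, lambda) leaves the minimizer unchanged; use it
    # to put the weights on unit mean scale for the solver
    scale = 1.0 / float(w[pos].mean())
    lam_eff = max(lam, _MIN_LAMBDA) * scale
    C = 1.0 / (2.0 * lam_eff * n)
    ws = w * scale
    a = 2.0 * np.asarray(A, float) - 1.0
    for attempt_tol, attempt_iter in ((tol, max_iter),
                                      (tol / 100, 50 * max_iter)):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            svc = SVC(C=C, kernel="linear", tol=attempt_tol, shrinking=True,
                      max_iter=attempt_iter, cache_size=64)
            svc.fit(Z, A, sample_weight=ws)
        beta = svc.coef_.ravel()
        b0 = float(svc.intercept_[0])
        # relative primal-dual gap of the SVM-scale problem; the dual bound
        # carries a -b0 * (y'alpha) correction for the (tiny) violation of
        # the equality constraint at early termination
        hinge = np.maximum(0.0, 1.0 - a * (b0 + Z @ beta))
        primal = 0.5 * beta @ beta + C * float(np.sum(ws * hinge))
        signed_alpha = svc.dual_coef_.ravel()
        dual = (float(np.abs(signed_alpha).sum()) - 0.5 * beta @ beta
                - b0 * float(signed_alpha.sum()))
        if primal - dual <= gap_tol * max(primal, 1.0):
            break
    else:   # pragma: no cover
        raise RuntimeError(
            f"libsvm did not reach a certified optimum (status "
            f"{svc.fit_status_}, relative gap {(primal - dual) / primal:.2e})")
    # classes_ is sorted [0, 1], so a positive decision score means telehealth
    return _make_rule(b0, beta.copy())


def apply_rule(rule, z: np.ndarray):
    """Score a standardized covariate row: (decision score, arm assignment)."""
    score = rule.score(z)
    return score, (np.asarray(score) >= 0).astype(int)


# ---------------------------------------------------------------------------
# penalty selection (jackknife)

@dataclass(frozen=True)
class TuningResult:
    """Leave-one-out tuning trace: grid, CV symptom values, selection."""

    grid: np.ndarray
    cv_values: np.ndarray
    selected_lambda: float
    assignments: dict = field(repr=False)   # lambda -> left-out assignments
    fold_indices: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"grid": self.grid.tolist(),
                "cv_values": [None if not np.isfinite(v) else float(v)
                              for v in self.cv_values],
                "selected_lambda": float(self.selected_lambda),
                "n_folds": (len(self.fold_indices)
                            if self.fold_indices is not None else None)}


def loocv_select_lambda(dataset: TrialDataset,
                        r: ObservationWeights,
                        grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                        propensities: Optional[np.ndarray] = None,
                        max_folds: Optional[int] = None,
                        rng=None) -> TuningResult:
    """Jackknife penalty selection.

    For each candidate penalty, each participant is left out in turn, the
    rule is refit on the remaining n - 1, and the left-out assignment is
    recorded.  Candidates are scored by the Hajek IPW value of the left-out
    assignments on the symptom scale (lower = better); ties break toward
    the larger penalty (more regularization).

    The OWL weights are normalized to unit mean before fitting (the
    objective is invariant to jointly scaling weights and penalty, so this
    only fixes the scale on which the grid is read; without it the
    meaningful penalty range would drift with the outcome scale).

    ``max_folds`` optionally subsamples the folds without replacement for
    large n (a computational concession; default is the full jackknife).
    """
    grid = np.sort(np.asarray(list(grid), dtype=float))
    if grid.size == 0:
        raise ValueError("penalty grid is empty")
    n = dataset.n
    if n < 3:
        raise ValueError("need at least 3 subjects for leave-one-out tuning")
    Z, A, Y = dataset.Z, dataset.A, dataset.Y
    pi = empirical_propensities(A) if propensities is None else propensities
    B = compute_rewards(Y)
    ow = owl_weights(B, r, A, propensities=pi)
    w = normalize_weights(ow.weights)

    folds = np.arange(n)
    if max_folds is not None and max_folds < n:
        folds = np.sort(np.random.default_rng(rng).choice(n, max_folds,
                                                          replace=False))
    obs = dataset.observed
    cv_values = np.empty(grid.size)
    assignments = {}
    for j, lam in enumerate(grid):
        assigned = np.full(n, -1)
        for i in folds:
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            rule = fit_owl(Z[mask], A[mask], w[mask], lam)
            assigned[i] = int(rule.assign(Z[i]))
        match = (assigned == A) & obs
        den = float(np.sum(r.weights[match] / pi[match]))
        if den <= 0:
            logger.warning("no usable left-out matches at lambda=%g", lam)
            cv_values[j] = np.inf
        else:
            num = float(np.sum(r.weights[match] * Y[match] / pi[match]))
            cv_values[j] = num / den
        assignments[float(lam)] = assigned
    best = np.min(cv_values)
    # ties toward the larger penalty: last index attaining the minimum
    sel = int(np.max(np.flatnonzero(cv_values <= best + 1e-12)))
    return TuningResult(grid=grid, cv_values=cv_values,
                        selected_lambda=float(grid[sel]),
                        assignments=assignments, fold_indices=folds)


# ---------------------------------------------------------------------------
# independent optimizers (verification only)

def subgradient_minimize(Z, A, w, lam: float, n_iter: int = 30_000):
    """Reference minimizer of the OWL objective by subgradient descent.

    Polyak-style subgradient method with a dynamic target: steps are sized
    as (f - (f_best - delta)) / ||g||^2, and the optimism gap ``delta`` is
    halved (restarting from the incumbent) whenever 100 consecutive steps
    fail to improve.  Entirely independent of the SVM route; used as a
    cross-check on small instances.

    Returns ((intercept, slopes), best objective value).
    """
    Z = np.asarray(Z, dtype=float)
    A = np.asarray(A)
    w = w.weights if isinstance(w, OwlWeights) else np.asarray(w, dtype=float)
    n, p = Z.shape
    a = 2.0 * A - 1.0
    scale = float(w[w > 0].mean()) if (w > 0).any() else 1.0
    ws = w / scale
    lam_s = max(lam, _MIN_LAMBDA) / scale
    wa = ws * a / n

    def f_and_g(theta):
        margins = a * (theta[0] + Z @ theta[1:])
        active = (1.0 - margins) > 0
        f = (np.mean(ws * np.maximum(0.0, 1.0 - margins))
             + lam_s * theta[1:] @ theta[1:])
        g = np.empty(p + 1)
        g[0] = -np.sum(wa[active])
        g[1:] = -(wa[active] @ Z[active]) + 2.0 * lam_s * theta[1:]
        return f, g

    theta = np.zeros(p + 1)
    best_f, _ = f_and_g(theta)
    best_theta = theta.copy()
    delta = max(best_f, 1.0) * 0.5
    stall = 0
    for _ in range(n_iter):
        f, g = f_and_g(theta)
        if f < best_f - 1e-14:
            best_f, best_theta, stall = f, theta.copy(), 0
        else:
            stall += 1
            if stall >= 100:
                delta *= 0.5
                stall = 0
                theta = best_theta.copy()
                continue
        gnorm2 = g @ g
        if gnorm2 < 1e-20:
            break
        theta = theta - ((f - (best_f - delta)) / gnorm2) * g
    # undo the weight normalization on the reported objective
    return (best_theta[0], best_theta[1:]), best_f * scale


def smoothed_hinge_minimize(Z, A, w, lam: float, theta0=None):
    """Minimize the OWL objective by smoothed-hinge continuation.

    Replaces the hinge with its softplus smoothing t*log(1 + exp(u/t)) and
    follows the solution path as the temperature t decreases from 1e-1 to
    1e-8 with L-BFGS at each stage; the smoothing bias in the objective is
    O(t), i.e. negligible at the final temperature.  Independent of the
    SVM route.

    Returns ((intercept, slopes), objective value at the unsmoothed hinge).
    """
    from scipy.optimize import minimize as _minimize

    Z = np.asarray(Z, dtype=float)
    A = np.asarray(A)
    w = w.weights if isinstance(w, OwlWeights) else np.asarray(w, dtype=float)
    n, p = Z.shape
    a = 2.0 * A - 1.0
    scale = float(w[w > 0].mean()) if (w > 0).any() else 1.0
    ws = w / scale
    lam_s = max(lam, _MIN_LAMBDA) / scale
    wn = ws / n
    theta = np.zeros(p + 1) if theta0 is None else np.asarray(theta0, float)
    for t in (1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8):
        def fg(th, t=t):
            u = (1.0 - a * (th[0] + Z @ th[1:])) / t
            f = wn @ (t * np.logaddexp(0.0, u)) + lam_s * th[1:] @ th[1:]
            sig = expit_clip(u)
            coef = -wn * sig * a
            g = np.empty(p + 1)
            g[0] = coef.sum()
            g[1:] = coef @ Z + 2.0 * lam_s * th[1:]
            return f, g
        theta = _minimize(fg, theta, jac=True, method="L-BFGS-B",
                          options={"maxiter": 5000, "ftol": 1e-18,
                                   "gtol": 1e-14}).x
    f = owl_objective(Z, A, ws, lam_s, theta[0], theta[1:]) * scale
    return (theta[0], theta[1:]), f


def expit_clip(u: np.ndarray) -> np.ndarray:
    """Overflow-safe logistic function."""
    return 1.0 / (1.0 + np.exp(-np.clip(u, -500.0, 500.0)))


def reference_minimize(Z, A, w, lam: float, subgrad_iter: int = 10_000):
    """Best-of independent reference minimum of the OWL objective.

    Combines the Polyak subgradient method (from zero) with smoothed-hinge
    continuation started both cold and from the subgradient incumbent, and
    returns the best of the three — a certified-independent benchmark for
    the production SVM fit.

    Returns ((intercept, slopes), objective value).
    """
    (b_sg, s_sg), f_sg = subgradient_minimize(Z, A, w, lam,
                                              n_iter=subgrad_iter)
    cand = [((b_sg, s_sg), f_sg)]
    cand.append(smoothed_hinge_minimize(Z, A, w, lam))
    cand.append(smoothed_hinge_minimize(Z, A, w, lam,
                                        theta0=np.concatenate([[b_sg], s_sg])))
    return min(cand, key=lambda c: c[1])


def weighted_01_value(assignments: np.ndarray, A: np.ndarray,
                      w: np.ndarray) -> float:
    """Weighted agreement sum_i w_i 1{A_i = d(z_i)} of an assignment vector."""
    return float(np.sum(np.asarray(w, float)
                        * (np.asarray(assignments) == np.asarray(A))))


def brute_force_oracle(Z, A, w, n_directions: int = 1440):
    """Exhaustive search over linear dichotomies for tiny instances.

    Restricted to p <= 2 and n <= 14.  Scans a dense grid of slope
    directions; for each, every threshold between consecutive projected
    points (plus the two extremes) is a candidate intercept, in both
    orientations, together with the two fixed rules.  Returns
    (best rule, best weighted 0-1 value).
    """
    Z = np.asarray(Z, dtype=float)
    A = np.asarray(A)
    w = np.asarray(w, dtype=float)
    n, p = Z.shape
    if p > 2 or n > 14:
        raise ValueError(f"instance too large for brute force (n={n}, p={p})")
    if p == 1:
        directions = np.array([[1.0], [-1.0]])
    else:
        angles = np.linspace(0.0, np.pi, n_directions, endpoint=False)
        directions = np.column_stack([np.cos(angles), np.sin(angles)])
        directions = np.vstack([directions, -directions])
    best_rule = GenericLinearRule(1.0, np.zeros(p))       # all telehealth
    best_val = weighted_01_value(np.ones(n, int), A, w)
    val0 = weighted_01_value(np.zeros(n, int), A, w)      # all in-person
    if val0 > best_val:
        best_rule, best_val = GenericLinearRule(-1.0, np.zeros(p)), val0
    for u in directions:
        s = Z @ u
        order = np.sort(np.unique(s))
        cuts = np.concatenate([[order[0] - 1.0],
                               (order[:-1] + order[1:]) / 2.0 if order.size > 1
                               else np.empty(0),
                               [order[-1] + 1.0]])
        for t in cuts:
            d = (s - t >= 0).astype(int)
            v = weighted_01_value(d, A, w)
            if v > best_val + 1e-12:
                best_rule, best_val = GenericLinearRule(float(-t), u.copy()), v
    return best_rule, best_val
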