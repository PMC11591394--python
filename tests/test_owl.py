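"""Outcome Weighted Learning core: rewards, weights, convex fit, tuning.

The weighted-SVM fit is checked against two independent optimizers: a
smoothed-hinge/subgradient reference minimizer on random instances, and an
exhaustive search over linear dichotomies on tiny low-dimensional ones.
"""

import numpy as np
import pytest

from owlitr import (DEFAULT_LAMBDA_GRID, DecisionRule, SyntheticConfig,
                    apply_rule, assemble_analysis_dataset, brute_force_oracle,
                    compute_rewards, empirical_propensities,
                    fit_observation_weights, fit_owl, generate_trial,
                    loocv_select_lambda, normalize_weights, owl_objective,
                    owl_weights, reference_minimize, subgradient_minimize,
                    weighted_01_value)

PRINTED_INTERCEPT = -0.23
PRINTED_SLOPES = np.array([-0.84, -0.96, 0.02, 0.08, 0.63, -0.02])


def separable_instance(rng, n=12, margin=0.25):
    """Weights aligned with a linear boundary, with an actual margin.

    Points inside the margin band are pushed out along the boundary normal;
    a hinge-loss minimizer pays a ridge price for razor-thin margins, so a
    margin-free construction would test the penalty, not the classifier.
    """
    Z = rng.normal(size=(n, 2))
    u = rng.normal(size=2)
    u /= np.linalg.norm(u)
    s = Z @ u
    tight = np.abs(s) < margin
    Z[tight] += np.outer(np.sign(s[tight]) * (margin - np.abs(s[tight])), u)
    A = (Z @ u >= 0).astype(int)
    if len(np.unique(A)) < 2:
        Z[0] = -Z[0]
        A[0] = 1 - A[0]
    return Z, A, rng.gamma(3.0, 1.0, n)


def _random_instance(rng, n=None, p=6):
    n = n or int(rng.integers(8, 31))
    Z = rng.normal(size=(n, p))
    A = rng.integers(0, 2, n)
    if len(np.unique(A)) < 2:
        A[0] = 1 - A[0]
    w = rng.gamma(2.0, 1.0, n)
    w[rng.random(n) < 0.2] = 0.0
    return Z, A, w


class TestRewardsAndWeights:
    def test_reward_transform_endpoints(self):
        np.testing.assert_allclose(compute_rewards(np.array([80.0, 0.0])),
                                   [0.0, 80.0])

    def test_reward_of_baseline_mean(self):
        assert compute_rewards(np.array([52.74]))[0] == pytest.approx(27.26)

    def test_out_of_range_outcome_rejected(self):
        with pytest.raises(ValueError):
            compute_rewards(np.array([90.0]))

    def test_weight_arithmetic(self):
        w = owl_weights(np.array([40.0, 40.0]), np.array([1.0, 1.0]),
                        np.array([1, 0]),
                        propensities=np.array([0.5, 0.5]))
        np.testing.assert_allclose(w.weights, [80.0, 80.0])

    def test_missing_outcome_weight_is_zero(self):
        w = owl_weights(np.array([np.nan, 40.0]), np.array([0.0, 2.0]),
                        np.array([1, 0]),
                        propensities=np.array([0.5, 0.5]))
        assert w.weights[0] == 0.0
        assert w.weights[1] == pytest.approx(160.0)

    def test_empirical_propensities_from_62_60_split(self):
        A = np.array([1] * 62 + [0] * 60)
        pi = empirical_propensities(A)
        assert pi[0] == pytest.approx(62 / 122, abs=1e-4)   # 0.5082
        assert pi[-1] == pytest.approx(60 / 122, abs=1e-4)

    def test_single_arm_propensity_rejected(self):
        with pytest.raises(ValueError):
            empirical_propensities(np.ones(10, int))


class TestFitOwl:
    def test_all_zero_weights_gives_zero_rule(self, rng):
        Z = rng.normal(size=(10, 6))
        A = np.array([0, 1] * 5)
        rule = fit_owl(Z, A, np.zeros(10), 0.1)
        assert rule.intercept == 0.0
        np.testing.assert_allclose(rule.slopes, 0.0)
        assert (rule.assign(Z) == 1).all()      # tie convention

    def test_two_subjects_strong_penalty_weighted_majority(self, rng):
        # with a large penalty the slopes are forced to ~0 and the optimal
        # intercept-only rule follows the heavier class: verified against a
        # 1-D grid search over the intercept
        Z = rng.normal(size=(2, 6))
        A = np.array([1, 0])
        w = np.array([10.0, 1.0])
        lam = 10.0
        rule = fit_owl(Z, A, w, lam)
        assert (rule.assign(Z) == 1).all()
        grid = np.linspace(-3, 3, 2001)
        objs = [owl_objective(Z, A, w, lam, b0, np.zeros(6)) for b0 in grid]
        best_b0 = grid[int(np.argmin(objs))]
        assert best_b0 > 0      # telehealth side
        assert owl_objective(Z, A, w, lam, rule.intercept, rule.slopes) \
            <= min(objs) + 1e-6

    def test_objective_matches_independent_minimizer(self, rng):
        for _ in range(10):
            Z, A, w = _random_instance(rng)
            lam = float(rng.choice([0.01, 0.1, 1.0]))
            rule = fit_owl(Z, A, w, lam)
            f_fit = owl_objective(Z, A, w, lam, rule.intercept, rule.slopes)
            _, f_ref = reference_minimize(Z, A, w, lam)
            assert abs(f_fit - f_ref) <= 1e-4 * max(abs(f_ref), 1.0)

    def test_subgradient_route_agrees_coarsely(self, rng):
        Z, A, w = _random_instance(rng, n=20)
        lam = 0.5
        rule = fit_owl(Z, A, w, lam)
        f_fit = owl_objective(Z, A, w, lam, rule.intercept, rule.slopes)
        _, f_sub = subgradient_minimize(Z, A, w, lam, n_iter=30_000)
        assert f_fit <= f_sub + 2e-3 * max(abs(f_sub), 1.0)

    def test_deterministic(self, rng):
        Z, A, w = _random_instance(rng, n=25)
        r1 = fit_owl(Z, A, w, 0.1)
        r2 = fit_owl(Z, A, w, 0.1)
        assert r1.intercept == pytest.approx(r2.intercept, abs=1e-8)
        np.testing.assert_allclose(r1.slopes, r2.slopes, atol=1e-8)

    def test_joint_weight_penalty_scaling_invariance(self, rng):
        Z, A, w = _random_instance(rng, n=25)
        r1 = fit_owl(Z, A, w, 0.2)
        r2 = fit_owl(Z, A, 7.0 * w, 7.0 * 0.2)
        np.testing.assert_array_equal(r1.assign(Z), r2.assign(Z))
        np.testing.assert_allclose(r1.slopes, r2.slopes, atol=1e-5)

    def test_objective_no_worse_than_zero_rule(self, rng):
        for _ in range(5):
            Z, A, w = _random_instance(rng)
            lam = float(rng.choice([0.05, 0.5]))
            rule = fit_owl(Z, A, w, lam)
            f_fit = owl_objective(Z, A, w, lam, rule.intercept, rule.slopes)
            f_zero = owl_objective(Z, A, w, lam, 0.0, np.zeros(6))
            assert f_fit <= f_zero + 1e-10

    def test_large_penalty_collapses_to_fixed_arm(self, rng):
        Z, A, w = _random_instance(rng, n=30)
        rule = fit_owl(Z, A, normalize_weights(w), 1e4)
        assert np.abs(rule.slopes).max() < 1e-2
        assert len(np.unique(rule.assign(Z))) == 1

    def test_negative_weight_rejected(self, rng):
        Z, A, w = _random_instance(rng, n=10)
        w[0] = -1.0
        with pytest.raises(ValueError):
            fit_owl(Z, A, w, 0.1)


class TestApplyRule:
    def test_printed_rule_at_origin(self):
        rule = DecisionRule(PRINTED_INTERCEPT, PRINTED_SLOPES)
        score, arm = apply_rule(rule, np.zeros(6))
        assert score == pytest.approx(-0.23)
        assert arm == 0

    def test_printed_rule_at_all_ones(self):
        rule = DecisionRule(PRINTED_INTERCEPT, PRINTED_SLOPES)
        score, arm = apply_rule(rule, np.ones(6))
        assert score == pytest.approx(-1.32)
        assert arm == 0

    def test_zero_rule_tie_is_telehealth(self):
        score, arm = apply_rule(DecisionRule(0.0, np.zeros(6)), np.ones(6))
        assert score == 0.0 and arm == 1


class TestLoocv:
    @staticmethod
    def _small_dataset(n=24, seed=31):
        trial = generate_trial(SyntheticConfig(n=n, seed=seed))
        ds = assemble_analysis_dataset(trial)
        return ds, fit_observation_weights(ds)

    def test_single_candidate_selected(self):
        ds, r = self._small_dataset()
        res = loocv_select_lambda(ds, r, grid=[0.5])
        assert res.selected_lambda == 0.5
        assert np.isfinite(res.cv_values).all()

    def test_matches_handrolled_loop(self):
        ds, r = self._small_dataset(n=12, seed=32)
        lam = 0.25
        res = loocv_select_lambda(ds, r, grid=[lam])
        pi = empirical_propensities(ds.A)
        w = normalize_weights(
            owl_weights(compute_rewards(ds.Y), r, ds.A, pi).weights)
        assigned = np.empty(ds.n, dtype=int)
        for i in range(ds.n):
            mask = np.ones(ds.n, bool)
            mask[i] = False
            rule_i = fit_owl(ds.Z[mask], ds.A[mask], w[mask], lam)
            assigned[i] = rule_i.assign(ds.Z[i])
        match = (assigned == ds.A) & ds.observed
        expect = (np.sum(r.weights[match] * ds.Y[match] / pi[match])
                  / np.sum(r.weights[match] / pi[match]))
        assert res.cv_values[0] == pytest.approx(expect, abs=1e-8)
        np.testing.assert_array_equal(res.assignments[lam], assigned)

    def test_ties_break_toward_larger_penalty(self):
        ds, r = self._small_dataset(n=15, seed=33)
        # duplicated candidate values guarantee an exact tie
        res = loocv_select_lambda(ds, r, grid=[0.5, 0.5])
        assert res.selected_lambda == 0.5
        res2 = loocv_select_lambda(ds, r, grid=[1e3, 2e3])
        # both collapse to the same fixed rule -> tie -> larger wins
        if res2.cv_values[0] == res2.cv_values[1]:
            assert res2.selected_lambda == 2e3

    def test_default_grid_shape(self):
        assert len(DEFAULT_LAMBDA_GRID) == 13
        assert DEFAULT_LAMBDA_GRID[0] == pytest.approx(2.0 ** -8)
        assert DEFAULT_LAMBDA_GRID[-1] == pytest.approx(2.0 ** 4)

    def test_tiny_n_rejected(self):
        ds, r = self._small_dataset(n=4, seed=34)
        sub = ds.subset(np.arange(2))
        with pytest.raises(ValueError):
            loocv_select_lambda(sub, r, grid=[0.1])


class TestBruteForceOracle:
    def test_refuses_large_instances(self, rng):
        with pytest.raises(ValueError, match="too large"):
            brute_force_oracle(rng.normal(size=(20, 2)),
                               rng.integers(0, 2, 20), np.ones(20))
        with pytest.raises(ValueError, match="too large"):
            brute_force_oracle(rng.normal(size=(10, 3)),
                               rng.integers(0, 2, 10), np.ones(10))

    def test_all_weight_on_one_arm(self, rng):
        Z = rng.normal(size=(8, 2))
        A = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        w = np.where(A == 1, 5.0, 0.0)
        rule, val = brute_force_oracle(Z, A, w)
        assert val == pytest.approx(20.0)
        assert (rule.assign(Z[A == 1]) == 1).all()

    def test_oracle_dominates_owl_fit(self, rng):
        for _ in range(5):
            Z = rng.normal(size=(10, 2))
            A = rng.integers(0, 2, 10)
            if len(np.unique(A)) < 2:
                A[0] = 1 - A[0]
            w = rng.gamma(2.0, 1.0, 10)
            _, oracle_val = brute_force_oracle(Z, A, w)
            owl_rule = fit_owl(Z, A, w, 0.05)
            owl_val = weighted_01_value(owl_rule.assign(Z), A, w)
            assert oracle_val >= owl_val - 1e-9

    def test_owl_near_oracle_on_separable_instances(self, rng):
        for _ in range(10):
            Z, A, w = separable_instance(rng)
            _, oracle_val = brute_force_oracle(Z, A, w)
            owl_rule = fit_owl(Z, A, w, 1e-3)
            owl_val = weighted_01_value(owl_rule.assign(Z), A, w)
            assert owl_val >= 0.95 * oracle_val
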