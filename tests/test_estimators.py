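"""Estimator correctness against hand arithmetic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import banditdose as bd
from banditdose import LoggedBandit, UniformPolicy
from banditdose.bandit_core import FunctionPolicy

from conftest import stub_ensemble


def _const_policy(prob_rows):
    """Policy returning fixed per-row probability vectors (fixture device)."""
    P = np.asarray(prob_rows, float)
    return FunctionPolicy(lambda X: P[: np.atleast_2d(X).shape[0]], P.shape[1])


def three_record_log():
    """The 3-record micro-fixture: p_h of logged actions 1, p_h0 = 0.5."""
    D = LoggedBandit(
        contexts=np.arange(3, dtype=float).reshape(3, 1),
        actions=[0, 0, 0],
        rewards=[1.0, 0.0, 1.0],
        n_actions=2,
    )
    h = _const_policy(np.tile([1.0, 0.0], (3, 1)))
    p_h0 = np.array([0.5, 0.5, 0.5])
    return D, h, p_h0


class TestIPS:
    def test_three_record_fixture(self):
        D, h, p_h0 = three_record_log()
        assert bd.ips(D, h, p_h0).estimate == pytest.approx(4 / 3, abs=1e-12)

    def test_h_equals_h0_recovers_mean_reward(self, rng):
        D = LoggedBandit(rng.standard_normal((50, 2)), rng.integers(0, 3, 50),
                         rng.random(50), n_actions=3)
        h = UniformPolicy(3)
        p_h0 = h.prob_of(D.contexts, D.actions)
        assert bd.ips(D, h, p_h0).estimate == pytest.approx(
            bd.empirical_mean_reward(D), abs=1e-12
        )

    def test_zero_rewards_give_zero(self, rng):
        D = LoggedBandit(rng.standard_normal((10, 2)), rng.integers(0, 2, 10),
                         np.zeros(10), n_actions=2)
        assert bd.ips(D, UniformPolicy(2), np.full(10, 0.3)).estimate == 0.0

    def test_overlap_violation_rejected(self):
        D, h, _ = three_record_log()
        with pytest.raises(ValueError, match="overlap"):
            bd.ips(D, h, np.array([0.5, 0.0, 0.5]))


class TestCappedIPS:
    def test_inactive_cap_equals_ips(self):
        D, h, p_h0 = three_record_log()
        capped = bd.capped_ips(D, h, p_h0, cap_M=0.4)  # cap below min p_h0
        assert capped.estimate == bd.ips(D, h, p_h0).estimate

    def test_single_record_hand_value(self):
        D = LoggedBandit([[0.0]], [0], [1.0], n_actions=2)
        h = _const_policy([[1.0, 0.0]])
        assert bd.capped_ips(D, h, np.array([0.25]), 0.3).estimate == pytest.approx(
            1 / 0.3, abs=1e-12
        )

    def test_cap_near_one_bounds_estimate(self, rng):
        D = LoggedBandit(rng.standard_normal((30, 2)), rng.integers(0, 3, 30),
                         rng.random(30), n_actions=3)
        h = UniformPolicy(3)
        est = bd.capped_ips(D, h, rng.uniform(0.01, 1, 30), 1 - 1e-9).estimate
        assert abs(est) <= np.mean(np.abs(D.rewards)) + 1e-9

    def test_invalid_cap_rejected(self):
        D, h, p_h0 = three_record_log()
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                bd.capped_ips(D, h, p_h0, bad)


class TestSNIPS:
    def test_three_record_fixture(self):
        D, h, p_h0 = three_record_log()
        # (2*1 + 2*0 + 2*1) / (2 + 2 + 2)
        assert bd.snips(D, h, p_h0).estimate == pytest.approx(2 / 3, abs=1e-12)

    def test_constant_reward_recovered_exactly(self, rng):
        c = 0.37
        D = LoggedBandit(rng.standard_normal((25, 2)), rng.integers(0, 3, 25),
                         np.full(25, c), n_actions=3)
        p_h0 = rng.uniform(0.05, 1.0, 25)
        assert bd.snips(D, UniformPolicy(3), p_h0).estimate == pytest.approx(
            c, abs=1e-12
        )

    def test_scale_invariance_of_weights(self):
        D, h, p_h0 = three_record_log()
        a = bd.snips(D, h, p_h0).estimate
        b = bd.snips(D, h, p_h0 / 7.0).estimate  # scales all weights by 7
        assert a == pytest.approx(b, abs=1e-12)

    def test_all_zero_weights_rejected(self):
        D, _, p_h0 = three_record_log()
        h_zero = _const_policy(np.tile([0.0, 1.0], (3, 1)))
        with pytest.raises(ValueError, match="zero"):
            bd.snips(D, h_zero, p_h0)


def one_record_two_members():
    D = LoggedBandit([[0.0]], [0], [1.0], n_actions=2)
    h = _const_policy([[1.0, 0.0]])
    E = stub_ensemble([np.array([[0.5, 0.5]]), np.array([[0.25, 0.75]])])
    return D, h, E


class TestEnsembleEstimators:
    def test_ips_avg_hand_value(self):
        D, h, E = one_record_two_members()
        # denominator mean(0.5, 0.25) = 0.375
        assert bd.ips_avg(D, h, E).estimate == pytest.approx(1 / 0.375, abs=1e-12)

    def test_ips_inv_hand_value(self):
        D, h, E = one_record_two_members()
        assert bd.ips_inv(D, h, E).estimate == pytest.approx(3.0, abs=1e-12)

    def test_singleton_ensemble_matches_plain_ips(self):
        D, h, p_h0 = three_record_log()
        P = np.column_stack([p_h0, 1 - p_h0])
        E = stub_ensemble([P])
        assert bd.ips_avg(D, h, E).estimate == pytest.approx(
            bd.ips(D, h, p_h0).estimate, abs=1e-12
        )

    def test_identical_members_collapse_to_plain(self):
        D, h, p_h0 = three_record_log()
        P = np.column_stack([p_h0, 1 - p_h0])
        E = stub_ensemble([P, P, P])
        for fn, ref in [(bd.ips_avg, bd.ips), (bd.ips_inv, bd.ips),
                        (bd.snips_avg, bd.snips), (bd.snips_inv, bd.snips)]:
            assert fn(D, h, E).estimate == pytest.approx(
                ref(D, h, p_h0).estimate, abs=1e-12
            )

    def test_ips_inv_is_mean_of_member_ips(self, rng):
        D = LoggedBandit(rng.standard_normal((12, 2)), rng.integers(0, 3, 12),
                         rng.random(12), n_actions=3)
        h = UniformPolicy(3)
        mats = [rng.dirichlet(np.ones(3), 12) for _ in range(4)]
        E = stub_ensemble(mats)
        per = [bd.ips(D, h, m[np.arange(12), D.actions]).estimate for m in mats]
        assert bd.ips_inv(D, h, E).estimate == pytest.approx(
            np.mean(per), abs=1e-12
        )

    def test_snips_constant_reward_survives_both_constructions(self, rng):
        c = 0.81
        D = LoggedBandit(rng.standard_normal((9, 2)), rng.integers(0, 3, 9),
                         np.full(9, c), n_actions=3)
        E = stub_ensemble([rng.dirichlet(np.ones(3), 9) for _ in range(3)])
        assert bd.snips_avg(D, UniformPolicy(3), E).estimate == pytest.approx(c)
        assert bd.snips_inv(D, UniformPolicy(3), E).estimate == pytest.approx(c)

    def test_snips_ensemble_two_record_hand_value(self):
        D = LoggedBandit([[0.0], [1.0]], [0, 1], [1.0, 0.0], n_actions=2)
        h = _const_policy([[0.8, 0.2], [0.4, 0.6]])
        E = stub_ensemble(
            [np.array([[0.5, 0.5], [0.5, 0.5]]),
             np.array([[0.25, 0.75], [0.1, 0.9]])]
        )
        # member weights: m1 -> (1.6, 1.2); m2 -> (3.2, 2/3)
        snips_m1 = 1.6 / (1.6 + 1.2)
        snips_m2 = 3.2 / (3.2 + 2 / 3)
        assert bd.snips_inv(D, h, E).estimate == pytest.approx(
            (snips_m1 + snips_m2) / 2, abs=1e-12
        )
        # averaged propensities: (0.375, 0.7); weights (0.8/0.375, 0.6/0.7)
        w1, w2 = 0.8 / 0.375, 0.6 / 0.7
        assert bd.snips_avg(D, h, E).estimate == pytest.approx(
            w1 / (w1 + w2), abs=1e-12
        )


class TestBalanceHeuristic:
    def test_single_part_reduces_to_ips(self):
        D, h, p_h0 = three_record_log()
        res = bd.balance_heuristic([D], h, [p_h0[None, :]])
        assert res.estimate == pytest.approx(bd.ips(D, h, p_h0).estimate, abs=1e-12)

    def test_equal_parts_equal_models_match_ips_avg(self, rng):
        # two parts of equal size whose models are evaluated everywhere:
        # the mixture denominator is then the member average, i.e. IPS_avg
        n_half = 4
        Xs = rng.standard_normal((2 * n_half, 2))
        a = rng.integers(0, 2, 2 * n_half)
        r = rng.random(2 * n_half)
        D_full = LoggedBandit(Xs, a, r, n_actions=2)
        h = UniformPolicy(2)
        m1 = rng.uniform(0.2, 0.9, 2 * n_half)
        m2 = rng.uniform(0.2, 0.9, 2 * n_half)
        E = stub_ensemble(
            [np.column_stack([m1, 1 - m1]), np.column_stack([m2, 1 - m2])]
        )
        parts = [D_full.subset(np.arange(n_half)),
                 D_full.subset(np.arange(n_half, 2 * n_half))]
        q1 = np.where(a == 0, m1, 1 - m1)  # member propensities of logged action
        q2 = np.where(a == 0, m2, 1 - m2)
        props = [
            np.stack([q1[:n_half], q2[:n_half]]),
            np.stack([q1[n_half:], q2[n_half:]]),
        ]
        res = bd.balance_heuristic(parts, h, props)
        assert res.estimate == pytest.approx(
            bd.ips_avg(D_full, h, E).estimate, rel=1e-12
        )

    def test_unequal_parts_hand_value(self):
        # 4 records split 3/1; hand-computed mixture denominators
        D1 = LoggedBandit([[0.0], [1.0], [2.0]], [0, 0, 0], [1.0, 1.0, 0.0],
                          n_actions=2)
        D2 = LoggedBandit([[3.0]], [0], [1.0], n_actions=2)
        h = _const_policy(np.tile([1.0, 0.0], (3, 1)))
        p1 = np.array([[0.5, 0.4, 0.8], [0.25, 0.2, 0.4]])  # models x records
        p2 = np.array([[0.5], [0.1]])
        res = bd.balance_heuristic([D1, D2], h, [p1, p2])
        # denominators: (3*p1_m1 + 1*p1_m2)/4 per record of part 1, etc.
        d1 = (3 * p1[0] + 1 * p1[1]) / 4
        d2 = (3 * p2[0] + 1 * p2[1]) / 4
        expected = (np.sum(np.array([1, 1, 0]) / d1) + np.sum(1 / d2)) / 4
        assert res.estimate == pytest.approx(expected, abs=1e-12)

    def test_size_mismatch_rejected(self):
        D, h, p_h0 = three_record_log()
        with pytest.raises(ValueError):
            bd.balance_heuristic([D], h, [np.ones((2, 2))])


class TestDirectMethod:
    def test_constant_reward_model(self):
        D, h, _ = three_record_log()
        res = bd.direct_method(D, h, lambda X, a: np.full(len(X), 0.42))
        assert res.estimate == pytest.approx(0.42, abs=1e-12)

    def test_point_mass_policy_reads_one_action(self, rng):
        D = LoggedBandit(rng.standard_normal((10, 2)), rng.integers(0, 2, 10),
                         rng.random(10), n_actions=2)
        h = _const_policy(np.tile([1.0, 0.0], (10, 1)))
        rhat = {0: rng.random(10), 1: rng.random(10)}
        res = bd.direct_method(D, h, lambda X, a: rhat[a])
        assert res.estimate == pytest.approx(np.mean(rhat[0]), abs=1e-12)

    def test_two_record_hand_value(self):
        D = LoggedBandit([[0.0], [1.0]], [0, 1], [0.0, 0.0], n_actions=2)
        h = _const_policy([[0.3, 0.7], [0.9, 0.1]])
        table = {0: np.array([1.0, 2.0]), 1: np.array([3.0, 4.0])}
        res = bd.direct_method(D, h, lambda X, a: table[a])
        expected = ((0.3 * 1 + 0.7 * 3) + (0.9 * 2 + 0.1 * 4)) / 2
        assert res.estimate == pytest.approx(expected, abs=1e-12)


class TestOrderingAndBounds:
    @given(st.integers(0, 10_000))
    @settings(max_examples=200)
    def test_am_hm_ordering(self, seed):
        """ips_inv >= ips_avg for nonnegative rewards: harmonic-mean
        denominators never exceed arithmetic-mean denominators."""
        rng = np.random.default_rng(seed)
        n, M, K = rng.integers(2, 10), rng.integers(2, 5), 3
        D = LoggedBandit(rng.standard_normal((n, 2)), rng.integers(0, K, n),
                         rng.random(n), n_actions=K)
        E = stub_ensemble([rng.dirichlet(np.ones(K), n) for _ in range(M)])
        h = UniformPolicy(K)
        assert bd.ips_inv(D, h, E).estimate >= bd.ips_avg(D, h, E).estimate - 1e-12

    @given(st.integers(0, 10_000))
    def test_snips_within_reward_range(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 20)
        r = rng.standard_normal(n) * 3
        D = LoggedBandit(rng.standard_normal((n, 2)), rng.integers(0, 3, n), r,
                         n_actions=3)
        est = bd.snips(D, UniformPolicy(3), rng.uniform(0.01, 1, n)).estimate
        assert r.min() - 1e-9 <= est <= r.max() + 1e-9

    def test_ips_can_leave_reward_range_but_snips_cannot(self):
        # a heavy weight pushes IPS above max(r) while SNIPS stays inside
        D = LoggedBandit([[0.0], [1.0]], [0, 0], [1.0, 1.0], n_actions=2)
        h = _const_policy(np.tile([1.0, 0.0], (2, 1)))
        p_h0 = np.array([0.1, 0.9])
        assert bd.ips(D, h, p_h0).estimate > 1.0
        assert bd.snips(D, h, p_h0).estimate <= 1.0


class TestUnbiasednessAndVariance:
    def test_ips_unbiased_with_true_propensities(self):
        """Mean IPS over simulated logs approaches the enumerated R(h)."""
        task = bd.make_discrete_task(n_contexts=6, K=3, seed=5)
        h = bd.policy_from_weights(np.zeros((2, 3)), "linear-softmax",
                                   bias=np.array([1.0, 0.0, -0.5]))
        log_policy = bd.UniformPolicy(3)
        truth = task.exact_policy_value(h)
        ests = []
        for s in range(300):
            D = task.sample_log(60, log_policy, seed=1000 + s)
            ests.append(bd.ips(D, h, D.logged_propensity).estimate)
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - truth) < 3 * se + 1e-12

    def test_snips_variance_below_ips_on_heavy_weights(self):
        """Self-normalization shrinks across-simulation variance when the
        target concentrates where the logging policy rarely goes."""
        task = bd.make_discrete_task(n_contexts=5, K=3, seed=3)
        # target prefers action 0 strongly; logging is uniform
        h = bd.policy_from_weights(np.zeros((2, 3)), "linear-softmax",
                                  bias=np.array([3.0, 0.0, 0.0]))
        log_policy = bd.UniformPolicy(3)
        ips_vals, snips_vals = [], []
        for s in range(200):
            D = task.sample_log(40, log_policy, seed=500 + s)
            ips_vals.append(bd.ips(D, h, D.logged_propensity).estimate)
            snips_vals.append(bd.snips(D, h, D.logged_propensity).estimate)
        assert np.var(snips_vals, ddof=1) <= np.var(ips_vals, ddof=1)


class TestBootstrappedEvaluation:
    def test_singleton_ci_degenerates(self, noisy_task):
        X, y = noisy_task.X[:150], noisy_task.y[:150]
        D = bd.supervised_to_bandit(X, y, UniformPolicy(3), seed=0)
        res = bd.bootstrapped_evaluation(
            D, UniformPolicy(3), estimator="snips_inv", M=1,
            propensity_cfg=bd.PropensityModelConfig(max_epochs=5), seed=0,
        )
        assert res.ci_low == pytest.approx(res.estimate)
        assert res.ci_high == pytest.approx(res.estimate)

    def test_ci_brackets_member_mean(self, noisy_task):
        X, y = noisy_task.X[:150], noisy_task.y[:150]
        D = bd.supervised_to_bandit(X, y, UniformPolicy(3), seed=1)
        res = bd.bootstrapped_evaluation(
            D, UniformPolicy(3), estimator="ips_inv", M=5,
            propensity_cfg=bd.PropensityModelConfig(max_epochs=5), seed=1,
        )
        mean = np.mean(res.per_member)
        assert res.ci_low <= mean <= res.ci_high

    def test_unknown_estimator_rejected(self, noisy_task):
        D = bd.supervised_to_bandit(noisy_task.X[:20], noisy_task.y[:20],
                                    UniformPolicy(3), seed=0)
        with pytest.raises(ValueError, match="unknown"):
            bd.bootstrapped_evaluation(D, UniformPolicy(3), estimator="doubly_robust")

    def test_coverage_on_enumerable_task(self):
        """The percentile CI over bootstrap members covers the enumerated
        true reward in most repeats on a small noisy task."""
        task = bd.make_discrete_task(n_contexts=6, d=2, K=3, seed=9)
        h = UniformPolicy(3)
        truth = task.exact_policy_value(h)
        log_policy = UniformPolicy(3)
        cfg = bd.PropensityModelConfig(max_epochs=15, hidden_units=8)
        hits = 0
        n_rep = 30
        for s in range(n_rep):
            D = task.sample_log(120, log_policy, seed=2000 + s)
            res = bd.bootstrapped_evaluation(
                D, h, estimator="snips_inv", M=6, propensity_cfg=cfg, seed=s,
            )
            if res.ci_low - 0.02 <= truth <= res.ci_high + 0.02:
                hits += 1
        assert hits / n_rep >= 0.8


class TestEvaluationError:
    def test_exact_estimates_give_zero(self):
        assert bd.evaluation_error([0.5, 0.5, 0.5], 0.5) == (0.0, 0.0, 0.0)

    def test_symmetric_errors_hand_value(self):
        mae, rmse, sd = bd.evaluation_error([1.5, -0.5], 0.5)
        assert (mae, rmse) == (1.0, 1.0)
        assert sd == pytest.approx(np.sqrt(2))  # sample (n-1) convention

    @given(st.integers(0, 500))
    def test_mae_le_rmse(self, seed):
        rng = np.random.default_rng(seed)
        est = rng.standard_normal(rng.integers(1, 20))
        mae, rmse, _ = bd.evaluation_error(est, 0.0)
        assert mae <= rmse + 1e-12


class TestPolicyEvaluationModel:
    def test_fit_reports_all_estimators(self, noisy_task):
        X, y = noisy_task.X[:200], noisy_task.y[:200]
        D = bd.supervised_to_bandit(X, y, UniformPolicy(3), seed=3)
        model = bd.PolicyEvaluation(
            D, UniformPolicy(3), estimators=("ips", "snips", "snips_avg"),
            n_members=3,
            propensity_cfg=bd.PropensityModelConfig(max_epochs=5),
        )
        res = model.fit(seed=0)
        assert set(res.estimates) == {"ips", "snips", "snips_avg"}
        assert res["snips_avg"].ci_low is not None
        out = res.summary()
        assert "snips_avg" in out and "estimate" in out

    def test_uses_logged_propensities_for_plain_estimators(self, noisy_task):
        X, y = noisy_task.X[:100], noisy_task.y[:100]
        D = bd.supervised_to_bandit(X, y, UniformPolicy(3), seed=4)
        res = bd.PolicyEvaluation(D, UniformPolicy(3), estimators=("ips",)).fit()
        # h == h0 == uniform with true propensities: IPS == mean reward
        assert res["ips"].estimate == pytest.approx(bd.empirical_mean_reward(D))

    def test_unknown_estimator_rejected(self, noisy_task):
        D = bd.supervised_to_bandit(noisy_task.X[:20], noisy_task.y[:20],
                                    UniformPolicy(3), seed=0)
        with pytest.raises(ValueError):
            bd.PolicyEvaluation(D, UniformPolicy(3), estimators=("poem",))
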