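"""The MAML head: losses, gradients, task sampling and adaptation."""

from dataclasses import replace

import numpy as np
import pytest

import metarf as mf
from metarf.meta_attention import (
    AttentionHead,
    MetaConfig,
    Scaler,
    Task,
    fine_tune,
    initialize_uniform_attention,
    inner_update,
    loss_gradient,
    meta_train,
    outer_gradient,
    sample_task,
    task_loss,
)


def constant_head(value: float, input_dim: int = 1) -> AttentionHead:
    """A head computing f(x) = value for every input (all weights zero)."""
    head = AttentionHead.initialize(input_dim, seed=0)
    params = {k: np.zeros_like(v) for k, v in head.params.items()}
    params["b3"] = np.array(value)
    return AttentionHead(params=params, input_dim=input_dim)


def numeric_gradient(fn, params, eps=1e-6):
    out = {}
    for k, v in params.items():
        g = np.zeros_like(np.atleast_1d(v), dtype=float)
        it = np.nditer(np.atleast_1d(v), flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            p_hi = {kk: vv.copy() for kk, vv in params.items()}
            p_lo = {kk: vv.copy() for kk, vv in params.items()}
            np.atleast_1d(p_hi[k])[idx] += eps
            np.atleast_1d(p_lo[k])[idx] -= eps
            g[idx] = (fn(p_hi) - fn(p_lo)) / (2 * eps)
        out[k] = g.reshape(np.shape(v))
    return out


def max_rel_err(analytic, numeric, floor=1e-4):
    """Worst relative deviation; the floor keeps finite-difference noise on
    near-zero entries from masquerading as relative error."""
    worst = 0.0
    for k in analytic:
        a = np.atleast_1d(analytic[k]).ravel()
        n = np.atleast_1d(numeric[k]).ravel()
        worst = max(worst, np.max(np.abs(a - n) / np.maximum(np.abs(n), floor)))
    return worst


class TestTaskLoss:
    def test_zero_residual_gives_zero(self):
        head = constant_head(7.0, 3)
        assert task_loss(head, np.ones((4, 3)), np.full(4, 7.0)) == 0.0

    def test_hand_computed_mean_of_squares(self):
        head = constant_head(0.0, 2)
        # predictions are 0, targets -1 and -2: mean(1 + 4) / 2 = 2.5
        x = np.zeros((2, 2))
        assert task_loss(head, x, np.array([-1.0, -2.0])) == pytest.approx(2.5)

    def test_adding_a_perfect_pair_rescales_by_count(self):
        head = constant_head(1.0, 2)
        x2 = np.zeros((2, 2))
        x3 = np.zeros((3, 2))
        l2 = task_loss(head, x2, np.array([0.0, 0.0]))
        l3 = task_loss(head, x3, np.array([0.0, 0.0, 1.0]))
        assert l3 == pytest.approx(l2 * 2 / 3)

    def test_empty_pairs_raise(self):
        with pytest.raises(ValueError):
            task_loss(constant_head(0.0), np.zeros((0, 1)), np.zeros(0))


class TestInnerUpdate:
    def test_zero_step_returns_identical_parameters(self, rng):
        head = AttentionHead.initialize(4, seed=1)
        out = inner_update(head, rng.normal(size=(3, 4)), rng.normal(size=3), 0.0)
        for k in head.params:
            np.testing.assert_array_equal(out.params[k], head.params[k])

    def test_analytic_scalar_example(self):
        """Constant head theta=1, one target 3, alpha=0.1.

        d/dtheta (theta - 3)^2 = 2(theta - 3) = -4, so theta' = 1.4.
        """
        head = constant_head(1.0)
        out = inner_update(head, np.zeros((1, 1)), np.array([3.0]), 0.1)
        assert float(out.params["b3"]) == pytest.approx(1.4)

    def test_gradient_matches_central_differences(self, rng):
        head = AttentionHead.initialize(5, seed=2)
        x, y = rng.normal(size=(6, 5)), rng.normal(size=6)
        analytic = loss_gradient(head, x, y)
        numeric = numeric_gradient(
            lambda p: task_loss(AttentionHead(p, 5), x, y), head.params
        )
        assert max_rel_err(analytic, numeric) < 1e-4

    def test_input_head_is_not_mutated(self, rng):
        head = AttentionHead.initialize(3, seed=3)
        before = {k: v.copy() for k, v in head.params.items()}
        inner_update(head, rng.normal(size=(4, 3)), rng.normal(size=4), 0.5)
        for k in before:
            np.testing.assert_array_equal(head.params[k], before[k])


class TestOuterGradient:
    def test_second_order_matches_finite_differences(self, rng):
        """Outer gradient of L_q(theta - a grad L_s(theta)) vs central FD."""
        head = AttentionHead.initialize(5, seed=4)
        task = Task("g", rng.normal(size=(6, 5)), rng.normal(size=6),
                    rng.normal(size=(7, 5)), rng.normal(size=7))
        cfg = MetaConfig(inner_lr=0.05, second_order=True)
        analytic = outer_gradient(head, task, cfg)

        def objective(p):
            h = AttentionHead(p, 5)
            adapted = inner_update(h, task.support_x, task.support_y, cfg.inner_lr)
            return task_loss(adapted, task.query_x, task.query_y)

        numeric = numeric_gradient(objective, head.params)
        assert max_rel_err(analytic, numeric) < 1e-4

    def test_first_order_drops_the_hessian_term(self, rng):
        head = AttentionHead.initialize(4, seed=5)
        task = Task("g", rng.normal(size=(5, 4)), rng.normal(size=5),
                    rng.normal(size=(5, 4)), rng.normal(size=5))
        second = outer_gradient(head, task, MetaConfig(inner_lr=0.1))
        first = outer_gradient(head, task,
                               MetaConfig(inner_lr=0.1, second_order=False))
        adapted = inner_update(head, task.support_x, task.support_y, 0.1)
        gq = loss_gradient(adapted, task.query_x, task.query_y)
        for k in first:
            np.testing.assert_array_equal(first[k], gq[k])
        assert any(not np.allclose(second[k], first[k]) for k in second)


class TestSampleTask:
    def test_support_query_counting(self, rng):
        pool = {"g": (rng.normal(size=(8, 3)), rng.normal(size=8))}
        task = sample_task(pool, k=5, seed=0)
        assert task.support_x.shape == (5, 3)
        assert task.query_x.shape == (3, 3)

    def test_support_and_query_are_disjoint(self, rng):
        x = np.arange(20, dtype=float).reshape(10, 2)
        pool = {"g": (x, np.arange(10, dtype=float))}
        task = sample_task(pool, k=4, seed=1)
        support = set(map(tuple, task.support_x))
        query = set(map(tuple, task.query_x))
        assert not support & query
        assert len(support | query) == 10

    def test_deterministic_for_fixed_seed(self, rng):
        pool = {g: (rng.normal(size=(7, 2)), rng.normal(size=7)) for g in "ab"}
        t1 = sample_task(pool, k=3, seed=9)
        t2 = sample_task(pool, k=3, seed=9)
        assert t1.group_value == t2.group_value
        np.testing.assert_array_equal(t1.support_x, t2.support_x)

    def test_groups_drawn_uniformly_over_1000_seeds(self, rng):
        pool = {g: (rng.normal(size=(6, 2)), rng.normal(size=6)) for g in "ab"}
        picks = sum(sample_task(pool, 2, seed=s).group_value == "a"
                    for s in range(1000))
        assert 400 <= picks <= 600

    def test_too_small_groups_are_excluded_then_error(self, rng):
        small = {"g": (rng.normal(size=(3, 2)), rng.normal(size=3))}
        with pytest.raises(ValueError):
            sample_task(small, k=3, seed=0)


class TestMetaTrain:
    def _pool(self, rng, groups=3, n=50, dim=6):
        pool = {}
        for g in range(groups):
            x = rng.normal(size=(n, dim))
            shift = 3.0 * (g - 1)
            pool[f"g{g}"] = (x, x[:, 0] + shift + 0.1 * rng.normal(size=n))
        return pool

    def test_zero_iterations_returns_seeded_initialization(self, rng):
        pool = self._pool(rng)
        cfg = MetaConfig(meta_iterations=0, seed=5)
        head = meta_train(pool, 6, cfg)
        again = meta_train(pool, 6, cfg)
        for k in head.params:
            np.testing.assert_array_equal(head.params[k], again.params[k])

    def test_trajectory_is_deterministic(self, rng):
        pool = self._pool(rng)
        cfg = MetaConfig(meta_iterations=10, support_size=20, seed=5)
        a = meta_train(pool, 6, cfg)
        b = meta_train(pool, 6, cfg)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_adaptation_improves_held_out_query_loss(self, rng):
        """After meta-training, one inner step lowers held-out query loss.

        Averaged over 5 seeds on shifted-task pools; the signature MAML
        property.
        """
        wins = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            pool = self._pool(r)
            held_x = r.normal(size=(40, 6))
            held_y = held_x[:, 0] + 4.5 + 0.1 * r.normal(size=40)
            cfg = MetaConfig(meta_iterations=200, support_size=20,
                             inner_lr=0.01, seed=seed)
            head = meta_train(pool, 6, cfg)
            adapted = fine_tune(head, held_x[:5], held_y[:5], cfg.inner_lr)
            before = task_loss(head, held_x[5:], held_y[5:])
            after = task_loss(adapted, held_x[5:], held_y[5:])
            wins += after < before
        assert wins >= 4

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            meta_train({}, 4, MetaConfig())

    def test_meta_training_does_not_touch_the_forest(self, small_dataset):
        dataset, _ = small_dataset
        forest = mf.fit_forest(dataset.features, dataset.yields,
                               mf.ForestConfig(m_trees=10, seed=0))
        dump_before = forest.to_json()
        xprime = mf.tree_transform(forest, dataset.features).values
        pool = {g: (xprime[dataset.indices_of_group(g)],
                    dataset.yields[dataset.indices_of_group(g)])
                for g in dataset.group_values()[:3]}
        meta_train(pool, 10, MetaConfig(meta_iterations=5, support_size=5, seed=0))
        assert forest.to_json() == dump_before


class TestFineTuneAndPredict:
    def test_fine_tune_equals_inner_update(self, rng):
        head = AttentionHead.initialize(4, seed=8)
        x, y = rng.normal(size=(5, 4)), rng.normal(size=5)
        a = fine_tune(head, x, y, 0.01)
        b = inner_update(head, x, y, 0.01)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_zero_alpha_fine_tune_is_identity(self, rng):
        head = AttentionHead.initialize(4, seed=8)
        out = fine_tune(head, rng.normal(size=(5, 4)), rng.normal(size=5), 0.0)
        for k in head.params:
            np.testing.assert_array_equal(out.params[k], head.params[k])

    def test_constant_head_predicts_its_bias(self, small_dataset):
        dataset, _ = small_dataset
        forest = mf.fit_forest(dataset.features, dataset.yields,
                               mf.ForestConfig(m_trees=4, seed=1))
        preds = mf.predict(forest, constant_head(42.0, 4), dataset.features[:7])
        np.testing.assert_allclose(preds, 42.0)

    def test_predictions_are_finite_and_clip_respects_bounds(self, small_dataset):
        dataset, _ = small_dataset
        forest = mf.fit_forest(dataset.features, dataset.yields,
                               mf.ForestConfig(m_trees=4, seed=1))
        head = AttentionHead.initialize(4, seed=2)
        raw = mf.predict(forest, head, dataset.features)
        assert np.all(np.isfinite(raw))
        clipped = mf.predict(forest, head, dataset.features, clip=True)
        assert clipped.min() >= 0.0 and clipped.max() <= 100.0


class TestUniformAttentionInit:
    def test_initial_function_is_the_ensemble_mean(self, small_dataset):
        dataset, _ = small_dataset
        forest = mf.fit_forest(dataset.features, dataset.yields,
                               mf.ForestConfig(m_trees=20, seed=3))
        xprime = mf.tree_transform(forest, dataset.features).values
        scaler = Scaler.fit(xprime, dataset.yields)
        head = initialize_uniform_attention(20, seed=0, scaler=scaler)
        pred = scaler.inverse_y(head.forward(scaler.transform_x(xprime)))
        np.testing.assert_allclose(pred, xprime.mean(axis=1), rtol=1e-10)

    def test_adaptation_pair_cancels_at_initialization(self):
        scaler = Scaler.identity(6)
        head = initialize_uniform_attention(6, seed=1, scaler=scaler)
        w3 = head.params["w3"]
        assert w3[2] == -w3[3] and w3[2] > 1.0
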