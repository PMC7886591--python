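"""Convolutional stager: primitive ops, forward oracle, gradients, staging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnnsad import cnn
from cnnsad.cnn import (
    STAGE_ANCHORS,
    CnnParams,
    ConvKernel,
    convolve,
    forward,
    init_params,
    max_pool,
    score_from_posterior,
    stage_from_score,
    train_step,
)
from cnnsad.records import STAGES


class TestConvolve:
    def test_hand_computed_sliding_dot_products(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        kernel = ConvKernel(window_m=2, weights=np.ones((2, 2)), bias=0.0)
        np.testing.assert_allclose(
            convolve(X, kernel, activation="identity"), [2.0, 3.0]
        )

    def test_zero_kernel_zero_bias(self):
        X = np.arange(12.0).reshape(4, 3)
        kernel = ConvKernel(window_m=2, weights=np.zeros((2, 3)), bias=0.0)
        np.testing.assert_array_equal(convolve(X, kernel), np.zeros(3))

    def test_bias_only_constant_map(self):
        X = np.arange(12.0).reshape(4, 3)
        kernel = ConvKernel(window_m=2, weights=np.zeros((2, 3)), bias=5.0)
        np.testing.assert_array_equal(
            convolve(X, kernel, activation="identity"), np.full(3, 5.0)
        )

    def test_matrix_shorter_than_window_rejected(self):
        kernel = ConvKernel(window_m=3, weights=np.zeros((3, 2)), bias=0.0)
        with pytest.raises(ValueError):
            convolve(np.zeros((2, 2)), kernel)


class TestMaxPool:
    def test_examples(self):
        assert max_pool([2.0, 3.0]) == 3.0
        assert max_pool([-1.0, -7.0]) == -1.0
        assert max_pool([4.2]) == 4.2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            max_pool(np.array([]))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30), st.randoms())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_invariance(self, xs, pyrandom):
        shuffled = list(xs)
        pyrandom.shuffle(shuffled)
        assert max_pool(xs) == max_pool(shuffled)


def _loop_oracle_posterior(X, params):
    """Nested-loop reimplementation of conv + pool + dense, no vectorized ops."""
    feats = []
    for kernel in params.kernels:
        m = kernel.window_m
        best = None
        for i in range(X.shape[0] - m + 1):
            s = kernel.bias
            for r in range(m):
                for c in range(X.shape[1]):
                    s += kernel.weights[r][c] * X[i + r][c]
            s = max(s, 0.0)  # relu
            best = s if best is None else max(best, s)
        feats.append(best)
    logits = []
    for j in range(len(params.classes)):
        z = params.fc_bias[j]
        for f_idx, f in enumerate(feats):
            z += f * params.fc_weights[f_idx][j]
        logits.append(z)
    mx = max(logits)
    exps = [np.exp(z - mx) for z in logits]
    total = sum(exps)
    return np.array([e / total for e in exps]), np.array(feats)


class TestForwardOracle:
    def test_matches_nested_loop_oracle_on_random_instances(self):
        """Vectorized forward == brute-force loop implementation, 100 cases."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            params = init_params(
                dim_k=4, classes=STAGES, windows=(2, 3), kernels_per_window=3,
                seed=trial,
            )
            X = rng.normal(size=(6, 4))
            expected_post, expected_feats = _loop_oracle_posterior(X, params)
            features, logits, _ = cnn._batch_cache(X[None], params)
            np.testing.assert_allclose(features[0], expected_feats, atol=1e-6)
            decision = forward(X, params)
            np.testing.assert_allclose(decision.posterior, expected_post, atol=1e-6)

    def test_concentrated_posterior_lands_in_stage_range(self):
        params = init_params(dim_k=4, classes=STAGES, windows=(2,), kernels_per_window=4, seed=0)
        # force a posterior concentrated on stage II via the fc bias
        params.fc_bias = np.array([0.0, 30.0, 0.0, 0.0])
        decision = forward(np.zeros((5, 4)), params)
        assert decision.posterior[1] >= 0.99
        assert decision.stage == "II"
        assert 57 < decision.f_value <= 119


class TestScoreFromPosterior:
    @pytest.mark.parametrize(
        "stage,anchor", [("I", 37.5), ("II", 88.5), ("III", 149.5), ("IV", 240.0)]
    )
    def test_one_hot_hits_anchor(self, stage, anchor):
        p = np.zeros(4)
        p[STAGES.index(stage)] = 1.0
        assert score_from_posterior(p) == anchor

    def test_even_mix_of_first_two_stages(self):
        assert score_from_posterior(np.array([0.5, 0.5, 0.0, 0.0])) == 63.0

    def test_uniform_posterior_is_anchor_mean(self):
        assert score_from_posterior(np.full(4, 0.25)) == pytest.approx(
            np.mean(list(STAGE_ANCHORS.values()))
        )

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            score_from_posterior(np.array([0.5, 0.2, 0.1, 0.1]))


class TestStageFromScore:
    @pytest.mark.parametrize(
        "value,stage",
        [
            (100.0, "II"),
            (200.0, "IV"),
            (10.0, "indeterminate"),
            (18.0, "indeterminate"),
            (18.5, "I"),
            (57.0, "I"),
            (119.0, "II"),
            (180.0, "III"),
            (180.5, "IV"),
        ],
    )
    def test_threshold_mapping(self, value, stage):
        assert stage_from_score(value) == stage

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stage_from_score(-1.0)

    def test_anchor_consistency_with_thresholds(self):
        """Each stage's anchor value maps back to that stage."""
        for stage, anchor in STAGE_ANCHORS.items():
            assert stage_from_score(anchor) == stage


def _flatten(params):
    parts = [params.fc_weights.ravel(), params.fc_bias.ravel()]
    for m in params.window_sizes:
        parts += [params.kernel_weights[m].ravel(), params.kernel_biases[m].ravel()]
    return np.concatenate(parts)


def _unflatten(vec, params):
    out = params.copy()
    i = 0

    def take(shape):
        nonlocal i
        size = int(np.prod(shape))
        block = vec[i : i + size].reshape(shape)
        i += size
        return block

    out.fc_weights = take(params.fc_weights.shape)
    out.fc_bias = take(params.fc_bias.shape)
    for m in params.window_sizes:
        out.kernel_weights[m] = take(params.kernel_weights[m].shape)
        out.kernel_biases[m] = take(params.kernel_biases[m].shape)
    return out


class TestTraining:
    def test_numeric_gradient_check(self):
        """Analytic backprop matches central differences on a 3-class toy."""
        rng = np.random.default_rng(0)
        params = init_params(
            dim_k=3, classes=("a", "b", "c"), windows=(2,), kernels_per_window=2, seed=1
        )
        X = rng.normal(size=(4, 5, 3))
        y = np.array([0, 1, 2, 0])
        lr = 1.0
        stepped, _ = train_step(X, y, params, lr)
        analytic = (_flatten(params) - _flatten(stepped)) / lr
        theta = _flatten(params)
        eps = 1e-6
        numeric = np.empty_like(theta)
        for i in range(len(theta)):
            up, dn = theta.copy(), theta.copy()
            up[i] += eps
            dn[i] -= eps
            numeric[i] = (
                cnn.batch_loss(X, y, _unflatten(up, params))
                - cnn.batch_loss(X, y, _unflatten(dn, params))
            ) / (2 * eps)
        denom = np.maximum(np.abs(numeric), 1e-3)
        assert np.max(np.abs(analytic - numeric) / denom) < 1e-4

    def test_zero_learning_rate_is_identity(self):
        params = init_params(dim_k=3, classes=("a", "b"), windows=(2,), kernels_per_window=2, seed=0)
        X = np.random.default_rng(1).normal(size=(3, 5, 3))
        stepped, _ = train_step(X, np.array([0, 1, 0]), params, 0.0)
        assert np.array_equal(stepped.fc_weights, params.fc_weights)
        assert np.array_equal(stepped.kernel_weights[2], params.kernel_weights[2])

    def test_deterministic_updates(self):
        params = init_params(dim_k=3, classes=("a", "b"), windows=(2,), kernels_per_window=2, seed=0)
        X = np.random.default_rng(2).normal(size=(4, 5, 3))
        y = np.array([0, 1, 0, 1])
        p1, l1 = train_step(X, y, params, 0.1)
        p2, l2 = train_step(X, y, params, 0.1)
        assert l1 == l2
        assert np.array_equal(p1.fc_weights, p2.fc_weights)

    def test_converges_on_separable_toy(self):
        """Loss < 0.1 within 200 steps on two linearly separable records."""
        rng = np.random.default_rng(3)
        X = np.stack([np.full((5, 3), 1.0), np.full((5, 3), -1.0)])
        X += 0.01 * rng.normal(size=X.shape)
        y = np.array([0, 1])
        params = init_params(dim_k=3, classes=("a", "b"), windows=(2,), kernels_per_window=4, seed=4)
        loss = np.inf
        for _ in range(200):
            params, loss = train_step(X, y, params, 0.3)
        assert loss < 0.1

    def test_empty_batch_rejected(self):
        params = init_params(dim_k=3, classes=("a", "b"), windows=(2,), kernels_per_window=2, seed=0)
        with pytest.raises(ValueError):
            train_step(np.zeros((0, 5, 3)), np.array([], dtype=int), params, 0.1)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        params = init_params(dim_k=4, classes=STAGES, windows=(2, 3), kernels_per_window=2, seed=5)
        path = tmp_path / "head.json"
        cnn.save_checkpoint(params, path, seed=5)
        back, meta = cnn.load_checkpoint(path)
        assert back.classes == params.classes
        np.testing.assert_allclose(back.fc_weights, params.fc_weights)
        np.testing.assert_allclose(back.kernel_weights[3], params.kernel_weights[3])
        assert meta["seed"] == 5

    def test_feature_length_invariant_enforced(self):
        with pytest.raises(ValueError, match="kernel count"):
            CnnParams(
                window_sizes=(2,),
                kernel_weights={2: np.zeros((3, 2, 4))},
                kernel_biases={2: np.zeros(3)},
                fc_weights=np.zeros((5, 2)),  # wrong: 3 kernels -> 3 features
                fc_bias=np.zeros(2),
                classes=("a", "b"),
            )
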