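"""Dynamic-sampling loop: initialization, draws, updates, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnnsad import cnn, sampler
from cnnsad.sampler import (
    LoopConfig,
    SamplingState,
    draw_balanced,
    init_probs,
    run_loop,
    update_probs,
)


def _state(n_pos, n_neg, size):
    pos = np.arange(n_pos)
    neg = np.arange(n_pos, n_pos + n_neg)
    return init_probs((pos, neg), size)


class TestInitProbs:
    def test_minimal_case_forces_probability_one(self):
        state = _state(1, 1, size=2)
        np.testing.assert_allclose(state.rho, [1.0, 1.0])

    def test_direct_substitution(self):
        state = _state(100, 900, size=64)
        assert state.rho[0] == pytest.approx(0.32)
        assert state.rho[-1] == pytest.approx(64 / 1800)  # 0.03555...

    def test_small_minority_exceeds_one(self):
        state = _state(4, 996, size=64)
        assert state.rho[0] == pytest.approx(8.0)

    def test_class_sums_exact(self):
        state = _state(7, 493, size=64)
        assert state.pos_sum == pytest.approx(32.0, abs=1e-9)
        assert state.neg_sum == pytest.approx(32.0, abs=1e-9)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            init_probs((np.array([], dtype=int), np.arange(5)), 4)

    def test_config_requires_even_size(self):
        with pytest.raises(ValueError):
            LoopConfig(size=63)


class TestDrawBalanced:
    def test_probability_one_always_included_once(self):
        state = _state(1, 1, size=2)  # both rho exactly 1
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert sorted(draw_balanced(state, rng)) == [0, 1]

    def test_probability_zero_never_included(self):
        state = _state(2, 2, size=4)
        state.rho[1] = 0.0
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert 1 not in draw_balanced(state, rng)

    def test_integer_rho_gives_deterministic_copies(self):
        state = _state(2, 2, size=8)  # positives rho = 2.0
        rng = np.random.default_rng(0)
        drawn = draw_balanced(state, rng)
        assert np.sum(drawn == 0) == 2

    def test_moments_match_binomial_oracle(self):
        """Mean drawn size and positives within 3 sd over 10,000 draws."""
        state = _state(100, 900, size=64)
        rng = np.random.default_rng(1)
        n_draws = 10_000
        totals = np.empty(n_draws)
        positives = np.empty(n_draws)
        for i in range(n_draws):
            drawn = draw_balanced(state, rng)
            totals[i] = len(drawn)
            positives[i] = np.sum(drawn < 100)
        var_pos = np.sum(state.rho[:100] * (1 - state.rho[:100]))
        var_neg = np.sum(state.rho[100:] * (1 - state.rho[100:]))
        sd_total = np.sqrt((var_pos + var_neg) / n_draws)
        sd_pos = np.sqrt(var_pos / n_draws)
        assert abs(totals.mean() - 64.0) <= 3 * sd_total
        assert abs(positives.mean() - 32.0) <= 3 * sd_pos

    def test_requires_rng(self):
        with pytest.raises(ValueError):
            draw_balanced(_state(1, 1, 2), None)


class TestUpdateProbs:
    def test_confident_positive_unchanged_before_renormalization(self):
        state = _state(2, 2, size=4)
        P = np.array([1.0, 1.0, 0.0, 0.0])  # perfect classification
        new = update_probs(state, P)
        # multipliers are exp(0)=1 for all, so renormalization is also identity
        np.testing.assert_allclose(new.rho, state.rho)
        assert new.h_pos == pytest.approx(state.pos_sum)

    def test_misclassified_positive_multiplier(self):
        state = _state(1, 1, size=2)
        new = update_probs(state, np.array([0.2, 0.0]))
        # single positive: renormalization cancels the multiplier, but the
        # pre-normalization class sum records exp(0.8) * rho
        assert new.h_pos == pytest.approx(np.exp(0.8) * 1.0)

    def test_hand_renormalization(self):
        pos = np.array([0, 1])
        neg = np.array([2, 3])
        state = SamplingState(
            rho=np.array([2.0, 6.0, 2.0, 2.0]), pos_index=pos, neg_index=neg, size=8
        )
        new = update_probs(state, np.array([1.0, 1.0, 0.0, 0.0]))
        np.testing.assert_allclose(new.rho[:2], [1.0, 3.0])
        assert new.pos_sum == pytest.approx(4.0)

    def test_rejects_out_of_range_posteriors(self):
        state = _state(2, 2, size=4)
        with pytest.raises(ValueError):
            update_probs(state, np.array([0.5, 1.2, 0.5, 0.5]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_posterior(self, seed):
        """Lower P => weakly larger updated rho among positives; the reverse
        among negatives."""
        rng = np.random.default_rng(seed)
        state = _state(10, 30, size=8)
        P = rng.random(40)
        new = update_probs(state, P)
        # positives: rho decreasing in P; negatives: rho increasing in P
        for idx_set, sign in ((state.pos_index, -1), (state.neg_index, 1)):
            order = np.argsort(sign * P[idx_set])  # worst-classified first
            rho_sorted = new.rho[idx_set][order]
            assert np.all(np.diff(rho_sorted) >= -1e-12)


@pytest.fixture(scope="module")
def small_task(request):
    corpus = request.getfixturevalue("corpus200")
    X = request.getfixturevalue("encoded200")
    stages = np.array([r.stage for r in corpus])
    return X, stages == "III"


class TestRunLoop:
    def test_conservation_every_iteration(self, small_task):
        X, is_pos = small_task
        config = LoopConfig(size=16, iterations=20, seed=0)
        params = cnn.init_params(
            dim_k=8, classes=("III", "rest"), kernels_per_window=4, seed=0
        )
        _, history, state = run_loop(X, is_pos, config, params)
        assert len(history) == 20
        for row in history:
            assert row["pos_rho_sum"] == pytest.approx(8.0, abs=1e-9)
            assert row["neg_rho_sum"] == pytest.approx(8.0, abs=1e-9)

    def test_deterministic_given_seed(self, small_task):
        X, is_pos = small_task
        config = LoopConfig(size=16, iterations=3, seed=5)
        params = cnn.init_params(
            dim_k=8, classes=("III", "rest"), kernels_per_window=4, seed=0
        )
        p1, h1, _ = run_loop(X, is_pos, config, params.copy())
        p2, h2, _ = run_loop(X, is_pos, config, params.copy())
        assert np.array_equal(p1.fc_weights, p2.fc_weights)
        assert h1 == h2

    def test_misclassified_positives_gain_sampling_mass(self, small_task):
        """After one update, positives the model gets wrong (P < 0.5) carry
        strictly more sampling probability than confident ones (P > 0.9)."""
        X, is_pos = small_task
        pos_idx = np.flatnonzero(is_pos)
        neg_idx = np.flatnonzero(~is_pos)
        state = init_probs((pos_idx, neg_idx), 16)
        rng = np.random.default_rng(2)
        P = np.where(is_pos, rng.uniform(0.0, 1.0, len(is_pos)), 0.1)
        new = update_probs(state, P)
        wrong = new.rho[pos_idx][P[pos_idx] < 0.5]
        confident = new.rho[pos_idx][P[pos_idx] > 0.9]
        assert wrong.mean() > confident.mean()

    def test_history_export(self, small_task, tmp_path):
        X, is_pos = small_task
        config = LoopConfig(size=16, iterations=2, seed=0)
        params = cnn.init_params(
            dim_k=8, classes=("III", "rest"), kernels_per_window=2, seed=0
        )
        _, history, _ = run_loop(X, is_pos, config, params)
        out = tmp_path / "history.tsv"
        sampler.history_to_tsv(history, out)
        header = out.read_text().splitlines()[0].split("\t")
        assert "pos_rho_sum" in header and "drawn_pos" in header
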