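"""SDSAE internals: corruption, sparsity penalty, gradients, training dynamics."""

import numpy as np
import pytest

from pairdx import sdsae
from pairdx.sdsae import (
    DSAELayer,
    TrainConfig,
    build_stack,
    corrupt,
    encode,
    finetune,
    kl_sparsity,
    layer_loss_and_grads,
    stack_forward,
    stack_loss_and_grads,
    stratified_split,
)

from conftest import max_rel_err, numeric_gradient


class TestCorrupt:
    def test_q_zero_identity(self):
        rng = np.random.default_rng(0)
        X = rng.random((5, 8))
        assert np.array_equal(corrupt(X, 0.0, rng), X)

    def test_q_one_all_zero(self):
        rng = np.random.default_rng(0)
        X = rng.random((5, 8)) + 1.0
        assert not corrupt(X, 1.0, rng).any()

    def test_exact_masking_count(self):
        """Exactly floor(q*d) coordinates zeroed per sample."""
        rng = np.random.default_rng(1)
        X = np.ones((50, 10_000))
        out = corrupt(X, 0.5, rng)
        zero_frac = (out == 0).mean(axis=1)
        assert np.all(zero_frac == 0.5)
        out3 = corrupt(np.ones((4, 10)), 0.37, rng)
        assert np.all((out3 == 0).sum(axis=1) == 3)  # floor(0.37*10)

    def test_masks_differ_per_sample(self):
        rng = np.random.default_rng(2)
        out = corrupt(np.ones((20, 100)), 0.5, rng)
        assert len({tuple(row) for row in (out == 0)}) > 1

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError, match="q"):
            corrupt(np.ones((2, 4)), 1.5, np.random.default_rng(0))


class TestKLSparsity:
    def test_zero_at_target(self):
        assert kl_sparsity(0.1, np.full(20, 0.1)) == 0.0

    def test_direct_two_term_evaluation(self):
        # 0.1*log(0.1/0.5) + 0.9*log(0.9/0.5)
        assert kl_sparsity(0.1, np.array([0.5])) == pytest.approx(0.368064, abs=1e-6)

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            rho_hat = rng.uniform(1e-4, 1 - 1e-4, size=5)
            assert kl_sparsity(0.1, rho_hat) >= 0.0

    def test_strictly_positive_off_target(self):
        assert kl_sparsity(0.1, np.array([0.1, 0.100001])) > 0.0

    def test_clamps_extremes(self):
        assert np.isfinite(kl_sparsity(0.1, np.array([0.0, 1.0])))


class TestGradients:
    @pytest.mark.parametrize("recon", ["bce", "mse"])
    def test_layer_gradients_match_finite_differences(self, recon):
        """Analytic gradients of every DSAE parameter block vs central differences."""
        rng = np.random.default_rng(4)
        X = (rng.random((6, 4)) > 0.5).astype(float)
        layer = DSAELayer(input_dim=4, hidden_dim=3).initialize(rng)
        Xc = corrupt(X, 0.5, rng)
        params = layer.params()
        _, grads = layer_loss_and_grads(params, X, Xc, rho=0.1, beta=0.7, recon_loss=recon)
        for name, arr in params.items():
            g_num = numeric_gradient(
                lambda: layer_loss_and_grads(params, X, Xc, rho=0.1, beta=0.7, recon_loss=recon)[0],
                arr,
            )
            assert max_rel_err(g_num, grads[name]) < 1e-5, name

    def test_stack_gradients_match_finite_differences(self):
        """Fine-tuning gradients for all layers and the softmax head."""
        rng = np.random.default_rng(5)
        X = (rng.random((8, 6)) > 0.5).astype(float)
        y = np.array([0, 1] * 4)
        params = [
            (sdsae.glorot_uniform(rng, 6, 4), rng.normal(0, 0.1, 4)),
            (sdsae.glorot_uniform(rng, 4, 3), rng.normal(0, 0.1, 3)),
            (sdsae.glorot_uniform(rng, 3, 2), rng.normal(0, 0.1, 2)),
        ]
        _, grads = stack_loss_and_grads(params, X, y)
        for k, (W, b) in enumerate(params):
            for arr, g in ((W, grads[k][0]), (b, grads[k][1])):
                g_num = numeric_gradient(lambda: stack_loss_and_grads(params, X, y)[0], arr)
                assert max_rel_err(g_num, g) < 1e-5, f"block {k}"


class TestPretrain:
    def _data(self, n=64, d=12, seed=6):
        rng = np.random.default_rng(seed)
        return (rng.random((n, d)) > 0.5).astype(float)

    def test_loss_trace_decreases_in_moving_average(self):
        X = self._data()
        layer = DSAELayer(input_dim=12, hidden_dim=5)
        sdsae.pretrain_layer(X, layer, TrainConfig(epochs_pretrain=40), np.random.default_rng(0))
        trace = np.array(layer.loss_trace)
        ma = np.convolve(trace, np.ones(10) / 10, mode="valid")
        assert ma[-1] <= ma[0]

    def test_plain_autoencoder_special_case(self):
        """q=0, beta=0 reduces to a plain autoencoder that fits the data."""
        X = self._data()
        layer = DSAELayer(input_dim=12, hidden_dim=8, q=0.0, beta=0.0)
        sdsae.pretrain_layer(X, layer, TrainConfig(epochs_pretrain=50), np.random.default_rng(0))
        assert layer.loss_trace[-1] < layer.loss_trace[0]

    def test_capacity_sanity_reconstruction_near_zero(self):
        """With hidden = input width, no corruption/sparsity, MSE recon -> ~0."""
        rng = np.random.default_rng(7)
        X = (rng.random((40, 6)) > 0.5).astype(float)
        layer = DSAELayer(input_dim=6, hidden_dim=6, q=0.0, beta=0.0, recon_loss="mse")
        sdsae.pretrain_layer(
            X, layer, TrainConfig(epochs_pretrain=3000, learning_rate=1.0), np.random.default_rng(1)
        )
        assert layer.loss_trace[-1] < 0.02 * layer.loss_trace[0]

    def test_width_mismatch_rejected(self):
        layer = DSAELayer(input_dim=5, hidden_dim=3)
        with pytest.raises(ValueError, match="input_dim"):
            sdsae.pretrain_layer(self._data(d=12), layer, TrainConfig(), np.random.default_rng(0))


class TestBuildStack:
    def test_each_stage_yields_twenty_units(self):
        rng = np.random.default_rng(8)
        X = (rng.random((80, 60)) > 0.5).astype(float)
        layers = build_stack(X, TrainConfig(epochs_pretrain=3))
        rep = X
        for layer in layers:
            rep = layer.encode(rep)
            assert rep.shape == (80, 20)

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        X = (rng.random((50, 30)) > 0.5).astype(float)
        l1 = build_stack(X, TrainConfig(epochs_pretrain=3, seed=11))
        l2 = build_stack(X, TrainConfig(epochs_pretrain=3, seed=11))
        for a, b in zip(l1, l2):
            assert np.array_equal(a.W_enc, b.W_enc)
            assert np.array_equal(a.b_dec, b.b_dec)

    def test_wrong_width_into_deeper_layer_rejected(self):
        rng = np.random.default_rng(10)
        X = (rng.random((30, 10)) > 0.5).astype(float)
        layers = build_stack(X, TrainConfig(epochs_pretrain=2), hidden_dims=(5, 4))
        with pytest.raises(ValueError, match="width"):
            layers[1].encode(X)  # layer 2 expects width 5


class TestFinetune:
    def _separable(self, n=200, seed=12):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < 0.6).astype(int)
        X = np.column_stack([y] * 4 + [(rng.random(n) > 0.5).astype(int)] * 8).astype(float)
        return X, y

    def test_validation_size_is_rounded_fraction(self):
        X, y = self._separable(n=103)
        layers = build_stack(X, TrainConfig(epochs_pretrain=2), hidden_dims=(6, 6))
        _, log = finetune(layers, X, y, TrainConfig(epochs_pretrain=2, epochs_finetune=3))
        assert log["n_val"] == round(0.2 * 103)

    def test_probabilities_sum_to_one(self):
        X, y = self._separable()
        layers = build_stack(X, TrainConfig(epochs_pretrain=2), hidden_dims=(6,))
        params, _ = finetune(layers, X, y, TrainConfig(epochs_finetune=5))
        probs = stack_forward(params, X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_overfits_small_separable_fixture(self):
        X, y = self._separable(n=20)
        layers = build_stack(X, TrainConfig(epochs_pretrain=5), hidden_dims=(6, 6))
        params, _ = finetune(
            layers, X, y, TrainConfig(epochs_finetune=400, patience=400, learning_rate=0.5)
        )
        calls = (stack_forward(params, X)[:, 1] >= 0.5).astype(int)
        assert np.array_equal(calls, y)

    def test_single_class_rejected(self):
        X = np.ones((10, 4))
        layers = build_stack(X, TrainConfig(epochs_pretrain=1), hidden_dims=(3,))
        with pytest.raises(ValueError, match="class"):
            finetune(layers, X, np.ones(10, dtype=int), TrainConfig())

    def test_early_stopping_restores_best(self):
        X, y = self._separable()
        layers = build_stack(X, TrainConfig(epochs_pretrain=2), hidden_dims=(6,))
        params, log = finetune(layers, X, y, TrainConfig(epochs_finetune=100, patience=5))
        assert log["best_val_loss"] == min(log["val_loss"])


class TestStratifiedSplit:
    def test_both_classes_in_both_parts(self):
        y = np.array([1] * 86 + [0] * 14)
        tr, va = stratified_split(y, 0.2, np.random.default_rng(0))
        assert len(va) == 20
        assert set(np.unique(y[tr])) == {0, 1}
        assert set(np.unique(y[va])) == {0, 1}
        assert len(np.intersect1d(tr, va)) == 0
        assert len(tr) + len(va) == 100
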