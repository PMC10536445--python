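"""Attention correctness, encoder equivariance and full-model contracts."""

import numpy as np
import pytest

from spo2former import (
    ModelConfig,
    build_model,
    load_model,
    predict_per_second,
    save_model,
    scaled_dot_product_attention,
)
from spo2former.nn import Tensor
from spo2former.train import PredictionError
from spo2former.transformer import ConfigurationError, EncoderLayer, MultiHeadAttention


class TestScaledDotProductAttention:
    def test_single_timestep_passes_value_through(self):
        out, w = scaled_dot_product_attention([[1.0, 2.0]], [[3.0, 1.0]], [[5.0, 7.0]])
        assert np.allclose(w, [[1.0]]) and np.allclose(out, [[5.0, 7.0]])

    def test_identical_keys_average_values(self, rng):
        K = np.tile(rng.normal(size=(1, 4)), (5, 1))
        Q = rng.normal(size=(3, 4))
        V = rng.normal(size=(5, 2))
        out, w = scaled_dot_product_attention(Q, K, V)
        assert np.allclose(w, 1 / 5)
        assert np.allclose(out, np.tile(V.mean(axis=0), (3, 1)))

    def test_hand_derived_two_by_two_example(self):
        out, w = scaled_dot_product_attention(np.eye(2), np.eye(2), [[1.0, 2.0], [3.0, 4.0]])
        expected = np.array([[1.6604, 2.6604], [2.3396, 3.3396]])
        assert np.allclose(out, expected, atol=1e-4)

    def test_rows_stochastic_and_output_in_value_envelope(self, rng):
        for _ in range(100):
            t_q, t_k, d = rng.integers(1, 8, size=3)
            Q, K = rng.normal(size=(t_q, d)), rng.normal(size=(t_k, d))
            V = rng.normal(size=(t_k, 3))
            out, w = scaled_dot_product_attention(Q, K, V)
            assert (w >= 0).all()
            assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)
            assert (out >= V.min(axis=0) - 1e-9).all() and (out <= V.max(axis=0) + 1e-9).all()

    def test_softmax_shift_invariance(self, rng):
        Q = rng.normal(size=(4, 3))
        K = rng.normal(size=(4, 3))
        V = rng.normal(size=(4, 2))
        out1, w1 = scaled_dot_product_attention(Q, K, V)
        # adding a constant vector to every query shifts each logit row uniformly
        out2, w2 = scaled_dot_product_attention(Q + 10.0 * K.mean(axis=0), K, V)
        logits1 = Q @ K.T
        logits2 = (Q + 10.0 * K.mean(axis=0)) @ K.T
        rowshift = logits2 - logits1
        if np.allclose(rowshift, rowshift[:, :1]):  # uniform per row
            assert np.allclose(w1, w2, atol=1e-9)

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            scaled_dot_product_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            scaled_dot_product_attention(np.zeros((2, 3)), np.zeros((4, 3)), np.zeros((2, 2)))


class TestMultiHeadAttention:
    def test_single_head_identity_projections_reduce_to_attention(self, rng):
        mha = MultiHeadAttention(4, 1, rng)
        for lin in (mha.wq, mha.wk, mha.wv, mha.wo):
            lin.weight.data = np.eye(4)
            lin.bias.data[...] = 0.0
        x = rng.normal(size=(1, 5, 4))
        out = mha(Tensor(x)).data[0]
        ref, _ = scaled_dot_product_attention(x[0], x[0], x[0])
        assert np.allclose(out, ref)

    def test_zero_output_projection_zeroes_result(self, rng):
        mha = MultiHeadAttention(8, 2, rng)
        mha.wo.weight.data[...] = 0.0
        mha.wo.bias.data[...] = 0.0
        out = mha(Tensor(rng.normal(size=(2, 6, 8)))).data
        assert np.array_equal(out, np.zeros_like(out))

    def test_shape_contract_and_divisibility(self, rng):
        assert mha_shape(rng, 3, 7, 8, 4) == (3, 7, 8)
        with pytest.raises(ConfigurationError):
            MultiHeadAttention(6, 4, rng)


def mha_shape(rng, b, t, d, h):
    return MultiHeadAttention(d, h, rng)(Tensor(rng.normal(size=(b, t, d)))).data.shape


class TestEncoderLayer:
    def test_shape_and_determinism_without_dropout(self, rng):
        layer = EncoderLayer(ModelConfig(dropout_rate=0.0, sequence_length=10), rng)
        layer.eval()
        x = rng.normal(size=(2, 10, 32))
        a = layer(Tensor(x)).data
        b = layer(Tensor(x)).data
        assert a.shape == x.shape and np.array_equal(a, b)

    def test_permutation_equivariance_of_single_layer(self, rng):
        layer = EncoderLayer(ModelConfig(dropout_rate=0.0, sequence_length=12), rng).eval()
        x = rng.normal(size=(1, 12, 32))
        perm = rng.permutation(12)
        out = layer(Tensor(x)).data
        out_p = layer(Tensor(x[:, perm])).data
        assert np.allclose(out[:, perm], out_p, atol=1e-5)


class TestFullModel:
    def test_batch_shape_and_probability_range(self, rng):
        model = build_model(ModelConfig(sequence_length=120), seed=0)
        p = model.predict_proba(rng.random((32, 120)))
        assert p.shape == (32, 120)
        assert (p > 0).all() and (p < 1).all()

    def test_same_seed_same_initial_parameters(self):
        cfg = ModelConfig(sequence_length=20)
        a, b = build_model(cfg, seed=3), build_model(cfg, seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    @pytest.mark.parametrize("pe", ["none", "constant", "sinusoidal"])
    def test_parameter_count_independent_of_sequence_length(self, pe):
        n20 = build_model(ModelConfig(sequence_length=20, pe=pe), 0).n_parameters()
        n120 = build_model(ModelConfig(sequence_length=120, pe=pe), 0).n_parameters()
        assert n20 == n120

    def test_no_pe_model_is_permutation_equivariant(self, rng):
        model = build_model(ModelConfig(sequence_length=16, pe="none", dropout_rate=0.0), 1).eval()
        x = rng.random((2, 16))
        perm = rng.permutation(16)
        assert np.allclose(model.predict_proba(x)[:, perm], model.predict_proba(x[:, perm]), atol=1e-5)

    @pytest.mark.parametrize("pe", ["constant", "sinusoidal"])
    def test_positional_encoding_breaks_equivariance(self, rng, pe):
        model = build_model(ModelConfig(sequence_length=16, pe=pe, dropout_rate=0.0), 1).eval()
        x = rng.random((2, 16))
        perm = rng.permutation(16)
        assert np.abs(model.predict_proba(x)[:, perm] - model.predict_proba(x[:, perm])).max() > 1e-5

    def test_learnable_pe_gets_gradient_through_classification_loss(self, rng):
        """Finite-difference check that the classification loss is sensitive
        to CAE weights, i.e. the autoencoder trains end-to-end."""
        from spo2former.nn import bce_with_logits

        model = build_model(
            ModelConfig(
                sequence_length=12, pe="learnable", n_encoder_layers=1,
                d_model=4, n_heads=1, d_ff=8, dropout_rate=0.0,
            ),
            seed=2,
        ).eval()
        x = rng.random((2, 12, 1))
        y = (rng.random((2, 12)) < 0.5).astype(float)

        def loss_value():
            return float(bce_with_logits(model.forward_logits(Tensor(x)), y).data)

        loss = bce_with_logits(model.forward_logits(Tensor(x)), y)
        loss.backward()
        w = model.cae.down[0].weight
        assert w.grad is not None and np.abs(w.grad).max() > 0
        i = np.unravel_index(np.abs(w.grad).argmax(), w.grad.shape)
        eps = 1e-6
        orig = w.data[i]
        w.data[i] = orig + eps
        hi = loss_value()
        w.data[i] = orig - eps
        lo = loss_value()
        w.data[i] = orig
        assert np.isclose((hi - lo) / (2 * eps), w.grad[i], rtol=1e-4, atol=1e-8)

    def test_invalid_configs_raise(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(d_model=30, n_heads=4)
        with pytest.raises(ConfigurationError):
            ModelConfig(pe="fourier")

    def test_segment_head_emits_one_logit_per_window(self, rng):
        model = build_model(ModelConfig(sequence_length=24, head="segment"), 0)
        p = model.predict_proba(rng.random((5, 24)))
        assert p.shape == (5,) and ((p > 0) & (p < 1)).all()

    def test_cae_additive_differs_from_replacement(self, rng):
        x = rng.random((2, 24))
        replace = build_model(ModelConfig(sequence_length=24, pe="learnable"), 7).eval()
        additive = build_model(
            ModelConfig(sequence_length=24, pe="learnable", cae_additive=True), 7
        ).eval()
        # same weights, different wiring of the reconstruction
        assert not np.allclose(replace.predict_proba(x), additive.predict_proba(x))

    def test_save_load_roundtrip(self, tmp_path, rng):
        model = build_model(ModelConfig(sequence_length=24), seed=5)
        x = rng.random((3, 24))
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        assert np.allclose(model.predict_proba(x), back.predict_proba(x))


class TestPredictPerSecond:
    def test_tiling_covers_every_second(self, clean_short_record):
        model = build_model(ModelConfig(sequence_length=120), 0)
        scores = predict_per_second(model, clean_short_record, 120, 120)
        t = len(clean_short_record)
        covered = ~np.isnan(scores)
        assert covered.sum() == (t // 120) * 120
        assert np.isnan(scores[(t // 120) * 120 :]).all()

    def test_deterministic(self, clean_short_record):
        model = build_model(ModelConfig(sequence_length=120), 0)
        a = predict_per_second(model, clean_short_record)
        b = predict_per_second(model, clean_short_record)
        assert np.array_equal(a, b, equal_nan=True)

    def test_overlapping_windows_average(self, clean_short_record):
        """With stride = length/2, interior seconds are the mean of the two
        window scores that cover them (overlap-count bookkeeping)."""
        model = build_model(ModelConfig(sequence_length=120), 0)
        scores = predict_per_second(model, clean_short_record, 120, 60)
        from spo2former.records import window_record

        segs = window_record(clean_short_record, 120, 60)
        per_window = model.predict_proba(np.stack([s.values for s in segs]))
        # second 130 is covered by windows starting at 60 and 120
        expected = 0.5 * (per_window[1][130 - 60] + per_window[2][130 - 120])
        assert np.isclose(scores[130], expected)

    def test_record_shorter_than_window_errors(self, rng):
        from spo2former.records import PatientRecord

        rec = PatientRecord("tiny", 90 + 5 * rng.random(50), np.zeros(50, dtype=int))
        model = build_model(ModelConfig(sequence_length=120), 0)
        with pytest.raises(PredictionError):
            predict_per_second(model, rec)
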