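"""GRU cell, corruption, loss, gradients and training behaviour.

The encoder/decoder are checked against a deliberately naive oracle that
re-evaluates the gate equations scalar by scalar, and the hand-derived
gradients are checked against central finite differences.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ehrdae import dae
from ehrdae.dae import (
    DaeConfig,
    GRUParams,
    NoiseSpec,
    OutputProjection,
    _forward_backward,
    _init_params,
    _pad_batch,
    _param_dict,
    corrupt,
    decode_sequence,
    encode_sequence,
    gru_cell,
    reconstruction_loss,
    train,
)
from ehrdae.io import full_size_schema
from ehrdae.schema import encode_patient


# --------------------------------------------------------------------------
# naive oracle: scalar re-evaluation of the gate equations
# --------------------------------------------------------------------------

def _sig(v):
    return 1.0 / (1.0 + math.exp(-v))


def oracle_cell(x, prev, p):
    """Per-coordinate evaluation of z, r, candidate and the state update."""
    H = p.W_z.shape[0]
    cat = list(prev) + list(x)
    z = [_sig(sum(p.W_z[i][k] * cat[k] for k in range(len(cat)))) for i in range(H)]
    r = [_sig(sum(p.W_r[i][k] * cat[k] for k in range(len(cat)))) for i in range(H)]
    cat_r = [r[i] * prev[i] for i in range(H)] + list(x)
    cand = [math.tanh(sum(p.W[i][k] * cat_r[k] for k in range(len(cat_r)))) for i in range(H)]
    h = [(1 - z[i]) * prev[i] + z[i] * cand[i] for i in range(H)]
    return np.array(h), np.array(z), np.array(r), np.array(cand)


def _zero_params(hidden, inp):
    shape = (hidden, hidden + inp)
    return GRUParams(np.zeros(shape), np.zeros(shape), np.zeros(shape))


def _rand_params(rng, hidden, inp, scale=0.5):
    shape = (hidden, hidden + inp)
    return GRUParams(*(rng.normal(0, scale, shape) for _ in range(3)))


class TestGruCell:
    def test_zero_weights_zero_state(self):
        st_ = gru_cell(np.array([1.0, -2.0]), np.zeros(3), _zero_params(3, 2))
        np.testing.assert_array_equal(st_.z, 0.5)
        np.testing.assert_array_equal(st_.r, 0.5)
        np.testing.assert_array_equal(st_.candidate, 0.0)
        np.testing.assert_array_equal(st_.h, 0.0)

    def test_zero_weights_unit_state_halves(self):
        # h' = (1 - 0.5)*1 + 0.5*0 = 0.5
        st_ = gru_cell(np.array([3.0]), np.array([1.0]), _zero_params(1, 1))
        assert st_.h[0] == pytest.approx(0.5)

    def test_matches_oracle_on_seeded_weights(self, rng):
        p = _rand_params(rng, 2, 3)
        x, prev = rng.normal(size=3), rng.normal(size=2)
        st_ = gru_cell(x, prev, p)
        h, z, r, cand = oracle_cell(x, prev, p)
        np.testing.assert_allclose(st_.h, h, atol=1e-6)
        np.testing.assert_allclose(st_.z, z, atol=1e-6)
        np.testing.assert_allclose(st_.r, r, atol=1e-6)
        np.testing.assert_allclose(st_.candidate, cand, atol=1e-6)

    def test_shape_mismatch_named(self):
        with pytest.raises(ValueError, match="state dim 3"):
            gru_cell(np.zeros(2), np.zeros(3), _zero_params(4, 2))

    @given(
        x=arrays(float, 3, elements=st.floats(-5, 5)),
        prev=arrays(float, 2, elements=st.floats(-5, 5)),
    )
    @settings(max_examples=100)
    def test_gate_ranges(self, x, prev):
        """Gates stay in (0,1), candidates in [-1,1] (strictness holds in
        exact arithmetic; extreme pre-activations saturate in float64, so
        the property is checked away from the saturation regime)."""
        p = _rand_params(np.random.default_rng(0), 2, 3)
        st_ = gru_cell(x, prev, p)
        assert np.all(st_.z > 0) and np.all(st_.z < 1)
        assert np.all(st_.r > 0) and np.all(st_.r < 1)
        assert np.all(np.abs(st_.candidate) <= 1)


class TestCorrupt:
    def test_zero_variance_is_identity(self, rng):
        X = rng.integers(0, 2, (4, 6)).astype(float)
        np.testing.assert_array_equal(corrupt(X, NoiseSpec(variance=0.0)), X)

    def test_moments_match_configuration(self):
        X = np.zeros((200, 500))
        Xc = corrupt(X, NoiseSpec(mean=0.0, variance=0.1, seed=5))
        assert Xc.mean() == pytest.approx(0.0, abs=0.01)
        assert Xc.var() == pytest.approx(0.1, abs=0.01)

    def test_seed_reproducibility(self):
        X = np.ones((3, 3))
        a = corrupt(X, NoiseSpec(variance=0.1, seed=11))
        b = corrupt(X, NoiseSpec(variance=0.1, seed=11))
        np.testing.assert_array_equal(a, b)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(variance=-0.1)


class TestEncodeDecode:
    def test_zero_weights_encode_to_zero(self, rng):
        X = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(encode_sequence(X, _zero_params(4, 3)), 0.0)

    def test_single_step_equals_cell(self, rng):
        p = _rand_params(rng, 3, 4)
        x = rng.normal(size=(1, 4))
        np.testing.assert_allclose(
            encode_sequence(x, p), gru_cell(x[0], np.zeros(3), p).h, atol=1e-12
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            encode_sequence(np.zeros((0, 3)), _zero_params(2, 3))

    def test_encoder_matches_stepwise_oracle(self, rng):
        p = _rand_params(rng, 5, 4)
        X = rng.normal(size=(4, 4))
        h = np.zeros(5)
        for t in range(4):
            h, *_ = oracle_cell(X[t], h, p)
        np.testing.assert_allclose(encode_sequence(X, p), h, atol=1e-6)

    def test_decoder_zero_weights_outputs_half(self):
        proj = OutputProjection(P=np.zeros((4, 3)), b=np.zeros(4))
        Y = decode_sequence(np.zeros(3), 2, _zero_params(3, 3), proj)
        np.testing.assert_allclose(Y, 0.5)

    def test_decoder_row_count(self, rng):
        p = _rand_params(rng, 3, 3)
        proj = OutputProjection(P=rng.normal(size=(6, 3)), b=rng.normal(size=6))
        assert decode_sequence(rng.normal(size=3), 4, p, proj).shape == (4, 6)

    def test_decoder_rejects_nonpositive_steps(self):
        proj = OutputProjection(P=np.zeros((2, 2)), b=np.zeros(2))
        with pytest.raises(ValueError):
            decode_sequence(np.zeros(2), 0, _zero_params(2, 2), proj)

    def test_decoder_matches_stepwise_oracle(self, rng):
        D, d = 3, 5
        p = _rand_params(rng, D, D)
        proj = OutputProjection(P=rng.normal(size=(d, D)), b=rng.normal(size=d))
        c = rng.normal(size=D)
        Y = decode_sequence(c, 3, p, proj)
        s = np.zeros(D)
        for t in range(3):
            s, *_ = oracle_cell(c, s, p)
            y = 1.0 / (1.0 + np.exp(-(proj.P @ s + proj.b)))
            np.testing.assert_allclose(Y[t], y, atol=1e-6)


class TestReconstructionLoss:
    def test_uniform_guess_on_two_dims(self):
        assert reconstruction_loss(
            np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]])
        ) == pytest.approx(2 * math.log(2), abs=1e-9)

    def test_single_entry(self):
        assert reconstruction_loss(
            np.array([[1.0]]), np.array([[0.8]])
        ) == pytest.approx(-math.log(0.8), abs=1e-9)

    def test_perfect_reconstruction_limit(self):
        X = np.array([[1.0, 0.0, 1.0]])
        assert reconstruction_loss(X, np.clip(X, 1e-7, 1 - 1e-7)) < 1e-5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_saturated_output_clamped_finite(self):
        assert np.isfinite(reconstruction_loss(np.array([[1.0]]), np.array([[0.0]])))

    @given(
        X=arrays(float, (2, 3), elements=st.sampled_from([0.0, 1.0])),
        Y=arrays(float, (2, 3), elements=st.floats(0.01, 0.99)),
    )
    def test_non_negative(self, X, Y):
        assert reconstruction_loss(X, Y) >= 0.0


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients agree with central differences on a mixed-length
        batch, for every parameter including biases."""
        d, H = 5, 4
        enc = _init_params(rng, H, d, use_bias=True)
        dec = _init_params(rng, H, H, use_bias=True)
        proj = OutputProjection(P=rng.normal(0, 0.3, (d, H)), b=rng.normal(0, 0.1, d))
        tensors = [rng.integers(0, 2, (n, d)).astype(float) for n in (3, 1, 4)]
        X, mask = _pad_batch(tensors, d)
        Xc = X + rng.normal(0, 0.2, X.shape)
        _, grads = _forward_backward(Xc, X, mask, enc, dec, proj, use_bias=True)
        params = _param_dict(enc, dec, proj, use_bias=True)

        def loss():
            return _forward_backward(Xc, X, mask, enc, dec, proj, use_bias=True)[0]

        eps = 1e-6
        for name, P in params.items():
            flat = P.reshape(-1)
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].reshape(-1)[idx]
                assert ana == pytest.approx(num, abs=1e-6, rel=1e-4), name


class TestTraining:
    def test_memorizes_single_repeated_sequence(self, rng):
        seq = rng.integers(0, 2, (3, 6)).astype(float)
        model = train(
            [seq] * 8,
            DaeConfig(latent_dim=8, noise_variance=0.1, epochs=200,
                      batch_size=8, learning_rate=0.01, seed=0),
        )
        c = encode_sequence(seq, model.encoder)
        Y = decode_sequence(c, 3, model.decoder, model.projection)
        assert np.abs(Y - seq).mean() < 0.1

    def test_epoch_loss_descends_on_cohort(self, trained_small):
        log = trained_small.training_log
        assert log[-1] < log[0]

    def test_same_seed_identical_training_log(self, rng):
        tensors = [rng.integers(0, 2, (n, 5)).astype(float) for n in (2, 3, 1, 4)]
        cfg = DaeConfig(latent_dim=4, epochs=3, seed=7)
        a = train(list(tensors), cfg)
        b = train(list(tensors), cfg)
        assert a.training_log == b.training_log

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], DaeConfig())


class TestDeepFeature:
    def test_default_dimensions_and_layout(self, small_cohort):
        """302 dims at the full study scale: [age, gender, 300-dim latent]."""
        schema = full_size_schema()
        rng = np.random.default_rng(0)
        enc = _init_params(rng, 300, schema.clinical_dim, use_bias=False)
        dec = _init_params(rng, 300, 300, use_bias=False)
        proj = OutputProjection(
            P=np.zeros((schema.clinical_dim, 300)), b=np.zeros(schema.clinical_dim)
        )
        model = dae.TrainedModel(
            encoder=enc, decoder=dec, projection=proj, noise=NoiseSpec(),
            config=DaeConfig(latent_dim=300),
            schema_fingerprint=schema.fingerprint(),
        )
        patient = small_cohort.patients[0]
        # codes absent from the full-size vocabulary are ignored by design;
        # demographics and the latent dimension still determine the layout
        f = dae.deep_feature(patient, model, schema)
        assert f.shape == (302,)
        from ehrdae.schema import normalize_age

        assert f[0] == pytest.approx(normalize_age(patient.age, schema))
        assert f[1] == float(patient.gender)
        X = encode_patient(patient, schema)
        np.testing.assert_array_equal(f[2:], encode_sequence(X, enc))

    def test_schema_mismatch_rejected(self, small_cohort, trained_small):
        with pytest.raises(ValueError, match="schema"):
            dae.deep_feature(small_cohort.patients[0], trained_small, full_size_schema())

    def test_batched_features_match_single(self, small_cohort, small_samples, trained_small):
        F = dae.sample_deep_features(small_samples[:5], trained_small, small_cohort.schema)
        for i, s in enumerate(small_samples[:5]):
            c = encode_sequence(s.tensor, trained_small.encoder)
            np.testing.assert_allclose(F[i, 2:], c, atol=1e-10)


class TestOrderAndRobustness:
    def test_order_reversal_changes_code(self, small_cohort, small_samples, trained_small):
        """> 95% of multi-record patients get a different latent code when
        their record order is reversed (sequence models see order)."""
        multi = [s for s in small_samples if s.prefix_length >= 2][:200]
        changed = 0
        for s in multi:
            a = encode_sequence(s.tensor, trained_small.encoder)
            b = encode_sequence(s.tensor[::-1], trained_small.encoder)
            changed += not np.allclose(a, b, atol=1e-8)
        assert changed / len(multi) > 0.95

    def test_denoising_robustness(self, small_cohort, small_samples, trained_small):
        """Latent codes from clean vs slightly perturbed inputs stay aligned."""
        rng = np.random.default_rng(0)
        sims = []
        for s in small_samples[:100]:
            a = encode_sequence(s.tensor, trained_small.encoder)
            b = encode_sequence(
                s.tensor + rng.normal(0, np.sqrt(0.01), s.tensor.shape),
                trained_small.encoder,
            )
            sims.append(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        assert np.mean(sims) > 0.9


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, trained_small, small_samples):
        path = tmp_path / "model.npz"
        dae.save_model(trained_small, path)
        back = dae.load_model(path)
        assert back.training_log == trained_small.training_log
        assert back.schema_fingerprint == trained_small.schema_fingerprint
        x = small_samples[0].tensor
        np.testing.assert_array_equal(
            encode_sequence(x, back.encoder), encode_sequence(x, trained_small.encoder)
        )
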