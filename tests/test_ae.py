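"""Autoencoder construction, training, inference and serialization."""

import dataclasses

import numpy as np
import pytest

from evlatent import ae as aemod
from evlatent.ae import (AEArchitecture, TrainConfig, build_model, decode, encode,
                         reconstruct, reconstruction_metrics, train)


class TestBuildModel:
    def test_default_layer_widths(self):
        arch = AEArchitecture()
        assert arch.layer_widths == [375, 128, 64, 32, 12, 32, 64, 128, 375]

    def test_parameter_count_closed_form(self):
        arch = AEArchitecture()
        widths = arch.layer_widths
        expected = sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))
        model = build_model(arch, TrainConfig(seed=0))
        actual = sum(W.size for W in model.weights) + sum(b.size for b in model.biases)
        assert arch.n_parameters == expected == actual

    def test_he_normal_scale_and_seeding(self):
        m1 = build_model(seed=7)
        m2 = build_model(seed=7)
        m3 = build_model(seed=8)
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)
        assert not np.array_equal(m1.weights[0], m3.weights[0])
        # first layer std ~ sqrt(2/375)
        assert abs(m1.weights[0].std() - np.sqrt(2 / 375)) < 0.005

    def test_latent_must_be_narrower_than_encoder(self):
        with pytest.raises(ValueError, match="smaller"):
            AEArchitecture(encoder_units=(16, 8), latent_dim=8)


class TestTrain:
    def test_zero_epochs_is_noop(self):
        model = build_model(
            AEArchitecture(input_dim=24, encoder_units=(16, 8), latent_dim=4),
            TrainConfig(seed=0, max_epochs=0))
        w0 = [W.copy() for W in model.weights]
        rng = np.random.default_rng(0)
        train(model, rng.random((10, 24)))
        for a, b in zip(model.weights, w0):
            np.testing.assert_array_equal(a, b)
        assert model.history["train_mae"] == []

    def test_deterministic_under_fixed_seed(self):
        arch = AEArchitecture(input_dim=24, encoder_units=(16, 8), latent_dim=4)
        rng = np.random.default_rng(1)
        X = rng.random((30, 24))
        runs = []
        for _ in range(2):
            m = build_model(arch, TrainConfig(seed=3, max_epochs=40, patience=40))
            train(m, X)
            runs.append(m)
        for a, b in zip(runs[0].weights, runs[1].weights):
            np.testing.assert_array_equal(a, b)
        assert runs[0].history["train_mae"] == runs[1].history["train_mae"]

    def test_overfits_repeated_spectra(self, processed_training):
        """Capacity sanity: with regularization off, the network drives
        training MAE below 0.01 on 20 copies of 5 distinct spectra."""
        base = processed_training.to_numpy()[:5]
        X = np.tile(base, (20, 1))
        model = build_model(train_config=TrainConfig(
            seed=0, learning_rate=1e-3, dropout_rate=0.0, l2_lambda=0.0,
            val_fraction=0.0, patience=800, max_epochs=800))
        train(model, X)
        assert model.history["train_mae"][-1] <= 0.01

    def test_best_so_far_loss_is_monotone(self, tiny_model):
        mae = tiny_model.history["train_mae"]
        best = np.minimum.accumulate(mae)
        assert best[-1] <= best[0]
        assert (np.diff(best) <= 1e-15).all()

    def test_nan_input_rejected(self, tiny_model):
        X = np.full((4, 24), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            train(tiny_model, X)

    def test_l2_shrinks_weight_norm(self, processed_training):
        """100x larger L2 penalty gives a strictly smaller weight norm
        on identical data and seed."""
        norms = []
        for l2 in (1e-4, 1e-2):
            m = build_model(train_config=TrainConfig(
                seed=0, learning_rate=1e-3, dropout_rate=0.0, l2_lambda=l2,
                val_fraction=0.0, patience=150, max_epochs=150))
            train(m, processed_training.to_numpy()[:40])
            norms.append(m.weight_norm)
        assert norms[1] < norms[0]


class TestEncodeDecode:
    def test_unfitted_model_rejected(self):
        model = build_model()
        with pytest.raises(ValueError, match="not fitted"):
            encode(model, np.zeros((1, 375)))

    def test_shapes_and_names(self, tiny_model):
        Z = encode(tiny_model, np.zeros((3, 24)))
        assert Z.shape == (3, 4)
        assert list(Z.columns) == ["F1", "F2", "F3", "F4"]
        assert np.isfinite(Z.to_numpy()).all()

    def test_identical_rows_encode_identically(self, tiny_model):
        row = np.linspace(0, 1, 24)
        Z = encode(tiny_model, np.vstack([row, row]))
        np.testing.assert_array_equal(Z.iloc[0].to_numpy(), Z.iloc[1].to_numpy())

    def test_latent_values_can_be_negative(self, study):
        """The code layer passes negatives through the leaky activation,
        so latent features may have negative means."""
        assert (study.Z_training.to_numpy() < 0).any()

    def test_decode_deterministic_at_origin(self, tiny_model):
        z = np.zeros((1, 4))
        a = decode(tiny_model, z)
        b = decode(tiny_model, z)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (1, 24)

    def test_decode_sensitive_to_each_coordinate(self, tiny_model):
        z = np.zeros((1, 4))
        base = decode(tiny_model, z)
        for j in range(4):
            zp = z.copy()
            zp[0, j] = 0.5
            assert not np.allclose(decode(tiny_model, zp), base)

    def test_wrong_widths_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            encode(tiny_model, np.zeros((2, 7)))
        with pytest.raises(ValueError):
            decode(tiny_model, np.zeros((2, 7)))

    def test_roundtrip_rmse_within_training_regime(self, study):
        rec = reconstruct(study.model, study.X_training)
        report = reconstruction_metrics(study.X_training.to_numpy(), rec)
        assert report.mean_rmse < 0.05  # small on [0, 1]-scaled spectra


class TestReconstructionMetrics:
    def test_identity_gives_zero(self):
        X = np.random.default_rng(0).random((4, 10))
        rep = reconstruction_metrics(X, X)
        assert rep.mean_rmse == 0.0 and np.all(rep.per_sample_rmse == 0)

    def test_closed_form_half_error(self):
        X = np.zeros((1, 10))
        Xh = np.concatenate([np.full(5, 0.1), np.zeros(5)])[None, :]
        rep = reconstruction_metrics(X, Xh)
        np.testing.assert_allclose(rep.per_sample_rmse, [0.1 / np.sqrt(2)])

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(5)
        X, Xh = rng.random((3, 20)), rng.random((3, 20))
        rep = reconstruction_metrics(X, Xh)
        loop = [np.sqrt(np.mean([(X[i, j] - Xh[i, j]) ** 2 for j in range(20)]))
                for i in range(3)]
        np.testing.assert_allclose(rep.per_sample_rmse, loop)
        np.testing.assert_allclose(rep.mean_rmse, np.mean(loop))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            reconstruction_metrics(np.zeros((2, 3)), np.zeros((2, 4)))


def test_reconstruction_beats_mean_baseline(study):
    """The 12-dimensional code captures structure: held-out-style
    reconstruction error is far below the global-mean predictor."""
    A = study.X_training.to_numpy()
    rec = reconstruct(study.model, A)
    ae_rmse = np.sqrt(((A - rec) ** 2).mean())
    mean_rmse = np.sqrt(((A - A.mean(0)) ** 2).mean())
    assert ae_rmse < 0.35 * mean_rmse


def test_serialization_roundtrip(tmp_path, tiny_model):
    path = tmp_path / "model.npz"
    tiny_model.save(path)
    back = aemod.AEModel.load(path)
    X = np.random.default_rng(2).random((5, 24))
    np.testing.assert_array_equal(reconstruct(back, X), reconstruct(tiny_model, X))
    np.testing.assert_array_equal(
        encode(back, X).to_numpy(), encode(tiny_model, X).to_numpy())
    assert back.train_config == tiny_model.train_config
    assert dataclasses.asdict(back.architecture) == dataclasses.asdict(
        tiny_model.architecture)
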