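"""Spectrogram front-end, vector quantization, attention gating, and the
training/inference harness (at tiny smoke scale)."""

import numpy as np
import pytest

from cardiosynth.autodiff import Tensor
from cardiosynth.framework import (GeneratorSpec, TrainConfig, _stft_tensor,
                                   load_checkpoint, reconstruct,
                                   save_checkpoint, stft_spectrogram, train,
                                   vector_quantize)
from cardiosynth.losses import LossWeights
from cardiosynth.nn import AttentionGate1d, AttentionUNet1d, VQVAE1d


class TestSTFT:
    def test_frame_count_and_shape(self):
        spec = stft_spectrogram(np.zeros(512), window_len=128, hop=32)
        assert spec.shape == (1 + (512 - 128) // 32, 65)

    def test_zero_signal_zero_spectrogram(self):
        assert np.all(stft_spectrogram(np.zeros(256)) == 0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            stft_spectrogram(np.zeros(100), window_len=128)

    def test_bin_centre_sine_concentrates_energy(self):
        # Hann analysis of a bin-centre tone: all energy lies in the main
        # lobe (bins k-1, k, k+1), with the centre bin twice the magnitude
        # of its neighbours
        fs, wl = 125.0, 128
        k = 8                                   # bin-centre frequency
        t = np.arange(512) / fs
        sig = np.sin(2 * np.pi * (k * fs / wl) * t)
        spec = stft_spectrogram(sig, wl, 32)
        energy = spec ** 2
        col = energy.sum(axis=0)
        assert np.argmax(col) == k
        lobe = col[k - 1:k + 2].sum() / col.sum()
        assert lobe > 0.99
        assert col[k] / col[k - 1] == pytest.approx(4.0, rel=0.05)

    def test_tensor_stft_matches_numpy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 1, 256))
        out = _stft_tensor(Tensor(x), window_len=128, hop=32).data
        for i in range(2):
            ref = stft_spectrogram(x[i, 0], 128, 32)
            assert np.allclose(out[i], ref, atol=1e-9)


class TestVectorQuantize:
    def test_exact_hit(self):
        cb = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        zq, idx = vector_quantize(np.array([[1.0, 1.0]]), cb)
        assert idx[0] == 1
        assert np.array_equal(zq[0], cb[1])

    def test_tie_breaks_to_lowest_index(self):
        cb = np.array([[0.0], [3.0]])
        _, idx = vector_quantize(np.array([[1.5]]), cb)
        assert idx[0] == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        cb = rng.normal(size=(17, 5))
        ze = rng.normal(size=(40, 5))
        _, idx = vector_quantize(ze, cb)
        for i, z in enumerate(ze):
            dists = [np.sum((z - c) ** 2) for c in cb]
            assert idx[i] == int(np.argmin(dists))

    def test_empty_codebook_raises(self):
        with pytest.raises(ValueError):
            vector_quantize(np.zeros((2, 3)), np.zeros((0, 3)))


class TestAttentionGate:
    def _gate(self):
        return AttentionGate1d(channels=3, gate_channels=3,
                               rng=np.random.default_rng(0))

    def test_saturated_coefficients_identity(self):
        gate = self._gate()
        gate.psi.b.data[:] = 50.0              # sigmoid saturates at 1
        skip = Tensor(np.random.default_rng(1).normal(size=(2, 3, 8)))
        out = gate(skip, Tensor(np.zeros((2, 3, 8))))
        assert np.allclose(out.data, skip.data, atol=1e-6)
        assert np.all(gate.last_coefficients > 0.999)

    def test_zero_gating_gives_constant_map(self):
        gate = self._gate()
        for conv in (gate.wx,):
            conv.w.data[:] = 0.0
        skip = Tensor(np.random.default_rng(2).normal(size=(2, 3, 8)))
        out = gate(skip, Tensor(np.zeros((2, 3, 8))))
        coeff = gate.last_coefficients
        assert np.ptp(coeff) < 1e-12           # constant sigmoid(bias) map
        assert np.allclose(out.data, skip.data * coeff)

    def test_coefficient_map_shape_and_range(self):
        gate = self._gate()
        skip = Tensor(np.random.default_rng(3).normal(size=(4, 3, 16)))
        gating = Tensor(np.random.default_rng(4).normal(size=(4, 3, 16)))
        out = gate(skip, gating)
        assert out.shape == skip.shape
        assert gate.last_coefficients.shape == (4, 1, 16)
        assert np.all((gate.last_coefficients >= 0)
                      & (gate.last_coefficients <= 1))

    def test_misaligned_shapes_raise(self):
        gate = self._gate()
        with pytest.raises(ValueError):
            gate(Tensor(np.zeros((2, 3, 8))), Tensor(np.zeros((2, 3, 4))))


def _toy_data(n=12, window=128, seed=0):
    """Paired toy segments: 'ECG' is a sharpened, shifted copy of 'PPG'."""
    rng = np.random.default_rng(seed)
    t = np.arange(window)
    ppg = np.stack([np.sin(2 * np.pi * (t + rng.integers(0, 40)) / 40.0)
                    for _ in range(n)])
    ecg = np.tanh(3.0 * np.roll(ppg, 5, axis=1))
    return ecg, ppg


SMOKE_SPEC = GeneratorSpec(depth=2, base_channels=4)


class TestTraining:
    def test_loss_decreases_and_deterministic(self):
        ecg, ppg = _toy_data()
        cfg = TrainConfig(epochs=8, batch_size=6, window=128, lr=2e-3,
                          seed=0, generator=SMOKE_SPEC)
        res1 = train(ecg, ppg, cfg)
        res2 = train(ecg, ppg, cfg)
        assert res1.history[-1]["p2e"] < res1.history[0]["p2e"]
        assert res1.history == res2.history        # same seed, same run

    def test_ablation_without_adversarial(self, tmp_path):
        ecg, ppg = _toy_data()
        cfg = TrainConfig(epochs=2, batch_size=6, window=128, lr=1e-3, seed=0,
                          weights=LossWeights(beta=0.0, gamma=0.0),
                          generator=SMOKE_SPEC)
        log = tmp_path / "losses.csv"
        res = train(ecg, ppg, cfg, log_path=str(log))
        assert all(r["l_t"] == 0.0 and r["l_f"] == 0.0 for r in res.history)
        header = log.read_text().splitlines()[0]
        assert header == "step,L_contrast,L_p2p,L_e2e,L_p2e,L_t,L_f,L_total"
        assert len(log.read_text().splitlines()) == 1 + 2 * 2  # 2 batches/epoch

    def test_unpaired_data_rejected(self):
        ecg, ppg = _toy_data()
        with pytest.raises(ValueError):
            train(ecg[:-1], ppg, TrainConfig(window=128))

    def test_vq_generator_trains(self):
        ecg, ppg = _toy_data(n=8)
        cfg = TrainConfig(epochs=3, batch_size=4, window=128, lr=2e-3, seed=1,
                          weights=LossWeights(beta=0.0, gamma=0.0),
                          generator=GeneratorSpec(kind="vqvae", depth=2,
                                                  base_channels=4,
                                                  latent_dim=8,
                                                  codebook_size=16))
        res = train(ecg, ppg, cfg)
        assert res.history[-1]["total"] < res.history[0]["total"]


@pytest.fixture(scope="module")
def trained():
    ecg, ppg = _toy_data(n=16, seed=3)
    cfg = TrainConfig(epochs=15, batch_size=8, window=128, lr=2e-3,
                      seed=0, weights=LossWeights(beta=0.0, gamma=0.0),
                      generator=SMOKE_SPEC)
    return ecg, ppg, train(ecg, ppg, cfg)


class TestReconstruct:
    def test_output_shape_range_determinism(self, trained):
        ecg, ppg, res = trained
        out1 = reconstruct(ppg, res.checkpoint)
        out2 = reconstruct(ppg, res.checkpoint)
        assert out1.shape == ppg.shape
        assert np.all(np.abs(out1) <= 1.0)
        assert np.array_equal(out1, out2)

    def test_beats_untrained_baseline(self, trained):
        ecg, ppg, res = trained
        cfg = res.checkpoint["config"]
        untrained = train(ecg, ppg, TrainConfig(
            epochs=0, batch_size=8, window=128, seed=cfg.seed,
            generator=cfg.generator))
        err_trained = np.sqrt(np.mean(
            (reconstruct(ppg, res.checkpoint) - ecg) ** 2))
        err_untrained = np.sqrt(np.mean(
            (reconstruct(ppg, untrained.checkpoint) - ecg) ** 2))
        assert err_trained < err_untrained

    def test_window_mismatch_raises(self, trained):
        _, _, res = trained
        with pytest.raises(ValueError):
            reconstruct(np.zeros((2, 64)), res.checkpoint)

    def test_inference_uses_only_cross_path(self, trained):
        # encoder of G_P and decoder of G_E only
        from cardiosynth.framework import _models_from_checkpoint
        _, ppg, res = trained
        g_e, g_p, config = _models_from_checkpoint(res.checkpoint)
        zp, skips = g_p.encode(Tensor(ppg[:, None, :]))
        g_e.decode(zp, skips)
        assert g_e.encode_calls == 0
        assert g_p.decode_calls == 0
        assert g_e.decode_calls == 1
        assert g_p.encode_calls == 1

    def test_checkpoint_round_trip(self, trained, tmp_path):
        _, ppg, res = trained
        path = tmp_path / "ckpt.h5"
        save_checkpoint(path, res.checkpoint)
        loaded = load_checkpoint(path)
        assert np.array_equal(reconstruct(ppg, loaded),
                              reconstruct(ppg, res.checkpoint))
        assert loaded["config"] == res.checkpoint["config"]
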