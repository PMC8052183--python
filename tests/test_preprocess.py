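"""Preprocessing chain: re-reference arithmetic, filter responses, epoch
segmentation, ICA recovery/identity, artifact-IC flagging and removal, and
the ±75 µV rejection rule."""

import numpy as np
import pytest
from scipy import signal as sps

from oscipain.core import Epochs, Recording
from oscipain.errors import (
    DecompositionError,
    EmptyResultError,
    LabeledChannelError,
    ParameterError,
)
from oscipain.montage import ALL_CHANNELS, FRONTAL
from oscipain.preprocess import (
    epoch,
    filter_recording,
    flag_artifact_ics,
    ica_decompose,
    preprocess_recording,
    reject_epochs,
    remove_ics,
    rereference,
)
from oscipain.simulate import BLINK_GAINS, CohortSimParams, simulate_subject

from conftest import clean_params


def _recording(data, fs=250.0):
    return Recording("s", list(ALL_CHANNELS[: data.shape[0]]), fs, data)


class TestRereference:
    def test_hand_arithmetic(self):
        data = np.zeros((32, 100))
        channels = list(ALL_CHANNELS)
        data[channels.index("Fz")] = 10.0
        data[channels.index("M1")] = 2.0
        data[channels.index("M2")] = 4.0
        out = rereference(Recording("s", channels, 250.0, data))
        assert len(out.channels) == 30
        assert "M1" not in out.channels and "M2" not in out.channels
        assert np.allclose(out.data[out.channels.index("Fz")], 7.0)  # 10 - (2+4)/2

    def test_zero_mastoids_leave_scalp_unchanged(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((32, 100))
        data[-2:] = 0.0  # M1, M2
        out = rereference(_recording(data))
        assert np.allclose(out.data, data[:30])

    def test_common_mode_is_removed(self):
        s = np.sin(np.linspace(0, 10, 500))
        data = np.tile(s, (32, 1))
        out = rereference(_recording(data))
        assert np.abs(out.data).max() < 1e-12

    def test_missing_mastoid_raises(self):
        rec = Recording("s", list(ALL_CHANNELS[:30]), 250.0, np.zeros((30, 100)))
        with pytest.raises(LabeledChannelError):
            rereference(rec)


class TestFilter:
    fs = 1000.0

    def _tone(self, f0, dur=20.0):
        t = np.arange(0, dur, 1 / self.fs)
        return np.sin(2 * np.pi * f0 * t)

    def _ratio(self, f0):
        sig = self._tone(f0)
        out = filter_recording(Recording("s", ["Cz"], self.fs, sig[None, :])).data[0]
        core = slice(int(2 * self.fs), int(18 * self.fs))
        return np.sqrt(np.mean(out[core] ** 2) / np.mean(sig[core] ** 2))

    def test_notch_kills_fifty_hz(self):
        assert self._ratio(50.0) < 0.1

    @pytest.mark.parametrize("f0", [2.0, 10.0, 40.0, 55.0, 75.0])
    def test_passband_tones_within_one_db(self, f0):
        assert 10 ** (-1 / 20) < self._ratio(f0) < 10 ** (1 / 20)

    @pytest.mark.parametrize("f0", [0.1, 95.0])
    def test_stopband_attenuation_at_least_20_db(self, f0):
        sig = self._tone(f0, dur=60.0)
        out = filter_recording(Recording("s", ["Cz"], self.fs, sig[None, :])).data[0]
        core = slice(int(10 * self.fs), int(50 * self.fs))
        ratio = np.sqrt(np.mean(out[core] ** 2) / np.mean(sig[core] ** 2))
        assert ratio < 10 ** (-20 / 20)

    def test_dc_offset_removed(self):
        sig = np.full(int(10 * self.fs), 100.0)
        out = filter_recording(Recording("s", ["Cz"], self.fs, sig[None, :])).data[0]
        assert abs(out[int(3 * self.fs):int(7 * self.fs)].mean()) < 0.5

    def test_zero_phase_on_symmetric_pulse(self):
        n = int(10 * self.fs)
        sig = np.zeros(n)
        center = n // 2
        pulse = sps.windows.gaussian(int(0.4 * self.fs), std=0.05 * self.fs)
        sig[center - len(pulse) // 2: center - len(pulse) // 2 + len(pulse)] = pulse
        out = filter_recording(Recording("s", ["Cz"], self.fs, sig[None, :])).data[0]
        assert abs(int(np.argmax(out)) - center) <= 1  # no group delay

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ParameterError):
            filter_recording(Recording("s", ["Cz"], 150.0, np.zeros((1, 1000))))


class TestEpoch:
    def test_three_hundred_seconds_gives_sixty_epochs(self):
        rec = Recording("s", ["Cz"], 200.0, np.zeros((1, int(300 * 200))))
        assert epoch(rec).n_epochs == 60

    def test_remainder_discarded(self):
        rec = Recording("s", ["Cz"], 200.0, np.zeros((1, int(12 * 200))))
        eps = epoch(rec)
        assert eps.n_epochs == 2
        assert eps.data.shape[2] == 1000

    def test_too_short_recording_rejected(self):
        rec = Recording("s", ["Cz"], 200.0, np.zeros((1, int(4 * 200))))
        with pytest.raises(ParameterError):
            epoch(rec)


def _epochs_from_matrix(X, fs=200.0, epoch_len_s=5.0):
    n_per = int(epoch_len_s * fs)
    n_ep = X.shape[1] // n_per
    data = X[:, : n_ep * n_per].reshape(X.shape[0], n_ep, n_per).transpose(1, 0, 2)
    return Epochs("s", [f"ch{i}" for i in range(X.shape[0])], fs, epoch_len_s,
                  data, np.ones(n_ep, dtype=bool))


class TestICA:
    def test_planted_supergaussian_sources_recovered(self):
        rng = np.random.default_rng(42)
        fs, n_ch = 100.0, 30
        n = 3000  # 30 one-second epochs: the minimum the precondition allows
        sources = rng.laplace(size=(2, n))  # super-Gaussian
        sources /= sources.std(axis=1, keepdims=True)
        mixing = rng.standard_normal((n_ch, 2))
        X = mixing @ sources + 0.3 * rng.standard_normal((n_ch, n))
        eps = _epochs_from_matrix(X, fs=fs, epoch_len_s=1.0)
        decomp = ica_decompose(eps, seed=1, max_iter=60)
        est = decomp.sources.transpose(1, 0, 2).reshape(n_ch, -1)
        kept = eps.n_epochs * eps.data.shape[2]
        corr = np.abs(np.corrcoef(np.vstack([sources[:, :kept], est]))[:2, 2:])
        assert corr.max(axis=1).min() > 0.95  # each true source matched

    def test_reconstruction_identity_and_determinism(self, blinky_decomposition):
        _, eps, decomp = blinky_decomposition
        recon = (np.einsum("ck,eks->ecs", decomp.mixing, decomp.sources)
                 + decomp.channel_means[None, :, None])
        rel = np.abs(recon - eps.data).max() / np.abs(eps.data).max()
        assert rel < 1e-6
        assert np.allclose(decomp.unmixing @ decomp.mixing, np.eye(30), atol=1e-8)

    def test_same_seed_reproduces_unmixing(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((4, int(200.0 * 25)))
        eps = _epochs_from_matrix(X)
        a = ica_decompose(eps, seed=7)
        b = ica_decompose(eps, seed=7)
        assert np.array_equal(a.unmixing, b.unmixing)

    def test_rank_deficient_data_rejected(self):
        X = np.zeros((3, int(200.0 * 20)))
        X[0] = np.random.default_rng(0).standard_normal(X.shape[1])
        X[1] = 2 * X[0]
        X[2] = -X[0]
        with pytest.raises(DecompositionError, match="rank"):
            ica_decompose(_epochs_from_matrix(X), seed=0)

    def test_too_few_epochs_rejected(self):
        X = np.random.default_rng(0).standard_normal((30, int(200.0 * 20)))
        with pytest.raises(ParameterError):
            ica_decompose(_epochs_from_matrix(X), seed=0)  # 4 epochs < 30 channels


class TestArtifactFlagging:
    def test_blink_component_is_flagged(self, blinky_decomposition):
        rec, eps, decomp = blinky_decomposition
        flags = flag_artifact_ics(decomp, eps)
        assert flags, "no components flagged on blink-contaminated data"
        # the component whose topography best matches the blink gain pattern
        gains = BLINK_GAINS[:30] / np.linalg.norm(BLINK_GAINS[:30])
        topo_match = [
            abs(np.dot(decomp.mixing[:, j] / np.linalg.norm(decomp.mixing[:, j]), gains))
            for j in range(decomp.n_components)
        ]
        assert int(np.argmax(topo_match)) in flags

    def test_clean_oscillatory_data_keeps_components(self):
        params = clean_params(duration_s=155.0, fs=200.0, seed=31)
        rec, _ = simulate_subject(params, 0.5, 13)
        eps = epoch(filter_recording(rereference(rec)))
        decomp = ica_decompose(eps, seed=2)
        flags = flag_artifact_ics(decomp, eps)
        assert len(flags) <= 1

    def test_all_zero_sources_not_flagged(self, blinky_decomposition):
        _, eps, decomp = blinky_decomposition
        import dataclasses

        silent = dataclasses.replace(
            decomp, sources=np.zeros_like(decomp.sources)
        )
        assert flag_artifact_ics(silent, eps) == []


class TestRemoveICs:
    def test_empty_flags_identity(self, blinky_decomposition):
        _, eps, decomp = blinky_decomposition
        out = remove_ics(eps, decomp, [])
        assert np.abs(out.data - eps.data).max() < 1e-6

    def test_all_flags_annihilate_centered_data(self, blinky_decomposition):
        _, eps, decomp = blinky_decomposition
        out = remove_ics(eps, decomp, list(range(decomp.n_components)))
        residual = out.data - decomp.channel_means[None, :, None]
        assert np.abs(residual).max() < 1e-6 * np.abs(eps.data).max()

    def test_blink_removal_halves_frontal_delta(self, blinky_decomposition):
        _, eps, decomp = blinky_decomposition
        flags = flag_artifact_ics(decomp, eps)
        clean = remove_ics(eps, decomp, flags)
        fi = [eps.channels.index(c) for c in FRONTAL]

        def delta_power(e):
            f, pxx = sps.welch(e.data[:, fi, :], fs=e.fs, nperseg=int(2 * e.fs))
            return pxx[..., (f >= 0.5) & (f <= 4)].mean()

        assert delta_power(clean) < 0.5 * delta_power(eps)

    def test_removal_does_not_increase_power(self, blinky_decomposition):
        _, eps, decomp = blinky_decomposition
        flags = flag_artifact_ics(decomp, eps)
        clean = remove_ics(eps, decomp, flags)
        centered = eps.data - decomp.channel_means[None, :, None]
        cleaned_centered = clean.data - decomp.channel_means[None, :, None]
        assert np.sum(cleaned_centered ** 2) <= np.sum(centered ** 2)

    def test_out_of_range_flag_rejected(self, blinky_decomposition):
        _, eps, decomp = blinky_decomposition
        with pytest.raises(IndexError):
            remove_ics(eps, decomp, [99])


class TestRejectEpochs:
    def _epochs(self, peaks):
        data = np.zeros((len(peaks), 2, 1000))
        for i, p in enumerate(peaks):
            data[i, 0, 100] = p
        return Epochs("s", ["a", "b"], 200.0, 5.0, data,
                      np.ones(len(peaks), dtype=bool))

    def test_strictly_exceeding_is_rejected_at_threshold_kept(self):
        eps, report = reject_epochs(self._epochs([75.1, 75.0, -75.1, 10.0]))
        assert eps.n_epochs == 2
        assert report.prop_epochs_rejected == 0.5

    def test_bounded_epochs_all_kept(self):
        eps, report = reject_epochs(self._epochs([10.0, -10.0, 5.0]))
        assert report.prop_epochs_rejected == 0.0

    def test_idempotent(self):
        eps, _ = reject_epochs(self._epochs([80.0, 10.0, 20.0]))
        again, report = reject_epochs(eps)
        assert np.array_equal(again.data, eps.data)
        assert report.prop_epochs_rejected == 0.0

    def test_all_rejected_raises(self):
        with pytest.raises(EmptyResultError):
            reject_epochs(self._epochs([100.0, 200.0]))

    def test_rejected_proportion_matches_injection_without_ica(self):
        """60 windows, 20% gross-artifact rate → exactly 12/60 rejected when
        nothing else crosses the threshold."""
        params = CohortSimParams(duration_s=300.0, fs=200.0, pink_scale=2.0,
                                 alpha_power=0, beta_power=0, gamma_power=0,
                                 line_noise_amp=0, blink_rate=0.0,
                                 gross_artifact_rate=0.2)
        rec, _ = simulate_subject(params, 0.0, 8)
        eps, report = preprocess_recording(rec, run_ica=False)
        assert report.prop_epochs_rejected == pytest.approx(12 / 60)
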