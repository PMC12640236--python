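import numpy as np
import pytest

from mucoh import montage
from mucoh.containers import EEGRecording
from mucoh.spectral import (mu_band, power_spectrum, preprocess, segment,
                            suppression)


def _raw(data, fs=250.0, labels=None):
    labels = labels or list(montage.RECORDED)
    return EEGRecording(data, fs, labels)


def _zeros_raw(fs=250.0, dur=78.0):
    n = int(dur * fs)
    return _raw(np.zeros((len(montage.RECORDED), n)), fs)


class TestPreprocess:
    def test_missing_mastoids_rejected(self):
        labels = [l for l in montage.RECORDED if l not in montage.MASTOIDS]
        rec = EEGRecording(np.zeros((len(labels), 250 * 78)), 250.0, labels)
        with pytest.raises(ValueError, match="mastoid"):
            preprocess(rec)

    def test_output_rate_channels_window(self):
        pre = preprocess(_zeros_raw())
        assert pre.sample_rate_hz == 90.0
        assert pre.n_samples == 6930
        assert set(pre.channel_labels) == set(montage.SCALP_64)

    def test_dc_offset_removed(self):
        rec = _zeros_raw()
        offs = 50.0 + np.arange(rec.n_channels)[:, None]
        rec.data = rec.data + offs
        pre = preprocess(rec)
        assert np.abs(pre.data).max() < 1e-6 * 50.0

    def test_common_signal_cancelled_by_mastoid_reference(self):
        """A signal added identically to every channel (mastoids included)
        is removed exactly by the mastoid-average re-reference."""
        rng = np.random.default_rng(0)
        n = int(78 * 250)
        base = rng.standard_normal((len(montage.RECORDED), n))
        common = 10 * np.sin(2 * np.pi * 7.0 * np.arange(n) / 250.0)
        pre_a = preprocess(_raw(base.copy()))
        pre_b = preprocess(_raw(base + common))
        assert np.allclose(pre_a.data, pre_b.data, atol=1e-8)

    def test_50hz_attenuated_at_least_20db(self):
        """Line noise on one scalp channel loses >= 20 dB through the
        1-40 Hz chain."""
        rng = np.random.default_rng(1)
        n = int(78 * 250)
        t = np.arange(n) / 250.0
        data = 0.01 * rng.standard_normal((len(montage.RECORDED), n))
        i_c3 = list(montage.RECORDED).index("C3")
        data[i_c3] += 10.0 * np.sin(2 * np.pi * 50.0 * t)
        pre = preprocess(_raw(data))
        out = pre.data[pre.channel_labels.index("C3")]
        p_in = 10.0 ** 2 / 2                  # mean-square of the injected tone
        p_out = np.mean(out ** 2)             # everything that survived
        assert 10 * np.log10(p_in / max(p_out, 1e-30)) > 20

    def test_artifact_hook_applied(self):
        rec = _zeros_raw()
        rec.data += 1.0
        called = {}

        def hook(d):
            called["yes"] = True
            return d * 0.0

        pre = preprocess(rec, artifact_hook=hook)
        assert called and np.allclose(pre.data, 0.0)


class TestSegment:
    def _pre(self, dur_s):
        n = int(dur_s * 90)
        return EEGRecording(np.zeros((3, n)), 90.0, ["C3", "C4", "Cz"])

    def test_77s_gives_77_epochs(self):
        assert segment(self._pre(77.0)).n_epochs == 77

    def test_partial_trailing_discarded(self):
        assert segment(self._pre(1.5)).n_epochs == 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            segment(self._pre(0.9))


class TestPowerSpectrum:
    def test_sine_power_concentrates_at_10hz(self):
        t = np.arange(77 * 90) / 90.0
        data = np.sin(2 * np.pi * 10.0 * t)[None, :]
        spec = power_spectrum(segment(EEGRecording(data, 90.0, ["C3"])))
        # Hann mainlobe on a 1-s epoch is +-1 Hz wide; >90% of the power
        # must sit within one mainlobe of the tone
        band = (spec.freqs_hz >= 9.0) & (spec.freqs_hz <= 11.0)
        total = spec.power[0].sum()
        assert spec.freqs_hz[np.argmax(spec.power[0])] == 10.0
        assert spec.power[0, band].sum() > 0.9 * total

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((1, 900 * 90))
        spec = power_spectrum(segment(EEGRecording(data, 90.0, ["C3"])))
        sel = (spec.freqs_hz >= 5) & (spec.freqs_hz <= 35)
        slope = np.polyfit(np.log(spec.freqs_hz[sel]),
                           np.log(spec.power[0, sel]), 1)[0]
        assert abs(slope) < 0.1

    def test_zero_input_zero_power(self):
        spec = power_spectrum(segment(EEGRecording(np.zeros((2, 900)), 90.0,
                                                   ["C3", "C4"])))
        assert np.all(spec.power == 0)

    def test_single_epoch_rejected(self):
        with pytest.raises(ValueError, match="2 epochs"):
            power_spectrum(segment(EEGRecording(np.zeros((1, 90)), 90.0, ["C3"])))

    def test_grid_is_79_half_hz_bins(self):
        spec = power_spectrum(segment(EEGRecording(np.zeros((1, 900)), 90.0,
                                                   ["C3"])))
        assert len(spec.freqs_hz) == 79
        assert spec.freqs_hz[0] == 1.0 and spec.freqs_hz[-1] == 40.0
        assert np.allclose(np.diff(spec.freqs_hz), 0.5)

    def test_channel_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((4, 900))
        labels = ["C3", "C4", "Cz", "Pz"]
        spec = power_spectrum(segment(EEGRecording(data, 90.0, labels)))
        perm = [2, 0, 3, 1]
        spec_p = power_spectrum(segment(EEGRecording(
            data[perm], 90.0, [labels[i] for i in perm])))
        assert np.allclose(spec_p.power, spec.power[perm])

    def test_power_scales_quadratically(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((1, 900))
        rec = EEGRecording(data, 90.0, ["C3"])
        rec3 = EEGRecording(3.0 * data, 90.0, ["C3"])
        mu1 = mu_band(power_spectrum(segment(rec)))
        mu3 = mu_band(power_spectrum(segment(rec3)))
        assert mu3.value == pytest.approx(9.0 * mu1.value)


class TestMuBand:
    def _spec(self, power_row):
        from mucoh.containers import SpectrumResult, analysis_freq_grid
        grid = analysis_freq_grid()
        return SpectrumResult(power=np.tile(power_row, (2, 1)), freqs_hz=grid,
                              channel_labels=["C3", "C4"], n_epochs=10)

    def test_constant_power(self):
        from mucoh.containers import analysis_freq_grid
        grid = analysis_freq_grid()
        mu = mu_band(self._spec(np.full(len(grid), 2.0)))
        assert np.allclose(mu.value, 2.0)

    def test_power_equal_to_bin_index(self):
        from mucoh.containers import analysis_freq_grid
        grid = analysis_freq_grid()
        idx = np.arange(len(grid), dtype=float)
        mu = mu_band(self._spec(idx))
        mu_bins = np.flatnonzero((grid >= 8.0) & (grid <= 13.0))
        assert len(mu_bins) == 11
        assert np.allclose(mu.value, mu_bins.mean())


class TestSuppression:
    def test_identical_conditions_zero(self):
        from mucoh.containers import MuPower
        a = MuPower(np.array([1.0, 2.0]), ["C3", "C4"], "AO")
        assert np.all(suppression(a, a) == 0)

    def test_channel_mismatch_rejected(self):
        from mucoh.containers import MuPower
        a = MuPower(np.array([1.0]), ["C3"], "AVc")
        b = MuPower(np.array([1.0]), ["C4"], "AO")
        with pytest.raises(ValueError):
            suppression(a, b)

    def test_reduced_mu_rhythm_gives_negative_suppression(self, default_envelope):
        """A 30% weaker intrinsic Mu rhythm under AV shows negative
        suppression indices at central channels in every replicate."""
        from mucoh.synth.eeg import CouplingSpec, gen_eeg

        neg = 0
        n_rep = 5
        for seed in range(n_rep):
            values = {}
            for name, scale in (("AV", 0.7), ("AO", 1.0)):
                spec = CouplingSpec(channel_coupling={}, mu_scale=scale)
                rec, _ = gen_eeg(default_envelope, spec, seed=seed + 50)
                pre = preprocess(rec)
                values[name] = mu_band(power_spectrum(segment(pre)))
            sup = suppression(values["AV"], values["AO"])
            cen = [values["AV"].channel_labels.index(c)
                   for c in montage.CENTRAL_SET]
            neg += np.all(sup[cen] < 0)
        assert neg >= int(np.ceil(0.95 * n_rep))
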