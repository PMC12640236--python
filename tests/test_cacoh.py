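import numpy as np
import pytest

from mucoh.cacoh import average_coherence, ms_coherence, mu_entrainment
from mucoh.containers import (CoherenceSpectrum, EEGRecording, EnvelopeSignal,
                              analysis_freq_grid)


def _env(samples):
    return EnvelopeSignal(samples=samples, sample_rate_hz=90.0)


def _rec(data, labels=None):
    labels = labels or [f"ch{i}" for i in range(data.shape[0])]
    return EEGRecording(data, 90.0, labels)


@pytest.fixture(scope="module")
def noise_env(rng=None):
    g = np.random.default_rng(7)
    return _env(g.standard_normal(6930))


class TestMsCoherence:
    def test_self_coherence_is_one(self, noise_env):
        rec = _rec(noise_env.samples[None, :])
        coh = ms_coherence(rec, noise_env)
        assert np.all(np.abs(coh.coherence - 1.0) < 1e-9)

    def test_rate_mismatch_rejected(self, noise_env):
        rec = EEGRecording(noise_env.samples[None, :], 100.0, ["C3"])
        with pytest.raises(ValueError, match="rate"):
            ms_coherence(rec, noise_env)

    def test_length_mismatch_rejected(self, noise_env):
        rec = _rec(np.zeros((1, 5000)))
        with pytest.raises(ValueError, match="mismatch"):
            ms_coherence(rec, noise_env)

    def test_single_segment_rejected(self, noise_env):
        """One Welch segment makes coherence identically 1: refuse it."""
        short = _env(noise_env.samples[:180])
        rec = _rec(np.random.default_rng(0).standard_normal((1, 180)))
        with pytest.raises(ValueError, match="segment"):
            ms_coherence(rec, short)

    def test_grid_is_analysis_grid(self, noise_env):
        rec = _rec(np.random.default_rng(1).standard_normal((2, 6930)))
        coh = ms_coherence(rec, noise_env)
        assert np.allclose(coh.freqs_hz, analysis_freq_grid())
        assert np.all((coh.coherence >= 0) & (coh.coherence <= 1))

    def test_null_bias_is_one_over_segments(self, noise_env):
        """Independent white noise vs the envelope: mean coherence equals
        the known 1/K Welch bias (non-overlapping segments, K=38)."""
        g = np.random.default_rng(42)
        means = []
        for _ in range(60):
            rec = _rec(g.standard_normal((1, 6930)))
            coh = ms_coherence(rec, noise_env, overlap_frac=0.0)
            assert coh.n_segments == 38
            means.append(coh.coherence.mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 1.0 / 38.0) < 3 * se

    def test_scale_invariance(self, noise_env):
        g = np.random.default_rng(3)
        data = g.standard_normal((2, 6930))
        a = ms_coherence(_rec(data), noise_env)
        b = ms_coherence(_rec(100.0 * data), _env(0.01 * noise_env.samples))
        assert np.allclose(a.coherence, b.coherence, atol=1e-12)

    def test_matches_direct_dft_oracle(self, noise_env):
        """Welch coherence equals a hand-rolled windowed-DFT cross-spectrum
        estimator to 1e-9 (non-overlapping segments)."""
        g = np.random.default_rng(5)
        x = g.standard_normal(6930)
        y = noise_env.samples
        nseg, nper = 38, 180
        win = np.hanning(nper + 1)[:-1]  # periodic Hann, as scipy uses
        Sxx = np.zeros(nper // 2 + 1)
        Syy = np.zeros(nper // 2 + 1)
        Sxy = np.zeros(nper // 2 + 1, complex)
        for k in range(nseg):
            seg_x = x[k * nper:(k + 1) * nper]
            seg_y = y[k * nper:(k + 1) * nper]
            X = np.fft.rfft(win * (seg_x - seg_x.mean()))
            Y = np.fft.rfft(win * (seg_y - seg_y.mean()))
            Sxx += np.abs(X) ** 2
            Syy += np.abs(Y) ** 2
            Sxy += X * np.conj(Y)
        oracle = np.abs(Sxy) ** 2 / (Sxx * Syy)
        freqs = np.fft.rfftfreq(nper, 1 / 90.0)
        grid_mask = (freqs >= 1.0 - 1e-9) & (freqs <= 40.0 + 1e-9)
        coh = ms_coherence(_rec(x[None, :]), noise_env, overlap_frac=0.0)
        assert np.allclose(coh.coherence[0], oracle[grid_mask], atol=1e-9)


class TestMuEntrainment:
    def test_constant_coherence_passthrough(self):
        grid = analysis_freq_grid()
        coh = CoherenceSpectrum(coherence=np.full((3, len(grid)), 0.3),
                                freqs_hz=grid, channel_labels=["a", "b", "c"],
                                n_segments=10)
        assert np.allclose(mu_entrainment(coh).value, 0.3)

    def test_average_coherence_is_mean(self):
        grid = analysis_freq_grid()
        specs = [CoherenceSpectrum(coherence=np.full((1, len(grid)), v),
                                   freqs_hz=grid, channel_labels=["a"],
                                   n_segments=10) for v in (0.2, 0.4)]
        avg = average_coherence(specs)
        assert np.allclose(avg.coherence, 0.3)

    def test_null_entrainment_exchangeable_across_channels(self, noise_env):
        """With zero coupling the Mu-entrainment distribution is the same
        for every channel (two-sample KS between channel pools)."""
        from scipy.stats import ks_2samp

        g = np.random.default_rng(11)
        vals = {0: [], 1: []}
        for _ in range(60):
            rec = _rec(g.standard_normal((2, 6930)))
            ent = mu_entrainment(ms_coherence(rec, noise_env))
            vals[0].append(ent.value[0])
            vals[1].append(ent.value[1])
        assert ks_2samp(vals[0], vals[1]).pvalue > 0.05


def test_coupled_channels_beat_uncoupled(default_envelope):
    """Coupling on Fp1/FC3 raises their Mu entrainment above uncoupled
    channels in (at least) 95% of replicates."""
    from mucoh.spectral import preprocess
    from mucoh.synth.eeg import CouplingSpec, gen_eeg

    spec = CouplingSpec(channel_coupling={"Fp1": 0.8, "FC3": 0.8})
    wins = 0
    n_rep = 12
    for seed in range(n_rep):
        rec, _ = gen_eeg(default_envelope, spec, seed=seed + 200)
        pre = preprocess(rec)
        ent = mu_entrainment(ms_coherence(pre, default_envelope))
        idx = [pre.channel_labels.index(c) for c in ("Fp1", "FC3")]
        rest = np.delete(ent.value, idx)
        wins += ent.value[idx].mean() > rest.mean()
    assert wins >= int(np.ceil(0.95 * n_rep))
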