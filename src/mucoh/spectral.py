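"""EEG preprocessing and Mu-band power.

Preprocessing: mastoid-average re-reference, 1-40 Hz band-pass, resample
to 90 Hz, drop mastoid/EOG channels, keep the first 77 s.  Spectra are
computed on non-overlapping 1-s epochs with a Hann taper, zero-padded to
2 s so the power lands on the 0.5 Hz analysis grid, and averaged across
epochs (and across trials within a condition).
"""

from __future__ import annotations

from fractions import Fraction
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import signal

from . import montage
from .containers import (ANALYSIS_BAND, EEG_RATE, FREQ_STEP, TRIAL_SECONDS,
                         EEGRecording, EpochSet, MuPower, SpectrumResult,
                         analysis_freq_grid, mu_bin_mask)


def preprocess(
    raw: EEGRecording,
    band: tuple[float, float] = ANALYSIS_BAND,
    target_rate: float = EEG_RATE,
    duration_s: float = TRIAL_SECONDS,
    artifact_hook: Callable[[np.ndarray], np.ndarray] | None = None,
) -> EEGRecording:
    """Reference to the mastoid average, band-pass, resample, crop.

    ``artifact_hook`` is an optional in-place stand-in for artifact removal
    (e.g. ICA); the default is the identity, since synthetic data carry no
    blink/cardiac artifacts.
    """
    labels = raw.channel_labels
    missing = [m for m in montage.MASTOIDS if m not in labels]
    if missing:
        raise ValueError(f"mastoid channel(s) missing: {missing}")
    m_idx = [labels.index(m) for m in montage.MASTOIDS]
    mastoid_mean = raw.data[m_idx].mean(axis=0)

    keep = [l for l in labels
            if l not in montage.MASTOIDS and l not in montage.EOG]
    keep_idx = [labels.index(l) for l in keep]
    data = raw.data[keep_idx] - mastoid_mean
    # drop the DC component up front: the 1 Hz high-pass removes it anyway,
    # and the resampler's FIR ripple would otherwise smear a large offset
    data = data - data.mean(axis=-1, keepdims=True)

    if artifact_hook is not None:
        data = artifact_hook(data)

    # polyphase resampling applies the anti-alias low-pass; the 1-40 Hz
    # band-pass then runs at the target rate (same passband, far cheaper)
    if abs(raw.sample_rate_hz - target_rate) > 1e-9:
        frac = Fraction(target_rate / raw.sample_rate_hz).limit_denominator(10000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator,
                                    axis=-1, padtype="line")
    sos = signal.butter(4, band, btype="bandpass", fs=target_rate,
                        output="sos")
    data = signal.sosfiltfilt(sos, data, axis=-1)

    n_out = int(round(duration_s * target_rate))
    if data.shape[1] < n_out:
        raise ValueError(
            f"recording covers {data.shape[1] / target_rate:.2f} s, "
            f"shorter than the {duration_s:.0f} s analysis window"
        )
    data = data[:, :n_out]
    return EEGRecording(
        data=data, sample_rate_hz=float(target_rate), channel_labels=keep,
        reference="mastoid-average", positions=raw.positions,
    )


def segment(eeg: EEGRecording, epoch_len_s: float = 1.0) -> EpochSet:
    """Cut a recording into non-overlapping epochs; trailing partial epoch dropped."""
    spe = int(round(epoch_len_s * eeg.sample_rate_hz))
    n_epochs = eeg.n_samples // spe
    if n_epochs < 1:
        raise ValueError(
            f"epoch of {epoch_len_s} s does not fit into "
            f"{eeg.n_samples / eeg.sample_rate_hz:.2f} s of data"
        )
    cut = eeg.data[:, : n_epochs * spe]
    data = cut.reshape(eeg.n_channels, n_epochs, spe).transpose(1, 0, 2)
    return EpochSet(data=data.copy(), sample_rate_hz=eeg.sample_rate_hz,
                    channel_labels=list(eeg.channel_labels),
                    epoch_len_s=epoch_len_s)


def power_spectrum(epochs: EpochSet | Sequence[EpochSet],
                   condition: str | None = None) -> SpectrumResult:
    """Hann-tapered periodogram per epoch, averaged, on the 0.5 Hz grid.

    Accepts one EpochSet or several (trials of the same condition), which
    are pooled before averaging.  1-s epochs at 90 Hz are zero-padded to
    2 s so the grid step is 0.5 Hz.
    """
    sets = [epochs] if isinstance(epochs, EpochSet) else list(epochs)
    if not sets:
        raise ValueError("no epochs supplied")
    labels = sets[0].channel_labels
    fs = sets[0].sample_rate_hz
    for s in sets[1:]:
        if s.channel_labels != labels or s.sample_rate_hz != fs:
            raise ValueError("epoch sets differ in channels or rate")
    data = np.concatenate([s.data for s in sets], axis=0)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 epochs for a stable spectrum")

    nfft = int(round(fs / FREQ_STEP))  # zero-pad to reach the 0.5 Hz grid
    freqs, pxx = signal.periodogram(
        data, fs=fs, window="hann", nfft=nfft, detrend=False, axis=-1,
        scaling="density",
    )
    power = pxx.mean(axis=0)  # average over epochs -> channels x freqs
    grid = analysis_freq_grid()
    idx = np.searchsorted(freqs, grid - 1e-9)
    if not np.allclose(freqs[idx], grid):
        raise RuntimeError("frequency grid mismatch")
    return SpectrumResult(power=power[:, idx], freqs_hz=grid,
                          channel_labels=list(labels),
                          n_epochs=int(data.shape[0]), condition=condition)


def mu_band(spectrum: SpectrumResult) -> MuPower:
    """Mean power over the 11 Mu-band bins (8.0-13.0 Hz inclusive)."""
    mask = mu_bin_mask(spectrum.freqs_hz)
    if mask.sum() == 0:
        raise ValueError("spectrum grid does not cover the Mu band")
    return MuPower(value=spectrum.power[:, mask].mean(axis=1),
                   channel_labels=list(spectrum.channel_labels),
                   condition=spectrum.condition)


def suppression(cond: MuPower, baseline_ao: MuPower) -> np.ndarray:
    """Per-channel Mu-power difference condition - AO (negative = suppression)."""
    if cond.channel_labels != baseline_ao.channel_labels:
        raise ValueError("channel sets differ between condition and baseline")
    return cond.value - baseline_ao.value
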