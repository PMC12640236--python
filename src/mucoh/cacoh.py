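"""Cerebral-acoustic coherence (CACoh).

Magnitude-squared coherence between every EEG channel and the music
amplitude envelope on the 1-40 Hz grid (0.5 Hz steps), Welch-estimated
with 2-s Hann segments (180 samples at 90 Hz gives the 0.5 Hz grid
natively) and 50% overlap by default.  The Mu entrainment scalar is the
mean coherence over the 8-13 Hz bins.

Coherence per trial is averaged across trials within a condition; trials
are never concatenated, to avoid boundary artifacts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import signal

from .containers import (EEG_RATE, CoherenceSpectrum, EEGRecording,
                         EnvelopeSignal, MuEntrainment, analysis_freq_grid,
                         mu_bin_mask)

SEGMENT_LEN_S = 2.0
OVERLAP_FRAC = 0.5


def _n_segments(n: int, nperseg: int, noverlap: int) -> int:
    step = nperseg - noverlap
    if n < nperseg:
        return 0
    return (n - noverlap) // step


def ms_coherence(
    eeg: EEGRecording,
    env: EnvelopeSignal,
    segment_len_s: float = SEGMENT_LEN_S,
    overlap_frac: float = OVERLAP_FRAC,
    condition: str | None = None,
    music_type: str | None = None,
) -> CoherenceSpectrum:
    """Welch magnitude-squared coherence of each channel with the envelope."""
    if abs(eeg.sample_rate_hz - env.sample_rate_hz) > 1e-9:
        raise ValueError(
            f"sample-rate mismatch: EEG {eeg.sample_rate_hz} Hz vs "
            f"envelope {env.sample_rate_hz} Hz"
        )
    y = np.asarray(env.samples, float)
    if eeg.n_samples != len(y):
        raise ValueError(
            f"length mismatch: EEG {eeg.n_samples} vs envelope {len(y)} samples"
        )
    fs = eeg.sample_rate_hz
    nperseg = int(round(segment_len_s * fs))
    noverlap = int(round(overlap_frac * nperseg))
    n_seg = _n_segments(len(y), nperseg, noverlap)
    if n_seg < 2:
        raise ValueError(
            f"only {n_seg} Welch segment(s); coherence is degenerate below 2"
        )
    freqs, coh = signal.coherence(
        eeg.data, y[np.newaxis, :], fs=fs, window="hann",
        nperseg=nperseg, noverlap=noverlap, detrend="constant",
    )
    grid = analysis_freq_grid()
    idx = np.searchsorted(freqs, grid - 1e-9)
    if not np.allclose(freqs[idx], grid):
        raise ValueError(
            "segment length does not realise the 0.5 Hz analysis grid"
        )
    return CoherenceSpectrum(
        coherence=np.clip(coh[:, idx], 0.0, 1.0), freqs_hz=grid,
        channel_labels=list(eeg.channel_labels), n_segments=n_seg,
        condition=condition, music_type=music_type,
    )


def average_coherence(specs: Sequence[CoherenceSpectrum]) -> CoherenceSpectrum:
    """Average per-trial coherence spectra within a condition."""
    if not specs:
        raise ValueError("no spectra to average")
    labels = specs[0].channel_labels
    for s in specs[1:]:
        if s.channel_labels != labels:
            raise ValueError("channel sets differ across trials")
    coh = np.mean([s.coherence for s in specs], axis=0)
    return CoherenceSpectrum(
        coherence=coh, freqs_hz=specs[0].freqs_hz, channel_labels=list(labels),
        n_segments=specs[0].n_segments, condition=specs[0].condition,
        music_type=specs[0].music_type,
    )


def mu_entrainment(coh: CoherenceSpectrum) -> MuEntrainment:
    """Mean coherence over the 11 Mu-band bins per channel."""
    mask = mu_bin_mask(coh.freqs_hz)
    if mask.sum() == 0:
        raise ValueError("coherence grid does not cover the Mu band")
    return MuEntrainment(value=coh.coherence[:, mask].mean(axis=1),
                         channel_labels=list(coh.channel_labels),
                         condition=coh.condition, music_type=coh.music_type)
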