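"""Music amplitude-envelope extraction.

The acoustic signal is passed through a bank of 16 fourth-order gammatone
filters with geometrically spaced centre frequencies from 100 to 4000 Hz
(ERB bandwidths), each band's amplitude envelope is taken as the magnitude
of the analytic signal, the 16 envelopes are averaged, the average is
resampled to the EEG analysis rate (90 Hz) with polyphase anti-aliasing,
and finally band-limited to 1-40 Hz with a zero-phase Butterworth filter.
Zero-phase filtering throughout keeps the envelope's phase aligned with
the audio, which matters for coherence with the EEG.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import (ANALYSIS_BAND, EEG_RATE, TRIAL_SECONDS,
                         AudioWaveform, EnvelopeSignal)

N_FILTERS = 16
FREQ_LO = 100.0
FREQ_HI = 4000.0


@dataclass
class GammatoneBank:
    """Fourth-order gammatone filterbank (all-pole digital approximation).

    Filters are applied as cascaded second-order sections; the direct
    transfer-function form of an 8-pole filter with poles near the unit
    circle (low centre frequencies) is numerically unreliable.
    """

    centre_freqs_hz: np.ndarray
    sample_rate_hz: float
    order: int = 4
    bandwidth_rule: str = "ERB"
    _sos: list[np.ndarray] | None = None

    @property
    def n_filters(self) -> int:
        return len(self.centre_freqs_hz)

    def filter_coeffs(self) -> list[np.ndarray]:
        if self._sos is None:
            self._sos = []
            for fc in self.centre_freqs_hz:
                b, a = signal.gammatone(fc, "iir", fs=self.sample_rate_hz)
                self._sos.append(signal.tf2sos(b, a))
        return self._sos


def design_bank(sample_rate_hz: float, n_filters: int = N_FILTERS,
                freq_lo: float = FREQ_LO, freq_hi: float = FREQ_HI) -> GammatoneBank:
    """Bank of gammatone filters, centre frequencies geometric from 100 to 4000 Hz."""
    if sample_rate_hz <= 2 * freq_hi:
        raise ValueError(
            f"sample_rate_hz={sample_rate_hz} too low: need > {2 * freq_hi} Hz "
            f"to represent the {freq_hi} Hz band edge"
        )
    centres = np.geomspace(freq_lo, freq_hi, n_filters)
    return GammatoneBank(centre_freqs_hz=centres, sample_rate_hz=float(sample_rate_hz))


def _resample_to(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def extract_envelope(
    audio: AudioWaveform,
    bank: GammatoneBank | None = None,
    target_rate: float = EEG_RATE,
    band: tuple[float, float] | None = ANALYSIS_BAND,
    duration_s: float = TRIAL_SECONDS,
) -> EnvelopeSignal:
    """Extract the band-averaged amplitude envelope of a music excerpt.

    Only the first ``duration_s`` (default 77 s) are analysed; shorter
    audio is rejected.  Stereo input is averaged to mono before filtering.
    Pass ``band=None`` to skip the final band-pass (the raw, positive
    envelope at the target rate — useful for DC-level checks).
    """
    x = np.asarray(audio.samples, dtype=float)
    if x.ndim == 2:  # stereo: channels in columns or rows
        x = x.mean(axis=0 if x.shape[0] in (1, 2) else 1)
    fs = audio.sample_rate_hz
    if len(x) / fs < duration_s - 1e-9:
        raise ValueError(
            f"audio is {len(x) / fs:.2f} s, shorter than the {duration_s:.0f} s "
            "analysis window"
        )
    x = x[: int(round(duration_s * fs))]
    if bank is None:
        bank = design_bank(fs)
    elif abs(bank.sample_rate_hz - fs) > 1e-6:
        raise ValueError("filterbank sample rate does not match the audio")

    acc = np.zeros(len(x))
    for sos in bank.filter_coeffs():
        band_sig = signal.sosfilt(sos, x)
        acc += np.abs(signal.hilbert(band_sig))
    env = acc / bank.n_filters

    env = _resample_to(env, fs, target_rate)
    n_out = int(round(duration_s * target_rate))
    if len(env) < n_out:
        env = np.pad(env, (0, n_out - len(env)), mode="edge")
    env = env[:n_out]

    if band is not None:
        sos = signal.butter(4, band, btype="bandpass", fs=target_rate, output="sos")
        env = signal.sosfiltfilt(sos, env)
    return EnvelopeSignal(
        samples=env, sample_rate_hz=float(target_rate), band_hz=band,
        source_audio_id=audio.audio_id,
    )
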