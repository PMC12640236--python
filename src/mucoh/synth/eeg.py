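"""Synthetic EEG with envelope-entrained Mu-band activity.

Each channel is a sum of independent components, in microvolts:

* 1/f background noise (FFT-shaped, exponent configurable);
* a narrowband 8-13 Hz "alpha" generator weighted towards occipital sites;
* a narrowband 8-13 Hz intrinsic Mu rhythm weighted towards central sites,
  whose amplitude can be scaled per condition (visual-induced suppression);
* on coupled channels, an entrained component: the supplied music
  envelope's own 8-13 Hz band content, scaled by the coupling strength.

The entrained component is phase-locked to the envelope by construction,
so magnitude-squared coherence between the channel and the envelope in the
Mu band grows monotonically with the planted coupling strength and is at
the estimator's chance level when coupling is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .. import montage
from ..containers import EEGRecording, EnvelopeSignal, MU_BAND
from .audio import _rng


@dataclass
class CouplingSpec:
    """Per-trial recipe for envelope-coupled Mu activity and backgrounds."""

    channel_coupling: dict[str, float] = field(default_factory=dict)  # label -> [0, 1]
    band_hz: tuple[float, float] = MU_BAND
    noise_exponent: float = 1.0     # 1/f slope of the background
    noise_scale_uV: float = 10.0    # background RMS per channel
    alpha_amp_uV: float = 4.0       # occipital alpha RMS at weight 1
    mu_amp_uV: float = 3.0          # intrinsic Mu RMS at weight 1
    mu_scale: float = 1.0           # condition factor on the intrinsic Mu rhythm
    coupled_amp_uV: float = 6.0     # entrained component RMS at coupling 1

    def __post_init__(self) -> None:
        for lab, c in self.channel_coupling.items():
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"coupling for {lab} out of [0, 1]: {c}")


def _one_over_f(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                exponent: float) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping (n_ch x n)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs >= 0.5  # flat below 0.5 Hz to avoid the DC singularity
    amp[nz] = freqs[nz] ** (-exponent / 2.0)
    amp[~nz & (freqs > 0)] = 0.5 ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal((n_ch, len(freqs)))
                  + 1j * rng.standard_normal((n_ch, len(freqs))))
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


import functools


@functools.lru_cache(maxsize=32)
def _band_shape(n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Magnitude response of a 4th-order Butterworth bandpass on the rfft grid."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=freqs, fs=fs)
    return np.abs(h)


def _narrowband(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (spectrally shaped), n_ch x n.

    For Gaussian noise, shaping random-phase spectra by the filter's
    magnitude response is statistically equivalent to zero-phase filtering
    white noise, and much cheaper for many channels.  Random numbers are
    drawn only for bins where the response is non-negligible.
    """
    amp = _band_shape(n, float(fs), tuple(band))
    sup = np.flatnonzero(amp > 1e-4 * amp.max())
    spec = np.zeros((n_ch, len(amp)), dtype=complex)
    spec[:, sup] = amp[sup] * (rng.standard_normal((n_ch, len(sup)))
                               + 1j * rng.standard_normal((n_ch, len(sup))))
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _envelope_mu_component(envelope: EnvelopeSignal, fs_out: float,
                           band: tuple[float, float]) -> np.ndarray:
    """Envelope's Mu-band content, resampled to the EEG rate, unit RMS."""
    sos = signal.butter(4, band, btype="bandpass",
                        fs=envelope.sample_rate_hz, output="sos")
    e = signal.sosfiltfilt(sos, np.asarray(envelope.samples, float))
    from fractions import Fraction
    frac = Fraction(fs_out / envelope.sample_rate_hz).limit_denominator(1000)
    e = signal.resample_poly(e, frac.numerator, frac.denominator)
    return e / max(e.std(), 1e-15)


def gen_eeg(
    envelope: EnvelopeSignal | None,
    coupling_spec: CouplingSpec,
    duration_s: float | None = None,
    sample_rate: float = 250.0,
    channels: tuple[str, ...] = montage.RECORDED,
    seed: int = 0,
) -> tuple[EEGRecording, dict]:
    """Generate one raw trial of multichannel EEG.

    Returns the recording (at the raw acquisition rate, reference 'raw')
    and a ground-truth dict (per-channel coupling, condition scales) meant
    for a JSON sidecar — analysis code never reads it.
    """
    unknown = set(coupling_spec.channel_coupling) - set(channels)
    if unknown:
        raise ValueError(f"unknown channel label(s) in coupling: {sorted(unknown)}")
    if duration_s is None:
        if envelope is None:
            raise ValueError("need duration_s when no envelope is given")
        duration_s = envelope.duration_s
    n = int(round(duration_s * sample_rate))

    e_mu = None
    if envelope is not None:
        e_mu = _envelope_mu_component(envelope, sample_rate, coupling_spec.band_hz)
        if len(e_mu) < n:
            e_mu = np.pad(e_mu, (0, n - len(e_mu)))
        e_mu = e_mu[:n]

    n_ch = len(channels)
    rng = _rng(seed, 1)
    is_eog = np.array([lab in montage.EOG for lab in channels])
    is_mastoid = np.array([lab in montage.MASTOIDS for lab in channels])
    is_scalp = ~(is_eog | is_mastoid)

    data = _one_over_f(rng, n_ch, n, sample_rate, coupling_spec.noise_exponent)
    scale = np.where(is_mastoid, 2.0, coupling_spec.noise_scale_uV)
    data *= scale[:, None]
    if is_eog.any():  # slower, larger ocular noise
        data[is_eog] = 20.0 * _one_over_f(rng, int(is_eog.sum()), n,
                                          sample_rate, 1.5)

    w_occ = np.array([montage.channel_weight(l, "occipital") if s else 0.0
                      for l, s in zip(channels, is_scalp)])
    w_cen = np.array([montage.channel_weight(l, "central") if s else 0.0
                      for l, s in zip(channels, is_scalp)])
    # alpha and intrinsic-Mu generators share the band; the sum of the two
    # independent Gaussian components equals one draw with combined scale
    band = coupling_spec.band_hz
    nb_scale = np.sqrt(
        (coupling_spec.alpha_amp_uV * w_occ) ** 2
        + (coupling_spec.mu_amp_uV * coupling_spec.mu_scale * w_cen) ** 2)
    data += nb_scale[:, None] * _narrowband(rng, n_ch, n, sample_rate, band)

    truth_coupling: dict[str, float] = {}
    for i, lab in enumerate(channels):
        if not is_scalp[i]:
            continue
        c = coupling_spec.channel_coupling.get(lab, 0.0)
        if c > 0 and e_mu is not None:
            data[i] += coupling_spec.coupled_amp_uV * c * e_mu
        truth_coupling[lab] = c if e_mu is not None else 0.0

    rec = EEGRecording(
        data=data, sample_rate_hz=float(sample_rate),
        channel_labels=list(channels), reference="raw",
    )
    truth = {
        "coupling": truth_coupling,
        "mu_scale": coupling_spec.mu_scale,
        "alpha_amp_uV": coupling_spec.alpha_amp_uV,
        "seed": int(seed),
    }
    return rec, truth
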