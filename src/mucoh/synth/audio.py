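"""Synthetic music-like audio: amplitude-modulated broadband carriers.

Real stimuli were ~80 s pop excerpts; what the analysis consumes from them
is the slow amplitude envelope, so the generator produces broadband noise
whose amplitude is modulated by a known slow signal.  The true modulator is
retained on the returned waveform as ground truth (never read by analysis
code).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from ..containers import AudioWaveform, TRIAL_SECONDS

#: Default modulator partials (Hz): slow, musically plausible rates.
DEFAULT_MODULATOR_FREQS: tuple[float, ...] = (0.6, 1.3, 2.4, 3.7)

#: Carrier partials: log-spaced across the 100-4000 Hz stimulus band, far
#: enough apart (> 45 Hz) that partial-partial beats fall outside the 1-40 Hz
#: envelope analysis band, so an unmodulated carrier has a near-constant
#: extracted envelope.
N_CARRIER_TONES = 10
CARRIER_NOISE_WEIGHT = 0.25


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def gen_music_audio(
    duration_s: float = 80.0,
    sample_rate: float = 16000.0,
    modulator_freqs: tuple[float, ...] = DEFAULT_MODULATOR_FREQS,
    mod_depth: float = 0.9,
    mod_noise_weight: float = 0.6,
    carrier_noise_weight: float = CARRIER_NOISE_WEIGHT,
    seed: int = 0,
    audio_id: str = "",
) -> AudioWaveform:
    """Generate an RMS-normalised amplitude-modulated broadband carrier.

    The carrier is a multitone complex (log-spaced partials across
    100-4000 Hz with seed-dependent phases) plus a white-noise floor.  The
    modulator is a mixture of slow sinusoids (``modulator_freqs``) and,
    with weight ``mod_noise_weight``, low-pass (<16 Hz) Gaussian noise; the
    noise term gives the envelope genuine content up to the Mu band, as real
    music envelopes have.  Set ``mod_noise_weight=0`` for a purely tonal
    modulator.

    Parameters
    ----------
    duration_s : trial length; must be at least 77 s (the analysed window).
    sample_rate : audio rate in Hz, >= 8000.
    mod_depth : modulation depth in [0, 1).
    """
    if duration_s < TRIAL_SECONDS:
        raise ValueError(
            f"duration_s={duration_s} is shorter than the {TRIAL_SECONDS:.0f} s "
            "analysis window; trials must cover it"
        )
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz (stimulus band is 100-4000 Hz)")
    rng = _rng(seed, 0)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate

    parts = []
    if len(modulator_freqs):
        phases = rng.uniform(0, 2 * np.pi, size=len(modulator_freqs))
        tonal = np.zeros(n)
        for f, ph in zip(modulator_freqs, phases):
            tonal += np.sin(2 * np.pi * f * t + ph)
        tonal /= max(len(modulator_freqs), 1)
        parts.append((1.0, tonal / max(tonal.std(), 1e-12)))
    if mod_noise_weight > 0:
        sos = signal.butter(4, 16.0, btype="low", fs=sample_rate, output="sos")
        slow = signal.sosfiltfilt(sos, rng.standard_normal(n))
        parts.append((mod_noise_weight, slow / max(slow.std(), 1e-12)))

    if parts:
        mix = sum(w * p for w, p in parts)
        mix = mix / max(mix.std(), 1e-12)
        modulator = 1.0 + mod_depth * mix / 3.0  # ~3 sigma within depth
        np.clip(modulator, 0.02, None, out=modulator)
    else:
        modulator = np.ones(n)

    carrier_freqs = np.geomspace(100.0, min(4000.0, 0.45 * sample_rate),
                                 N_CARRIER_TONES)
    carrier_phases = rng.uniform(0, 2 * np.pi, size=N_CARRIER_TONES)
    carrier = np.zeros(n)
    for f, ph in zip(carrier_freqs, carrier_phases):
        carrier += np.sin(2 * np.pi * f * t + ph)
    carrier /= carrier.std()
    if carrier_noise_weight > 0:
        carrier = carrier + carrier_noise_weight * rng.standard_normal(n)
        carrier /= carrier.std()
    wave = modulator * carrier
    wave = wave / np.sqrt(np.mean(wave**2))  # RMS normalise
    return AudioWaveform(
        samples=wave, sample_rate_hz=float(sample_rate),
        modulator=modulator, audio_id=audio_id,
    )
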