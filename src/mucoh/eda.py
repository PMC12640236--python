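"""Skin-conductance analysis: tonic/phasic decomposition, SCR detection,
and condition indices relative to the audio-only baseline.

Traces are decimated to 20 Hz (SCR bandwidth is far below that), split
into a slow tonic trend (zero-phase low-pass, 0.05 Hz default) and a
phasic residual, and phasic events are detected trough-to-peak.  Only
events peaking between 2 s after onset (the typical SCR latency) and the
end of the 77-s analysis window are counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.ndimage import median_filter

from .containers import TRIAL_SECONDS, EDATrace, SCREvent, SCRIndices, SCRSet

DETECTION_RATE = 20.0     # Hz
TONIC_CUTOFF = 0.05       # Hz
MIN_AMPLITUDE = 0.01      # uS
SMOOTH_CUTOFF = 1.0       # Hz, phasic smoothing before peak picking


@dataclass
class Decomposition:
    tonic: np.ndarray
    phasic: np.ndarray
    sample_rate_hz: float
    trial_id: int | None = None


def decompose(trace: EDATrace, tonic_cutoff: float = TONIC_CUTOFF,
              target_rate: float = DETECTION_RATE,
              median_win_s: float = 20.0) -> Decomposition:
    """Split a trace into tonic trend and phasic residual at 20 Hz.

    The tonic estimate is robust to the phasic events themselves: a
    rolling-median trend flags event-dominated samples, which are then
    bridged by interpolation before the zero-phase low-pass (``tonic_cutoff``)
    produces the final trend.  A plain low-pass would absorb a sizeable
    fraction of each SCR into the tonic and create rebound artifacts.
    """
    x = np.asarray(trace.samples, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("EDA trace contains non-finite samples")
    if trace.sample_rate_hz < DETECTION_RATE:
        raise ValueError("EDA sample rate below the 20 Hz detection rate")
    if trace.sample_rate_hz > target_rate:
        frac = Fraction(target_rate / trace.sample_rate_hz).limit_denominator(10000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator,
                                 padtype="line")
        fs = target_rate
    else:
        fs = trace.sample_rate_hz
    med = median_filter(x, size=int(median_win_s * fs) | 1, mode="nearest")
    resid = x - med
    mad = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    mask = resid < max(0.01, 3.0 * mad)      # samples not dominated by events
    t = np.arange(len(x))
    base = np.interp(t, t[mask], x[mask]) if mask.any() else x
    # low-pass around a linear trend so ramps pass through untouched
    # (filtfilt edge transients on a raw ramp would leak into the phasic)
    coef = np.polyfit(t, base, 1)
    trend = np.polyval(coef, t)
    sos = signal.butter(2, tonic_cutoff, btype="low", fs=fs, output="sos")
    tonic = signal.sosfiltfilt(sos, base - trend) + trend
    return Decomposition(tonic=tonic, phasic=x - tonic, sample_rate_hz=fs,
                         trial_id=trace.trial_id)


def detect_scrs(decomp: Decomposition, min_amplitude_uS: float = MIN_AMPLITUDE,
                window_s: tuple[float, float] = (2.0, TRIAL_SECONDS)) -> SCRSet:
    """Trough-to-peak SCR detection on the phasic component.

    Amplitude is peak minus the preceding trough; events whose peak lies
    outside ``window_s`` or whose amplitude is below the threshold are
    discarded.  An empty result is valid.
    """
    fs = decomp.sample_rate_hz
    sos = signal.butter(2, SMOOTH_CUTOFF, btype="low", fs=fs, output="sos")
    ph = signal.sosfiltfilt(sos, decomp.phasic)
    if np.ptp(ph) < min_amplitude_uS:
        return SCRSet(events=[], window_s=window_s)
    peaks, _ = signal.find_peaks(ph, prominence=min_amplitude_uS / 2)
    events: list[SCREvent] = []
    prev_peak = 0
    for pk in peaks:
        seg = ph[prev_peak:pk + 1]
        trough_rel = int(np.argmin(seg))
        trough = prev_peak + trough_rel
        amp = float(ph[pk] - ph[trough])
        peak_t = pk / fs
        onset_t = trough / fs
        prev_peak = pk
        if amp < min_amplitude_uS:
            continue
        if not (window_s[0] <= peak_t <= window_s[1]):
            continue
        events.append(SCREvent(onset_s=onset_t, peak_s=peak_t, amplitude_uS=amp))
    return SCRSet(events=events, window_s=window_s)


def indices(scrs: SCRSet, condition: str,
            ao_baseline: SCRSet | SCRIndices | None = None) -> SCRIndices:
    """SCR count and summed amplitude, optionally relative to the AO cell."""
    out = SCRIndices(count=scrs.count,
                     summed_amplitude_uS=scrs.summed_amplitude_uS,
                     condition=condition)
    if condition in ("AVc", "AVic"):
        if ao_baseline is None:
            raise ValueError(
                f"relative indices for {condition} need the AO baseline")
        if isinstance(ao_baseline, SCRSet):
            ao_baseline = SCRIndices(count=ao_baseline.count,
                                     summed_amplitude_uS=ao_baseline.summed_amplitude_uS,
                                     condition="AO")
        out.relative_count = float(out.count - ao_baseline.count)
        out.relative_amplitude_uS = float(out.summed_amplitude_uS
                                          - ao_baseline.summed_amplitude_uS)
    return out
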