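"""Synthetic electrodermal activity: tonic drift plus Bateman-kernel SCRs.

A single skin-conductance response is modelled as a difference of
exponentials (Bateman kernel) with a rise and a decay time constant; the
kernel is normalised so the planted event amplitude equals the kernel peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..containers import EDATrace
from .audio import _rng

#: Default Bateman time constants (s): peak latency ~2 s after onset.
RISE_TAU = 0.75
DECAY_TAU = 2.0


@dataclass
class SCRPlan:
    """Planted phasic events and tonic behaviour for one trial."""

    event_times: list[float] = field(default_factory=list)      # onsets, s
    event_amplitudes: list[float] = field(default_factory=list)  # uS, > 0
    tonic_level: float = 5.0          # uS
    tonic_drift: float = 0.002        # uS / s
    rise_tau: float = RISE_TAU
    decay_tau: float = DECAY_TAU

    def __post_init__(self) -> None:
        if len(self.event_times) != len(self.event_amplitudes):
            raise ValueError("event_times and event_amplitudes length mismatch")
        times = np.asarray(self.event_times, float)
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if any(a <= 0 for a in self.event_amplitudes):
            raise ValueError("event amplitudes must be positive")
        if not (0 < self.rise_tau < self.decay_tau):
            raise ValueError("require 0 < rise_tau < decay_tau")


def bateman_peak_latency(rise_tau: float = RISE_TAU, decay_tau: float = DECAY_TAU) -> float:
    """Closed-form latency of the Bateman kernel peak after event onset."""
    return (np.log(decay_tau) - np.log(rise_tau)) * rise_tau * decay_tau / (decay_tau - rise_tau)


def bateman_kernel(t: np.ndarray, rise_tau: float = RISE_TAU, decay_tau: float = DECAY_TAU) -> np.ndarray:
    """Unit-peak Bateman kernel evaluated at times ``t`` (s, 0 at onset)."""
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay_tau) - np.exp(-np.maximum(t, 0) / rise_tau), 0.0)
    tpk = bateman_peak_latency(rise_tau, decay_tau)
    peak = np.exp(-tpk / decay_tau) - np.exp(-tpk / rise_tau)
    return k / peak


def gen_eda(
    duration_s: float,
    scr_plan: SCRPlan,
    sample_rate: float = 2000.0,
    noise_sd: float = 0.005,
    seed: int = 0,
    trial_id: int | None = None,
) -> EDATrace:
    """Generate a skin-conductance trace from a plan.

    trace(t) = tonic_level + tonic_drift * t
               + sum_i amp_i * bateman(t - onset_i) + N(0, noise_sd)
    """
    if any(t >= duration_s for t in scr_plan.event_times):
        raise ValueError("event_times must fall within the trial duration")
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    trace = scr_plan.tonic_level + scr_plan.tonic_drift * t
    for onset, amp in zip(scr_plan.event_times, scr_plan.event_amplitudes):
        trace = trace + amp * bateman_kernel(t - onset, scr_plan.rise_tau, scr_plan.decay_tau)
    if noise_sd > 0:
        trace = trace + noise_sd * _rng(seed, 3).standard_normal(n)
    return EDATrace(samples=trace, sample_rate_hz=float(sample_rate), trial_id=trial_id)
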