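"""Shared in-memory containers for the analysis pipeline.

Everything downstream of file I/O works on these small dataclasses rather
than on raw arrays, so that sample rates, channel labels and band
definitions travel with the data instead of being re-asserted at every
call site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: EEG analysis rate (Hz) after preprocessing; everything coherence-related
#: assumes this rate.
EEG_RATE = 90.0
#: Length of the analysed window per trial, in seconds.
TRIAL_SECONDS = 77.0
#: Analysis band and frequency grid.
ANALYSIS_BAND = (1.0, 40.0)
FREQ_STEP = 0.5
#: Mu band (sensorimotor rhythm) used for scalar reductions.
MU_BAND = (8.0, 13.0)

MUSIC_TYPES = ("vocal", "violin")
CONDITIONS = ("AVc", "AVic", "AO", "VO")


def analysis_freq_grid() -> np.ndarray:
    """The 1-40 Hz grid in 0.5 Hz steps (79 bins, both edges inclusive)."""
    lo, hi = ANALYSIS_BAND
    n = int(round((hi - lo) / FREQ_STEP)) + 1
    return lo + FREQ_STEP * np.arange(n)


def mu_bin_mask(freqs: np.ndarray) -> np.ndarray:
    """Boolean mask of the 11 Mu-band bins (8.0-13.0 Hz inclusive)."""
    lo, hi = MU_BAND
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)


@dataclass
class AudioWaveform:
    """Mono audio with the generator's true modulator kept as ground truth."""

    samples: np.ndarray          # float, RMS-normalised
    sample_rate_hz: float
    modulator: np.ndarray | None = None   # same length as samples, or None
    audio_id: str = ""

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass
class EnvelopeSignal:
    """Band-averaged amplitude envelope at the EEG analysis rate."""

    samples: np.ndarray
    sample_rate_hz: float = EEG_RATE
    band_hz: tuple[float, float] | None = ANALYSIS_BAND
    source_audio_id: str = ""

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass
class EEGRecording:
    """Multichannel EEG, channels x samples, in microvolts."""

    data: np.ndarray
    sample_rate_hz: float
    channel_labels: list[str]
    reference: str = "raw"
    positions: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be channels x samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def pick(self, labels: Sequence[str]) -> "EEGRecording":
        idx = [self.channel_labels.index(l) for l in labels]
        return replace(self, data=self.data[idx], channel_labels=list(labels))


@dataclass
class EpochSet:
    """Non-overlapping fixed-length epochs: epochs x channels x samples."""

    data: np.ndarray
    sample_rate_hz: float
    channel_labels: list[str]
    epoch_len_s: float

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclass
class SpectrumResult:
    """Per-channel power spectrum on the analysis grid, averaged over epochs."""

    power: np.ndarray            # channels x freqs, uV^2
    freqs_hz: np.ndarray
    channel_labels: list[str]
    n_epochs: int
    condition: str | None = None


@dataclass
class MuPower:
    """Mu-band (8-13 Hz) mean power per channel."""

    value: np.ndarray            # channels, uV^2
    channel_labels: list[str]
    condition: str | None = None


@dataclass
class CoherenceSpectrum:
    """Magnitude-squared coherence per channel on the analysis grid."""

    coherence: np.ndarray        # channels x freqs, in [0, 1]
    freqs_hz: np.ndarray
    channel_labels: list[str]
    n_segments: int
    condition: str | None = None
    music_type: str | None = None


@dataclass
class MuEntrainment:
    """Mu-band mean coherence per channel (cerebral-acoustic coherence)."""

    value: np.ndarray
    channel_labels: list[str]
    condition: str | None = None
    music_type: str | None = None


@dataclass
class EDATrace:
    """Skin conductance trace in microsiemens."""

    samples: np.ndarray
    sample_rate_hz: float = 2000.0
    trial_id: int | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass
class SCREvent:
    onset_s: float
    peak_s: float
    amplitude_uS: float


@dataclass
class SCRSet:
    """Detected phasic skin-conductance responses within the analysis window."""

    events: list[SCREvent] = field(default_factory=list)
    window_s: tuple[float, float] = (2.0, TRIAL_SECONDS)

    @property
    def count(self) -> int:
        return len(self.events)

    @property
    def summed_amplitude_uS(self) -> float:
        return float(sum(e.amplitude_uS for e in self.events))


@dataclass
class SCRIndices:
    count: int
    summed_amplitude_uS: float
    condition: str | None = None
    relative_count: float | None = None
    relative_amplitude_uS: float | None = None
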