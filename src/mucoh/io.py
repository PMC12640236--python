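"""File-format adapters.

Audio is WAV (float32 or PCM16), EEG is a BrainVision triplet
(.vhdr/.vmrk/.eeg, IEEE float32 multiplexed, written here and read back
through MNE), EDA is a two-column CSV {time_s, eda_uS}, the design table
and envelopes are CSV, and reports/ground truth are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (CONDITIONS, MUSIC_TYPES, AudioWaveform, EDATrace,
                         EEGRecording, EnvelopeSignal)

# -- WAV -------------------------------------------------------------------

def wav_write(path: str | Path, audio: AudioWaveform) -> None:
    from scipy.io import wavfile

    wavfile.write(str(path), int(round(audio.sample_rate_hz)),
                  np.asarray(audio.samples, dtype=np.float32))


def wav_read(path: str | Path, audio_id: str | None = None) -> AudioWaveform:
    from scipy.io import wavfile

    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype == np.int16:
        data = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(float) / 2147483648.0
    else:
        data = data.astype(float)
    if data.ndim == 2:  # stereo: samples x channels on disk
        data = data.T
    return AudioWaveform(samples=data, sample_rate_hz=float(rate),
                         audio_id=audio_id or Path(path).stem)


# -- BrainVision -----------------------------------------------------------

def brainvision_write(rec: EEGRecording, vhdr_path: str | Path) -> None:
    """Write an EEG recording as a BrainVision triplet (IEEE float32, uV)."""
    vhdr = Path(vhdr_path)
    if vhdr.suffix != ".vhdr":
        raise ValueError("BrainVision header path must end in .vhdr")
    stem = vhdr.stem
    eeg_name, vmrk_name = f"{stem}.eeg", f"{stem}.vmrk"
    interval_us = 1e6 / rec.sample_rate_hz
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "", "[Common Infos]", "Codepage=UTF-8",
        f"DataFile={eeg_name}", f"MarkerFile={vmrk_name}",
        "DataFormat=BINARY", "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:.6f}",
        "", "[Binary Infos]", "BinaryFormat=IEEE_FLOAT_32",
        "", "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    (vhdr.parent / vmrk_name).write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg_name}\n\n[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,00000000000000000000\n",
        encoding="utf-8",
    )
    data = np.asarray(rec.data, dtype=np.float32).T  # multiplexed: sample-major
    data.tofile(vhdr.parent / eeg_name)


def eeg_read(path: str | Path) -> EEGRecording:
    """Read a BrainVision triplet (via MNE) into an EEGRecording, in uV."""
    import mne

    path = Path(path)
    if path.suffix != ".vhdr":
        raise ValueError(f"expected a .vhdr header, got {path.name}")
    raw = mne.io.read_raw_brainvision(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(data=data, sample_rate_hz=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names), reference="raw")


# -- EDA / envelope --------------------------------------------------------

def eda_write(trace: EDATrace, path: str | Path) -> None:
    t = np.arange(len(trace.samples)) / trace.sample_rate_hz
    pd.DataFrame({"time_s": t, "eda_uS": trace.samples}).to_csv(path, index=False)


def eda_read(path: str | Path, trial_id: int | None = None) -> EDATrace:
    df = pd.read_csv(path)
    if not {"time_s", "eda_uS"} <= set(df.columns):
        raise ValueError(f"{path}: EDA CSV needs columns time_s, eda_uS")
    dt = np.diff(df.time_s.to_numpy())
    if len(dt) < 1 or np.ptp(dt) > 1e-6:
        raise ValueError(f"{path}: non-uniform or empty time axis")
    return EDATrace(samples=df.eda_uS.to_numpy(float),
                    sample_rate_hz=float(1.0 / dt[0]), trial_id=trial_id)


def envelope_write(env: EnvelopeSignal, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"envelope": env.samples}).to_csv(path, index=False)
    meta = {"sample_rate_hz": env.sample_rate_hz, "band_hz": env.band_hz,
            "source_audio_id": env.source_audio_id}
    path.with_suffix(".json").write_text(json.dumps(meta))


def envelope_read(path: str | Path) -> EnvelopeSignal:
    path = Path(path)
    samples = pd.read_csv(path)["envelope"].to_numpy(float)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    band = meta.get("band_hz")
    return EnvelopeSignal(samples=samples,
                          sample_rate_hz=float(meta.get("sample_rate_hz", 90.0)),
                          band_hz=tuple(band) if band else None,
                          source_audio_id=meta.get("source_audio_id", ""))


# -- design table ----------------------------------------------------------

def validate_design(df: pd.DataFrame) -> None:
    """Check the design-table invariants; raise with a precise message."""
    required = {"trial_id", "subject_id", "music_type", "condition"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"design table missing columns: {sorted(missing_cols)}")
    bad_music = set(df.music_type) - set(MUSIC_TYPES)
    if bad_music:
        raise ValueError(f"unknown music_type values: {sorted(bad_music)}")
    bad_cond = set(df.condition) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition values: {sorted(bad_cond)}")
    for subj, grp in df.groupby("subject_id"):
        cells = set(zip(grp.music_type, grp.condition))
        for m in MUSIC_TYPES:
            for c in CONDITIONS:
                if (m, c) not in cells:
                    raise ValueError(
                        f"subject {subj} is missing the {m} x {c} cell")
    if "familiarity" in df.columns:
        vo_fam = df[(df.condition == "VO") & df.familiarity.notna()]
        if len(vo_fam):
            raise ValueError(
                "VO trials must not carry familiarity ratings "
                f"(subject(s) {sorted(set(vo_fam.subject_id))})")
    if "duration_s" in df.columns and (df.duration_s < 77.0 - 1e-9).any():
        short = df[df.duration_s < 77.0 - 1e-9]
        raise ValueError(
            f"trial(s) shorter than 77 s: {sorted(short.trial_id)[:5]}")


def table_write(df: pd.DataFrame, path: str | Path) -> None:
    validate_design(df)
    df.to_csv(path, index=False)


def table_read(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_design(df)
    return df


def report_write(report: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(report, indent=1, default=default))
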