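"""Full synthetic experiment: audio, EEG, EDA and ratings for every
subject x music-type x condition cell.

The generator mirrors the structure of the audiovisual music study it
emulates: two music types (vocal, violin) crossed with four visual
conditions (AVc, AVic, AO, VO), 77-s analysed trials, ratings on a 0-9
scale, and planted effects:

* envelope-Mu coupling higher under AVc than AVic for vocal music (on a
  frontal electrode set), equal for violin;
* intrinsic Mu rhythm suppressed whenever visual input is present;
* more and larger skin-conductance responses under AVc for vocal music;
* pleasure ratings raised under AVc for vocal music, with the per-subject
  rating benefit tied to that subject's coupling benefit (so that
  mediation has a genuine indirect path to find).

EEG and EDA traces are generated on demand per trial (deterministically
from the master seed) to keep memory bounded; audio, envelopes, ratings
and all ground truth are materialised eagerly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .. import montage
from ..containers import (CONDITIONS, MUSIC_TYPES, TRIAL_SECONDS,
                          AudioWaveform, EDATrace, EEGRecording,
                          EnvelopeSignal)
from ..envelope import extract_envelope
from .audio import _rng, gen_music_audio
from .eda import SCRPlan, gen_eda
from .eeg import CouplingSpec, gen_eeg

RATING_SCALES = ("liking", "pleasure", "arousal", "familiarity")


@dataclass
class CellEffect:
    """Planted parameters for one music_type x condition cell."""

    coupling: float = 0.0          # mean envelope-Mu coupling in [0, 1]
    mu_scale: float = 1.0          # intrinsic Mu rhythm factor (1 = AO level)
    scr_rate: float = 2.0          # expected SCR count per 77-s trial
    ratings: dict[str, float] = field(default_factory=dict)  # scale -> mean


def _default_cells(congruency_effect: bool) -> dict[tuple[str, str], CellEffect]:
    base_ratings = {"liking": 5.0, "pleasure": 5.0, "arousal": 5.0}
    cells: dict[tuple[str, str], CellEffect] = {}
    for music in MUSIC_TYPES:
        fam = 1.0 if music == "vocal" else 2.3
        for cond in CONDITIONS:
            r = dict(base_ratings)
            if cond != "VO":
                r["familiarity"] = fam
            coupling = 0.0 if cond == "VO" else 0.3
            mu_scale = 1.0 if cond == "AO" else 0.7
            scr_rate = 2.0
            if congruency_effect and music == "vocal" and cond == "AVc":
                coupling = 0.6
                scr_rate = 4.0
                r["pleasure"] = 6.0
                r["liking"] = 6.0
            cells[(music, cond)] = CellEffect(coupling=coupling,
                                              mu_scale=mu_scale,
                                              scr_rate=scr_rate, ratings=r)
    return cells


@dataclass
class EffectSpec:
    """Planted effect structure for a whole experiment."""

    cells: dict[tuple[str, str], CellEffect] = field(default_factory=lambda: _default_cells(True))
    coupled_channels: tuple[str, ...] = montage.FRONTAL_SET
    coupling_subject_sd: float = 0.20   # per-subject, per-cell coupling spread
    rating_sd: float = 1.0
    pleasure_coupling_gain: float = 6.0  # rating points per unit coupling deviation
    scr_amp_mean_uS: float = 0.4
    scr_amp_sd_uS: float = 0.15

    @classmethod
    def effect_on(cls) -> "EffectSpec":
        return cls()

    @classmethod
    def effect_off(cls) -> "EffectSpec":
        """Null spec: all conditions share identical distributions."""
        cells = _default_cells(False)
        return cls(cells=cells, pleasure_coupling_gain=0.0)


class ExperimentDataset:
    """Synthetic dataset with lazy per-trial EEG/EDA generation."""

    def __init__(self, design: pd.DataFrame, audio: dict, envelopes: dict,
                 effect: EffectSpec, seed: int, subject_coupling: dict,
                 scr_plans: dict, eeg_rate: float):
        self.design = design
        self.audio = audio
        self.envelopes = envelopes
        self.effect = effect
        self.seed = seed
        self.subject_coupling = subject_coupling   # (subj, music, cond) -> float
        self.scr_plans = scr_plans                 # trial_id -> SCRPlan
        self.eeg_rate = eeg_rate

    # -- per-trial accessors -------------------------------------------------
    def _row(self, trial_id: int) -> pd.Series:
        rows = self.design[self.design.trial_id == trial_id]
        if len(rows) != 1:
            raise KeyError(f"unknown trial_id {trial_id}")
        return rows.iloc[0]

    def envelope_for(self, music_type: str, rep: int) -> EnvelopeSignal:
        return self.envelopes[(music_type, rep)]

    def eeg_trial(self, trial_id: int) -> tuple[EEGRecording, dict]:
        row = self._row(trial_id)
        cell = self.effect.cells[(row.music_type, row.condition)]
        env = None
        coupling: dict[str, float] = {}
        if row.condition != "VO":
            env = self.envelope_for(row.music_type, row.rep)
            c = self.subject_coupling[(row.subject_id, row.music_type, row.condition)]
            coupling = {ch: c for ch in self.effect.coupled_channels}
        spec = CouplingSpec(channel_coupling=coupling, mu_scale=cell.mu_scale)
        rec, truth = gen_eeg(env, spec, duration_s=TRIAL_SECONDS,
                             seed=_trial_seed(self.seed, int(trial_id)),
                             channels=montage.RECORDED)
        truth["trial_id"] = int(trial_id)
        return rec, truth

    def eda_trial(self, trial_id: int) -> EDATrace:
        plan = self.scr_plans[int(trial_id)]
        return gen_eda(TRIAL_SECONDS + 1.0, plan, seed=_trial_seed(self.seed, int(trial_id)),
                       trial_id=int(trial_id))

    # -- persistence ---------------------------------------------------------
    def save(self, outdir: str | Path, write_eeg: bool = False,
             write_eda: bool = True) -> None:
        """Write the dataset using the package's file conventions.

        EEG is optional (BrainVision triplets are large); ground truth goes
        to a JSON sidecar that analysis code never reads.
        """
        from .. import io as mio

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        mio.table_write(self.design, out / "design.csv")
        for (music, rep), au in self.audio.items():
            mio.wav_write(out / f"audio_{music}_{rep}.wav", au)
        for (music, rep), env in self.envelopes.items():
            mio.envelope_write(env, out / f"envelope_{music}_{rep}.csv")
        truth = {
            "subject_coupling": {
                f"{s}|{m}|{c}": v for (s, m, c), v in self.subject_coupling.items()
            },
            "coupled_channels": list(self.effect.coupled_channels),
            "scr_plans": {
                str(tid): {
                    "event_times": list(map(float, p.event_times)),
                    "event_amplitudes": list(map(float, p.event_amplitudes)),
                } for tid, p in self.scr_plans.items()
            },
            "seed": self.seed,
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
        if write_eda:
            for tid in self.design.trial_id:
                mio.eda_write(self.eda_trial(int(tid)), out / f"eda_{tid:05d}.csv")
        if write_eeg:
            for tid in self.design.trial_id:
                rec, _ = self.eeg_trial(int(tid))
                mio.brainvision_write(rec, out / f"eeg_{tid:05d}.vhdr")


def _trial_seed(seed: int, trial_id: int) -> int:
    return (seed * 100003 + trial_id) % (2**31 - 1)


def gen_experiment(
    n_subjects: int = 29,
    effect_spec: EffectSpec | None = None,
    n_trials: int = 1,
    seed: int = 0,
    audio_sample_rate: float = 16000.0,
    audio_duration_s: float = 78.0,
) -> ExperimentDataset:
    """Generate a complete experiment dataset.

    ``n_trials`` is the number of trials per subject x music x condition
    cell (the emulated study used 4; the default of 1 keeps simulations
    light).  Audio excerpts are shared across subjects, like real stimuli.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for paired statistics")
    if audio_duration_s < TRIAL_SECONDS:
        raise ValueError("audio must cover the 77 s analysis window")
    effect = effect_spec if effect_spec is not None else EffectSpec.effect_on()

    audio: dict[tuple[str, int], AudioWaveform] = {}
    envelopes: dict[tuple[str, int], EnvelopeSignal] = {}
    for mi, music in enumerate(MUSIC_TYPES):
        for rep in range(n_trials):
            au = gen_music_audio(
                duration_s=audio_duration_s, sample_rate=audio_sample_rate,
                seed=_trial_seed(seed, 7919 + 31 * mi + rep),
                audio_id=f"{music}_{rep}",
            )
            audio[(music, rep)] = au
            envelopes[(music, rep)] = extract_envelope(au)

    rng = _rng(seed, 9)
    rows: list[dict] = []
    subject_coupling: dict[tuple[int, str, str], float] = {}
    scr_plans: dict[int, SCRPlan] = {}
    trial_id = 0
    for subj in range(1, n_subjects + 1):
        for music in MUSIC_TYPES:
            # per-subject coupling deviations, one per condition
            for cond in CONDITIONS:
                cell = effect.cells[(music, cond)]
                c = cell.coupling
                if c > 0:
                    c = float(np.clip(
                        c + effect.coupling_subject_sd * rng.standard_normal(),
                        0.0, 1.0))
                subject_coupling[(subj, music, cond)] = c
            cdiff = (subject_coupling[(subj, music, "AVc")]
                     - subject_coupling[(subj, music, "AVic")])
            cdiff_mean = (effect.cells[(music, "AVc")].coupling
                          - effect.cells[(music, "AVic")].coupling)
            for cond in CONDITIONS:
                cell = effect.cells[(music, cond)]
                for rep in range(n_trials):
                    ratings = {}
                    for scale in RATING_SCALES:
                        if scale not in cell.ratings:
                            ratings[scale] = None
                            continue
                        mean = cell.ratings[scale]
                        if scale == "pleasure" and cond == "AVc":
                            # tie the pleasure benefit to the coupling benefit
                            mean = mean + effect.pleasure_coupling_gain * (cdiff - cdiff_mean)
                        v = mean + effect.rating_sd * rng.standard_normal()
                        ratings[scale] = int(np.clip(round(v), 0, 9))
                    n_ev = rng.poisson(cell.scr_rate)
                    times = np.sort(rng.uniform(2.0, TRIAL_SECONDS - 3.0, size=n_ev))
                    # enforce a minimal separation so events stay resolvable
                    keep, last = [], -10.0
                    for tt in times:
                        if tt - last >= 2.5:
                            keep.append(float(tt))
                            last = tt
                    amps = np.maximum(
                        rng.normal(effect.scr_amp_mean_uS, effect.scr_amp_sd_uS,
                                   size=len(keep)), 0.05)
                    scr_plans[trial_id] = SCRPlan(
                        event_times=keep, event_amplitudes=list(map(float, amps)))
                    rows.append({
                        "trial_id": trial_id, "subject_id": subj,
                        "music_type": music, "condition": cond, "rep": rep,
                        "duration_s": float(audio_duration_s), **ratings,
                    })
                    trial_id += 1

    design = pd.DataFrame(rows)
    return ExperimentDataset(design=design, audio=audio, envelopes=envelopes,
                             effect=effect, seed=seed,
                             subject_coupling=subject_coupling,
                             scr_plans=scr_plans, eeg_rate=250.0)
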