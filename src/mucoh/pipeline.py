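"""End-to-end orchestration: generation -> envelope -> spectra & CACoh ->
cluster inference -> SCR indices -> behavioural tests -> regressions ->
mediation, with a machine-readable run report.

Every numeric default matches the analysis constants: 77-s trials, 90 Hz
analysis rate, 1-40 Hz grid in 0.5 Hz steps, 8-13 Hz Mu band, 5000
permutations / Monte-Carlo draws, alpha 0.05.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import cacoh, cluster, eda, io, montage, spectral, stats
from .containers import MUSIC_TYPES
from .synth.experiment import EffectSpec, ExperimentDataset, gen_experiment

log = logging.getLogger("mucoh.pipeline")

EEG_CONDITIONS = ("AVc", "AVic", "AO")   # VO has no audio: no entrainment


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    n_subjects: int = 29
    n_trials: int = 1
    effect: str = "on"              # "on" | "off"
    seed: int = 0
    out_dir: str | None = None
    n_perm: int = 5000
    n_mc: int = 5000
    cluster_alpha: float = 0.05
    cluster_forming_alpha: float = 0.05
    alpha: float = 0.05
    mu_band: tuple[float, float] = (8.0, 13.0)
    analysis_band: tuple[float, float] = (1.0, 40.0)
    freq_step: float = 0.5
    trial_seconds: float = 77.0
    save_dataset: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        defaults = cls()
        for name in known:
            if getattr(cfg, name) != getattr(defaults, name) and name in raw:
                log.info("config override: %s=%r", name, raw[name])
        return cfg

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config: dict
    config_hash: str
    stages: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        io.report_write(asdict(self), path)


def _subject_matrices(ds: ExperimentDataset):
    """Per-subject Mu power and Mu entrainment matrices for each condition.

    Returns (channel_labels, mu_power, entrainment) where the latter two
    map (music_type, condition) -> subjects x channels arrays, averaged
    over the trials of the cell.
    """
    design = ds.design
    subjects = sorted(design.subject_id.unique())
    labels: list[str] | None = None
    mu_power: dict = {}
    entrain: dict = {}
    for music in MUSIC_TYPES:
        for cond in EEG_CONDITIONS:
            rows_pw: list[np.ndarray] = []
            rows_en: list[np.ndarray] = []
            for subj in subjects:
                sel = design[(design.subject_id == subj)
                             & (design.music_type == music)
                             & (design.condition == cond)]
                pw_trials, en_trials = [], []
                for _, row in sel.iterrows():
                    rec, _ = ds.eeg_trial(int(row.trial_id))
                    pre = spectral.preprocess(rec)
                    if labels is None:
                        labels = pre.channel_labels
                    spec = spectral.power_spectrum(spectral.segment(pre),
                                                   condition=cond)
                    pw_trials.append(spectral.mu_band(spec).value)
                    env = ds.envelope_for(music, int(row.rep))
                    coh = cacoh.ms_coherence(pre, env, condition=cond,
                                             music_type=music)
                    en_trials.append(cacoh.mu_entrainment(coh).value)
                rows_pw.append(np.mean(pw_trials, axis=0))
                rows_en.append(np.mean(en_trials, axis=0))
            mu_power[(music, cond)] = np.asarray(rows_pw)
            entrain[(music, cond)] = np.asarray(rows_en)
    return labels, mu_power, entrain


def _scr_tables(ds: ExperimentDataset):
    """Per-subject relative SCR indices (condition minus AO), per music type."""
    design = ds.design
    subjects = sorted(design.subject_id.unique())
    out: dict = {}
    for music in MUSIC_TYPES:
        rel_count = {c: [] for c in ("AVc", "AVic")}
        rel_amp = {c: [] for c in ("AVc", "AVic")}
        for subj in subjects:
            per_cond: dict[str, eda.SCRIndices] = {}
            for cond in ("AVc", "AVic", "AO"):
                sel = design[(design.subject_id == subj)
                             & (design.music_type == music)
                             & (design.condition == cond)]
                counts, amps = [], []
                for _, row in sel.iterrows():
                    scrs = eda.detect_scrs(
                        eda.decompose(ds.eda_trial(int(row.trial_id))))
                    counts.append(scrs.count)
                    amps.append(scrs.summed_amplitude_uS)
                per_cond[cond] = eda.SCRIndices(
                    count=int(np.round(np.mean(counts))),
                    summed_amplitude_uS=float(np.mean(amps)), condition=cond)
                per_cond[cond].count_mean = float(np.mean(counts))  # type: ignore
            for cond in ("AVc", "AVic"):
                rel_count[cond].append(per_cond[cond].count_mean
                                       - per_cond["AO"].count_mean)
                rel_amp[cond].append(per_cond[cond].summed_amplitude_uS
                                     - per_cond["AO"].summed_amplitude_uS)
        out[music] = {
            "relative_count": {c: np.asarray(v) for c, v in rel_count.items()},
            "relative_amplitude": {c: np.asarray(v) for c, v in rel_amp.items()},
        }
    return out


def _rating_matrix(ds: ExperimentDataset, music: str, scale: str,
                   conds: tuple[str, ...]) -> np.ndarray:
    design = ds.design
    subjects = sorted(design.subject_id.unique())
    cols = []
    for cond in conds:
        vals = []
        for subj in subjects:
            sel = design[(design.subject_id == subj)
                         & (design.music_type == music)
                         & (design.condition == cond)]
            vals.append(sel[scale].astype(float).mean())
        cols.append(vals)
    return np.asarray(cols).T   # subjects x conditions


def run_full(config: RunConfig) -> RunReport:
    """Execute the whole analysis on a (generated) dataset."""
    report = RunReport(config=asdict(config),
                       config_hash=config.content_hash())
    t_start = time.time()

    def stage(name):
        def deco(fn):
            t0 = time.time()
            log.info("stage %s ...", name)
            try:
                out = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            report.timings_s[name] = round(time.time() - t0, 3)
            return out
        return deco

    @stage("generate")
    def ds() -> ExperimentDataset:
        effect = (EffectSpec.effect_on() if config.effect == "on"
                  else EffectSpec.effect_off())
        d = gen_experiment(n_subjects=config.n_subjects,
                           effect_spec=effect, n_trials=config.n_trials,
                           seed=config.seed)
        if config.save_dataset and config.out_dir:
            d.save(Path(config.out_dir) / "dataset")
        return d

    @stage("eeg_features")
    def features():
        return _subject_matrices(ds)

    labels, mu_power, entrain = features
    adj = cluster.build_adjacency(montage.positions_2d(tuple(labels)))

    @stage("cluster_tests")
    def cluster_results():
        res = {}
        contrasts = [("entrainment", "AVc", "AVic", entrain),
                     ("mu_power", "AVc", "AO", mu_power),
                     ("mu_power", "AVic", "AO", mu_power),
                     ("mu_power", "AVc", "AVic", mu_power)]
        for music in MUSIC_TYPES:
            for meas, ca, cb, mats in contrasts:
                r = cluster.cluster_test(
                    mats[(music, ca)], mats[(music, cb)], adj,
                    n_perm=config.n_perm, cluster_alpha=config.cluster_alpha,
                    cluster_forming_alpha=config.cluster_forming_alpha,
                    seed=config.seed + 1)
                res[f"{music}:{meas}:{ca}-{cb}"] = {
                    "clusters": [
                        {"channels": c.channels, "sign": c.sign,
                         "stat": c.stat, "p": c.p} for c in r.clusters],
                    "n_significant": len(r.significant_clusters()),
                }
        return res

    @stage("eda_indices")
    def scr():
        return _scr_tables(ds)

    @stage("behaviour")
    def behaviour():
        res = {}
        for music in MUSIC_TYPES:
            for scale in ("pleasure", "liking"):
                mat = _rating_matrix(ds, music, scale, ("AVc", "AVic", "AO"))
                aov = stats.rm_anova(mat)
                posthoc = {}
                for (i, j, nm) in ((0, 2, "AVc-AO"), (1, 2, "AVic-AO"),
                                   (0, 1, "AVc-AVic")):
                    posthoc[nm] = asdict(stats.paired_tests(
                        mat[:, i], mat[:, j], n_comparisons=3))
                res[f"{music}:{scale}"] = {"anova": asdict(aov),
                                           "posthoc": posthoc}
            for meas in ("relative_count", "relative_amplitude"):
                t = scr[music][meas]
                res[f"{music}:scr_{meas}"] = asdict(stats.paired_tests(
                    t["AVc"], t["AVic"], method="wilcoxon"))
        return res

    # channels carrying the vocal congruency effect on entrainment
    vocal_key = "vocal:entrainment:AVc-AVic"
    sig = [c for c in cluster_results[vocal_key]["clusters"]
           if c["p"] <= config.cluster_alpha and c["sign"] > 0]
    if sig:
        effect_channels = sorted({ch for c in sig for ch in c["channels"]})
    else:
        effect_channels = list(montage.FRONTAL_SET)
        report.warnings.append(
            "no significant vocal entrainment cluster; regressions/mediation "
            "use the canonical frontal set")
    ch_idx = [labels.index(c) for c in effect_channels]

    def mean_ent(music, cond):
        return entrain[(music, cond)][:, ch_idx].mean(axis=1)

    @stage("regressions")
    def regressions():
        res = {}
        d_ent = mean_ent("vocal", "AVc") - mean_ent("vocal", "AVic")
        d_pl = (_rating_matrix(ds, "vocal", "pleasure", ("AVc", "AVic"))
                @ np.array([1.0, -1.0]))
        res["vocal:d_entrainment~d_pleasure"] = asdict(
            stats.robust_regression(d_ent, d_pl))
        d_amp = scr["vocal"]["relative_amplitude"]["AVc"] \
            - scr["vocal"]["relative_amplitude"]["AVic"]
        res["vocal:d_entrainment~d_scr_amplitude"] = asdict(
            stats.robust_regression(d_ent, d_amp))
        # violin: entrainment difference vs suppression and SCR differences
        cen_idx = [labels.index(c) for c in montage.CENTRAL_SET]
        d_ent_v = mean_ent("violin", "AVc") - mean_ent("violin", "AVic")
        d_sup_v = (mu_power[("violin", "AVc")][:, cen_idx].mean(axis=1)
                   - mu_power[("violin", "AVic")][:, cen_idx].mean(axis=1))
        d_cnt_v = scr["violin"]["relative_count"]["AVc"] \
            - scr["violin"]["relative_count"]["AVic"]
        res["violin:d_entrainment~d_suppression"] = asdict(
            stats.robust_regression(d_ent_v, d_sup_v))
        res["violin:d_entrainment~d_scr_count"] = asdict(
            stats.robust_regression(d_ent_v, d_cnt_v))
        res["_effect_channels"] = effect_channels
        return res

    @stage("mediation")
    def mediation():
        res = {}
        m = np.column_stack([mean_ent("vocal", "AVic"),
                             mean_ent("vocal", "AVc")])
        pl = _rating_matrix(ds, "vocal", "pleasure", ("AVic", "AVc"))
        res["vocal:congruency->entrainment->pleasure"] = asdict(
            stats.within_mediation(m, pl, n_mc=config.n_mc,
                                   alpha=config.alpha, seed=config.seed + 2))
        cen_idx = [labels.index(c) for c in montage.CENTRAL_SET]
        d_ent_v = mean_ent("violin", "AVc") - mean_ent("violin", "AVic")
        d_sup_v = (mu_power[("violin", "AVc")][:, cen_idx].mean(axis=1)
                   - mu_power[("violin", "AVic")][:, cen_idx].mean(axis=1))
        d_cnt_v = scr["violin"]["relative_count"]["AVc"] \
            - scr["violin"]["relative_count"]["AVic"]
        res["violin:d_ent->d_suppression->d_scr_count"] = asdict(
            stats.mediation_continuous(d_ent_v, d_sup_v, d_cnt_v,
                                       n_mc=config.n_mc, alpha=config.alpha,
                                       seed=config.seed + 3))
        return res

    report.stages = {
        "cluster_tests": cluster_results,
        "behaviour": behaviour,
        "regressions": regressions,
        "mediation": mediation,
    }
    report.timings_s["total"] = round(time.time() - t_start, 3)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.write(out / "run_report.json")
    return report
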