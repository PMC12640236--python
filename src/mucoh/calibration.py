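"""Self-calibration simulations: error rates and parameter recovery.

These routines measure, by Monte-Carlo simulation, the operating
characteristics of the package's own inferential machinery:

* the family-wise false-positive rate of the electrode-cluster permutation
  test under a null with no condition differences;
* the false-positive rate of the within-participant mediation Monte-Carlo
  confidence interval under a null with no effects;
* monotonicity of Mu entrainment in the planted envelope-Mu coupling;
* recovery of a planted indirect effect;
* end-to-end recovery (or correct absence) of the planted congruency
  effect through the full audio -> EEG -> coherence -> cluster ->
  mediation chain.
"""

from __future__ import annotations

import numpy as np

from . import montage
from .cacoh import ms_coherence, mu_entrainment
from .cluster import build_adjacency, cluster_test
from .envelope import extract_envelope
from .spectral import preprocess
from .stats import within_mediation
from .synth.audio import gen_music_audio
from .synth.eeg import CouplingSpec, gen_eeg

#: 16-channel sub-layout used for null-calibration runs: an evenly spread
#: grid over the scalp.
SUBLAYOUT_16: tuple[str, ...] = (
    "F3", "Fz", "F4", "FC3", "FCz", "FC4", "C3", "Cz", "C4",
    "CP3", "CPz", "CP4", "P3", "Pz", "P4", "POz",
)


def cluster_fwer(n_runs: int = 200, n_subjects: int = 29,
                 channels: tuple[str, ...] = SUBLAYOUT_16,
                 n_perm: int = 1000, cluster_alpha: float = 0.05,
                 seed: int = 0) -> float:
    """Empirical FWER of the cluster test under i.i.d. normal nulls."""
    adj = build_adjacency(montage.positions_2d(channels))
    rng = np.random.default_rng(seed)
    false_pos = 0
    for run in range(n_runs):
        a = rng.standard_normal((n_subjects, len(channels)))
        b = rng.standard_normal((n_subjects, len(channels)))
        res = cluster_test(a, b, adj, n_perm=n_perm,
                           cluster_alpha=cluster_alpha,
                           seed=int(rng.integers(2**31 - 1)))
        false_pos += bool(res.significant_clusters(cluster_alpha))
    return false_pos / n_runs


def mediation_null_rate(n_runs: int = 500, n_subjects: int = 31,
                        n_mc: int = 2000, seed: int = 0) -> float:
    """Fraction of null datasets whose mediation MC CI excludes zero."""
    rng = np.random.default_rng(seed)
    hits = 0
    for run in range(n_runs):
        m = rng.standard_normal((n_subjects, 2))
        y = rng.standard_normal((n_subjects, 2))
        res = within_mediation(m, y, n_mc=n_mc,
                               seed=int(rng.integers(2**31 - 1)))
        hits += res.significant
    return hits / n_runs


def entrainment_by_coupling(couplings=(0.0, 0.3, 0.6, 1.0), n_seeds: int = 50,
                            channel: str = "C3", seed: int = 0) -> np.ndarray:
    """Mean Mu entrainment at one channel for each planted coupling level.

    Returns an array of per-level means over ``n_seeds`` replicates; the
    planted coupling is injected at ``channel`` only.
    """
    audio = gen_music_audio(78.0, seed=seed)
    env = extract_envelope(audio)
    means = []
    for c in couplings:
        spec = CouplingSpec(channel_coupling={channel: c} if c > 0 else {})
        vals = []
        for s in range(n_seeds):
            rec, _ = gen_eeg(env, spec, seed=seed * 1000 + s)
            pre = preprocess(rec)
            ent = mu_entrainment(ms_coherence(pre, env))
            vals.append(ent.value[pre.channel_labels.index(channel)])
        means.append(float(np.mean(vals)))
    return np.asarray(means)


def mediation_recovery(n_reps: int = 200, n_subjects: int = 31,
                       a: float = 0.5, b: float = 0.5, noise_sd: float = 0.5,
                       n_mc: int = 500, seed: int = 0):
    """Mean recovered indirect effect for planted paths (truth = a*b).

    Returns (mean_indirect, se_of_mean).
    """
    rng = np.random.default_rng(seed)
    est = []
    for rep in range(n_reps):
        m0 = rng.normal(0.0, 0.3, n_subjects)
        md = rng.normal(a, 0.3, n_subjects)
        m = np.column_stack([m0, m0 + md])
        yd = b * md + rng.normal(0.0, noise_sd, n_subjects)
        y = np.column_stack([np.zeros(n_subjects), yd])
        res = within_mediation(m, y, n_mc=n_mc,
                               seed=int(rng.integers(2**31 - 1)))
        est.append(res.indirect)
    est = np.asarray(est)
    return float(est.mean()), float(est.std(ddof=1) / np.sqrt(n_reps))


def end_to_end_run(seed: int, effect_on: bool = True, n_subjects: int = 29,
                   n_perm: int = 1000, n_mc: int = 2000) -> dict:
    """One full-chain run on the vocal AVc-vs-AVic contrast.

    Generates audio once, per-subject AVc and AVic EEG trials with the
    planted coupling structure, runs the cluster test over all 64
    channels, and the congruency -> entrainment -> pleasure mediation.
    Returns which effects were detected and where.
    """
    from .synth.experiment import EffectSpec, gen_experiment

    spec = EffectSpec.effect_on() if effect_on else EffectSpec.effect_off()
    ds = gen_experiment(n_subjects=n_subjects, effect_spec=spec, seed=seed)
    design = ds.design
    subjects = sorted(design.subject_id.unique())
    ent = {}
    labels = None
    for cond in ("AVc", "AVic"):
        rows = []
        for subj in subjects:
            sel = design[(design.subject_id == subj)
                         & (design.music_type == "vocal")
                         & (design.condition == cond)]
            row = sel.iloc[0]
            rec, _ = ds.eeg_trial(int(row.trial_id))
            pre = preprocess(rec)
            labels = pre.channel_labels
            env = ds.envelope_for("vocal", int(row.rep))
            rows.append(mu_entrainment(ms_coherence(pre, env)).value)
        ent[cond] = np.asarray(rows)

    adj = build_adjacency(montage.positions_2d(tuple(labels)))
    res = cluster_test(ent["AVc"], ent["AVic"], adj, n_perm=n_perm,
                       seed=seed + 1)
    sig_pos = [c for c in res.significant_clusters() if c.sign > 0]
    overlap = any(set(c.channels) & set(montage.FRONTAL_SET)
                  for c in sig_pos)

    idx = [labels.index(c) for c in montage.FRONTAL_SET]
    m = np.column_stack([ent["AVic"][:, idx].mean(axis=1),
                         ent["AVc"][:, idx].mean(axis=1)])
    pleasure = design[design.music_type == "vocal"].pivot_table(
        index="subject_id", columns="condition", values="pleasure")
    y = pleasure[["AVic", "AVc"]].to_numpy(float)
    med = within_mediation(m, y, n_mc=n_mc, seed=seed + 2)

    return {
        "cluster_found": bool(sig_pos),
        "cluster_overlaps_planted": bool(overlap),
        "mediation_significant": bool(med.significant),
        "indirect": med.indirect,
        "ci": med.ci,
    }
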