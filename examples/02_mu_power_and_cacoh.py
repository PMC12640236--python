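"""Mu-band power and cerebral-acoustic coherence on one synthetic trial.

Couples a frontal channel set to the music envelope, preprocesses the raw
trial (mastoid reference, 1-40 Hz, 90 Hz), and prints Mu power and Mu
entrainment for coupled vs uncoupled channels.
"""

import numpy as np

from mucoh import montage
from mucoh.cacoh import ms_coherence, mu_entrainment
from mucoh.envelope import extract_envelope
from mucoh.spectral import mu_band, power_spectrum, preprocess, segment
from mucoh.synth.audio import gen_music_audio
from mucoh.synth.eeg import CouplingSpec, gen_eeg

audio = gen_music_audio(78.0, seed=3)
env = extract_envelope(audio)

spec = CouplingSpec(channel_coupling={ch: 0.6 for ch in montage.FRONTAL_SET})
raw, truth = gen_eeg(env, spec, seed=42)
pre = preprocess(raw)

mu_pow = mu_band(power_spectrum(segment(pre)))
ent = mu_entrainment(ms_coherence(pre, env))

coupled = [pre.channel_labels.index(c) for c in montage.FRONTAL_SET]
uncoupled = [i for i in range(len(pre.channel_labels)) if i not in coupled]

print(f"preprocessed: {pre.n_channels} channels at {pre.sample_rate_hz:.0f} Hz, "
      f"{pre.n_samples / pre.sample_rate_hz:.0f} s")
print(f"Mu power (8-13 Hz), grand mean: {mu_pow.value.mean():.2f} uV^2/Hz")
print(f"Mu entrainment, coupled frontal set:   {ent.value[coupled].mean():.3f}")
print(f"Mu entrainment, remaining channels:    {ent.value[uncoupled].mean():.3f}")
print("Coupled channels show coherence far above the ~1/n_segments chance "
      "level because their Mu-band activity is phase-locked to the envelope.")
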