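# Methods

`mucoh` implements the analysis chain of an audiovisual music-reward
experiment — from stimuli to inference — together with a synthetic-data
module that emulates the experiment's structure, so that every stage can
be validated without recorded data.  This note documents the models, the
defaults and their rationale, the numerical choices, and what the
synthetic validation does and does not establish.

## Analysis constants

All stages share one set of constants: trials are analysed over their
first **77 s**; EEG analysis runs at **90 Hz**; spectra and coherence live
on a **1–40 Hz grid in 0.5 Hz steps** (79 bins); the **Mu band is
8–13 Hz** (11 bins, both edges inclusive); permutation and Monte-Carlo
procedures default to **5000** iterations at **α = 0.05**.  `RunConfig`
carries these defaults and logs any override.

## Envelope extraction (`mucoh.envelope`)

The music amplitude envelope is extracted with a bank of 16 fourth-order
gammatone filters, centre frequencies geometrically spaced from 100 to
4000 Hz.  Per band, the envelope is the magnitude of the analytic signal;
the 16 band envelopes are averaged, resampled to 90 Hz by polyphase
filtering, and band-limited to 1–40 Hz with a zero-phase 4th-order
Butterworth filter.  Choices worth noting:

* **Geometric spacing** is the literal reading of "logarithmically
  spaced"; ERB-number spacing is a plausible alternative and would move
  centre frequencies by < 1/3 octave — it does not change any qualitative
  behaviour of the envelope.
* **ERB bandwidths** via the digital all-pole gammatone approximation in
  SciPy.  Filters are applied as **cascaded second-order sections**: the
  direct 8-coefficient transfer-function form is ill-conditioned at
  low centre frequencies (poles close to the unit circle) and visibly
  breaks the scale-covariance of the envelope.
* **Zero-phase** resampling and band-limiting, because phase distortion
  in the envelope would bias coherence with the EEG.
* The analysis window is enforced: audio shorter than 77 s is rejected
  rather than padded.

## EEG preprocessing and Mu power (`mucoh.spectral`)

Raw recordings (64 scalp channels, M1/M2 mastoids, 2 EOG) are
re-referenced to the mastoid average, demeaned, resampled to 90 Hz
(polyphase, with its anti-alias low-pass), band-passed 1–40 Hz
(zero-phase Butterworth), cropped to 77 s, and the mastoid/EOG channels
dropped.  Resampling before the band-pass is equivalent in passband to
the reverse order and several-fold cheaper.  An `artifact_hook` is the
identity by default — synthetic data carry no blink or cardiac
artifacts; the hook is the seam where ICA would sit on recorded data.

Power spectra use non-overlapping 1-s epochs with a single Hann taper.
A 1-s epoch at 90 Hz natively yields a 1-Hz grid; epochs are zero-padded
to 2 s so the spectrum lands on the 0.5-Hz analysis grid.  Zero-padding
interpolates the spectrum; it does not add resolution, and any taper on a
1-s epoch has a mainlobe at least ±1 Hz wide.  Validation therefore
checks tone-power concentration within ±1 Hz of the tone, not tighter.
Mu power is the arithmetic mean of the 11 Mu-band bins; the suppression
index is the raw power difference `condition − AO` (negative =
suppression), matching how paired tests are run on power.

## Cerebral-acoustic coherence (`mucoh.cacoh`)

Magnitude-squared coherence between each channel and the envelope is
Welch-estimated with 2-s Hann segments (180 samples → the 0.5 Hz grid
natively) and 50% overlap; trials are estimated separately and averaged
within condition, never concatenated (concatenation would create
boundary artifacts).  Mu entrainment is the mean coherence over the Mu
bins.  Properties used in validation: self-coherence is identically 1;
the estimator is invariant to linear rescaling of either signal; under
independence the mean coherence equals the known 1/K bias for K
non-overlapping segments; a single segment would give coherence ≡ 1, so
fewer than two segments is an error.

## Cluster-based permutation inference (`mucoh.cluster`)

Per channel, a two-sided paired t-test; channels beyond the
cluster-forming threshold (per-channel α = 0.05 two-sided — a
convention, since only the cluster-level α is prescribed) are grouped by
spatial adjacency, separately by sign, and scored by their summed t.
Adjacency is the Delaunay triangulation of the 2-D layout (pruned of the
longest edges when that keeps the graph connected; collinear layouts fall
back to a nearest-neighbour chain).  The null distribution of the
maximum |cluster score| is built from random within-subject sign flips of
the condition differences; each observed cluster gets the Monte-Carlo
p-value `(b+1)/(m+1)`, which is never zero and valid under
exchangeability.  Degenerate channels (no difference at all) contribute
t = 0.  Family-wise error control is verified empirically (≈200 null
simulations at the study's n; the measured rate sits at or below the
nominal 0.05 within binomial error).

## Electrodermal analysis (`mucoh.eda`)

Traces (2000 Hz) are decimated to 20 Hz — SCR bandwidth is well below
that — and split into tonic and phasic parts.  The tonic trend is
estimated robustly: a 20-s rolling median flags event-dominated samples
(3 MAD above the local trend), those samples are bridged by linear
interpolation, and the result is smoothed by a zero-phase 0.05 Hz
low-pass applied around a linear fit (so pure drift passes through
exactly).  A plain low-pass would absorb 30%+ of each SCR into the tonic
and produce rebound artifacts that register as spurious events.

Detection is trough-to-peak on the 1 Hz-smoothed phasic: amplitude =
peak minus preceding trough, minimum amplitude 0.01 µS, and only events
**peaking between 2 s and 77 s** are kept (SCR latency ≈ 2 s; the
Bateman kernel with the default τ_rise = 0.75 s, τ_decay = 2 s peaks
1.18 s after onset, so an onset at t=0 peaks inside the dead window and
is correctly discarded).  Condition indices are counts and summed
amplitudes; AVc/AVic values are reported relative to the AO baseline of
the same subject and music type.

## Statistics (`mucoh.stats`)

* **Test selection**: Shapiro–Wilk on the paired differences at α=0.05
  chooses between the paired t-test (effect size Cohen's d on the
  difference scores) and the Wilcoxon signed-rank test (effect size
  r = Z/√N).  Bonferroni correction multiplies p by the number of
  comparisons, capped at 1.
* **Wilcoxon**: Pratt's treatment of zeros, mid-ranks for ties.  Exact
  enumeration of the sign-flip null for n ≤ 12 pairs; beyond that a
  normal approximation with zero/tie variance corrections and a 0.5
  continuity correction.
* **Repeated-measures ANOVA** (via pingouin): Greenhouse–Geisser
  corrected p whenever Mauchly's test rejects sphericity; with two
  levels ε = 1 identically.  Effect size is partial eta squared computed
  from the sums of squares.  The degenerate identical-columns case (0/0)
  reports F = 0, p = 1.
* **Robust regression**: IRLS with a Tukey bisquare M-estimator
  (statsmodels RLM), started from a Huber fit — Huber's loss is convex,
  so the initialization is reproducible and the bisquare stage starts
  near the bulk of the data; this stands in for an LTS-style subsample
  search and is adequate at the contamination levels validated (10%
  gross outliers).  Variables are standardised by default (`standardize=
  False` gives raw-scale slopes).  p-values use a t reference with n−2
  df; the null rejection rate at n=29 is verified to sit at the nominal
  5% within binomial error.
* **Within-participant mediation** (two conditions per subject,
  difference-score formulation): a = mean mediator difference; b = slope
  of the outcome difference on the centred mediator difference,
  controlling the centred per-subject mediator mean (dropped
  automatically if collinear); indirect = a·b exactly.  The CI comes
  from 5000 independent normal draws of (a, b) at their estimated
  standard errors — only the interval is stochastic, and it is
  reproducible given a seed.  Total (mean outcome difference) and direct
  (intercept after controlling the mediator) effects are reported, with
  a "full mediation" reading when the total is significant, the CI
  excludes 0, and the direct effect is not significant.  A
  product-of-coefficients variant (`mediation_continuous`) serves the
  across-subject difference-score mediation (continuous predictor),
  on standardised variables.

## Synthetic data (`mucoh.synth`)

The generator produces the statistical structure the analysis assumes;
it is not a biophysical simulation.

* **Audio**: an RMS-normalised multitone carrier (10 log-spaced partials,
  100–4000 Hz, seed-dependent phases, plus a 0.25-weight noise floor)
  amplitude-modulated by a known modulator (slow sinusoids plus <16 Hz
  low-pass noise, depth 0.9).  Partials are spaced > 45 Hz apart so that
  partial-beat products fall outside the 1–40 Hz envelope band and an
  unmodulated carrier yields a near-constant envelope (CV ≈ 0.02); a
  white-noise carrier would contribute irreducible ERB-band Rayleigh
  fading (CV ≈ 0.09) that has nothing to do with the modulator.  The
  modulator's noise term gives the envelope genuine Mu-band content, as
  real music envelopes have.  The true modulator rides along as ground
  truth and is never read by analysis code.
* **EEG** (250 Hz raw, 64+2+2 channels): per channel, 1/f background
  (exponent 1, 10 µV RMS), a narrowband 8–13 Hz generator weighted
  towards occipital sites (alpha, 4 µV) and central sites (intrinsic Mu,
  3 µV, scaled per condition to emulate visually induced suppression,
  0.7 under AV/VO vs 1.0 under AO), and — on coupled channels — an
  entrained component: the envelope's own 8–13 Hz band content, scaled
  by `coupling_strength` (6 µV at coupling 1).  **Why additive injection
  rather than amplitude-modulating an independent carrier:** coherence
  measures phase-locked content; multiplying a stochastic carrier by the
  envelope creates sidebands but zero expected cross-spectrum with the
  envelope at Mu frequencies, so no coupling parameter of that form
  could produce the monotone coherence the validation requires.  The
  injected component is exactly "Mu-band activity entrained to the
  envelope", and measured Mu coherence grows monotonically from the 1/K
  chance level (coupling 0) to ≈0.6 (coupling 1).  Narrowband noise is
  synthesised spectrally (random-phase spectra shaped by the Butterworth
  magnitude response), which is statistically equivalent to zero-phase
  filtering white noise and much cheaper across 68 channels.
* **EDA** (2000 Hz): tonic level + drift, plus Bateman kernels
  (difference of exponentials normalised to unit peak, so the planted
  amplitude is the event amplitude) at planted times, plus Gaussian
  noise (0.005 µS).
* **Experiment**: 2 music types × 4 conditions per subject (default one
  trial per cell; the emulated study used four — the scaled-down default
  keeps whole-experiment simulations tractable and does not change any
  per-trial property).  Planted effects, chosen once to emulate the
  qualitative result pattern at realistic effect sizes: vocal AVc
  coupling 0.6 vs 0.3 elsewhere (violin: 0.3 everywhere; VO: 0); Mu
  scale 0.7 under visual conditions; SCR rate 4.0/trial under vocal AVc
  vs 2.0 elsewhere (amplitudes ≈ N(0.4, 0.15) µS, ≥ 2.5 s apart);
  ratings are truncated-discretised Gaussians on 0–9 (sd 1), with vocal
  AVc pleasure/liking raised by 1.0 point.  Per-subject coupling varies
  (sd 0.20), and each subject's AVc pleasure is additionally shifted by
  6 rating points per unit of that subject's coupling benefit — this
  individual-difference link is what gives the mediation a true indirect
  path; its size was set so that the planted effect is comfortably
  detectable at the study's n=29, as the original effects were.
  Ratings/SCR distributions are package conventions, not values taken
  from the study.  Determinism: a master seed fixes everything;
  EEG/EDA are regenerated on demand per trial from seeds derived from
  (master seed, trial id), so datasets need not be held in memory.

## Validation strategy and its limits

The test-suite and `scripts/acceptance.py` measure the package's own
operating characteristics: family-wise false-positive rate of the
cluster test (200 null runs at n=29), the mediation CI's null exclusion
rate (500 runs at n=31), exact-oracle agreement (Wilcoxon enumeration,
exhaustive sign flips at n=5, direct-DFT coherence), parameter recovery
(coherence monotone in coupling; indirect effect 0.25 recovered), and
end-to-end recovery of the planted congruency effect (25 effect-on and
25 effect-off runs at n=29).  Problem sizes were chosen so the whole
suite runs on one CPU in well under half an hour.

What this does **not** show: the synthetic EEG has no artifacts, no
volume-conduction structure, no non-stationarity, and its envelope
coupling is linear and stationary — so passing tests demonstrate the
correctness and calibration of the *analysis machinery*, not that the
machinery would extract these effects from arbitrary recorded data.
File-format handling is exercised with WAV, BrainVision (written by the
package, read back through MNE), CSV and JSON; EDF input is not
supported (no EDF writer is available in the dependency set, so a
round-trip contract could not be honoured).

## Known limitations

* The cluster test clusters electrodes only (scalar per channel), not
  time-frequency points.
* The robust-regression initialisation is Huber-based, not a true
  high-breakdown LTS/MM chain; with >30% contamination it can fail like
  any M-estimator.
* Ratings are modelled as independent across cells given the subject's
  coupling; real raters drift and anchor.
* The Welch parameters of the coherence (2 s, 50% overlap, Hann) and the
  per-trial-then-average convention are declared defaults; alternatives
  (e.g. multitaper, concatenation) would change absolute coherence
  levels but not the monotonicity or calibration properties tested.
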