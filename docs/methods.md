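# Methods

`fceeg` implements a case–control EEG analysis of the kind used to probe
brain–gut-axis involvement in functional constipation: relative band power
by lobe, imaginary-coherence functional networks summarized by
threshold-integrated graph metrics, and age-adjusted group statistics —
together with a synthetic-cohort generator so that every stage can be
exercised and validated without access to patient recordings.

## The synthetic cohort

Real recordings from such studies are rarely deposited, so the generator
is a first-class part of the package. It emulates the study design the
analysis assumes: 21 patients (ages 23–80) and 37 controls (ages 20–60),
64 channels in a 10-20/10-10 layout, 250 Hz sampling, and a task schedule
of a 420 s eyes-open resting baseline, a 160 s cognitive block (split
60/50/50 s into two counting tasks and a word-formation task; the split
within the block is the package's choice), and defecation-related blocks
(30 s imagery, 250 s execution for both simulated defecation and anal
contraction). Execution blocks can optionally be annotated with
hold/relax cycles via `cycle_timing`; no within-block gain changes are
modelled.

Each channel is the sum of:

* **1/f background** — FFT-shaped Gaussian noise with power ∝ f^(−χ) over
  the analysed range (default χ = 1, a typical broadband EEG slope),
  flattened below 0.5 Hz so drifts stay bounded; overall scale 5 µV RMS.
* **Five band-limited oscillators per lobe** — band-pass-filtered white
  noise in the canonical delta/theta/alpha/beta/gamma bands with baseline
  amplitudes 3/2/4/1.5/0.8 µV RMS (alpha-dominant, gamma-weak, as in
  resting EEG). Each lobe's oscillator is a mixture of a region-shared
  latent source, seen by every member channel through a random constant
  phase lag (uniform in ±π/2, applied via the analytic signal), and
  channel-private noise. The shared fraction (default 0.5) controls
  coherence, and the nonzero lags are what make the *imaginary* part of
  coherence nonzero — instantaneous mixing alone would be invisible to it.
* **Artifacts** — whole-channel flatlines (per-channel probability),
  transient single-channel flatlines (Poisson rate per minute, 0.5–2 s),
  and stereotyped biphasic blinks (~0.4 s, 120 µV) weighted by a frontal
  spatial profile. Default rates are set so cohort QC lands near a few
  percent of channels/duration, the range typical of clinical recordings.

Group effects are injected as multiplicative amplitude gains per
(group, region, task, band). A log-normal per-subject amplitude jitter
(σ = 0.2 per region × band) provides the between-subject variability that
gives effect sizes meaning. `calibrate_effect` maps a target Cohen's d of
relative power onto a patient/control gain ratio by bisection against
pilot simulations. The pilot uses a paired common-random-numbers design
(each pilot subject simulated twice from the same stream, once per group),
which removes almost all mean-difference noise; the remaining error is the
pooled-SD estimate, about ±8% relative at 60 pilot pairs.

What the generator does **not** model: head-geometry forward fields and
realistic volume conduction, ECG/EMG artifacts, nonstationarity within a
task block, age effects on the spectrum, or spatially graded (rather than
lobe-uniform) effects. Passing tests therefore demonstrate that the
analysis recovers the statistical structure it assumes, not that it is
robust to everything real data contain.

## Preprocessing

* **Band-pass** 0.5–45 Hz, 4th-order Butterworth applied forward–backward
  (zero phase, so oscillatory phase used by coherence is undistorted).
  The zero-phase response attenuates ≥40 dB by 0.25 and 67.5 Hz.
* **Flatline QC** — a channel is bad when strictly more than 60% of its
  samples are below 1e-10 µV in magnitude; transient flatlines in any
  channel lasting ≥0.2 s (configurable; no canonical value exists) become
  bad segments, merged across channels by interval union. The narrative
  stage order is filter → bad channels → interpolation → bad segments →
  artifact removal, but detection always inspects the *raw* amplitudes: a
  zero-phase IIR filter smears energy into an exactly-zero window, so the
  near-zero criterion is only meaningful before filtering.
* **Spherical-spline interpolation** (Perrin-style) reconstructs bad
  channels on the unit sphere: stiffness order m = 4, Legendre series
  truncated at 50 terms, ridge 1e-5 on the spline system. Good channels
  pass through bit-exactly. Electrode positions come from the idealized
  standard 10-05 layout, re-centred and projected onto the unit sphere.
* **Artifact components** — classifier-based component labelling is out of
  scope (it needs trained weights), so the package ships a pluggable
  stand-in: FastICA unmixing (deterministic given a seed; component count
  capped at the numerical rank of the data, which matters once channels
  have been interpolated), zeroing of components whose |correlation| with
  a caller-supplied artifact reference exceeds 0.8, and remixing. Any
  callable with the same signature can replace it. The removed-duration
  fraction counts samples where the removed signal's cross-channel RMS
  exceeds 10% of its peak.
* **QC percentages** — bad channels / total channels; summed per-channel
  flatline time / (channels × duration) (the per-interval convention is
  reported alongside); removed-artifact duration / duration. Cohort
  aggregation is mean ± SD.
* Only the first 120 s of the resting block are analysed; other blocks are
  used whole. Excised bad segments split a recording into continuous
  chunks that are never concatenated across a gap.

## Spectra and relative power

Welch estimation with 2 s Hann windows and 50% overlap (0.5 Hz
resolution, enough to resolve the 0.5 Hz delta edge); the segments of all
good chunks of a recording are pooled. Relative power of band b is the
trapezoid integral of the PSD over b divided by the integral over
0.5–45 Hz; because the five bands tile that range and share edge
frequencies, the five fractions sum to 1 by construction (edge bins
contribute half an interval to each neighbour). Channels with zero total
power yield NaN with a warning. Lobe values average the member channels'
relative power (scale-invariant per channel); averaging PSDs first is
available via `region_average: psd`. Scalp maps are thin-plate-spline
interpolations onto a grid in the azimuthal-equidistant projection,
masked outside the head circle, and exported as numeric matrices.

## Connectivity and network topology

The cross-spectral matrix uses exactly the same Welch segmentation as the
PSD (so the CSD diagonal *is* the PSD). For each band the connectivity
entry of a channel pair is the band average of |Im C_xy(f)|, with
C_xy = S_xy/√(S_xx S_yy); the magnitude is taken per bin so
opposite-signed lags at different frequencies cannot cancel (`signed=True`
averages first). Zero-lag mixtures of independent sources produce purely
real coherency and stay at the estimator's noise floor (~1/√K for K
segments) — the property that motivates the measure under volume
conduction.

Networks keep the strongest s·n(n−1)/2 connections at sparsities
0.10–0.30 in steps of 0.05 and are binarized (the convention of the
proportional-threshold literature; a weighted variant is behind
`weighted=True`). Edge counts use round-half-to-even; cutoff ties break
by ascending (row, column) so thresholding is deterministic and nested.
Global efficiency is the mean inverse BFS shortest-path length over
ordered pairs (disconnected pairs contribute 0; no largest-component
restriction); average local efficiency applies the same quantity to each
node's open neighborhood (nodes with <2 neighbors contribute 0);
clustering is triangles over possible triangles, averaged over nodes.
Each metric's trajectory over the sparsity grid is integrated by the
trapezoid rule into a single AUC feature (range 0–0.2 for a metric
bounded by 1 over a grid of width 0.2).

## Group statistics

Per (task, band, region) cell: ANCOVA as the least-squares linear model
value ~ 1 + group + age, with a partial F-test of the group term on
(1, n−3) df (type-III-equivalent for this two-term model). A singular
design (constant age) falls back to the group-only model, i.e. one-way
ANOVA, with a warning; zero residual variance reports p = 0 with a
degenerate-fit warning. Benjamini–Hochberg adjustment is applied within
each (task, band) family across the five lobes; network AUC metrics are
reported with raw p (singleton families), mirroring the asymmetric
reporting convention of the analysis this package reproduces. Cohen's d
uses the pooled SD, signed patient − control, and |d| > 0.5 flags a
medium effect; significance (p_fdr < 0.05, two-sided) and the effect-size
flag are reported as independent columns, never merged.

## Pipeline, determinism, problem sizes

`run_all` validates the whole configuration before any computation,
executes simulate → preprocess → features → stats, writes every
intermediate table as CSV, and records a manifest (config hash, seeds,
stage wall times). All stages are pure functions of (inputs, config,
seed); reruns are bit-identical. Randomness flows from a single seed
through spawned `SeedSequence` streams per subject and task.

The test suite and the acceptance script run cohorts at reduced problem
sizes chosen to keep the statistical questions intact: full 64-channel
montages and the study's 21/37 group sizes, but 30 s single-task blocks
and 10–20 cohort replicates; the null FDR calibration uses 1000 simulated
feature families at the stats level. These sizes were chosen so the whole
validation runs comfortably on a single CPU while the quantities being
checked (effect-size recovery, false-discovery rate, spectral slopes)
retain enough precision to be meaningful.

## Known limitations

* The ICA-based artifact stand-in needs an explicit artifact reference;
  it is a hook for a real classifier, not a replacement.
* Imaginary coherence discards genuinely zero-lag physiological coupling
  by design; the package offers no corrected alternative (PLI variants
  are out of scope).
* Effect calibration is accurate to roughly ±10% of the target d; the
  dominant residual error is pooled-SD sampling noise in the pilot.
* The EDF writer emits plain EDF (not EDF+); annotations and QC state
  travel in a JSON sidecar.
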