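# Methods

This note documents the models, estimators and numerical choices behind
`plugadapt`, in the order data flow through the package.

## Stimulus spectra

All stimuli are represented as log-amplitude spectra (dB relative to a
flat reference) on a grid uniform in log2 frequency; no waveform is ever
synthesized, and duration (100 ms), ramp (10 ms) and nominal sampling
rate (97.6 kHz) are carried as metadata only.  The default grid spans
0.5–20 kHz at 1/24 octave (128 points) — four times the Nyquist density
needed for the spectral-modulation content described next.

**Randomization vectors.**  A random-spectrum stimulus adds to the flat
spectrum a vector built by (1) drawing i.i.d. Gaussian noise per grid
bin, (2) removing all modulation energy above 3 cycles/octave with a
brickwall real-FFT filter along the log2-frequency axis, and
(3) rescaling to an RMS of exactly 10 dB.  Normalizing after filtering
makes the RMS target exact; the hard cutoff makes the band limit testable
to numerical precision.  The modulation-domain distribution of the
source is white Gaussian — the minimal assumption, since nothing in the
procedure constrains modulation-domain shaping below the cutoff.
Zero-crossing spacing (the width of surviving peaks/notches) is
reported by a diagnostic, `feature_width_check`, using linear
interpolation between bins; it is a report, not a constraint, because
sums of band-limited components can in principle cross faster than the
1/6-octave half-period of the cutoff.

The Nyquist requirement (grid step ≤ 1/6 octave) is enforced where it
physically applies — in the vector generator — rather than in the grid
constructor, so coarse grids remain usable for band statistics.

## Directional templates

Templates stand in for the direction-dependent spectral filtering of the
head and external ear: one profile per speaker, smooth (≤ 3
cycles/octave), with across-location variability confined to high
frequencies (default: ~0 dB below 4 kHz, 6 dB SD above — the band where
human spectral cues are prominent).  They are constructed by alternating
projection (8 rounds) between the per-bin across-location statistics
(zero mean, SD equal to a prominence mask with a half-cosine transition
ending at the split) and the band limit.  The band limit here uses a DCT
(symmetric-extension) brickwall rather than the circular FFT: a circular
transform wraps the prominence step around the grid edges and its
ringing destroys both the low-band quiescence and the SD target, whereas
under mirror extension the final templates hold the SD within roughly
[5.5, 6.5] dB above the split with < 0.4 dB leakage below the
transition, and are exactly band-limited in the symmetric-extension
sense.

The 6 dB prominence is deliberately moderate.  It was chosen, together
with the listener parameters below, so that the generator actually
exhibits the phenomenon the reverse-correlation analysis measures: with
much stronger templates (10+ dB) the spectral evidence is so decisive
that the 10 dB RMS randomization vector almost never changes a response,
and the response-triggered average carries no detectable footprint at
realistic trial counts.

## The synthetic listener

The listener is a generative stand-in, not a mechanistic claim.  On each
trial it samples a response from a posterior over the 12 speakers that
multiplies:

* a Gaussian likelihood on the front-back-collapsed azimuth with mean
  `collapse(target) + bias_s · open_sign` and SD `binaural_sd_deg`
  (default 45°).  `bias_s` interpolates linearly from 40° to 5° across
  sessions: the latent attraction toward the open ear shrinks as
  binaural remapping proceeds.  The *observed* mean signed error is
  substantially smaller than the latent bias because responses are
  confined to the ±90° collapsed lattice;
* a spectral likelihood ∝ exp(w_s · similarity), where similarity is the
  negative variance-weighted mean squared difference between the
  spectrum at the ear (stimulus profile + template of the true source)
  and each candidate's template, with per-bin weights proportional to
  the across-location template variance (so only cue-bearing bins
  count).  w_s interpolates linearly from 0 to 0.5 per weighted dB²:
  spectral reliance grows from nothing (cue reweighting).

Tones carry no spectral term; their front/rear hemifield is chosen
wrongly with probability 0.25, and all trials lapse to a uniform
response with probability 0.02.  Defaults were fixed once, during
design, to the regime that expresses every qualitative pattern the
analyses must detect — flat-spectrum performance improving faster than
random-spectrum (whose vectors mislead a spectrum-using listener), tone
bias and error declining, and a reverse-correlation footprint confined
to the template band.  Because the footprint saturates quickly in w, the
reliance schedule must start near zero for the session-1-referenced
reweighting estimate to register a change; the accompanying consequence
— a steep early performance jump — is accepted as part of this minimal
linear-schedule model.

Sessions hold exactly `trials_per_session` standard trials (default
800), half flat-spectrum, the rest split evenly between random-spectrum
noise and tones (1/2/4/8 kHz uniform), levels roved over 49–77 dB SPL in
7 dB steps.  Feedback exists only for flat-spectrum trials; an error
there appends a correction trial (same stimulus), and a second error an
easy trial.  Correction/easy trials are labeled and excluded from all
scoring by default (a flag includes them): the repetition of a just-missed
stimulus would otherwise double-count errors.  The ~800 trials per
session are therefore standard trials, with correction/easy extra.

What the generator does **not** emulate: measured head-related transfer
functions, earplug acoustics at the signal level (attenuation/delay),
attention or learning within a session, head movements on easy trials,
and any coupling between remapping and reweighting.  Passing the
recovery tests therefore shows that the estimators detect the structure
they target at realistic sample sizes — not that real listeners obey
this decision model.

## Behavioral scoring

Front-back collapse: θ ↦ θ for |θ| ≤ 90°, else sign(θ)·(180° − |θ|);
180° ↦ 0°.  Percent correct uses the exact-speaker criterion (chance
100/12), so front-back confusions count as errors for noise; error
magnitude and bias use the collapsed scale, which removes them.  The
circular (non-collapsed) error min(|Δ|, 360° − |Δ|) is available for
comparison and exhaustively dominates the collapsed error over all 144
speaker pairs.

Tone classes: per frequency, plus `tone_low` (1 kHz, ITD-dominated),
`tone_high` (2/4/8 kHz pooled, ILD-dominated; the 1.5 kHz boundary is
the conventional duplex split) and `tone_all`.  A separate 4 kHz split
is used when comparing remapping with reweighting band-wise, matching
the reweighting band boundary.

Adaptation slopes are ordinary least squares of the per-session score on
the session index coded 1…n (the coding affects intercepts only).
`AdaptationModel.fit` attaches percentile bootstrap CIs obtained by
resampling trials with replacement within each session × class cell and
refitting; the slope distributions are stored so CIs at any level can be
read off (joint null checks across several slopes use Bonferroni-widened
levels).  z-standardization of cross-measure values uses the population
(divide-by-n) SD, consistently here and in the neural module.

## Reverse correlation

For each session and response location with at least `min_trials`
(default 10) random-spectrum trials, the triggered mean of the stored
randomization vectors is thresholded at its own mean ± 1.5 SD, the
statistics taken per location across that location's frequency bins
(a degenerate SD of 0 zeroes the row).  Sub-threshold bins are set to 0
— not dropped — so location averaging keeps a fixed denominator;
locations below `min_trials` are flagged missing and excluded from the
strength denominator rather than zero-filled, which would dilute
strength for rarely chosen locations.  Correct and incorrect trials both
enter the averaging.

Feature strength is the mean unsigned thresholded value across
non-missing locations; cue reweighting per bin is the mean of
(strength_s − strength_1) over s = 2…n, summarized also as band averages
below/above 4 kHz.  The null distribution shuffles response labels
across trials *within each session* and recomputes the whole pipeline;
this preserves per-location trial counts and the marginal stimulus
ensemble, so the observed statistic is exchangeable with the permuted
ones under "responses do not depend on spectra".  The 95th percentile
per bin (and per band) is the significance bound; with ≥ 100
permutations required.  Calibration on spectrum-independent listeners
puts the per-bin exceedance at ~5%, which also means a handful of
isolated "significant" bins outside the cue band is expected behavior,
not a defect; the band-level bound is the robust summary.

## Resampling inference

* **Bootstrap CI**: percentile method (no BCa), default 10,000
  resamples.  The CI is widened to include the point estimate in the
  rare discrete edge case.  At n = 50 the percentile interval's true
  coverage is slightly below nominal (~93–94% at 95%), a well-known
  small-sample property of the method.
* **Group test**: the two samples are pooled; each resample draws two
  new samples of the original sizes with replacement from the pool and
  recomputes the statistic (mean difference, pooled-variance t, or
  rank-sum), giving the null ensemble.  Two-sidedness is extremity of
  |statistic − null center|, with the add-one correction
  p = (k+1)/(n+1) so p is never exactly zero.  The paired variant
  centers the within-subject differences and resamples them against
  zero.
* **Permutation ANOVA**: a two-way linear model with effect coding;
  F per effect from partial sums of squares (residual-projection form,
  so each permutation is a matrix product; F values match a standard
  Type-II ANOVA table exactly on balanced designs).  Observations are
  freely permuted across all cells; under an additive truth the
  interaction test is approximately (not exactly) exact — calibration
  runs put it within a couple of points of 5%.
* Cohen's d uses the pooled ddof-1 SD; Bonferroni is min(1, m·p).

All routines are deterministic under a fixed seed.

## Cortical tuning and the band × process comparison

`estimate_tuning` averages the 30 repetitions, smooths along frequency
with a 0.75-octave boxcar (3 bins at ¼-octave sampling; the window is
truncated — not padded — at the range edges, and a window narrower than
one bin is the identity), subtracts the spontaneous rate, and masks the
driven rate below 20% of its maximum (values above keep their
magnitude).  Interpreting the cut relative to the *driven* maximum makes
the whole estimate exactly invariant to adding a constant to all rates
and the spontaneous rate together.  Threshold is the lowest level with
any supra-mask response; CF is the frequency of the largest response at
that level (ties to the lower frequency); bandwidth at threshold + 10 dB
is the trapezoid area of the masked curve against log2 frequency divided
by its peak — the width of the equal-area rectangle.

For noiseless Gaussian tuning of width σ this equal-area width is
σ√(2π) ≈ 1.064 × FWHM.  In the pipeline two systematic biases act in
opposite directions: boxcar smoothing preserves area but lowers the peak
(widening the estimate), while the 20% mask truncates the tails
(narrowing it).  Around σ = 0.5–1 octave they nearly cancel (estimates
within ~5% of σ√(2π)); below σ ≈ 0.4 octave the smoothing bias dominates
and the estimate is substantially wide (≈ +30% at σ = 0.25).  Bandwidths
near the sampling/smoothing scale should therefore be read as upper
bounds.

`best_ild` returns the ILD at the peak of the binaural interaction
function, ties resolved toward 0 dB, with warnings for flat or monotone
(boundary-peaked) functions.

Plugged and control units' best ILDs and weighting indices are z-scored
with the control mean and population SD of their hemisphere × CF-band
cell (split 8 kHz, where ferret spectral cues become prominent;
configurable), then each measure is re-standardized to overall mean 0
and variance 1 — an affine step that preserves unit order and
between-measure correlations while making remapping and reweighting
magnitudes comparable.  The mutual-information weighting index itself is
consumed as a number, never computed from spike trains.  The
band × process interaction is tested with the permutation ANOVA on the
long-format (unit, band, measure, value) table of plugged units, with
bootstrap high-vs-low band contrasts per measure, Bonferroni-corrected.

One caveat measured during development: because z-scoring uses a
*finite* control sample, the estimated cell SDs carry sampling error
that shifts whole cells coherently — structure the unit-level
permutation null cannot represent.  With ~50 controls per cell this
inflates the interaction test's Type-I rate severely (tens of percent);
with ~500 per cell it is within a few points of nominal.  Calibration
claims are therefore made with large control samples, and analyses of
small control groups should treat marginal interaction p-values with
caution.

## Synthetic neural population and FRAs

Control units draw best ILD from hemisphere-specific Gaussians
(contralateral preference, SD 8 dB) and weighting index from band-specific
Gaussians (SD 0.15); CFs are log-uniform on 0.5–32 kHz, hemispheres
alternate so every cell is populated.  Plugged units add a best-ILD
shift (in control SD units) at all CFs and a weighting-index shift only
above the CF split; the two per-unit deviations are independent draws,
so their population correlation is zero by construction — the package's
analogue of remapping and reweighting being expressed in different
neurons.  `simulate_fra` builds Gaussian-tuned V-shaped response areas
(rate-level function: 0 below threshold, 0.3 at threshold, saturating to
1 at 10 dB above) with Poisson-like repetition noise (Gaussian,
SD = noise_sd·√mean, clipped at 0); `noise_sd = 0` gives the exact mean,
which is what the closed-form tuning checks use.

## Problem sizes and reproducibility

Default analysis sizes follow the study design they emulate: 7 sessions
× 800 trials, 12 speakers, 10,000 bootstrap resamples (library default;
demo runs and calibration suites use 500–2,000), 200–1,000 permutations
for the reverse-correlation and factorial nulls, and populations of
~500 plugged units.  Calibration suites use 300–500 simulations with
reduced resample counts — enough for binomial tolerances of two to three
points around the nominal rates.  Every stochastic routine takes a seed;
the CLI derives per-stage sub-seeds by hashing (global seed, stage
name), so a rerun with the same config reproduces every numeric table
byte for byte and stages can be rerun independently.

## Known limitations

* The listener's linear schedules and posterior form are conveniences;
  only the qualitative patterns they generate are meaningful.
* The reverse-correlation estimator's absolute dB scale depends on
  trial counts and thresholding; only its frequency profile and change
  across sessions are interpretable (and the map scale need not match
  any physical transfer function).
* The percentile bootstrap is mildly anticonservative at small n; the
  free-permutation interaction test is approximate under strong main
  effects and is sensitive to control-sample normalization noise (see
  above).
* Equal-area bandwidths below ~0.4 octave are inflated by the mandated
  0.75-octave smoothing.
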