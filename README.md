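# plugadapt

Tools for quantifying how listeners adapt to a unilateral earplug during
sound-localization training, and for the matching auditory-cortex analyses.

When one ear is occluded, two adaptive processes can restore localization:

* **cue remapping** — learning the new correspondence between altered
  binaural cues (ILD/ITD) and space, visible as a shrinking response bias
  toward the open ear;
* **cue reweighting** — relying more on the intact spectral (pinna) cues
  of the open ear, visible as a growing influence of high-frequency
  spectral features on responses.

`plugadapt` implements the full analysis chain used to separate the two
processes, plus synthetic-data generators (an adapting model listener and
a model cortical population) so every stage is testable without any
external data:

| stage | module | what it does |
|---|---|---|
| stimulus construction | `plugadapt.spectra` | flat/random-spectrum noise and tones as log-spectral profiles on a log-frequency grid; the randomization vector is band-limited Gaussian noise (≤ 3 cycles/octave) normalized to 10 dB RMS |
| synthetic experiments | `plugadapt.synthdata` | 12-speaker ring (30° spacing), 7 sessions × 800 trials (~50% flat-spectrum with feedback, correction/easy trials after errors), a posterior-sampling listener with session-linear bias and spectral-weight schedules, and a control/plugged cortical population with frequency-response areas |
| behavioral scoring | `plugadapt.behavior` | front-back-collapsed % correct, mean unsigned error and signed bias per session and stimulus class; OLS adaptation slopes with bootstrap CIs (`AdaptationModel`) |
| reverse correlation | `plugadapt.revcorr` | response-triggered mean spectra, mean ± 1.5 SD thresholding, feature-strength profiles, training-induced reweighting with a within-session permutation null (`SpectralReweightingModel`) |
| resampling inference | `plugadapt.stats` | percentile bootstrap CIs, pooled-resampling group tests (mean difference / t / rank-sum), two-way permutation ANOVA, Cohen's d, Bonferroni |
| cortical tuning | `plugadapt.neuro` | CF, threshold and equal-area bandwidth from frequency-response areas; best ILD; control-referenced z-scoring and the CF-band × process comparison (`CuePlasticityModel`) |
| orchestration | `plugadapt.cli` | `plugadapt simulate / score / revcorr / neuro / report / stats selftest` with YAML configs and derived sub-seeds |

## The measures

With speaker azimuths θ ∈ (−180°, 180°], front-back collapsing maps
θ ↦ θ for |θ| ≤ 90° and θ ↦ sign(θ)·(180° − |θ|) otherwise, so the 12
speakers fold onto 7 positions and front-back confusions (a spectral-cue
failure) do not contaminate the binaural measures.  Per session *s* and
stimulus class, the package scores

* % correct (exact-speaker criterion, chance = 100/12 ≈ 8.33%),
* error magnitude  ⟨|collapse(resp) − collapse(target)|⟩,
* bias  ⟨collapse(resp) − collapse(target)⟩, sign-flipped so + points
  toward the open ear,

and fits each against *s* = 1…7 by ordinary least squares: the slopes are
the **adaptation rate** (%/session), **Δ error** and **Δ bias**
(deg/session; improvement ⇒ negative).

Reweighting is estimated by reverse correlation on random-spectrum
trials: the mean randomization vector conditioned on each response
location is thresholded at its mean ± 1.5 SD (across frequency bins);
**feature strength** is the mean |thresholded value| across locations,
and **cue reweighting** per frequency is the average of sessions 2…n
feature strength minus session 1, referred to the 95th percentile of the
same quantity under within-session shuffling of response labels.

For cortical units, frequency tuning comes from a frequency-response
area (0.5–32 kHz in ¼-octave steps, 30–80 dB SPL in 10 dB steps, 30
repetitions): repetition average, 0.75-octave boxcar smooth, threshold at
spontaneous + 20% of the maximum driven rate; CF is the frequency with
the greatest response at threshold and bandwidth 10 dB above threshold is
the equal-area rectangle width (area under the tuning curve ÷ peak rate
≈ 1.064 × FWHM for Gaussian tuning).  Best-ILD and weighting-index values
are z-scored against controls per hemisphere × CF band (split 8 kHz),
re-standardized to overall mean 0 / variance 1, and compared with a
band × process permutation ANOVA.

## Worked example

```python
from plugadapt import synthdata, AdaptationModel, SpectralReweightingModel

params = synthdata.ListenerParams(seed=42)          # adapting listener, left plug
data = synthdata.simulate_experiment(params)        # 7 sessions x 800 trials

res = AdaptationModel(data.trials, plug_side="left").fit(n_boot=1000, seed=0)
print(res.summary())

rc = SpectralReweightingModel(data.trials, data.profiles, data.grid).fit(
    n_perm=500, seed=0
)
print(rc.summary())
```

prints (abridged):

```
Behavioral adaptation summary
  plug side: left; bootstrap: 1000 resamples
  class     measure                slope                95% CI
  flat      adaptation_rate       +9.482      [+9.000, +9.920]
  random    adaptation_rate       +5.607      [+4.518, +6.679]
  tone_all  delta_error           -1.227      [-1.977, -0.445]
  tone_all  delta_bias            -3.434      [-4.645, -2.223]

Spectral-cue reweighting (reverse correlation)
  sessions: 7; permutations: 500
  band split: 4.0 kHz
  delta feature strength  <split: -0.1551 dB (null95 +0.1354, significant=False)
  delta feature strength >=split: +0.4299 dB (null95 +0.2313, significant=True)
  significant bins: 14/128
```

Reading it: flat-spectrum performance improves ~9.5 %/session — faster
than random-spectrum (~5.6 %/session), whose spectral content misleads
the listener; tone bias declines ~3.4°/session toward zero (remapping);
and feature strength grows significantly only above 4 kHz, where the
directional templates carry spectral cues (reweighting).

The same pipeline runs from the shell:

```bash
plugadapt report --seed 42 --out runs/demo        # simulate -> score -> revcorr -> neuro
plugadapt stats selftest                          # quick calibration check
```

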