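"""Synthetic experiments: an adapting earplugged listener and a cortical population.

The behavioral generator emulates the structure of a unilateral-earplug
training study: a 12-speaker ring at 30 degree spacing, ~7 sessions of
~800 trials each, about half of them flat-spectrum broadband noise (the
only stimuli with feedback), the remainder split between random-spectrum
noise and pure tones (1-8 kHz in octave steps), with correction and easy
trials appended after errors on feedback trials.

The listener's decision model is deliberately minimal.  On each trial a
posterior over the 12 speakers combines

* a Gaussian binaural likelihood on the front-back-collapsed azimuth,
  whose mean is displaced toward the open ear by a session-dependent bias
  (the bias shrinks linearly across sessions as binaural remapping
  proceeds), and
* a spectral likelihood proportional to ``exp(w_s * similarity)`` between
  the spectrum observed at the ear (stimulus profile plus the directional
  template of the true source) and each candidate location's template,
  with the weight w_s growing linearly across sessions (cue reweighting).

Tones carry no usable spectral profile: their spectral term is flat and
the front/rear hemifield is chosen wrongly with a fixed confusion
probability.  A small lapse rate makes responses occasionally uniform.

Directional templates play the role of head-related spectral cues: smooth
(<= 3 cycles/octave) location-specific profiles whose across-location
variability is confined to frequencies above a split (4 kHz for the
human-like default), where real spectral cues are prominent.

The neural generator draws control and plugged cortical units with a
characteristic frequency, a spectral-cue weighting index, and a best ILD.
Plugged units have their best ILD shifted at all CFs (cue remapping) and
their weighting index shifted only above a CF split (8 kHz, where ferret
spectral cues live; cue reweighting).  ``simulate_fra`` builds noiseless
or noisy frequency-response areas for the tuning-curve estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import (
    DEFAULT_CUTOFF_CPO,
    LEVELS_DB_SPL,
    TONE_FREQS_HZ,
    FrequencyGrid,
    SpectralProfile,
    StimulusSpec,
    _modulation_lowpass_sym,
    _rng_from,
    default_grid,
    generate_random_vector,
)

__all__ = [
    "SPEAKER_AZIMUTHS_DEG",
    "SpeakerArray",
    "DirectionalTemplates",
    "ListenerParams",
    "ExperimentData",
    "make_templates",
    "simulate_trial",
    "simulate_experiment",
    "simulate_neuro_population",
    "simulate_fra",
    "TuningMatrix",
    "write_trials",
    "read_trials",
]

#: The 12 loudspeaker azimuths, degrees (0 = straight ahead, + = right).
SPEAKER_AZIMUTHS_DEG = np.array(
    [-150.0, -120.0, -90.0, -60.0, -30.0, 0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0]
)

TRIAL_COLUMNS = [
    "session",
    "trial_index",
    "trial_class",
    "kind",
    "tone_freq_hz",
    "level_db_spl",
    "target_deg",
    "response_deg",
    "feedback",
    "profile_id",
]


@dataclass(frozen=True)
class SpeakerArray:
    """Ring of 12 loudspeakers at 30 degree intervals."""

    azimuths_deg: np.ndarray = field(
        default_factory=lambda: SPEAKER_AZIMUTHS_DEG.copy()
    )

    def __post_init__(self) -> None:
        az = np.sort(np.asarray(self.azimuths_deg, dtype=float))
        object.__setattr__(self, "azimuths_deg", az)
        if az.size != 12 or not np.allclose(np.diff(az), 30.0):
            raise ValueError("speaker array must have 12 speakers at 30 deg spacing")
        if not (np.all(az > -180.0) and np.all(az <= 180.0)):
            raise ValueError("azimuths must lie in (-180, 180]")


@dataclass(frozen=True)
class DirectionalTemplates:
    """One spectral template per speaker: the stand-in for HRTF spectral cues.

    ``profiles_db`` is a (12, n_freq) array, row order matching
    ``array.azimuths_deg``.  Across-location variability per bin is about
    ``prominence_low`` dB below ``split_hz`` and ``prominence_high`` above.
    """

    grid: FrequencyGrid
    array: SpeakerArray
    profiles_db: np.ndarray
    prominence_low: float
    prominence_high: float
    split_hz: float

    def __post_init__(self) -> None:
        p = np.asarray(self.profiles_db, dtype=float)
        object.__setattr__(self, "profiles_db", p)
        if p.shape != (self.array.azimuths_deg.size, self.grid.n):
            raise ValueError("profiles_db must be (n_speakers, n_freq)")

    def profile_for(self, azimuth_deg: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.array.azimuths_deg - azimuth_deg)))
        if abs(self.array.azimuths_deg[idx] - azimuth_deg) > 1e-6:
            raise ValueError(f"{azimuth_deg} is not a speaker azimuth")
        return self.profiles_db[idx]


def make_templates(
    grid: FrequencyGrid | None = None,
    array: SpeakerArray | None = None,
    prominence_low: float = 0.0,
    prominence_high: float = 6.0,
    split_hz: float = 4000.0,
    seed: int | np.random.Generator = 0,
    transition_oct: float = 1.0 / 3.0,
    n_iter: int = 8,
) -> DirectionalTemplates:
    """Generate smooth location-specific spectral templates.

    Construction: independent band-limited noise per location, then
    ``n_iter`` rounds of alternating projection between (a) the per-bin
    constraint -- zero mean and SD equal to a prominence mask across
    locations (half-cosine ramp of ``transition_oct`` octaves ending at
    ``split_hz``, so every bin at or above the split carries full
    ``prominence_high``) -- and (b) the 3 cycles/octave band limit under
    symmetric extension.  Ending on the filter step makes the band limit
    exact while the across-location SD stays close to the mask.
    """
    if prominence_low < 0 or prominence_high < 0:
        raise ValueError("prominences must be nonnegative")
    grid = grid if grid is not None else default_grid()
    array = array if array is not None else SpeakerArray()
    rng = _rng_from(seed)
    n_loc = array.azimuths_deg.size
    if prominence_low == 0.0 and prominence_high == 0.0:
        return DirectionalTemplates(
            grid=grid,
            array=array,
            profiles_db=np.zeros((n_loc, grid.n)),
            prominence_low=0.0,
            prominence_high=0.0,
            split_hz=split_hz,
        )
    u = np.log2(grid.frequencies)
    u0 = np.log2(split_hz)
    # half-cosine ramp on [u0 - transition, u0]; full prominence at u >= u0
    ramp = np.clip((u - (u0 - transition_oct)) / transition_oct, 0.0, 1.0)
    ramp = 0.5 - 0.5 * np.cos(np.pi * ramp)
    mask = prominence_low + (prominence_high - prominence_low) * ramp
    profiles = _modulation_lowpass_sym(
        rng.standard_normal((n_loc, grid.n)), grid.spacing_oct, DEFAULT_CUTOFF_CPO
    )
    for _ in range(n_iter):
        profiles = profiles - profiles.mean(axis=0, keepdims=True)
        sd = profiles.std(axis=0)
        profiles = profiles / np.where(sd > 1e-9, sd, 1.0) * mask
        profiles = _modulation_lowpass_sym(
            profiles, grid.spacing_oct, DEFAULT_CUTOFF_CPO
        )
    return DirectionalTemplates(
        grid=grid,
        array=array,
        profiles_db=profiles,
        prominence_low=prominence_low,
        prominence_high=prominence_high,
        split_hz=split_hz,
    )


@dataclass(frozen=True)
class ListenerParams:
    """Generative parameters of the simulated earplugged listener.

    Session schedules are linear: the open-ear bias runs from
    ``bias_start_deg`` to ``bias_end_deg`` (collapsed-azimuth degrees) and
    the spectral weight from ``spectral_weight_start`` to
    ``spectral_weight_end`` (per dB^2 of weighted spectral mismatch) across
    ``n_sessions`` sessions.
    """

    plug_side: str = "left"
    n_sessions: int = 7
    trials_per_session: int = 800
    frac_flat: float = 0.5
    bias_start_deg: float = 40.0
    bias_end_deg: float = 5.0
    binaural_sd_deg: float = 45.0
    spectral_weight_start: float = 0.0
    spectral_weight_end: float = 0.5
    tone_fb_confusion: float = 0.25
    lapse_rate: float = 0.02
    seed: int = 0
    template_set: DirectionalTemplates | None = None

    def __post_init__(self) -> None:
        if self.plug_side not in ("left", "right"):
            raise ValueError("plug_side must be 'left' or 'right'")
        if self.n_sessions < 2:
            raise ValueError("need at least 2 sessions")
        for p in (self.frac_flat, self.tone_fb_confusion, self.lapse_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.bias_start_deg) > 90 or abs(self.bias_end_deg) > 90:
            raise ValueError("bias magnitudes must be <= 90 deg")
        if self.spectral_weight_start < 0 or self.spectral_weight_end < 0:
            raise ValueError("spectral weights must be nonnegative")
        if self.binaural_sd_deg < 0:
            raise ValueError("binaural_sd_deg must be nonnegative")

    @property
    def open_sign(self) -> float:
        """+1 if the open ear is on the right (left plug), else -1."""
        return 1.0 if self.plug_side == "left" else -1.0

    def templates(self) -> DirectionalTemplates:
        if self.template_set is not None:
            return self.template_set
        return make_templates(seed=self.seed + 101)

    def session_bias(self, session: int) -> float:
        frac = (session - 1) / (self.n_sessions - 1)
        return self.bias_start_deg + frac * (self.bias_end_deg - self.bias_start_deg)

    def session_weight(self, session: int) -> float:
        frac = (session - 1) / (self.n_sessions - 1)
        return self.spectral_weight_start + frac * (
            self.spectral_weight_end - self.spectral_weight_start
        )


def _collapse(az: np.ndarray | float) -> np.ndarray | float:
    """Fold rear hemifield onto front: theta -> sign(theta) * (180 - |theta|)."""
    az = np.asarray(az, dtype=float)
    out = np.where(np.abs(az) <= 90.0, az, np.sign(az) * (180.0 - np.abs(az)))
    return out if out.ndim else float(out)


def _template_bin_weights(templates: DirectionalTemplates) -> np.ndarray:
    """Per-bin weights for spectral similarity: across-location variance."""
    v = templates.profiles_db.var(axis=0)
    total = v.sum()
    if total <= 0:
        return np.full(templates.grid.n, 1.0 / templates.grid.n)
    return v / total


def _spectral_similarity(
    observed: np.ndarray, templates: DirectionalTemplates, weights: np.ndarray
) -> np.ndarray:
    """Negative weighted mean squared difference to each location's template."""
    diff = observed[None, :] - templates.profiles_db
    return -np.sum(weights[None, :] * diff**2, axis=1)


def simulate_trial(
    params: ListenerParams,
    session: int,
    stimulus: StimulusSpec,
    target_deg: float,
    rng: int | np.random.Generator = 0,
    templates: DirectionalTemplates | None = None,
    _weights: np.ndarray | None = None,
) -> float:
    """Draw one response from the listener's posterior over the 12 speakers."""
    rng = _rng_from(rng)
    templates = templates if templates is not None else params.templates()
    weights = _weights if _weights is not None else _template_bin_weights(templates)
    speakers = templates.array.azimuths_deg

    if rng.random() < params.lapse_rate:
        return float(rng.choice(speakers))

    c_speakers = _collapse(speakers)
    mu = _collapse(target_deg) + params.session_bias(session) * params.open_sign
    sd = params.binaural_sd_deg
    if sd == 0:
        log_bin = np.where(np.isclose(c_speakers, mu), 0.0, -np.inf)
        if np.all(np.isneginf(log_bin)):
            # degenerate likelihood off the speaker lattice: take the nearest
            nearest = np.abs(c_speakers - mu) == np.abs(c_speakers - mu).min()
            log_bin = np.where(nearest, 0.0, -np.inf)
    else:
        log_bin = -0.5 * ((c_speakers - mu) / sd) ** 2

    if stimulus.kind == "tone":
        log_spec = np.zeros_like(log_bin)
    else:
        observed = stimulus.profile.amp_db + templates.profile_for(target_deg)
        sim = _spectral_similarity(observed, templates, weights)
        log_spec = params.session_weight(session) * sim

    logp = log_bin + log_spec
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    response = float(rng.choice(speakers, p=p))

    if stimulus.kind == "tone":
        # front/rear hemifield is unresolvable for tones: pick the target's
        # hemifield, wrongly with probability tone_fb_confusion
        response = _apply_hemifield(
            response, target_deg, wrong=bool(rng.random() < params.tone_fb_confusion)
        )
    return response


def _apply_hemifield(response: float, target: float, wrong: bool) -> float:
    """Move ``response`` to the target's front/rear hemifield (or its opposite)."""
    c = _collapse(response)
    if abs(c) == 90.0:
        return response  # +-90 have a single speaker
    target_front = abs(target) < 90.0
    want_front = target_front if not wrong else not target_front
    if want_front:
        return float(c)
    # rear speaker with the same collapsed azimuth; collapsed 0 maps to 180
    return float(180.0 if c == 0.0 else np.sign(c) * (180.0 - abs(c)))


@dataclass
class ExperimentData:
    """A simulated training experiment: trial table plus profile store.

    ``trials`` follows the trial-table schema (one row per trial);
    ``profiles`` holds the per-trial spectral randomization vectors, one row
    per ``profile_id``, columns = grid frequencies.
    """

    trials: pd.DataFrame
    profiles: pd.DataFrame
    grid: FrequencyGrid
    params: ListenerParams

    def profile_matrix(self, profile_ids) -> np.ndarray:
        return self.profiles.loc[list(profile_ids)].to_numpy(dtype=float)


def simulate_experiment(params: ListenerParams | None = None) -> ExperimentData:
    """Simulate a full training experiment.

    Each session holds ``trials_per_session`` standard trials
    (``frac_flat`` flat-spectrum, the remainder split evenly between
    random-spectrum noise and tones drawn uniformly from 1/2/4/8 kHz).
    Errors on feedback (flat-spectrum) trials are followed by a correction
    trial with the same stimulus; a second error triggers an easy trial.
    Correction/easy trials are labeled and, by downstream default,
    excluded from scoring.  Deterministic in ``params.seed``.
    """
    params = params if params is not None else ListenerParams()
    rng = np.random.default_rng(params.seed)
    templates = params.templates()
    weights = _template_bin_weights(templates)
    grid = templates.grid
    speakers = templates.array.azimuths_deg

    n = params.trials_per_session
    n_flat = int(round(params.frac_flat * n))
    n_rand = (n - n_flat) // 2
    n_tone = n - n_flat - n_rand

    rows = []
    profile_rows: dict[str, np.ndarray] = {}
    flat_profile = SpectralProfile(grid=grid, amp_db=np.zeros(grid.n))

    for session in range(1, params.n_sessions + 1):
        kinds = np.array(["flat"] * n_flat + ["random"] * n_rand + ["tone"] * n_tone)
        rng.shuffle(kinds)
        trial_index = 0
        for kind in kinds:
            target = float(rng.choice(speakers))
            level = float(rng.choice(LEVELS_DB_SPL))
            tone_freq = float(rng.choice(TONE_FREQS_HZ)) if kind == "tone" else None
            if kind == "random":
                profile = generate_random_vector(grid, seed=rng)
            elif kind == "flat":
                profile = flat_profile
            else:
                profile = None
            stim = StimulusSpec(
                kind=kind, level_db_spl=level, tone_freq_hz=tone_freq, profile=profile
            )
            feedback = kind == "flat"

            def record(trial_class: str, stim=stim, target=target) -> bool:
                nonlocal trial_index
                trial_index += 1
                response = simulate_trial(
                    params, session, stim, target, rng=rng,
                    templates=templates, _weights=weights,
                )
                profile_id = ""
                if stim.kind == "random":
                    profile_id = f"s{session}_t{trial_index}"
                    profile_rows[profile_id] = stim.profile.amp_db
                rows.append(
                    (
                        session,
                        trial_index,
                        trial_class,
                        stim.kind,
                        stim.tone_freq_hz if stim.tone_freq_hz is not None else np.nan,
                        stim.level_db_spl,
                        target,
                        response,
                        feedback,
                        profile_id,
                    )
                )
                return response == target

            correct = record("standard")
            if feedback and not correct:
                correct2 = record("correction")
                if not correct2:
                    record("easy")

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    profiles = pd.DataFrame.from_dict(
        profile_rows, orient="index", columns=[f"{f:.3f}" for f in grid.frequencies]
    )
    profiles.index.name = "profile_id"
    return ExperimentData(trials=trials, profiles=profiles, grid=grid, params=params)


def write_trials(data: ExperimentData, trials_path, profiles_path) -> None:
    """Write the trial table and its companion profile store as CSV."""
    data.trials.to_csv(trials_path, index=False)
    data.profiles.to_csv(profiles_path)


def read_trials(trials_path, profiles_path=None):
    """Read a trial table (and optionally its profile store)."""
    trials = pd.read_csv(
        trials_path, dtype={"profile_id": str}, keep_default_na=False,
        na_values={"tone_freq_hz": [""]},
    )
    trials["feedback"] = trials["feedback"].astype(str).str.lower().isin(["true", "1"])
    if profiles_path is None:
        return trials
    profiles = pd.read_csv(profiles_path, index_col="profile_id")
    return trials, profiles


# ---------------------------------------------------------------------------
# Synthetic cortical population
# ---------------------------------------------------------------------------

#: Baseline unit statistics per hemisphere: (best ILD mean, SD) and
#: (weighting index mean, SD).  Best ILD favors the contralateral ear.
_BASE_ILD = {"left": (8.0, 8.0), "right": (-8.0, 8.0)}
_BASE_WI = {"low": (0.30, 0.15), "high": (0.45, 0.15)}


def simulate_neuro_population(
    n_control: int = 200,
    n_plugged: int = 500,
    remap_shift_sd_units: float = 1.0,
    reweight_shift_sd_units: float = 1.0,
    cf_split_hz: float = 8000.0,
    seed: int | np.random.Generator = 0,
    cf_range_hz: tuple[float, float] = (500.0, 32000.0),
) -> pd.DataFrame:
    """Draw a synthetic population of cortical units.

    Control units come from fixed baseline distributions per hemisphere and
    CF band.  Plugged units additionally receive a best-ILD shift
    (``remap_shift_sd_units`` control SDs, all CFs) and a weighting-index
    shift (``reweight_shift_sd_units`` control SDs, only CF >
    ``cf_split_hz``).  The two per-unit deviations are drawn independently,
    so their population correlation is zero by construction.
    """
    rng = _rng_from(seed)
    frames = []
    for group, count in (("control", n_control), ("plugged", n_plugged)):
        # alternate hemispheres so every hemisphere x band cell is populated
        hemis = np.array(["left", "right"])[np.arange(count) % 2]
        rng.shuffle(hemis)
        lo, hi = np.log2(cf_range_hz[0]), np.log2(cf_range_hz[1])
        cfs = 2.0 ** rng.uniform(lo, hi, size=count)
        high = cfs > cf_split_hz
        ild_mu = np.where(hemis == "left", _BASE_ILD["left"][0], _BASE_ILD["right"][0])
        ild_sd = np.where(hemis == "left", _BASE_ILD["left"][1], _BASE_ILD["right"][1])
        wi_mu = np.where(high, _BASE_WI["high"][0], _BASE_WI["low"][0])
        wi_sd = np.where(high, _BASE_WI["high"][1], _BASE_WI["low"][1])
        ild = ild_mu + ild_sd * rng.standard_normal(count)
        wi = wi_mu + wi_sd * rng.standard_normal(count)
        if group == "plugged":
            ild = ild + remap_shift_sd_units * ild_sd
            wi = wi + np.where(high, reweight_shift_sd_units * wi_sd, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "unit_id": [f"{group[0]}{i:04d}" for i in range(count)],
                    "hemisphere": hemis,
                    "group": group,
                    "cf_hz": cfs,
                    "weighting_index": wi,
                    "best_ild_db": ild,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    _check_control_cells(df, cf_split_hz)
    return df


def _check_control_cells(df: pd.DataFrame, cf_split_hz: float) -> None:
    ctrl = df[df["group"] == "control"]
    band = np.where(ctrl["cf_hz"] > cf_split_hz, "high", "low")
    counts = ctrl.groupby([ctrl["hemisphere"], band]).size()
    if (counts < 2).any() or len(counts) < 4:
        raise ValueError("need >= 2 control units per hemisphere x CF-band cell")


# ---------------------------------------------------------------------------
# Frequency-response areas
# ---------------------------------------------------------------------------

#: Tone frequencies for tuning measurement: 0.5-32 kHz in 0.25-octave steps.
FRA_FREQS_HZ = 500.0 * 2.0 ** (0.25 * np.arange(25))
#: Tone levels: 30-80 dB SPL in 10 dB steps.
FRA_LEVELS_DB = np.arange(30.0, 90.0, 10.0)
FRA_N_REPS = 30


@dataclass(frozen=True)
class TuningMatrix:
    """Frequency x level x repetition firing rates plus the spontaneous rate."""

    freqs_hz: np.ndarray
    levels_db: np.ndarray
    rates: np.ndarray  # (n_freq, n_level, n_rep), spikes/s
    spontaneous_rate: float

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", r)
        if r.shape[:2] != (len(self.freqs_hz), len(self.levels_db)):
            raise ValueError("rates shape inconsistent with freqs/levels")
        if np.any(r < 0):
            raise ValueError("firing rates must be nonnegative")


def _level_gain(levels_db: np.ndarray, threshold_db: float) -> np.ndarray:
    """Rate-level function: 0 below threshold, 0.3 at threshold, 1 from
    10 dB above threshold upward."""
    g = np.where(
        levels_db < threshold_db,
        0.0,
        np.clip(0.3 + 0.07 * (levels_db - threshold_db), 0.0, 1.0),
    )
    return g


def simulate_fra(
    cf_hz: float,
    bandwidth_sigma_oct: float = 0.5,
    threshold_db: float = 40.0,
    max_rate: float = 50.0,
    spontaneous_rate: float = 2.0,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    n_reps: int = FRA_N_REPS,
) -> TuningMatrix:
    """Simulate a V-shaped frequency-response area with Gaussian tuning.

    Mean rate = spontaneous + max_rate * G(level) * exp(-d^2 / (2 sigma^2))
    with d the CF distance in octaves and G a saturating rate-level
    function.  Repetition noise is Poisson-like: Gaussian with SD
    ``noise_sd * sqrt(mean)``, clipped at zero.  ``noise_sd = 0`` returns
    the exact mean on every repetition.
    """
    if not (FRA_FREQS_HZ[0] <= cf_hz <= FRA_FREQS_HZ[-1]):
        raise ValueError("cf_hz outside the stimulus range")
    if max_rate < 0 or spontaneous_rate < 0:
        raise ValueError("rates must be nonnegative")
    rng = _rng_from(seed)
    d_oct = np.log2(FRA_FREQS_HZ / cf_hz)
    tuning = np.exp(-(d_oct**2) / (2.0 * bandwidth_sigma_oct**2))
    gain = _level_gain(FRA_LEVELS_DB, threshold_db)
    mean = spontaneous_rate + max_rate * tuning[:, None] * gain[None, :]
    reps = np.repeat(mean[:, :, None], n_reps, axis=2)
    if noise_sd > 0:
        reps = reps + noise_sd * np.sqrt(np.maximum(mean[:, :, None], 1e-12)) * (
            rng.standard_normal(reps.shape)
        )
        reps = np.clip(reps, 0.0, None)
    return TuningMatrix(
        freqs_hz=FRA_FREQS_HZ.copy(),
        levels_db=FRA_LEVELS_DB.copy(),
        rates=reps,
        spontaneous_rate=float(spontaneous_rate),
    )
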