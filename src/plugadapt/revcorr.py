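"""Reverse-correlation estimate of spectral-cue reweighting.

Random-spectrum trials carry a stored spectral randomization vector.
Averaging those vectors over the trials on which the listener responded
to a particular location (the response-triggered mean) reveals the
spectral features that drive responses toward that location.  Each
location's triggered mean is denoised with a mean +- 1.5 SD threshold
(statistics taken across that location's frequency bins; sub-threshold
bins are set to zero, supra-threshold bins keep their signed value),
yielding a reverse correlation map (RCM).

"Feature strength" is the mean unsigned magnitude of the thresholded map
across response locations, per frequency bin.  Training-induced cue
reweighting is the average change of feature strength in sessions 2..n
relative to session 1.  Its significance is assessed against a
permutation null built by shuffling response-location labels across
trials within each session (which preserves per-location trial counts
and the marginal stimulus ensemble): the upper 95% bound of the permuted
reweighting values, per bin and per frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import FrequencyGrid, SpectralProfile
from .synthdata import SPEAKER_AZIMUTHS_DEG

__all__ = [
    "RCMap",
    "FeatureStrengthProfile",
    "ReweightingEstimate",
    "response_triggered_mean",
    "build_rcmap",
    "feature_strength",
    "cue_reweighting",
    "reweighting_null",
    "SpectralReweightingModel",
    "ReweightingResults",
]

DEFAULT_THRESHOLD_K = 1.5
DEFAULT_MIN_TRIALS = 10
DEFAULT_SPLIT_HZ = 4000.0


@dataclass(frozen=True)
class RCMap:
    """Reverse correlation map: thresholded triggered means per location."""

    response_locations: np.ndarray
    grid: FrequencyGrid
    values_db: np.ndarray  # (n_locations, n_freq)
    missing: np.ndarray  # bool per location
    n_trials_per_location: np.ndarray
    threshold_k: float


@dataclass(frozen=True)
class FeatureStrengthProfile:
    """Per-frequency mean unsigned RCM magnitude across locations."""

    grid: FrequencyGrid
    strength_db: np.ndarray
    session: int

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.strength_db) < 0):
            raise ValueError("feature strength must be nonnegative")


@dataclass(frozen=True)
class ReweightingEstimate:
    """Training-induced change in feature strength with its permutation null."""

    grid: FrequencyGrid
    delta_strength_db: np.ndarray
    null_upper95_db: np.ndarray | None
    significant: np.ndarray | None
    band_low: float
    band_high: float
    band_low_null95: float | None = None
    band_high_null95: float | None = None
    split_hz: float = DEFAULT_SPLIT_HZ


def _random_trials(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials[(trials["kind"] == "random") & (trials["trial_class"] == "standard")]
    return t


def _profile_matrix(profiles: pd.DataFrame, ids) -> np.ndarray:
    return profiles.loc[list(ids)].to_numpy(dtype=float)


def response_triggered_mean(
    trials: pd.DataFrame,
    profiles: pd.DataFrame,
    grid: FrequencyGrid,
    location: float,
) -> SpectralProfile:
    """Mean randomization vector over random-spectrum trials with the given
    response location."""
    t = _random_trials(trials)
    sel = t[t["response_deg"] == location]
    if len(sel) == 0:
        raise ValueError(f"no random-spectrum trials with response {location}")
    mat = _profile_matrix(profiles, sel["profile_id"])
    return SpectralProfile(grid=grid, amp_db=mat.mean(axis=0))


def _threshold_rows(means: np.ndarray, threshold_k: float) -> np.ndarray:
    """Zero bins within mean +- k*SD of each row; keep signed values outside."""
    m = means.mean(axis=1, keepdims=True)
    s = means.std(axis=1, keepdims=True)
    keep = np.abs(means - m) > threshold_k * s
    return np.where(keep, means, 0.0)


def build_rcmap(
    trials: pd.DataFrame,
    profiles: pd.DataFrame,
    grid: FrequencyGrid,
    threshold_k: float = DEFAULT_THRESHOLD_K,
    min_trials: int = DEFAULT_MIN_TRIALS,
    locations: np.ndarray = SPEAKER_AZIMUTHS_DEG,
) -> RCMap:
    """Reverse correlation map for one session's random-spectrum trials.

    Locations with fewer than ``min_trials`` qualifying trials are flagged
    missing (all-zero rows).  Threshold statistics (mean, SD) are computed
    per location across that location's frequency bins; a location whose
    triggered mean is constant (SD = 0) thresholds to an all-zero row.
    """
    t = _random_trials(trials)
    resp = t["response_deg"].to_numpy(dtype=float)
    mat = _profile_matrix(profiles, t["profile_id"]) if len(t) else np.zeros((0, grid.n))
    values = np.zeros((len(locations), grid.n))
    counts = np.zeros(len(locations), dtype=int)
    missing = np.ones(len(locations), dtype=bool)
    for i, loc in enumerate(locations):
        rows = mat[resp == loc]
        counts[i] = rows.shape[0]
        if counts[i] >= min_trials:
            missing[i] = False
            values[i] = _threshold_rows(rows.mean(axis=0)[None, :], threshold_k)[0]
    return RCMap(
        response_locations=np.asarray(locations, dtype=float),
        grid=grid,
        values_db=values,
        missing=missing,
        n_trials_per_location=counts,
        threshold_k=threshold_k,
    )


def feature_strength(rcmap: RCMap, session: int = 0) -> FeatureStrengthProfile:
    """Mean |RCM| across non-missing locations, per frequency bin."""
    present = ~rcmap.missing
    if not present.any():
        raise ValueError("all RCM rows are missing")
    strength = np.abs(rcmap.values_db[present]).mean(axis=0)
    return FeatureStrengthProfile(grid=rcmap.grid, strength_db=strength, session=session)


def cue_reweighting(
    strengths: list[FeatureStrengthProfile],
    split_hz: float = DEFAULT_SPLIT_HZ,
    null_upper95_db: np.ndarray | None = None,
    band_nulls: tuple[float, float] | None = None,
) -> ReweightingEstimate:
    """Average change in feature strength of sessions 2..n vs session 1."""
    if len(strengths) < 2:
        raise ValueError("need feature strengths from >= 2 sessions")
    grid = strengths[0].grid
    mat = np.stack([s.strength_db for s in strengths])
    delta = (mat[1:] - mat[0]).mean(axis=0)
    low = grid.frequencies < split_hz
    band_low = float(delta[low].mean())
    band_high = float(delta[~low].mean())
    significant = None
    bl95 = bh95 = None
    if null_upper95_db is not None:
        significant = delta > null_upper95_db
    if band_nulls is not None:
        bl95, bh95 = band_nulls
    return ReweightingEstimate(
        grid=grid,
        delta_strength_db=delta,
        null_upper95_db=null_upper95_db,
        significant=significant,
        band_low=band_low,
        band_high=band_high,
        band_low_null95=bl95,
        band_high_null95=bh95,
        split_hz=split_hz,
    )


def _strength_from_codes(
    mat: np.ndarray,
    codes: np.ndarray,
    counts: np.ndarray,
    keep: np.ndarray,
    threshold_k: float,
) -> np.ndarray:
    """Session feature strength from integer response codes.

    ``counts``/``keep`` (per-location trial counts and the min-trials mask)
    are permutation-invariant, so they are computed once by the caller.
    """
    n_loc = counts.size
    onehot = np.zeros((n_loc, codes.size))
    onehot[codes, np.arange(codes.size)] = 1.0
    means = (onehot @ mat)[keep] / counts[keep][:, None]
    thr = _threshold_rows(means, threshold_k)
    return np.abs(thr).mean(axis=0)


def reweighting_null(
    trials: pd.DataFrame,
    profiles: pd.DataFrame,
    grid: FrequencyGrid,
    n_perm: int = 1000,
    seed: int = 0,
    threshold_k: float = DEFAULT_THRESHOLD_K,
    min_trials: int = DEFAULT_MIN_TRIALS,
    split_hz: float = DEFAULT_SPLIT_HZ,
    locations: np.ndarray = SPEAKER_AZIMUTHS_DEG,
):
    """Permutation null for cue reweighting.

    Each permutation shuffles response-location labels across
    random-spectrum trials within every session and recomputes the full
    delta-strength pipeline.  Returns the per-bin upper 95% bound and the
    (low band, high band) 95% bounds of the band-averaged deltas.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable 95% bound")
    rng = np.random.default_rng(seed)
    sessions = sorted(trials["session"].unique())
    if len(sessions) < 2:
        raise ValueError("need >= 2 sessions")
    t = _random_trials(trials)
    locations = np.asarray(locations, dtype=float)
    mats, code_list, count_list, keep_list = [], [], [], []
    for s in sessions:
        ts = t[t["session"] == s]
        mats.append(_profile_matrix(profiles, ts["profile_id"]))
        resp = ts["response_deg"].to_numpy(dtype=float)
        codes = np.argmin(np.abs(resp[:, None] - locations[None, :]), axis=1)
        counts = np.bincount(codes, minlength=locations.size)
        keep = counts >= min_trials
        if not keep.any():
            raise ValueError(f"no location reaches min_trials in session {s}")
        code_list.append(codes)
        count_list.append(counts)
        keep_list.append(keep)

    low = grid.frequencies < split_hz
    deltas = np.empty((n_perm, grid.n))
    band_lo = np.empty(n_perm)
    band_hi = np.empty(n_perm)
    for p in range(n_perm):
        strengths = np.stack(
            [
                _strength_from_codes(
                    mat, codes[rng.permutation(codes.size)], counts, keep, threshold_k
                )
                for mat, codes, counts, keep in zip(
                    mats, code_list, count_list, keep_list
                )
            ]
        )
        d = (strengths[1:] - strengths[0]).mean(axis=0)
        deltas[p] = d
        band_lo[p] = d[low].mean()
        band_hi[p] = d[~low].mean()
    bound = np.percentile(deltas, 95.0, axis=0)
    return bound, (float(np.percentile(band_lo, 95.0)), float(np.percentile(band_hi, 95.0)))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class SpectralReweightingModel:
    """Reverse-correlation reweighting analysis over a training experiment.

    Parameters
    ----------
    trials, profiles : DataFrame
        Trial table and companion profile store (synthdata schema).
    grid : FrequencyGrid
        Grid the stored profiles live on.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        profiles: pd.DataFrame,
        grid: FrequencyGrid,
        threshold_k: float = DEFAULT_THRESHOLD_K,
        min_trials: int = DEFAULT_MIN_TRIALS,
        split_hz: float = DEFAULT_SPLIT_HZ,
    ) -> None:
        self.trials = trials
        self.profiles = profiles
        self.grid = grid
        self.threshold_k = threshold_k
        self.min_trials = min_trials
        self.split_hz = split_hz

    def session_strengths(self) -> list[FeatureStrengthProfile]:
        sessions = sorted(self.trials["session"].unique())
        out = []
        for s in sessions:
            rc = build_rcmap(
                self.trials[self.trials["session"] == s],
                self.profiles,
                self.grid,
                self.threshold_k,
                self.min_trials,
            )
            out.append(feature_strength(rc, session=int(s)))
        return out

    def fit(self, n_perm: int = 1000, seed: int = 0) -> "ReweightingResults":
        strengths = self.session_strengths()
        bound, band_nulls = reweighting_null(
            self.trials,
            self.profiles,
            self.grid,
            n_perm=n_perm,
            seed=seed,
            threshold_k=self.threshold_k,
            min_trials=self.min_trials,
            split_hz=self.split_hz,
        )
        estimate = cue_reweighting(
            strengths, self.split_hz, null_upper95_db=bound, band_nulls=band_nulls
        )
        return ReweightingResults(self, strengths, estimate, n_perm, seed)


class ReweightingResults:
    """Fitted reweighting estimate with its permutation null."""

    def __init__(self, model, strengths, estimate, n_perm, seed) -> None:
        self.model = model
        self.strengths = strengths
        self.estimate = estimate
        self.n_perm = n_perm
        self.seed = seed

    @property
    def significant_frequencies_hz(self) -> np.ndarray:
        return self.estimate.grid.frequencies[self.estimate.significant]

    def band_significant(self) -> dict[str, bool]:
        e = self.estimate
        return {
            "low": e.band_low > e.band_low_null95,
            "high": e.band_high > e.band_high_null95,
        }

    def summary(self) -> str:
        e = self.estimate
        n_sig = int(e.significant.sum())
        sig = self.band_significant()
        lines = [
            "Spectral-cue reweighting (reverse correlation)",
            f"  sessions: {len(self.strengths)}; permutations: {self.n_perm}",
            f"  band split: {e.split_hz / 1000:.1f} kHz",
            f"  delta feature strength  <split: {e.band_low:+.4f} dB"
            f" (null95 {e.band_low_null95:+.4f}, significant={sig['low']})",
            f"  delta feature strength >=split: {e.band_high:+.4f} dB"
            f" (null95 {e.band_high_null95:+.4f}, significant={sig['high']})",
            f"  significant bins: {n_sig}/{e.grid.n}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        e = self.estimate
        return pd.DataFrame(
            {
                "freq_hz": e.grid.frequencies,
                "delta_strength_db": e.delta_strength_db,
                "null_upper95_db": e.null_upper95_db,
                "significant": e.significant,
            }
        )

    def plot(self, ax=None):
        """Delta feature strength vs frequency with the permutation bound."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        e = self.estimate
        f_khz = e.grid.frequencies / 1000.0
        ax.plot(f_khz, e.delta_strength_db, color="k", label="reweighting")
        ax.plot(f_khz, e.null_upper95_db, ":", color="gray", label="null 95%")
        sig = e.significant
        ax.plot(f_khz[sig], e.delta_strength_db[sig], "r.", label="significant")
        ax.axvline(e.split_hz / 1000.0, color="b", lw=0.5)
        ax.set_xscale("log")
        ax.set_xlabel("frequency (kHz)")
        ax.set_ylabel("delta feature strength (dB)")
        ax.legend(frameon=False)
        return ax
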