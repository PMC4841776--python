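"""Cortical tuning characterization and cue-plasticity comparison.

Frequency tuning is extracted from frequency-response areas (FRAs:
firing rate vs tone frequency and level, 30 repetitions): repetition
averaging, a 0.75-octave boxcar smooth along frequency (truncated at the
range edges), then a response threshold at the spontaneous rate plus 20%
of the maximum driven rate.  Driven rates below that threshold are
zeroed; values above keep their magnitude.  The characteristic frequency
(CF) is the frequency with the greatest thresholded response at the
lowest responsive level; bandwidth 10 dB above threshold is the
equal-area rectangle width: the area under the thresholded tuning curve
(vs log2 frequency) divided by its peak rate, which approximates the
full width at half maximum for Gaussian tuning (ratio sqrt(2*pi) /
(2*sqrt(2*ln 2)) ~ 1.064).

A unit's best ILD is the interaural level difference at the peak of its
binaural interaction function (ties resolved toward 0 dB).

For the plasticity comparison, each unit's best ILD and spectral
weighting index are z-scored against the control group's mean and SD
within the unit's hemisphere x CF-band cell (band split at 8 kHz, where
ferret spectral cues become prominent); the two measures are then
re-standardized to overall mean 0 and variance 1 so remapping
(best-ILD) and reweighting (weighting-index) changes are comparable.
``CuePlasticityModel`` runs the band x process permutation ANOVA with
Bonferroni-corrected post-hoc band contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bonferroni, bootstrap_group_test, permutation_anova
from .synthdata import TuningMatrix

__all__ = [
    "TuningEstimate",
    "NoTuningError",
    "BandwidthUndefinedError",
    "estimate_tuning",
    "best_ild",
    "zscore_vs_controls",
    "standardize_adaptation_measures",
    "compare_bands",
    "CuePlasticityModel",
    "CuePlasticityResults",
]

DEFAULT_CF_SPLIT_HZ = 8000.0
BOXCAR_OCT = 0.75
RATE_FRACTION = 0.2


class NoTuningError(ValueError):
    """No level drives the unit above the response threshold."""


class BandwidthUndefinedError(ValueError):
    """Threshold sits at the top level: no level 10 dB above it."""


@dataclass(frozen=True)
class TuningEstimate:
    """CF, threshold and equal-area bandwidth from one FRA."""

    cf_hz: float
    threshold_db: float
    bw10_oct: float

    def __post_init__(self) -> None:
        if self.bw10_oct <= 0:
            raise ValueError("bw10_oct must be positive")


def _boxcar_smooth(mat: np.ndarray, width_bins: int) -> np.ndarray:
    """Boxcar along axis 0, truncated (window shrinks) at the edges."""
    if width_bins <= 1:
        return mat
    kernel = np.ones(width_bins)
    ones = np.ones(mat.shape[0])
    norm = np.convolve(ones, kernel, mode="same")
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        out[:, j] = np.convolve(mat[:, j], kernel, mode="same") / norm
    return out


def estimate_tuning(
    m: TuningMatrix,
    boxcar_oct: float = BOXCAR_OCT,
    rate_fraction: float = RATE_FRACTION,
) -> TuningEstimate:
    """Extract CF, threshold and equal-area bandwidth from an FRA.

    Raises :class:`NoTuningError` when nothing exceeds the response
    threshold and :class:`BandwidthUndefinedError` when the threshold sits
    at the top level.  Adding a constant to all rates and to the
    spontaneous rate simultaneously leaves the estimate unchanged.
    """
    mean = m.rates.mean(axis=2)  # (n_freq, n_level)
    spacing = float(np.median(np.diff(np.log2(m.freqs_hz))))
    width = max(1, int(round(boxcar_oct / spacing)))
    smoothed = _boxcar_smooth(mean, width)
    driven = smoothed - m.spontaneous_rate
    peak = driven.max()
    if peak <= 0:
        raise NoTuningError("no response above the spontaneous rate")
    cut = rate_fraction * peak  # threshold: spontaneous + 20% of max driven rate
    thresholded = np.where(driven > cut, driven, 0.0)
    responsive_levels = np.flatnonzero(thresholded.max(axis=0) > 0)
    if responsive_levels.size == 0:
        raise NoTuningError("no level exceeds the response threshold")
    thr_idx = int(responsive_levels[0])
    threshold_db = float(m.levels_db[thr_idx])
    cf_idx = int(np.argmax(thresholded[:, thr_idx]))  # ties -> lowest frequency
    cf_hz = float(m.freqs_hz[cf_idx])
    bw_level = threshold_db + 10.0
    bw_idx = np.flatnonzero(np.isclose(m.levels_db, bw_level))
    if bw_idx.size == 0:
        raise BandwidthUndefinedError(
            "threshold at the top level: bandwidth undefined"
        )
    curve = thresholded[:, int(bw_idx[0])]
    peak10 = curve.max()
    if peak10 <= 0:
        raise BandwidthUndefinedError("no response 10 dB above threshold")
    area = float(np.trapezoid(curve, np.log2(m.freqs_hz)))
    return TuningEstimate(cf_hz=cf_hz, threshold_db=threshold_db, bw10_oct=area / peak10)


def best_ild(ild_values, responses) -> float:
    """ILD at the peak of the binaural interaction function.

    Ties are broken toward the ILD closest to 0 dB.  A flat or monotone
    function (peak at the boundary or everywhere) triggers a warning.
    """
    ilds = np.asarray(ild_values, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if ilds.size < 3 or resp.shape != ilds.shape:
        raise ValueError("need >= 3 matched (ILD, response) samples")
    peak = resp.max()
    ties = np.flatnonzero(np.isclose(resp, peak, rtol=1e-12, atol=1e-12))
    if ties.size == resp.size:
        warnings.warn("flat binaural interaction function; returning ILD nearest 0")
    best_idx = ties[np.argmin(np.abs(ilds[ties]))]
    if ties.size < resp.size and (best_idx == 0 or best_idx == resp.size - 1):
        warnings.warn("peak at boundary ILD: best ILD may be unbounded")
    return float(ilds[best_idx])


def _with_bands(units: pd.DataFrame, cf_split_hz: float) -> pd.DataFrame:
    out = units.copy()
    out["cf_band"] = np.where(out["cf_hz"] > cf_split_hz, "high", "low")
    return out


def zscore_vs_controls(
    units: pd.DataFrame, cf_split_hz: float = DEFAULT_CF_SPLIT_HZ
) -> pd.DataFrame:
    """z-score best ILD and weighting index against control statistics.

    Normalization is done separately per hemisphere x CF band (split at
    ``cf_split_hz``), using the control group's mean and population SD of
    each measure.  Control units z-scored against their own cell come out
    with mean 0, SD 1.  Occupied cells with fewer than 2 controls raise.
    """
    out = _with_bands(units, cf_split_hz)
    out["remap_z"] = np.nan
    out["reweight_z"] = np.nan
    for (hemi, band), cell in out.groupby(["hemisphere", "cf_band"]):
        ctrl = cell[cell["group"] == "control"]
        if len(ctrl) < 2:
            raise ValueError(
                f"cell ({hemi}, {band}): need >= 2 control units, got {len(ctrl)}"
            )
        for src, dst in (("best_ild_db", "remap_z"), ("weighting_index", "reweight_z")):
            mu = ctrl[src].mean()
            sd = ctrl[src].std(ddof=0)
            if sd == 0:
                raise ValueError(f"zero control SD for {src} in cell ({hemi}, {band})")
            out.loc[cell.index, dst] = (cell[src] - mu) / sd
    return out


def standardize_adaptation_measures(z_table: pd.DataFrame) -> pd.DataFrame:
    """Re-standardize remap/reweight z-scores to overall mean 0, variance 1.

    An affine transform per measure: preserves within-measure unit order
    and between-measure correlations.
    """
    if len(z_table) < 2:
        raise ValueError("need >= 2 units")
    out = z_table.copy()
    for col in ("remap_z", "reweight_z"):
        v = out[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(f"zero variance in {col}")
        out[col] = (v - v.mean()) / sd
    return out


def compare_bands(std_table: pd.DataFrame, group: str = "plugged") -> pd.DataFrame:
    """Long-format (unit, band, measure, value) table for the band x process
    permutation ANOVA."""
    sel = std_table[std_table["group"] == group]
    if sel["cf_band"].nunique() < 2:
        raise ValueError("both CF bands must be populated")
    long = sel.melt(
        id_vars=["unit_id", "cf_band"],
        value_vars=["remap_z", "reweight_z"],
        var_name="measure",
        value_name="value",
    )
    long["measure"] = long["measure"].map(
        {"remap_z": "remap", "reweight_z": "reweight"}
    )
    return long


class CuePlasticityModel:
    """Band-resolved comparison of neural cue remapping vs reweighting.

    Built from a unit table (unit_id, hemisphere, group, cf_hz,
    weighting_index, best_ild_db).  ``fit`` z-scores plugged units against
    controls, standardizes the two measures, and tests the CF-band x
    adaptation-process interaction by permutation, with
    Bonferroni-corrected bootstrap post-hoc band contrasts per measure.
    """

    def __init__(self, units: pd.DataFrame, cf_split_hz: float = DEFAULT_CF_SPLIT_HZ):
        self.units = units
        self.cf_split_hz = cf_split_hz

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CuePlasticityModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(
        self, n_perm: int = 1000, n_boot: int = 2000, seed: int = 0
    ) -> "CuePlasticityResults":
        z = zscore_vs_controls(self.units, self.cf_split_hz)
        std = standardize_adaptation_measures(z)
        long = compare_bands(std)
        anova = permutation_anova(
            long["value"].to_numpy(),
            long["cf_band"].to_numpy(),
            long["measure"].to_numpy(),
            n_perm=n_perm,
            seed=seed,
        )
        posthoc = {}
        for i, measure in enumerate(("remap", "reweight")):
            sel = long[long["measure"] == measure]
            hi = sel[sel["cf_band"] == "high"]["value"].to_numpy()
            lo = sel[sel["cf_band"] == "low"]["value"].to_numpy()
            posthoc[measure] = bootstrap_group_test(
                hi, lo, n_resamples=n_boot, seed=seed + 1 + i
            )
        adj = bonferroni(list(posthoc.values()))
        posthoc_adj = dict(zip(posthoc, adj))
        return CuePlasticityResults(self, z, std, long, anova, posthoc_adj, seed)


class CuePlasticityResults:
    """Fitted band x process comparison."""

    def __init__(self, model, z_table, std_table, long, anova, posthoc, seed):
        self.model = model
        self.z_table = z_table
        self.std_table = std_table
        self.long = long
        self.anova = anova
        self.posthoc = posthoc  # Bonferroni-adjusted high-vs-low p per measure
        self.seed = seed

    @property
    def interaction_p(self) -> float:
        return self.anova["interaction"].p_value

    def band_means(self) -> pd.DataFrame:
        return (
            self.long.groupby(["measure", "cf_band"])["value"]
            .mean()
            .unstack("cf_band")
        )

    def summary(self) -> str:
        bm = self.band_means()
        lines = [
            "Neural cue plasticity (plugged vs control)",
            f"  CF band split: {self.model.cf_split_hz / 1000:.0f} kHz",
            "  mean standardized shift (control SD units, re-standardized):",
        ]
        for measure in bm.index:
            lines.append(
                f"    {measure:<10} low: {bm.loc[measure, 'low']:+.3f}"
                f"   high: {bm.loc[measure, 'high']:+.3f}"
                f"   post-hoc p (Bonferroni): {self.posthoc[measure]:.4f}"
            )
        a = self.anova["interaction"]
        lines.append(
            f"  band x process interaction: F = {a.f_obs:.2f}, p = {a.p_value:.4f}"
            f" ({a.n_perm} permutations)"
        )
        return "\n".join(lines)
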