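"""Behavioral scoring and adaptation-slope fitting.

Trial tables are scored per session and stimulus class into three
measures: percent correct (exact-speaker criterion on the 12-alternative
task), mean unsigned error on the front-back-collapsed azimuth scale
(precision), and mean signed collapsed error with its sign pointing
toward the open ear (bias).  Front-back collapsing removes the front-back
confusions that reflect spectral- rather than binaural-cue failures:
each azimuth is folded about the interaural axis, so the 12 speakers map
onto 7 collapsed positions {0, +-30, +-60, +-90}.

Per-session scores are regressed on session number (1..n, ordinary least
squares); the slopes quantify adaptation: improvement gives a positive
adaptation rate for percent correct, and negative "delta error" and
"delta bias" slopes for the tone measures.

Tone responses are scored per frequency and pooled: localization of
frequencies at or above 2 kHz changes comparably with training, so the
2/4/8 kHz classes are combined into ``tone_high``; 1 kHz (``tone_low``)
indexes ITD-based performance.

``AdaptationModel`` wraps the whole analysis in a statsmodels-like
Model/Results pair with bootstrap confidence intervals for every slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "collapse_front_back",
    "percent_correct",
    "error_magnitude",
    "response_bias",
    "session_scores",
    "fit_adaptation_slope",
    "standardize_measures",
    "AdaptationSlopes",
    "AdaptationModel",
    "AdaptationResults",
    "STIMULUS_CLASSES",
]

STIMULUS_CLASSES = (
    "flat",
    "random",
    "tone_low",
    "tone_high",
    "tone_all",
    "tone_1k",
    "tone_2k",
    "tone_4k",
    "tone_8k",
)

#: Tone-frequency split separating ITD-dominated from ILD-dominated tones.
ITD_ILD_SPLIT_HZ = 1500.0


def collapse_front_back(azimuth_deg):
    """Fold rear-hemifield azimuths onto the front: result in [-90, 90].

    theta -> theta if |theta| <= 90, else sign(theta) * (180 - |theta|);
    180 maps to 0.  Accepts scalars or arrays; azimuths must lie in
    (-180, 180].
    """
    az = np.asarray(azimuth_deg, dtype=float)
    if np.any(az <= -180.0) or np.any(az > 180.0):
        raise ValueError("azimuths must lie in (-180, 180]")
    out = np.where(np.abs(az) <= 90.0, az, np.sign(az) * (180.0 - np.abs(az)))
    return float(out) if out.ndim == 0 else out


def circular_distance(a, b):
    """Angular distance on the full circle: min(|d|, 360 - |d|)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    return np.minimum(d, 360.0 - d)


def _standard(trials: pd.DataFrame, include_correction: bool) -> pd.DataFrame:
    if include_correction:
        return trials
    return trials[trials["trial_class"] == "standard"]


def percent_correct(trials: pd.DataFrame, include_correction: bool = False) -> float:
    """Percent of trials with an exact speaker match (front-back confusions
    count as errors)."""
    t = _standard(trials, include_correction)
    if len(t) == 0:
        raise ValueError("no trials to score")
    return 100.0 * float(
        np.mean(t["response_deg"].to_numpy() == t["target_deg"].to_numpy())
    )


def error_magnitude(
    trials: pd.DataFrame, collapsed: bool = True, include_correction: bool = False
) -> float:
    """Mean unsigned localization error, degrees.

    Collapsed (default): |collapse(response) - collapse(target)|, which is
    blind to front-back confusions.  Otherwise the circular distance.
    """
    t = _standard(trials, include_correction)
    if len(t) == 0:
        raise ValueError("no trials to score")
    resp = t["response_deg"].to_numpy(dtype=float)
    targ = t["target_deg"].to_numpy(dtype=float)
    if collapsed:
        return float(np.mean(np.abs(collapse_front_back(resp) - collapse_front_back(targ))))
    return float(np.mean(circular_distance(resp, targ)))


def response_bias(
    trials: pd.DataFrame, plug_side: str, include_correction: bool = False
) -> float:
    """Mean signed collapsed error, positive toward the open ear."""
    if plug_side not in ("left", "right"):
        raise ValueError("plug_side must be 'left' or 'right'")
    t = _standard(trials, include_correction)
    if len(t) == 0:
        raise ValueError("no trials to score")
    signed = collapse_front_back(t["response_deg"].to_numpy(dtype=float)) - (
        collapse_front_back(t["target_deg"].to_numpy(dtype=float))
    )
    open_sign = 1.0 if plug_side == "left" else -1.0
    return float(open_sign * np.mean(signed))


def _class_mask(trials: pd.DataFrame, stimulus_class: str) -> pd.Series:
    kind = trials["kind"]
    if stimulus_class in ("flat", "random"):
        return kind == stimulus_class
    tone = kind == "tone"
    freq = trials["tone_freq_hz"]
    if stimulus_class == "tone_all":
        return tone
    if stimulus_class == "tone_low":
        return tone & (freq < ITD_ILD_SPLIT_HZ)
    if stimulus_class == "tone_high":
        return tone & (freq >= ITD_ILD_SPLIT_HZ)
    if stimulus_class.startswith("tone_") and stimulus_class.endswith("k"):
        khz = float(stimulus_class[5:-1])
        return tone & np.isclose(freq, khz * 1000.0)
    raise ValueError(f"unknown stimulus class {stimulus_class!r}")


def session_scores(
    trials: pd.DataFrame,
    plug_side: str = "left",
    include_correction: bool = False,
    classes: tuple[str, ...] = STIMULUS_CLASSES,
) -> pd.DataFrame:
    """Per-session, per-stimulus-class behavioral summaries.

    Returns a tidy table with columns session, stimulus_class, n_trials,
    pct_correct, err_mag_deg, bias_deg.  Session/class cells with no trials
    are omitted with a warning.
    """
    sessions = sorted(trials["session"].unique())
    if len(sessions) < 2:
        raise ValueError("need trials from at least 2 sessions")
    t = _standard(trials, include_correction)
    rows = []
    for session in sessions:
        in_session = t[t["session"] == session]
        for cls in classes:
            sel = in_session[_class_mask(in_session, cls)]
            if len(sel) == 0:
                warnings.warn(
                    f"no {cls} trials in session {session}; row omitted",
                    stacklevel=2,
                )
                continue
            rows.append(
                (
                    session,
                    cls,
                    len(sel),
                    percent_correct(sel, include_correction=True),
                    error_magnitude(sel, include_correction=True),
                    response_bias(sel, plug_side, include_correction=True),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "session",
            "stimulus_class",
            "n_trials",
            "pct_correct",
            "err_mag_deg",
            "bias_deg",
        ],
    )


@dataclass(frozen=True)
class AdaptationSlopes:
    """OLS slope/intercept of one behavioral measure against session number."""

    measure: str
    stimulus_class: str
    slope: float
    intercept: float
    n_sessions: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if self.n_sessions < 2:
            raise ValueError("slope requires >= 2 sessions")



def fit_adaptation_slope(
    sessions, values, measure: str = "adaptation_rate", stimulus_class: str = "flat"
) -> AdaptationSlopes:
    """Ordinary least squares of per-session scores on session number."""
    sessions = np.asarray(sessions, dtype=float)
    values = np.asarray(values, dtype=float)
    if sessions.size < 2:
        raise ValueError("need >= 2 sessions to fit a slope")
    fit = sps.linregress(sessions, values)
    return AdaptationSlopes(
        measure=measure,
        stimulus_class=stimulus_class,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_sessions=int(sessions.size),
    )


def standardize_measures(values, axis: int | None = None) -> np.ndarray:
    """z-score values to mean 0, SD 1 (population SD, divide-by-n).

    For 1-D input, standardizes across entries (e.g. across subjects).  For
    2-D input with ``axis`` given, standardizes along that axis (e.g. each
    measure's time course across sessions).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values to standardize")
    mean = v.mean(axis=axis, keepdims=axis is not None)
    sd = v.std(axis=axis, keepdims=axis is not None)
    if np.any(sd == 0):
        raise ValueError("zero variance: cannot standardize")
    return (v - mean) / sd


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class AdaptationModel:
    """Behavioral adaptation model: per-session scores + OLS slopes.

    Parameters
    ----------
    trials : DataFrame
        Trial table (synthdata schema).
    plug_side : {'left', 'right'}
        Side of the earplug; fixes the bias sign convention.
    include_correction : bool
        Include correction/easy trials in scoring (default False).
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        plug_side: str = "left",
        include_correction: bool = False,
    ) -> None:
        self.trials = trials
        self.plug_side = plug_side
        self.include_correction = include_correction

    @classmethod
    def from_csv(cls, trials_path, **kwargs) -> "AdaptationModel":
        from .synthdata import read_trials

        return cls(read_trials(trials_path), **kwargs)

    def _per_trial_values(self, measure: str) -> np.ndarray:
        t = _standard(self.trials, self.include_correction)
        resp = collapse_front_back(t["response_deg"].to_numpy(dtype=float))
        targ = collapse_front_back(t["target_deg"].to_numpy(dtype=float))
        if measure == "adaptation_rate":
            return 100.0 * (
                t["response_deg"].to_numpy() == t["target_deg"].to_numpy()
            ).astype(float)
        if measure == "delta_error":
            return np.abs(resp - targ)
        if measure == "delta_bias":
            open_sign = 1.0 if self.plug_side == "left" else -1.0
            return open_sign * (resp - targ)
        raise ValueError(f"unknown measure {measure!r}")

    def fit(self, n_boot: int = 1000, seed: int = 0) -> "AdaptationResults":
        """Score sessions, fit slopes, and bootstrap their CIs.

        The bootstrap resamples trials with replacement within each
        session x class cell, recomputes the per-session measure and
        refits the slope; CIs are percentile 95%.
        """
        scores = session_scores(
            self.trials, self.plug_side, self.include_correction
        )
        rng = np.random.default_rng(seed)
        t = _standard(self.trials, self.include_correction)
        rows = []
        boot_dists: dict[tuple[str, str], np.ndarray] = {}
        for cls in STIMULUS_CLASSES:
            mask = _class_mask(t, cls)
            sel = t[mask]
            if len(sel) == 0:
                continue
            sessions = np.sort(sel["session"].unique())
            if sessions.size < 2:
                continue
            for measure in ("adaptation_rate", "delta_error", "delta_bias"):
                vals = {
                    s: self._per_trial_values(measure)[mask.to_numpy()][
                        (sel["session"] == s).to_numpy()
                    ]
                    for s in sessions
                }
                means = np.array([vals[s].mean() for s in sessions])
                fitted = fit_adaptation_slope(sessions, means, measure, cls)
                boot_means = np.empty((n_boot, sessions.size))
                for j, s in enumerate(sessions):
                    v = vals[s]
                    idx = rng.integers(0, v.size, size=(n_boot, v.size))
                    boot_means[:, j] = v[idx].mean(axis=1)
                slopes = _ols_slopes(sessions, boot_means)
                boot_dists[(cls, measure)] = slopes
                lo, hi = np.percentile(slopes, [2.5, 97.5])
                rows.append(
                    (
                        cls,
                        measure,
                        fitted.slope,
                        fitted.intercept,
                        float(lo),
                        float(hi),
                        int(sessions.size),
                    )
                )
        slopes_df = pd.DataFrame(
            rows,
            columns=[
                "stimulus_class",
                "measure",
                "slope",
                "intercept",
                "ci_low",
                "ci_high",
                "n_sessions",
            ],
        )
        return AdaptationResults(self, scores, slopes_df, n_boot, seed, boot_dists)


def _ols_slopes(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Closed-form OLS slopes of each row of ``ys`` against ``x``."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    return (ys - ys.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)


class AdaptationResults:
    """Fitted behavioral adaptation: per-session scores and slope table."""

    def __init__(self, model, scores, slopes, n_boot, seed, boot_dists=None) -> None:
        self.model = model
        self.scores = scores
        self.slopes = slopes
        self.n_boot = n_boot
        self.seed = seed
        self._boot_dists = boot_dists or {}

    def slope(self, stimulus_class: str, measure: str) -> AdaptationSlopes:
        row = self.slopes[
            (self.slopes["stimulus_class"] == stimulus_class)
            & (self.slopes["measure"] == measure)
        ]
        if len(row) == 0:
            raise KeyError(f"no slope for ({stimulus_class}, {measure})")
        r = row.iloc[0]
        return AdaptationSlopes(
            measure=measure,
            stimulus_class=stimulus_class,
            slope=float(r["slope"]),
            intercept=float(r["intercept"]),
            n_sessions=int(r["n_sessions"]),
        )

    def slope_ci(
        self, stimulus_class: str, measure: str, level: float = 0.95
    ) -> tuple[float, float]:
        """Percentile bootstrap CI of a slope at any confidence level."""
        if level == 0.95 or (stimulus_class, measure) not in self._boot_dists:
            row = self.slopes[
                (self.slopes["stimulus_class"] == stimulus_class)
                & (self.slopes["measure"] == measure)
            ].iloc[0]
            if level == 0.95:
                return float(row["ci_low"]), float(row["ci_high"])
            raise KeyError("bootstrap distribution unavailable for this cell")
        dist = self._boot_dists[(stimulus_class, measure)]
        alpha = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(dist, [alpha, 100.0 - alpha])
        return float(lo), float(hi)

    def summary(self) -> str:
        lines = [
            "Behavioral adaptation summary",
            f"  plug side: {self.model.plug_side}; bootstrap: {self.n_boot} resamples",
            f"  {'class':<10}{'measure':<18}{'slope':>10}{'95% CI':>22}",
        ]
        for _, r in self.slopes.iterrows():
            ci = f"[{r['ci_low']:+.3f}, {r['ci_high']:+.3f}]"
            lines.append(
                f"  {r['stimulus_class']:<10}{r['measure']:<18}{r['slope']:>+10.3f}{ci:>22}"
            )
        return "\n".join(lines)
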