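"""Resampling inference: bootstrap CIs and tests, permutation ANOVA, effect sizes.

Implements the study's statistical toolkit:

* percentile bootstrap confidence intervals (default 10,000 resamples);
* a pooled-resampling bootstrap test for group differences (the two
  groups are pooled and resampled with replacement into two new samples;
  the observed statistic is referred to that null ensemble), with mean
  difference, pooled-variance t, and rank-sum statistics, plus a paired
  variant that resamples within-subject differences against zero;
* a permutation test for two-way factorial effects: observations are
  freely permuted across cells and an F statistic (explained over
  unexplained variance) is recomputed per effect;
* Cohen's d and Bonferroni correction.

All p-values are two-sided, use the add-one correction
p = (k + 1) / (n + 1) so they are never exactly zero, and every
resampling routine is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BootstrapResult",
    "PermutationResult",
    "bootstrap_ci",
    "bootstrap_group_test",
    "permutation_anova",
    "cohens_d",
    "bonferroni",
]

DEFAULT_N_RESAMPLES = 10_000


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate with percentile bootstrap CI and a two-sided p vs 0."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("percentile CI must contain the estimate")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


@dataclass(frozen=True)
class PermutationResult:
    """Observed F and permutation p-value for one factorial effect."""

    effect: str
    f_obs: float
    p_value: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


def _resample_statistic(
    values: np.ndarray,
    statistic,
    rng: np.random.Generator,
    n_resamples: int,
) -> np.ndarray:
    """Bootstrap distribution of ``statistic``; vectorized for the mean."""
    n = values.size
    idx = rng.integers(0, n, size=(n_resamples, n))
    if statistic is np.mean or statistic == "mean":
        return values[idx].mean(axis=1)
    try:
        out = statistic(values[idx], axis=1)
        out = np.asarray(out, dtype=float)
        if out.shape == (n_resamples,):
            return out
    except TypeError:
        pass
    return np.array([statistic(values[i]) for i in idx], dtype=float)


def bootstrap_ci(
    values,
    statistic=np.mean,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    confidence: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap CI of ``statistic`` over ``values``.

    The p-value is two-sided for the null that the statistic is zero,
    computed from the tail masses of the bootstrap distribution.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 values")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    boots = _resample_statistic(values, statistic, rng, n_resamples)
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.percentile(boots, [100 * alpha, 100 * (1 - alpha)])
    est = float(statistic(values)) if callable(statistic) else float(np.mean(values))
    lo, hi = min(lo, est), max(hi, est)
    k = min(int(np.sum(boots <= 0.0)), int(np.sum(boots >= 0.0)))
    p = min(1.0, 2.0 * (k + 1) / (n_resamples + 1))
    return BootstrapResult(
        estimate=est,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        n_resamples=n_resamples,
        seed=seed,
    )


def _group_stat(a: np.ndarray, b: np.ndarray, statistic: str) -> float:
    if statistic == "mean_diff":
        return float(a.mean() - b.mean())
    if statistic == "t":
        na, nb = a.size, b.size
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        if sp2 <= 0:
            raise ValueError("degenerate pooled variance for the t statistic")
        return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))
    if statistic == "ranksum":
        return float(sps.ranksums(a, b).statistic)
    raise ValueError(f"unknown statistic {statistic!r}")


def bootstrap_group_test(
    a,
    b,
    statistic: str = "mean_diff",
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    paired: bool = False,
) -> float:
    """Two-sided pooled-resampling bootstrap p-value for a group difference.

    Unpaired: the groups are pooled; each resample draws two new samples of
    the original sizes with replacement from the pool and recomputes the
    statistic, giving its null distribution.  Paired: within-subject
    differences are centered and resampled against zero.  Extremity is
    measured as distance from the null distribution's center;
    p = (k + 1) / (n + 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(seed)

    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length groups")
        d = a - b
        obs = float(d.mean())
        d0 = d - d.mean()
        idx = rng.integers(0, d0.size, size=(n_resamples, d0.size))
        null = d0[idx].mean(axis=1)
    else:
        obs = _group_stat(a, b, statistic)
        pooled = np.concatenate([a, b])
        n = pooled.size
        if statistic == "mean_diff":
            ia = rng.integers(0, n, size=(n_resamples, a.size))
            ib = rng.integers(0, n, size=(n_resamples, b.size))
            null = pooled[ia].mean(axis=1) - pooled[ib].mean(axis=1)
        elif statistic == "t":
            ia = rng.integers(0, n, size=(n_resamples, a.size))
            ib = rng.integers(0, n, size=(n_resamples, b.size))
            sa, sb = pooled[ia], pooled[ib]
            na, nb = a.size, b.size
            sp2 = (
                (na - 1) * sa.var(axis=1, ddof=1) + (nb - 1) * sb.var(axis=1, ddof=1)
            ) / (na + nb - 2)
            sp2 = np.maximum(sp2, 1e-300)
            null = (sa.mean(axis=1) - sb.mean(axis=1)) / np.sqrt(
                sp2 * (1 / na + 1 / nb)
            )
        else:
            null = np.array(
                [
                    _group_stat(
                        pooled[rng.integers(0, n, a.size)],
                        pooled[rng.integers(0, n, b.size)],
                        statistic,
                    )
                    for _ in range(n_resamples)
                ]
            )

    center = float(null.mean())
    k = int(np.sum(np.abs(null - center) >= abs(obs - center) - 1e-12))
    return (k + 1) / (n_resamples + 1)


def _anova_projections(fa: np.ndarray, fb: np.ndarray):
    """Orthonormal bases (Q matrices) for the full and reduced two-way models."""
    la, ia = np.unique(fa, return_inverse=True)
    lb, ib = np.unique(fb, return_inverse=True)
    if la.size < 2 or lb.size < 2:
        raise ValueError("each factor needs >= 2 levels")
    n = fa.size

    def dummies(idx, k):
        d = np.zeros((n, k - 1))
        for j in range(k - 1):
            d[idx == j, j] = 1.0
            d[idx == k - 1, j] = -1.0  # effect coding
        return d

    A = dummies(ia, la.size)
    B = dummies(ib, lb.size)
    AB = np.concatenate(
        [A[:, i : i + 1] * B[:, j : j + 1] for i in range(A.shape[1]) for j in range(B.shape[1])],
        axis=1,
    )
    one = np.ones((n, 1))
    blocks = {"factorA": A, "factorB": B, "interaction": AB}
    X_full = np.concatenate([one, A, B, AB], axis=1)
    q_full, _ = np.linalg.qr(X_full)
    qs = {"__full__": q_full}
    dfs = {"factorA": A.shape[1], "factorB": B.shape[1], "interaction": AB.shape[1]}
    for eff in blocks:
        cols = [one] + [blocks[o] for o in blocks if o != eff]
        X_red = np.concatenate(cols, axis=1)
        q, _ = np.linalg.qr(X_red)
        qs[eff] = q
    df_resid = n - X_full.shape[1]
    if df_resid < 1:
        raise ValueError("not enough observations per cell")
    return qs, dfs, df_resid


def _f_stats(y: np.ndarray, qs, dfs, df_resid) -> dict[str, np.ndarray]:
    """F per effect for y of shape (n,) or (n, n_perm)."""
    y = y if y.ndim == 2 else y[:, None]
    tot = np.sum(y * y, axis=0)
    rss_full = tot - np.sum((qs["__full__"].T @ y) ** 2, axis=0)
    rss_full = np.maximum(rss_full, 1e-300)
    out = {}
    for eff, df_e in dfs.items():
        rss_red = tot - np.sum((qs[eff].T @ y) ** 2, axis=0)
        out[eff] = ((rss_red - rss_full) / df_e) / (rss_full / df_resid)
    return out


def permutation_anova(
    values,
    factor_a,
    factor_b,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, PermutationResult]:
    """Permutation test of two-way factorial effects.

    Observations are freely permuted across cells; for each permutation F
    statistics for both main effects and the interaction are recomputed
    from the two-way linear model (effect coding, partial sums of
    squares).  p per effect = fraction of permutations with F at least the
    observed value, with add-one correction.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.shape == fa.shape == fb.shape) or y.ndim != 1:
        raise ValueError("values and factors must be equal-length 1-D")
    # every cell must be populated with >= 2 observations
    cells, counts = np.unique(
        np.stack([fa.astype(str), fb.astype(str)]), axis=1, return_counts=True
    )
    la, lb = np.unique(fa).size, np.unique(fb).size
    if cells.shape[1] < la * lb or np.any(counts < 2):
        raise ValueError("need >= 2 observations in every factor cell")
    qs, dfs, df_resid = _anova_projections(fa, fb)
    f_obs = {e: float(v[0]) for e, v in _f_stats(y, qs, dfs, df_resid).items()}
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, y.size)), axis=1)
    f_null = _f_stats(y[perms].T, qs, dfs, df_resid)
    results = {}
    for eff in dfs:
        k = int(np.sum(f_null[eff] >= f_obs[eff] - 1e-12))
        results[eff] = PermutationResult(
            effect=eff,
            f_obs=f_obs[eff],
            p_value=(k + 1) / (n_perm + 1),
            n_perm=n_perm,
            seed=seed,
        )
    return results


def cohens_d(a, b=None) -> float:
    """Cohen's d: mean difference over pooled SD (one-sample: mean / SD)."""
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("empty input")
    if b is None:
        sd = a.std(ddof=1)
        if sd == 0:
            raise ValueError("zero SD")
        return float(a.mean() / sd)
    b = np.asarray(b, dtype=float)
    if b.size == 0:
        raise ValueError("empty input")
    na, nb = a.size, b.size
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if sp == 0:
        raise ValueError("zero pooled SD")
    return float((a.mean() - b.mean()) / sp)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size if m is None else int(m)
    return np.minimum(1.0, m * p)
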