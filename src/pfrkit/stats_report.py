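"""Statistical layer: t-tests with JZS Bayes factors, Pearson correlation,
bootstrap confidence intervals, the exponential NDR-PFR fit with a binomial
confidence-band overlap test, and pooled-by-participant variants.

The Bayes factor is the default-prior (Jeffreys-Zellner-Siow) BF10 for
t-tests: a Cauchy prior with scale sqrt(2)/2 on the standardized effect
size, integrated numerically against the noncentral-t likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

__all__ = [
    "TTestResult",
    "GroupResult",
    "NdrPfrFit",
    "t_test",
    "jzs_bayes_factor",
    "pearson_r2",
    "bootstrap_ci",
    "group_summary",
    "overlap_binomial_p",
    "ndr_pfr_exponential",
    "pooled_by_participant",
]

DEFAULT_PRIOR_SCALE = np.sqrt(2.0) / 2.0
DEFAULT_B = 10_000


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    zero_variance: bool = False


@dataclass
class GroupResult:
    """Group mean with bootstrap CI, t-test vs zero and JZS Bayes factor."""

    mean: float
    ci_low: float
    ci_high: float
    t: float
    df: float
    p: float
    bayes_factor: float
    n: int


@dataclass
class NdrPfrFit:
    """Exponential fit gain = a*exp(-b*ndr) + c to intact-field pairs,
    with a bootstrap confidence band and the blind-field overlap count."""

    coeffs: tuple[float, float, float]
    grid: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    k_overlap: int
    n_tested: int
    binomial_p: float
    converged: bool = True


def t_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float] | None = None,
    paired: bool = False,
    welch: bool = False,
) -> TTestResult:
    """One-sample (vs 0), paired, or two-sample t-test, two-sided.

    Two-sample tests pool variances by default (df = n1 + n2 - 2); Welch's
    correction is available behind ``welch``.  A zero-variance sample with
    n > 1 yields an infinite t, flagged rather than raised.
    """
    a = np.asarray(sample_a, dtype=float)
    if a.size < 2:
        raise ValueError("need n >= 2 per sample")
    if sample_b is None:
        diff = a
    elif paired:
        b = np.asarray(sample_b, dtype=float)
        if b.size != a.size:
            raise ValueError("paired samples must have equal length")
        diff = a - b
    else:
        b = np.asarray(sample_b, dtype=float)
        if b.size < 2:
            raise ValueError("need n >= 2 per sample")
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            delta = a.mean() - b.mean()
            t = np.inf * np.sign(delta) if delta != 0 else 0.0
            return TTestResult(float(t), a.size + b.size - 2, 0.0 if delta else 1.0, True)
        res = stats.ttest_ind(a, b, equal_var=not welch)
        return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))
    if np.var(diff, ddof=1) == 0:
        m = diff.mean()
        t = np.inf * np.sign(m) if m != 0 else 0.0
        return TTestResult(float(t), diff.size - 1, 0.0 if m else 1.0, True)
    res = stats.ttest_1samp(diff, 0.0)
    return TTestResult(float(res.statistic), float(diff.size - 1), float(res.pvalue))


def jzs_bayes_factor(
    t: float,
    n1: int,
    n2: int | None = None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> float:
    """JZS Bayes factor BF10 for a t statistic.

    The alternative places a Cauchy(0, ``prior_scale``) prior on the
    standardized effect size delta; the marginal likelihood is the
    noncentral-t density averaged over that prior (effective sample size
    n for one-sample/paired, n1*n2/(n1+n2) for two-sample), divided by the
    central-t density under the null.  BF10 > 1 favors the alternative.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n1 < 2:
        raise ValueError("need n >= 2")
    if n2 is None:
        neff, df = float(n1), n1 - 1
    else:
        if n2 < 2:
            raise ValueError("need n >= 2")
        neff, df = n1 * n2 / (n1 + n2), n1 + n2 - 2

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, df, delta * np.sqrt(neff)) * stats.cauchy.pdf(
            delta, scale=prior_scale
        )

    marginal, err = integrate.quad(
        integrand, -np.inf, np.inf, epsabs=1e-12, epsrel=1e-10, limit=200
    )
    if marginal <= 0 or err > max(1e-8, 1e-4 * marginal):
        raise RuntimeError("Bayes factor quadrature did not converge")
    return float(marginal / stats.t.pdf(t, df))


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float, float]:
    """Pearson r, r-squared, regression F with (1, n-2) df, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant sample")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r2 = r * r
    dfe = x.size - 2
    if r2 >= 1.0:
        return r, 1.0, np.inf, 0.0
    F = r2 * dfe / (1.0 - r2)
    p = float(stats.f.sf(F, 1, dfe))
    return r, r2, float(F), p


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    B: int = DEFAULT_B,
    level: float = 0.95,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of ``statistic`` over B resamples."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(B, v.size))
    if statistic is np.mean:
        reps = v[idx].mean(axis=1)
    else:
        reps = np.apply_along_axis(statistic, 1, v[idx])
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(reps, alpha)), float(np.quantile(reps, 1.0 - alpha))


def group_summary(
    values: Sequence[float],
    B: int = DEFAULT_B,
    seed: int | np.random.SeedSequence = 0,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> GroupResult:
    """Mean, bootstrap 95% CI, one-sample t vs 0 and JZS BF10 for one group."""
    v = np.asarray(values, dtype=float)
    tt = t_test(v)
    lo, hi = bootstrap_ci(v, np.mean, B=B, seed=seed)
    bf = (
        jzs_bayes_factor(tt.t, v.size, prior_scale=prior_scale)
        if np.isfinite(tt.t)
        else np.inf
    )
    return GroupResult(float(v.mean()), lo, hi, tt.t, tt.df, tt.p, bf, v.size)


def overlap_binomial_p(k: int, n: int, level: float = 0.95) -> float:
    """Lower-tail binomial p for k of n points inside a ``level`` confidence band.

    If tested points were draws from the fitted population, each falls
    inside a pointwise 95% band with probability ~0.95; a small k of n is
    then evidence the distributions differ.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binom.cdf(k, n, level))


def _exp_model(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(-b * x) + c


def ndr_pfr_exponential(
    pairs_intact: Sequence[tuple[float, float]],
    pairs_blind: Sequence[tuple[float, float]],
    ndr_cut: float = 0.35,
    B: int = 2000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence = 0,
) -> NdrPfrFit:
    """Exponential NDR-PFR fit on intact pairs + blind-field overlap test.

    Fits gain = a*exp(-b*ndr) + c by least squares to the intact-field
    (ndr, gain) pairs, builds a pointwise bootstrap confidence band on
    [0, 1], and counts how many blind-field locations with recovered
    perception (ndr < ``ndr_cut``) fall inside the band.  The binomial
    tail p is P(X <= k) for X ~ Binomial(n, ``level``): if blind locations
    were draws from the intact distribution, each would fall inside a
    95% band with probability ~0.95.
    """
    intact = np.asarray(pairs_intact, dtype=float)
    blind = np.asarray(pairs_blind, dtype=float)
    if intact.shape[0] < 4:
        raise ValueError("need >= 4 intact pairs")
    x, y = intact[:, 0], intact[:, 1]
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct intact NDR values")

    def fit(xx: np.ndarray, yy: np.ndarray) -> np.ndarray | None:
        best, best_cost = None, np.inf
        for b0 in (1.0, 3.0, 8.0):
            try:
                with warnings.catch_warnings():
                    # near-degenerate resamples give unusable covariance;
                    # only the point estimate is used here
                    warnings.simplefilter("ignore", optimize.OptimizeWarning)
                    popt, _ = optimize.curve_fit(
                        _exp_model,
                        xx,
                        yy,
                        p0=(yy.max() - yy.min(), b0, yy.min()),
                        maxfev=5000,
                    )
            except RuntimeError:
                continue
            cost = float(np.sum((yy - _exp_model(xx, *popt)) ** 2))
            if cost < best_cost:
                best, best_cost = popt, cost
        return best

    popt = fit(x, y)
    if popt is None:
        return NdrPfrFit(
            (np.nan,) * 3, np.array([]), np.array([]), np.array([]), 0, 0, np.nan, False
        )

    grid = np.linspace(0.0, 1.0, 101)
    rng = np.random.default_rng(seed)
    curves = []
    while len(curves) < B:
        idx = rng.integers(0, x.size, size=x.size)
        if np.unique(x[idx]).size < 3:
            continue
        p = fit(x[idx], y[idx])
        if p is not None:
            curves.append(_exp_model(grid, *p))
    curves = np.asarray(curves)
    alpha = (1.0 - level) / 2.0
    band_low = np.quantile(curves, alpha, axis=0)
    band_high = np.quantile(curves, 1.0 - alpha, axis=0)

    tested = blind[blind[:, 0] < ndr_cut] if blind.size else np.empty((0, 2))
    k = 0
    for nx, g in tested:
        lo = np.interp(nx, grid, band_low)
        hi = np.interp(nx, grid, band_high)
        if lo <= g <= hi:
            k += 1
    n = tested.shape[0]
    p_binom = overlap_binomial_p(k, n, level) if n else np.nan
    return NdrPfrFit(tuple(popt), grid, band_low, band_high, k, n, p_binom)


def pooled_by_participant(per_location: pd.DataFrame) -> pd.DataFrame:
    """Pool location-level rows to one row per participant x field.

    ``per_location`` needs columns ``participant``, ``field`` and any
    numeric measure columns (e.g. ``gain``, ``ndr``); pooling is the
    unweighted mean of locations within participant and field.
    Participants with no locations in a field simply have no row there.
    """
    required = {"participant", "field"}
    if not required.issubset(per_location.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    pooled = (
        per_location.groupby(["participant", "field"], as_index=False)
        .mean(numeric_only=True)
    )
    return pooled
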