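"""Statistical models for microcarrier culture metrics.

Implements the zero-truncated Poisson (ZTP) model for cells-per-microcarrier
(CPM) data — the Poisson law conditioned on k >= 1, appropriate because empty
microcarriers are excluded from sampling — together with its maximum-likelihood
fit, the ordinary-least-squares growth correlation between cell number and
total cell volume, and a bootstrap estimator of how many populated
microcarriers must be sampled to pin down the mean CPM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "ZTPModel",
    "GrowthCorrelation",
    "SamplingAdequacy",
    "ztp_pmf",
    "ztp_rvs",
    "ztp_fit",
    "fit_growth_correlation",
    "sampling_adequacy",
]

# Bracket for the rate root-finder.  The upper bound comfortably covers the
# largest per-microcarrier counts seen in practice (max ~19 cells/carrier).
_LAMBDA_LO = 1e-6
_LAMBDA_HI = 50.0


def ztp_pmf(k, lam: float):
    """Zero-truncated Poisson probability mass P(K = k | K >= 1).

    P(k; lam) = exp(-lam) lam^k / (k! (1 - exp(-lam))) for integer k >= 1.

    Parameters
    ----------
    k : int or array of int
        Count value(s), all >= 1.
    lam : float
        Poisson rate, > 0.
    """
    k_arr = np.asarray(k)
    if lam <= 0:
        raise ValueError(f"rate must be > 0, got {lam}")
    if np.any(k_arr < 1):
        raise ValueError("zero-truncated Poisson is defined for k >= 1 only")
    p = sps.poisson.pmf(k_arr, lam) / -np.expm1(-lam)
    return float(p) if np.isscalar(k) else p


def ztp_rvs(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw `size` zero-truncated Poisson variates by inverse-CDF sampling.

    Uniforms are mapped into the conditional CDF range (P(0), 1] so every
    draw is >= 1; exact for any lam > 0 (no rejection loop).
    """
    if lam <= 0:
        raise ValueError(f"rate must be > 0, got {lam}")
    p0 = np.exp(-lam)
    u = rng.uniform(size=size)
    k = sps.poisson.ppf(p0 + u * (1.0 - p0), lam).astype(np.int64)
    return np.maximum(k, 1)


def ztp_mean(lam: float) -> float:
    """Mean of the zero-truncated Poisson: lam / (1 - exp(-lam))."""
    return lam / -np.expm1(-lam)


@dataclass(frozen=True)
class ZTPModel:
    """Maximum-likelihood zero-truncated Poisson fit."""

    lam: float
    se: float
    loglik: float
    n: int
    converged: bool

    def pmf(self, k):
        return ztp_pmf(k, self.lam)

    @property
    def mean(self) -> float:
        return ztp_mean(self.lam)


def _ztp_loglik(lam: float, counts: np.ndarray) -> float:
    return float(np.sum(sps.poisson.logpmf(counts, lam) - np.log(-np.expm1(-lam))))


def ztp_fit(counts: Sequence[int]) -> ZTPModel:
    """Fit a zero-truncated Poisson to CPM counts by maximum likelihood.

    The MLE solves the moment equation lam / (1 - exp(-lam)) = sample mean by
    bracketed root finding (Brent, xtol 1e-8).  The standard error comes from
    the observed Fisher information of the truncated likelihood,

        -l''(lam) = n * (mean / lam^2 - exp(-lam) / (1 - exp(-lam))^2).

    A sample mean <= 1 (all counts equal to 1) sits on the boundary of the
    parameter space; the fit then returns the bracket's lower bound with
    ``converged=False``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size < 2:
        raise ValueError("need at least 2 observations")
    if np.any(counts < 1):
        raise ValueError("all counts must be >= 1 (zero-truncated data)")

    m = float(counts.mean())
    if m <= 1.0 + 1e-12:
        lam = _LAMBDA_LO
        return ZTPModel(lam, float("nan"), _ztp_loglik(lam, counts), counts.size, False)
    if m >= ztp_mean(_LAMBDA_HI):
        lam = _LAMBDA_HI
        return ZTPModel(lam, float("nan"), _ztp_loglik(lam, counts), counts.size, False)

    lam = optimize.brentq(lambda l: ztp_mean(l) - m, _LAMBDA_LO, _LAMBDA_HI, xtol=1e-8)
    e = np.exp(-lam)
    info = counts.size * (m / lam**2 - e / (1.0 - e) ** 2)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("nan")
    return ZTPModel(float(lam), se, _ztp_loglik(lam, counts), counts.size, True)


@dataclass(frozen=True)
class GrowthCorrelation:
    """OLS fit of total cell volume (μm³) on cell count."""

    slope: float  # μm³ per cell
    intercept: float  # μm³
    r_squared: float
    n: int


def fit_growth_correlation(
    cell_counts: Sequence[float], total_volumes: Sequence[float]
) -> GrowthCorrelation:
    """Ordinary least squares of total cell volume on cell number.

    Volume is the response and count the predictor, matching how the growth
    trend is plotted (cell number on x, total volume on y); R² is the usual
    1 - SS_res / SS_tot.
    """
    x = np.asarray(cell_counts, dtype=float)
    y = np.asarray(total_volumes, dtype=float)
    if x.shape != y.shape:
        raise ValueError("cell_counts and total_volumes must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a growth regression")
    if np.ptp(x) == 0:
        raise ValueError("cell counts have zero variance; regression undefined")
    res = sps.linregress(x, y)
    return GrowthCorrelation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )


@dataclass(frozen=True)
class SamplingAdequacy:
    """Smallest sample size meeting a CI-half-width target for mean CPM."""

    m: int
    achieved: bool
    halfwidth: float  # attained 95% CI half-width at m (same units as CPM)
    target_halfwidth: float  # absolute target (fraction × sample mean)


def _as_counts(cpm) -> np.ndarray:
    """Accept a CPMDistribution, a {k: count} mapping, or a raw count vector."""
    hist = getattr(cpm, "histogram", None)
    if hist is None and isinstance(cpm, Mapping):
        hist = cpm
    if hist is not None:
        return np.repeat(
            np.fromiter(hist.keys(), dtype=np.int64),
            np.fromiter(hist.values(), dtype=np.int64),
        )
    return np.asarray(cpm, dtype=np.int64)


def sampling_adequacy(
    cpm,
    target_halfwidth: float = 0.2,
    n_boot: int = 300,
    seed: int = 0,
) -> SamplingAdequacy:
    """Minimum number of populated microcarriers to estimate mean CPM.

    For each candidate subsample size m the CPM data are bootstrap-resampled
    ``n_boot`` times; the smallest m whose 95% percentile CI half-width for
    the mean is at most ``target_halfwidth`` × (full-sample mean) is returned.
    If no m up to n attains the target, m = n is returned with
    ``achieved=False``.  Deterministic for a fixed seed, and a single rng is
    used across all m so that tightening the target can only increase m.
    """
    counts = _as_counts(cpm)
    if counts.size == 0:
        raise ValueError("empty CPM distribution")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    n = counts.size
    target = target_halfwidth * float(counts.mean())
    rng = np.random.default_rng(seed)
    last_hw = float("inf")
    for m in range(1, n + 1):
        means = rng.choice(counts, size=(n_boot, m), replace=True).mean(axis=1)
        lo, hi = np.quantile(means, [0.025, 0.975])
        last_hw = float((hi - lo) / 2.0)
        if last_hw <= target:
            return SamplingAdequacy(m, True, last_hw, target)
    return SamplingAdequacy(n, False, last_hw, target)
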