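"""Extreme-value analysis of lognormally distributed dissociation rates.

Across a random peptide library, log10 of the dissociation rate ``k_d`` is
taken to be normally distributed with mean ``mu`` and spread ``sigma``. The
best binder in a library of ``N`` members is the minimum of ``N`` draws, so
its expected ``log10 k_d`` falls roughly linearly in ``log10 N`` — bigger
libraries buy slower-dissociating best binders. The module provides the
closed-form best-binder location (a quantile surrogate and the exact expected
minimum), the fold-improvement between two library sizes, a calibration of
``sigma`` from an observed fold-per-decades statement, and seeded Monte-Carlo
simulation of the best binder (direct sampling, or exact order-statistic
sampling via the Beta transform when ``N`` is astronomically large).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import ndtri

__all__ = [
    "EVTParams",
    "expected_min_log10_kd",
    "fold_improvement",
    "calibrate_sigma",
    "simulate_best_binder",
    "BestBinderSummary",
    "evt_table",
]

#: above this library size, direct sampling switches to the Beta-transform
#: order-statistic sampler
DIRECT_SAMPLING_LIMIT = 10**7


@dataclass(frozen=True)
class EVTParams:
    """Lognormal ``k_d`` model: ``log10 k_d ~ Normal(mu, sigma)``, library size N."""

    mu: float
    sigma: float
    N: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.N < 1:
            raise ValueError("library size must be >= 1")


def _min_quantile(N: float) -> float:
    """Standard-normal quantile surrogate for the minimum of N draws."""
    return float(ndtri(1.0 / (N + 1.0)))


def _exact_mean_min(N: float, n_nodes: int = 1024) -> float:
    """Exact expected minimum of N standard normals by Gauss-Legendre.

    Uses the substitution ``min = ndtri(B)`` with ``B ~ Beta(1, N)``; with
    ``B = 1 - V^(1/N)`` for uniform V the integrand is evaluated stably as
    ``-expm1(log(v)/N)`` even for N ~ 1e14.
    """
    x, w = leggauss(n_nodes)
    v = 0.5 * (x + 1.0)
    w = 0.5 * w
    eps = -np.expm1(np.log(v) / N)
    return float(np.sum(w * ndtri(eps)))


def expected_min_log10_kd(p: EVTParams, method: str = "quantile") -> float:
    """Expected best-binder ``log10 k_d`` among ``N`` library members.

    ``method="quantile"`` (default) is the quantile surrogate
    ``mu + sigma * Phi^-1(1/(N+1))``; ``method="mean"`` is the exact expected
    minimum (order-statistic mean, numerically integrated), which sits
    0.07-0.15 standard units below the surrogate over N = 1e3..1e13.
    Both decrease in N for sigma > 0 and reduce to ``mu`` at N=1 or sigma=0.
    """
    if method == "quantile":
        return p.mu + p.sigma * _min_quantile(p.N)
    if method == "mean":
        return p.mu + p.sigma * _exact_mean_min(p.N)
    raise ValueError(f"unknown method {method!r}")


def fold_improvement(N1: float, N2: float, sigma: float) -> float:
    """Fold-slowing of the best binder's ``k_d`` going from N1 to N2 members.

    ``10 ** (sigma * (q(N1) - q(N2)))`` with ``q(N) = Phi^-1(1/(N+1))``;
    independent of ``mu`` and monotone in ``sigma`` and in ``N2/N1``.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if not N2 >= N1 >= 1:
        raise ValueError("require N2 >= N1 >= 1")
    return 10.0 ** (sigma * (_min_quantile(N1) - _min_quantile(N2)))


def calibrate_sigma(
    target_fold: float, decades_of_diversity: float, anchor_N: float = 1e6
) -> float:
    """Spread ``sigma`` that yields ``target_fold`` per ``decades`` of diversity.

    ``fold_improvement`` is loglinear in sigma, so the inversion is exact:
    ``sigma = log10(fold) / (q(anchor) - q(anchor * 10^decades))``.
    """
    if target_fold < 1:
        raise ValueError("target_fold must be >= 1")
    if decades_of_diversity <= 0:
        raise ValueError("decades_of_diversity must be positive")
    denom = _min_quantile(anchor_N) - _min_quantile(anchor_N * 10**decades_of_diversity)
    return math.log10(target_fold) / denom


@dataclass
class BestBinderSummary:
    """Monte-Carlo distribution summary of the best binder's log10 k_d."""

    mean: float
    sd: float
    quantiles: Dict[float, float]
    replicates: int
    method: str  # "direct" or "order-statistic"
    values: np.ndarray


def simulate_best_binder(
    p: EVTParams,
    replicates: int = 500,
    seed: Optional[int] = None,
    method: str = "auto",
) -> BestBinderSummary:
    """Seeded Monte Carlo of the minimum ``log10 k_d`` over N library members.

    Direct sampling draws N normals per replicate (chunked); for N beyond
    :data:`DIRECT_SAMPLING_LIMIT` (or on request) the exact distribution of
    the minimum is sampled through the Beta(1, N) transform
    ``min = mu + sigma * Phi^-1(1 - U^(1/N))``, which is equivalent in
    distribution and O(replicates) regardless of N.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if method == "auto":
        method = "direct" if p.N <= DIRECT_SAMPLING_LIMIT else "order-statistic"
    rng = np.random.default_rng(seed)
    n = int(round(p.N))
    if method == "direct":
        if n > DIRECT_SAMPLING_LIMIT * 10:
            raise ValueError("N too large for direct sampling; use order-statistic")
        mins = np.empty(replicates)
        chunk = max(1, min(n, 4_000_000))
        for i in range(replicates):
            best = np.inf
            remaining = n
            while remaining > 0:
                draw = rng.standard_normal(min(chunk, remaining))
                best = min(best, float(draw.min()))
                remaining -= draw.size
            mins[i] = best
    elif method == "order-statistic":
        u = rng.random(replicates)
        eps = -np.expm1(np.log(u) / p.N)  # Beta(1, N) via inverse CDF, stable
        mins = ndtri(eps)
    else:
        raise ValueError(f"unknown method {method!r}")
    values = p.mu + p.sigma * mins
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    return BestBinderSummary(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if replicates > 1 else 0.0,
        quantiles={q: float(np.quantile(values, q)) for q in qs},
        replicates=replicates,
        method=method,
        values=values,
    )


def evt_table(
    mu: float,
    sigma: float,
    library_sizes,
    replicates: int = 200,
    seed: Optional[int] = None,
):
    """Closed-form and Monte-Carlo best-binder ``k_d`` over a grid of N.

    Returns a DataFrame with one row per library size: the quantile-surrogate
    and exact-mean expectations and the Monte-Carlo mean +- SD, all on the
    ``k_d`` scale (s^-1) and in log10.
    """
    import pandas as pd

    rows = []
    for i, n in enumerate(library_sizes):
        params = EVTParams(mu=mu, sigma=sigma, N=float(n))
        closed = expected_min_log10_kd(params, method="quantile")
        exact = expected_min_log10_kd(params, method="mean")
        sim = simulate_best_binder(
            params, replicates=replicates, seed=None if seed is None else seed + i
        )
        rows.append(
            {
                "N": float(n),
                "log10_kd_quantile": closed,
                "log10_kd_mean": exact,
                "log10_kd_mc_mean": sim.mean,
                "log10_kd_mc_sd": sim.sd,
                "best_kd_per_s": 10.0**closed,
                "mc_method": sim.method,
            }
        )
    return pd.DataFrame(rows)
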