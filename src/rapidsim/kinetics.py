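"""Binding-kinetics core: 1:1 Langmuir model, wash survival, SPR fitting.

Every displayed peptide is characterised by an association rate ``k_a``
(M^-1 s^-1) and a dissociation rate ``k_d`` (s^-1); the equilibrium
dissociation constant is ``K_D = k_d / k_a``. Selection pressure decomposes
into an association step (pseudo-first-order 1:1 binding over the incubation)
and a wash step (exponential survival of the complex over the total wash
time), which is why slow-``k_d`` binders win under stringent washing.

Family-average kinetics are geometric means ("averages in the logarithm
scale"), which makes the average ``K_D`` exactly the ratio of the average
rates. Sensorgram simulation and nonlinear 1:1 fitting close the loop between
assumed kinetics and what an SPR experiment would report.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "KineticParams",
    "FamilyKinetics",
    "Sensorgram",
    "FitResult",
    "dissociation_constant",
    "family_log_average",
    "fraction_bound",
    "wash_retention",
    "simulate_sensorgram",
    "fit_one_to_one",
    "write_sensorgram",
    "read_sensorgram",
]


@dataclass(frozen=True)
class KineticParams:
    """1:1 binding rates of one species: ``k_a`` (M^-1 s^-1), ``k_d`` (s^-1)."""

    k_a: float
    k_d: float

    def __post_init__(self) -> None:
        if not (self.k_a > 0 and self.k_d > 0):
            raise ValueError("k_a and k_d must be positive")

    @property
    def K_D(self) -> float:
        return self.k_d / self.k_a


@dataclass(frozen=True)
class FamilyKinetics:
    """Log-scale (geometric-mean) family averages of the member rates."""

    k_a_avg: float
    k_d_avg: float

    @property
    def K_D_avg(self) -> float:
        return self.k_d_avg / self.k_a_avg


def dissociation_constant(p: KineticParams) -> float:
    """Equilibrium dissociation constant ``K_D = k_d / k_a`` in M."""
    return p.k_d / p.k_a


def family_log_average(members: Sequence[KineticParams]) -> FamilyKinetics:
    """Geometric means of member rates.

    Because the mean is taken in log space, the identity
    ``K_D_avg = k_d_avg / k_a_avg = geomean(member K_Ds)`` holds exactly.
    """
    if len(members) == 0:
        raise ValueError("family must have at least one member")
    log_ka = np.log10([m.k_a for m in members])
    log_kd = np.log10([m.k_d for m in members])
    return FamilyKinetics(
        k_a_avg=float(10 ** log_ka.mean()), k_d_avg=float(10 ** log_kd.mean())
    )


def fraction_bound(p: KineticParams, target_conc: float, t: float) -> float:
    """Fraction of peptide bound after incubating with target for ``t`` s.

    Pseudo-first-order 1:1 solution with excess free target at concentration
    ``C``::

        f(t) = (k_a C / (k_a C + k_d)) * (1 - exp(-(k_a C + k_d) t))

    Monotone nondecreasing in both ``t`` and ``C``; limits to the equilibrium
    occupancy ``C / (C + K_D)`` as ``t -> inf``.
    """
    if target_conc < 0 or t < 0:
        raise ValueError("target concentration and time must be nonnegative")
    k_obs = p.k_a * target_conc + p.k_d
    amplitude = p.k_a * target_conc / k_obs
    return amplitude * -math.expm1(-k_obs * t)


def wash_retention(k_d: float, n_washes: int, t_wash: float) -> float:
    """Survival of the bound complex through ``n_washes`` washes of ``t_wash`` s.

    Rebinding during washes is neglected (no free target in the wash buffer),
    so survival is pure first-order decay ``exp(-k_d * n_washes * t_wash)``.
    """
    if k_d < 0 or n_washes < 0 or t_wash < 0:
        raise ValueError("k_d, n_washes and t_wash must be nonnegative")
    return math.exp(-k_d * n_washes * t_wash)


# ---------------------------------------------------------------------------
# Sensorgrams


@dataclass
class Sensorgram:
    """A concentration series of 1:1 SPR traces on a shared time grid."""

    concentrations: np.ndarray  # M, one per trace
    times: np.ndarray  # s, strictly increasing, covers both phases
    response: np.ndarray  # RU, shape (n_conc, n_times)
    t_assoc_end: float  # s, boundary between association and dissociation

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")
        if self.response.shape != (self.concentrations.size, self.times.size):
            raise ValueError("response must have shape (n_conc, n_times)")
        if not (self.times[0] <= self.t_assoc_end <= self.times[-1]):
            raise ValueError("association phase must precede dissociation phase")


def _one_to_one_response(
    k_a: float, k_d: float, rmax: float, concs: np.ndarray, times: np.ndarray, t_assoc: float
) -> np.ndarray:
    """Noise-free 1:1 forward model, continuous at the phase boundary."""
    concs = np.asarray(concs, float)[:, None]
    times = np.asarray(times, float)[None, :]
    k_obs = k_a * concs + k_d
    req = rmax * concs / (concs + k_d / k_a)
    assoc = req * -np.expm1(-k_obs * np.minimum(times, t_assoc))
    r_end = req * -np.expm1(-k_obs * t_assoc)
    dissoc = r_end * np.exp(-k_d * np.clip(times - t_assoc, 0.0, None))
    return np.where(times <= t_assoc, assoc, dissoc)


def simulate_sensorgram(
    p: KineticParams,
    concentrations: Sequence[float],
    rmax: float,
    t_assoc: float = 120.0,
    t_dissoc: float = 180.0,
    n_points: int = 241,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Sensorgram:
    """Simulate a 1:1 sensorgram with optional iid Gaussian noise."""
    concs = np.asarray(concentrations, dtype=float)
    if np.any(concs <= 0):
        raise ValueError("analyte concentrations must be positive")
    if rmax <= 0:
        raise ValueError("Rmax must be positive")
    times = np.linspace(0.0, t_assoc + t_dissoc, n_points)
    resp = _one_to_one_response(p.k_a, p.k_d, rmax, concs, times, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
    return Sensorgram(
        concentrations=concs, times=times, response=resp, t_assoc_end=t_assoc
    )


@dataclass
class FitResult:
    """Outcome of a 1:1 sensorgram fit (never raised on non-convergence)."""

    params: Optional[KineticParams]
    rmax: Optional[float]
    residual_norm: float
    converged: bool
    degenerate: bool = False
    message: str = ""


def _initial_guess(s: Sensorgram) -> "tuple[float, float, float]":
    """Two-stage start: k_d from the dissociation tail, k_a from the plateau."""
    mask = s.times > s.t_assoc_end
    t_tail = s.times[mask] - s.t_assoc_end
    kd0 = 1e-3
    slopes = []
    for trace in s.response:
        tail = trace[mask]
        ok = tail > max(1e-9, 0.02 * np.max(np.abs(trace)))
        if ok.sum() >= 3:
            slope = np.polyfit(t_tail[ok], np.log(tail[ok]), 1)[0]
            if slope < 0:
                slopes.append(-slope)
    if slopes:
        kd0 = float(np.clip(np.median(slopes), 1e-8, 10.0))
    # equilibrium plateau at the end of association per concentration
    i_assoc = np.searchsorted(s.times, s.t_assoc_end, side="right") - 1
    req = s.response[:, max(i_assoc, 0)]
    rmax0 = float(max(np.max(req) * 1.3, 1e-6))
    c = s.concentrations
    with np.errstate(divide="ignore", invalid="ignore"):
        kd_eq = c * (rmax0 / np.clip(req, 1e-12, None) - 1.0)
    kd_eq = kd_eq[np.isfinite(kd_eq) & (kd_eq > 0)]
    K_D0 = float(np.median(kd_eq)) if kd_eq.size else 1e-7
    ka0 = float(np.clip(kd0 / K_D0, 1.0, 1e9))
    return ka0, kd0, rmax0


def fit_one_to_one(s: Sensorgram) -> FitResult:
    """Nonlinear least squares of the 1:1 model over ``(k_a, k_d, Rmax)``.

    Optimised in log10 space for scale robustness. Non-convergence and
    degenerate (flat) inputs return a flagged result rather than raising.
    """
    if s.concentrations.size < 2:
        raise ValueError("need at least two analyte concentrations")
    span = float(np.ptp(s.response))
    if span <= 1e-12:
        return FitResult(
            params=None,
            rmax=None,
            residual_norm=0.0,
            converged=False,
            degenerate=True,
            message="flat responses; nothing to fit",
        )
    ka0, kd0, rmax0 = _initial_guess(s)
    x0 = np.log10([ka0, kd0, rmax0])

    def residuals(x: np.ndarray) -> np.ndarray:
        ka, kd, rmax = 10.0 ** x
        model = _one_to_one_response(
            ka, kd, rmax, s.concentrations, s.times, s.t_assoc_end
        )
        return (model - s.response).ravel()

    sol = least_squares(
        residuals,
        x0,
        bounds=(np.array([0.0, -8.0, -3.0]), np.array([9.0, 2.0, 6.0])),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    ka, kd, rmax = 10.0**sol.x
    return FitResult(
        params=KineticParams(k_a=float(ka), k_d=float(kd)),
        rmax=float(rmax),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        message=sol.message,
    )


# ---------------------------------------------------------------------------
# Delimited import/export


def write_sensorgram(path, s: Sensorgram) -> None:
    """Write a sensorgram as a small-header TSV (times x concentrations)."""
    with open(path, "w") as fh:
        fh.write(
            "# concentrations_M\t"
            + "\t".join(f"{c:.8g}" for c in s.concentrations)
            + "\n"
        )
        fh.write(f"# t_assoc_end_s\t{s.t_assoc_end:.8g}\n")
        df = pd.DataFrame(
            s.response.T,
            index=pd.Index(s.times, name="time_s"),
            columns=[f"conc_{i}" for i in range(s.concentrations.size)],
        )
        df.to_csv(fh, sep="\t")


def read_sensorgram(path) -> Sensorgram:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        concs = np.array([float(x) for x in header[1:]])
        t_assoc = float(fh.readline().rstrip("\n").split("\t")[1])
        df = pd.read_csv(io.StringIO(fh.read()), sep="\t", index_col=0)
    return Sensorgram(
        concentrations=concs,
        times=df.index.to_numpy(dtype=float),
        response=df.to_numpy(dtype=float).T,
        t_assoc_end=t_assoc,
    )
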