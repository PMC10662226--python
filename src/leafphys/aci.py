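"""A/ci photosynthetic capacity models and fitting.

C3 leaves (tomato, barley) are modelled with the Farquhar–von Caemmerer–Berry
(FvCB) scheme: net assimilation is the minimum of a Rubisco-limited rate
(governed by Vcmax) and an RuBP-regeneration-limited rate (governed by Jmax),
minus day respiration Rd.  Capacity parameters are estimated with the bilinear
method: each candidate transition point splits the curve into a low-ci segment
fitted as a linear regression in the Rubisco substrate term and a high-ci
segment fitted in the electron-transport term, and the split with the smallest
full-curve squared error wins.

C4 leaves (maize) are treated empirically: the maximum PEPc carboxylation rate
Vpmax is estimated from the initial (low-ci) slope region with a
Michaelis–Menten form, and the CO2- and light-saturated rate Amax as the
horizontal asymptote of a four-parameter non-rectangular hyperbola fitted to
the whole curve.

All fits are on a ci basis (mesophyll conductance assumed infinite) and all
kinetic constants are fixed scalars at the 25 °C measurement temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticConstants",
    "ACiCurve",
    "FvCBFit",
    "VpmaxFit",
    "C4Fit",
    "FitError",
    "fvcb_ac",
    "fvcb_aj",
    "fvcb_an",
    "c4_pepc_limited",
    "nrh",
    "fit_fvcb_bilinear",
    "fit_vpmax",
    "fit_nrh_amax",
    "compute_iwue",
]


class FitError(ValueError):
    """Raised when a curve cannot be fitted (too few points, degenerate data)."""


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetic constants at 25 °C (the community defaults).

    gammastar : CO2 compensation point in the absence of Rd, µmol mol⁻¹
    Kc        : Michaelis constant for CO2, µmol mol⁻¹
    Ko        : Michaelis constant for O2, mmol mol⁻¹
    O         : oxygen concentration, mmol mol⁻¹
    leaf_temp : leaf temperature, °C (informational; no temperature response)
    """

    gammastar: float = 42.75
    Kc: float = 404.9
    Ko: float = 278.4
    O: float = 210.0
    leaf_temp: float = 25.0

    def __post_init__(self) -> None:
        for name in ("gammastar", "Kc", "Ko", "O"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def Km(self) -> float:
        """Effective Michaelis constant Kc·(1 + O/Ko), µmol mol⁻¹."""
        return self.Kc * (1.0 + self.O / self.Ko)


DEFAULT_CONSTANTS = KineticConstants()


@dataclass
class ACiCurve:
    """One replicate's CO2-response series.

    Arrays are aligned per measurement point, in measurement order.
    """

    species: str
    treatment: str
    time_of_day: str
    replicate_id: str
    co2_set: np.ndarray
    ci: np.ndarray
    A: np.ndarray
    gs: np.ndarray

    def __post_init__(self) -> None:
        self.co2_set = np.asarray(self.co2_set, dtype=float)
        self.ci = np.asarray(self.ci, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.gs = np.asarray(self.gs, dtype=float)
        n = len(self.co2_set)
        if not (len(self.ci) == len(self.A) == len(self.gs) == n):
            raise ValueError("co2_set, ci, A, gs must have equal length")
        if not np.all(np.isfinite(self.ci)) or np.any(self.ci < 0):
            raise ValueError("ci must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.ci)


@dataclass
class FvCBFit:
    """Bilinear FvCB fit result (C3)."""

    Vcmax: float
    Jmax: float
    Rd: float
    transition_ci: float
    sse: float
    n_points: int
    success: bool = True
    message: str = ""


@dataclass
class VpmaxFit:
    """Initial-slope PEPc fit result (C4)."""

    Vpmax: float
    Kp: float
    Rd_slope: float
    sse: float
    n_points: int
    success: bool = True
    message: str = ""


@dataclass
class C4Fit:
    """Four-parameter non-rectangular hyperbola fit result (C4)."""

    Amax: float
    phi: float
    theta: float
    offset: float
    Asat: float
    sse: float
    n_points: int
    success: bool = True
    theta_pinned: bool = False
    message: str = ""


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def fvcb_ac(ci, Vcmax: float, Rd: float, constants: KineticConstants = DEFAULT_CONSTANTS):
    """Rubisco-limited net assimilation: Vcmax·(ci − Γ*)/(ci + Km) − Rd."""
    ci = np.asarray(ci, dtype=float)
    _check_ci(ci)
    return Vcmax * (ci - constants.gammastar) / (ci + constants.Km) - Rd


def fvcb_aj(ci, J: float, Rd: float, constants: KineticConstants = DEFAULT_CONSTANTS):
    """RuBP-regeneration-limited net assimilation: J·(ci − Γ*)/(4ci + 8Γ*) − Rd."""
    ci = np.asarray(ci, dtype=float)
    _check_ci(ci)
    g = constants.gammastar
    return J * (ci - g) / (4.0 * ci + 8.0 * g) - Rd


def fvcb_an(ci, Vcmax: float, J: float, Rd: float,
            constants: KineticConstants = DEFAULT_CONSTANTS):
    """Net assimilation min(Ac, Aj), both already net of Rd."""
    return np.minimum(fvcb_ac(ci, Vcmax, Rd, constants),
                      fvcb_aj(ci, J, Rd, constants))


def c4_pepc_limited(ci, Vpmax: float, Kp: float, Rd: float):
    """PEPc-limited net assimilation: Vpmax·ci/(ci + Kp) − Rd."""
    ci = np.asarray(ci, dtype=float)
    _check_ci(ci)
    return Vpmax * ci / (ci + Kp) - Rd


def nrh(ci, phi: float, Asat: float, theta: float, offset: float = 0.0):
    """Four-parameter non-rectangular hyperbola.

    A(ci) = [φ·ci + Asat − √((φ·ci + Asat)² − 4θ·φ·ci·Asat)]/(2θ) + offset

    The horizontal asymptote is Asat + offset; the initial slope is φ.
    """
    ci = np.asarray(ci, dtype=float)
    x = phi * ci
    disc = (x + Asat) ** 2 - 4.0 * theta * x * Asat
    disc = np.maximum(disc, 0.0)  # exact zero possible only at theta == 1
    return (x + Asat - np.sqrt(disc)) / (2.0 * theta) + offset


def _check_ci(ci: np.ndarray) -> None:
    if np.any(ci < 0):
        raise ValueError("ci must be non-negative")


def compute_iwue(A, gs):
    """Intrinsic water-use efficiency iWUE = A/gs (µmol CO2 per mol H2O)."""
    A = np.asarray(A, dtype=float)
    gs = np.asarray(gs, dtype=float)
    if np.any(gs <= 0):
        raise ValueError("iWUE undefined for gs <= 0")
    out = A / gs
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_fvcb_bilinear(curve: ACiCurve,
                      constants: KineticConstants = DEFAULT_CONSTANTS,
                      min_segment: int = 3) -> FvCBFit:
    """Fit the FvCB model with the bilinear transition-point method.

    Points are sorted by ci; for every split leaving at least ``min_segment``
    points on each side, the low-ci segment is regressed as
    A = Vcmax·x1 − Rd with x1 = (ci − Γ*)/(ci + Km), and the high-ci segment
    (with Rd fixed from the low segment) as A + Rd = Jmax·x2 with
    x2 = (ci − Γ*)/(4ci + 8Γ*).  The split minimising the full-curve SSE
    against min(Ac, Aj) wins; ties go to the smaller split index.
    """
    n = len(curve)
    if n < 2 * min_segment:
        raise FitError(f"need at least {2 * min_segment} points, got {n}")

    order = np.argsort(curve.ci, kind="stable")
    ci = curve.ci[order]
    A = curve.A[order]
    g = constants.gammastar
    Km = constants.Km
    x1 = (ci - g) / (ci + Km)
    x2 = (ci - g) / (4.0 * ci + 8.0 * g)

    best: tuple[float, float, float, float, int] | None = None
    for k in range(min_segment, n - min_segment + 1):
        X = np.column_stack([x1[:k], np.ones(k)])
        coef, *_ = np.linalg.lstsq(X, A[:k], rcond=None)
        Vcmax, intercept = float(coef[0]), float(coef[1])
        Rd = -intercept
        if Vcmax <= 1e-6:   # flat/degenerate segment, not a real capacity
            continue
        xu = x2[k:]
        yu = A[k:] + Rd
        denom = float(xu @ xu)
        if denom <= 0:
            continue
        J = float(xu @ yu) / denom
        if J <= 1e-6:
            continue
        pred = np.minimum(Vcmax * x1, J * x2) - Rd
        sse = float(np.sum((A - pred) ** 2))
        if best is None or sse < best[0]:
            best = (sse, Vcmax, J, Rd, k)

    if best is None:
        return FvCBFit(np.nan, np.nan, np.nan, np.nan, np.nan, n,
                       success=False, message="no valid split (degenerate data)")

    sse, Vcmax, J, Rd, k = best
    transition_ci = 0.5 * (ci[k - 1] + ci[k])
    return FvCBFit(Vcmax=Vcmax, Jmax=J, Rd=Rd, transition_ci=float(transition_ci),
                   sse=sse, n_points=n)


def fit_vpmax(curve: ACiCurve, ci_cutoff: float = 100.0,
              Kp_fixed: float = 80.0) -> VpmaxFit:
    """Estimate Vpmax from the initial (low-ci) region of a C4 curve.

    With Kp fixed, A = Vpmax·u − Rd with u = ci/(ci + Kp) is linear in the
    two unknowns; the least-squares optimum is computed in closed form.
    """
    mask = curve.ci <= ci_cutoff
    n = int(mask.sum())
    if n < 3:
        raise FitError(f"need >= 3 points with ci <= {ci_cutoff}, got {n}")
    ci = curve.ci[mask]
    A = curve.A[mask]
    u = ci / (ci + Kp_fixed)
    X = np.column_stack([u, -np.ones(n)])
    coef, _, rank, _ = np.linalg.lstsq(X, A, rcond=None)
    Vpmax, Rd = float(coef[0]), float(coef[1])
    sse = float(np.sum((X @ coef - A) ** 2))
    if rank < 2 or Vpmax <= 1e-6:   # no resolvable initial slope
        return VpmaxFit(np.nan, Kp_fixed, np.nan, sse, n, success=False,
                        message="degenerate low-ci data (no resolvable slope)")
    return VpmaxFit(Vpmax=Vpmax, Kp=Kp_fixed, Rd_slope=Rd, sse=sse, n_points=n)


def fit_nrh_amax(curve: ACiCurve,
                 theta_bounds: tuple[float, float] = (0.01, 0.999),
                 n_restarts: int = 5,
                 seed: int = 0) -> C4Fit:
    """Fit the four-parameter non-rectangular hyperbola; Amax = asymptote.

    Multi-start Levenberg-style least squares (trust-region reflective, to
    honour the theta bounds): the base start uses the slope of the two
    lowest-ci points for φ, 1.1·max(A) for Asat, 0.7 for θ and min(0, min A)
    for the offset, followed by jittered restarts.
    """
    n = len(curve)
    if n < 6:
        raise FitError(f"need >= 6 points, got {n}")
    order = np.argsort(curve.ci, kind="stable")
    ci = curve.ci[order]
    A = curve.A[order]

    dci = ci[1] - ci[0]
    phi0 = (A[1] - A[0]) / dci if dci > 0 else 0.1
    phi0 = max(phi0, 1e-3)
    Asat0 = 1.1 * max(float(np.max(A)), 1e-3)
    theta0 = 0.7
    offset0 = min(0.0, float(np.min(A)))
    p0 = np.array([phi0, Asat0, theta0, offset0])

    lo = np.array([1e-6, 1e-6, theta_bounds[0], -np.inf])
    hi = np.array([np.inf, np.inf, theta_bounds[1], np.inf])

    def resid(p):
        return nrh(ci, p[0], p[1], p[2], p[3]) - A

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(n_restarts + 1):
        if trial == 0:
            start = p0
        else:
            jitter = rng.normal(0.0, 0.2, size=4)
            start = p0 * (1.0 + jitter)
            start[3] = p0[3] + jitter[3] * max(abs(p0[3]), 1.0)
        start = np.clip(start, lo, hi)
        start[2] = min(max(start[2], theta_bounds[0] + 1e-3), theta_bounds[1] - 1e-3)
        try:
            res = least_squares(resid, start, bounds=(lo, hi),
                                ftol=1e-8, xtol=1e-10, gtol=1e-10)
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        sse = float(2.0 * res.cost)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, res.x)

    if best is None:
        return C4Fit(*([np.nan] * 6), n_points=n, success=False,
                     message="non-convergence after all starts")

    sse, (phi, Asat, theta, offset) = best
    eps = 1e-4
    pinned = (theta <= theta_bounds[0] + eps) or (theta >= theta_bounds[1] - eps)
    if pinned:
        warnings.warn("NRH curvature theta pinned at a bound", RuntimeWarning,
                      stacklevel=2)
    return C4Fit(Amax=float(Asat + offset), phi=float(phi), theta=float(theta),
                 offset=float(offset), Asat=float(Asat), sse=sse, n_points=n,
                 theta_pinned=bool(pinned))
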