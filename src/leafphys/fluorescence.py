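"""Chlorophyll-fluorescence traits and NPQ induction/relaxation kinetics.

Non-photochemical quenching at each saturating pulse is
NPQ = (Fm − Fm′)/Fm′, with Fm the dark-adapted maximal fluorescence and Fm′
the light-adapted maximal fluorescence at the pulse.  The light-induction
phase is fitted with a saturating exponential, NPQ(t) = a·(1 − e^(−b·t)),
and the dark-relaxation phase (time re-zeroed at light-off) with a decaying
exponential plus offset, NPQ(t) = a·e^(−b·t) + c, where a is the amplitude,
b the rate constant (min⁻¹) and c the sustained (non-relaxing) quenching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .aci import FitError

__all__ = [
    "FluorTrace",
    "NPQFit",
    "compute_npq",
    "compute_fvfm",
    "npq_induction",
    "npq_relaxation",
    "fit_induction",
    "fit_relaxation",
    "max_npq",
]


@dataclass
class FluorTrace:
    """Pulse fluorescence time-series for one leaf.

    Times are minutes since the start of the respective phase (relaxation
    re-zeroed at light-off).  Instrument tag keeps leaf-chamber and imaging
    traces separate; they are never pooled in analysis.
    """

    leaf_id: str
    Fm_dark: float
    Fo: float
    t_induction: np.ndarray
    fm_prime_induction: np.ndarray
    t_relaxation: np.ndarray
    fm_prime_relaxation: np.ndarray
    treatment: str = ""
    instrument: str = "chamber"

    def __post_init__(self) -> None:
        self.t_induction = np.asarray(self.t_induction, dtype=float)
        self.fm_prime_induction = np.asarray(self.fm_prime_induction, dtype=float)
        self.t_relaxation = np.asarray(self.t_relaxation, dtype=float)
        self.fm_prime_relaxation = np.asarray(self.fm_prime_relaxation, dtype=float)
        if self.Fm_dark <= 0 or self.Fo <= 0:
            raise ValueError("Fm and Fo must be positive")
        if self.Fo >= self.Fm_dark:
            raise ValueError("Fo must be below Fm")
        for t in (self.t_induction, self.t_relaxation):
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError("pulse times must be strictly increasing")
        if np.any(self.fm_prime_induction <= 0) or np.any(self.fm_prime_relaxation <= 0):
            raise ValueError("Fm' values must be positive")

    def npq_induction_values(self) -> np.ndarray:
        return compute_npq(self.Fm_dark, self.fm_prime_induction)

    def npq_relaxation_values(self) -> np.ndarray:
        return compute_npq(self.Fm_dark, self.fm_prime_relaxation)

    @property
    def fvfm(self) -> float:
        return compute_fvfm(self.Fm_dark, self.Fo)


@dataclass
class NPQFit:
    phase: str                     # 'induction' or 'relaxation'
    a: float
    b: float
    c: Optional[float]             # None for induction
    rmse: float
    success: bool = True
    message: str = ""


def compute_npq(Fm, Fm_prime):
    """NPQ = (Fm − Fm′)/Fm′; may be negative (never clipped)."""
    Fm_prime = np.asarray(Fm_prime, dtype=float)
    if np.any(Fm_prime <= 0):
        raise ValueError("Fm' must be positive")
    out = (Fm - Fm_prime) / Fm_prime
    return float(out) if out.ndim == 0 else out


def compute_fvfm(Fm: float, Fo: float) -> float:
    """Maximum PSII efficiency Fv/Fm = (Fm − Fo)/Fm, in (0, 1)."""
    if Fm <= 0:
        raise ValueError("Fm must be positive")
    if not (0 < Fo < Fm):
        raise ValueError("require 0 < Fo < Fm")
    return (Fm - Fo) / Fm


def npq_induction(t, a: float, b: float):
    """Induction model a·(1 − e^(−b·t))."""
    return a * (1.0 - np.exp(-b * np.asarray(t, dtype=float)))


def npq_relaxation(t, a: float, b: float, c: float):
    """Relaxation model a·e^(−b·t) + c."""
    return a * np.exp(-b * np.asarray(t, dtype=float)) + c


def _fit(resid, p0, bounds, n_restarts, seed):
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(n_restarts + 1):
        start = p0 if trial == 0 else p0 * (1.0 + rng.normal(0, 0.3, size=len(p0)))
        start = np.clip(start, bounds[0], bounds[1])
        try:
            res = least_squares(resid, start, bounds=bounds, xtol=1e-10,
                                ftol=1e-12, gtol=1e-12)
        except Exception:  # pragma: no cover
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    return best


def fit_induction(trace: FluorTrace, n_restarts: int = 3, seed: int = 0) -> NPQFit:
    """Fit NPQ(t) = a·(1 − e^(−b·t)) to the induction pulses.

    a, b are bounded below by 0.  a starts at the final NPQ; b from a
    log-linearisation of the first half of the rise.
    """
    t = trace.t_induction
    if len(t) < 4:
        raise FitError("need >= 4 induction pulses")
    y = trace.npq_induction_values()
    if np.all(y <= 0):
        return NPQFit("induction", np.nan, np.nan, None, np.nan,
                      success=False, message="all NPQ <= 0")

    a0 = max(float(y[-1]), 1e-3)
    half = max(2, len(t) // 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - y[:half] / (1.05 * a0)
        ok = (frac > 1e-6) & (t[:half] > 0)
        b0 = float(-np.polyfit(t[:half][ok], np.log(frac[ok]), 1)[0]) if ok.sum() >= 2 else 0.5
    b0 = b0 if np.isfinite(b0) and b0 > 0 else 0.5

    bounds = (np.array([0.0, 0.0]), np.array([np.inf, np.inf]))
    res = _fit(lambda p: npq_induction(t, *p) - y, np.array([a0, b0]),
               bounds, n_restarts, seed)
    if res is None:
        return NPQFit("induction", np.nan, np.nan, None, np.nan,
                      success=False, message="non-convergence")
    a, b = res.x
    rmse = float(np.sqrt(np.mean((npq_induction(t, a, b) - y) ** 2)))
    return NPQFit("induction", float(a), float(b), None, rmse)


def fit_relaxation(trace: FluorTrace, n_restarts: int = 3, seed: int = 0) -> NPQFit:
    """Fit NPQ(t) = a·e^(−b·t) + c to the relaxation pulses.

    a, b bounded below by 0; the sustained-quenching offset c is free in
    sign.  c starts at the final NPQ, a at (first − c).
    """
    t = trace.t_relaxation
    if len(t) < 4:
        raise FitError("need >= 4 relaxation pulses")
    y = trace.npq_relaxation_values()
    if np.all(y <= 0):
        return NPQFit("relaxation", np.nan, np.nan, None, np.nan,
                      success=False, message="all NPQ <= 0")

    c0 = float(y[-1])
    a0 = max(float(y[0]) - c0, 1e-3)
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    b0 = 2.0 / span

    bounds = (np.array([0.0, 0.0, -np.inf]), np.array([np.inf] * 3))
    res = _fit(lambda p: npq_relaxation(t, *p) - y, np.array([a0, b0, c0]),
               bounds, n_restarts, seed)
    if res is None:
        return NPQFit("relaxation", np.nan, np.nan, np.nan, np.nan,
                      success=False, message="non-convergence")
    a, b, c = res.x
    rmse = float(np.sqrt(np.mean((npq_relaxation(t, a, b, c) - y) ** 2)))
    return NPQFit("relaxation", float(a), float(b), float(c), rmse)


def max_npq(trace: FluorTrace) -> float:
    """Maximum observed induction-phase NPQ (a per-leaf scalar trait).

    The observed maximum is used rather than the fitted amplitude so the
    trait stays meaningful when induction has not plateaued.
    """
    if len(trace.t_induction) == 0:
        raise FitError("empty induction phase")
    return float(np.max(trace.npq_induction_values()))
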