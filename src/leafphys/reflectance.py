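"""Hyperspectral leaf-reflectance analysis.

Technical replicates are averaged per leaf, literature-standard reflectance
indices are evaluated from a configurable registry, and treatment effects
are tested wavelength-by-wavelength with one-way ANOVA under Bonferroni
family-wise control (threshold α/N over the N wavelengths actually tested).
p-values are reported alongside their −log10 transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Spectrum",
    "SpectraSet",
    "IndexDefinition",
    "DEFAULT_INDICES",
    "UndefinedIndexError",
    "default_wavelength_grid",
    "average_technical_reps",
    "compute_index",
    "compute_indices",
    "spectra_wide_anova",
    "bonferroni_threshold",
]


class UndefinedIndexError(ArithmeticError):
    """Raised when an index expression hits a zero denominator."""


def default_wavelength_grid() -> np.ndarray:
    """Spectroradiometer grid: 350–2500 nm at 1 nm (2151 points)."""
    return np.arange(350, 2501, dtype=float)


@dataclass
class Spectrum:
    """A single reflectance spectrum on an ascending wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    leaf_id: str = ""
    treatment: str = ""
    time_of_day: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if len(self.wavelengths) != len(self.reflectance):
            raise ValueError("wavelengths and reflectance must align")
        if len(self.wavelengths) > 1 and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")

    def at(self, wavelength: float) -> float:
        """Reflectance at the nearest grid point (λ must be within the span)."""
        wl = self.wavelengths
        if not (wl[0] <= wavelength <= wl[-1]):
            raise ValueError(f"wavelength {wavelength} outside grid span "
                             f"[{wl[0]}, {wl[-1]}]")
        idx = int(np.argmin(np.abs(wl - wavelength)))
        return float(self.reflectance[idx])


@dataclass
class SpectraSet:
    """Per-leaf spectra on a common grid with treatment/time labels.

    ``reflectance`` is (n_spectra, n_wavelengths); ``meta`` has one row per
    spectrum with columns leaf_id, treatment, time_of_day and (optionally)
    tech_rep.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.shape != (len(self.meta), len(self.wavelengths)):
            raise ValueError("reflectance shape must be (n_meta_rows, n_wavelengths)")

    def spectra(self) -> list[Spectrum]:
        out = []
        for i, row in enumerate(self.meta.itertuples(index=False)):
            out.append(Spectrum(self.wavelengths, self.reflectance[i],
                                leaf_id=row.leaf_id, treatment=row.treatment,
                                time_of_day=row.time_of_day))
        return out

    def average_technical(self) -> "SpectraSet":
        """Collapse technical replicates to one mean spectrum per leaf."""
        keys = ["leaf_id", "treatment", "time_of_day"]
        groups = self.meta.groupby(keys, sort=False).indices
        rows, refl = [], []
        for key, idx in groups.items():
            rows.append(dict(zip(keys, key)))
            refl.append(self.reflectance[np.asarray(idx)].mean(axis=0))
        return SpectraSet(self.wavelengths, np.array(refl), pd.DataFrame(rows))


def average_technical_reps(spectra: Sequence[Spectrum]) -> Spectrum:
    """Element-wise mean of one leaf's technical-replicate spectra."""
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, first.wavelengths):
            raise ValueError("mismatched wavelength grids")
    mean = np.mean([s.reflectance for s in spectra], axis=0)
    return Spectrum(first.wavelengths, mean, leaf_id=first.leaf_id,
                    treatment=first.treatment, time_of_day=first.time_of_day)


@dataclass(frozen=True)
class IndexDefinition:
    """A named reflectance index over band reflectances R(λ).

    ``expression`` receives a band-lookup callable (nearest grid point) and
    returns the index value.  ``bands`` lists the wavelengths used, for
    validation against the grid span.
    """

    name: str
    expression: Callable[[Callable[[float], float]], float]
    bands: tuple[float, ...]


def _ratio(num: float, den: float) -> float:
    if den == 0.0:
        raise UndefinedIndexError("zero denominator")
    return num / den


DEFAULT_INDICES: dict[str, IndexDefinition] = {
    # chlorophyll-content proxy
    "Datt": IndexDefinition(
        "Datt", lambda R: _ratio(R(850) - R(710), R(850) - R(680)),
        (850, 710, 680)),
    # moisture stress (inverse water-content proxy)
    "MSI": IndexDefinition(
        "MSI", lambda R: _ratio(R(1599), R(819)), (1599, 819)),
    "NDVI": IndexDefinition(
        "NDVI", lambda R: _ratio(R(800) - R(680), R(800) + R(680)), (800, 680)),
    "PRI": IndexDefinition(
        "PRI", lambda R: _ratio(R(531) - R(570), R(531) + R(570)), (531, 570)),
    # water index
    "WI": IndexDefinition(
        "WI", lambda R: _ratio(R(900), R(970)), (900, 970)),
}


def compute_index(spectrum: Spectrum, definition: IndexDefinition) -> float:
    """Evaluate one index on one spectrum (bands resolved to nearest point)."""
    wl = spectrum.wavelengths
    for band in definition.bands:
        if not (wl[0] <= band <= wl[-1]):
            raise ValueError(f"band {band} nm outside grid span for index "
                             f"{definition.name}")
    return float(definition.expression(spectrum.at))


def compute_indices(spectra_set: SpectraSet,
                    registry: dict[str, IndexDefinition] | None = None
                    ) -> pd.DataFrame:
    """Index values per leaf (technical reps averaged first).

    Returns a tidy frame: leaf_id, treatment, time_of_day, index, value.
    Undefined indices (zero denominator) are recorded as NaN with a warning.
    """
    registry = DEFAULT_INDICES if registry is None else registry
    averaged = spectra_set.average_technical()
    rows = []
    for spec in averaged.spectra():
        for name, definition in registry.items():
            try:
                value = compute_index(spec, definition)
            except UndefinedIndexError:
                warnings.warn(f"index {name} undefined for leaf {spec.leaf_id}",
                              RuntimeWarning, stacklevel=2)
                value = np.nan
            rows.append({"leaf_id": spec.leaf_id, "treatment": spec.treatment,
                         "time_of_day": spec.time_of_day, "index": name,
                         "value": value})
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold α/N."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def spectra_wide_anova(spectra_set: SpectraSet, grouping: str = "treatment",
                       alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA at every wavelength across the grouping factor.

    Spectra are averaged across technical replicates first.  Returns one row
    per wavelength: wavelength, F, p, neglog10_p, significant (Bonferroni at
    α/N with N = number of wavelengths tested here).  Wavelengths with zero
    total variance get F = 0, p = 1 with a warning.
    """
    averaged = spectra_set.average_technical()
    groups = averaged.meta[grouping].to_numpy()
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    idx_by_group = [np.flatnonzero(groups == lab) for lab in labels]
    for lab, idx in zip(labels, idx_by_group):
        if len(idx) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 leaves")

    Y = averaged.reflectance            # (n_leaves, n_wl)
    N, n_wl = Y.shape
    k = len(labels)
    grand = Y.mean(axis=0)
    ssb = np.zeros(n_wl)
    ssw = np.zeros(n_wl)
    for idx in idx_by_group:
        sub = Y[idx]
        gm = sub.mean(axis=0)
        ssb += len(idx) * (gm - grand) ** 2
        ssw += ((sub - gm) ** 2).sum(axis=0)

    df_num, df_den = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_num) / (ssw / df_den)
    p = stats.f.sf(F, df_num, df_den)

    degenerate = (ssb + ssw) <= 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} wavelength(s) with zero "
                      "variance; reported as F=0, p=1", RuntimeWarning,
                      stacklevel=2)
        F = np.where(degenerate, 0.0, F)
        p = np.where(degenerate, 1.0, p)
    # zero within-group variance with real between-group separation
    blowup = ~degenerate & (ssw <= 0)
    if blowup.any():
        F = np.where(blowup, np.inf, F)
        p = np.where(blowup, 0.0, p)

    threshold = bonferroni_threshold(alpha, n_wl)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    return pd.DataFrame({
        "wavelength": averaged.wavelengths,
        "F": F,
        "p": p,
        "neglog10_p": neglog,
        "significant": p < threshold,
    })
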