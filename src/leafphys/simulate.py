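"""Synthetic-experiment generator.

Emulates the structure of an excised-vs-attached leaf phenotyping campaign
on tomato, barley and maize: CO2-response curves on the species-specific
setpoint sequences, the 12-pulse light / 8-pulse dark NPQ protocol,
three-technical-replicate leaf reflectance spectra on the 350–2500 nm grid,
and scalar trait tables with an additive treatment × time effect structure.
Every generator is fully determined by its seed; random streams are split
per leaf and per data type so adding replicates never perturbs existing
draws.

The generators lie exactly on their forward models at zero noise, which is
what makes downstream parameter-recovery tests meaningful.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aci import ACiCurve, KineticConstants, DEFAULT_CONSTANTS, fvcb_an, \
    c4_pepc_limited, nrh
from .fluorescence import FluorTrace, npq_induction, npq_relaxation
from .reflectance import SpectraSet, default_wavelength_grid

__all__ = [
    "EffectSpec",
    "ExperimentDesign",
    "C3TrueParams",
    "C4TrueParams",
    "NPQProtocol",
    "C3_CO2_SEQUENCE",
    "C4_UP_SEQUENCE",
    "C4_DOWN_SEQUENCE",
    "DEFAULT_REPS",
    "base_leaf_spectrum",
    "generate_aci_c3",
    "generate_aci_c4",
    "generate_aci_dataset",
    "generate_npq_trace",
    "generate_npq_dataset",
    "generate_spectra",
    "generate_trait_table",
]

# reference CO2 setpoint sequences (µmol mol⁻¹), in measurement order
C3_CO2_SEQUENCE: tuple[float, ...] = (400, 300, 200, 100, 50, 400, 400,
                                      700, 1000, 1300, 1800)
C4_UP_SEQUENCE: tuple[float, ...] = (400, 600, 800, 1000, 1250)
C4_DOWN_SEQUENCE: tuple[float, ...] = (400, 300, 250, 200, 100, 75, 25)

# default biological replicates per treatment, by species
DEFAULT_REPS: dict[str, int] = {"tomato": 10, "barley": 8, "maize": 12}

# stream codes keeping data types on independent substreams of one seed
_STREAM_GAS, _STREAM_FLUOR, _STREAM_SPECTRA, _STREAM_TRAIT = 1, 2, 3, 4


@dataclass(frozen=True)
class EffectSpec:
    """Additive effect structure for one trait (the two-way ANOVA model).

    value = baseline + treatment_delta·1[excised] + time_delta·1[PM]
            + interaction_delta·1[excised & PM] + N(0, noise_sd)
    """

    baseline: float
    treatment_delta: float = 0.0
    time_delta: float = 0.0
    interaction_delta: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def mean(self, treatment: str, time: str = "AM") -> float:
        excised = treatment == "excised"
        pm = time == "PM"
        return (self.baseline
                + self.treatment_delta * excised
                + self.time_delta * pm
                + self.interaction_delta * (excised and pm))


@dataclass
class ExperimentDesign:
    """Species × treatment × time × replicate layout with effect sizes."""

    species: str
    n_reps_per_treatment: int | None = None
    treatments: tuple[str, str] = ("attached", "excised")
    times: tuple[str, str] = ("AM", "PM")
    seed: int = 0
    effects: dict[str, EffectSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in DEFAULT_REPS:
            raise ValueError(f"unknown species {self.species!r}")
        if self.n_reps_per_treatment is None:
            self.n_reps_per_treatment = DEFAULT_REPS[self.species]
        if self.n_reps_per_treatment < 2:
            raise ValueError("n_reps_per_treatment must be >= 2")


@dataclass(frozen=True)
class C3TrueParams:
    """Generating FvCB parameters for a C3 leaf."""

    Vcmax: float = 100.0
    Jmax: float = 180.0
    Rd: float = 1.5
    gammastar: float = DEFAULT_CONSTANTS.gammastar
    Km: float = DEFAULT_CONSTANTS.Km

    def __post_init__(self) -> None:
        if min(self.Vcmax, self.Jmax, self.gammastar, self.Km) <= 0 or self.Rd < 0:
            raise ValueError("invalid C3 parameters")

    def constants(self) -> KineticConstants:
        # back out a Kc giving the requested Km at the default O/Ko ratio
        scale = self.Km / DEFAULT_CONSTANTS.Km
        return KineticConstants(gammastar=self.gammastar,
                                Kc=DEFAULT_CONSTANTS.Kc * scale)


@dataclass(frozen=True)
class C4TrueParams:
    """Generating parameters for the composite C4 forward model.

    A(ci) = min(Vpmax·ci/(ci + Kp), NRH(ci; φ, Amax, θ)) − Rd.  The
    saturating branch's initial slope φ defaults above Vpmax/Kp so that the
    low-ci response is PEPc-limited, as in real C4 leaves.
    """

    Vpmax: float = 110.0
    Kp: float = 80.0
    Amax: float = 45.0
    phi: float = 3.0
    theta: float = 0.7
    Rd: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.theta <= 1):
            raise ValueError("theta must be in (0, 1]")
        if min(self.Vpmax, self.Amax, self.Kp) <= 0 or self.Rd < 0:
            raise ValueError("invalid C4 parameters")

    def forward(self, ci):
        gross = np.minimum(c4_pepc_limited(ci, self.Vpmax, self.Kp, 0.0),
                           nrh(ci, self.phi, self.Amax, self.theta))
        return gross - self.Rd


@dataclass(frozen=True)
class NPQProtocol:
    """Saturating-pulse schedule: 12 pulses over the 10 min induction,
    8 over the 12 min relaxation (minutes since phase start)."""

    induction_times: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 10.0, 12), 6))
    relaxation_times: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 9.0, 12.0)

    def __post_init__(self) -> None:
        for times in (self.induction_times, self.relaxation_times):
            arr = np.asarray(times)
            if len(arr) > 1 and np.any(np.diff(arr) <= 0):
                raise ValueError("pulse times must be strictly increasing")


DEFAULT_PROTOCOL = NPQProtocol()


def _rng(seed: int, stream: int, *key: int) -> np.random.Generator:
    """Independent substream keyed by data type and structural position
    (treatment index, replicate, time index), so adding replicates never
    perturbs existing draws."""
    return np.random.default_rng([int(seed), int(stream), *map(int, key)])


# ---------------------------------------------------------------------------
# gas exchange
# ---------------------------------------------------------------------------

def _gen_aci(forward, co2_sequence, noise_sd, rng, drawdown, ci_jitter_sd,
             gs_baseline, gs_noise_sd, meta, ci_offset=0.0) -> ACiCurve:
    setpoints = np.asarray(co2_sequence, dtype=float)
    if len(setpoints) == 0:
        raise ValueError("co2_sequence must be nonempty")
    if np.any(setpoints <= 0):
        raise ValueError("CO2 setpoints must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ci = drawdown * setpoints + ci_offset
    if ci_jitter_sd > 0:
        ci = np.maximum(ci + rng.normal(0.0, ci_jitter_sd, len(ci)), 1.0)
    A = forward(ci) + (rng.normal(0.0, noise_sd, len(ci)) if noise_sd > 0 else 0.0)
    gs = np.full(len(ci), float(gs_baseline))
    if gs_noise_sd > 0:
        gs = gs + rng.normal(0.0, gs_noise_sd, len(ci))
    gs = np.maximum(gs, 1e-4)
    return ACiCurve(co2_set=setpoints, ci=ci, A=A, gs=gs, **meta)


def generate_aci_c3(params: C3TrueParams,
                    co2_sequence: Sequence[float] = C3_CO2_SEQUENCE,
                    noise_sd: float = 0.0, seed: int = 0,
                    drawdown: float = 0.7, ci_offset: float = 15.0,
                    ci_jitter_sd: float = 0.0,
                    gs_baseline: float = 0.3, gs_noise_sd: float = 0.0,
                    species: str = "tomato", treatment: str = "attached",
                    time_of_day: str = "AM", replicate_id: str = "r1"
                    ) -> ACiCurve:
    """One synthetic C3 CO2-response curve on the given setpoint sequence.

    ci is a fixed affine drawdown of the setpoint, ci = drawdown·setpoint +
    ci_offset (optionally jittered); the positive offset keeps low-setpoint
    ci above Γ*, mirroring how real ci approaches the ambient value as A
    falls toward the compensation point.  A = min(Ac, Aj) − Rd at the
    realised ci plus additive Gaussian noise.
    """
    constants = params.constants()

    def forward(ci):
        return fvcb_an(ci, params.Vcmax, params.Jmax, params.Rd, constants)

    rng = _rng(seed, _STREAM_GAS)
    meta = dict(species=species, treatment=treatment, time_of_day=time_of_day,
                replicate_id=replicate_id)
    return _gen_aci(forward, co2_sequence, noise_sd, rng, drawdown,
                    ci_jitter_sd, gs_baseline, gs_noise_sd, meta,
                    ci_offset=ci_offset)


def generate_aci_c4(params: C4TrueParams,
                    up_sequence: Sequence[float] = C4_UP_SEQUENCE,
                    down_sequence: Sequence[float] = C4_DOWN_SEQUENCE,
                    noise_sd: float = 0.0, seed: int = 0,
                    drawdown: float = 0.4, ci_jitter_sd: float = 0.0,
                    gs_baseline: float = 0.2, gs_noise_sd: float = 0.0,
                    species: str = "maize", treatment: str = "attached",
                    time_of_day: str = "AM", replicate_id: str = "r1"
                    ) -> ACiCurve:
    """One synthetic C4 curve: ascending then descending setpoints,
    concatenated in measurement order."""
    sequence = tuple(up_sequence) + tuple(down_sequence)
    rng = _rng(seed, _STREAM_GAS)
    meta = dict(species=species, treatment=treatment, time_of_day=time_of_day,
                replicate_id=replicate_id)
    return _gen_aci(params.forward, sequence, noise_sd, rng, drawdown,
                    ci_jitter_sd, gs_baseline, gs_noise_sd, meta)


def _shifted(params, design: ExperimentDesign, treatment: str, time: str):
    """Apply any parameter-named EffectSpecs to the generating parameters."""
    updates = {}
    for name in params.__dataclass_fields__:
        spec = design.effects.get(name)
        if spec is not None:
            updates[name] = spec.mean(treatment, time)
    return replace(params, **updates) if updates else params


def generate_aci_dataset(design: ExperimentDesign,
                         c3_params: C3TrueParams | None = None,
                         c4_params: C4TrueParams | None = None,
                         noise_sd: float = 0.3,
                         ci_jitter_sd: float = 2.0,
                         gs_noise_sd: float = 0.02) -> list[ACiCurve]:
    """Full curve set for a design: one curve per treatment × replicate × time.

    Capacity parameters named in ``design.effects`` (e.g. 'Vcmax', 'Vpmax')
    shift additively with treatment/time; 'gs' shifts the conductance
    baseline the same way.
    """
    is_c4 = design.species == "maize"
    base = (c4_params or C4TrueParams()) if is_c4 else (c3_params or C3TrueParams())
    curves = []
    for ti, treatment in enumerate(design.treatments):
        for rep in range(design.n_reps_per_treatment):
            rep_id = f"{treatment}_r{rep + 1}"
            for hi, time in enumerate(design.times):
                params = _shifted(base, design, treatment, time)
                gs_spec = design.effects.get("gs")
                gs0 = gs_spec.mean(treatment, time) if gs_spec else (0.2 if is_c4 else 0.3)
                rng = _rng(design.seed, _STREAM_GAS, ti, rep, hi)
                meta = dict(species=design.species, treatment=treatment,
                            time_of_day=time, replicate_id=rep_id)
                if is_c4:
                    seq = tuple(C4_UP_SEQUENCE) + tuple(C4_DOWN_SEQUENCE)
                    curve = _gen_aci(params.forward, seq, noise_sd, rng, 0.4,
                                     ci_jitter_sd, gs0, gs_noise_sd, meta)
                else:
                    constants = params.constants()
                    forward = lambda ci, p=params, c=constants: \
                        fvcb_an(ci, p.Vcmax, p.Jmax, p.Rd, c)
                    curve = _gen_aci(forward, C3_CO2_SEQUENCE, noise_sd, rng,
                                     0.7, ci_jitter_sd, gs0, gs_noise_sd,
                                     meta, ci_offset=15.0)
                curves.append(curve)
    return curves


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def generate_npq_trace(a_ind: float, b_ind: float, a_rel: float, b_rel: float,
                       c_rel: float, protocol: NPQProtocol = DEFAULT_PROTOCOL,
                       noise_sd: float = 0.0, seed: int = 0,
                       fvfm: float = 0.8, Fm: float = 2.0,
                       leaf_id: str = "leaf1", treatment: str = "attached",
                       instrument: str = "chamber") -> FluorTrace:
    """Synthetic pulse trace from the induction/relaxation kinetics.

    True NPQ at each pulse follows the phase model; Fm′ is back-computed as
    Fm/(NPQ + 1) and then perturbed by multiplicative log-normal noise
    (fluorescence is strictly positive).  Fo is set from the configured
    Fv/Fm.
    """
    if min(a_ind, b_ind, a_rel, b_rel, c_rel) < 0:
        raise ValueError("kinetic parameters must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (0 < fvfm < 1):
        raise ValueError("Fv/Fm must be in (0, 1)")
    t_ind = np.asarray(protocol.induction_times, dtype=float)
    t_rel = np.asarray(protocol.relaxation_times, dtype=float)
    npq_ind = npq_induction(t_ind, a_ind, b_ind)
    npq_rel = npq_relaxation(t_rel, a_rel, b_rel, c_rel)
    fm_ind = Fm / (npq_ind + 1.0)
    fm_rel = Fm / (npq_rel + 1.0)
    if noise_sd > 0:
        rng = _rng(seed, _STREAM_FLUOR)
        fm_ind = fm_ind * np.exp(rng.normal(0.0, noise_sd, len(fm_ind)))
        fm_rel = fm_rel * np.exp(rng.normal(0.0, noise_sd, len(fm_rel)))
    return FluorTrace(leaf_id=leaf_id, Fm_dark=Fm, Fo=Fm * (1.0 - fvfm),
                      t_induction=t_ind, fm_prime_induction=fm_ind,
                      t_relaxation=t_rel, fm_prime_relaxation=fm_rel,
                      treatment=treatment, instrument=instrument)


def generate_npq_dataset(design: ExperimentDesign,
                         a_ind: float = 2.5, b_ind: float = 0.4,
                         a_rel: float = 2.0, b_rel: float = 0.5,
                         c_rel: float = 0.4, fvfm: float = 0.8,
                         noise_sd: float = 0.02,
                         protocol: NPQProtocol = DEFAULT_PROTOCOL,
                         instrument: str = "chamber") -> list[FluorTrace]:
    """One trace per treatment × replicate.

    Kinetic parameters or Fv/Fm named in ``design.effects`` ('a_ind',
    'b_ind', 'a_rel', 'b_rel', 'c_rel', 'fvfm') shift with treatment.
    """
    base = dict(a_ind=a_ind, b_ind=b_ind, a_rel=a_rel, b_rel=b_rel,
                c_rel=c_rel, fvfm=fvfm)
    traces = []
    for ti, treatment in enumerate(design.treatments):
        for rep in range(design.n_reps_per_treatment):
            kw = dict(base)
            for name in base:
                spec = design.effects.get(name)
                if spec is not None:
                    kw[name] = spec.mean(treatment)
            traces.append(generate_npq_trace(
                kw["a_ind"], kw["b_ind"], kw["a_rel"], kw["b_rel"],
                kw["c_rel"], protocol=protocol, noise_sd=noise_sd,
                seed=int(_rng(design.seed, _STREAM_FLUOR, ti, rep)
                         .integers(2 ** 31)),
                fvfm=kw["fvfm"], leaf_id=f"{treatment}_r{rep + 1}",
                treatment=treatment, instrument=instrument))
    return traces


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def base_leaf_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Parametric green-leaf reflectance template.

    Low visible reflectance with a green-region bump, a logistic NIR
    shoulder at ~715 nm, water-absorption dips near 1450 and 1940 nm and a
    declining SWIR tail.  A smooth qualitative shape, not a
    radiative-transfer model.
    """
    wl = np.asarray(wavelengths, dtype=float)
    r = 0.05 + 0.40 / (1.0 + np.exp(-(wl - 715.0) / 18.0))
    r += 0.06 * np.exp(-0.5 * ((wl - 550.0) / 30.0) ** 2)       # green bump
    r -= 0.18 * np.exp(-0.5 * ((wl - 1450.0) / 40.0) ** 2)      # water dip
    r -= 0.28 * np.exp(-0.5 * ((wl - 1940.0) / 60.0) ** 2)      # water dip
    r -= 0.10 * np.exp(-0.5 * ((wl - 1200.0) / 50.0) ** 2) * 0.3
    r -= 0.25 / (1.0 + np.exp(-(wl - 2200.0) / 120.0))          # SWIR decline
    return np.clip(r, 0.0, 1.0)


def _band_bump(wl: np.ndarray, center: float, width: float,
               amplitude: float) -> np.ndarray:
    """Compact-support Gaussian bump (zero beyond 3 widths from center)."""
    d = np.abs(wl - center)
    bump = amplitude * np.exp(-0.5 * (d / width) ** 2)
    bump[d > 3.0 * width] = 0.0
    return bump


def generate_spectra(design: ExperimentDesign,
                     effect_bands: Sequence[tuple[float, float, float]] = (),
                     n_technical: int = 3, noise_sd: float = 0.01,
                     leaf_sd: float = 0.01,
                     wavelengths: np.ndarray | None = None,
                     affected_treatment: str = "excised") -> SpectraSet:
    """Technical-replicate leaf spectra for a full design.

    Each leaf's spectrum is the base template, plus the treatment-dependent
    Gaussian effect bands (applied to ``affected_treatment`` only), plus an
    independent per-leaf deviation (sd ``leaf_sd``) and per-technical-rep
    measurement noise (sd ``noise_sd``), clipped to [0, 1].
    """
    if n_technical < 1:
        raise ValueError("n_technical must be >= 1")
    wl = default_wavelength_grid() if wavelengths is None else np.asarray(wavelengths, float)
    for center, width, amplitude in effect_bands:
        if not (wl[0] <= center <= wl[-1]):
            raise ValueError(f"effect band center {center} nm outside grid")
    base = base_leaf_spectrum(wl)
    bump_total = np.zeros_like(wl)
    for center, width, amplitude in effect_bands:
        bump_total += _band_bump(wl, center, width, amplitude)

    rows, refl = [], []
    for ti, treatment in enumerate(design.treatments):
        for rep in range(design.n_reps_per_treatment):
            for hi, time in enumerate(design.times):
                rng = _rng(design.seed, _STREAM_SPECTRA, ti, rep, hi)
                mean = base + (bump_total if treatment == affected_treatment else 0.0)
                leaf_dev = rng.normal(0.0, leaf_sd, len(wl)) if leaf_sd > 0 else 0.0
                for tech in range(n_technical):
                    noise = rng.normal(0.0, noise_sd, len(wl)) if noise_sd > 0 else 0.0
                    refl.append(np.clip(mean + leaf_dev + noise, 0.0, 1.0))
                    rows.append({"leaf_id": f"{treatment}_r{rep + 1}",
                                 "treatment": treatment, "time_of_day": time,
                                 "tech_rep": tech + 1})
    return SpectraSet(wl, np.array(refl), pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# scalar traits
# ---------------------------------------------------------------------------

def generate_trait_table(design: ExperimentDesign, trait: str,
                         repeated: bool = True) -> pd.DataFrame:
    """Tidy trait table with the additive treatment × time effect structure.

    One row per replicate × treatment × time (or per replicate × treatment
    when ``repeated`` is False, for traits measured once, e.g. end-of-day
    water potential).  Replicate IDs are shared across AM/PM rows.
    """
    spec = design.effects.get(trait)
    if spec is None:
        raise KeyError(f"trait {trait!r} has no EffectSpec in the design")
    rows = []
    trait_code = zlib.crc32(trait.encode("utf-8"))
    for ti, treatment in enumerate(design.treatments):
        for rep in range(design.n_reps_per_treatment):
            rep_id = f"{treatment}_r{rep + 1}"
            rng = _rng(design.seed, _STREAM_TRAIT, trait_code, ti, rep)
            times = design.times if repeated else (None,)
            for time in times:
                mean = spec.mean(treatment, time or "AM")
                noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                row = {"trait": trait, "replicate": rep_id,
                       "treatment": treatment, "value": mean + noise}
                if repeated:
                    row["time"] = time
                rows.append(row)
    cols =["trait", "replicate", "treatment"] + (["time"] if repeated else []) + ["value"]
    return pd.DataFrame(rows)[cols]
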