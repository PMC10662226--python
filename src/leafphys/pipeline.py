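"""End-to-end orchestration: simulate → fit → test → infer.

A run is fully reproducible from (config, seed): every output CSV uses a
canonical float format and the report carries no wall-clock state, so two
runs with the same configuration are byte-identical.

Stage order mirrors the experimental workflow: gas exchange (curve fitting
per species model), reflectance (spectra-wide tests and indices),
fluorescence (NPQ kinetics), then the inference layer over every trait
table produced upstream.  Species routing is fixed: tomato and barley use
the C3 bilinear FvCB fit, maize the C4 initial-slope + non-rectangular
hyperbola fit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aci import (KineticConstants, fit_fvcb_bilinear, fit_vpmax,
                  fit_nrh_amax, compute_iwue, FitError)
from .fluorescence import fit_induction, fit_relaxation, max_npq
from .inference import (two_way_rm_anova, compare_treatments_t,
                        DegenerateDataError)
from .io import (write_csv, write_gas_exchange, write_fluorescence,
                 write_spectra)
from .reflectance import spectra_wide_anova, compute_indices, SpectraSet
from .simulate import (ExperimentDesign, EffectSpec, C3TrueParams,
                       C4TrueParams, generate_aci_dataset,
                       generate_npq_dataset, generate_spectra,
                       generate_trait_table)

__all__ = ["PipelineConfig", "RunReport", "ConfigError", "validate_config",
           "load_config", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "fit_aci", "fit_npq", "spectra", "inference")

_PARAM_NAMES = {"Vcmax", "Jmax", "Rd", "Vpmax", "Amax", "Kp", "phi", "theta",
                "a_ind", "b_ind", "a_rel", "b_rel", "c_rel", "fvfm"}


class ConfigError(ValueError):
    """Raised with the complete list of configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass
class PipelineConfig:
    species: str = "tomato"
    n_reps_per_treatment: int | None = None
    seed: int = 0
    alpha: float = 0.05
    stages: tuple[str, ...] = ALL_STAGES
    effects: dict[str, EffectSpec] = field(default_factory=dict)
    traits: tuple[str, ...] = ()          # repeated-measures scalar traits
    scalar_traits: tuple[str, ...] = ()   # once-per-day traits (t-tested)
    aci_noise_sd: float = 0.3
    ci_jitter_sd: float = 2.0
    npq_noise_sd: float = 0.02
    spectra_noise_sd: float = 0.01
    spectra_leaf_sd: float = 0.01
    n_technical: int = 3
    effect_bands: tuple[tuple[float, float, float], ...] = ()
    constants: KineticConstants = field(default_factory=KineticConstants)

    def design(self) -> ExperimentDesign:
        return ExperimentDesign(species=self.species,
                                n_reps_per_treatment=self.n_reps_per_treatment,
                                seed=self.seed, effects=dict(self.effects))


@dataclass
class RunReport:
    files: dict[str, str]
    counts: dict[str, int]
    warnings: list[str]
    version: str
    config: dict[str, Any]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


_TOP_KEYS = {"species", "n_reps_per_treatment", "seed", "alpha", "stages",
             "effects", "traits", "scalar_traits", "aci_noise_sd",
             "ci_jitter_sd", "npq_noise_sd", "spectra_noise_sd",
             "spectra_leaf_sd", "n_technical", "effect_bands", "constants"}
_EFFECT_KEYS = {"baseline", "treatment_delta", "time_delta",
                "interaction_delta", "noise_sd"}
_CONST_KEYS = {"gammastar", "Kc", "Ko", "O", "leaf_temp"}


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default and invariant-check a YAML config file.

    Raises :class:`ConfigError` carrying the complete list of violations;
    unknown keys are violations (no silent typo tolerance).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    violations: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])

    for key in raw:
        if key not in _TOP_KEYS:
            violations.append(f"unknown key {key!r}")

    effects = {}
    for name, spec in (raw.get("effects") or {}).items():
        if not isinstance(spec, dict):
            violations.append(f"effects.{name} must be a mapping")
            continue
        bad = set(spec) - _EFFECT_KEYS
        if bad:
            violations.append(f"effects.{name}: unknown key(s) {sorted(bad)}")
            continue
        if "baseline" not in spec:
            violations.append(f"effects.{name}: baseline is required")
            continue
        if spec.get("noise_sd", 0.0) < 0:
            violations.append(f"effects.{name}: noise_sd must be >= 0")
            continue
        effects[name] = EffectSpec(**spec)

    const_raw = raw.get("constants") or {}
    bad = set(const_raw) - _CONST_KEYS
    if bad:
        violations.append(f"constants: unknown key(s) {sorted(bad)}")
        const_raw = {k: v for k, v in const_raw.items() if k in _CONST_KEYS}

    species = raw.get("species", "tomato")
    if species not in ("tomato", "barley", "maize"):
        violations.append(f"unknown species {species!r}")
    n_reps = raw.get("n_reps_per_treatment")
    if n_reps is not None and n_reps < 2:
        violations.append("n_reps_per_treatment must be >= 2")
    alpha = raw.get("alpha", 0.05)
    if not (0 < alpha < 1):
        violations.append("alpha must be in (0, 1)")
    stages = tuple(raw.get("stages", ALL_STAGES))
    for s in stages:
        if s not in ALL_STAGES:
            violations.append(f"unknown stage {s!r}")
    for t in tuple(raw.get("traits", ())) + tuple(raw.get("scalar_traits", ())):
        if t not in effects:
            violations.append(f"trait {t!r} has no entry under effects")

    if violations:
        raise ConfigError(violations)

    return PipelineConfig(
        species=species, n_reps_per_treatment=n_reps,
        seed=int(raw.get("seed", 0)), alpha=float(alpha), stages=stages,
        effects=effects, traits=tuple(raw.get("traits", ())),
        scalar_traits=tuple(raw.get("scalar_traits", ())),
        aci_noise_sd=float(raw.get("aci_noise_sd", 0.3)),
        ci_jitter_sd=float(raw.get("ci_jitter_sd", 2.0)),
        npq_noise_sd=float(raw.get("npq_noise_sd", 0.02)),
        spectra_noise_sd=float(raw.get("spectra_noise_sd", 0.01)),
        spectra_leaf_sd=float(raw.get("spectra_leaf_sd", 0.01)),
        n_technical=int(raw.get("n_technical", 3)),
        effect_bands=tuple(tuple(b) for b in raw.get("effect_bands", ())),
        constants=KineticConstants(**const_raw),
    )


load_config = validate_config


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute the configured stages, writing every table under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design()
    files: dict[str, str] = {}
    counts: dict[str, int] = {}
    caught: list[str] = []

    def _record(name: str, path: Path) -> None:
        files[name] = str(path.relative_to(out))

    curves = []
    spectra_set: SpectraSet | None = None
    traces = []
    trait_tables: list[pd.DataFrame] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        if "simulate" in config.stages:
            # generate the inputs enabled downstream stages need; a pure
            # simulate run (no downstream stages) generates everything
            need_curves = "fit_aci" in config.stages or config.stages == ("simulate",)
            need_traces = "fit_npq" in config.stages or config.stages == ("simulate",)
            need_spectra = "spectra" in config.stages or config.stages == ("simulate",)
            if need_curves:
                curves = generate_aci_dataset(
                    design, noise_sd=config.aci_noise_sd,
                    ci_jitter_sd=config.ci_jitter_sd)
                p = out / "gas_exchange.csv"
                write_gas_exchange(curves, p)
                _record("gas_exchange", p)
                counts["curves"] = len(curves)
            if need_traces:
                traces = generate_npq_dataset(design,
                                              noise_sd=config.npq_noise_sd)
                p = out / "fluorescence.csv"
                write_fluorescence(traces, p)
                _record("fluorescence", p)
                counts["fluorescence_traces"] = len(traces)
            if need_spectra:
                spectra_set = generate_spectra(
                    design, effect_bands=config.effect_bands,
                    n_technical=config.n_technical,
                    noise_sd=config.spectra_noise_sd,
                    leaf_sd=config.spectra_leaf_sd)
                p = out / "spectra.csv"
                write_spectra(spectra_set, p)
                _record("spectra", p)
                counts["spectra"] = len(spectra_set.meta)
            for trait in config.traits:
                trait_tables.append(generate_trait_table(design, trait))
            for trait in config.scalar_traits:
                trait_tables.append(
                    generate_trait_table(design, trait, repeated=False))
            if trait_tables:
                p = out / "traits.csv"
                write_csv(pd.concat(trait_tables, ignore_index=True), p)
                _record("traits", p)
                counts["trait_rows"] = int(sum(len(t) for t in trait_tables))

        capacity = pd.DataFrame()
        if "fit_aci" in config.stages:
            if not curves:
                raise RuntimeError("fit_aci: zero usable records")
            capacity = _fit_aci_stage(curves, config, caught)
            p = out / "capacity.csv"
            write_csv(capacity, p)
            _record("capacity", p)
            counts["capacity_fits"] = len(capacity)
            counts["capacity_failed"] = int((~capacity["success"]).sum())

        npq_table = pd.DataFrame()
        if "fit_npq" in config.stages:
            if not traces:
                raise RuntimeError("fit_npq: zero usable records")
            npq_table = _fit_npq_stage(traces)
            p = out / "npq.csv"
            write_csv(npq_table, p)
            _record("npq", p)
            counts["npq_fits"] = len(npq_table)
            counts["npq_failed"] = int((~npq_table["success"]).sum())

        index_table = pd.DataFrame()
        if "spectra" in config.stages:
            if spectra_set is None:
                raise RuntimeError("spectra: zero usable records")
            for time in design.times:
                mask = spectra_set.meta["time_of_day"] == time
                subset = SpectraSet(spectra_set.wavelengths,
                                    spectra_set.reflectance[mask.to_numpy()],
                                    spectra_set.meta[mask].reset_index(drop=True))
                res = spectra_wide_anova(subset, alpha=config.alpha)
                p = out / f"spectra_tests_{time}.csv"
                write_csv(res, p)
                _record(f"spectra_tests_{time}", p)
                counts[f"significant_wavelengths_{time}"] = int(res["significant"].sum())
            index_table = compute_indices(spectra_set)
            p = out / "indices.csv"
            write_csv(index_table, p)
            _record("indices", p)

        if "inference" in config.stages:
            inference, ttests = _inference_stage(
                config, trait_tables, capacity, npq_table, index_table, caught)
            if inference.empty and ttests.empty:
                raise RuntimeError("inference: zero usable records")
            if not inference.empty:
                p = out / "inference.csv"
                write_csv(inference, p)
                _record("inference", p)
                counts["anova_rows"] = len(inference)
            if not ttests.empty:
                p = out / "ttests.csv"
                write_csv(ttests, p)
                _record("ttests", p)
                counts["ttest_rows"] = len(ttests)

        caught.extend(str(w.message) for w in wlist)

    report = RunReport(files=files, counts=counts, warnings=sorted(set(caught)),
                       version=__version__,
                       config=_config_echo(config))
    (out / "report.json").write_text(report.to_json() + "\n")
    return report


def _fit_aci_stage(curves, config: PipelineConfig,
                   caught: list[str]) -> pd.DataFrame:
    rows = []
    for curve in curves:
        meta = {"species": curve.species, "treatment": curve.treatment,
                "time": curve.time_of_day, "replicate": curve.replicate_id}
        try:
            if curve.species == "maize":
                vp = fit_vpmax(curve)
                nrh_fit = fit_nrh_amax(curve)
                rows.append({**meta, "model": "c4", "Vpmax": vp.Vpmax,
                             "Amax": nrh_fit.Amax, "phi": nrh_fit.phi,
                             "theta": nrh_fit.theta,
                             "sse": vp.sse + nrh_fit.sse,
                             "success": vp.success and nrh_fit.success})
            else:
                fit = fit_fvcb_bilinear(curve, config.constants)
                rows.append({**meta, "model": "c3", "Vcmax": fit.Vcmax,
                             "Jmax": fit.Jmax, "Rd": fit.Rd,
                             "transition_ci": fit.transition_ci,
                             "sse": fit.sse, "success": fit.success})
        except FitError as exc:
            caught.append(f"fit_aci {meta['replicate']}/{meta['time']}: {exc}")
            rows.append({**meta, "model": "c4" if curve.species == "maize" else "c3",
                         "success": False})
    return pd.DataFrame(rows)


def _fit_npq_stage(traces) -> pd.DataFrame:
    rows = []
    for tr in traces:
        ind = fit_induction(tr)
        rel = fit_relaxation(tr)
        rows.append({"leaf_id": tr.leaf_id, "treatment": tr.treatment,
                     "instrument": tr.instrument, "fvfm": tr.fvfm,
                     "a_ind": ind.a, "b_ind": ind.b,
                     "a_rel": rel.a, "b_rel": rel.b, "c_rel": rel.c,
                     "max_npq": max_npq(tr),
                     "success": ind.success and rel.success})
    return pd.DataFrame(rows)


def _inference_stage(config, trait_tables, capacity, npq_table, index_table,
                     caught):
    anova_rows, ttest_rows = [], []

    def _anova(table: pd.DataFrame, trait: str) -> None:
        try:
            res = two_way_rm_anova(table)
        except (DegenerateDataError, ValueError) as exc:
            caught.append(f"inference {trait}: {exc}")
            return
        frame = res.to_frame()
        frame.insert(0, "trait", trait)
        frame["significant"] = frame["p"] < config.alpha
        anova_rows.append(frame)

    def _ttest(excised, attached, trait: str) -> None:
        try:
            res = compare_treatments_t(excised, attached)
        except (DegenerateDataError, ValueError) as exc:
            caught.append(f"inference {trait}: {exc}")
            return
        ttest_rows.append({"trait": trait, "t": res.t, "df": res.df,
                           "p": res.p, "mean_difference": res.mean_difference,
                           "flavor": res.flavor,
                           "significant": res.p < config.alpha})

    for table in trait_tables:
        trait = table["trait"].iloc[0]
        if "time" in table.columns:
            _anova(table, trait)
        else:
            _ttest(table.loc[table["treatment"] == "excised", "value"],
                   table.loc[table["treatment"] == "attached", "value"], trait)

    if not capacity.empty:
        ok = capacity[capacity["success"]]
        params = [c for c in ("Vcmax", "Jmax", "Vpmax", "Amax") if c in ok.columns]
        for param in params:
            table = ok.rename(columns={param: "value"})[
                ["replicate", "treatment", "time", "value"]].assign(trait=param)
            _anova(table, param)

    if not npq_table.empty:
        ok = npq_table[npq_table["success"]]
        for param in ("fvfm", "a_ind", "b_ind", "b_rel", "max_npq"):
            _ttest(ok.loc[ok["treatment"] == "excised", param],
                   ok.loc[ok["treatment"] == "attached", param], param)

    if not index_table.empty:
        for name, grp in index_table.groupby("index", sort=False):
            table = grp.rename(columns={"leaf_id": "replicate",
                                        "time_of_day": "time"})
            _anova(table, f"index_{name}")

    inference = (pd.concat(anova_rows, ignore_index=True)
                 if anova_rows else pd.DataFrame())
    ttests = pd.DataFrame(ttest_rows)
    return inference, ttests


def _config_echo(config: PipelineConfig) -> dict[str, Any]:
    echo = dataclasses.asdict(config)
    echo["constants"] = dataclasses.asdict(config.constants)
    echo["effects"] = {k: dataclasses.asdict(v)
                       for k, v in config.effects.items()}
    return echo
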