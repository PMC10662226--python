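"""CSV readers and writers for the pipeline's tabular formats.

All files are comma-separated UTF-8 with a header row.  Floats are written
in a canonical 10-significant-digit format so that repeated runs with the
same seed produce byte-identical files.  Readers accept a minimal
instrument-export dialect: lines starting with '#' are ignored and required
columns are matched by name, case-insensitively.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aci import ACiCurve
from .fluorescence import FluorTrace
from .reflectance import SpectraSet

__all__ = [
    "FLOAT_FORMAT",
    "write_csv",
    "write_gas_exchange",
    "read_gas_exchange",
    "write_fluorescence",
    "read_fluorescence",
    "write_spectra",
    "read_spectra",
]

FLOAT_FORMAT = "%.10g"


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a frame with the canonical float format (reproducible bytes)."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a CSV skipping '#' comment lines; columns matched case-insensitively."""
    df = pd.read_csv(path, comment="#")
    lower = {c.lower(): c for c in df.columns}
    missing = [c for c in required if c.lower() not in lower]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df.rename(columns={lower[c.lower()]: c for c in required})


# ---------------------------------------------------------------------------
# gas exchange (long format)
# ---------------------------------------------------------------------------

_GAS_COLS = ["species", "treatment", "time", "replicate", "co2_set", "ci", "A", "gs"]


def write_gas_exchange(curves: Iterable[ACiCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for j in range(len(c)):
            rows.append({"species": c.species, "treatment": c.treatment,
                         "time": c.time_of_day, "replicate": c.replicate_id,
                         "co2_set": c.co2_set[j], "ci": c.ci[j],
                         "A": c.A[j], "gs": c.gs[j]})
    write_csv(pd.DataFrame(rows, columns=_GAS_COLS), path)


def read_gas_exchange(path: str | Path) -> list[ACiCurve]:
    df = _read_table(path, _GAS_COLS)
    curves = []
    keys = ["species", "treatment", "time", "replicate"]
    for key, grp in df.groupby(keys, sort=False):
        species, treatment, time, rep = key
        curves.append(ACiCurve(species=species, treatment=treatment,
                               time_of_day=time, replicate_id=str(rep),
                               co2_set=grp["co2_set"].to_numpy(),
                               ci=grp["ci"].to_numpy(),
                               A=grp["A"].to_numpy(),
                               gs=grp["gs"].to_numpy()))
    return curves


# ---------------------------------------------------------------------------
# fluorescence (long format; one 'reference' row per leaf carries Fm and Fo)
# ---------------------------------------------------------------------------

_FLUOR_COLS = ["leaf_id", "treatment", "instrument", "phase", "t_min",
               "Fm_prime", "Fo"]


def write_fluorescence(traces: Iterable[FluorTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        rows.append({"leaf_id": tr.leaf_id, "treatment": tr.treatment,
                     "instrument": tr.instrument, "phase": "reference",
                     "t_min": np.nan, "Fm_prime": tr.Fm_dark, "Fo": tr.Fo})
        for phase, t, fm in (("induction", tr.t_induction, tr.fm_prime_induction),
                             ("relaxation", tr.t_relaxation, tr.fm_prime_relaxation)):
            for j in range(len(t)):
                rows.append({"leaf_id": tr.leaf_id, "treatment": tr.treatment,
                             "instrument": tr.instrument, "phase": phase,
                             "t_min": t[j], "Fm_prime": fm[j], "Fo": np.nan})
    write_csv(pd.DataFrame(rows, columns=_FLUOR_COLS), path)


def read_fluorescence(path: str | Path) -> list[FluorTrace]:
    df = _read_table(path, _FLUOR_COLS)
    traces = []
    for (leaf, treatment, instrument), grp in df.groupby(
            ["leaf_id", "treatment", "instrument"], sort=False):
        ref = grp[grp["phase"] == "reference"]
        if len(ref) != 1:
            raise ValueError(f"leaf {leaf}: expected exactly one reference row")
        ind = grp[grp["phase"] == "induction"].sort_values("t_min")
        rel = grp[grp["phase"] == "relaxation"].sort_values("t_min")
        traces.append(FluorTrace(
            leaf_id=str(leaf), Fm_dark=float(ref["Fm_prime"].iloc[0]),
            Fo=float(ref["Fo"].iloc[0]),
            t_induction=ind["t_min"].to_numpy(),
            fm_prime_induction=ind["Fm_prime"].to_numpy(),
            t_relaxation=rel["t_min"].to_numpy(),
            fm_prime_relaxation=rel["Fm_prime"].to_numpy(),
            treatment=str(treatment), instrument=str(instrument)))
    return traces


# ---------------------------------------------------------------------------
# spectra (wide format: wavelength + one column per leaf x technical rep)
# ---------------------------------------------------------------------------

def _column_name(row) -> str:
    tech = getattr(row, "tech_rep", 1)
    return f"{row.leaf_id}|{row.treatment}|{row.time_of_day}|t{tech}"


def write_spectra(spectra_set: SpectraSet, path: str | Path) -> None:
    data = {"wavelength": spectra_set.wavelengths}
    for i, row in enumerate(spectra_set.meta.itertuples(index=False)):
        data[_column_name(row)] = spectra_set.reflectance[i]
    write_csv(pd.DataFrame(data), path)


def read_spectra(path: str | Path) -> SpectraSet:
    df = _read_table(path, ["wavelength"])
    wl = df["wavelength"].to_numpy(dtype=float)
    rows, refl = [], []
    for col in df.columns:
        if col == "wavelength":
            continue
        parts = col.split("|")
        if len(parts) != 4:
            raise ValueError(f"unparseable spectra column {col!r} "
                             "(expected leaf|treatment|time|tN)")
        leaf_id, treatment, time, tech = parts
        rows.append({"leaf_id": leaf_id, "treatment": treatment,
                     "time_of_day": time, "tech_rep": int(tech.lstrip("t"))})
        refl.append(df[col].to_numpy(dtype=float))
    return SpectraSet(wl, np.array(refl), pd.DataFrame(rows))
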