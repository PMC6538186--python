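"""Readers, filters and writers for the four tabular schemas.

Schemas (CSV, documented headers in the README):

* chemical parameters: ``chemical_id,name,mw,logp,pka_donor,pka_acceptor,
  fup,fup_below_lod,clint_1,clint_10,logwsol,loghenry`` (pKa lists are
  semicolon separated)
* in vitro activity: ``chemical_id,assay_endpoint,ac50,hit_call,flags``
* endpoint-level in vivo: ``chemical_id,study_id,study_type,
  effect_category,effect_type,effect_target,dose,study_length``
* POD-level in vivo: ``chemical_id,pod_type,dose,dose_units,study_type,
  route,duration_days``

Column aliases mirroring the public supplementary files are accepted so
those tables drop in unedited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_params import ChemicalRecord, resolve_fup
from .pbtk import STUDY_LENGTHS

__all__ = [
    "AssayHit",
    "EndpointDoseRecord",
    "PodRecord",
    "SchemaError",
    "read_chem_params",
    "read_ac50",
    "filter_ac50",
    "derive_endpoint_doses",
    "read_endpoint_doses",
    "read_pod_records",
    "derive_pod",
    "write_results",
]

ENDPOINT_STUDY_TYPES = ("chronic", "subchronic", "developmental")
POD_STUDY_TYPES = ("subacute", "subchronic", "chronic")

# alias -> canonical column name, covering the supplementary spellings
COLUMN_ALIASES = {
    "casrn": "chemical_id",
    "casn": "chemical_id",
    "dsstox_substance_id": "chemical_id",
    "dtxsid": "chemical_id",
    "compound": "name",
    "chemical_name": "name",
    "average_mass": "mw",
    "logp_use": "logp",
    "funbound_plasma": "fup",
    "fu": "fup",
    "clint_1um": "clint_1",
    "clint_10um": "clint_10",
    "aenm": "assay_endpoint",
    "assay_component_endpoint_name": "assay_endpoint",
    "modl_ga": "ac50",
    "ac50_um": "ac50",
    "hitc": "hit_call",
    "study_type_desc": "study_type",
    "dose_level": "dose",
    "pod_value": "dose",
    "toxval_numeric": "dose",
    "toxval_units": "dose_units",
    "toxval_type": "pod_type",
    "exposure_route": "route",
    "study_duration_days": "duration_days",
}


class SchemaError(ValueError):
    """A table failed validation; the message carries the row index."""


@dataclass(frozen=True)
class AssayHit:
    chemical_id: str
    assay_endpoint: str
    ac50: float  # uM
    hit_call: bool
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.hit_call and not self.ac50 > 0:
            raise ValueError("positive hit requires ac50 > 0")


@dataclass(frozen=True)
class EndpointDoseRecord:
    chemical_id: str
    study_id: str
    study_type: str
    effect_category: str
    effect_type: str
    effect_target: str
    dose: float  # mg/kg/day
    study_length: float  # days

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.study_type not in ENDPOINT_STUDY_TYPES:
            raise ValueError(f"unknown study type {self.study_type!r}")

    @property
    def endpoint_id(self) -> str:
        return "|".join(
            (self.study_type, self.effect_category, self.effect_type,
             self.effect_target)
        )


@dataclass(frozen=True)
class PodRecord:
    chemical_id: str
    pod_type: str  # LOEL | LOAEL
    dose: float
    study_type: str
    route: str = "oral"
    duration: float = float("nan")  # days
    dose_units: str = "mg/kg/day"


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    renames = {
        c: COLUMN_ALIASES[c.lower()]
        for c in df.columns
        if c.lower() in COLUMN_ALIASES
    }
    df = df.rename(columns=renames)
    df.columns = [c.lower() for c in df.columns]
    return df


def _parse_pka(cell) -> list:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    return [float(tok) for tok in text.replace(",", ";").split(";") if tok.strip()]


def read_chem_params(path: str | Path) -> list[ChemicalRecord]:
    """Read a chemical-parameter table into validated records.

    The below-LOD fup default and the clearance concentration-selection
    rule are applied while reading.
    """
    df = pd.read_csv(path)
    if df.empty and len(df.columns) <= 1:
        return []
    df = _canonical(df)
    required = {"chemical_id", "mw", "logp"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            below_lod = bool(row.get("fup_below_lod", False)) or pd.isna(
                row.get("fup", np.nan)
            )
            fup = resolve_fup(
                None if pd.isna(row.get("fup", np.nan)) else float(row["fup"]),
                below_lod,
            )
            clint_1 = row.get("clint_1", np.nan)
            clint_10 = row.get("clint_10", np.nan)
            records.append(
                ChemicalRecord(
                    id=str(row["chemical_id"]),
                    name=str(row.get("name", "")),
                    mw=float(row["mw"]),
                    logp=float(row["logp"]),
                    pka_donor=_parse_pka(row.get("pka_donor")),
                    pka_acceptor=_parse_pka(row.get("pka_acceptor")),
                    fup=fup,
                    fup_below_lod=below_lod,
                    clint_1=None if pd.isna(clint_1) else float(clint_1),
                    clint_10=None if pd.isna(clint_10) else float(clint_10),
                    logwsol=float(row.get("logwsol", np.nan)),
                    loghenry=float(row.get("loghenry", np.nan)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return records


def read_ac50(path: str | Path) -> list[AssayHit]:
    df = pd.read_csv(path)
    if df.empty:
        return []
    df = _canonical(df)
    hits = []
    for i, row in df.iterrows():
        flags_cell = row.get("flags", "")
        if pd.isna(flags_cell):
            flags: tuple = ()
        else:
            flags = tuple(
                tok.strip() for tok in str(flags_cell).split(";") if tok.strip()
            )
        try:
            hits.append(
                AssayHit(
                    chemical_id=str(row["chemical_id"]),
                    assay_endpoint=str(row["assay_endpoint"]),
                    ac50=float(row["ac50"]),
                    hit_call=bool(row["hit_call"]),
                    flags=flags,
                )
            )
        except (ValueError, TypeError, KeyError) as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return hits


def filter_ac50(hits: list[AssayHit]) -> list[AssayHit]:
    """Keep positive hit calls with no curve-fitting flags."""
    return [h for h in hits if h.hit_call and not h.flags]


def _study_length(row) -> float:
    length = row.get("study_length", np.nan)
    if pd.isna(length):
        return STUDY_LENGTHS[row["study_type"]]
    return float(length)


def derive_endpoint_doses(df: pd.DataFrame) -> list[EndpointDoseRecord]:
    """Reduce raw study rows to endpoint-level dose records.

    For each (study, chemical, endpoint) combination the lowest dose at
    which the response was observed is kept.  Multigenerational studies
    are excluded; multiple studies of the same chemical and endpoint each
    contribute a record.
    """
    df = _canonical(df.copy())
    df = df[df["study_type"].isin(ENDPOINT_STUDY_TYPES)]
    keys = [
        "study_id", "chemical_id", "study_type", "effect_category",
        "effect_type", "effect_target",
    ]
    records = []
    for key_vals, grp in sorted(df.groupby(keys), key=lambda kv: kv[0]):
        row = grp.loc[grp["dose"].idxmin()]
        records.append(
            EndpointDoseRecord(
                chemical_id=str(row["chemical_id"]),
                study_id=str(row["study_id"]),
                study_type=str(row["study_type"]),
                effect_category=str(row["effect_category"]),
                effect_type=str(row["effect_type"]),
                effect_target=str(row["effect_target"]),
                dose=float(grp["dose"].min()),
                study_length=_study_length(row),
            )
        )
    return records


def read_endpoint_doses(path: str | Path) -> list[EndpointDoseRecord]:
    df = pd.read_csv(path)
    if df.empty:
        return []
    return derive_endpoint_doses(df)


_UNIT_TO_DAYS = {"days": 1.0, "day": 1.0, "weeks": 7.0, "week": 7.0,
                 "months": 30.4, "month": 30.4}


def read_pod_records(path: str | Path) -> list[PodRecord]:
    df = pd.read_csv(path)
    if df.empty:
        return []
    df = _canonical(df)
    records = []
    for i, row in df.iterrows():
        duration = row.get("duration_days", np.nan)
        unit = str(row.get("duration_units", "days")).lower()
        if not pd.isna(duration) and unit in _UNIT_TO_DAYS:
            duration = float(duration) * _UNIT_TO_DAYS[unit]
        try:
            records.append(
                PodRecord(
                    chemical_id=str(row["chemical_id"]),
                    pod_type=str(row["pod_type"]).upper(),
                    dose=float(row["dose"]),
                    study_type=str(row["study_type"]).lower(),
                    route=str(row.get("route", "oral")).lower(),
                    duration=float(duration) if not pd.isna(duration)
                    else float("nan"),
                    dose_units=str(row.get("dose_units", "mg/kg/day")),
                )
            )
        except (ValueError, TypeError, KeyError) as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return records


def derive_pod(records: list[PodRecord]) -> dict[str, float]:
    """Per-chemical minimum over pooled LOEL and LOAEL values.

    Records are first filtered to oral, positive, mg/kg/day doses of
    subacute/subchronic/chronic studies with a usable duration.
    """
    kept = [
        r for r in records
        if r.pod_type in ("LOEL", "LOAEL")
        and r.dose > 0
        and r.route == "oral"
        and r.study_type in POD_STUDY_TYPES
        and r.dose_units == "mg/kg/day"
        and not math.isnan(r.duration)
    ]
    pods: dict[str, float] = {}
    for r in kept:
        if r.chemical_id not in pods or r.dose < pods[r.chemical_id]:
            pods[r.chemical_id] = r.dose
    return pods


def pod_study_lengths(records: list[PodRecord]) -> dict[str, float]:
    """Duration accompanying each chemical's minimum POD record."""
    best: dict[str, PodRecord] = {}
    for r in records:
        if (
            r.pod_type in ("LOEL", "LOAEL") and r.dose > 0
            and r.route == "oral" and r.study_type in POD_STUDY_TYPES
            and r.dose_units == "mg/kg/day" and not math.isnan(r.duration)
        ):
            if r.chemical_id not in best or r.dose < best[r.chemical_id].dose:
                best[r.chemical_id] = r
    return {cid: r.duration for cid, r in best.items()}


def write_results(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write result tables as CSV with deterministic column order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.15g")
        paths.append(path)
    return paths
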