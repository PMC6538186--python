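"""Synthetic chemicals, activity tables and in vivo dose tables.

The generator couples in vivo doses to in vitro potencies through the
dose-to-concentration ratio of a designated "true" assumption set:
dose = (AC50 / kappa_true) * 10^eps with eps ~ Normal(0, noise_sd), so
the pipeline's ability to recover the generating assumption set is
testable end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pbtk
from .chem_params import ChemicalRecord, FUP_LOD_DEFAULT
from .dosimetry import KappaCalculator
from .io_formats import AssayHit, EndpointDoseRecord, PodRecord

__all__ = [
    "SyntheticConfig",
    "gen_chemicals",
    "gen_ac50",
    "gen_invivo",
    "chemicals_to_frame",
    "ac50_to_frame",
    "endpoint_to_frame",
    "pod_to_frame",
]

_STUDY_TYPES = ("chronic", "subchronic", "developmental")
_EFFECT_CATEGORIES = ("systemic", "reproductive")
_EFFECT_TYPES = ("nonneoplastic", "clinical")
_EFFECT_TARGETS = ("liver", "kidney", "bodyweight")


@dataclass
class SyntheticConfig:
    n_chemicals: int = 200
    n_assays: int = 20
    n_endpoints: int = 12
    hit_rate: float = 0.4
    ac50_log_mean: float = 0.5  # log10 uM, mean of the latent potency
    ac50_log_sd: float = 1.0  # spread of the latent per-chemical potency
    ac50_within_sd: float = 0.25  # assay-to-assay spread around the potency
    noise_sd: float = 0.3  # sd of eps in log10 dose
    flag_rate: float = 0.0
    clint_zero_frac: float = 0.1
    fup_logit_mean: float = -2.0
    fup_logit_sd: float = 1.5
    clint_log_mean: float = 1.0  # log10 uL/min/1e6 cells
    clint_log_sd: float = 0.7
    logp_mean: float = 2.0
    logp_sd: float = 1.2
    endpoint_activity_rate: float = 0.5
    pod_extra_sd: float = 0.0  # extra across-study-type dispersion of PODs
    true_assumptions: pbtk.AssumptionSet = field(
        default_factory=pbtk.AssumptionSet
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hit_rate", "flag_rate", "clint_zero_frac",
                     "endpoint_activity_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("ac50_log_sd", "ac50_within_sd", "noise_sd",
                     "fup_logit_sd", "clint_log_sd", "logp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def gen_chemicals(cfg: SyntheticConfig) -> list[ChemicalRecord]:
    """Draw chemicals with logit-normal fup, lognormal Clint (with a
    point mass at zero), normal logP, mixed ionization classes and
    uniform molecular weight."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i in range(cfg.n_chemicals):
        fup = 1.0 / (1.0 + np.exp(-rng.normal(cfg.fup_logit_mean,
                                              cfg.fup_logit_sd)))
        fup = float(np.clip(fup, FUP_LOD_DEFAULT, 1.0))
        if rng.random() < cfg.clint_zero_frac:
            clint_1: float | None = 0.0
            clint_10: float | None = None
        else:
            clint_1 = float(10.0 ** rng.normal(cfg.clint_log_mean,
                                               cfg.clint_log_sd))
            clint_10 = clint_1 * float(10.0 ** rng.normal(0.0, 0.1))
        logp = float(rng.normal(cfg.logp_mean, cfg.logp_sd))
        ion_class = rng.choice(("neutral", "acid", "base"),
                               p=(0.5, 0.25, 0.25))
        pka_donor, pka_acceptor = [], []
        if ion_class == "acid":
            pka_donor = [float(rng.uniform(3.0, 10.0))]
        elif ion_class == "base":
            pka_acceptor = [float(rng.uniform(4.0, 10.5))]
        records.append(ChemicalRecord(
            id=f"CHEM{i:04d}",
            name=f"synthetic-{i}",
            mw=float(rng.uniform(100.0, 500.0)),
            logp=logp,
            pka_donor=pka_donor,
            pka_acceptor=pka_acceptor,
            fup=fup,
            fup_below_lod=bool(fup <= FUP_LOD_DEFAULT),
            clint_1=clint_1,
            clint_10=clint_10,
            logwsol=float(rng.normal(-3.0, 1.0)),
            loghenry=float(rng.normal(-7.0, 1.5)),
        ))
    return records


def _latent_potencies(
    chemicals: list[ChemicalRecord], cfg: SyntheticConfig
) -> dict[str, float]:
    """Per-chemical latent log10 potency shared by all assays; this is
    what couples the activity table to the generated in vivo doses."""
    rng = np.random.default_rng(cfg.seed + 11)
    return {
        c.id: float(rng.normal(cfg.ac50_log_mean, cfg.ac50_log_sd))
        for c in chemicals
    }


def gen_ac50(
    chemicals: list[ChemicalRecord], cfg: SyntheticConfig
) -> list[AssayHit]:
    """Bernoulli activity with AC50 drawn around the chemical's latent
    potency; a configurable fraction of positive rows carries a
    synthetic curve flag."""
    rng = np.random.default_rng(cfg.seed + 1)
    potency = _latent_potencies(chemicals, cfg)
    hits = []
    for chem in chemicals:
        for a in range(cfg.n_assays):
            if rng.random() >= cfg.hit_rate:
                continue
            ac50 = float(10.0 ** (
                potency[chem.id] + rng.normal(0.0, cfg.ac50_within_sd)
            ))
            flags = ("noisy",) if rng.random() < cfg.flag_rate else ()
            hits.append(AssayHit(
                chemical_id=chem.id,
                assay_endpoint=f"ASSAY{a:03d}",
                ac50=ac50,
                hit_call=True,
                flags=flags,
            ))
    return hits


def _endpoint_taxonomy(cfg: SyntheticConfig) -> list[tuple]:
    crossed = [
        (st, cat, et, tgt)
        for st in _STUDY_TYPES
        for cat in _EFFECT_CATEGORIES
        for et in _EFFECT_TYPES
        for tgt in _EFFECT_TARGETS
    ]
    return crossed[: cfg.n_endpoints]


def gen_invivo(
    chemicals: list[ChemicalRecord],
    ac50_hits: list[AssayHit],
    cfg: SyntheticConfig,
    calculator: KappaCalculator | None = None,
    shuffle_labels: bool = False,
) -> tuple[list[EndpointDoseRecord], list[PodRecord]]:
    """Generate endpoint-level doses and POD records coupled to AC50s.

    Each active (chemical, endpoint) pair takes its dose from a randomly
    linked assay hit of that chemical: dose = AC50/kappa_true * 10^eps.
    With ``shuffle_labels=True`` the dose is generated from a permuted
    chemical instead (that chemical's linked AC50 and kappa), fully
    decoupling doses from the labelled chemical (null generator).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    calc = calculator or KappaCalculator()
    chem_map = {c.id: c for c in chemicals}
    hits_by_chem: dict = {}
    for h in ac50_hits:
        if not h.flags:
            hits_by_chem.setdefault(h.chemical_id, []).append(h)

    kappa_source = {c.id: c.id for c in chemicals}
    if shuffle_labels:
        ids = [c.id for c in chemicals]
        shuffled = list(ids)
        rng.shuffle(shuffled)
        kappa_source = dict(zip(ids, shuffled))

    taxonomy = _endpoint_taxonomy(cfg)
    endpoint_records = []
    pod_records = []
    for chem in chemicals:
        if not hits_by_chem.get(chem.id):
            continue
        kap_chem = chem_map[kappa_source[chem.id]]
        source_hits = hits_by_chem.get(kap_chem.id)
        if not source_hits:
            continue
        for e_idx, (study_type, cat, etype, target) in enumerate(taxonomy):
            if rng.random() >= cfg.endpoint_activity_rate:
                continue
            hit = source_hits[rng.integers(0, len(source_hits))]
            length = pbtk.STUDY_LENGTHS[study_type]
            kappa = calc.compute(kap_chem, length, cfg.true_assumptions).kappa
            eps = rng.normal(0.0, cfg.noise_sd)
            dose = hit.ac50 / kappa * 10.0**eps
            endpoint_records.append(EndpointDoseRecord(
                chemical_id=chem.id,
                study_id=f"STUDY-{chem.id}-{e_idx}",
                study_type=study_type,
                effect_category=cat,
                effect_type=etype,
                effect_target=target,
                dose=dose,
                study_length=length,
            ))
        # POD rows: LOEL/LOAEL near the chemical's lowest endpoint dose,
        # inheriting that record's study type and duration so the
        # noiseless generator is an exact fixed point of the POD pipeline
        own = [r for r in endpoint_records if r.chemical_id == chem.id]
        if own:
            base = min(own, key=lambda r: r.dose)
            study_type = {"chronic": "chronic", "subchronic": "subchronic",
                          "developmental": "subacute"}[base.study_type]
            jitter_sd = 0.5 * cfg.noise_sd + cfg.pod_extra_sd
            for pod_type in ("LOEL", "LOAEL"):
                pod_records.append(PodRecord(
                    chemical_id=chem.id,
                    pod_type=pod_type,
                    dose=float(base.dose * 10.0 ** rng.normal(0.0, jitter_sd)),
                    study_type=study_type,
                    route="oral",
                    duration=base.study_length,
                ))
    return endpoint_records, pod_records


# --- frame conversions (round-trippable through io_formats readers) ---

def chemicals_to_frame(chemicals: list[ChemicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chemical_id": c.id,
            "name": c.name,
            "mw": c.mw,
            "logp": c.logp,
            "pka_donor": ";".join(str(v) for v in c.pka_donor),
            "pka_acceptor": ";".join(str(v) for v in c.pka_acceptor),
            "fup": c.fup,
            "fup_below_lod": c.fup_below_lod,
            "clint_1": c.clint_1,
            "clint_10": c.clint_10,
            "logwsol": c.logwsol,
            "loghenry": c.loghenry,
        }
        for c in chemicals
    ])


def ac50_to_frame(hits: list[AssayHit]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chemical_id": h.chemical_id,
            "assay_endpoint": h.assay_endpoint,
            "ac50": h.ac50,
            "hit_call": h.hit_call,
            "flags": ";".join(h.flags),
        }
        for h in hits
    ])


def endpoint_to_frame(records: list[EndpointDoseRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chemical_id": r.chemical_id,
            "study_id": r.study_id,
            "study_type": r.study_type,
            "effect_category": r.effect_category,
            "effect_type": r.effect_type,
            "effect_target": r.effect_target,
            "dose": r.dose,
            "study_length": r.study_length,
        }
        for r in records
    ])


def pod_to_frame(records: list[PodRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chemical_id": r.chemical_id,
            "pod_type": r.pod_type,
            "dose": r.dose,
            "dose_units": r.dose_units,
            "study_type": r.study_type,
            "route": r.route,
            "duration_days": r.duration,
        }
        for r in records
    ])
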