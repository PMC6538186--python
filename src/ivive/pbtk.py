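"""Rat physiologically based toxicokinetic model.

Compartments: gut lumen (oral depot), gut, liver, kidney, lung,
rest-of-body, arterial plasma and venous plasma, plus a cumulative
cleared-amount sink used for mass-balance accounting.  Oral boluses are
absorbed first order from the gut lumen; tissues exchange with plasma in
a flow-limited fashion with tissue:plasma ratio Kp*fup (Kp being the
tissue:unbound-plasma partition coefficient); the liver receives the gut
venous outflow plus its arterial supply and clears chemical by a
well-stirred hepatic clearance, and the kidney clears by glomerular
filtration of free chemical.

The system is linear, so the time course is propagated exactly with
matrix exponentials (interval propagator plus an exact integral block
from an augmented exponential); dose linearity and mass balance then
hold to machine precision rather than solver tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable

import numpy as np
import yaml
from scipy.linalg import expm

from .chem_params import ChemicalRecord, neutral_fraction

__all__ = [
    "RatPhysiology",
    "PartitionCoefficientSet",
    "PBTKParameters",
    "DoseRegimen",
    "TimeCourse",
    "ConcentrationMetric",
    "AssumptionSet",
    "default_physiology",
    "default_tissue_composition",
    "tissue_partition_coefficients",
    "fu_hep",
    "hepatic_clearance",
    "renal_clearance",
    "build_params",
    "simulate",
    "extract_concentration",
    "steady_state_mean_oracle",
    "STUDY_LENGTHS",
]

TISSUES = ("gut", "liver", "kidney", "lung", "rest")

#: Canonical simulation horizons (days) per study type.  The developmental
#: horizon is a config default; no authoritative number exists for it.
STUDY_LENGTHS = {
    "chronic": 730.0,
    "subchronic": 90.0,
    "subacute": 28.0,
    "developmental": 21.0,
}


def _load_yaml(name: str) -> dict:
    with resources.files("ivive.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@dataclass
class RatPhysiology:
    body_weight: float
    tissue_volumes: dict
    plasma_flows: dict
    gfr: float
    hepatocellularity: float
    liver_mass_frac: float
    plasma_volume: float
    arterial_fraction: float
    k_gutabs: float
    fu_hep_enabled: bool = True
    fu_hep_vr: float = 0.005

    def __post_init__(self) -> None:
        for t in TISSUES:
            if self.tissue_volumes[t] <= 0:
                raise ValueError(f"tissue volume for {t} must be positive")
        flows = sum(self.plasma_flows[t] for t in ("gut", "liver", "kidney", "rest"))
        if not math.isclose(flows, self.plasma_flows["cardiac"], rel_tol=1e-6):
            raise ValueError(
                "tissue plasma flows must sum to cardiac output "
                f"({flows} != {self.plasma_flows['cardiac']})"
            )


def default_physiology() -> RatPhysiology:
    cfg = _load_yaml("physiology.yaml")
    return RatPhysiology(
        body_weight=cfg["body_weight"],
        tissue_volumes=dict(cfg["tissue_volumes"]),
        plasma_flows=dict(cfg["plasma_flows"]),
        gfr=cfg["gfr"],
        hepatocellularity=cfg["hepatocellularity"],
        liver_mass_frac=cfg["liver_mass_frac"],
        plasma_volume=cfg["plasma_volume"],
        arterial_fraction=cfg["arterial_fraction"],
        k_gutabs=cfg["k_gutabs"],
        fu_hep_enabled=cfg.get("fu_hep_enabled", True),
        fu_hep_vr=cfg.get("fu_hep_vr", 0.005),
    )


def default_tissue_composition() -> dict:
    return _load_yaml("tissue_composition.yaml")


@dataclass
class PartitionCoefficientSet:
    """Tissue:unbound-plasma partition coefficients, one per tissue."""

    kp: dict

    def __post_init__(self) -> None:
        for t, v in self.kp.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"non-finite or non-positive Kp for {t}: {v}")


def _default_kp_scheme(chemical: ChemicalRecord, composition: dict) -> dict:
    """Schmitt-style composition-based partition calculator.

    Kp (tissue : unbound plasma) sums a water term, neutral-fraction
    weighted lipid terms with affinity set by logP, and a protein-binding
    term scaled to plasma protein binding through fup.
    """
    fn = neutral_fraction(chemical.pka_donor, chemical.pka_acceptor)
    p_nl = 10.0 ** chemical.logp
    p_pl = 10.0 ** (
        composition["pl_slope"] * chemical.logp + composition["pl_intercept"]
    )
    plasma_prot = composition["plasma_protein_frac"]
    # tissue protein binds like plasma protein; (1/fup - 1) is the
    # bound:unbound ratio per unit plasma protein
    bound_ratio = (1.0 / chemical.fup - 1.0) if chemical.fup < 1.0 else 0.0
    kp = {}
    for tissue, frac in composition["tissues"].items():
        kp[tissue] = (
            frac["water"]
            + fn * frac["neutral_lipid"] * p_nl
            + fn * frac["phospholipid"] * p_pl
            + frac["protein"] / plasma_prot * bound_ratio
        )
    return kp


def tissue_partition_coefficients(
    chemical: ChemicalRecord,
    physiology: RatPhysiology | None = None,
    scheme: Callable[[ChemicalRecord, dict], dict] | None = None,
    composition: dict | None = None,
) -> PartitionCoefficientSet:
    """Compute tissue:unbound-plasma partition coefficients.

    ``scheme`` is pluggable; the default is a composition-based
    calculator using the fractions shipped in ``tissue_composition.yaml``.
    """
    if composition is None:
        composition = default_tissue_composition()
    if scheme is None:
        scheme = _default_kp_scheme
    return PartitionCoefficientSet(kp=scheme(chemical, composition))


def fu_hep(logp: float, vr: float = 0.005) -> float:
    """Unbound fraction in the hepatocyte incubation (logP-dependent)."""
    log_kc = 0.072 * logp**2 + 0.067 * logp - 1.126
    return 1.0 / (1.0 + 125.0 * vr * 10.0**log_kc)


def hepatic_clearance(
    chemical: ChemicalRecord,
    physiology: RatPhysiology,
    restrictive: bool,
) -> float:
    """Whole-body hepatic clearance, L/h/kg, via the well-stirred model.

    The intrinsic clearance (uL/min/1e6 cells) is divided by the unbound
    fraction in the clearance assay, scaled by hepatocellularity and
    liver mass to whole-body units, then passed through
    CL_h = Q_liver * fub * Clint_u / (Q_liver + fub * Clint_u) with
    fub = fup under restrictive clearance and fub = 1 otherwise.
    """
    if math.isnan(chemical.clint) or chemical.clint < 0:
        raise ValueError(f"{chemical.id}: clint must be resolved and >= 0")
    clint_u = chemical.clint
    if physiology.fu_hep_enabled:
        clint_u = clint_u / fu_hep(chemical.logp, physiology.fu_hep_vr)
    # uL/min/1e6 cells -> L/h/kg body weight
    clint_scaled = (
        clint_u
        * physiology.hepatocellularity
        * physiology.liver_mass_frac
        * 60.0
        / 1e6
    )
    q_liver = physiology.plasma_flows["liver"] + physiology.plasma_flows["gut"]
    fub = chemical.fup if restrictive else 1.0
    denom = q_liver + fub * clint_scaled
    cl = q_liver * fub * clint_scaled / denom if denom > 0 else 0.0
    # the well-stirred value is strictly below Q_liver; keep it that way
    # numerically when fub*Clint_u overflows the flow scale
    return min(cl, q_liver * (1.0 - 1e-12))


def renal_clearance(
    chemical: ChemicalRecord, physiology: RatPhysiology
) -> float:
    """Renal clearance by passive glomerular filtration: GFR * fup."""
    return physiology.gfr * chemical.fup


@dataclass
class PBTKParameters:
    chemical: ChemicalRecord
    physiology: RatPhysiology
    kp: PartitionCoefficientSet
    cl_hepatic: float
    cl_renal: float
    restrictive: bool

    def __post_init__(self) -> None:
        if self.cl_hepatic < 0:
            raise ValueError("cl_hepatic must be >= 0")
        q_liver = (
            self.physiology.plasma_flows["liver"]
            + self.physiology.plasma_flows["gut"]
        )
        if self.cl_hepatic >= q_liver:
            raise ValueError("cl_hepatic must be below hepatic plasma flow")


def build_params(
    chemical: ChemicalRecord,
    restrictive: bool,
    physiology: RatPhysiology | None = None,
    kp: PartitionCoefficientSet | None = None,
) -> PBTKParameters:
    if physiology is None:
        physiology = default_physiology()
    if kp is None:
        kp = tissue_partition_coefficients(chemical, physiology)
    return PBTKParameters(
        chemical=chemical,
        physiology=physiology,
        kp=kp,
        cl_hepatic=hepatic_clearance(chemical, physiology, restrictive),
        cl_renal=renal_clearance(chemical, physiology),
        restrictive=restrictive,
    )


@dataclass
class DoseRegimen:
    dose: float  # mg/kg/day
    doses_per_day: int = 1
    length_days: float = 1.0
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.doses_per_day < 1:
            raise ValueError("doses_per_day must be >= 1")
        if self.length_days <= 0:
            raise ValueError("length_days must be positive")
        if self.route != "oral":
            raise ValueError("only oral dosing is supported")


# state ordering for the linear system
_STATES = (
    "gut_lumen", "gut", "liver", "kidney", "lung", "rest",
    "arterial", "venous", "cleared",
)
_IDX = {s: i for i, s in enumerate(_STATES)}


@dataclass
class TimeCourse:
    """Solution of the model on an output grid.

    ``concentrations`` maps compartment name to a uM series (amount for
    the gut lumen); ``auc`` maps compartment to the exact uM*h area;
    ``amounts`` is the full state trajectory in umol/kg (with the
    cumulative cleared amount last), used for mass-balance checks.
    """

    times: np.ndarray
    concentrations: dict
    auc: dict
    amounts: np.ndarray
    administered: np.ndarray  # cumulative dosed amount, umol/kg
    duration: float  # h

    @property
    def auc_venous(self) -> float:
        return self.auc["venous_plasma"]


def _system_matrix(params: PBTKParameters) -> np.ndarray:
    phys = params.physiology
    fup = params.chemical.fup
    v = phys.tissue_volumes
    q = phys.plasma_flows
    v_art = phys.plasma_volume * phys.arterial_fraction
    v_ven = phys.plasma_volume * (1.0 - phys.arterial_fraction)
    r = {t: params.kp.kp[t] * fup for t in TISSUES}  # tissue:plasma ratios
    q_liver_total = q["liver"] + q["gut"]

    m = np.zeros((9, 9))
    gl, gut, liv, kid, lun, rest, art, ven, clr = range(9)

    m[gl, gl] -= phys.k_gutabs
    m[gut, gl] += phys.k_gutabs

    # arterial supply to tissues
    for t, i in (("gut", gut), ("liver", liv), ("kidney", kid), ("rest", rest)):
        m[i, art] += q[t] / v_art
    m[art, art] -= q["cardiac"] / v_art

    # gut outflow feeds the liver (portal)
    k_gut_out = q["gut"] / (v["gut"] * r["gut"])
    m[liv, gut] += k_gut_out
    m[gut, gut] -= k_gut_out

    # liver outflow to venous plasma + hepatic clearance of outflow plasma
    k_liv_out = q_liver_total / (v["liver"] * r["liver"])
    m[ven, liv] += k_liv_out
    m[liv, liv] -= k_liv_out
    k_liv_cl = params.cl_hepatic / (v["liver"] * r["liver"])
    m[clr, liv] += k_liv_cl
    m[liv, liv] -= k_liv_cl

    # kidney outflow + renal clearance
    k_kid_out = q["kidney"] / (v["kidney"] * r["kidney"])
    m[ven, kid] += k_kid_out
    m[kid, kid] -= k_kid_out
    k_kid_cl = params.cl_renal / (v["kidney"] * r["kidney"])
    m[clr, kid] += k_kid_cl
    m[kid, kid] -= k_kid_cl

    # rest-of-body outflow
    k_rest_out = q["rest"] / (v["rest"] * r["rest"])
    m[ven, rest] += k_rest_out
    m[rest, rest] -= k_rest_out

    # venous -> lung -> arterial
    m[lun, ven] += q["cardiac"] / v_ven
    m[ven, ven] -= q["cardiac"] / v_ven
    k_lun_out = q["cardiac"] / (v["lung"] * r["lung"])
    m[art, lun] += k_lun_out
    m[lun, lun] -= k_lun_out
    return m


def simulate(
    params: PBTKParameters,
    regimen: DoseRegimen,
    samples_per_interval: int = 48,
) -> TimeCourse:
    """Integrate the model for a repeated oral bolus regimen.

    The linear system is advanced one dosing interval at a time with the
    interval propagator exp(M*dt); per-interval areas come from the
    integral block of the augmented exponential, so AUCs are exact.
    Output concentrations are sampled on ``samples_per_interval`` points
    per dosing interval.
    """
    m = _system_matrix(params)
    interval = 24.0 / regimen.doses_per_day
    n_doses = max(1, round(regimen.length_days * regimen.doses_per_day))
    duration = n_doses * interval
    # umol/kg per bolus
    bolus = regimen.dose / regimen.doses_per_day / params.chemical.mw * 1000.0

    # augmented exponential: [[E, S], [0, I]] with S = int_0^dt exp(M t) dt
    n = m.shape[0]
    aug = np.zeros((2 * n, 2 * n))
    aug[:n, :n] = m * interval
    aug[:n, n:] = np.eye(n) * interval
    e_aug = expm(aug)
    e_int = e_aug[:n, :n]
    s_int = e_aug[:n, n:]

    dt = interval / samples_per_interval
    p_step = expm(m * dt)
    # propagators at the sub-interval sample points 0..samples_per_interval
    p = np.empty((samples_per_interval + 1, n, n))
    p[0] = np.eye(n)
    for j in range(1, samples_per_interval + 1):
        p[j] = p_step @ p[j - 1]

    e0 = np.zeros(n)
    e0[_IDX["gut_lumen"]] = bolus

    starts = np.empty((n_doses, n))
    x = e0.copy()
    for k in range(n_doses):
        starts[k] = x
        x = e_int @ x + e0
    final = e_int @ starts[-1]  # state at duration, before any next dose

    # trajectory on the sample grid: for interval k use points 0..spi-1,
    # and append the terminal state.
    traj = np.einsum("jab,kb->kja", p[:-1], starts).reshape(-1, n)
    amounts = np.vstack([traj, final])
    times = np.arange(amounts.shape[0]) * dt

    if np.any(amounts < -1e-9 * max(bolus, 1.0)):
        raise RuntimeError("negative state beyond tolerance")

    auc_amount = s_int @ starts.sum(axis=0)

    phys = params.physiology
    v_art = phys.plasma_volume * phys.arterial_fraction
    v_ven = phys.plasma_volume * (1.0 - phys.arterial_fraction)
    vols = {
        "gut": phys.tissue_volumes["gut"],
        "liver": phys.tissue_volumes["liver"],
        "kidney": phys.tissue_volumes["kidney"],
        "lung": phys.tissue_volumes["lung"],
        "rest": phys.tissue_volumes["rest"],
        "arterial_plasma": v_art,
        "venous_plasma": v_ven,
    }
    name_map = {
        "gut": "gut", "liver": "liver", "kidney": "kidney", "lung": "lung",
        "rest": "rest", "arterial": "arterial_plasma", "venous": "venous_plasma",
    }
    concentrations = {"gut_lumen": amounts[:, _IDX["gut_lumen"]]}
    auc = {}
    for state, out in name_map.items():
        concentrations[out] = amounts[:, _IDX[state]] / vols[out]
        auc[out] = auc_amount[_IDX[state]] / vols[out]

    administered = bolus * (np.floor(times / interval + 1e-12) + 1.0)
    administered = np.minimum(administered, bolus * n_doses)
    return TimeCourse(
        times=times,
        concentrations=concentrations,
        auc=auc,
        amounts=amounts,
        administered=administered,
        duration=duration,
    )


@dataclass(frozen=True)
class ConcentrationMetric:
    """Which concentration to read off the model solution."""

    statistic: str = "mean"  # mean | max
    compartment: str = "venous_plasma"  # venous_plasma | tissue name
    binding: str = "total"  # total | free

    def __post_init__(self) -> None:
        if self.statistic not in ("mean", "max"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.binding not in ("total", "free"):
            raise ValueError(f"unknown binding {self.binding!r}")
        if self.binding == "free" and self.compartment not in (
            "venous_plasma", "arterial_plasma",
        ):
            raise ValueError("free metric applies only to plasma compartments")


@dataclass(frozen=True)
class AssumptionSet:
    """One evaluated combination of model assumptions.

    The label follows the grammar ``{res.|nres.}-{tot.|free}-vein-{mean|max}``
    or ``{res.|nres.}-tis.-{mean|max}`` with an ``-Armitage`` suffix when
    the in vitro disposition model is applied.
    """

    clearance: str = "restrictive"  # restrictive | nonrestrictive
    metric: ConcentrationMetric = field(default_factory=ConcentrationMetric)
    armitage: bool = False

    def __post_init__(self) -> None:
        if self.clearance not in ("restrictive", "nonrestrictive"):
            raise ValueError(f"unknown clearance {self.clearance!r}")

    @property
    def restrictive(self) -> bool:
        return self.clearance == "restrictive"

    @property
    def label(self) -> str:
        cl = "res." if self.restrictive else "nres."
        if self.metric.compartment == "venous_plasma":
            conc = "tot.-vein" if self.metric.binding == "total" else "free-vein"
        else:
            conc = "tis."
        parts = [cl, conc, self.metric.statistic]
        if self.armitage:
            parts.append("Armitage")
        return "-".join(parts)

    @classmethod
    def from_label(cls, label: str) -> "AssumptionSet":
        parts = label.split("-")
        armitage = parts[-1] == "Armitage"
        if armitage:
            parts = parts[:-1]
        clearance = "restrictive" if parts[0] == "res." else "nonrestrictive"
        statistic = parts[-1]
        if parts[1] == "tis.":
            metric = ConcentrationMetric(statistic, "liver", "total")
        else:
            binding = "total" if parts[1] == "tot." else "free"
            metric = ConcentrationMetric(statistic, "venous_plasma", binding)
        return cls(clearance=clearance, metric=metric, armitage=armitage)


def extract_concentration(
    tc: TimeCourse, metric: ConcentrationMetric, fup: float
) -> float:
    """Read a summary concentration (uM) off a time course.

    mean = AUC / dosing duration; max = series maximum; free plasma
    metrics multiply the total plasma value by fup.
    """
    if metric.compartment not in tc.concentrations:
        raise KeyError(f"unknown compartment {metric.compartment!r}")
    if metric.statistic == "mean":
        value = tc.auc[metric.compartment] / tc.duration
    else:
        value = float(tc.concentrations[metric.compartment].max())
    if metric.binding == "free":
        value *= fup
    return value


def steady_state_mean_oracle(params: PBTKParameters, dose: float) -> float:
    """Analytic long-time mean venous concentration for continuous dosing.

    Css = dose rate / total clearance; valid as a long-horizon check for
    chemicals whose plasma gradients are small (clearance << flows).
    """
    cl_total = params.cl_hepatic + params.cl_renal
    if cl_total <= 0:
        raise ZeroDivisionError("oracle undefined for zero total clearance")
    rate = dose * 1000.0 / params.chemical.mw / 24.0  # umol/h/kg
    return rate / cl_total
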