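"""Equilibrium distribution of a chemical in an in vitro assay well.

A linear mass balance partitions the dosed amount among the aqueous
medium, serum lipid, serum protein, cell storage lipid, cell membrane
lipid, cell protein, headspace and the plastic well wall:

    C_aq = M_total / (V_aq + sum_i V_i * K_i)

with phase affinities K_i taken from configurable QSPR relations (storage
lipid ~ 10^logP, a membrane-lipid relation, an albumin-type protein
relation, Henry's law for the headspace and an area-based relation for
the wall).  Only the neutral fraction leaves the aqueous phase by
default.  The aqueous:nominal concentration ratio is the factor used to
adjust dose-to-concentration ratios when the free in vitro concentration
is assumed bioactive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import yaml

from .chem_params import ChemicalRecord, neutral_fraction

__all__ = [
    "AssayWellSpec",
    "InVitroDistribution",
    "default_well",
    "distribute_in_vitro",
    "adjust_kappa",
]

R_ATM_M3 = 8.205736e-5  # atm m^3 / (mol K)


def _load_cfg() -> dict:
    with resources.files("ivive.data").joinpath("wells.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class AssayWellSpec:
    well_format: int
    media_volume: float  # uL
    well_area: float  # mm^2
    headspace_volume: float  # uL
    cell_count: float
    cell_volume: float  # uL total
    fbs_fraction: float
    serum_lipid_frac: float
    serum_protein_frac: float
    cell_storage_lipid_frac: float
    cell_membrane_lipid_frac: float
    cell_protein_frac: float
    cell_water_frac: float

    def __post_init__(self) -> None:
        for name in ("media_volume", "headspace_volume", "cell_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        cell_fracs = (
            self.cell_storage_lipid_frac
            + self.cell_membrane_lipid_frac
            + self.cell_protein_frac
            + self.cell_water_frac
        )
        if cell_fracs > 1.0 + 1e-9:
            raise ValueError("cell composition fractions sum above 1")


def default_well(
    well_format: int | None = None, cell_based: bool = True
) -> AssayWellSpec:
    """Well of the given footprint with default serum/cell composition.

    ``cell_based=False`` drops the cells and serum (biochemical assay).
    """
    cfg = _load_cfg()
    d = cfg["defaults"]
    if well_format is None:
        well_format = d["well_format"]
    geom = cfg["well_formats"][well_format]
    cell_count = d["cell_count"] if cell_based else 0.0
    return AssayWellSpec(
        well_format=well_format,
        media_volume=geom["media_volume"],
        well_area=geom["well_area"],
        headspace_volume=geom["headspace_volume"],
        cell_count=cell_count,
        cell_volume=cell_count * d["cell_volume_per_cell"],
        fbs_fraction=d["fbs_fraction"] if cell_based else 0.0,
        serum_lipid_frac=d["serum_lipid_frac"],
        serum_protein_frac=d["serum_protein_frac"],
        cell_storage_lipid_frac=d["cell_storage_lipid_frac"],
        cell_membrane_lipid_frac=d["cell_membrane_lipid_frac"],
        cell_protein_frac=d["cell_protein_frac"],
        cell_water_frac=d["cell_water_frac"],
    )


@dataclass
class InVitroDistribution:
    masses: dict  # phase -> mol
    c_aqueous: float  # uM
    c_nominal: float  # uM
    factor: float  # c_aqueous / c_nominal

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("factor must be positive")


def distribute_in_vitro(
    chemical: ChemicalRecord,
    well: AssayWellSpec,
    nominal: float = 1.0,
    qspr: dict | None = None,
) -> InVitroDistribution:
    """Solve the well mass balance at the given nominal concentration.

    The model is linear (non-saturable), so ``factor`` is independent of
    the nominal concentration.
    """
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    cfg = _load_cfg()
    q = dict(cfg["qspr"])
    if qspr:
        q.update(qspr)

    logp = chemical.logp
    if q.get("ions_partition", False):
        fn = 1.0
    else:
        fn = neutral_fraction(chemical.pka_donor, chemical.pka_acceptor)

    k_storage = fn * 10.0**logp
    k_membrane = fn * 10.0 ** (
        q["membrane_slope"] * logp + q["membrane_intercept"]
    )
    k_protein = fn * 10.0 ** (q["protein_slope"] * logp + q["protein_intercept"])
    if well.headspace_volume > 0:
        if math.isnan(chemical.loghenry):
            warnings.warn(
                f"{chemical.id}: no Henry constant; treating as nonvolatile",
                stacklevel=2,
            )
            k_air = 0.0
        else:
            t = cfg.get("temperature_k", 310.0)
            k_air = fn * 10.0**chemical.loghenry / (R_ATM_M3 * t)
    else:
        k_air = 0.0
    # wall sorption: K_plastic in m of equivalent water column per area
    k_plastic_m = fn * 10.0 ** (q["plastic_slope"] * logp + q["plastic_intercept"])
    # mm^2 * m -> uL:  1 mm^2 * 1 m = 1e-6 m^3 * 1e9 uL/m^3 / 1e3 = 1e3 uL... (1 m^3 = 1e9 uL)
    v_plastic_eq = well.well_area * 1e-6 * k_plastic_m * 1e9  # uL equivalent

    v_serum = well.media_volume * well.fbs_fraction
    volumes = {  # uL of each sorbing phase
        "serum_lipid": v_serum * well.serum_lipid_frac,
        "serum_protein": v_serum * well.serum_protein_frac,
        "cell_storage_lipid": well.cell_volume * well.cell_storage_lipid_frac,
        "cell_membrane_lipid": well.cell_volume * well.cell_membrane_lipid_frac,
        "cell_protein": well.cell_volume * well.cell_protein_frac,
        "headspace": well.headspace_volume,
    }
    ks = {
        "serum_lipid": k_storage,
        "serum_protein": k_protein,
        "cell_storage_lipid": k_storage,
        "cell_membrane_lipid": k_membrane,
        "cell_protein": k_protein,
        "headspace": k_air,
    }
    v_aq = (
        well.media_volume
        - volumes["serum_lipid"]
        - volumes["serum_protein"]
        + well.cell_volume * well.cell_water_frac
    )

    total_mol = nominal * 1e-6 * well.media_volume * 1e-6  # uM * L -> mol
    capacity = v_aq + v_plastic_eq + sum(
        volumes[p] * ks[p] for p in volumes
    )
    c_aq_molar = total_mol / (capacity * 1e-6)  # mol/L
    c_aq = c_aq_molar * 1e6  # uM

    masses = {"aqueous": c_aq_molar * v_aq * 1e-6}
    for p in volumes:
        masses[p] = c_aq_molar * ks[p] * volumes[p] * 1e-6
    masses["plastic"] = c_aq_molar * v_plastic_eq * 1e-6

    return InVitroDistribution(
        masses=masses, c_aqueous=c_aq, c_nominal=nominal, factor=c_aq / nominal
    )


def adjust_kappa(kappa: float, factor: float) -> float:
    """Divide a concentration-to-dose ratio by the aqueous:nominal factor."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return kappa / factor
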