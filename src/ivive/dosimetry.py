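"""Concentration-to-dose ratios and the forward/reverse dosimetry transforms.

kappa is the internal concentration (uM) produced by a 1 mg/kg/day
once-daily regimen over a given study length, under a given assumption
set; forward dosimetry maps dose -> concentration (C = dose * kappa) and
reverse dosimetry maps an in vitro active concentration to an
administered equivalent dose (AED = AC50 / kappa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import armitage, pbtk
from .chem_params import ChemicalRecord

__all__ = [
    "KappaEntry",
    "DosimetryResult",
    "KappaCalculator",
    "compute_kappa",
    "forward_concentration",
    "reverse_aed",
]

REFERENCE_DOSE = 1.0  # mg/kg/day


@dataclass(frozen=True)
class KappaEntry:
    chemical_id: str
    study_length: float  # days
    assumption_label: str
    kappa: float  # uM per (mg/kg/day)

    def __post_init__(self) -> None:
        if not (self.kappa > 0 and math.isfinite(self.kappa)):
            raise ValueError(
                f"kappa must be positive and finite, got {self.kappa}"
            )


@dataclass
class DosimetryResult:
    """Forward and reverse predictions for one (dose, AC50) record.

    The forward residual log10(AC50) - log10(C) equals minus the reverse
    residual log10(dose) - log10(AED) identically.
    """

    chemical_id: str
    dose: float
    ac50: float
    c_pbtk: float
    aed_pbtk: float

    @property
    def residual(self) -> float:
        return math.log10(self.ac50) - math.log10(self.c_pbtk)


class KappaCalculator:
    """Computes and caches kappa values.

    Simulations are cached per (chemical, study length, clearance mode):
    all concentration metrics are read off the same time course, and the
    in vitro disposition factor is cached per chemical, so a full
    assumption grid costs two integrations per chemical and study length.
    """

    def __init__(
        self,
        physiology: pbtk.RatPhysiology | None = None,
        well: armitage.AssayWellSpec | None = None,
        samples_per_interval: int = 48,
    ) -> None:
        self.physiology = physiology or pbtk.default_physiology()
        self.well = well or armitage.default_well()
        self.samples_per_interval = samples_per_interval
        self._tc_cache: dict = {}
        self._factor_cache: dict = {}
        self._kp_cache: dict = {}

    def _timecourse(
        self, chemical: ChemicalRecord, study_length: float, restrictive: bool
    ) -> pbtk.TimeCourse:
        fp = chemical.fingerprint
        key = (fp, study_length, restrictive)
        if key not in self._tc_cache:
            if fp not in self._kp_cache:
                self._kp_cache[fp] = pbtk.tissue_partition_coefficients(
                    chemical, self.physiology
                )
            params = pbtk.build_params(
                chemical,
                restrictive,
                self.physiology,
                kp=self._kp_cache[fp],
            )
            regimen = pbtk.DoseRegimen(
                dose=REFERENCE_DOSE, doses_per_day=1, length_days=study_length
            )
            self._tc_cache[key] = pbtk.simulate(
                params, regimen, self.samples_per_interval
            )
        return self._tc_cache[key]

    def armitage_factor(self, chemical: ChemicalRecord) -> float:
        fp = chemical.fingerprint
        if fp not in self._factor_cache:
            dist = armitage.distribute_in_vitro(chemical, self.well)
            self._factor_cache[fp] = dist.factor
        return self._factor_cache[fp]

    def compute(
        self,
        chemical: ChemicalRecord,
        study_length: float,
        assumptions: pbtk.AssumptionSet,
    ) -> KappaEntry:
        tc = self._timecourse(chemical, study_length, assumptions.restrictive)
        kappa = pbtk.extract_concentration(
            tc, assumptions.metric, chemical.fup
        ) / REFERENCE_DOSE
        if assumptions.armitage:
            kappa = armitage.adjust_kappa(
                kappa, self.armitage_factor(chemical)
            )
        return KappaEntry(
            chemical_id=chemical.id,
            study_length=study_length,
            assumption_label=assumptions.label,
            kappa=kappa,
        )


def compute_kappa(
    chemical: ChemicalRecord,
    study_length: float,
    assumptions: pbtk.AssumptionSet,
    physiology: pbtk.RatPhysiology | None = None,
) -> KappaEntry:
    """One-shot kappa; use :class:`KappaCalculator` for batch work."""
    return KappaCalculator(physiology=physiology).compute(
        chemical, study_length, assumptions
    )


def forward_concentration(dose: float, kappa: KappaEntry | float) -> float:
    """Predicted internal concentration (uM) at the given dose."""
    k = kappa.kappa if isinstance(kappa, KappaEntry) else kappa
    return dose * k


def reverse_aed(ac50: float, kappa: KappaEntry | float) -> float:
    """Administered equivalent dose (mg/kg/day) for an active concentration."""
    k = kappa.kappa if isinstance(kappa, KappaEntry) else kappa
    return ac50 / k
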