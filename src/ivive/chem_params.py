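"""Chemical toxicokinetic and physicochemical parameter handling.

This module holds the canonical per-chemical record used throughout the
pipeline and the measurement-handling rules applied when assembling it:
the below-limit-of-detection default for the fraction unbound in plasma,
the concentration-based selection of the intrinsic clearance measurement,
and the pH 7.4 distribution coefficient derived from logP and pKa values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = [
    "ChemicalRecord",
    "FUP_LOD_DEFAULT",
    "resolve_fup",
    "correct_fup_nonspecific_binding",
    "select_clint",
    "compute_logd",
    "neutral_fraction",
    "MissingDataError",
]

#: Default fraction unbound in plasma assumed when the measured value is
#: below the limit of detection of the equilibrium dialysis assay.
FUP_LOD_DEFAULT = 0.005

PH_PLASMA = 7.4


class MissingDataError(ValueError):
    """Raised when a required measurement is absent."""


@dataclass
class ChemicalRecord:
    """One chemical's TK and physicochemical parameters.

    Attributes
    ----------
    id : str
        Chemical identifier (CAS number or DTXSID).
    mw : float
        Molecular weight, g/mol.
    logp : float
        log10 octanol-water partition coefficient.
    pka_donor, pka_acceptor : list of float
        Acidic (proton-donor) and basic (proton-acceptor) pKa values.
    fup : float
        Fraction unbound in plasma, in (0, 1].
    clint : float
        Resolved intrinsic hepatic clearance, uL/min/1e6 cells.
    """

    id: str
    name: str = ""
    mw: float = float("nan")
    logp: float = float("nan")
    pka_donor: list = field(default_factory=list)
    pka_acceptor: list = field(default_factory=list)
    fup: float = float("nan")
    fup_below_lod: bool = False
    clint_1: float | None = None
    clint_10: float | None = None
    clint: float = float("nan")
    logwsol: float = float("nan")
    loghenry: float = float("nan")
    logd: float = float("nan")

    def __post_init__(self) -> None:
        if not math.isnan(self.mw) and self.mw <= 0:
            raise ValueError(f"{self.id}: mw must be positive, got {self.mw}")
        if not math.isnan(self.fup) and not (0.0 < self.fup <= 1.0):
            raise ValueError(f"{self.id}: fup must be in (0, 1], got {self.fup}")
        if math.isnan(self.clint) and (
            self.clint_1 is not None or self.clint_10 is not None
        ):
            self.clint = select_clint(self.clint_1, self.clint_10)
        if not math.isnan(self.clint) and self.clint < 0:
            raise ValueError(f"{self.id}: clint must be >= 0, got {self.clint}")
        if math.isnan(self.logd) and not math.isnan(self.logp):
            self.logd = compute_logd(
                self.logp, self.pka_donor, self.pka_acceptor, PH_PLASMA
            )


    @property
    def fingerprint(self) -> tuple:
        """Identity of the parameters that drive model behaviour; used as
        a cache key so records sharing an id but not parameters are never
        conflated."""
        return (
            self.id, self.mw, self.logp, tuple(self.pka_donor),
            tuple(self.pka_acceptor), self.fup, self.clint,
            self.logwsol, self.loghenry,
        )


def resolve_fup(
    measured_value: float | None,
    below_lod: bool,
    default: float = FUP_LOD_DEFAULT,
) -> float:
    """Resolve a plasma unbound fraction measurement.

    Returns the measured value when it is present and above the limit of
    detection; otherwise the assay default (half the minimum detectable
    level, 0.005).
    """
    if below_lod or measured_value is None or (
        isinstance(measured_value, float) and math.isnan(measured_value)
    ):
        return default
    if not (0.0 < measured_value <= 1.0):
        raise ValueError(f"fup must be in (0, 1], got {measured_value}")
    return float(measured_value)


def correct_fup_nonspecific_binding(
    fup: float, correction: Callable[[float], float] | None = None
) -> float:
    """Apply a correction for non-specific binding in the dialysis assay.

    The published correction is not reproduced here; the default is the
    identity and callers may inject the correction of their choice. The
    injected function must map (0, 1] into (0, 1] and be monotone
    non-decreasing.
    """
    if not (0.0 < fup <= 1.0):
        raise ValueError(f"fup must be in (0, 1], got {fup}")
    if correction is None:
        return fup
    out = correction(fup)
    if not (0.0 < out <= 1.0):
        raise ValueError(f"correction returned value outside (0, 1]: {out}")
    return out


def select_clint(
    clint_1: float | None, clint_10: float | None
) -> float:
    """Select the intrinsic clearance measurement to carry forward.

    The measurement at 1 uM is used when available, otherwise the one at
    10 uM.  A value of 0 is a valid measurement (no observed parent
    disappearance) and is preserved.
    """
    def _present(v: float | None) -> bool:
        return v is not None and not (isinstance(v, float) and math.isnan(v))

    if _present(clint_1):
        value = float(clint_1)
    elif _present(clint_10):
        value = float(clint_10)
    else:
        raise MissingDataError("no intrinsic clearance measurement available")
    if value < 0:
        raise ValueError(f"clint must be >= 0, got {value}")
    return value


def _ionized_terms(
    pka_donor: Sequence[float], pka_acceptor: Sequence[float], ph: float
) -> float:
    # Henderson-Hasselbalch, each site treated independently.
    total = 0.0
    for pka in pka_donor:
        total += 10.0 ** (ph - pka)
    for pka in pka_acceptor:
        total += 10.0 ** (pka - ph)
    return total


def compute_logd(
    logp: float,
    pka_donor: Sequence[float] = (),
    pka_acceptor: Sequence[float] = (),
    ph: float = PH_PLASMA,
) -> float:
    """pH-dependent distribution coefficient.

    logD = logP - log10(1 + sum of ionized-fraction terms); equals logP
    for a neutral chemical.
    """
    if not (0.0 <= ph <= 14.0):
        raise ValueError(f"ph must be in [0, 14], got {ph}")
    return logp - math.log10(1.0 + _ionized_terms(pka_donor, pka_acceptor, ph))


def neutral_fraction(
    pka_donor: Sequence[float] = (),
    pka_acceptor: Sequence[float] = (),
    ph: float = PH_PLASMA,
) -> float:
    """Fraction of the chemical in its neutral form at the given pH."""
    return 1.0 / (1.0 + _ionized_terms(pka_donor, pka_acceptor, ph))
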