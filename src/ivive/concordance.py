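"""Concordance evaluation of dosimetry predictors.

For every in vitro assay endpoint x in vivo endpoint pairing (or assay
endpoint x per-chemical POD), the association between log10-transformed,
standardized variables is scored by the orthogonal root mean square
error about the identity line,

    ORMSE = sqrt( sum(((phi_i - theta_i)/sqrt(2))^2) / n ),

for three predictors: the chemical-specific model transformation, ten
resampled-chemical randomizations of it, and the untransformed values.
The predictor with the lowest ORMSE per contest receives a "win"; win
counts are aggregated per assumption set, dosimetry direction and
random-set index as medians and standard deviations over the ten sets.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ComparisonSet",
    "OrmseRecord",
    "RandomizationPlan",
    "PodComparisonRecord",
    "CorrelationRecord",
    "DegenerateComparisonError",
    "build_comparisons",
    "standardize",
    "ormse",
    "make_randomization_plan",
    "comparison_seed",
    "evaluate_comparison",
    "allocate_wins",
    "aggregate_counts",
    "pod10_aed10",
    "residual_param_correlations",
    "PREDICTORS",
    "N_RANDOM_SETS",
]

log = logging.getLogger(__name__)

PREDICTORS = ("pbtk", "random", "untransformed")
N_RANDOM_SETS = 10

# tie priority, conservative against the model under evaluation
_TIE_ORDER = {"untransformed": 0, "random": 1, "pbtk": 2}


class DegenerateComparisonError(ValueError):
    """Zero variance on one side; the comparison cannot be standardized."""


@dataclass
class ComparisonSet:
    """One assay endpoint x in vivo endpoint pairing, vectors aligned."""

    assay_endpoint: str
    in_vivo_endpoint: str  # endpoint id or "POD"
    chemical_ids: list
    doses: np.ndarray  # mg/kg/day
    ac50s: np.ndarray  # uM
    study_lengths: np.ndarray  # days

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.ac50s = np.asarray(self.ac50s, dtype=float)
        self.study_lengths = np.asarray(self.study_lengths, dtype=float)
        sizes = {len(self.chemical_ids), self.doses.size, self.ac50s.size,
                 self.study_lengths.size}
        if len(sizes) != 1:
            raise ValueError("comparison vectors are not aligned")
        if np.any(self.doses <= 0) or np.any(self.ac50s <= 0):
            raise ValueError("doses and AC50s must be positive")

    @property
    def n(self) -> int:
        return len(set(self.chemical_ids))

    @property
    def key(self) -> str:
        return f"{self.assay_endpoint}::{self.in_vivo_endpoint}"


@dataclass(frozen=True)
class OrmseRecord:
    predictor: str  # pbtk | random | untransformed
    direction: str  # forward | reverse
    ormse: float
    random_index: int | None = None

    def __post_init__(self) -> None:
        if self.ormse < 0:
            raise ValueError("ormse must be >= 0")


@dataclass
class RandomizationPlan:
    seed: int
    permuted_indices: np.ndarray  # (n_sets, n) row indices into the comparison

    @property
    def n_sets(self) -> int:
        return self.permuted_indices.shape[0]


@dataclass(frozen=True)
class PodComparisonRecord:
    chemical_id: str
    pod10: float
    aed10: float

    @property
    def residual(self) -> float:
        return math.log10(self.pod10) - math.log10(self.aed10)


@dataclass(frozen=True)
class CorrelationRecord:
    parameter: str
    abs_cor: float
    n: int


def build_comparisons(
    ac50_hits,
    invivo,
    min_n: int = 5,
    level: str = "endpoint",
    pod_study_lengths: dict | None = None,
) -> list[ComparisonSet]:
    """Merge activity and toxicity tables into comparison sets.

    ``ac50_hits`` is a list of filtered AssayHit records (duplicates per
    (chemical, assay) are collapsed to the minimum AC50).  For the
    endpoint level, ``invivo`` is a list of EndpointDoseRecord and one
    set is built per (assay endpoint, in vivo endpoint) with at least
    ``min_n`` unique chemicals; for the POD level, ``invivo`` is a
    per-chemical dose mapping and one set is built per assay endpoint.
    """
    ac50_map: dict = {}
    for h in ac50_hits:
        key = (h.chemical_id, h.assay_endpoint)
        if key not in ac50_map or h.ac50 < ac50_map[key]:
            ac50_map[key] = h.ac50
    assays = sorted({a for (_, a) in ac50_map})
    by_assay: dict = {a: {} for a in assays}
    for (cid, a), v in ac50_map.items():
        by_assay[a][cid] = v

    comparisons = []
    if level == "endpoint":
        by_endpoint: dict = {}
        for r in invivo:
            by_endpoint.setdefault(r.endpoint_id, []).append(r)
        for assay in assays:
            chems = by_assay[assay]
            for endpoint_id in sorted(by_endpoint):
                rows = [r for r in by_endpoint[endpoint_id]
                        if r.chemical_id in chems]
                if len({r.chemical_id for r in rows}) < min_n:
                    continue
                comparisons.append(ComparisonSet(
                    assay_endpoint=assay,
                    in_vivo_endpoint=endpoint_id,
                    chemical_ids=[r.chemical_id for r in rows],
                    doses=np.array([r.dose for r in rows]),
                    ac50s=np.array([chems[r.chemical_id] for r in rows]),
                    study_lengths=np.array([r.study_length for r in rows]),
                ))
    elif level == "pod":
        lengths = pod_study_lengths or {}
        for assay in assays:
            chems = by_assay[assay]
            shared = sorted(set(chems) & set(invivo))
            if len(shared) < min_n:
                continue
            comparisons.append(ComparisonSet(
                assay_endpoint=assay,
                in_vivo_endpoint="POD",
                chemical_ids=list(shared),
                doses=np.array([invivo[c] for c in shared]),
                ac50s=np.array([chems[c] for c in shared]),
                study_lengths=np.array(
                    [lengths.get(c, 90.0) for c in shared]
                ),
            ))
    else:
        raise ValueError(f"unknown level {level!r}")
    return comparisons


def standardize(values: np.ndarray) -> np.ndarray:
    """Center and scale by the sample (n-1) standard deviation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateComparisonError("zero variance")
    return (values - values.mean()) / sd


def ormse(phi: np.ndarray, theta: np.ndarray) -> float:
    """RMS orthogonal distance of (theta, phi) points from the phi=theta line."""
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if phi.shape != theta.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean(((phi - theta) / np.sqrt(2.0)) ** 2)))


def comparison_seed(master_seed: int, comparison_key: str) -> int:
    """Stable per-comparison seed derived from the master seed."""
    digest = hashlib.sha256(
        f"{master_seed}:{comparison_key}".encode()
    ).digest()
    return int.from_bytes(digest[:8], "little")


def make_randomization_plan(
    comparison: ComparisonSet, seed: int, n_sets: int = N_RANDOM_SETS
) -> RandomizationPlan:
    """Resample the comparison's chemical vector with replacement n_sets times."""
    n = len(comparison.chemical_ids)
    if n < 2:
        raise ValueError("need at least 2 records")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_sets, n))
    return RandomizationPlan(seed=seed, permuted_indices=idx)


def _kappa_vector(comparison, kappa_lookup, label, chem_ids=None):
    """kappa per record, joined on (chemical, the record's study length)."""
    chem_ids = comparison.chemical_ids if chem_ids is None else chem_ids
    return np.array([
        kappa_lookup(cid, length, label)
        for cid, length in zip(chem_ids, comparison.study_lengths)
    ])


def evaluate_comparison(
    comparison: ComparisonSet,
    kappa_lookup,
    plan: RandomizationPlan,
    direction: str,
    label: str,
) -> list[OrmseRecord]:
    """Score the three predictors for one comparison and direction.

    ``kappa_lookup(chemical_id, study_length, label)`` returns the kappa
    for that chemical at that study length.  Randomized kappas use the
    substituted chemical at the original record's study length; dose,
    AC50 and study length stay with the original record.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError(f"unknown direction {direction!r}")
    log_dose = np.log10(comparison.doses)
    log_ac50 = np.log10(comparison.ac50s)
    kap = _kappa_vector(comparison, kappa_lookup, label)
    chem_arr = np.asarray(comparison.chemical_ids, dtype=object)

    if direction == "forward":
        y = log_ac50
        x_pbtk = log_dose + np.log10(kap)
        x_untr = log_dose
    else:
        y = log_dose
        x_pbtk = log_ac50 - np.log10(kap)
        x_untr = log_ac50

    phi = standardize(y)
    records = [
        OrmseRecord("pbtk", direction, ormse(phi, standardize(x_pbtk))),
        OrmseRecord("untransformed", direction, ormse(phi, standardize(x_untr))),
    ]
    for i in range(plan.n_sets):
        sub_ids = chem_arr[plan.permuted_indices[i]]
        kap_r = _kappa_vector(comparison, kappa_lookup, label, sub_ids)
        if direction == "forward":
            x_r = log_dose + np.log10(kap_r)
        else:
            x_r = log_ac50 - np.log10(kap_r)
        records.append(
            OrmseRecord("random", direction, ormse(phi, standardize(x_r)),
                        random_index=i)
        )
    return records


def allocate_wins(records: list[OrmseRecord]) -> dict[int, str]:
    """Winner per random-set index from one comparison's OrmseRecords.

    Each contest pits the pbtk and untransformed records against one
    random record.  Exact ties go untransformed > random > pbtk.
    """
    fixed = {r.predictor: r for r in records if r.predictor != "random"}
    if set(fixed) != {"pbtk", "untransformed"}:
        raise ValueError("need exactly one pbtk and one untransformed record")
    winners = {}
    for r in records:
        if r.predictor != "random":
            continue
        contest = [fixed["pbtk"], fixed["untransformed"], r]
        best = min(contest, key=lambda c: (c.ormse, _TIE_ORDER[c.predictor]))
        winners[r.random_index] = best.predictor
    return winners


def aggregate_counts(win_table: pd.DataFrame) -> pd.DataFrame:
    """Summarize per-set win counts into medians, SDs and win fractions.

    ``win_table`` has columns (label, direction, set_index, predictor,
    wins).  Returns one row per (label, direction, predictor) with the
    median and SD of the counts across sets and the median per-set win
    fraction.
    """
    totals = win_table.groupby(["label", "direction", "set_index"])["wins"].sum()
    rows = []
    for (label, direction, predictor), grp in win_table.groupby(
        ["label", "direction", "predictor"]
    ):
        counts = grp.set_index("set_index")["wins"]
        tot = totals.loc[label, direction].reindex(counts.index)
        frac = (counts / tot).replace([np.inf, -np.inf], np.nan)
        rows.append({
            "label": label,
            "direction": direction,
            "predictor": predictor,
            "median_wins": float(counts.median()),
            "sd_wins": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
            "median_fraction": float(frac.median()),
        })
    return pd.DataFrame(rows).sort_values(
        ["label", "direction", "predictor"]
    ).reset_index(drop=True)


def _quantile(values, q: float) -> float:
    # linear interpolation at rank 1 + (n-1) q on the ordered values
    return float(np.quantile(np.asarray(values, dtype=float), q))


def pod10_aed10(
    pods: dict[str, list],
    aeds: dict[str, list],
    q: float = 0.10,
) -> tuple[list[PodComparisonRecord], float, float]:
    """Per-chemical lower-q quantiles of PODs and AEDs, with RMSE and ORMSE.

    RMSE is of the log10 pairs; ORMSE is of the standardized log10 pairs.
    """
    shared = sorted(set(pods) & set(aeds))
    records = [
        PodComparisonRecord(
            chemical_id=cid,
            pod10=_quantile(pods[cid], q),
            aed10=_quantile(aeds[cid], q),
        )
        for cid in shared
    ]
    log_pod = np.array([math.log10(r.pod10) for r in records])
    log_aed = np.array([math.log10(r.aed10) for r in records])
    rmse = float(np.sqrt(np.mean((log_pod - log_aed) ** 2)))
    if len(records) >= 2 and log_pod.std(ddof=1) > 0 and log_aed.std(ddof=1) > 0:
        o = ormse(standardize(log_pod), standardize(log_aed))
    else:
        o = float("nan")
    return records, rmse, o


PARAMETER_FIELDS = {
    "fup": "fup",
    "clint": "clint",
    "logP": "logp",
    "logD": "logd",
    "MW": "mw",
}


def residual_param_correlations(
    records: list[PodComparisonRecord],
    chemicals: dict,
) -> list[CorrelationRecord]:
    """|Pearson r| between POD10/AED10 residuals and chemical parameters."""
    out = []
    for name, attr in PARAMETER_FIELDS.items():
        pairs = [
            (r.residual, getattr(chemicals[r.chemical_id], attr))
            for r in records
            if r.chemical_id in chemicals
            and np.isfinite(getattr(chemicals[r.chemical_id], attr))
        ]
        if len(pairs) < 3:
            continue
        resid, param = map(np.asarray, zip(*pairs))
        if resid.std() == 0 or param.std() == 0:
            continue
        r = float(np.corrcoef(resid, param)[0, 1])
        out.append(CorrelationRecord(parameter=name, abs_cor=abs(r),
                                     n=len(pairs)))
    return out
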