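"""Orchestration of the full concordance workflow across assumption sets.

Endpoint-level and POD-level analyses share the same engine: merge the
filtered activity table with the in vivo doses, compute dose-to-
concentration ratios per chemical and study length, score the model,
randomized and untransformed predictors by ORMSE in both dosimetry
directions, and tally wins per random set.  Study types are evaluated
separately (the in vivo endpoint identity includes the study type) and
the counts compiled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import concordance, io_formats, pbtk
from .chem_params import ChemicalRecord
from .concordance import (
    DegenerateComparisonError,
    N_RANDOM_SETS,
    PREDICTORS,
)
from .dosimetry import KappaCalculator, reverse_aed

__all__ = [
    "RunConfig",
    "DEFAULT_ASSUMPTION_LABELS",
    "KappaTable",
    "run_endpoint_analysis",
    "run_pod_analysis",
    "run_pod10_comparison",
]

log = logging.getLogger(__name__)

#: Default evaluated grid: clearance x concentration selection, with the
#: in vitro disposition model combined only with the mean venous plasma
#: concentrations.
DEFAULT_ASSUMPTION_LABELS = (
    "res.-tot.-vein-mean",
    "res.-tot.-vein-max",
    "res.-free-vein-mean",
    "res.-free-vein-max",
    "res.-tis.-mean",
    "res.-tis.-max",
    "nres.-tot.-vein-mean",
    "nres.-tot.-vein-max",
    "nres.-free-vein-mean",
    "nres.-free-vein-max",
    "nres.-tis.-mean",
    "nres.-tis.-max",
    "res.-tot.-vein-mean-Armitage",
    "res.-free-vein-mean-Armitage",
    "nres.-tot.-vein-mean-Armitage",
    "nres.-free-vein-mean-Armitage",
)


@dataclass
class RunConfig:
    analysis_level: str = "endpoint"  # endpoint | pod
    assumption_labels: tuple = DEFAULT_ASSUMPTION_LABELS
    min_n: int = 5
    directions: tuple = ("forward", "reverse")
    n_random_sets: int = N_RANDOM_SETS
    master_seed: int = 0
    quantile: float = 0.10

    def __post_init__(self) -> None:
        if not self.assumption_labels:
            raise ValueError("at least one assumption set is required")
        if self.min_n < 2:
            raise ValueError("min_n must be >= 2")


class KappaTable:
    """Memoized kappa lookup over chemicals, study lengths and labels."""

    def __init__(
        self,
        chemicals: list[ChemicalRecord],
        calculator: KappaCalculator | None = None,
    ) -> None:
        self.chemicals = {c.id: c for c in chemicals}
        self.calculator = calculator or KappaCalculator()
        self._cache: dict = {}
        self._assumptions: dict = {}

    def __call__(self, chemical_id: str, study_length: float, label: str) -> float:
        key = (chemical_id, study_length, label)
        if key not in self._cache:
            if label not in self._assumptions:
                self._assumptions[label] = pbtk.AssumptionSet.from_label(label)
            self._cache[key] = self.calculator.compute(
                self.chemicals[chemical_id],
                study_length,
                self._assumptions[label],
            ).kappa
        return self._cache[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chemical_id": cid, "study_length_days": length,
             "assumption_label": label, "kappa": kappa}
            for (cid, length, label), kappa in sorted(self._cache.items())
        ]
        return pd.DataFrame(
            rows, columns=["chemical_id", "study_length_days",
                           "assumption_label", "kappa"]
        )


def _evaluate_level(
    comparisons: list[concordance.ComparisonSet],
    kappa_table: KappaTable,
    cfg: RunConfig,
) -> dict:
    ormse_rows = []
    win_rows = []
    skipped = []
    for label in cfg.assumption_labels:
        for comp in comparisons:
            plan = concordance.make_randomization_plan(
                comp,
                concordance.comparison_seed(cfg.master_seed, comp.key),
                cfg.n_random_sets,
            )
            for direction in cfg.directions:
                try:
                    records = concordance.evaluate_comparison(
                        comp, kappa_table, plan, direction, label
                    )
                except DegenerateComparisonError as exc:
                    log.info("skipping %s (%s): %s", comp.key, direction, exc)
                    skipped.append((label, comp.key, direction, str(exc)))
                    continue
                for r in records:
                    ormse_rows.append({
                        "label": label,
                        "assay_endpoint": comp.assay_endpoint,
                        "in_vivo_endpoint": comp.in_vivo_endpoint,
                        "n_chemicals": comp.n,
                        "direction": direction,
                        "predictor": r.predictor,
                        "random_index": r.random_index,
                        "ormse": r.ormse,
                    })
                winners = concordance.allocate_wins(records)
                for set_index, predictor in winners.items():
                    win_rows.append({
                        "label": label,
                        "direction": direction,
                        "set_index": set_index,
                        "winner": predictor,
                    })
    ormse_df = pd.DataFrame(ormse_rows)
    if win_rows:
        wins = (
            pd.DataFrame(win_rows)
            .groupby(["label", "direction", "set_index", "winner"])
            .size()
            .rename("wins")
            .reset_index()
            .rename(columns={"winner": "predictor"})
        )
        # zero-fill predictors that never won in a set
        full_index = pd.MultiIndex.from_product(
            [list(cfg.assumption_labels), list(cfg.directions),
             range(cfg.n_random_sets), list(PREDICTORS)],
            names=["label", "direction", "set_index", "predictor"],
        )
        wins = (
            wins.set_index(["label", "direction", "set_index", "predictor"])
            .reindex(full_index, fill_value=0)
            .reset_index()
        )
        summary = concordance.aggregate_counts(wins)
    else:
        wins = pd.DataFrame(
            columns=["label", "direction", "set_index", "predictor", "wins"]
        )
        summary = pd.DataFrame(
            columns=["label", "direction", "predictor", "median_wins",
                     "sd_wins", "median_fraction"]
        )
    return {
        "ormse": ormse_df,
        "wins": wins,
        "summary": summary,
        "skipped": skipped,
        "n_comparisons": len(comparisons),
    }


def _variance_summary(comparisons: list[concordance.ComparisonSet]) -> dict:
    """Median across comparisons of the per-comparison variances of the
    log10 AC50 and log10 dose vectors."""
    var_ac50 = [np.var(np.log10(c.ac50s), ddof=1) for c in comparisons]
    var_dose = [np.var(np.log10(c.doses), ddof=1) for c in comparisons]
    return {
        "median_var_log10_ac50": float(np.median(var_ac50)) if var_ac50 else float("nan"),
        "median_var_log10_dose": float(np.median(var_dose)) if var_dose else float("nan"),
    }


def run_endpoint_analysis(
    chemicals: list[ChemicalRecord],
    ac50_hits,
    endpoint_records,
    cfg: RunConfig,
    calculator: KappaCalculator | None = None,
) -> dict:
    """Fig-style endpoint-level workflow: one comparison per assay x
    in vivo endpoint with at least ``cfg.min_n`` unique chemicals."""
    hits = io_formats.filter_ac50(list(ac50_hits))
    comparisons = concordance.build_comparisons(
        hits, endpoint_records, min_n=cfg.min_n, level="endpoint"
    )
    kappa_table = KappaTable(chemicals, calculator)
    result = _evaluate_level(comparisons, kappa_table, cfg)
    result["variances"] = _variance_summary(comparisons)
    result["kappa_table"] = kappa_table
    return result


def run_pod_analysis(
    chemicals: list[ChemicalRecord],
    ac50_hits,
    pod_records,
    cfg: RunConfig,
    calculator: KappaCalculator | None = None,
) -> dict:
    """POD-level workflow: one comparison per assay endpoint against the
    per-chemical pooled LOEL/LOAEL minimum."""
    hits = io_formats.filter_ac50(list(ac50_hits))
    pods = io_formats.derive_pod(pod_records)
    lengths = io_formats.pod_study_lengths(pod_records)
    comparisons = concordance.build_comparisons(
        hits, pods, min_n=cfg.min_n, level="pod",
        pod_study_lengths=lengths,
    )
    kappa_table = KappaTable(chemicals, calculator)
    result = _evaluate_level(comparisons, kappa_table, cfg)
    result["variances"] = _variance_summary(comparisons)
    result["kappa_table"] = kappa_table
    return result


def run_pod10_comparison(
    chemicals: list[ChemicalRecord],
    ac50_hits,
    pod_records,
    cfg: RunConfig,
    calculator: KappaCalculator | None = None,
) -> dict:
    """Lower-quantile POD vs AED comparison with residual bias analysis.

    Per chemical, the lower 10th percentile of its pooled LOEL/LOAEL
    values is compared with the lower 10th percentile of the AEDs of its
    positive assay results, with kappa computed at the study length of
    the chemical's lowest POD record.
    """
    hits = io_formats.filter_ac50(list(ac50_hits))
    chem_map = {c.id: c for c in chemicals}
    lengths = io_formats.pod_study_lengths(pod_records)

    pods: dict = {}
    for r in pod_records:
        if (
            r.pod_type in ("LOEL", "LOAEL") and r.dose > 0
            and r.route == "oral"
            and r.study_type in io_formats.POD_STUDY_TYPES
            and r.dose_units == "mg/kg/day"
            and not np.isnan(r.duration)
        ):
            pods.setdefault(r.chemical_id, []).append(r.dose)

    kappa_table = KappaTable(chemicals, calculator)
    pod10_rows = []
    cor_rows = []
    for label in cfg.assumption_labels:
        aeds: dict = {}
        for h in hits:
            if h.chemical_id not in pods or h.chemical_id not in chem_map:
                continue
            length = lengths[h.chemical_id]
            kappa = kappa_table(h.chemical_id, length, label)
            aeds.setdefault(h.chemical_id, []).append(
                reverse_aed(h.ac50, kappa)
            )
        records, rmse, o = concordance.pod10_aed10(
            pods, aeds, q=cfg.quantile
        )
        conservatism = (
            float(np.mean([r.aed10 <= r.pod10 for r in records]))
            if records else float("nan")
        )
        for r in records:
            pod10_rows.append({
                "label": label,
                "chemical_id": r.chemical_id,
                "pod10": r.pod10,
                "aed10": r.aed10,
                "residual": r.residual,
            })
        pod10_rows_meta = {
            "label": label, "rmse": rmse, "ormse": o,
            "conservatism": conservatism, "n_chemicals": len(records),
        }
        cor_rows.append(pod10_rows_meta | {"kind": "summary"})
        for cr in concordance.residual_param_correlations(records, chem_map):
            cor_rows.append({
                "label": label, "kind": "correlation",
                "parameter": cr.parameter, "abs_cor": cr.abs_cor, "n": cr.n,
            })
    pairs = pd.DataFrame(pod10_rows)
    cor_df = pd.DataFrame([r for r in cor_rows if r["kind"] == "correlation"])
    summary = pd.DataFrame([r for r in cor_rows if r["kind"] == "summary"])
    if not summary.empty:
        summary = summary.drop(columns=["kind"])
    if not cor_df.empty:
        cor_df = cor_df.drop(columns=["kind"])
    return {
        "pairs": pairs,
        "summary": summary,
        "correlations": cor_df,
        "kappa_table": kappa_table,
    }
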