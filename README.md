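# ivive

Toolkit for evaluating in vitro–in vivo extrapolation (IVIVE) assumptions
with a rat physiologically based toxicokinetic (PBTK) model and a
concordance analysis of in vitro potency versus in vivo dose data.

The pipeline:

1. reads (or synthesizes) four tables — chemical TK/physchem parameters,
   an in vitro AC50 activity table, endpoint-level in vivo doses, and
   POD-level (LOEL/LOAEL) records;
2. computes per-chemical dose-to-concentration ratios **κ** (µM per
   mg/kg/day at a 1 mg/kg/day once-daily regimen) from a compartmental rat
   PBTK model under configurable assumption sets — restrictive vs
   nonrestrictive hepatic clearance, choice of concentration metric
   (mean/max; total/free venous plasma; tissue), and an optional in vitro
   assay-well disposition model that converts nominal to free aqueous
   concentration;
3. applies forward (`C = dose·κ`) and reverse (`AED = AC50/κ`) dosimetry
   and scores every assay-endpoint × in-vivo-endpoint comparison by the
   orthogonal RMSE of standardized log10 values, against an untransformed
   comparison and ten resampled-chemical randomizations;
4. tallies which predictor wins each contest, summarizes win counts and
   fractions per assumption set, and runs a per-chemical lower-decile
   POD₁₀ vs AED₁₀ comparison with residual-vs-parameter bias analysis.

## CLI

```bash
# generate a coupled synthetic dataset (4 CSVs)
ivive simulate-data --seed 1 --n-chemicals 100 --out data/

# κ table for a grid of assumption sets
ivive compute-kappa --data data/ --out results/kappa.csv

# endpoint-level and POD-level win-count analyses
ivive run-endpoint --data data/ --seed 1 --out results/
ivive run-pod      --data data/ --seed 1 --out results/

# lower-decile POD vs AED comparison + residual correlations
ivive pod10 --data data/ --seed 1 --out results/

# print win-fraction summaries found in a results directory
ivive report --results results/
```

Assumption sets are named by a compact label grammar, e.g.
`res.-free-vein-mean-Armitage` = restrictive clearance, mean free venous
plasma concentration, in vitro disposition model on. `--label` may be
repeated to select a subset; the default grid covers
{res., nres.} × {tot.-vein, free-vein, tis.} × {mean, max} plus the
Armitage variants of the mean venous metrics.

## Input schemas (CSV)

| table | required columns |
|---|---|
| `chemicals.csv` | `chemical_id,name,mw,logp,pka_donor,pka_acceptor,fup,fup_below_lod,clint_1,clint_10,logwsol,loghenry` |
| `ac50.csv` | `chemical_id,assay_endpoint,ac50,hit_call,flags` |
| `endpoint_doses.csv` | `chemical_id,study_id,study_type,effect_category,effect_type,effect_target,dose,study_length` |
| `pod.csv` | `chemical_id,pod_type,dose,dose_units,study_type,route,duration_days` |

pKa lists and curve flags are semicolon-separated. Common alternative
spellings from public exports (`casrn`, `funbound_plasma`, `clint_1um`,
`hitc`, `toxval_numeric`, …) are accepted via an alias map. Readers apply
the documented inclusion rules: fup below the limit of detection defaults
to 0.005; clearance measured at 1 µM is preferred over 10 µM; positive
hit calls with any curve-fitting flag are discarded; endpoint doses are
per-(study, chemical, endpoint) minima excluding multigenerational
studies; PODs are per-chemical minima over pooled LOEL/LOAEL values from
oral subacute/subchronic/chronic studies with usable units and duration.

## Configuration

Model constants ship as editable YAML under `src/ivive/data/`:
`physiology.yaml` (rat flows, volumes, GFR, hepatocellularity, absorption
rate, fu_hep correction switch), `tissue_composition.yaml` (partition
scheme fractions) and `wells.yaml` (assay well geometry by plate format,
serum/cell composition, phase-affinity QSPRs).
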