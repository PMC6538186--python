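# In vitro assay well geometry by plate footprint (vendor catalog class
# values) and default serum/cell composition for the disposition model.
well_formats:
  96:
    media_volume: 200.0      # uL
    well_area: 34.0          # mm^2 (growth area)
    headspace_volume: 170.0  # uL
  384:
    media_volume: 50.0
    well_area: 8.4
    headspace_volume: 62.0
  1536:
    media_volume: 8.0
    well_area: 2.3
    headspace_volume: 4.0

defaults:
  well_format: 384
  cell_count: 8000.0           # cells per well
  cell_volume_per_cell: 2.5e-6 # uL per cell
  fbs_fraction: 0.10           # volume fraction serum in media
  serum_lipid_frac: 0.0021     # volume fraction of serum
  serum_protein_frac: 0.060    # volume fraction of serum
  cell_storage_lipid_frac: 0.015
  cell_membrane_lipid_frac: 0.025
  cell_protein_frac: 0.20
  cell_water_frac: 0.70

# Phase-affinity QSPRs (log10 scale, functions of logP unless noted):
qspr:
  membrane_slope: 0.304        # log Kmw = slope*logP + intercept
  membrane_intercept: 1.294
  protein_slope: 0.71          # albumin-type binding: log Kp = slope*logP + intercept
  protein_intercept: 0.42
  plastic_slope: 0.97          # log Kplastic(m) = slope*logP + intercept
  plastic_intercept: -6.94
  ions_partition: false        # only the neutral fraction leaves the aqueous phase
temperature_k: 310.0
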