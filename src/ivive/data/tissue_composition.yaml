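# Tissue composition fractions used by the default partition-coefficient
# scheme (volume fractions of total tissue).
plasma_protein_frac: 0.074
tissues:
  gut:
    water: 0.72
    neutral_lipid: 0.049
    phospholipid: 0.017
    protein: 0.16
  liver:
    water: 0.72
    neutral_lipid: 0.035
    phospholipid: 0.025
    protein: 0.20
  kidney:
    water: 0.78
    neutral_lipid: 0.012
    phospholipid: 0.024
    protein: 0.17
  lung:
    water: 0.79
    neutral_lipid: 0.022
    phospholipid: 0.013
    protein: 0.16
  rest:
    water: 0.65
    neutral_lipid: 0.120
    phospholipid: 0.010
    protein: 0.18
# phospholipid affinity: log Kpl = pl_slope * logP + pl_intercept
pl_slope: 0.80
pl_intercept: 0.0
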