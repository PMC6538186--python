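# Default rat physiology (per-kg-body-weight basis unless noted).
# Values are editable configuration, representative of a ~0.25 kg rat.
body_weight: 0.25          # kg
tissue_volumes:            # L per kg body weight
  gut: 0.027
  liver: 0.034
  kidney: 0.007
  lung: 0.005
  rest: 0.770
plasma_volume: 0.0312      # L/kg, split arterial/venous below
arterial_fraction: 0.333   # fraction of plasma volume that is arterial
plasma_flows:              # L plasma / h / kg body weight
  cardiac: 7.50
  gut: 1.50
  liver: 0.55              # hepatic arterial supply only; portal flow enters via gut
  kidney: 1.40
  rest: 4.05
gfr: 0.312                 # glomerular filtration rate, L/h/kg
hepatocellularity: 110.0   # 1e6 cells per g liver
liver_mass_frac: 34.0      # g liver per kg body weight
k_gutabs: 2.0              # oral absorption rate, 1/h

# Unbound fraction in the hepatocyte clearance assay: logP-dependent
# correction (disable by setting fu_hep_enabled: false).
fu_hep_enabled: true
fu_hep_vr: 0.005           # hepatocyte volume ratio in the incubation
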