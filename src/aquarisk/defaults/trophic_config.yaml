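# Default eutrophication-index configuration.
#
# NON-AUTHORITATIVE: the "extremely poor" reference concentrations c0 and
# all grade boundaries except the 39.42 mesotrophic/eutrophic boundary are
# editable conventions.  x_j = x_max * C/c0 (harm) or x_max * c0/C (DO,
# benefit), clamped to [1, x_max]; a reading at c0 maps to x_max.
x_max: 100.0

references:
  DO: {c0: 1.5, orientation: benefit}
  TP: {c0: 0.10, orientation: harm}
  TN: {c0: 3.2, orientation: harm}
  COD_Mn: {c0: 16.0, orientation: harm}
  BOD_5: {c0: 11.0, orientation: harm}
  NH3_N: {c0: 1.6, orientation: harm}
  NO3_N: {c0: 5.5, orientation: harm}

# Equal weights (1/7) are used when weights is null.
weights: null

# Strictly increasing EI grade boundaries; an EI exactly on a boundary goes
# to the higher (more eutrophic) grade.  Only 39.42 (grade 2 -> 3) is an
# established anchor.
thresholds: [21.71, 39.42, 54.53, 68.26, 80.0]
grades:
  - oligotrophic
  - mesotrophic
  - light_eutrophic
  - middle_eutrophic
  - heavy_eutrophic
  - hyper_eutrophic
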