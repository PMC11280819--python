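# Default WQI configuration.
#
# NON-AUTHORITATIVE: the normalization score tables below are editable
# conventions assembled from common surface-water WQI practice (piecewise
# linear between [concentration, score] nodes), not measured constants.
# Units: mg/L except pH (unitless).
k: 1.0

# Integer weights P_i in 1..4; the nutrient parameters TP and TN carry the
# maximum weight 4.
weights:
  pH: 1
  DO: 4
  COD_Mn: 3
  BOD_5: 3
  NH3_N: 3
  TP: 4
  TN: 4
  NO3_N: 2

# [breakpoint, score] nodes; strictly increasing breakpoints, scores 0-100.
# Scores fall with concentration for pollutants, rise for DO, peak for pH.
curves:
  pH:
    - [2.0, 0]
    - [4.0, 25]
    - [6.0, 80]
    - [6.5, 90]
    - [7.0, 100]
    - [7.5, 100]
    - [8.5, 90]
    - [9.0, 80]
    - [11.0, 25]
    - [12.0, 0]
  DO:
    - [0.0, 0]
    - [3.0, 30]
    - [5.0, 60]
    - [6.0, 70]
    - [7.0, 80]
    - [8.0, 90]
    - [10.0, 100]
  COD_Mn:
    - [1.0, 100]
    - [2.0, 90]
    - [4.0, 80]
    - [6.0, 70]
    - [10.0, 50]
    - [15.0, 25]
    - [20.0, 0]
  BOD_5:
    - [1.0, 100]
    - [2.0, 90]
    - [4.0, 80]
    - [6.0, 70]
    - [10.0, 50]
    - [15.0, 25]
    - [20.0, 0]
  NH3_N:
    - [0.05, 100]
    - [0.15, 90]
    - [0.5, 80]
    - [1.0, 70]
    - [1.5, 50]
    - [2.0, 25]
    - [3.0, 0]
  TP:
    - [0.005, 100]
    - [0.02, 90]
    - [0.05, 80]
    - [0.1, 70]
    - [0.2, 50]
    - [0.3, 25]
    - [0.5, 0]
  TN:
    - [0.2, 100]
    - [0.5, 90]
    - [1.0, 75]
    - [1.5, 60]
    - [2.0, 40]
    - [3.0, 0]
  NO3_N:
    - [0.5, 100]
    - [2.0, 90]
    - [5.0, 80]
    - [10.0, 70]
    - [20.0, 50]
    - [50.0, 25]
    - [100.0, 0]

# Class labels with lower WQI bounds, descending; a WQI exactly on a bound
# belongs to the better class.
scheme:
  - [excellent, 90]
  - [good, 70]
  - [medium, 50]
  - [poor, 25]
  - [very_poor, 0]

# Class III surface-water limits (GB 3838-2002 style); kind: max = upper
# limit, min = lower limit (DO), range = two-sided (pH).
class3_limits:
  pH: {kind: range, low: 6.0, high: 9.0}
  DO: {kind: min, value: 5.0}
  COD_Mn: {kind: max, value: 6.0}
  BOD_5: {kind: max, value: 4.0}
  NH3_N: {kind: max, value: 1.0}
  TP: {kind: max, value: 0.05}
  TN: {kind: max, value: 1.0}
  NO3_N: {kind: max, value: 10.0}
  As: {kind: max, value: 0.05}
  Hg: {kind: max, value: 0.0001}
  Cd: {kind: max, value: 0.005}
  Cr6: {kind: max, value: 0.05}
  Pb: {kind: max, value: 0.05}
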