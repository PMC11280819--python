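# aquarisk

Analysis toolkit for surface **drinking-water sources**: water-quality
indexing, eutrophication scoring, probabilistic heavy-metal health-risk
assessment, and geodetector-based source apportionment — built for
monitoring campaigns of the kind run on reservoir and river intakes
(tens of sites, sampled in wet, dry and normal seasons, with
concentrations of pH, DO, COD_Mn, BOD_5, NH3-N, TP, TN, NO3-N and the
trace metals As, Hg, Cd, Cr6+, Pb, plus per-site environmental
covariates).

It is aimed at environmental scientists and water-resource managers who
need the full chain — from raw site/season concentration tables to "which
factors explain the spatial pattern of each metal" — as reproducible,
configurable, tested code. Because agency monitoring data are usually not
redistributable, the package includes a first-class synthetic-data
generator that emulates such a campaign with *known* ground truth
(planted stratum effects whose geodetector q-value is computed
analytically), so every downstream stage can be validated end to end.

## Methods at a glance

**Water-quality index.** For parameters *i* with normalized 0–100 scores
*C_i* and integer weights *P_i* ∈ 1..4,

    WQI = k · Σ C_i·P_i / Σ P_i,        k ∈ {1.00, 0.75, 0.50, 0.25}

with piecewise-linear score tables and a configurable class scheme
(boundary values go to the better class). Exceedance rates, means, SDs
and coefficients of variation are reported against Class III
surface-water limits.

**Eutrophication index.** Each indicator concentration *C_j* is scaled to
x_j ∈ [1, x_max] relative to an "extremely poor" reference C_j0
(inverted for DO), scored with the logarithmic power-function universal
formula

    EI_j = 10.77 · (ln x_j)^1.1826,     EI = Σ W_j · EI_j  (equal W_j = 1/n),

and graded; the mesotrophic/eutrophic boundary sits at EI = 39.42.

**Health risk.** Oral-ingestion dose ADD = C·IR·EF·ED/(BW·AT), with
carcinogenic risk CR = ADD·SF and hazard quotient HQ = ADD/RfD, evaluated
deterministically or by Monte Carlo (10,000 draws by default) for adults
and children, with exceedance fractions P(CR > 10⁻⁶), P(CR > 10⁻⁴),
P(HQ > 1) and cumulative-frequency curves. Hg carries no slope factor
(not treated as an oral carcinogen).

**Geodetector.** For a response y stratified by a factor into strata h,

    q = 1 − Σ_h N_h·σ_h² / (N·σ²)   (population variances, so q = SSB/SST)

measures the factor's explanatory power; continuous covariates are
discretized (exact Jenks natural breaks by default). The interaction
detector compares q(X1∩X2) with q(X1), q(X2) and labels each pair
(nonlinear/bivariable enhancement, independence, weakening).

**Association.** Spearman correlation matrix among metals and a
two-component PCA of the correlation matrix with varimax rotation, for
source grouping.

## Worked example

Run the full pipeline on a simulated 59-site campaign:

```bash
aquarisk run --seed 1 --outdir out --n-iter 10000
```

This writes `sites.csv`, `covariates.csv`, `measurements.csv`, per-stage
outputs (`wqi_results.csv`, `exceedance.csv`, `ei_results.csv`,
`ei_correlations.csv`, `risk_summary.csv`, `cumulative_frequency.csv`,
`q_factors.csv`, `q_interactions.csv`, `correlations.csv`,
`pca_loadings.csv`) and a `report.json` with the headline numbers. With
seed 1 the report contains, among others:

- overall EI **36.21**, with 81.4% of sites mesotrophic and 18.6%
  light-eutrophic — the network sits just under the 39.42 eutrophication
  boundary;
- mean WQI **90.8** (119 site/season records "excellent", 58 "good");
  TN exceeds its Class III limit in 4.0% of records and TP in 0.6%,
  the other parameters comply;
- carcinogenic risk ranking **As > Cr6 > Cd > Pb** by mean CR, with
  P(CR > 10⁻⁶) = 0.999 for Cr6+ in adults but no metal crossing 10⁻⁴ —
  a "potential risk" band typical of trace-level contamination;
- for Cr6+, **Soil_Type** attains the top factor q (0.83) — exactly the
  stratum effect the generator planted — and the strongest interactions
  combine a natural and a second factor, e.g. q(DEM ∩ Soil_Type) = 0.80
  for As;
- the two rotated components explain **86.1%** of the metals' correlation
  structure (As/Cr6 soil-driven vs Cd/Pb/Hg land-use-driven grouping).

Every stage can also be run separately (`aquarisk simulate | wqi | ei |
hra | geodetect | associate`) on your own CSV tables, with editable YAML
configs; the defaults under `src/aquarisk/defaults/` document every
assumed constant.

From Python:

```python
from aquarisk.geodetector import q_statistic, interact
q_statistic([1, 2, 3, 4], ["A", "A", "B", "B"]).q   # 0.8
interact([1, 2, 3, 4], ["A", "A", "B", "B"], ["A", "B", "A", "B"]).category
# 'independent'  (q12 = 1.0 = q1 + q2)
```

## Layout

```
src/aquarisk/
  synthetic_data.py   site/covariate/measurement generator, expected_q
  wq_index.py         WQI, classification, exceedance summaries
  trophic_state.py    EI formula, grading, EI-parameter correlations
  exposure_risk.py    ADD/CR/HQ, distributions, Monte Carlo engine
  geodetector.py      q-statistic, discretization, interaction detector
  association.py      Spearman matrix, varimax-rotated PCA
  pipeline.py         stage orchestration, validation, report.json
  cli.py              click command group
  defaults/*.yaml     editable default configurations
docs/methods.md       model assumptions, parameter choices, limitations
```
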