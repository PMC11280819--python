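# Methods

This note records the models implemented, the assumptions and defaults
behind them, and what the synthetic-data tests do and do not demonstrate
about real monitoring data.

## Water-quality index

The index is a weighted mean of normalized parameter scores scaled by a
subjective constant, WQI = k·ΣC_iP_i/ΣP_i over pH, DO, COD_Mn, BOD_5,
NH3-N, TP, TN and NO3-N. The substantive content is entirely in the
normalization tables and weights:

- **Score tables** (`defaults/wqi_config.yaml`) are piecewise-linear
  [concentration, score] node lists, clamped to the terminal scores
  outside the tabulated range. They are *non-authoritative conventions*:
  different agencies publish different tables, so they ship as editable
  YAML rather than constants in code. Scores fall with concentration for
  pollutants, rise for DO, and peak near neutral for pH.
- **Weights** are integers 1–4; the nutrients TP and TN carry the
  maximum weight 4 (they are the binding pollutants in nutrient-rich
  source areas), DO 4, organics 3, NO3-N 2, pH 1.
- **k defaults to 1.00** (no prior judgement of significant pollution);
  it only rescales the index, and classification thresholds assume k = 1.
- Class boundaries (90/70/50/25) are likewise conventions; a WQI exactly
  on a boundary goes to the *better* class. This tie rule is arbitrary
  but must be fixed for reproducible class counts.

## Eutrophication index

Single-indicator scores use the logarithmic power-function universal
formula EI_j = 10.77·(ln x_j)^1.1826, defined for x_j ≥ 1, composited
with equal weights over DO, TP, TN, COD_Mn, BOD_5, NH3-N and NO3-N.

The normalization to x_j is a ratio-to-reference transform: x_j =
x_max·C_j/C_j0 for harm-oriented indicators and x_max·C_j0/C_j for DO,
clamped to [1, x_max]. C_j0 is the "extremely poor" anchor (a reading at
C_j0 maps to x_max, hence to the maximum single-indicator score). The
reference table and x_max = 100 are editable defaults marked
non-authoritative; the only anchored grade boundary is 39.42 between
mesotrophic (grade 2) and eutrophic (grade 3). An EI exactly on a
boundary is assigned the *higher* (more eutrophic) grade — conservative
for a screening tool. Other boundaries (21.71, 54.53, 68.26, 80) and
labels are configurable.

Per-site EI aggregates the three seasonal records by the arithmetic mean
of indicator concentrations before scoring. Averaging concentrations
(rather than averaging per-season EIs) was chosen because the EI is
nonlinear and the season means are the better estimate of the site's
typical state; with mild seasonality the two differ little.

## Health-risk model

Oral ingestion only; dermal and inhalation routes are out of scope. The
dose is ADD = C·IR·EF·ED/(BW·AT) in mg/(kg·d); CR = ADD·SF and
HQ = ADD/RfD. Banding: CR < 10⁻⁶ low, 10⁻⁶–10⁻⁴ potential, > 10⁻⁴ high;
HQ ≤ 1 acceptable.

Parameter choices (`defaults/exposure.yaml`, `defaults/toxicity.yaml`,
all editable, all non-authoritative):

- **AT is derived by default**: ED·365 d for noncarcinogenic doses and a
  70-year lifetime for carcinogenic ones (the standard convention that
  makes HQ independent of ED while CR accumulates with it). A sampled AT
  distribution may be supplied instead (`at_mode: spec`).
- **Adults**: IR lognormal around 2 L/d, ED 30 a, BW normal 60.6 kg;
  **children**: IR around 1 L/d, ED 6 a, BW 22.9 kg; EF 365 d/a. These
  follow standard oral-ingestion exposure-factor tables for East-Asian
  populations.
- **Toxicity**: oral SFs for As (1.5), Cd (6.1), Cr6+ (0.5), Pb (0.0085)
  in (mg/(kg·d))⁻¹; RfDs 3e-4 (As, Hg), 5e-4 (Cd), 3e-3 (Cr6+), 1.4e-3
  (Pb) mg/(kg·d). Hg has no oral slope factor, so no CR is computed for
  it — rankings therefore cover four metals for CR and five for HQ.

**Monte Carlo.** Concentrations are fitted per metal (maximum-likelihood
lognormal by default; a constant series collapses to a point mass) and
all inputs are drawn independently — no correlation structure is
imposed, which tends to overstate tail spread slightly if IR and BW are
in fact correlated. 10,000 iterations give a binomial standard error
below 0.005 on any exceedance fraction. Random substreams are keyed by
the *content* of each (metal, concentration, exposure) specification, so
identical specifications reproduce identical draws and swapping the
adult/child specifications swaps the results exactly; everything is
reproducible from a single seed. Degenerate (all point-mass)
specifications reproduce the deterministic formulas exactly, with the
standard error reported as exactly zero.

## Geodetector

q = 1 − ΣN_hσ_h²/(Nσ²) with **population** (divide-by-count) variances,
which makes q identically the between-strata share of the total sum of
squares. Consequences worth stating:

- q ∈ [0, 1] whenever the total variance is positive; zero total
  variance raises an explicit "undefined q" error.
- The intersection of two stratifications refines both, so
  q(X1∩X2) ≥ max(q1, q2) up to round-off. The five interaction labels
  are all implemented (including both weakening categories, reachable
  only through the classification tolerance, default 1e-9), with
  independence checked first: |q12 − (q1+q2)| ≤ tol.
- Singleton strata are legal (σ_h² = 0) but counted and surfaced as a
  data-quality signal, since they mechanically inflate q.

Continuous covariates are discretized before detection. The default is
**exact Jenks natural breaks with 5 classes** — solved by dynamic
programming over the sorted values, not a heuristic — because that is
the dominant convention in geodetector applications; quantile,
equal-interval and geometric binning are available, and the method/class
count are explicit config (the choice is an assumption, not an
established value, and materially affects q for continuous factors).
The screening response is the per-site mean over seasons for each metal
plus TN and TP.

No significance test for q is provided (out of scope).

## Association stage

Spearman rank correlations (average ranks on ties; constant columns
yield missing entries) are used for consistency with the EI correlation
analysis and robustness to skewed metal distributions. The PCA acts on
the correlation matrix of standardized variables; "orthogonal rotation"
is implemented as varimax (delegated to statsmodels' factor-rotation
routines). Explained variance is recomputed from the rotated loadings;
the rotation redistributes but preserves the retained subspace's total
variance (checked to 1e-8). Sign convention: each component's
largest-magnitude loading is positive.

## Synthetic-data generator

The generator emulates the study conditions the pipeline targets — 59
sites uniformly scattered over a planar lon/lat rectangle, three seasons
(wet/dry/normal) per site, nine covariates — and its defaults *are* the
test conditions; they are not tuned per run.

- **Covariates**: continuous factors are linear lat/lon gradients plus
  Gaussian noise (southern mountains: high DEM/NDVI/Precipitation;
  northern plains: high road density, GDP, population density);
  categorical factors (Soil Type, Land Use) bin a latent spatial field
  by quantiles so every label is represented.
- **Concentrations**: lognormal noise by default (guaranteeing
  positivity, the convention in exposure modelling); the normal option
  redraws and finally clips the rare non-positive values. Nutrient and
  organic parameters share a per-site standard-normal "pollution" factor
  (half tied to latitude) through per-parameter loadings — this produces
  persistent between-site differences, an EI spread straddling the
  39.42 boundary, and the expected correlation signs (EI positive with
  TN/COD/BOD/NH3-N, negative with DO). Defaults put TN exceedance of
  its Class III limit at a few percent and TP below one percent.
- **Planted effects**: a metal's central value is stratified by a
  categorical covariate (`EffectSpec`), with soil-type effects on
  Cr6+/As and land-use effects on Cd/Pb/Hg; the spreads give Cr6+ and
  Pb coefficients of variation near or above 90%. Planted effects
  bypass the shared site factor so their within-stratum variance is
  exactly the specified noise.
- **expected_q** evaluates the q implied by an effect analytically from
  first and second moments (lognormal moments in closed form), with an
  `n_replicates` argument for the k-fold within-variance reduction when
  k independent seasonal draws are averaged. This is the ground truth
  against which recovery is tested: on 200-site campaigns the detector
  recovers planted q ∈ {0.2, 0.5, 0.8} within ±0.05 in ≥95 of 100
  seeds when reading all 600 records. Note the sampling standard
  deviation of the q estimator has a design-independent floor of about
  2(1−q)√(q(1−q)/N) — at q = 0.2 and N = 600 that is ≈ 0.026, so the
  ±0.05 band is an ~1.9σ interval and the low-q leg of this guarantee
  is intrinsically near its feasibility edge.

What passing these tests does *not* show about real data: the generator
draws seasons independently around a site mean (no hydrological
seasonality or storm events), imposes no spatial autocorrelation beyond
smooth gradients, uses exactly the configured noise families, and
contains no censored values (field data have detection limits). Planted
effects are cleanly categorical; real drivers are mixtures. Recovery of
q on generated data therefore validates the *estimator and plumbing*,
not the identifiability of sources in any particular real basin.

## Pipeline and numerics

One global seed fans out to fixed per-stage child seeds (a seed-sequence
split keyed by stage constants), so toggling a stage never perturbs
another stage's stream; `report.json` and all CSVs are byte-identical
across reruns with the same seed (timings are logged to stderr, never
written into outputs). On any stage failure the files written by the
failed run are removed before the error propagates. Machine outputs
carry full precision.

Problem sizes used by the shipped test-suite and demonstrations — 59 to
200 sites, 3 seasons, 10,000 Monte Carlo iterations, 100-seed recovery
replicates — match the study conditions the generator emulates and keep
any single check to seconds.

## Known limitations

- WQI/EI normalization tables, trophic references and all toxicity and
  exposure values are editable conventions, not authoritative constants;
  results shift with them, which is why they live in YAML.
- No geodetector significance testing, no kriging/mapping, no raster
  covariate extraction (covariates are consumed as per-site tables).
- The Monte Carlo engine assumes independent inputs.
- Coordinates are abstract planar degrees; no projection handling.
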