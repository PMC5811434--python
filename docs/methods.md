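# Methods

This note documents the models implemented in `cicereco`, the defaults and
numerical choices, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the underlying field
protocols leave the construction open.

## Color calibration and the crypsis test

**Camera model.** Each RGB channel's radiance response is modelled as a
power law, `reflectance = a · measured^b`, estimated by ordinary least
squares on log–log values of the six gray reflectance standards imaged in
the same session (reflectances 0.031–0.88, a standard six-step neutral
scale).  A power law is the standard choice for linearizing consumer
camera sensors against gray standards; an exponent of 1 recovers an
already-linear sensor, and a channel distorted by gamma γ is inverted with
b = 1/γ.  Per-channel R² of the log–log fit is reported; non-monotone
standards raise a warning rather than an error.  Equalization divides each
channel by its mean linearized value over the six standards — a choice of
reference that uses all standards rather than a single one for robustness —
after which all three channels report the same value on every gray
standard and the calibrated channels are denoted LW/MW/SW.  Raw channel
means at or above 245 of 255 are flagged as possible over-exposure.

**Distances.** Seed colors are replicate means per genotype (nominally 5),
soil colors are means over samples and aliquots per site (nominally 5 × 3).
Each genotype is compared to every site's soil by Euclidean distance in
the 3-D calibrated space; distances are square-root transformed before
modelling, which symmetrizes their right-skewed distribution.

**Mixed model.** The crypsis hypothesis — seeds match their *native*
site's soil better than foreign soils — is tested on the transformed
distances with a linear mixed model: fixed effects for the native/foreign
indicator and for the compared soil site, an optional species or
population factor with its interaction with the indicator, and a random
intercept per genotype (genotype labels are unique within population, so
this realizes genotype-nested-within-population).  The soil-site fixed
effect matters: every genotype is compared against the same soils, so each
soil's baseline distance level is a shared, repeated quantity.  Left in
the residual it inflates the error variance while cancelling out of the
balanced native/foreign contrast, and the test becomes badly conservative
(empirically, type-I error ~0.002 at nominal 0.05 under the null
generator).  With soil baselines absorbed the test holds its nominal level
(empirically 0.036–0.064 over 500-replicate batches).  `site_effects=False`
restores the bare model for comparison.

The model is fit by REML.  Because a single random intercept admits a
one-dimensional profile likelihood in λ = σ²_g/σ²_e, the fitter
(`cicereco.lmm`) optimizes the profiled REML criterion on log λ (bounded
scalar minimization, checked against the σ²_g = 0 boundary) and recovers
β and σ²_e by generalized least squares via the Woodbury identity.  The
native/foreign F statistic is the squared Wald ratio with Satterthwaite
denominator df, computed from numerical derivatives of the contrast
variance with respect to (σ²_g, σ²_e) and the observed information of the
restricted likelihood; at the boundary the df fall back to the OLS
residual df, and with σ²_g pinned to zero the whole test reduces exactly
to the fixed-effects ANOVA F (this reduction is a regression test).
statsmodels' MixedLM is used in the test suite as an independent REML
implementation to cross-check estimates; it is not used in the pipeline
because it does not provide Satterthwaite df.

## Dry-down physiology

Daily transpiration is bookkeeping: weight drop between successive
mornings plus water added in between, so the series sums exactly to total
weight loss plus total additions.  Day gaps are never bridged; negative
values (weighing error) are flagged but retained.  FTSW uses explicit
initial (field-capacity) and final weights when known; read from a CSV the
final weight defaults to the observed minimum, the operational endpoint of
the dry-down.  Out-of-range FTSW is flagged, never silently clamped.

**NTR normalization.**  The published protocols cite prior work without
printing formulas; the two-stage construction implemented here follows the
FTSW literature: (1) divide each water-stressed pot's daily transpiration
by the same-day mean of its genotype's well-watered controls (days with
zero control transpiration are excluded); (2) rescale each pot's ratio
series by its own mean ratio over wet days (FTSW > 0.8, configurable) so
NTR starts near 1.  The experiment's termination rule — stop when NTR
drops below 0.1 — is recorded per pot as the termination day.

**Plateau regression.**  NTR(F) = 1 for F ≥ X and 1 + s(F − X) for F < X,
with s > 0; X is located by a grid search over observed FTSW values (the
slope has a closed-form profile minimum at fixed X) and refined by bounded
scalar minimization between the neighboring grid points (xatol 1e-10;
noise-free curves are recovered to ~1e-11).  Points with NTR below the 0.1
termination threshold are excluded from the fit by default: past that
level the experiment would have been stopped, and a near-zero transpiration
tail otherwise drags the decline segment and biases X.  An unconstrained
plateau level is available by flag.  At noise SD 0.05 with 30 points the
breakpoint lands within ±0.05 of truth in ≳97% of curves.

**Inflection.**  A degree-4 polynomial is fit to the (F, NTR) points and
the real roots of its second derivative inside the observed range are the
candidates.  Where several exist, descending curvature crossings (third
derivative < 0 — the shoulder of the decline) are preferred, with
proximity to the plateau breakpoint as the tie-break; a pure
nearest-to-breakpoint rule flips between the shoulder root and a
plateau-side wiggle root near the top of the trait range and destroys the
monotone relationship between fitted inflection and planted breakpoint.
Note a structural property: on a piecewise-linear decline the polynomial
inflection sits below the breakpoint by roughly half the transition width,
so the two trait definitions coincide (within 0.08 FTSW) only when the
decline is steep; across the realistic trait range they are monotonely
related (Spearman ρ ≈ 0.88 under noise).  Both traits are reported because
either could underlie a published 0.41–0.60 trait range.  Degenerate
cases: a quadratic-shaped cloud has a constant second derivative and
raises a no-inflection error rather than returning an extrapolated root.

Trait–aridity association reports Pearson and Spearman coefficients of a
per-genotype trait against source-site aridity (precipitation / potential
evapotranspiration), with errors for constant inputs.

## VPD and residual transpiration

SVP uses the Tetens constants 610.7 Pa and 237.3 °C with the power-of-ten
form `610.7 · 10^(7.5T/(237.3+T))`.  A "literal" variant of the formula as
sometimes typeset (`610.7·107.5T/(237.3+T)`, dimensionally a linear
function of T) is available behind a flag for audit only — it is not a
vapor-pressure model.  TR normalizes grams transpired per interval by leaf
area and interval minutes; intervals other than 60 min are rescaled using
their actual length (the generator's seven weighings between 08:00 and
16:00 give six 80-min intervals).  Residual transpiration is the per-pot
residual of an OLS regression of total daytime transpiration on leaf area;
residuals sum to zero by construction, and a genotype transpiring more
than its canopy predicts (e.g. a weak feedback of VPD on stomata) shows a
positive residual.

## Thermal environment

Daily means require ≥4 of the nominal six 4-hourly readings, otherwise
the day is missing (no imputation).  Degree days accumulate
max(0, T̄ − T_base) per calendar month over a window whose default
semantics run 1 November–15 May (the wild species' growing season); the
base temperature defaults to 0 °C and is configurable, as the published
value is unstated.  An optional photoperiod multiplier (daylength/24 from
latitude and day-of-year by the standard solar-declination formula)
converts degree days into photo-thermal units; it is off by default
because the exact modification used with such loggers is not specified.
Among-site comparisons use one-way ANOVA on whole-window totals with
plant microsites (five per site in the emulated design) as replicates.
Humidity is passed through unmodified; vendor-protocol normalization is
out of scope.

## Soil chemistry and PCA

The 18-variable schema and the per-variable transforms are fixed lists:
natural log for Zn, Fe, Ca, Mn, Na, Mg, N, total C, inorganic C, S,
lime-CaCO₃, EC and K; exponential for pH; identity for Cu, organic C,
P₂O₅ and organic matter.  Non-positive values under a log become missing
with a warning; unknown variable names are schema errors.  The PCA
centers and unit-scales after transforms (correlation-matrix PCA;
covariance PCA by flag), mean-imputes missing values (count reported) and
is computed by SVD so p > n degrades gracefully.  Loadings are reported as
eigenvector × √eigenvalue (variable–component correlations, bounded by 1);
the display thresholds 1.0 and 1.5 circulate as presets for flagging
"high" loadings, though on this scale only sub-1 thresholds can trigger.

## Host suitability

HSI = (larval weight gain / damage rating) × survival per replicate, with
survival as the fraction of ten released neonates (integer counts are
converted).  Genotype summaries are per-replicate HSI means ± SD;
computing HSI from genotype means instead is possible by pre-aggregating,
but per-replicate is the default since it preserves replicate error.
Comparisons use the tie-corrected Kruskal–Wallis H (identical inputs give
H = 0, p = 1 by convention) and Dunn's z tests on joint mean ranks with
the standard tie-corrected variance and Bonferroni adjustment capped at 1.

## Population-genetic summaries

Diversity statistics use the classical estimators on biallelic dose
matrices: per-site π = c(n−c)/C(n,2) summed over a window, θ_W = S/a₁, and
Tajima's D with the e₁/e₂ variance constants; windows tile the reference
from position 1 in 100 bp steps (non-overlapping by default; the step is
configurable) and are emitted 0-based half-open.  Sites with missing calls
in the focal population are excluded so the haplotype count n is constant;
windows with S < 3 report D as missing.  Heterozygosity discards calls
with read depth < 4 before counting, guarding against false heterozygotes
at low coverage.

f3 and f4 are plain means over sites of (c−a)(c−b) and (p1−p2)(p3−p4) on
sample allele frequencies, with delete-one block-jackknife SEs over
consecutive 100-SNP blocks ((B−1)/B convention; a trailing partial block
merges into the last full one) and |Z| > 3 as the significance rule.  No
finite-sample bias correction is applied to f3 — the estimator is the
frequency-level definition — so E[f̂3] carries a positive Var(ĉ) term of
order c(1−c)/(2n_C).  Consequently a negative f3 is conservative evidence
of admixture, and detecting admixture requires drift large relative to
that term; the power simulations use binomial drift of 5 chromosomes
(F ≈ 0.2, well inside the Fst range of strongly structured wild
populations), under which 50/50 admixture is detected in ~100% of runs
while the unadmixed null stays non-negative in expectation.

## Synthetic-data generators

All generators draw from a single `numpy` Generator seeded per invocation,
emit byte-identical tables for a fixed (seed, config), and write their
planted parameters into a truth record.

- *Color study*: site soil colors scatter around a global mean reflectance
  (SD 0.08 per channel); genotype seed colors are the global mean pulled a
  fraction δ toward the native site's soil plus genotype noise (SD 0.03);
  replicates add SD 0.01; a per-channel gamma distortion (0.8, 1.0, 1.2)
  and the <245 exposure cap emulate the camera.  δ = 0 is the exact null.
  The power condition "effect = 1.5 × residual SD" corresponds to δ = 0.41
  under these defaults (calibrated once on a large pilot and frozen).
  The default design is 20 genotypes × 8 sites, 5 seed replicates, 5 soil
  samples × 3 aliquots.
- *Dry-down*: a soil water pool of 800 g below a 2000 g field-capacity
  weight; per-genotype two-segment NTR curves with breakpoints on a grid
  spanning 0.41–0.60 and slope 2.5; well-watered pots held within 200 g of
  field capacity; water stress imposed by partial compensation (losses
  above 50 g/day early, 70 g/day late are watered back); termination at
  NTR < 0.1.  The truth record carries the true transpirable-water
  endpoint, so noise-free recovery of the planted breakpoint is exact;
  from CSV alone the operational final weight shifts the FTSW scale
  slightly, which is the same compression a real dry-down has.
- *VPD day*: seven weighings 08:00–16:00 under a diurnal temperature/RH
  course; transpiration proportional to leaf area × VPD with designated
  high-residual genotypes responding extra under above-median VPD.
- *Loggers*: 4-h sinusoidal seasonal + diurnal temperature with site
  offsets, five microsites per site, November–May.
- *Soils*: 18 variables on their measurement scales via lognormal site and
  sample effects; pH stays within (0, 14).
- *Bioassay*: five replicates per genotype; lognormal weight gain (CV
  0.15), damage ratings ~N(4.5, 0.8) clipped to 1–9, survival
  Binomial(10, 0.7) — a total within-genotype HSI CV of ~0.3, consistent
  with assays that resolve ~3.5× differences between susceptible and
  resistant checks; planted multiplicative HSI shifts are recorded in the
  truth.
- *Genotypes*: ancestral frequencies Uniform(0.05, 0.95); populations by
  binomial drift (default 50 chromosomes); scenarios for a two-clade tree
  (f4 null), independent drift (f3 null) and α-mixture admixture (f3
  alternative); diploid doses with Poisson(20) depths; VCF/popmap export.

What the generators do **not** emulate: linkage and recombination (sites
are independent, so the block jackknife is exercised but not stressed by
real LD), imaging segmentation artifacts, phenological structure in the
dry-down (every genotype starts at field capacity), spatial autocorrelation
among sites, and multi-session camera variation (single session by
default).  Passing tests therefore demonstrate correctness of the
estimators and calibration of the tests under these idealized conditions,
not robustness to every field artifact.

## Problem sizes and runtime

The replicated studies use 500 null and 200 power replicates for the
crypsis test (20 genotypes × 8 sites each), 200 curves for breakpoint
recovery, 400/200 runs for the f4 null and f3 power rates (5,000 SNPs,
50 jackknife blocks, 10 diploids per population), and 200 bioassay runs —
sizes chosen so the whole suite and the acceptance script each finish in a
few minutes on one CPU while keeping Monte-Carlo error well below the
decision margins.

## Known limitations

- Satterthwaite df are exact only for single-df contrasts; multi-df Wald
  tests fall back to residual-style df.
- Tajima's D uses complete-case sites within the focal population rather
  than a per-site adjusted n.
- The f3/f4 implementation targets allele-frequency tables and VCFs of
  moderate size (in-memory, dense); it is not an out-of-core scan.
- The plateau model assumes the normalized plateau is 1; genotypes whose
  WW controls are themselves stressed would violate stage-2 normalization.
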