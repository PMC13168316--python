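# Methods

This note documents the models, estimators, numerical choices and
limitations of `glycofeed`. Everything stated here is computed by the code;
the test suite and `scripts/acceptance.py` exercise each claim.

## Cell-specific rate estimation

Daily pre-feed measurements of one fed-batch replicate are the unit of
analysis. With VCD in 10⁶ cells·mL⁻¹, titer in mg·L⁻¹ and lactate in mM,
the unit conversions (1 mg·L⁻¹ = 10⁶ pg·mL⁻¹, 1 mM = 10⁶ pmol·mL⁻¹) cancel
against the 10⁶ factor in VCD, so plain ratios are already in pg·cell⁻¹·d⁻¹
and pmol·cell⁻¹·d⁻¹.

- μ is computed per interval as Δln(VCD)/Δt; intervals with non-positive
  VCD are flagged missing (NaN) rather than raised, since a culture collapse
  is data, not an error.
- IVCD uses the trapezoid rule, which is exact for VCD affine in time
  (asserted to 1e-12 relative in the tests).
- q_P is evaluated on 24-h intervals and q_LAC on 48-h intervals; when a
  sampling day is missing the interval widens to the nearest available days
  and is flagged. A process-average q_P divides the titer change over days
  3–11 by the IVCD accumulated in that window. Negative interval q_P values
  are retained: feed additions dilute the titer, and no dilution correction
  is applied to measured concentrations.
- q_GLC is minus the slope of an OLS fit of glucose concentration on
  cumulative IVCD within each feeding window (consumption positive).
  Windows are half-open [feed_k, feed_{k+1}): the sample taken on a feed day
  is pre-feed and closes the *previous* window, so every window mixes only
  post-feed decline points. Windows with fewer than two interior samples are
  skipped with a warning. Fits are per replicate; strategy-level summaries
  aggregate afterwards.
- All rate operations are invariant to shifting the time axis by a constant.

## Glycoform nomenclature and indices

A species is an unordered pair of Fc N-glycans; tokens are G0/G1/G2 with an
optional trailing F (core fucose) and `none` for an unoccupied site. The
canonical arm order sorts by (present, galactose count, fucosylation, token
text), so `G1F ⋅ G0F` and `G0F ⋅ G1F` are one species rendered
`G0F ⋅ G1F`. A present bi-antennary glycan contributes two galactosylation
sites; an absent arm contributes none — sites cannot exist without a glycan,
so `G0F ⋅ none` has d = 2, not 4.

Fractional abundances are normalized to sum to 100 % per sample; relative
ratios are preserved, all-zero samples are errors, and rows already near
100 % that deviate by more than 0.5 percentage points are renormalized with
a logged warning. The galactosylation index is the abundance-weighted
fraction of occupied galactosylation sites; the glycation index is the
abundance-weighted occupancy of a fixed maximum of three glycation sites on
the deglycosylated antibody. Both are percentages in [0, 100], and both are
ratios of abundance-weighted sums, hence mixture-linear in the numerator and
denominator (property-tested).

### Hexosylation-bias correction

At the intact level a glycation hexose and a galactose both add 162 Da, so
the annotated galactosylation ladder of each fucosylation backbone is the
true ladder convolved with the glycation hexose-count distribution
(measured independently on deglycosylated antibody), assuming the two are
independent. The correction inverts this per sample and backbone by
non-negative least squares on the convolution matrix; components driven
negative by noise are clipped at zero and rows renormalized to 100 %.
Species that are isobaric within a (backbone, galactose-count) class —
e.g. `G1F ⋅ G1F` and `G0F ⋅ G2F` — cannot be separated by intact mass, so
corrected class mass is redistributed proportionally to the pre-correction
ratios. This is a deliberately simple, documented deconvolution, not a
reimplementation of any published graph-based correction tool; its forward
model (also provided) makes it exactly invertible when no clipping occurs,
which the tests assert to 1e-8.

## Compositional statistics

Fractional abundances are compositional; all multivariate work happens
after the centered log-ratio transform clr(x) = ln(x / geometric mean),
which is scale-invariant and yields zero row sums. Zeros are an error under
the default `strict` policy — appropriate when every glycoform is detected
in every sample — with an explicit `replace(δ)` policy (δ = 0.01 % default)
for data that needs imputation.

- PCA is on the covariance of clr values (the standard choice for clr data,
  where all parts share a scale); component signs are fixed by making each
  component's largest-magnitude loading positive.
- Sample correlations are Spearman, computed across glycoforms so each
  entry compares two samples' glycan rankings; constant profiles are
  flagged NaN.
- PERMANOVA uses squared Euclidean distances, the Gower-centered inner
  product matrix, and sequential (Type-I) sums of squares via hat-matrix
  projections, with terms in the order given and interactions entered last.
  Pseudo-F uses the full-model residual. The null distribution comes from
  free permutation of samples; p-values use the add-one convention
  (minimum reportable p = 1/(n_perm+1)), and an exhaustive mode enumerates
  all orderings for small n (used by the oracle tests, which also verify
  that 1-D Euclidean PERMANOVA reproduces the classical one-way ANOVA F to
  1e-10 and that the one-term case matches scikit-bio's implementation).
  Residual SS below 1e-12 of the total is treated as exactly zero so
  perfectly separated configurations tie reproducibly instead of depending
  on float noise.
- The dispersion test measures each sample's Euclidean distance to its
  group *centroid* (not the spatial median some implementations default to;
  the centroid is consistent with the Euclidean PERMANOVA above) and
  permutes group labels of those distances under an F-like ratio.

## Differential abundance

Each glycoform's clr values are fitted with a cell-means OLS over the
(strategy × phase) cells (all glycoforms share the design, so one solve
covers the matrix; residual df = n − #cells, and cells need ≥ 2
replicates). Zero-sum contrasts of cell means give effects on the natural-
log-ratio scale, reported divided by ln 2 as log₂FC — a documented,
switchable convention. With moderation on (the default), residual variances
are shrunk toward a pooled scaled-inverse-χ² prior fitted by matching the
mean and variance of log s² to their theoretical values (the trigamma
inverse solved by Newton iteration), and the t reference distribution gains
the prior df. With moderation off, results equal the classical contrast
t-test exactly (asserted to 1e-10). BH adjustment is applied within one
comparison (one contrast across glycoforms), mirroring per-panel
presentation; stars are `***`/`**`/`*` below 0.001/0.01/0.05.

## Gated group comparisons

For scalar process quantities, Shapiro-Wilk on the pooled group-centered
residuals and Levene's test gate at α = 0.05: both pass → one-way ANOVA +
Tukey HSD; otherwise Kruskal-Wallis + Dunn's test with tie-corrected z
statistics and BH correction (switchable to Holm/Bonferroni). A
reference-group mode keeps only comparisons against a designated standard
strategy. The gated procedure's overall type-I error is checked by
simulation (500 null datasets, 4 groups × 4 replicates) to be 5 % within
three binomial standard errors.

## The synthetic study generator

The generator emulates a seven-strategy fed-batch screen in TubeSpin-scale
vessels (30 mL start volume) and is the package's source of ground truth:
every stochastic element is seeded, and the generating parameters are
attached to each course and table.

**Culture model.** A daily explicit update matches the daily sampling
granularity (no continuous ODE solver; sub-day events are not observable in
these data). Each day, in order: the pre-feed measurement is recorded
(optional multiplicative measurement noise, CV 3 % by default); the
scheduled feed applies volume dilution (5.0 % v/v for 48-h strategies,
2.5 % for daily ones) to cells, titer and metabolites, replenishes glucose
to the strategy target — withheld for pH-triggered strategies while
pH < 7.2 — and adds the Gal+ bolus (1.25 mM galactose) every other day from
day 3; then one day of dynamics is integrated. Growth is Monod-limited on
glucose with lactate and galactose as discounted secondary substrates,
capped logistically at 27 × 10⁶ cells·mL⁻¹. Carbon demand is
q_GLC · IVCD · V in glucose-equivalent mass; shortfalls are covered by
lactate (1 mmol ≈ 90 mg glucose-equivalent, C3 vs C6) up to an uptake cap,
then galactose. Growth only uses carbon beyond a maintenance fraction
(40 % of demand), which lets chronically limited cultures (the pH-triggered
strategies) settle at a sustainable density instead of overshooting; when
supply falls below 35 % of demand the culture starves and VCD and viability
decay first-order. Lactate is produced in overflow while glucose is
plentiful (above 2.5 g·L⁻¹, molar yield 0.4, stalling toward a 45 mM cap)
and consumed otherwise; pH is a phenomenological decreasing function of
lactate (7.5 − 0.0125·LAC, clipped), which closes the HIPDOG-like loop:
feed → lactate → pH drop → feeding withheld → lactate consumed → pH
recovery → feed. Titer accumulates as q_P times the daily IVCD. Glucose
mass is strictly book-kept (initial + fed = consumed + removed + residual
to 1e-9, a tested invariant).

Default rates (q_P = 15 pg·cell⁻¹·d⁻¹, q_GLC = 0.30 g·L⁻¹ per
10⁶ cells·d·mL⁻¹ ≈ 1.7 pmol·cell⁻¹·d⁻¹, μ_max = 0.55 d⁻¹) are typical CHO
fed-batch magnitudes chosen so the seven presets reproduce the screen's
qualitative fingerprint: every strategy grows alike through day ~7; the
4 g/L 48-h strategies exhaust glucose before day 9, drain their lactate
pool and collapse (viability < 30 % by day 10) while all others finish
above 90 %; the pH-triggered strategies stabilize at the lowest densities
and the 8 g/L strategies at the highest. Replicate counts are 4 for the
48-h strategies and 3 for the daily ones; biological variability enters as
a 5 % CV log-normal jitter on the per-replicate kinetic parameters.

**Glycoforms.** Compositions are logistic-normal over an eight-species
vocabulary around a typical IgG Fc baseline (G0F ⋅ G0F dominant). Ground-
truth clr shifts encode the screen's effects: +δ_gal on galactosylated
species under Gal+, +δ_fuc on fully fucosylated and −δ_afuc on
afucosylated species in the stationary phase, plus an extra Gal+ ×
stationary galactosylation term (δ_gal_sta = 0.4) so the factors genuinely
interact. Defaults δ_gal = δ_fuc = δ_afuc = 0.75 with clr noise σ = 0.25
put the primary effects at effect/noise = 3, a realistic signal strength
for n = 3–4 biological replicates. Samples are drawn at day 5 (exponential)
and day 10 (collapsing strategies) or 11 (stationary).

**Glycation.** The per-site hexosylation probability is a clipped linear
function (slope 0.004 per g·d·L⁻¹) of the titer-weighted time integral of
residual glucose up to the sampling day — early-secreted antibody
accumulates more exposure — and the 0–3 hexose distribution is binomial
with 3 sites. This reproduces the mechanism of interest (more residual
glucose ⇒ more glycation) monotonically, which the tests assert.

**What the generator does not emulate.** Mechanistic nucleotide-sugar
(UDP-Gal/GDP-Fuc) fluxes, amino-acid metabolism, osmolality and temperature
effects, technical-replicate measurement structure, and instrument-level
artifacts are all absent; manganese is folded into δ_gal rather than
modeled. Passing recovery and power tests on this generator therefore shows
the estimators are correct and adequately powered under a faithful effect
*structure* — not that real mass-spectrometric abundance tables meet the
logistic-normal noise model.

## Problem sizes and numerical settings

The default verification suite uses the study's native sizes (50 glycoform
samples, 25 culture replicates) with 999 permutations for reported
PERMANOVA tables; calibration and power simulations use 500 null datasets
(permutation count 199) and 100 seeds respectively, sizes at which binomial
error on the checked rates is a few percent. NNLS comes from scipy;
permutation engines are seeded `numpy.random.default_rng` throughout, and
identical seeds reproduce results bit-for-bit (tested). Floating-point
output files carry six significant digits.

## Known limitations

- The hexosylation correction assumes glycation is independent of the
  glycoform and identically distributed across backbones within a sample.
- Sequential (Type-I) PERMANOVA terms mean R² values depend on term order;
  the conventional order (phase, strategy, interaction) is the default.
- The dispersion test uses centroids; spatial-median implementations can
  give different p-values on skewed clouds.
- The simulator's daily explicit update cannot represent sub-day glucose
  depletion; depletion within a day appears as a clipped consumption mass.
- With only 3–4 replicates per cell, moderated variances depend on the
  pooled prior; single-glycoform analyses should disable moderation.
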