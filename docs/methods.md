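# Methods

This note documents the statistical models implemented by `allomass`,
the defaults and numerical choices, what the synthetic-data generators
do and do not emulate, and known limitations.

## Data model and units

A measurement table holds one row per species: live body mass, maximum
stylopodial (humerus/femur) lengths and minimum diaphyseal
circumferences, plus class (Mammalia / Reptilia / Lissamphibia), clade
and lifestyle labels.  Internal units are **grams and millimetres**;
the published predictive equations presuppose exactly these units (the
coefficients reproduce reference estimates only under g/mm), and mass
output is additionally reported in kg.  Missing measurements are NaN —
never zero — and every analysis uses the complete-case subset for its
own variable pair, so length-based and circumference-based analyses
legitimately have different sample sizes.  No imputation is performed.
Lissamphibian rows load and can be plotted but are excluded from all
fits by default; their empirical samples are too small and narrow for
meaningful line fitting.

All bivariate work is done on log10-transformed values.  Size data are
strongly right-skewed; the log transform approximates normality,
reduces heteroscedasticity, and turns power laws into straight lines.

## Standardized major axis fitting

For a log-log sample the SMA slope is m = sign(r)·s_y/s_x with the line
through the bivariate mean.  SMA treats x and y symmetrically, which is
appropriate when both variables carry comparable (biological plus
measurement) error and the target is the scaling exponent itself rather
than prediction.

The slope CI uses the F-based construction
B = F(1−α; 1, n−2)·(1−r²)/(n−2), CI = m·(√(B+1) ∓ √B).
This reproduces published interval bounds exactly from (m, n, R²)
triples, which doubles as a validation of the formula and as a way to
rebuild intervals from printed tables.

**Slope-value test.** H₀: m = b₀ is tested through the correlation
between residual scores (y − b₀x) and axis scores (y + b₀x), which is
zero iff b₀ equals the SMA slope; t = r√((n−2)/(1−r²)) on n−2 df,
two-tailed.  A numerically collinear sample makes the test degenerate:
b₀ equal to the exact slope returns p = 1, anything else is an error.

**Similarity models.** Theoretical scaling models predict fixed
exponents: geometric similarity — circumference ∝ length, mass ∝
length³, mass ∝ circumference³; elastic — length^1.5, length⁴,
circumference^(8/3); static — length², length⁵, circumference^(5/2).
Each registered exponent is tested at α = 0.05; the verdict lists all
non-rejected models ("G", "E, S", …), codes a slope strictly between
two adjacent exponents relative to both ("> G, < E"), uses "0" for
slopes outside the span of all models, and "−" for relations (such as
femur length vs humerus length) with no registered models.  The
elastic mass~circumference exponent is 8/3 — the reciprocal-looking
2/3 sometimes quoted is a slip, since observed slopes near 2.69 can
only be classified elastic under 8/3.

**Common-slope LRT.** For a candidate common slope b, each group's
profile log-likelihood reduces to (n_i/2)·ln(1 − r²_uv,i(b)), where
r_uv is the residual/axis-score correlation (the Jacobian and
determinant terms cancel; the group optimum is exactly the group's own
SMA slope).  The common slope maximizes the sum by bounded scalar
minimization over [½·min slope, 2·max slope] (relative xatol 1e-10),
and −2·ΔlogL is referred to χ² with g−1 df.  Monte-Carlo calibration at
n = 50 per group gives a null rejection rate of ≈ 0.055 at α = 0.05.

**Elevation (intercept) test.** Elevations b_i(x*) = m_i·x* + b_i are
compared by t = Δ/SE with the delta-method variance
SE² = Σ_i [s²_resid,i/n_i + (x̄_i − x*)²·Var(m_i)],
Var(m_i) = m_i²(1−r_i²)/(n_i−2), df = n₁+n₂−4.  The classical test sits
at x* = 0, but for size data that is an extrapolation to 1 mm; the
report therefore also evaluates at the minimum x of the pooled data,
where apparent intercept differences caused by extrapolation vanish.

**Multiple comparisons.** Within each variable-pair analysis the
comparison family comprises the ten clade pairs, Mammalia vs Reptilia,
and the three size-class splits (14 comparisons); Benjamini–Hochberg
FDR is applied within the family, separately for the LRT, intercept,
and shifted-intercept p-value columns.  The family composition is
configuration, not code.  Groups with n < 10 are excluded with a
warning.  BH ties are handled by stable step-up on sorted order.

## Phylogenetic correction

Species values are non-independent under shared ancestry.  Two
complementary corrections are implemented, both assuming Brownian
motion on a rooted bifurcating tree with branch lengths in Myr:

- **Independent contrasts** by Felsenstein pruning: contrast
  (x₁−x₂)/√(v₁+v₂) at each node, ancestral values by 1/v-weighted
  averaging, parent edges lengthened by v₁v₂/(v₁+v₂).  Adequate
  standardization requires |contrast| to be uncorrelated with its
  expected SD (Pearson, pass iff p ≥ 0.05); when raw branch lengths
  fail this, ln-transformed lengths are the standard remedy.  ln is
  undefined for edges ≤ 1 Myr (the transformed variance would be ≤ 0),
  so such edges are a hard error and ln(length+1) is offered as the
  documented fallback.  Polytomies are a hard error for contrasts; a
  zero-length auto-resolution is deliberately not offered because the
  ln transform could not accept the resulting edges.  A constant column
  in the standardization diagnostic leaves the correlation undefined;
  since that carries no evidence of a trend it is reported as
  correlation 0, pass, with a warning.
- **Contrast regression** passes through the origin (contrasts have
  arbitrary sign), with |m| = √(Σy²/Σx²) for SMA and Σxy/Σx² for OLS;
  the OLS-through-origin slope on contrasts is the Brownian ML estimate
  and coincides with the PGLS slope on the same tree to machine
  precision — a cross-check wired into the tests.
- **PGLS** solves β = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y via Cholesky whitening, where
  C[i,j] is the shared root-to-MRCA path length.  On a star tree C is
  proportional to the identity and PGLS reduces exactly to OLS.
  Standard errors use the unbiased σ̂² = RSS/(n−k−1); the Gaussian ML
  log-likelihood is reported.

Tip names are joined to the table by exact string match with an
optional underscore/space normalization.

## Predictive regression and mass estimation

Prediction of mass from a measurement is an asymmetric problem, so
predictive models use OLS (or PGLS), not SMA.  Models are scored by R²,
SEE = √(RSS/(n−k−1)) on the log scale, AIC = n·ln(RSS/n) + 2(k+2)
(Gaussian profile likelihood with the variance counted as a parameter;
only within-dataset differences are meaningful), and mean **percent
prediction error** PPE = |obs − pred|/pred × 100 computed on the
back-transformed raw-mass scale, with a t-based 95% CI over species.
The predicted value is the PPE denominator, following the
mass-estimation literature's convention (switchable for sensitivity
analysis).  No smearing/back-transformation bias correction is applied
by default, matching the published coefficients; a ratio-estimator
correction exists but is off.

Mass estimates are point = 10^(Σβ·log₁₀ input + b) grams with range
point·(1 ± meanPPE/100).  The six published equations are registered
read-only; equations without a published PPE return point estimates
with a warning.  Outlier screens: externally studentized residuals
against the Bonferroni-corrected t critical value (the residual-outlier
rule is this package's choice — no specific test is canonical, so
counts may differ slightly from other implementations), and Tukey
fences (type-7 quartiles ± 1.5·IQR) for extreme values.  The raw-scale
power fit y = a·xᵇ uses Levenberg–Marquardt initialized from the
log-log OLS fit.

## Synthetic data

`simulate_allometric_table` draws log10 combined circumference
uniformly on [1.3, 3.2] (log-uniform rather than log-normal, to
guarantee leverage across the span and stable var(x) for
slope-recovery tests) and sets log10 BM = 2.78·x − 1.16 + N(0, σ), with
σ solved from a target R² of 0.986 by default — the empirical all-data
conditions.  The humeral share of the combined circumference is
Beta(48, 52) (mean 0.48), loosely matching mammalian proportions; the
split only matters for multiple-predictor models.  Lengths derive from
circumferences through a near-isometric log-linear relation with its
own noise.  Clade labels follow the empirical sample composition.
`simulate_tree_and_traits` grows a Yule tree (default 0.1
births/lineage/Myr) and evolves x by Brownian motion with an
independent Brownian residual added to y = slope·x.

What the generators do **not** emulate: measurement-protocol error,
ontogenetic variation, clade-specific scaling differences (all clades
share one generating relation, which is what makes the null-comparison
calibration tests meaningful), non-Brownian trait evolution, and the
lumpy taxon sampling of real databases.  Passing tests therefore
demonstrate correctness and calibration of the machinery under the
stated model, not the empirical claims themselves.

Simulated Yule trees have many edges shorter than 1 Myr, so the ln
branch-length transform is inapplicable to them; simulation-based
checks use raw lengths or the ln(length+1) fallback.

## Problem sizes and determinism

Monte-Carlo calibration uses 2,000 null replicates for the LRT type-I
rate (n = 50 per group) and 400–500 replicates for OLS (n = 247) and
PGLS (100 tips) slope-CI coverage — sizes at which the binomial noise
of the estimated rates is well inside the asserted bands.  All
generators take explicit integer seeds and are bit-reproducible;
re-running a report with the same data, config and seed yields
byte-identical output files.

## Known limitations

- Bipeds are out of scope: mass loads two limbs, not four, so the
  quadrupedal circumference equations do not transfer.
- PGLS supports only the Brownian covariance (no Pagel's λ or OU).
- The elevation-test SE is a delta-method approximation; at very small
  n it can be mildly anticonservative.
- Published-equation estimates inherit the extant calibration range;
  extrapolation far beyond ~1384 mm combined circumference (the largest
  reference specimen) carries unquantified additional uncertainty.
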