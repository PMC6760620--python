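# Methods

## Scope and data model

`bivakit` analyses cohorts of children and adolescents (4–20 y) with
duplicate 50 kHz bio-impedance readings (resistance R, reactance Xc,
phase angle PA), anthropometry, and optionally the inputs to the
4-component body-composition model (deuterium dilution space, body
volume by plethysmography, bone mineral content by DXA). The canonical
record is one row per child; cohort CSVs use comma separation, UTF-8, a
mandatory header, `.` decimals, and empty cells for missing optional
values. Sex is an internal two-level enumeration; input coding is a
configuration mapping, not code. Ages are decimal years computed
upstream; the package does no date arithmetic. Parsing never silently
drops rows: every rejected row is recorded with its reason and
`rows_read = kept + rejected` always holds.

## Vector components and QC

Analyses use the duplicate means: R/H = mean(R₁,R₂)/height and likewise
Xc/H (Ω/m); PA is the mean of the instrument-reported duplicates
(degrees). The package additionally recomputes arctan(Xc/R)·180/π from
the averaged readings as an internal consistency angle — the standard
phase-angle definition — but the instrument PA remains the primary
datum.

QC excludes a record iff any of four rules fires, and reports every rule
that fired:

| rule | condition | default |
| --- | --- | --- |
| implausible PA | mean PA > pa_max (strict) | 8.0° |
| PA repeatability | \|PA₁−PA₂\| > pa_dup_max (strict) | 0.5° |
| R/H repeatability | \|R₁−R₂\|/H ≥ rh_dup_max | 6.0 Ω/m |
| Xc/H repeatability | \|Xc₁−Xc₂\|/H ≥ xch_dup_max | 6.0 Ω/m |

Healthy phase angles run roughly 5–7°, so 8° allows for measurement
error. The R/H rule is interpreted on the height-adjusted duplicate
difference (Ω/m) with a non-strict ≥, matching the printed symbols; the
PA rules are strict. The filter is a true partition (kept ∪ excluded =
input, disjoint) and idempotent.

## 4-component body composition

TBW = dilution space / 1.044, correcting deuterium's proton-exchange
overestimate. Fat mass uses the Fuller-type linear 4C combination

    FM = 2.747·BV − 0.710·TBW + 1.460·BMC − 2.050·weight

(BV in litres, masses in kg). The coefficient set is a configuration
object recorded in every output, so alternative published 4C
formulations can be swapped in; BMC enters as measured bone mineral
content with no ash-conversion factor unless configured. FFM is the
exact complement weight − FM, so mass closure holds to machine
precision by construction. H_FFM = TBW/FFM; values outside the healthy
paediatric band [0.70, 0.80] are flagged, not rejected, as are
physically impossible FM values (< 0 or > weight) — cohort runs should
see and count these, not crash. BMI = weight/height².

## LMS references and SDS

For each trait and sex separately, the package fits Cole's LMS model:
conditional on age t, z = ((y/M(t))^{L(t)} − 1)/(L(t)·S(t)) is standard
normal (log form in the L→0 limit). The log-likelihood per observation
is −z²/2 + L·ln(y/M) − ln S (constants dropped), maximised by L-BFGS
with analytic gradients over coefficients of L, log M and log S on
spline bases in (standardised) age.

Curve complexity is counted in degrees of freedom per curve: 1 =
constant, 2 = linear, 3 = quadratic, ≥ 4 = cubic B-spline with that many
basis functions (interior knots at age quantiles). These are regression
splines fitted by direct maximum likelihood rather than penalised
smoothing splines; at the complexities searched (≤ 6 df per curve) the
two families express the same curve shapes, and counting integer df
keeps the deviance-based selection rule exact and auditable. Selection
is greedy — grow M first (most data-supported), then S, then L, one df
at a time — accepting a step only if the deviance falls by more than
ln N, the BIC threshold for one parameter. An explicit list of candidate
(df_L, df_M, df_S) triples can be supplied instead; the full selection
trace (every candidate, its deviance, and the accept/reject reason) is
kept in `fit_meta`.

At the optimum the score equations force the fitting sample's SDS to
have variance 1 (when S contains a constant) and near-zero mean, which
is the self-calibration property the tests assert (mean within ±0.05,
SD within ±0.05 of 1, half the sample below the fitted median ±0.03).

Fitted curves are sampled on a 161-point age grid spanning the data and
queried by monotone (PCHIP) interpolation; extrapolation beyond the grid
is refused (with a 1e−6 y boundary tolerance absorbing serialisation
rounding). Centile curves invert the transform,
value = M·(1 + L·S·z_p)^{1/L}; where the inverse is undefined
(1 + L·S·z_p ≤ 0) the curve has a NaN gap rather than an error.
References serialise to a CSV of (trait, sex, age_y, L, M, S) rows —
also the expected layout for ingesting externally published reference
tables — and reading validates monotone ages and positive M, S.

The SDS API refuses non-positive measurement values because the Box-Cox
form requires positivity; all traits handled here (impedance components,
PA, BMI, masses, hydration) are positive.

## RXc-plane geometry

With sample mean m, covariance S (eigenvalues λ₁ ≥ λ₂) and p = 2:

* confidence ellipse (region for the mean): semi-axes
  √(λᵢ · p(n−1)/(n(n−p)) · F_{p,n−p}(level)), axes along the
  eigenvectors, centred at m;
* tolerance ellipse (region for individuals): semi-axes
  √(λᵢ · p(n²−1)/(n(n−p)) · F_{p,n−p}(level)).

Exact F scalings are the default because BIVA group sizes are typically
a few dozen; the large-sample chi-square variant is available behind a
flag for cross-checking against other BIVA software. Orientation is the
semi-major-axis angle in [0°, 180°); an (near-)circular ellipse reports
0°. Degenerate covariance raises a geometry error rather than returning
a collapsed ellipse.

The two-sample Hotelling statistic is
T² = (n₁n₂/(n₁+n₂))·dᵀS_pooled⁻¹d with pooled covariance, transformed to
F = ((n₁+n₂−p−1)/(p(n₁+n₂−2)))·T² on (p, n₁+n₂−p−1) df. Only the
independent-groups comparison is provided (no paired variant, no
one-sample test against a reference mean). T² is invariant under any
common full-rank affine map of both groups; with a signal-free second
coordinate it collapses to the squared two-sample t statistic.

## Cohort analyses

All cohort statistics operate on the seven SDS columns (PA, R/H, Xc/H,
BMI, FFM, FM, H_FFM). SDS-band categories use left-open/right-closed
intervals ((a, b], outermost open) by default; the boundary rule is part
of the scheme object so group counts are auditable. The shipped schemes
split FFM-SDS at (−1, 0, 0.75, 1.5) and H_FFM-SDS at (−1, −0.5, 0, 1),
five bands each. Correlations are Pearson with two-sided p-values;
zero-variance columns are flagged explicitly. Regressions are OLS on the
SDS columns as-is — they are standardised by construction, so
coefficients are already on the SDS scale; rank-deficient designs raise
an error naming the collinear columns. Group contrasts are pairwise
pooled-variance t tests (Welch optional) with Bonferroni over all pairs,
adjusted p = min(1, p·n_pairs), α = 0.05, two-sided throughout.
Singleton groups yield flagged, undefined p-values. Slope heterogeneity
fits y ~ x + group dummies + x:group interactions against a reference
group (largest by default); groups below 3 members are excluded from
coding and listed on the result.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes, with
known ground truth:

* ages uniform on 4–20 y, sexes alternating (balanced);
* a 7-vector of trait SDS per subject drawn from a multivariate normal
  whose correlation is the nearest-positive-definite projection of the
  target matrix. The shipped target is the published whole-cohort trait
  correlation matrix; its rounded entries are strongly non-PD (smallest
  eigenvalue ≈ −0.71, driven by the BMI–FFM 0.74 / BMI–FM 0.92 /
  FFM–FM −0.61 triple), so the projection adjusts some entries by up to
  ≈ 0.35 and the generator records the adjustment;
* SDS back-transform through per-sex median curves with log-normal
  spreads (L = 0): trait = M_sex(age)·exp(cv·z). Median anchors (ages
  4/12/20, PCHIP-interpolated) encode the qualitative growth pattern:
  R/H 600→380→300 Ω/m (curvilinear decline, females slightly higher),
  Xc/H 65→45→35 Ω/m, PA rising linearly 5.0→6.5° within the healthy
  5–7° band, H_FFM declining 0.765→0.735 with chemical maturation, and
  BMI/FFM/FM on conventional paediatric scales chosen so the implied
  median height runs ≈ 1.05 m at 4 y to ≈ 1.70 m at 20 y. The log-normal
  back-transform deliberately exercises the LMS fitter's selection of
  L toward 0;
* weight = FFM + FM, height = √(weight/BMI), TBW = H_FFM·FFM, dilution
  space = TBW·1.044, BMC = 0.052·FFM, and body volume from inverting the
  4C equation — so the composition stage reproduces the intended
  FM/FFM/H_FFM exactly (closure to ~1e−15);
* duplicate readings with Gaussian noise (SD 2 Ω for R, 1 Ω for Xc,
  0.1° for PA — inside the QC thresholds for typical heights, though
  the R rule can fire on rare tail draws for the shortest children);
* optional contamination: configured fractions of records receive one
  QC violation each (PA set above 8°, or a duplicate gap pushed past the
  relevant threshold);
* a single seeded generator drives every draw, so identical config+seed
  gives byte-identical output.

The drawn PA is *not* constrained to equal arctan(Xc/R) of the drawn
components — the three BIVA traits are generated from their own SDS so
the target correlation structure is exact, mirroring how the instrument
reports PA as its own datum. What passing tests show is therefore that
the pipeline recovers the *statistical* structure it is pointed at; they
do not validate instrument physics, real growth curves (the anchors are
invented, constrained only by the qualitative pattern above), secular or
ethnic variation, or disease-state fluid perturbations, none of which
the generator models.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations as
follows: correlation recovery 200,000 pairs (±0.01), LMS recovery 5,000
points, ellipse coverage 5,000 replicates of n = 50 plus a 10,000-point
tolerance check, Hotelling type-I error 5,000 null replicates of
30 + 30, 4C closure 4,000 subjects, and full-pipeline correlation
closure 50,000 subjects (entry-wise tolerance ±0.02 against the
PD-projected target). The LMS optimiser uses analytic gradients,
standardised age, warm starts along the selection path, and clipped
exponents for numerical safety; the L→0 branch switches at |L| < 1e−8
with a series form continuous to ~1e−4 across the switch.

## Known limitations

* The 4C coefficient set is configurable but the default is fixed; no
  ash-conversion or adipose-hydration refinements are modelled.
* LMS fitting assumes the Box-Cox-normal family; no kurtosis adjustment
  is provided, and references refuse extrapolation outside the fitted
  age range rather than modelling it.
* The tolerance-ellipse content guarantee is asymptotic (plug-in
  covariance); at small n it under-covers slightly.
* Published group counts and regression coefficients from any specific
  cohort are not reproducible without that cohort's raw data; the
  package validates itself by parameter recovery on synthetic data
  instead.
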