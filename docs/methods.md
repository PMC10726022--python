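# Methods

This note records the models, algorithms, numerical choices and known
limitations of the package. It is written for a reader who wants to
know exactly what is computed and why, in the order the pipeline runs.

## Study system and data layout

The analysis targets body-size and ultrasound carcass traits of
yearling water-buffalo calves measured on smallholder farms: body
weight (BW, kg), wither height (WH), rump height (RH), body length
(BL), chest width (CW), hip width (HW), chest circumference (CC) and
cannon-bone circumference (CBC) in cm, plus in-vivo ultrasound
longissimus muscle area (LMA, cm²), muscle depth (LMD, cm) and
subcutaneous fat thickness (SFT, cm). The reference population is 313
calves of one birth year across 36 farms with a shallow
calf–dam–sire pedigree. Three input tables drive everything: a
pedigree (animal, sire, dam; unknowns allowed), a long-format
measurement table (animal, trait, age in days, value, plus the
categorical management factors), and a genotype table (animal, locus,
biallelic call).

## Age standardization

Animals are measured whenever a farm is visited, so each animal holds
a short series of records at arbitrary ages. The 365-day value is
taken from the straight line through the two records flanking day 365;
when 365 lies outside the observed range, the line through the two
records nearest the target is extended. Interpolation is exact for
any affine growth trajectory; over a 60–120-day window around one year
of age, growth in these traits is close enough to linear that the
kernel choice is second-order. A single record is passed through
unchanged and flagged. The extrapolation distance in days is kept per
cell, with a QC flag (default threshold 90 d) that marks but never
drops distant extrapolations; the kernel is a pluggable function so a
nonlinear growth curve could be substituted without touching callers.

## Fixed-effects model and adjustment

Per trait, on farms with at least four usable records (the filter
counts records with a non-missing value of the trait being analysed,
so a farm can pass for one trait and fail for another):

    y = mu + farm_i + season_j + sex_k + damage_l + bwclass_m + e

All factors are categorical — including birth-weight class, a
two-level (<33 kg / ≥33 kg) classification rather than a covariate —
and the model is purely additive. Effects are sum-to-zero coded, so
the intercept is the overall least-square mean and each level effect
is a deviation; least-square means are `mu + effect`, which under this
coding equals the equal-weight average of predicted cell means. The
ANOVA uses partial (adjusted) sums of squares — the rise in residual
SS when one factor's columns are dropped from the full model — so
factor order is irrelevant. Multiple comparisons use the studentized
range on the least-square means with Tukey–Kramer standard errors from
the coefficient covariance; compact letters are the maximal cliques of
the not-significantly-different graph, lettered highest mean first
("a" = highest).

Downstream analyses (phenotypic correlations, SNP ANOVA) use
*adjusted* phenotypes: each record minus the sum of its estimated
effects for the factors significant at P < 0.05 (a switch allows
adjusting for all factors). In unbalanced data the record-wise sum of
sum-coded effects has a nonzero mean, so the adjusted values are
recentred to preserve the grand mean exactly.

## Animal model and EM-REML

Per trait the univariate animal model with an uncorrelated maternal
genetic effect is

    y = Xb + Z_a a + Z_m m + e
    a ~ N(0, A sa2),  m ~ N(0, A sm2),  e ~ N(0, I se2),  Cov(a, m) = 0

where A is the numerator relationship matrix from the pedigree
(tabular method; founders unrelated and non-inbred; at herd scale the
dense O(n²) recursion and dense inverses are trivial). X carries the
significant environmental factors (sum-to-zero coded); Z_a links each
record to its animal and Z_m to its dam. Records whose dam is unknown
receive a private dummy founder dam so Z_m is always defined.

Variance components are estimated by EM-REML. The restricted
likelihood depends on the data only through the record-level
covariance

    V = sa2 A_rr + sm2 Z_d A_dd Z_d' + se2 I

(A_rr among recorded animals, A_dd among dams), so the implementation
iterates on this marginalised form — mathematically identical to
carrying every pedigree animal as an explicit random-effect level, but
with per-sweep cost set by the number of records rather than the
pedigree size. Each sweep applies the classical updates

    s_u2 <- s_u2 + (s_u2² / q_u) (y'P G_u P y − tr(P G_u))

for u ∈ {a, m, e} (G_a = A_rr, G_m = Z_d A_dd Z_d', G_e = I; q_u the
number of levels, n for the residual; P the REML projection at the
current components). These updates never decrease the restricted
log-likelihood and keep every component non-negative; the
log-likelihood is evaluated every sweep from the same factorisation
(|V|, |X'V⁻¹X| and y'Py fall out of the Cholesky) and monotonicity is
checked each iteration.

Because plain EM stalls near variance boundaries, an optional
accelerated mode (on by default in the pipeline) interleaves a
squared-extrapolation step of the SQUAREM family: two EM sweeps give a
secant direction and curvature, an extrapolated candidate is formed,
and it is **kept only if the restricted log-likelihood does not
decrease** — so the accelerated path inherits EM's monotonicity
guarantee. Convergence requires the relative change of every
component below `tol` (default 1e-8) *and* a log-likelihood change
below `tol × 1e-2` (1e-10 at the default); non-convergence returns the
last iterate flagged `converged=False`. Components are floored at
1e-12 × var(y); a component below 1e-6 of the phenotypic variance at
the optimum is flagged as a boundary solution and its standard error
reported as 0 (the information matrix is singular in that direction).
Starting values split the sample variance equally among the modelled
components. A design with no pedigree links among recorded animals
and no maternal effect leaves the additive/residual split
unidentified; this is detected and warned about rather than silently
"converged".

Standard errors come from the inverse average-information matrix
AI_ij = ½ y'P G_i P G_j P y at the optimum, restricted to
off-boundary components; heritability standard errors use the delta
method with that covariance. Note the published variance-component
table reports "± 0.000" for every direct additive variance — likely a
boundary convention of the original software's output — whereas this
package reports true information-based SEs plus an explicit boundary
flag, and does not attempt to reproduce those zeros.

Breeding values are BLUPs from Henderson's mixed-model equations built
on the **full** pedigree at the REML optimum, so parents and other
unrecorded relatives receive EBVs (an unrecorded offspring's EBV is
exactly the parental average). Prediction-error variances are the
corresponding diagonal of the inverse coefficient matrix times se2.

## Genetic parameters and selection responses

With Cov(a, m) = 0:

    h2_a = sa2 / sp2,   h2_m = sm2 / sp2,   h2_T = (sa2 + 0.5 sm2) / sp2

`h2_T` is Willham's total heritability; it reproduces every published
total-heritability cell from the published components (e.g. BW:
(260.172 + 0.5·503.610)/779.945 = 0.656).

The genetic correlation between two traits is approximated as the
Pearson correlation of their EBVs over the common animals (the Calo
approach). The denominator is the geometric mean of the *EBV*
variances — the only scaling that keeps the estimate inside [−1, 1] —
and estimates are clamped to [−1, 1] with a logged warning if sampling
noise pushes them outside. Significance uses the t test for a
correlation at the common-animal count; a trait whose EBV vector has
zero variance (a boundary heritability, as for LMA) yields an
undefined, flagged correlation rather than a number. Phenotypic
correlations are Pearson correlations of the adjusted phenotypes,
pairwise-complete.

Expected responses at selection intensity i (taken as 1 throughout):

    direct:      dG = i · h2 · sigma_P            [trait units/generation]
    correlated:  CR_i = rG(i, j) · h_j / h_i      [relative, dimensionless]

with h the square root of the direct heritability, j the (auxiliary)
trait selected on and i the responding trait. The response matrix puts
selected traits on rows and responding traits on columns — the
orientation fixed by cross-checking the published wither-height row
against the formula. A zero responding-trait heritability makes CR
unbounded and raises an error with guidance (the LMA column, at
h2 = 0.0001, shows how fragile these ratios are near the boundary).

Reconstructing the published 11-trait response matrix from the
published heritabilities, phenotypic variances and genetic
correlations reproduces 118 of the 121 printed cells within ±0.005
(the residual is rounding of the printed inputs). The other three
cells contradict the published formula itself: the (WH, CC) cell
prints the raw genetic correlation 0.7600 where the formula gives
0.8008, and the (LMD, RH) and (SFT, RH) cells duplicate the adjacent
BL column to all four decimals. These are printing artifacts, and the
tests document them as such rather than reproducing them.

## Candidate-SNP analysis

Genotypes are unordered biallelic calls (TC ≡ CT); more than two
alleles at a locus is an error. Per locus the package reports
genotype counts and frequencies, allele frequencies
(p = (2n_AA + n_Aa)/2n), a monomorphism flag, and — as a clearly
marked QC extension beyond the core analysis — an exact
Hardy–Weinberg test (Levene–Haldane conditional distribution, summing
tables no more probable than the observed one). Genotype effects on
adjusted phenotypes use one-way ANOVA over genotype classes; classes
below a size floor (default 2, the smallest class with a defined
within-class variance) are reported but excluded from the F test, and
fewer than two usable classes skips the test with an explanation —
the monomorphic-locus case.

## The synthetic-herd generator

No raw data are deposited for this population, so the generator
produces herds with the published structure, and every stage of the
pipeline is tested against known truth:

* **Pedigree**: founder sires and dams plus calf cohorts with known
  parents; dam reuse bounded by a litter parameter; depth is a knob
  (the default single cohort mirrors the plausible real structure of
  one birth-year of calves under shallow recording).
* **Genetic values**: a and m for *all* pedigree animals are drawn
  from N(0, A ⊗ Σ) through the Cholesky factor of A, with Σ built
  from the published per-trait components and the published genetic
  correlation matrix (used for both the additive and maternal
  structures; only dams' maternal values reach phenotypes).
* **Phenotypes**: y = mean + farm effect + factor contrasts + a +
  m(dam) + e. Default means and two-level factor contrasts equal the
  published least-square means and their level differences (e.g. the
  14.8 kg sex contrast on BW), so simulated ANOVAs have realistic
  power; farm effects are N(0, (0.5 σ_P)²), strong enough that the
  farm factor is essentially always significant, as observed. The
  residual correlation across traits defaults to the genetic one (a
  simplification; the published phenotypic correlations are close to
  the genetic ones throughout).
* **Measurements**: linear trajectories through each animal's 365-day
  value with slope 0.7 × mean/365 per day (roughly the growth from a
  one-third-of-mean birth value to the yearling value), sampled at
  ages {300, 360, 420} ± a per-animal jitter of up to 15 d, with
  measurement noise of SD 1 % of the trait mean.
* **Genotypes**: founder gametes drawn at the configured allele
  frequency (defaults implied by the published genotype counts, e.g.
  T at 463/472 for the LCORL-linked locus), then gene-dropped —
  one random allele from each parent. Optional per-copy additive
  effects can be injected into phenotypes.

One integer seed drives all stages through independent spawned
streams, so the bundle is bit-reproducible and stages can be re-run
alone. What the generator does **not** emulate: selection or
assortative mating, genotype-by-environment interaction, heteroscedastic
measurement error, non-linear growth, missing-data patterns of real
field work, and real pedigree depth/completeness (unknown for this
population). Passing recovery tests therefore demonstrate correctness
of the estimation machinery under the stated model, not robustness to
model violations in real data.

## Problem sizes and tolerances used in the test suite

* The REML-versus-oracle equivalence uses 8- and 12-record pedigrees
  whose data are drawn from the animal model itself so the REML
  optimum is interior (tiny datasets otherwise sit on a variance
  boundary, where relative-tolerance comparisons are meaningless);
  agreement is required to 1e-4 relative against a Nelder–Mead search
  of the direct-V restricted likelihood, and BLUP against GLS to 1e-8.
* The wither-height recovery study simulates 1500 recorded calves (50
  sires, 500 dams, 3 calves per dam — three progeny per dam keeps the
  maternal variance identifiable in a strictly two-generation
  pedigree) under the published WH components and fits the maternal
  animal model per seed, requiring the 20-seed mean direct
  heritability within ±0.05 of 0.483. The phenotypes carry exactly
  the generating components; the measurement/standardization leg is
  validated by its own round-trip and noise-propagation tests. These
  runs use `tol = 1e-3` with at most 120 accelerated sweeps: the
  additive share of variance stabilises long before the slow
  maternal/residual direction finishes crawling, and spot checks
  against fully converged runs put the per-seed difference in the
  heritability below 0.01.
* The genetic-correlation recovery runs at n = 600–1000 over 8–20
  seeds (±0.1 band), and the gene-drop calibration at the published
  236-animal scale.

## Known limitations

* Univariate REML only; genetic correlations come from EBV
  correlations, which are biased toward the phenotypic correlation
  when accuracies are low — they are reported as the analysis defines
  them, not as bivariate-REML estimates.
* The EM boundary crawl means near-zero components "converge" slowly;
  the boundary flag, not the iteration count, is the honest signal.
* Maternal and additive variances are weakly separated in shallow
  one-progeny-per-dam pedigrees (the real data structure); standard
  errors on maternal components are accordingly large.
* The age-standardization kernel is linear by declaration; the
  original description of the method is not independently verifiable,
  and linearity is this package's explicit assumption.
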