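# Methods

## The trait and the models

Hatch of fertile (HoF) is the percentage of fertile eggs that hatch,
recorded weekly per hen over the laying period (ages 27–58 weeks here).
It is mostly a trait of the hen (egg quality) and of the embryo; the
mate's additive genetic effect is negligible once the egg is fertilized
and is not modelled, but the mate contributes a permanent environment
effect to every record of the hens he is mated to.

All models in the ladder share the linear mixed-model skeleton

    y = X b + Σ_k Z_k u_k + e,    u_k ~ N(0, A_k ⊗ K_k),

with `A_k` the pedigree numerator relationship matrix for the hen
additive genetic effect (`aF`) and an identity for the permanent
environment of the hen (`peF`) and of her mate (`peM`); `K_k` is a
scalar variance or a coefficient covariance over normalized Legendre
polynomials of standardized age.  Fixed effects are the contemporary
group POU (3 successive hatch weeks reared together, reference-coded),
the mean egg storage age as a linear covariate, and either a linear hen
age covariate (CUM/REP) or a fixed degree-4 Legendre lay-cycle curve
(FRM/RRM).

* **CUM** – one record per hen, her mean HoF; genetic effect and
  residual only.  Averaging removes most week-to-week noise, which is
  why this model reports the highest heritability while actually using
  the least information.
* **REP** – weekly records with scalar `aF`, `peF`, `peM`; assumes a
  genetic correlation of one between all ages.
* **FRM** – REP plus the fixed lay-cycle curve.
* **RRM** – each hen (and mate) deviates from the fixed curve by her
  own random Legendre regression: genetic degree 2, both permanent
  environment terms degree 3, residual variance heterogeneous with one
  class per week of age.  Variances at age t are φ(t)ᵀKφ(t); genetic
  correlations between ages follow from the same covariance function.
* **MTM** – mean HoF in weeks 27–37 / 38–47 / 48–58 treated as three
  traits with a full 3×3 genetic covariance.  The three per-hen
  averages are disjoint, so residual covariances between traits are not
  identifiable and are fixed at zero; the hen permanent environment,
  which the model omits, is consequently absorbed into the genetic
  covariances.  On data generated with a persistent hen environment
  this inflates MTM heritabilities and pushes genetic correlations
  toward one — the model's known failure mode, reproduced here.
* **Threshold** – the REP structure on the logit liability scale with
  binomial denominators (fertile eggs per week).  The latent residual
  is the logistic variance π²/3, so liability heritability is
  σ²a/(σ²a+σ²pe+σ²pm+π²/3).  The Dempster–Lerner probit transform with
  the observed mean incidence converts liability heritability to the
  0/1 scale.

Heritability at the record level is σ²a/σ²P with σ²P the sum of all
fitted components (the mate permanent environment is part of a record's
variance); repeatability adds both permanent environment components to
the numerator.  The RRM "average heritability" is the unweighted mean
of h²(t) over the weekly age grid.

## Pedigree machinery

`A` is built by Henderson's tabular method (dense, for desk-scale
pedigrees); inbreeding by Meuwissen–Luo; the sparse `A⁻¹` directly by
the Henderson/Quaas rules with exact inbreeding, which is what the
mixed-model equations consume.  log|A| = Σ log dᵢ over the Mendelian
sampling variances feeds the REML likelihood.  Founders are assumed
unrelated and non-inbred; ids 0, blank, ".", "NA" all mean "unknown
parent".  Pedigrees are topologically sorted internally (Kahn's
algorithm) because external files rarely arrive sorted.

## REML

Variance components maximize the restricted likelihood
−2ℓ = log|R| + log|G| + log|C| + yᵀPy, evaluated through a dense
Cholesky factorization of the mixed-model coefficient matrix C (a few
thousand equations at the scales used here).  The driver alternates:

1. **EM steps** (monotone, used for warm-up and as a fallback):
   K ← (ÛᵀA⁻¹Û + T)/q with T the A⁻¹-weighted trace of the
   corresponding block of C⁻¹; residual classes
   σ²c ← (êcᵀêc + tr(C⁻¹ WᵀDcW))/nc.
2. **Average-information steps** taken in log-Cholesky coordinates
   (K = LLᵀ with log diagonal, log residual variances): the AI matrix
   and exact scores are transformed through the Jacobian, a trust
   region caps the step at 2 units in the unconstrained coordinates,
   and the step is halved until the likelihood does not decrease.  Any
   step yields a positive-definite K, so no projection is needed and
   boundary estimates (effectively zero variances) are reached smoothly
   instead of being clipped.

Scores were verified against numerical differentiation of the
likelihood, and the whole engine against statsmodels MixedLM (an
independent REML implementation) and balanced-ANOVA closed forms.

Convergence is declared when the largest relative parameter change is
below `tol` (default 1e-6) and the likelihood change below 1e-8;
non-convergence returns the best-so-far estimates with a flag.
Components are reported "at the boundary" when effectively zero
(minimum eigenvalue ≤ 1e-6 × var(y)).  Near-singular coefficient
covariances produce long, nearly flat likelihood valleys in which the
parameter estimates stabilize long before the likelihood stops creeping;
the recovery studies therefore cap iterations (40 for the RRM at
tol 1e-4), which we verified moves the h² surface by less than a tenth
of its Monte-Carlo spread relative to a fully polished optimum.

The threshold model is fitted by penalized quasi-likelihood: iteratively
reweighted working variates z = η + (y/n − p)/(p(1−p)) with weights
np(1−p) are passed to the same REML engine with the working residual
fixed at diag(1/w), and the linear predictor is refreshed until stable.
PQL's finite-denominator bias is small here because the latent effects
live at the hen level, where each hen accumulates ~150 Bernoulli trials
over her records; the residual recovery study quantifies what remains.

## The synthetic data

The generator emulates the structure of field data: a hierarchical
pedigree (sires × dams × offspring, optionally over generations) whose
final-generation hens are phenotyped; breeding values by sequential
Mendelian sampling (founder ~ N(0, K); offspring = parent average +
N(0, (½ − ¼(F_s + F_d))K)); mates assigned to randomized blocks of 5
hens (the true mating ratio is not public; randomization keeps the mate
environment separable from genetics); POU from 3-week blocks of hatch
dates shared between a hen and her mates' group; egg storage age as a
truncated normal (3.23 ± 1.36 d, max 13); eggs set per hen-week as a
rounded truncated normal (5.63 ± 1.89, min 1); ~30% of weeks missing
plus a small weekly drop-out hazard, giving ~17–20 records per hen; and
a lay-cycle mean curve interpolating ~75% at onset, ~90% at peak,
declining to ~65% at 58 weeks.

Gaussian mode writes the linear predictor directly as `hof` (not
clamped to [0,100], because the linear models do not clamp); binomial
mode builds the same predictor on the logit scale (percent-scale fixed
effects are converted locally through d logit/d pct) and draws
hatched ~ Binomial(fertile, p), with fertility itself a constant rate
(0.93) rather than a modelled trait; Jensen's inequality pulls the
realized mean a few points below the percent curve when the liability
variance is large.  Scalar truths act on the record
scale; matrix truths are Legendre coefficient covariances.  The default
scalar partition is genetic 5%, hen permanent environment 8.31%, mate
permanent environment 1.05% of the phenotypic variance.  The
random-regression truth is built by projecting smooth age-covariance
kernels (Gaussian correlation, length 24 weeks) onto the Legendre
bases; the projected matrices are nearly singular, so their eigenvalues
are floored at 5% of the largest — fitted coefficient covariances in
practice are full rank, and a comfortably positive-definite truth keeps
the recovery study away from degenerate boundary optima.  The per-week
residual profile is U-shaped (larger at onset and end of lay) with mean
0.8564 of the total variance.

What the generator does *not* emulate: the strong non-normality of
percentage records near 100%, calendar-time environmental trends
(year/season within POU), genetic change over generations, egg
production as a correlated trait, and fertility as anything but a
constant thinning rate.  Passing recovery tests therefore demonstrate
that the estimators are correct under the models' own assumptions, not
that those assumptions hold for any particular flock.

## Recovery studies (study sizes)

* Repeatability: 800 hens × ~20 records, 20 replicates; mean estimates
  vs truth within ±2 empirical SE.
* Random regression: 400 hens, 4 replicates, genetic degree 2 and
  permanent environment degree 3 with per-week residuals; the truth
  h²(t) must lie inside the mean ± 2 SD Monte-Carlo band at ≥90% of
  ages (pointwise bands over 32 ages are allowed a small number of
  excursions), and fitted genetic correlations must decline with age
  distance in every replicate.
* Threshold: ~1,000 hens of binomial records at liability h² = 0.11,
  4 replicates, mean estimate within ±2 SE of truth.

These sizes are desk-scale study designs: large enough that the
recovery checks are informative, small enough to run routinely.

## Selection calculus

Truncation selection intensity i = z/p; annualized response
R = i·r·σa/L for a single record and R = i·r·σa·√(n/(1+(n−1)re))/L for
n repeated records of repeatability re.  The square-root form is the
standard accuracy of the mean of n records; the package also exposes
the multiplier without the root behind a flag, since both readings
appear in applied work.  For the multitrait case the Smith–Hazel index
b = P⁻¹Ga (equal economic weights by default) gives Var(I) = bᵀPb and
R = i·√Var(I)/L.  Accuracy r is computed from prediction error
variances as √(1 − PEV/((1+F)σ²a)) averaged over the selection
candidates (the phenotyped hens); the generation interval L has no
public value for this population and defaults to 1 year — absolute
annual gains are only meaningful once L is set to the program's own
value, though model *comparisons* are unaffected because L scales all
models equally.

## Numerical choices and limitations

* Dense linear algebra throughout: the MME here are a few thousand
  equations; pedigrees beyond ~5,000 animals would need sparse
  factorization of C, which is out of scope.
* Reference-level coding of POU; covariates centered; any full-rank
  coding leaves the REML likelihood unchanged.
* Variance floors: K eigenvalues ≥ 1e-8 × var(y) inside the optimizer,
  residuals ≥ 1e-6 × var(y).
* The editing operation applies, in order: zero-set week removal, an
  optional year-window truncation (hens with records before the window
  are removed entirely), then the minimum-record rule (default 5).
* MTM residual covariances are structurally zero (disjoint averages);
  a design with repeated records per trait would identify them.
* Age standardization bounds default to 27–58 weeks and are
  configurable; records outside the bounds are an error, never
  extrapolated.
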