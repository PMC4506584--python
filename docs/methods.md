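# Methods

## Model and statistics

`epijack` tests for gene–gene interaction between two biallelic markers G
and H using cases only. Genotypes are coded 0/1/2 as copies of the coded
(risk) allele. Writing `p_lm` for the joint genotype probability among cases
and assuming the two loci are in linkage equilibrium in the general
population, the interaction parameter is the vector of four local log odds
ratios of the 3×3 case genotype table,

    beta_lm = log( p_lm p_{l+1,m+1} / (p_{l,m+1} p_{l+1,m}) ),   l, m ∈ {0, 1}.

`beta = 0` holds exactly when the two-locus penetrance is multiplicative
(`f(g,h) = mu * alpha_g * gamma_h`), which is the case-only definition of
"no interaction". For typed markers, `beta` is estimated by plugging the
joint genotype counts `n_lm` into the formula above; for untyped (imputed)
markers the counts are replaced by null expected counts

    E[N_lm] = sum_i P(G_i = l | data) * P(H_i = m | data),

the product of the two marginal imputation posteriors — valid because under
the null the joint posterior factorizes, so marginal imputation output is
sufficient.

Two test statistics are computed from an estimate `b` and a covariance
estimate `V` of it:

* **WTT** (Wald-type test): `b' V^{-1} b`, referred to chi-square with 4 df.
* **WTT_c** (sign-constrained Wald-type test):
  `b' V^{-1} b − min_{x ∈ Θ1} (b−x)' V^{-1} (b−x)`, where
  `Θ1 = {x ≥ 0} ∪ {x ≤ 0}` is the union of the two sign-coherent orthants.
  All six classical epistasis penetrance archetypes (unions/intersections of
  dominant/recessive conditions at the two loci) put the case-distribution
  `beta` in `Θ1`, which is what the constraint exploits for power.

The cone projection is solved exactly: each orthant is a 4-variable
sign-constrained quadratic program whose minimizer lies on one of the 16
faces (a subset of coordinates pinned at zero); the unconstrained face
optima solve `W_SS x_S = (W b)_S` with `W = V^{-1}`, sign-feasible
candidates are compared and the smaller of the two orthant minima is taken
(exact ties break to the nonnegative orthant for reproducibility). The face
enumeration doubles as its own brute-force oracle; the test suite also
cross-checks it against an independent NNLS solver on the
Cholesky-whitened problem.

## Chi-bar-square reference for WTT_c

Under the null, the projection residual onto a *convex* cone gives the
classical chi-bar-square mixture: conditioning on the dimension of the
projection, the statistic is chi-square with that many df, and the mixture
weights are the face probabilities of a `N(0, V)` draw. The constraint set
here is a union of two orthants, which is not convex, so no exact finite
mixture of that form exists. We approximate the tail by inclusion–exclusion
without the overlap term:

    P(stat ≥ t) ≈ P(stat⁺ ≥ t) + P(stat⁻ ≥ t)
                = Σ_{l=1..4} [w⁺_l + w⁻_l] P(chi2_l ≥ t),

where `stat±` are the two per-orthant statistics (each exactly chi-bar) and
`w±_l` are the per-orthant projection-dimension probabilities, estimated by
seeded Monte Carlo (default 20,000 draws of `N(0, V)`; the weights depend
on V only through its correlation structure). The neglected overlap term
`P(stat⁺ ≥ t, stat⁻ ≥ t)` is nonnegative, so the approximation is a valid
upper bound on the tail at every threshold — p-values are never
anti-conservative — and it vanishes rapidly with t: numerically, rejection
probabilities at the mixture's own 5% and 1% critical values are within a
few percent relative of nominal across identity and randomly correlated
covariances, while at small thresholds (t ≲ 3) the bound is visibly
conservative (the p-value is clipped at 1). This matches the observed
behavior of the constrained test in null simulations: exact size control
with a slightly conservative p-value distribution overall.

Two alternative modes exist for cross-checking: `method="winning"`
(mixture over the dimension of the closer orthant's projection, which
normalizes to 1 but *underestimates* the tail and is therefore not the
default), and `chibar_tail_mc`, a direct Monte Carlo tail of the simulated
statistic. For single-orthant constraints (`cone="nonneg"`) the classical
exact weights are recovered (binomial(4, 1/2)/16 at V = identity).

Weights are recomputed per dataset from that dataset's estimated V; in the
study harness this happens per replicate.

## Jackknife variance for imputed markers

Plugging expected counts into the multinomial variance formula (the
"dosage-as-observed" shortcut) is wrong for case-only interaction tests:
dosage is *less* variable than the genotype it replaces, so the plug-in
variance overestimates and the test is conservative — severely so at low
imputation information. `epijack` instead estimates the covariance of the
imputed-marker estimator by the delete-1 jackknife over individuals:
pseudo-values `ps_i = n b_n − (n−1) b^{(i)}`, covariance
`V = 1/(n(n−1)) Σ (ps_i − ps̄)(ps_i − ps̄)'` centered at the pseudo-value
mean. This is valid when imputing one individual does not depend on the
others (posteriors estimated from an external reference panel), because
deleting a case then leaves every other posterior row unchanged. Two
implementation choices keep it O(n):

* the leave-one-out table is the full expected table minus the individual's
  outer-product contribution (no table rebuild); tiny negative residuals
  (< 1e-9, floating-point cancellation) are clipped to zero;
* individuals with identical posterior row pairs share one leave-one-out
  computation, weighted by group size ("categorical grouping"). Emulated
  imputation produces at most 3 distinct rows per marker, hence ≤ 9 groups.
  Grouped and ungrouped results agree to 1e-12 (associativity only).

## Degenerate inputs and numerical choices

* Zero cells make the log odds ratios undefined. Default policy is a hard
  error naming the cell (or the sample whose deletion created it); the
  optional Haldane–Anscombe policy adds 0.5 to all nine cells and flags the
  estimate. Low allele frequencies remain a genuine limitation of the
  asymptotic test either way.
* `V^{-1}` is applied through a Cholesky factorization; positive
  definiteness is checked on the eigenvalues with a tolerance *relative* to
  the largest one (1e-12), because legitimate covariances span many orders
  of magnitude — at nearly uninformative imputation the estimator shrinks
  hard and its jackknife covariance is uniformly tiny without being
  singular.
* All Monte Carlo is driven by `numpy` Generators seeded explicitly;
  studies spawn per-replicate generators from one master `SeedSequence`,
  so results are bit-reproducible and methods are paired within replicate.

## What the simulator emulates

Cases are drawn i.i.d. from
`P(G=l, H=m | case) ∝ penetrance[l,m] · HWE_G(l) · HWE_H(m)` (Bayes rule
with Hardy–Weinberg marginals and linkage equilibrium). The six epistasis
archetypes are built from the caption logic — dominant means ≥ 1 risk
allele, recessive means 2; unions assign `f` where either locus condition
holds, intersections where both hold, `g < f` elsewhere.

Marginal imputation is emulated with a single tag SNP per target marker:
target and tag alleles live on haplotypes with frequencies determined by
allele frequencies (p, q) and a haplotype correlation r; a reference panel
of R haplotypes (default 120, a HapMap-CEU-sized panel) is drawn to
*estimate* those frequencies, each case's tag genotype is drawn from the
true model given its true target genotype, and the emitted posterior is
P(target | tag) under the panel-estimated model and HWE. This preserves the
features that matter for the statistics: posteriors are marginal per
marker, depend only on each individual's own observed data, carry
reference-panel estimation noise, and have tunable information content
(dosage r² ≈ r²; the presets r = 0.950, 0.872 and 0.150 at p = q = 0.3
realize information ≈ 0.90, 0.76 and 0.02, spanning high, medium and
nearly-uninformative imputation regimes). What it does *not* emulate:
multi-marker haplotype models, phasing uncertainty shared across
individuals of a real imputation run, LD between the two tested loci, and
allele frequency mismatch between panel and study. Passing tests therefore
demonstrate correct statistical behavior under marginal, individually
independent imputation with panel noise — the regime the method assumes —
not performance under model misspecification.

Study-design defaults mirror the size/power design: 5000 cases per
replicate, 3000 replicates for size at level 0.01, 100 (default) to 1000
replicates for power at level 0.05. Where the original penetrance and
frequency values were not available, the package fixes MAF 0.3 at both
markers, a null of multiplicative penetrances (`mu = 0.01` with per-allele
multiplier 1.2 at each locus), and a default power model of
recessive-AND-recessive epistasis with `f/g = 2` (so `beta = (0,0,0,log 2)`),
chosen so that at n = 5000 the imputed-data arms sit well away from power 1
and the orderings between arms are informative rather than saturated.

## Known limitations

* The chi-bar tail approximation is conservative at small statistics;
  p-values near 1 are reported as exactly 1.
* The asymptotic tests (and the jackknife) degrade at low minor allele
  frequency, where cells empty out; the zero-cell policies surface rather
  than hide this.
* The emulator's information calibration (r² of dosage vs truth) is a
  proxy for multi-locus LD information measures, adequate for controlling
  the information *level* but not a reimplementation of any particular
  measure.
* Case-only validity requires population-level independence of the two
  loci (unlinked genes); linked pairs need a case-control formulation,
  which is out of scope.
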