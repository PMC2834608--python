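# Methods

## Model and assumptions

The analysis model is a linear mixed model for a single Gaussian trait,

    y = X beta + Z gbar + e,    gbar = g + a,

where `g` is the genomic genetic effect and `a` a residual polygenic
effect.  Writing `w` for the polygenic share of the total genetic variance
`sigma2_g`, the combined effect has covariance `sigma2_g H_w` with

    H_w = (1 - w) G*(m_obs) + w A.

`A` is the pedigree numerator relationship matrix.  `G*` extends the
marker-based matrix `G` to non-genotyped animals by treating their gene
contents as unobserved random variables with pedigree covariance and
marginalising them: block 1 (genotyped) keeps `G`, and

    G*_21 = A21 A11^-1 G,
    G*_22 = A22 - A21 A11^-1 (A11 - G) A11^-1 A12.

Assumptions worth keeping in mind:

* Gene contents are assumed to have mean `1 p_j` and covariance
  proportional to `A` across animals.  Cross-locus covariances cancel in
  the derivation, so no linkage-disequilibrium model is needed or
  implemented — this is a property of the construction, not a shortcut.
* The conditional distribution of `g` given observed markers is treated
  as Gaussian.  For non-genotyped animals this is an approximation: the
  true conditional variance of a gene content depends on the observed
  genotype configuration, while the pedigree-linear form only matches it
  in expectation.  The test suite demonstrates both the configuration
  where the two coincide exactly and (implicitly) the general gap, and no
  correction is attempted.
* Allele frequencies refer to the founder (base) population.  Frequency
  choice is consequential under selection: with frequencies estimated from
  a selected sample the profile of `w` can collapse to the plain animal
  model (`w_hat = 1`).  `evaluate.allele_freq_sensitivity` reruns the
  profile under base-sample, current-sample and GLS (pedigree-weighted,
  Gengler-style) frequency estimates to expose this.

## Computational structure

Only `A^-1` (sparse, Henderson's rules with Meuwissen–Luo inbreeding
coefficients) and the genotyped block are ever formed:

* `A11 = ((A^-1)_11 - (A^-1)_12 (A^-1)_22^-1 (A^-1)_21)^-1`, with the
  side-2 solves done against a sparse factorisation of `(A^-1)_22`;
* `A21 A11^-1 v = -(A^-1)_22^-1 (A^-1)_21 v` (one sparse solve);
* `H_w^-1 = A^-1 + blockdiag(G_w^-1 - A11^-1, 0)` with
  `G_w = (1-w) G + w A11`, positive definite for any `w > 0` even when
  `G` is singular;
* `log det H_w = log det G_w + log det(A22 - A21 A11^-1 A12)`, where the
  Schur term equals `-log det((A^-1)_22)`.

All sparse factorisations use SuperLU with the symmetric MMD ordering,
which on these matrices reduces fill by an order of magnitude relative to
the default column ordering.  Dense `G*` blocks exist only in oracle code
paths for tests and small problems; the estimation path never materialises
side-2 dense algebra.

## REML

For fixed `w` there are exactly two variance components, so the REML
log-likelihood

    -2 l = (n-p-q) log sigma2_e + q log sigma2_g + log det H_w
           + log det C_lambda + (y'y - sol'rhs) / sigma2_e

profiles analytically over the residual variance
(`sigma2_e = (y'y - sol'rhs)/(n-p)` at fixed `lambda = sigma2_e/sigma2_g`)
and reduces to an exact one-dimensional maximisation over `log lambda`,
performed by bounded Brent search (bounds 1e-6..1e6, tolerance 1e-5 on
`log lambda`, maximum 100 evaluations).  This is the package's own design
choice in place of the average-information iteration that large multi-
component solvers use: with two components the profiled search is exact,
has no step-rejection logic, and each evaluation is a single sparse
factorisation.  The likelihood value is identical (to rounding) to the
dense REML expression `-1/2 [log det V + log det(X'V^-1X) + y'Py]`, which
the tests assert directly.

The polygenic weight is estimated by profiling over a grid, default
`w = 0.01, 0.03, ..., 0.19`.  The uncertainty interval is
`{w : logL(w) > logL(w_hat) - ci_drop}` with `ci_drop = 3.84` (the 95%
quantile of chi-square(1)) applied as a direct log-likelihood drop.  The
conventional likelihood-ratio interval would use half that drop; the
direct drop is the documented convention here and `ci_drop` is
configurable.  The interval is reported as the min/max of qualifying grid
points, extended to the parameter bounds when a grid boundary qualifies.
Ties at the maximum resolve to the smallest `w` (favouring the genomic
information).

Rank-deficient fixed-effect designs are reparameterised by pivoted QR with
a warning rather than rejected.  Starting values are immaterial to the
profiled search; degenerate data (no residual degrees of freedom, all-
monomorphic panels, non-positive-definite `G_w` at `w = 0`) raise typed
errors.

## Prediction

GEBVs for estimation animals come from the sparse mixed-model equations at
the estimated components; prediction error variances are
`sigma2_e (C^-1)_ii` over the genetic block, computed per requested animal
by one triangular solve each.  Animals outside the estimation run are
scored by either

* the extended system: rebuild the equations over the full pedigree with
  the extra animals record-less.  Block elimination guarantees estimation
  animals' solutions are unchanged, which the tests assert to 1e-8; or
* the shortcut `ghat_3 = G_w,31 G_w^-1 ghat_1` for genotyped outside
  animals, exact when `A32 - A31 A11^-1 A12 = 0` (outside animals touch
  the non-genotyped block only through genotyped animals).  The `A31`
  product is obtained from one sparse solve against the full-pedigree
  `A^-1`; the index-3 self block of `G` is never formed, and no PEV is
  produced on this route.  The condition check is off by default (it needs
  dense pedigree algebra) and switchable on.  In the simulated breeding
  program the condition fails — candidates' dams are non-genotyped sows —
  and the shortcut then agrees with the extended system to a correlation
  of about 0.96–0.98 rather than exactly; the exact case is covered by
  constructed pedigrees in the tests.

## The simulator

`ssgblup.simulate` emulates a simplified pig-nucleus program.  Defaults
(the full-scale study conditions): 10 chromosomes of 160 cM; 5000
equidistant SNPs and 500 QTL at uniform-random positions; QTL effect sizes
|effect| ~ Gamma(shape 0.42, rate 5.4) with random signs, rescaled so the
base-population additive variance hits 4.0; heritability 0.2, hence
residual variance 16; a base population of effective size 100 (50 males +
50 females, discrete random mating) drifting 50 generations from unlinked
frequency-0.5 founders; expansion into 150 boars and 1500 sows; then 5
generations of 15000 offspring (constant litters of 10, half male), boars
selected as the top 150 on own phenotype, sows at random.  7000 random
males are phenotyped per generation (35000 records total; a
`phenotype_all_males` switch records all 7500).  Genotyped: the 150 base
boars (also the source of the reference allele-frequency estimates), the
boars selected in the last three generations (450), and 300 generation-6
candidates without phenotypes.  Recombination follows the Haldane model
(Poisson crossovers on the cM map, no interference, independent phase per
chromosome); there is no mutation after the founders.

What the simulator does not emulate: real marker ascertainment (founder
frequencies start at 0.5), variable litter sizes, maternal or litter
environmental effects, non-additive gene action, genotyping error, or
overlapping generations.  Passing tests therefore validate the estimation
machinery and its behaviour under selection and partial genotyping, not
robustness to those real-data features.

Tests and the acceptance script run the program at one tenth the animal
counts (15 boars x 150 sows x 1500 offspring, 700 recorded males per
generation) with the full locus panel and the full 300 candidates — the
panel and candidate set are kept at scale because thinning them erodes the
marker information the comparison is about, while the animal counts
dominate runtime.  The REML parameter-recovery experiment uses 5000
records on a 5000-animal random pedigree with 400 genotyped animals and
300 unlinked marker loci, with the genetic effect drawn exactly from
`N(0, sigma2_g H_w)` via a dense factorisation.

## Numerical choices and edge cases

* Allele frequencies are clamped to [1e-6, 1 - 1e-6]; loci monomorphic in
  the frequency-estimation sample are dropped before `G` is built.
* Sporadic missing genotype calls inside "genotyped" animals are mean-
  imputed per locus with a warning; the method itself treats animals as
  wholly genotyped or not, and the partition stays binary.
* Unknown parents (token "0" by default, configurable) are unrelated base
  animals; there are no genetic groups or metafounders.
* Matrix animal order is always genotyped block first; a stored
  permutation maps back to input order.
* `w = 0` is allowed only when `G` is invertible; the error message
  advises `w > 0`.
* Boar selection ties break by animal id (stable sort), making replicates
  bit-reproducible for a given seed; all randomness flows from one seed
  through per-stage substreams.

## Known limitations

* Single trait, Gaussian response, homogeneous residual variance.
* The two-step comparator fits pedigree EBVs with iid residuals (no
  deregression or reliability weighting), mirroring the reference design
  it reproduces.
* PEVs are exact but computed per animal on request; no approximate
  reliability algorithm for very large systems.
* The genotyped block is materialised densely (intended for up to a few
  tens of thousands of genotyped animals; here exercised to ~10^3).
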