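# Methods

This note records the models, algorithms, defaults and design choices
behind `animalz`, and what the synthetic-data tests do and do not show.

## The models

Both models are Gaussian animal models for a trait `y_i` observed on
`N_d` of the `N_p` pedigree members:

* **AI** (autosomal inheritance): `y_i = beta_0 + x_i'beta + a_i + e_i`
* **AZI** (autosomal + sex-linked): `y_i = beta_0 + x_i'beta + a_i + z_i + e_i`

with `a ~ N(0, sigma2_a A)`, `z ~ N(0, sigma2_z Z)` and
`e ~ N(0, sigma2_e I)`.  `A` is the numerator relationship matrix (twice
the autosomal coancestry).  `Z` encodes sex-chromosome transmission under
ZW (mirror rules for XY via `heterogametic_sex`): a female's single Z comes
from her sire (expected coefficient 1/2, one random copy of his two); a
male receives one of his sire's two copies (coefficient 1/2) plus his dam's
single copy in full (coefficient 1).  Consequences used throughout and
verified by the test suite: female Z-diagonals are exactly 1/2 (inbred or
not), noninbred male diagonals 1, a male's diagonal is `1 + Z_sd` for
parents `(s, d)`, and a 1:1-sex-ratio noninbred population carries
`3/4 sigma2_z` of sex-linked variance.  `sigma2_z` is always reported on
the male (homogametic) scale; summaries derive the female scale
(`sigma2_z/2`), the population scale (`3/4 sigma2_z`) and
`h2 = (sigma2_a + 3/4 sigma2_z)/(sigma2_a + 3/4 sigma2_z + sigma2_e)`.

Assumptions inherited from the underlying theory: gametic equilibrium,
equal allelic effects in both sexes (no dosage compensation), equal allele
frequencies in the sexes, an inert W (or Y), and unknown parents treated as
unrelated base-population members.  Phenotype missingness is assumed
ignorable (missing at random).

Priors: variances get invGamma(1, 0.001) — equivalently precisions get
Gamma(shape 1, rate 0.001) — and fixed effects N(0, 1000), a vague choice
on a standardized trait; both are configurable per `ModelSpec`.
String-valued covariates (sex, hatch year) are treatment-coded factors with
the first sorted level as reference.

## Sparse inverses

`A^-1` and `Z^-1` are assembled as sums of per-individual outer products
`(1/v_i)(e_i - c_s e_s - c_d e_d)(...)'` where `v_i` is the
Mendelian-sampling variance.  Autosomal: `c = 1/2` per known parent,
`v_i = 1/2 - (F_s + F_d)/4` (both parents), `3/4 - F_p/4` (one),
1 (none); inbreeding coefficients `F` come from exact ancestor-restricted
path walks, so no dense pass is ever required.  Sex-linked: coefficients as
in the transmission rules, `v_i = 1/2 - Z_ss/4` when the homogametic parent
`s` is known (either offspring sex), `1 - Z_ss/4` for a male with unknown
dam, `1/2` for unknown-sire cases, founders male 1 / female 1/2.  The
parental diagonals and mate covariances feeding `v_i` and the male
diagonals come from the same path-walk machinery (the gene-flow
decomposition `Z = L V L'`).

Because the sex-linked recursion cannot be checked against an external
implementation here, it is gated on an independent **gene-dropping oracle**:
alleles (base variance 1/2 per copy) are dropped through the pedigree under
the literal transmission rules and the empirical covariance of the summed
allelic values must match `Z` within 3 Monte-Carlo standard errors
(10^5 replicates in the acceptance test).  The matrix-product identities
`A^-1 A = I` and `Z^-1 Z = I` are property-tested on random pedigrees
containing unknown parents, multiple matings and inbreeding (including
parent-offspring matings, whose exact cancellations in `Z^-1` are handled
explicitly).

## Inference

The latent field `x = (a, z, beta)` is a Gaussian Markov random field with
block prior precision `diag(tau_a A^-1, tau_z Z^-1, I/1000)`; its full
conditional has precision `Q = P0 + tau_e W'W` with the sparse incidence
`W`.  All samplers run on a hand-rolled sparse Cholesky (numba, CSparse-style
up-looking, symbolic analysis done once and reused) because no sparse
Cholesky library is part of the dependency set and the replicated studies
need thousands of refactorizations.  The fill-reducing permutation is not
generic minimum degree but the pedigree-aware order "reverse pedigree,
`a_i`/`z_i` interleaved, fixed effects last": pedigree precisions factor
with near-zero fill in reverse topological order (`A^-1` is
`(I-P)'D^-1(I-P)` with `P` strictly lower triangular), and measured fill is
~60x smaller than minimum degree on the study-scale AZI problem.

Two MCMC update schemes target the identical posterior:

* `update="gibbs"`: draw `x` jointly from its Gaussian conditional, then
  each precision from its conjugate Gamma conditional
  (`tau ~ Gamma(a* + n/2, b* + q/2)` with the matching quadratic form).
  Simple and exactly as classically described, but the strong posterior
  coupling between the latent field and its precisions makes variance
  components mix slowly at this data size.
* `update="collapsed"` (default for reporting fits): an independence
  Metropolis step on `theta = log tau` with the latent field integrated out
  analytically — the marginal `log p(theta | y)` needs only the
  factorization of `Q` (log-determinant plus a quadratic form) — followed
  by a joint redraw of `x`.  The proposal is a multivariate t (7 df,
  covariance 1.3x the Laplace fit of the marginal posterior, located by
  Nelder-Mead with a finite-difference Hessian).  Acceptance rates are
  typically 0.6-0.9 and the effective sample size approaches the number of
  kept draws.  Agreement of the two schemes, and of both with closed-form
  conditionals on tiny pedigrees, is part of the test suite.

Defaults: 6000 iterations, 1000 burn-in, 2 chains for reporting fits;
breeding-value vectors are stored every `latent_thin`=10 iterations to
bound memory.  Convergence reporting uses split-R-hat (flag > 1.05) and
ESS (flag < 200); single chains omit R-hat with a NaN.

### DIC

DIC uses the conditional-likelihood focus: deviance
`D = -2 sum_i log N(y_i; eta_i, sigma2_e)`, `Dbar` the posterior mean,
`Dhat` the deviance at the posterior means of each `eta_i` and of
`sigma2_e` (variance scale), `pD = Dbar - Dhat`, `DIC = Dbar + pD`.  DIC is
parameterization dependent; this focus is declared, not the only option.
Two estimators are produced: the plain one (sampled linear predictor) and a
Rao-Blackwellised one that replaces the deviance draw by
`||y - W mu||^2 + ||W(x - mu)||^2` (the zero-mean cross term dropped),
an unbiased estimate of the same posterior mean with much less noise.

### Deterministic quadrature fits

For replicated model comparison, even the Rao-Blackwellised MCMC DIC
carries sampling noise of a few units per fit at affordable chain lengths —
material when a spread of ΔDIC values is compared against a fixed
threshold of 10.  `marginal_fit` therefore computes the DIC ingredients by
deterministic numerical integration: for a Gaussian trait the marginal
posterior of the 2-3 log-precisions is known exactly up to its constant, so
posterior expectations reduce to adaptive Gauss-Hermite quadrature (default
3 nodes per dimension, importance-corrected with exact density evaluations;
3 vs 5 nodes moves DIC by well under one unit).  The conditional
expectation `E[D | theta]` needs `tr(W Q^-1 W')`, computed exactly via a
Takahashi partial inverse of the sparse factor (with a precomputed lookup
plan, one partial inverse costs about as much as a factorization).
`marginal_fit` is validated against long MCMC runs (variance means to a few
thousandths, DIC within the chains' own Monte-Carlo error) and makes the
replicated ΔDIC studies exactly reproducible.  The ΔDIC simulation test and
the stepwise search use it by default (`fit_method="mcmc"` remains
available); full posteriors, credible intervals and trends always come from
MCMC.

## The ΔDIC test

`simulate_test` simulates `S` datasets from given variance components on a
pedigree, imposes ONE fixed missing-data mask on all of them (matching a
calibration that mirrors a real dataset's missingness), fits AI and AZI to
each, and reports the proportion of `ΔDIC = DIC(AI) - DIC(AZI)`
strictly above the threshold (default 10; ties do not reject).  Simulated
without sex-linked variance this proportion estimates the type-I error;
with it, the power.  Per-replicate seeds derive from one master seed, so
results are order- and scheduling-independent.  Replicate failures are
excluded with a warning; more than 5% aborts.

## The synthetic study system

The generator emulates a long-term wild population study: 12 hatch cohorts
(1996-2007), 45 monogamous pairs per cohort, pair survival 0.5 between
years, immigrant probability 0.35 per new breeder, Poisson(5.0) offspring
per pair, offspring sex male with probability 0.483, and i.i.d. phenotype
missingness 0.152.  These values were calibrated once so the preset's gross
bookkeeping matches the target system — about 3000 individuals with a
slight female excess and ~15% of pedigree members unphenotyped — and are
not meant to reproduce its true demography (age structure, mate fidelity,
dispersal, brood-size variation are all simplified).  Phenotypes are
simulated at total variance ~1 with heritability 0.6 grids
(`sigma2_a = 0.6 - 3/4 sigma2_z`, `sigma2_e = 0.4`), optionally with a
standardized sexual-dimorphism fixed effect (the field reference for the
emulated trait corresponds to roughly -1 SD in males).

What passing tests show: the estimator recovers variance components with
small bias and nominal coverage, and the ΔDIC rule is calibrated and has
the expected power profile, *on a pedigree of this size and shape with this
missingness*.  What they do not show: behaviour under non-random
missingness, pedigree error, selection, dominance, maternal effects or an
intersex genetic correlation below 1 — all outside this package's scope.

## Problem sizes and numerical choices

Acceptance-scale runs use S = 200 replicates per condition for the ΔDIC
calibration (quadrature fits) and 100 replicates for bias/coverage (MCMC
fits at 500 iterations, single chain) — sizes chosen as a practical
desk-scale compromise; S = 1000 reproduces the reference setting when more
precision is wanted.  Trait standardization is always pooled across sexes;
within-sex standardization is deliberately not offered because it is
inconsistent with a sex-linked covariance structure.  Degenerate inputs are
policed: zero-variance traits, single-sex pedigrees (allowed with a
warning — identifiability then rests on within-sex contrasts), parents
recorded with the wrong sex, ancestry cycles, and non-positive-definite
precisions (a hard error naming the pivot).

## Known limitations

* Only Gaussian traits with identity link; no maternal/permanent
  environment effects; single trait.
* `Z` theory assumes no dosage compensation and gametic equilibrium; no
  corrections offered.
* Genetic groups for unknown parents are not implemented.
* The quadrature fit returns means/sds of variance components but not full
  credible intervals; use MCMC when intervals matter.
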