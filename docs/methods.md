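# Methods

This note documents the statistical machinery implemented in `gpcv`, the
choices made where several constructions were defensible, and what the
validation on synthetic data does and does not establish.

## Prediction models

### Bayesian-alphabet marker regressions

All four families fit `y = mu + X beta + e` with `X` the centered dosage
matrix and a shrinkage prior on the marker effects `beta_j`:

| family | prior on `beta_j` |
|---|---|
| BRR | normal with one pooled variance `sigma_b^2` |
| BayesA | normal with per-marker variance, scaled-inv-chi²(nu, S) hyperprior (marginally scaled-t) |
| BayesB | point mass at zero with probability `pi`, otherwise the BayesA prior |
| BayesC | point mass at zero with probability `pi`, otherwise a pooled normal slab |

The scaled-inverse-chi-square is parameterized by the density
`p(s²) ∝ (s²)^-(nu/2+1) exp(-S / 2s²)`, so its mode is `S/(nu+2)` and the
conjugate update for a pooled variance given `m` effects is
`(S + Σ beta²) / chi²_{nu+m}`.

Fitting is by single-site Gibbs sampling with the standard conjugate full
conditionals: normal updates for the intercept and each effect, Bernoulli
inclusion updates for the spike-slab families (computed from the exact
marginal Bayes factor of slab vs spike given the current residual), and
scaled-inverse-chi-square updates for all variances. Chains are a pure
function of the seed. Defaults are 12 000 iterations, 2 000 burn-in,
thinning 5 — generous for these conjugate samplers at typical panel sizes;
the validation suite uses shorter chains except where it checks Monte-Carlo
convergence itself.

`pi` is treated as a fixed hyper-parameter (default 0.5), not sampled: in
this workflow it is a tuning dial to be compared across values, not a
quantity to learn. `pi = 1` (empty slab) is accepted as a degenerate
configuration useful in tests. Fixed effects are intercept-only throughout;
missing phenotypes are excluded from training rather than imputed.

**Prior elicitation.** When `S` is not given it is set so that the prior
*mode* of the total genomic variance equals a chosen share `R2geno`
(default 0.5) of the phenotypic variance:
`S = var(y) · R2geno / MSx · (nu + 2)` with `MSx = Σ_j var(x_j)`, and a
`1/(1-pi)` inflation for the spike-slab families so the thinned-out slab
still carries the same total variance. The residual scale is elicited the
same way from the `1 - R2geno` share. Default `nu = 5`. This is the
weakly-informative default rule of mainstream whole-genome-regression
software; a deliberate offset in its constant would be absorbed by any grid
sweep over `R2geno`.

**Validation.** With both variances frozen (`fix_variances=True`), BRR is a
Monte-Carlo ridge regression whose posterior mean has the closed form
`(Xc'Xc + lambda I)^-1 Xc' (y - ybar)`, `lambda = sigma_e²/sigma_b²`; the
suite checks the sampler against it within a Monte-Carlo error bound of
3 SE, where the SE uses the posterior SDs accumulated by the sampler and a
conservative effective sample size of one tenth of the kept draws.

### Kernel mixed models

`y = X b + Σ_i Z u_i + e`, `u_i ~ N(0, K_i sigma_ui²)`. Kernels implemented:

* **G** (additive GRM): `W W' / (2 Σ p_j(1-p_j))` with `W = M - 2·1p'` —
  the standard VanRaden scaling;
* **H** (epistatic GRM): the Hadamard square `G ⊙ G`, PSD by the Schur
  product theorem;
* **Cm / Ce** (categorical): `Cm_ij` = fraction of markers with *exactly*
  equal dosage (genotypes as categories, so heterozygote similarity is not
  graded), `Ce = (Cm⊙Cm + Cm)/2`;
* **Gaussian** `K_ij = exp(-D_ij/h)` on the mean squared dosage distance
  `D_ij = (1/p) Σ_k (M_ik - M_jk)²`. The exponent is negative: a kernel
  increasing in distance is not positive semidefinite and is not a valid
  covariance, so the decaying form is the only defensible reading.

All kernels are defined up to a multiplicative constant which REML absorbs
into the variance component; the suite verifies this equivariance end to
end (identical CV accuracies after scaling a kernel by any c > 0).

**REML.** One kernel: the model is rotated onto the kernel's
eigendecomposition, the residual variance profiled out, and the restricted
likelihood maximized by a bounded scalar search over the log variance ratio
(bounds e^±12, tolerance 1e-10). Several kernels: L-BFGS-B on log variance
components (nonnegativity by construction, bounds e^±25, ftol 1e-8).
`h2_hat` weights each component by its kernel's mean diagonal so that the
estimate is invariant to the arbitrary kernel constant. Kernels must pass a
PSD check (smallest eigenvalue ≥ -1e-8 × largest; 1e-6 relative at fit
time to tolerate accumulated rounding).

**Prediction** for held-out lines uses the conditional-mean algebra
`u_test = C_cross (C_train + sigma_e² I)^-1 (y - X b)` with
`C = Σ_i sigma_ui² K_i`, plus the fixed part. Kernels are computed once on
the full line set and *sliced* per fold — never rebuilt on subsets, which
would silently change allele-frequency centering between folds.

**rrBLUP ≡ G-BLUP.** With `G = WW'/c` and `sigma_u² = c·sigma_b²` the
marker-ridge and kernel-BLUP routes are the same predictor (Woodbury
duality). The package keeps both code paths (`ridge_predict` solves p×p,
`predict_kernel` solves n×n) and the suite requires agreement to 1e-6 on a
200×500 panel, both routes using the sample-mean intercept.

**Gaussian bandwidth.** The multi-kernel ("kernel averaging") default uses
bandwidths `{median(D)/5, median(D), 5·median(D)}` so REML can weight a
narrow, a reference and a nearly-flat kernel. Bandwidths anchored to
*quantiles* of D were considered and rejected: in an unstructured panel
with many independent markers the pairwise distances concentrate tightly
around their mean, all quantiles nearly coincide, and every kernel in such
a grid is almost the same almost-constant matrix. Multiples of the median
keep genuine contrast between the kernels regardless of how concentrated D
is.

## Cross validation

A `FoldPlan` draws r independent random partitions of the n lines into k
folds whose sizes differ by at most one; it is a pure function of its seed
and is shared by *all* models in a comparison — this pairing is the central
design device. Per-fold accuracy is the Pearson correlation between
predictions and held-out phenotypes (invariant to the location/scale shifts
that inflate MSE without changing rankings; MSE is recorded alongside as a
secondary measure). A fold on which any model fails is dropped for every
model and logged, because an unbalanced drop would break the paired
variance accounting. The primary summary is the unweighted mean of fold
accuracies (the fold is the unit of the paired analysis); a pooled
within-replicate prediction correlation is available as a secondary
summary. Only random partitions are implemented; grouped or stratified
schemes (families, generations, sub-populations) are a documented
limitation, as is leave-one-out.

Accuracy against phenotypes understates accuracy against true genetic
values by √h²; `rescale_by_heritability` divides by a *single* full-data
REML estimate on the additive G kernel per trait (one common estimate for
every model compared, otherwise the rescaling would re-rank them). The
genetic-gain scale multiplies accuracy by the selection intensity
`i_q = phi(z_{1-q})/q` (truncation selection of the best fraction q,
random mating); being linear, it transforms paired differences by the same
factor, so equivalence margins can be stated in units of expected gain per
phenotypic SD.

## Comparison machinery

Per-fold differences `d_f = acc_A,f - acc_B,f` have variance
`2 sigma² (1 - rho)` when the two models' fold scores share variance
sigma² and correlate at rho; at rho = 0.8 the paired design needs one
fifth of the unpaired variance, which is where its power comes from
(`power_paired_vs_unpaired` gives the noncentral-t curves).

Four tests run on the mean difference with one shared t machinery
(r·k - 1 df by default; a conservative replicate-averaged variant with
r - 1 df is available since fold overlap across replicates induces
dependence):

* `sd`: H0 d = 0 (two-sided);
* `eq`: H0 |d| > Δ, by two one-sided tests — equivalently the two-sided
  (1-2α) interval lies inside (-Δ, Δ);
* `noi`: H0 d < -Δ (lower bound of that interval above -Δ);
* `sup`: H0 d < Δ (lower bound above +Δ).

Because all four read the same interval, `sup ⇒ noi` and, for Δ > 0,
`eq ⇒ ¬sup` hold for every input, and the suite verifies this
exhaustively. Δ = 0 makes equivalence undecidable and is answered with a
warning and a non-rejection. **There is no default margin**: Δ encodes a
domain judgement about what difference matters (often best expressed on
the genetic-gain scale) and must be supplied by the user. The reported
interval defaults to a seeded nonparametric percentile bootstrap of the
fold differences (B = 2000); the t interval is also exposed, and the two
agree closely for the near-normal difference samples the suite checks. No
multiplicity correction is applied across pairs by default; a Bonferroni
option exists for the all-pairs mode.

**Labels.** Pairwise equivalence rejections form an undirected graph; each
*maximal clique* (via `networkx`) receives one letter and a model's label
is the set of its cliques' letters — so sharing a letter certifies
equivalence, unlike conventional significance letters which certify only
absence of evidence. Directed superiority (or non-inferiority) rejections
form a digraph that must be acyclic (a cycle is reported as an
inconsistency); ordinals are assigned by longest-path layering, the
operationalization chosen here for "consensus of all topological orders":
models incomparable in every topological order share an ordinal, and a
higher ordinal means confidently better. The convention is that
`outcomes[(a, b)] = True` records "a confidently beats b".

## Synthetic data

The generator emulates a biallelic inbreeding-free panel: per-marker
alternate-allele frequencies uniform on [maf_low, maf_high], dosages
Binomial(2, freq) independent across markers and lines (Hardy–Weinberg, no
LD, no population structure, no pedigree). Traits are additive (random
normal effects on randomly placed QTL, centered dosages) plus
pairwise-epistatic (products of centered dosages for random marker pairs),
each component rescaled to its target variance share, plus Gaussian noise.
`sim_fold_scores` draws correlated bivariate-normal fold-score pairs so
the comparison machinery can be tested without fitting any model.

What passing tests therefore show: correctness of the estimators, the
identities, the test logic and the pairing mechanics under a clean
exchangeable design. What they do not show: behavior under LD, relatedness
structure, selection, genotype–environment interaction or non-Gaussian
residuals — all properties of real breeding data that the generator
deliberately omits.

**The epistatic demonstration.** In an unstructured panel the
pairwise-interaction space has ~p²/2 effective dimensions, and no kernel
can learn it unless the training set is comparable in size; with hundreds
of independent markers every model collapses to zero accuracy on a purely
epistatic trait. The demonstration therefore uses a deliberately sparse
panel — n = 600 lines, p = 25 markers, 150 interacting pairs, broad-sense
h² = 0.7, none additive — where the interaction space (300 dimensions) is
learnable. There the median-bandwidth Gaussian kernel reaches ~0.6
accuracy while additive G-BLUP stays at zero, and the paired superiority
test at Δ = 0.01 rejects decisively. The contrast is structural, not
seed-dependent.

## Numerical choices and degenerate inputs

* PSD tolerance: smallest eigenvalue ≥ -1e-8 × largest (builders), 1e-6
  relative at REML entry; negative eigenvalues from rounding are clipped
  in the spectral REML path.
* Monomorphic markers carry no information and are skipped by the Gibbs
  sampler; an all-monomorphic panel is a degenerate-kernel error.
* Zero-variance fold predictions raise an undefined-accuracy error (the
  fold is then dropped, pairwise) rather than returning NaN.
* `rho = ±1` fold scores are constructed exactly (shared normal draw), not
  through a singular covariance factorization.
* Degenerate (all-equal) difference vectors yield point intervals with a
  warning, and the tests fall back to position checks.
* Bootstrap and fold plans use `numpy.random.default_rng` seeded
  explicitly everywhere; nothing reads global RNG state.

## Problem sizes used in validation

The suite validates at sizes where the checked quantities are already
stable: h² recovery on n = 1000 panels (17 traits per heritability level),
the Gibbs-vs-ridge check at 50 000 iterations on a 100×40 panel, type-I
calibration on 2000 simulated null comparisons, the variance-reduction
identity on 10 000 fold pairs, and the epistatic demonstration at
n = 600 with 2×10-fold CV. The acceptance script re-runs the same
computations at equal or slightly reduced sizes.
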