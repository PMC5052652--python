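# Methods

This note records the models implemented in `ornamass`, the defaults and
their units, the numerical choices that matter, and what the synthetic
generators do and do not emulate. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Trees and time-scaling

A `TimeTree` is a rooted tree with branch durations in Ma; tips carry ages
in Ma before present derived from `root_age` minus the root-to-tip path, so
extinct taxa sit above the present. Newick parsing is delegated to
dendropy; a missing branch length is an error, never a silent zero.

Time-scaling starts from the "basic" rule (every node as old as its oldest
descendant tip, using interval midpoints by default or seeded uniform draws
within each (FAD, LAD) interval), which leaves zero-length branches, then:

- **ABA** adds `vartime` (default 1 Ma) to every branch. This is known to
  distort relative tip ages — root-to-tip paths grow by the path's edge
  count — and the tree is re-anchored so the oldest implied tip age is
  kept. The distortion is inherent to the method, not a bug.
- **MBL** raises every branch to at least `vartime`, debiting the time from
  ancestor branches (a node needing room moves older, cascading rootward).
  The root may move older without bound by default; passing `max_root_age`
  makes infeasibility an explicit error instead.
- **Equal** extends the root by `vartime` and repairs each zero-length
  branch by dividing the nearest positive ancestral branch equally among
  itself and the run of zero branches below it; the root extension is the
  donor of last resort. Branches are processed in preorder, so when two
  zero-length siblings compete for one donor the first in preorder borrows
  first — a documented tie-break, since no published rule resolves it.

Consensus over calibration replicates takes the arithmetic per-edge mean on
the shared topology and errors on the first conflicting bipartition.
`mrca_trim` keeps or drops the clade spanned by two tips, suppressing
degree-2 nodes with durations summed, so retained pairwise path lengths are
unchanged.

The covariance `C[i, j]` is the depth of the most recent common ancestor of
tips i and j. Transforms apply in the order κ (branch lengths to the power
κ, covariance rebuilt), δ (entrywise power of the depth matrix), λ
(off-diagonal multiplier). κ and δ are implemented as the standard power
transforms; (λ, κ, δ) = (1, 1, 1) is the exact identity.

## PGLS

`gls_fit` whitens with the Cholesky factor of `C` (no explicit inverse);
σ² is the ML residual rate RSS/n. R² is defined as 1 − RSS/TSS in the
whitened space with TSS taken about the GLS grand mean — a bounded,
reproducible definition chosen because dispersion summaries of this kind
are not uniquely defined for GLS; the whitened residual s.d. is reported
separately and deliberately not equated with any other package's ε.

`pgls_ml` profiles any subset of (λ, κ, δ) by bounded L-BFGS-B from three
starting points (bounds: λ ∈ [0, 1], κ, δ ∈ [10⁻⁶, 3]); K counts the
regression coefficients, σ², and the free transforms; AICc uses n = tips.

`pgls_mcmc` is Metropolis-within-Gibbs over coefficients (uniform ±100
prior), log σ² (uniform on [−20, 20]), the transform pair (λ with κ or δ),
and — when several calibrated trees are supplied — a tree index proposed
from the uniform tree prior and accepted by Metropolis, which marginalizes
calibration uncertainty. Proposal scales adapt only during burn-in,
preserving detailed balance afterwards. Default chain settings are the
published ones (1,010,000 iterations, thin 1,000, burn-in 10,000); every
run requires a seed. `fix_slope_zero=True` pins non-intercept coefficients
at zero, providing the null chain for the Bayes-factor slope test. The
phylogenetic ANOVA is the same machinery with clade-dummy and interaction
columns and proportion-above-zero readouts; no separate code path exists.

The ornamented-mass threshold is `exp(b0 + b_Orna)` in kg — the model's
predicted mass of an ornamented taxon. PGLS prediction is extrapolation;
the function logs a warning to that effect with every call.

Ancestral states for continuous traits use the re-rooted GLS estimate: the
tree metric is re-rooted at the target node and the estimate is the GLS
grand mean with variance σ̂²/(1ᵀC⁻¹1). A test verifies equivalence with
direct numerical maximization of the joint tips-plus-node density.

## Threshold model

The binary trait is the sign of a latent liability evolving by Brownian
motion jointly with the continuous trait; the 2×2 rate matrix fixes the
liability rate at 1 and the threshold at 0 (identifiability). Tip
liabilities are Gibbs-sampled from their conditional normals truncated to
the observed side of 0, using the Kronecker structure R⁻¹ ⊗ C⁻¹ so each
update is O(n); r (uniform prior on [−1, 1], implemented as a reflected
random walk, which induces the same uniform prior as a spherical
parameterization would), the continuous rate, and both root means move by
Metropolis. Truncated-normal draws use the inverse CDF in the body and an
exponential rejection sampler beyond 6 s.d. Default 1,020,000 generations.
Liability-sign consistency is asserted on every retained draw. The
posterior mean of r² is reported as the comparable "mean R²" quantity of a
threshold-correlation analysis, without claiming it equals any specific
regression R².

## Discrete characters

The pruning likelihood uses closed-form 2×2 transition matrices and
eigendecomposition (scaling-and-squaring fallback) for the 4-state model.
Root state frequencies default to the observed tip frequencies
("empirical"); flat and stationary are available. Polytomies are refused
by likelihood code; the I/O layer accepts them.

RJMCMC explores four binary rate models (one rate, two rates, either rate
zero) with within-model multiplicative random-walk updates under an
exponential rate prior whose mean is itself uniform on (0, 10). Jumps
propose a model uniformly among the other three and redraw the affected
rates from the prior, so the acceptance ratio is exactly the likelihood
ratio — a Jacobian-free sampler that is valid because the proposal equals
the prior. Fixed-model mode (`ER`/`ARD`) disables jumps and yields the
plain Metropolis chains used for Bayes-factor tests. Defaults are the
published 2,010,000/1,000/100,000 settings; a pipeline-level divisor
scales them for desk runs and logs the scaling.

The dependent model combines two binary traits into four states with
double transitions structurally zero: 4 free rates in independent mode, 8
in dependent mode, sampled the same way. The reported contrast is
rate(mass gain | ornamented) / rate(mass gain | unornamented). With
pairwise-equal rates the dependent likelihood reproduces the independent
one (nesting check in the tests).

Node fossilization runs two equal-rates chains with an internal node
constrained to each state; the Bayes factor is 2×(log harmonic mean
difference), positive favouring the first-listed state. Harmonic-mean
marginal likelihoods are computed by log-sum-exp and carry a batch-means
Monte-Carlo s.e., because the estimator's instability is well known; large
BF values with large s.e. should not be trusted.

Stochastic maps draw node states from conditional pruning distributions
and branch histories by rejection sampling (50 attempts) with an exact
uniformization bridge as fallback, so endpoint conditioning is exact; tip
states are honoured on every map.

## Generalized Hansen models

Per-node recursions accumulate the decay product W, the trait variance V
and the linear mean weights along each branch's segments, giving
Cov(i, j) = V[mrca]·W_i·W_j / W²[mrca]; fossil tips integrate variance only
over their realized lifespans. `root_mode='stationary'` seeds the root
with variance σ²/(2α) of the root regime and pins the root mean to that
regime's optimum; `'estimated'` adds the root value as a parameter. BM
variants always estimate the root (no stationary distribution exists), and
passing α = 0 to an OU model is an error directing to the BM variants; the
α → 0 limit is continuous (verified to 1e−6).

Optima enter the mean linearly and are profiled by GLS, so the numerical
search runs only over log α and log σ² (bounds 10⁻⁹–50, five seeded
multi-starts — the documented pathologies of multi-peak OU optimization
motivate the restarts). Standard errors come from the numerical Hessian of
the full parameter vector with delta-method back-transformation; a
singular Hessian leaves SEs absent and flags the fit. Diagnostics mirror
the failure modes seen on over-heterogeneous trees: `alpha_degenerate`
(α < 10⁻⁶/Ma), `theta_outside` (an optimum beyond twice the data range),
`theta_unreliable` (SE exceeding the estimate). Model averaging computes
AICc weights within each map over unflagged fits, excludes flagged fits
(listed separately), weight-averages the optima, and reports the
phylogenetic half-life ln 2/α with its fraction of tree depth. The
regime at a node is the painting's state at the tipward end of its branch;
the root takes the oldest segment's state.

## Synthetic data

The generators state one world and keep it: a birth–death tree (birth 0.1,
death 0.05 per Ma) grown until 111 total tips with extinct lineages kept
as fossil tips (the present is placed a random way into the inter-event
gap so no tip has a zero branch); a symmetric ornament process
(0.012/Ma, retried until the ornamented count lands in 30–46, the band
around the empirical 38/111 split); log mass from the two-optimum OU truth
α = 0.131, σ² = (1.358, 0.313), θ = (2.394, 7.241) on the true painting;
and a clade of about half the tips flagged as the maniraptoriform
analogue. A regression-style generator (intercept 1.98, slope 2.09,
residuals from a λ/κ-transformed Brownian covariance, defaults λ = 0.9,
κ = 0.3) supports the PGLS recovery tests. All generators are
deterministic under their seed and return truth sidecars.

What the fixture does not emulate: non-random fossil sampling, clade-biased
taxon selection, body-mass measurement error, ornament coding ambiguity,
or correlated diversification — so a green recovery test establishes that
the estimators work on data generated by their own model class at the
study's size, not that the empirical conclusions are correct. The
dataset-level posterior quantities of the original study depend on its
unpublished 111-taxon supertree and are not reproducible from this
package; only structurally analogous recoveries and the instantly
derivable printed numbers (half-life from α, kg back-transforms of θ,
exp of the regression coefficients, the rate-contrast ratio) are checked.

The femoral-length allometry is a configurable power law `a·Lᵇ` with no
default coefficients, because the source equation's constants are not part
of this package's inputs.

## Numerical and scaling choices

- Natural logs everywhere; Bayes factors on the 2×log scale with verdicts
  at >5 (strong) and >10 (very strong).
- AICc requires n > K + 1 and errors otherwise; n = number of tips.
- Chain lengths default to the published settings; the pipeline exposes a
  single `scale_divisor` (tests and the acceptance script use 200–4,000)
  and logs the scaled settings. Desk-scale chains trade Monte-Carlo
  precision for minutes of runtime; thresholds in the test suite were
  calibrated to that scale before freezing.
- MCMC acceptance rates outside [0.05, 0.7] after burn-in produce warnings,
  not errors; short scaled chains trip these warnings benignly.
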