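# Methods

This note documents the statistical models implemented in `allometree`,
the choices made where the design was genuinely open, and what the
synthetic-data verification does and does not establish.

## Model and likelihood

All analyses assume trait evolution on a rooted, time-calibrated phylogeny
(branch lengths in Myr) under Brownian motion. For tips *y* with design
matrix *X*,

> *y* ~ N(*X*β, σ² *V*),  *V*ᵢⱼ = shared root-to-MRCA path length,

and every quantity — likelihoods, GLS estimates, Bayesian posteriors,
marginal likelihoods — is computed through a single primitive: the pruning
(contrast) transform *U* = *L*⁻¹*M* with *V* = *LL*ᵀ, obtained in one
postorder pass (numba-compiled) without materializing *V*. Polytomies are
handled by sequential pairwise combination, which is exact for Brownian
covariance (equivalent to zero-length resolution). Zero combined branch
lengths raise a singularity error; a branch-length floor is available at
the I/O layer but defaults to 0.

**Masses** are log₁₀ grams everywhere; inputs in raw grams are aggregated
across duplicate species rows by sample-size-weighted arithmetic mean on
the raw scale and logged once at the boundary. The log base and mass unit
are a package-wide convention stated here because downstream coefficients
(curvature, trend slopes) are unit-dependent.

**R²** is reported on the whitened (phylogenetically decorrelated) scale:
1 − RSS/TSS with TSS taken about the GLS (phylogenetically weighted) mean.
This choice is stated wherever R² appears, since an ordinary-scale R² can
differ substantially.

## Priors

Bayesian fits use Zellner's unit-information g-prior,
β | σ² ~ N(0, g·σ²(*X*ᵀ*V*⁻¹*X*)⁻¹) with g = n, and a diffuse proper
inverse-gamma IG(0.001, 0.001) on σ². The g-prior shrinks estimates by
n/(n+1) — numerically indistinguishable from a flat prior for estimation —
but, unlike an improper flat prior, yields marginal likelihoods that are
comparable across models of different dimension. This is essential because
model comparison by Bayes factor is a primary output. Note that the
g-prior is conditioned on the (possibly rate-scaled) covariance, so in the
variable-rates model the coefficient prior co-varies with the rate
configuration; this is the standard unit-information construction and is
part of the model definition.

## Variable-rates regression

Branch *b* may carry a multiplicative scalar *r_b*; the residual
covariance uses branch lengths *t_b·r_b*. Priors: the number of shifts is
geometric with mean 2 by default (Poisson optional); shifted branches are
uniform among the B branches; scalar magnitudes are log-uniform on
[1/500, 500]. Sampling is by reversible jump over the shift configuration
with β and σ²_b integrated out analytically (collapsed marginal
likelihood), which mixes far better than conditional updates; β and σ²_b
are then drawn from their exact conditional posterior for every retained
sample, so the output is a draw from the full joint posterior. Moves: add
(scalar proposed from its prior, Jacobian 1), delete, and a log-normal
random walk on an existing scalar whose step is tuned during burn-in to a
20–40% acceptance rate and then frozen. Two independent chains run by
default; split-chain potential scale reduction on σ²_b and all
coefficients above 1.01 triggers a warning and a flag on the posterior,
never silence. Identical seeds give bit-identical chains.

Desk-scale defaults (40,000 iterations × 2 chains, quarter burn-in,
thinning 20) are chosen so a 100-tip analysis completes in seconds;
production-scale settings are plain configuration values.

**What branch-level scalars can and cannot recover.** Because shifts are
per-branch (no whole-clade single-scalar moves), a clade evolving at an
elevated rate is detected in aggregate — elevated posterior-mean scalars
and strong evidence for the true configuration — but an individual branch
only earns a confident (posterior probability > ½) shift when its own
realized change is large relative to background, which under Brownian
noise happens on roughly a third of the branches of a ×10 clade. Per-branch
posterior *medians* therefore understate clade-wide heterogeneity at
desk scale. Consequently:

- the **median** rate-scaled tree (branch length × branchwise posterior
  median, the display convention) is conservative;
- pathwise rates for analysis default to the **mean** summary — per-sample
  path sums averaged across the posterior — and trend regressions run on
  the **mean**-scaled tree, which keeps uncertain rate mass in both the
  predictor and the error model. The median/mode summaries remain
  switchable; the per-species median across posterior path sums is *not*
  the path sum of branchwise medians (medians do not commute with sums),
  and both collapse to the time tree when no single branch reaches
  posterior probability ½.

## Evidence and significance

Stepping-stone sampling integrates from prior to posterior along powers
placed at Beta(0.40, 1) quantiles (K stones include the prior stone;
the identity log m = Σₖ log E<sub>βₖ</sub>[L^(βₖ₊₁−βₖ)] is evaluated by
log-sum-exp with a delta-method Monte Carlo standard error, treating
within-stone draws as independent — exact for the conjugate calibration
model, an approximation for MCMC stones). For homogeneous-rate models the
marginal likelihood is closed-form under the conjugate priors and no
sampling is needed; for variable-rates models the stepping stone runs on
the collapsed rate-scalar space, whose evidence equals the full model's.
Desk-scale defaults are 50 stones × 20,000 iterations.

Bayes factors are reported as BF = 2(log m₁ − log m₀), so support for
model 1 is positive and BF > 2 is the conventional positive-support
threshold (the equivalent formula is sometimes printed with a negated
sign; the orientation used here is the self-consistent one).

Px is the fraction of a parameter's posterior on the opposite side of
zero from its median; Px < 0.05 declares a direction. Px is one-tailed by
construction (maximum ½; exact zeros count as non-crossing; an all-zero
posterior returns ½ with a warning). Under a true null with near-flat
priors Px is approximately uniform on (0, ½), so the expected rate of
Px < 0.05 under the null is ~10%, not 5% — Px is a descriptive posterior
probability, not a calibrated two-sided test, and users comparing it to a
frequentist α should halve the threshold. The package reports Px as
defined and leaves the interpretation explicit here.

## Allometric model family

Variants: `single` (intercept + slope), `multiple-slopes` (intercept and
slope per group, restricted to groups with ≥ 20 species — two parameters
per group at ten observations per parameter; the threshold is inclusive),
`quadratic` (single curvilinear rule; the squared term is computed on
mean-centered log body mass for conditioning and coefficients are reported
back-transformed to the raw scale), `quadratic+covariates` (e.g. basal
metabolic rate, brain-network mean shortest path, grey/white matter as
extra columns), and an experimental `asymptotic` saturating form
y = c − d·exp(−k·x) with k profiled by 1-D optimization — a stand-in for
power-curve alternatives whose exact published forms vary.

Diagnostics: the marginal slope β₁ + 2β₂x and its percentage reduction
across the observed range; per-group slopes from the multiple-slopes fit
against group median body mass by Spearman rank correlation (average
ranks; exact permutation p below 10 groups, t-approximation otherwise;
exclusion lists supported).

## Trends

Relative brain mass is the residual from the posterior-median quadratic
fit (a joint model with body as covariate is available as a switch and
agrees in simulation). The trend regression is Bayesian phylogenetic
regression of relative brain mass on pathwise rate, on the rate-scaled
tree, so the larger residual variance of high-rate lineages sits in the
error model rather than masquerading as a trend. Per-group variants share
a common intercept with group-specific slopes — the parameterization under
which a clade-level trend (elevated residuals in the clade with elevated
pathwise rates) is identified; freeing per-group intercepts (a switch)
leaves only within-group covariation and is much weaker. A pathwise-rate
predictor with zero variance (no detected rate heterogeneity) raises an
error: the trend is unidentifiable without it. Group-specific slopes
require ≥ 20 species per group; smaller groups pool into a `rest`
category.

## Branchwise reconstruction

Internal-node states are conditional expectations under the Gaussian model
given the tips (BLUP), computed by upward–downward message passing on the
rate-scaled tree in linear time, with a flat prior on the root level (so a
two-tip tree reconstructs its root as the branch-length-precision-weighted
mean). Node-specific prior means carry the directional structure: body
mass uses α + β × (node pathwise rate) from the maximum-likelihood fit of
tip body mass on tip pathwise rate from a body-only variable-rates run
(the phylogenetic expression of Cope's rule); if the body run detects no
rate heterogeneity the pathwise predictor is constant and the trend term
drops out automatically. Brain mass uses the quadratic prediction at the
node's imputed body mass plus trend slope × node pathwise rate
(group-specific where a node lies wholly within a group with an estimated
trend), plus the Brownian-conditional residual component.

Branch changes are descendant − ancestor between point reconstructions
(posterior-median parameters); imputation uncertainty is *not* propagated
into the downstream ANCOVA — a documented limitation shared with the
realized-visualization convention this follows. Per-Myr proportional
change is the geometric rate 10^(Δ/t) − 1, flagged undefined on zero-length
branches. Z columns are z-scores of |Δ| over all branches per trait.

The clade comparison regresses branchwise brain change on body change with
a group factor ("accounting for ancestry" is implemented as an optional
start-of-branch brain-value covariate, on by default and switchable, since
the published description is underspecified); all-pairs comparisons of
covariate-adjusted group means use the studentized range distribution at
family-wise α = 0.05, and the compact letter display is an exact minimal
clique cover of the non-significance graph (group counts are small enough
for exhaustive search).

## Synthetic studies

The generator emulates: a pure-birth (Yule) tree rescaled to 100 Myr
(optionally partitioned into named monophyletic groups hanging off a
backbone, so order-like clades exist by construction); body mass by
Brownian motion, root 1.5 log₁₀ g (≈30 g), σ²_body = 0.04 per Myr (tip
spread spanning the few-gram to multi-tonne range) and drift +0.005 per
Myr (+0.5 log₁₀ units per 100 Myr — a gentle Cope's-rule pull); brain mass
β₀ = −1.5, β₁ = 0.9, β₂ = −0.019 (placing a 30 g mammal near a 0.35 g
brain and a 5-tonne one near 4 kg, with the mammal-wide curvature);
residual σ²_b = 0.001 per Myr (≈0.3 log₁₀ units of relative brain mass at
the tips). Selected clades receive residual rate scalars; within a shifted
clade, per-branch scalars are drawn log-normally around the clade value
(log-sd `rate_jitter`, default 1.0) — *branch-specific* rates, which is
both the biologically natural picture of episodic selection and the
condition under which a pathwise-rate trend is statistically identifiable:
a clade with one uniform rate and a uniform trend is confounded with a
single Brownian excursion of the whole clade. Trends add
slope × (r·t) to the residual per branch of the trending clade (default
0.01 per rate-scaled Myr, i.e. roughly one log₁₀ unit of relative brain
mass accumulated over a trending clade's history — a strong,
primate-like trend). True node states, branch scalars and all parameters
are saved in a truth manifest.

**What passing recovery tests shows — and what they do not.** The
generator matches the analysis model exactly (Brownian residuals, clade
rate structure, trend construct). Recovery therefore verifies the
estimation machinery, not the model's adequacy for real data: real
datasets have measurement error and intraspecific variation, non-Brownian
tails, taxonomy errors, correlated predictor noise and calibration
uncertainty in the tree, none of which are emulated. Desk-scale chain
lengths also leave per-branch shift probabilities conservative (see
above); full-scale analyses should use longer chains and check the
convergence diagnostics the posterior carries.

## Numerical conventions

- Traversals and tip order are deterministic for a fixed input; all
  randomness flows from explicit integer seeds, and chains/streams derived
  from a master seed use fixed offsets.
- Duplicate species rows aggregate by weighted mean before analysis; rows
  without sample sizes get weight 1.
- Pruning vs dense-likelihood agreement is verified to 1e−8 on hundreds of
  random trees; BLUP vs dense joint-Gaussian conditioning likewise.
- Spearman p-values switch from exact permutation to the t-approximation
  at 10 groups; Tukey p-values use the studentized-range survival
  function with the model's residual degrees of freedom.
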