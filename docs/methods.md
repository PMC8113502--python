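# Methods

This note documents the models and procedures implemented in `phylotraits`,
the defaults and why they were chosen, the numerical strategy, and what the
synthetic-data tests do and do not demonstrate.

## The phylogenetic multilevel model

Each of the 12 leaf traits (leaf area cm², SLA cm² g⁻¹, thickness mm,
toughness kN m⁻¹, DMC mg g⁻¹, foliar N, P, Ca, K, Mg, Al mg g⁻¹, N/P) is
modelled separately on the natural-log scale.  The observational unit is the
individual tree:

    log(Y_i) ~ Normal(mu_i, sigma)
    mu_ijk   = alpha0 + beta * site_i + a_plot[j] + a_species[k]

Site is categorical with treatment contrasts and the lowest elevation
(1000 m) as the reference; plots get ordinary Gaussian random intercepts
(`tau_plot`); the species intercept is the sum of two components with joint
covariance `Sigma_phyl` — `tau_phyl^2 + tau_ind^2` on the diagonal and
`tau_phyl^2 * rho[m,n]` off it, where `rho` is the Brownian-motion
correlation implied by the phylogeny (depth of the most recent common
ancestor of two tips, divided by the geometric mean of the two tip depths).
The log transform makes all model math unit-covariant, so declared units are
never converted.

`rho` is computed per pair (cov2cor) rather than assuming an ultrametric
tree; polytomies are fine (Brownian covariance is well-defined on them), and
effectively identical tips (zero-length splits) are allowed with a warning —
any near-singularity is handled by the global diagonal ridge (below).

### Marginal likelihood

The response is Gaussian, so plot and species effects are marginalized
analytically: `y ~ N(X theta, V)` with

    V = Zp tau_plot^2 Zp' + Zs (tau_phyl^2 rho + tau_ind^2 I) Zs' + sigma^2 I.

V is n×n but the random-effect structure has rank J+S (plots + species), so
the likelihood is evaluated via the Woodbury identity: with `U = [Zp | Zs]`
and `D` the block-diagonal random-effect covariance,
`det V = s2^n det(I + W G W / s2)` where `W = D^{1/2}` (symmetric square
root, computed from one cached eigendecomposition of `rho`), `G = U'U`, and
`s2 = sigma^2 + ridge`.  All sufficient statistics (`U'U`, `U'X`, `U'y`,
`X'X`, `X'y`, `y'y`) are precomputed once per trait, making each evaluation
O((J+S)^3) ≈ O(61^3) regardless of n.  Unit tests verify agreement with an
explicitly constructed dense multivariate-normal density to 1e-8.

A ridge of 1e-8 is always added to V's diagonal before factorization; it
changes log-likelihoods by ~1e-7 at most and guarantees positive
definiteness at `sigma -> 0` and for degenerate trees.

### ML backend

Profile likelihood: for fixed `(tau_plot, tau_phyl, tau_ind, sigma)` the
fixed effects have the closed-form GLS solution, so the optimizer works on
the 4-dimensional log-SD scale (L-BFGS-B, bounds [-12, 6], ftol 1e-13) from
5 seeded starts; ties are broken by log-likelihood.  The response is
mean-centered internally and the offset restored into the intercept, which
makes the variance-parameter optimization exactly invariant to shifting all
responses by a constant.  Fixed-effect standard errors come from
`(X' V^{-1} X)^{-1}` at the optimum.

Estimates on the boundary (`tau -> 0`) are reported as the back-transformed
bound (~6e-6); the `log_sd_at_bound` diagnostic flags them.  When `rho = I`
(star phylogeny) only `tau_phyl^2 + tau_ind^2` is identified; the individual
components then sit anywhere on that ridge, but their summed variance
fraction remains stable, and the test suite checks exactly that.

### MCMC backend

The sampler works on the same marginal likelihood over
`(alpha0, beta, log tau_plot, log tau_phyl, log tau_ind, log sigma)` —
sampling the marginalized model rather than the latent effects is what makes
a general-purpose ensemble sampler adequate here.  Priors: Normal(0, 5) on
intercept and contrasts (log scale), half-t(df 3, scale 2.5) on every
standard deviation (with the log-scale Jacobian).  These are deliberately
weakly informative; the scales are package defaults, declared rather than
estimated.

Sampling uses affine-invariant ensembles (emcee) with a 0.8/0.2 mixture of
differential-evolution and snooker moves, which mix much better than the
default stretch move on this correlated posterior.  `chains` independent
ensembles (default 2) of 16 walkers are initialized by scattering (sd 0.25)
around a quick internal ML fit, run for `warmup` steps (discarded) plus
`iters` retained steps.  Defaults are 10,000 + 10,000; the test suite runs a
reduced 500 + 500 configuration, which is enough for calibrated interval
coverage though not for split-Rhat < 1.01.  Convergence is assessed by
rank-normalized split-Rhat treating every walker as a chain; a result whose
largest Rhat exceeds the threshold is returned with `converged=False`, never
silently.  A `target_accept` setting is accepted and recorded for interface
compatibility with step-size-adapting samplers, but ensemble moves have no
step size to adapt.  Runs are exactly reproducible by seed.

95% intervals are highest-density intervals computed by the sorted-window
method (shortest window containing 95% of sorted draws; ≥100 draws
required).  An effect is "credibly non-zero" when its HDI excludes zero.

### Variance decomposition

On the log scale the five variance components are: the variance of the
fitted fixed effects over the realized design (`var(X beta-hat)`,
Nakagawa–Schielzeth convention extended to the two-component species level),
`tau_plot^2`, `tau_phyl^2`, `tau_ind^2` and `sigma^2`; fractions are each
term over their sum.  For MCMC the fractions are computed per draw and
summarized by the posterior mean (the sum of the means is exactly 1 because
the per-draw fractions sum to 1); computing fractions at the posterior means
of the parameters is a slightly different estimator that we do not use.

## Rao quadratic entropy

For a single trait the dissimilarity is `d_ij = (x_i - x_j)^2 / 2`, under
which Rao's Q is identically the weighted variance.  Per trait and site:

* individuals are weighted equally within species; species are weighted by
  relative basal-area abundance, renormalized over the species actually
  sampled for traits at that site (field designs never sample every species);
* `Q_within = sum_s p_s Q_s`, `Q_between` = Q over species means with
  weights `p_s`, and `Q_total` (computed independently over all individuals
  with weights `p_s / n_s`) equals their sum exactly — the law of total
  variance makes the decomposition additive to machine precision, and the
  tests assert 1e-10;
* traits are first standardized by their range — the observed min–max over
  **all individuals of all sites pooled**, not per site, so entropies are
  comparable across sites.  A literature-derived "possible range" would be
  an alternative; the observed pooled range is used because it requires no
  external data, at the cost of dataset dependence.

## Trait space

Species means are arithmetic means per species on the raw trait scale.  PCA
z-scores the species-mean matrix per trait and eigendecomposes the
correlation matrix; components are ordered by eigenvalue, and the sign of
each loading vector is fixed by making its largest-magnitude entry positive.
Tukey HSD compares sites per trait with **species as the replication unit**
(one log-scale mean per species) — individuals would pseudo-replicate since
they share species identity; raw-scale site means are reported next to the
letters.  Compact letters use the insert-and-absorb algorithm; groups
sharing a letter are not significantly different at alpha = 0.05.

## Trait networks

Per site, Pearson correlations between all trait pairs over species means
(raw scale, matching how species-mean trait matrices are usually analysed);
p-values from the t transform on n-2 df.  Edges require p < 0.05 with no
multiple-testing correction (the threshold is a screening device, not an
inference); the integer weight is `floor(|r| * 10)` — truncation, not
rounding — and the sign is stored separately.  Traits with no significant
partner stay in the node set as isolated nodes.

Metric conventions (these matter and are pinned by worked examples in the
tests):

* **edge density** counts all nodes, including isolated ones, in the
  denominator `n(n-1)/2`;
* **average path length** and **betweenness** use the *unweighted* graph —
  the integer weights encode correlation strength, not distance — and the
  path-length average runs over reachable pairs only (unreachable pairs are
  excluded, not set to 0 or infinity);
* **average clustering** averages local clustering over nodes of degree ≥ 2
  only (it is undefined below that).

With these conventions, a 12-node network with 13 edges has density 0.197,
one with 31 edges has 0.470, and a 31-edge network on 10 connected nodes
(two isolated) with distance multiset {31×1, 13×2, 1×3} has average path
length 1.333.  Note that adding an edge can *increase* the average path
length when it newly connects components (previously excluded pairs enter
the average); monotonicity holds only while the reachable set is fixed.

## Synthetic data

The generator emulates the target study design: 3 elevation sites
(1000/2000/3000 m), 3 plots per site, 20/20/12 species assigned to sites
disjointly (complete turnover) and at random with respect to the phylogeny,
8–10 individuals per species (uniform; ~421–473 trees), one global Yule tree
rescaled to unit depth whose terminal edges get a common 5% extension so no
two tips coincide.  Traits are drawn from exactly the fitted model — MVN
species effects over the tree, Gaussian plot effects and residuals, fixed
site contrasts — so there is no model mismatch by default; a `heavy_tails`
toggle (t(3)-scaled residuals) exists for robustness experiments.
Abundances are symmetric Dirichlet (concentration 1.5, giving the uneven
shares typical of basal-area data).

Default generating parameters per trait are chosen as realistic magnitudes
for tropical montane canopy trees (e.g. SLA ~110 cm² g⁻¹, N ~20 mg g⁻¹) with
qualitative gradient trends (SLA/N/Ca/N-P declining, thickness/toughness/DMC
increasing with elevation) and variance-component emphases (phylogeny
dominant for most traits, elevation for SLA/thickness/Ca, large residual for
K); they are documented in `default_trait_params`.

Because the generator matches the model exactly, passing recovery and
coverage tests demonstrates correctness of the implementation, not
robustness to real-data features: measurement error structure, lognormal
misfit, shared species across sites, phylogenetic signal in sampling
effort, or non-Brownian evolution are all absent.  Trait–trait correlations
are absent from the default tables too; network tests use
`simulate_correlated_means` with an explicit target correlation instead.

## Problem sizes in the tests

Recovery tests run 20 ML replicates and 10 reduced-scale MCMC replicates at
the study's design size (52 species × 9 individuals); the Rao
within-fraction check uses 400 species × 50 individuals because the realized
between-species variance has relative sd ≈ sqrt(2/n_species), which must be
well below the ±0.05 check band.  Graph metrics are cross-checked against a
brute-force BFS/enumeration implementation on 50 random graphs with ≤10
nodes.

## Known limitations

* One trait at a time: no multivariate response, no multi-trait Rao.
* Gaussian-on-log-scale responses only.
* ML standard errors for variance parameters are not reported (profile
  intervals would be the natural extension); the MCMC backend provides
  full uncertainty.
* The ensemble sampler's split-Rhat (walkers as chains) is conservative at
  short runs; reduced-scale fits are typically flagged unconverged even when
  interval coverage is already calibrated.
* Species appearing at several sites are not supported by the generator's
  default disjoint assignment (an overlap option is out of scope).
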