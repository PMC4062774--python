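# Methods

## The estimand

A continuous diagnostic marker Y is measured in non-diseased (group 0) and
diseased (group 1) subjects, with high values indicating disease. A test
"positive if Y > c" has sensitivity Sen(c) = 1 − F1(c) and specificity
Spe(c) = F0(c). The optimal threshold c* maximizes the generalized Youden
index

    U(c) = Sen(c) + R · Spe(c),     R = (NC/NB) · (1 − π) / π,

where π is the disease prevalence and NB/NC the ratio of the net benefit of
detecting a diseased subject to the net cost of falsely flagging a healthy
one. R = 1 (π = 0.5, NB/NC = 1) recovers the classical Youden index; a rare
disease or a costly false positive inflates R and pushes c* toward high
specificity. At an interior smooth maximum, c* solves the density-crossing
equation f1(c*) = R·f0(c*).

## Bayesian estimation

Each group's marker distribution is given a parametric or semi-parametric
model and a posterior sample of size K is drawn by MCMC. Pairing draw k of
group 0 with draw k of group 1 (the chains are independent) and maximizing
U draw by draw yields K thresholds — a sample from the posterior of c*.
We report its KDE mode, median, and mean, an equal-tail (quantile) credible
interval, and a highest-posterior-density (HPD) interval. Uncertainty in π
(from a cohort of Bernoulli observations, via its Beta posterior) and in
NB/NC (resampled from elicited expert values) can be propagated by giving
each draw its own weights (`sample_weights`).

### Group models

* **Gaussian** — Gibbs on (μ, σ²) with μ ~ N(0, 10⁶) and a flat prior on
  log σ (truncated to ±20, never active in practice).
* **Student-t** — location-scale t(μ, σ, ν), written as a normal scale
  mixture with a latent variance V_i per observation:
  y_i | V_i ~ N(μ, V_i), V_i ~ Inv-Gamma(ν/2, νσ²/2). Gibbs updates of
  V, μ, σ² are conjugate; 1/ν has a uniform prior on (0, 1] and is updated
  by a random-walk Metropolis step (proposal SD 0.08). σ is the *scale*:
  the SD does not exist for ν ≤ 2, so scale is the only parameterization
  valid on the prior's whole support, and the simulation designs' "standard
  deviation" for t variables is interpreted as this scale.
* **Dirichlet-process mixture (DPM)** — y_i ~ N(μ_{z_i}, σ²_{z_i}) with
  cluster parameters drawn from a random measure G ~ DP(M, G0);
  G0 is the conjugate normal/inverse-gamma
  μ_c | σ²_c ~ N(m, σ²_c/k), σ²_c ~ Inv-Gamma(a, b), with m = sample mean,
  k = 0.01, a = 2, and a hierarchical scale b ~ Gamma(1, 1/s²) (s² the
  sample variance) refreshed each sweep from the sampled cluster variances
  (its conditional is Gamma(1 + aK, 1/s² + Σ_c 1/σ²_c)). The hierarchy
  matters: a fixed data-scaled b equal to the *pooled* variance is an
  order of magnitude above the within-cluster variances whenever the group
  is itself a mixture, which inflates cluster scales and biases the
  threshold; the hierarchical b self-scales to the cluster spread. The
  concentration has an M ~ Gamma(2, 2) prior updated with the
  Escobar–West auxiliary-variable step. Cluster assignments move by
  collapsed conjugate Gibbs (the marginal cluster predictive is a
  closed-form Student-t).

  A posterior **draw of the distribution** is a draw of G, not the Polya-urn
  predictive mean: given the partition, the occupied-atom masses and the
  leftover mass are jointly Dirichlet(n_1, …, n_K, M), and the leftover
  falls on G0's closed-form t predictive. Sampling these weights matters:
  plug-in weights n_c/(n + M) are nearly deterministic for well-separated
  clusters and therefore understate mixture-weight uncertainty, which
  measurably undercovers the threshold in the mixture designs below.

All samplers are numba-compiled, deterministic given (data, prior, seed),
and return K = n_iter − burn_in draws (optionally thinned). Defaults for
data analysis: 2000 retained draws after 1000 burn-in for Gaussian/t, 3000
after 1000 for the DPM. The simulation harness uses 1000 after 500.

### Maximizing the Youden function per draw

Each draw's U(c) is evaluated on a bracketing grid spanning both groups'
supports (posterior locations ± 6 scales; 512 points for single fits, 256
in the simulation harness), and the chosen grid point is refined by
Newton–Raphson on g(c) = R·f0(c) − f1(c) with analytic density
derivatives; if Newton leaves the bracket or the stationary point is not a
maximum, a golden-section pass inside the bracket finishes the job.

When the two group densities cross more than once, U has several local
maxima and the *global* argmax is a discontinuous functional: with two
near-tied maxima, infinitesimal posterior perturbations flip the argmax
between distant crossings, and the resulting posterior is bimodal and
unstable (its mode can sit at either crossing from one dataset to the
next). A Newton–Raphson search — the numerical method the procedure is
built around — instead tracks one crossing: the threshold is the
intersection of f1 with R·f0 adjacent to the non-diseased bulk. The
default per-draw maximization therefore hill-climbs U from the
non-diseased group's location to the nearest local maximum before refining
(`branch="local"`); `branch="global"` switches to the global grid argmax.
For unimodal surfaces (all Gaussian/t fits in Designs 1–3 below) the two
are identical. `maximize_youden` and `theoretical_threshold` — single
fully-specified distribution pairs — always return the global maximizer.

### Intervals and the mode

Quantile intervals use the type-7 (linear-interpolation) empirical
quantiles. The HPD interval is the shortest [Q(p), Q(p + 1 − α)] over
p ∈ [0, α], with Q the same type-7 quantile function; the width is
piecewise linear in p, so minimizing over its knots is exact. Using one
quantile convention for both intervals guarantees HPD width ≤ quantile
width. The posterior mode is the argmax of a Gaussian KDE (Silverman
bandwidth) on a 2048-point grid; below 30 draws the median is returned
with a warning.

## Frequentist comparators

* **Empirical**: maximize the empirical-CDF version of U over midpoints
  between consecutive pooled order statistics (±∞ sentinels; ties take the
  smallest cut).
* **Box-Cox**: a common exponent λ for both groups by profile likelihood on
  a grid over [−3, 3] (step 0.01, Jacobian included), the explicit binormal
  threshold on the transformed scale (equal variances: midpoint shifted by
  s² log R/(m1−m0); unequal: the quadratic root between the means, else a
  grid fallback), back-transformed. Non-positive markers are shifted into
  the positive domain (shift = 10⁻³·range − min) and the shift undone
  afterwards.
* **Kernel**: U computed from Gaussian-kernel smoothed group CDFs with
  Silverman's per-group bandwidth, maximized on a dense grid.

Each gets a stratified (within-group) percentile bootstrap CI, 1000
resamples by default. The bootstrap resample count and interval type are
conventions: only "bootstrap 95% CI" is pinned by the comparator
literature.

## The simulation study

Four data-generating designs on a log-marker-like scale, π = 0.5,
NB/NC = 1 (R = 1):

1. **D1** N(−0.3, σ0²) vs N(−0.2, σ1²); N ∈ {50, 100} per group,
   σ ∈ {0.03, 0.05, 0.07}, plus unequal-variance pairs (0.07, 0.03) and
   (0.03, 0.07). True threshold −0.25 for equal variances.
2. **D2** N(−0.3, 0.05²) vs t(−0.25, 0.05, ν), ν ∈ {1, 4, 8, 12}, 100 per
   group. At ν = 1 the diseased group is Cauchy: many outliers.
3. **D3** N(−0.3, 0.05²) vs the scale mixture
   (1−p)·N(−0.25, 0.05²) + p·N(−0.25, σ2²), σ2 ∈ {0.075, 0.10},
   p ∈ {0.1, 0.2, 0.3}; heterogeneous measurement precision.
4. **D4** N(−0.3, 0.07²) vs 0.5·N(0.05, σ1²) + 0.5·N(−0.25, σ2²);
   disease-stage heterogeneity giving a bimodal diseased distribution.

Per replicate: generate a dataset, fit the chosen model(s) in each group,
form the threshold posterior, and record the mode/median/mean plus both
95% intervals. Metrics per scenario: relative bias (mean estimate −
true)/true, signed by the true threshold (the tables' positive entries
correspond to its magnitude; the true threshold here is negative);
coverage probability, mean width, and left/right non-coverage of each
interval method, all against the design's true threshold computed by the
global maximizer on the exact densities. Replication at desk scale is 200
datasets for Designs 1–3 and 100 for Design 4 (the source study used
5000); Monte-Carlo tolerance is taken as 3 standard errors of the
estimated quantity at this replication. Per-replicate seeds spawn from a
root seed, so scenarios are reproducible and order-independent.

What the generator does *not* emulate: real markers come with detection
limits, measurement error, covariate structure, and non-deposited clinical
quirks; passing these tests shows correct inference under the stated
mixture/t/normal laws, not robustness to everything a real assay does.

## Known behaviour and limitations

* **Design 4's near-tied maxima.** The true U there has two local maxima
  differing by only ~0.02 in U; the global argmax flips to the upper
  crossing in ~10% (N=200) to ~20% (N=100) of datasets under the
  generating law itself. With the branch-local convention the estimate
  tracks the main crossing, matching the published coverage; the residual
  upward skew of the crossing posterior at N = 100 keeps the DPM's
  relative bias above the source study's ≤ 3.5% figure there (ours is
  ~7–12% depending on the estimator) — the one headline number this
  implementation does not reproduce. The exact DPM parameterization and
  sampler of the original are not public, so the gap cannot be attributed
  further.
* The Gaussian sampler's flat log-σ prior is improper on an infinite
  window; the ±20 truncation makes it proper without affecting any
  realistic fit.
* 1/ν mixes by random-walk Metropolis; at ν near 1 (the prior boundary)
  acceptance drops but the threshold functional, driven mainly by
  locations and scales, is insensitive.
* The DPM needs ≥ ~10 observations per group to say anything useful; the
  recommendation from the simulations is ≥ 50 per group for mixture-shaped
  data.
* Markers where *low* values indicate disease should be negated upstream;
  the high-is-diseased convention is assumed throughout.
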