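# Methods

## The complexity metric

A solid's three-dimensional shape complexity is measured through alpha
shapes. Given an interior point cloud of the solid, the alpha complex at
radius α is the union of Delaunay tetrahedra whose circumsphere radius is
below α (the plain circumradius criterion; no regularized or boundary
variants). As
α grows from zero the retained complex grows monotonically from empty to the
convex hull, so its volume V(α) is a non-decreasing step function with steps
at the sorted circumradii.

The cloud is first *normalized*: centered on its centroid and scaled by
V_ref^(−1/3), where V_ref is the solid's true reference volume (occupied
voxels × voxel volume for CT data, divergence-theorem signed volume for
meshes, closed form or fine voxelization for synthetic solids). After
normalization V_ref = 1 and α is a dimensionless length, which makes the
metric exactly invariant to uniform scaling — complexity compares shape, not
size.

The *optimal alpha* α\* solves V(α\*) = V_ref: a convex rod is matched by a
coarse fit (large α\*), while grooves, hooks and rugosities force a finer
fit (small α\*). Complexity is reported as 1/α\*, so elaborate solids score
high. The reciprocal's normalization — measuring α in unit-volume
coordinates — is this package's convention; it is the choice that makes the
score scale-free.

Search: V(α) is evaluated on a 32-point log grid from α_min (median
nearest-neighbor distance — below it the complex is mostly empty) to α_max
(bounding-box diagonal — above it nothing changes), the bracketing pair is
refined by bisection to a relative α tolerance of 1e-3. Because V(α) is
monotone under the circumradius rule the crossing is unique; the grid is
scanned from the hull end so the implementation also behaves correctly if a
non-monotone variant were substituted. Two boundary cases:

* **Ceiling** — a near-convex cloud (sphere, straight rod) can have hull
  volume ≤ V_ref because sampled points sit strictly inside the solid. No
  crossing exists; α\* = α_max is returned with `at_ceiling=True`, the
  minimum measurable complexity at that sampling density. Ceiling values are
  still comparable across equally sampled specimens.
* **Gross mismatch** — hull volume < 0.5·V_ref means the stated reference
  volume cannot belong to this cloud (wrong units, wrong specimen) and is an
  error rather than a ceiling.

Degenerate (near-flat) tetrahedra receive infinite circumradius, so they
join the complex only in the hull limit and cannot destabilize the search.
One further subtlety: tetrahedra spanning large voids (e.g. across a torus
hole) can have circumradii *exceeding* the bbox diagonal, so V(α_max) may
sit slightly below the full hull volume; the ceiling test deliberately uses
V(α_max), not the hull sum.

### Regional complexity

The long axis is the first principal component of the cloud; region
boundaries cut the PC1 coordinate *range* (not the point count) into equal
spans — three by default: proximal, midshaft, distal. Each subregion
inherits a reference volume proportional to its point count (valid because
interior points are uniform) and is independently re-normalized to unit
volume before its own optimal-alpha fit (`renormalize=False` restores the
shared scale if regional size should matter). PC1's sign is fixed by making
its largest-magnitude loading positive; which end is anatomically proximal
is not derivable from geometry, so `flip_axis` is a user flag.

### Sampling choices

Defaults follow the analysis protocol the package models: 100 000 interior
points per specimen, uniform without replacement over occupied voxel
centers (or ray-parity rejection sampling inside a watertight mesh).
Greyscale CT stacks are binarized by Otsu's threshold on a 256-bin
histogram; internal cavities — background voxels not reachable from the
grid border by 6-connected steps — are filled before point extraction, so
the reference volume is the volume of the closed solid. Only isotropic
voxels are supported; anisotropic data must be resampled upstream.

Tests run at 15k–50k points. At 50k points, regenerating the cloud with a
different seed moves complexity by under 5%; rigid motions move it by under
0.1%.

## Synthetic solids

Primitives (sphere, cuboid, torus, cylinder) have closed-form volumes.
The parametric bone-like solid is constructive solid geometry on an
inclusion test: a circular-arc shaft of radius r and arc length L (curvature
angle φ; φ=0 is a straight cylinder), minus a ventral groove channel (a
circle of radius d·r centered on the ventral surface, running the full
shaft), plus an optional distal hook (a torus segment continuing smoothly
from the tip), an optional two-prong distal bifurcation, and sinusoidal
basal rugosity. All features at zero recover the plain cylinder exactly.
Reference volumes come from voxelizing the same inclusion test (default
pitch r/50, ≲0.3% error against 2× refinement), so they are independent of
any meshing step and isolate alpha-shape error from geometry error.

Hook geometry matters: the default is a tight curl (bend radius = shaft
radius, 240° arc) that creates a narrow concave slot. A wide-open hook
instead creates a large coarse void which the alpha shape removes at coarse
refinement, and can *lower* the measured complexity — a real property of
volume-matching metrics worth remembering when interpreting real specimens.
With the tight curl the feature ladder plain < +groove < +groove+hook is
strictly ordered at 50k points.

## Comparative simulators

Trees are pure-birth (Yule) with the crown rescaled to unit height, so the
OU pull parameter a and rates σ² are comparable across fixtures. Discrete
regime histories follow a continuous-time Markov chain simulated by
exponential waiting times from a root state drawn from given frequencies.
Continuous traits evolve along the painted branches with *exact* Gaussian
transitions per constant-regime segment — BM: x' ~ N(x, σ²_r t); OU:
x' ~ N(θ_r + (x−θ_r)e^(−at), σ²_r(1−e^(−2at))/(2a)) — so there is no
time-discretization error at any branch length. Regression datasets draw
predictors as unit-rate Brownian traits and the response as
intercept + Xβ + N(0, σ²C(λ)), where C(λ) scales off-diagonal covariances
by Pagel's λ; trait pairs come from bivariate Brownian motion with a chosen
evolutionary correlation. Everything is generated directly on the log10
scale the analyses use.

What the generators emulate — and what they do not: they reproduce the
statistical structure the comparative methods assume (Markov regimes,
Gaussian trait evolution, phylogenetic error). They do not emulate
measurement error, intraspecific variation, cartilaginous structures
missing from skeletal specimens, fossil (non-ultrametric) tips, or
extinction. Passing recovery tests therefore demonstrates the estimators
are correct and calibrated under their own assumptions, not that those
assumptions hold for any particular empirical dataset.

## Evolutionary models and fitting

Every trait model is a multivariate normal over tips. BM1: covariance
σ²·(shared path time). BMS: the shared root→MRCA path integrates
regime-specific σ². OU models use per-node recursions for the mean
(E' = θ_r + (E−θ_r)e^(−at)) and variance
(V' = V e^(−2at) + σ²_r(1−e^(−2at))/(2a)), with tip covariance
e^(−a·(d_i + d_j))·V(mrca) where d are MRCA→tip times. The root starts *at*
the root-regime optimum with zero variance; this keeps the parameter counts
minimal (BM1 k=2; BMS k=1+m; OU1 k=3; OUM k=2+m; OUMV k=1+2m for m regimes)
and makes the a→0 limit recover Brownian motion exactly (verified to 1e-4
log-units), at the cost of ignoring root-state uncertainty — a documented
convention, switchable only by reparameterizing.

Fitting exploits the model structure: the optima θ (and the BM root) enter
the Gaussian mean linearly through a regime-weight matrix, and one overall
σ² scale factors out of the covariance, so both are profiled exactly by
generalized least squares. What remains is a multi-start (5 starts,
jittered) bounded quasi-Newton search over only the OU pull
a ∈ [1e-8, 100] (log scale; half-lives from ~7 tree heights down to ~0.7%
of one on unit-height trees) and, for multi-rate models, the log σ² ratios
between regimes — one or two dimensions in practice, which makes the fits
fast and reliably reproducible. Validity filters on each fit: the
finite-difference Hessian of the negative log-likelihood, taken in the
*full* statistical parameterization at the optimum, must be positive
definite (`hessian_ok` — a pull estimate pinned at the a→0 boundary, where
OU degenerates into BM, rightly fails this), and fitted optima must lie
within an order of magnitude of the observed trait range on the raw scale
(`theta_ok`, i.e. within ±1 log10 unit); invalid fits are excluded before
model averaging. AICc = −2lnL + 2k + 2k(k+1)/(n−k−1); Akaike weights are
computed from mean AICc across stochastic maps, and a per-map best-model
tally plus the fraction of maps with a runner-up within ±2 AICc are
reported alongside.

Pagel's λ is profiled analytically (GLS mean and σ² in closed form) leaving
a 1-D bounded search; the LRT against λ=0 uses χ²(1). Under the null the
statistic is the boundary mixture ½χ²₀+½χ²₁, so reported p-values are
conservative; the calibration test checks uniformity of the interior
(non-boundary) p-values. Ancestral states are GLS conditional expectations
under BM. The Mk model (ER/SYM/ARD; SYM default, equal root frequencies by
default) is fitted by pruning with matrix exponentials; stochastic maps
sample node states root-down from conditional distributions and fill
within-branch histories by uniformization (jump-count sampling against the
exact transition probability, then an endpoint-conditioned jump chain).

## Bayesian regression and coevolution

The MCMC PGLS samples (β, intercept, log σ², λ) by single-component
random-walk Metropolis with acceptance-rate adaptation during burn-in.
Priors are proper but diffuse: uniform boxes on coefficients (±50 on log10
traits), log-uniform error variance, uniform λ ∈ [0,1]; the analysis they
model does not publish its priors, so these are package conventions. On
ultrametric trees the λ-likelihood is evaluated in the eigenbasis of C
(O(n) per iteration after one decomposition), and the single-tree sampler
runs as a compiled (numba) loop; otherwise a per-λ Cholesky fallback runs
in plain Python. With a tree distribution, a new tree is drawn every 1000
iterations. A slope's "p-value" is the proportion of post-burn-in samples
whose sign opposes the posterior median (one-tailed crossing-zero mass);
r² is the squared correlation of fitted vs observed values in λ-whitened
space at the posterior mean — both definitions are package conventions and
stated in the output.

Marginal likelihoods use stepping-stone sampling with temperatures at
quantiles of Beta(0.3, 1) (t_k = (k/K)^(1/0.3)), a short reflected
random-walk chain per stone (proposals folded into the prior box by exact
reflection and capped at half the box width — an uncapped adaptive scale
can ping-pong between box corners and wreck the estimate), and per-stone
log-mean-exp ratios. Accuracy on a conjugate normal-mean model with a known
closed-form marginal is within 0.1 log-units at 100 stones × 2000
iterations.

The coevolution test compares bivariate Brownian motion with a full 2×2
evolutionary rate (covariance) matrix against its diagonal restriction,
each marginal likelihood by stepping stone after whitening the data once by
the Cholesky factor of C; logBF = 2(logML_dep − logML_indep) with the
conventional reading ≤0 independent, 0–2 weak, 2–5 positive, >5 strong.
Replicate analyses are run as three chains and the chain with the median
log marginal likelihood is kept.

Chain-length profiles: `fast` (20k iterations, thin 10, burn-in 5k; 20
stones × 300) for tests and smoke runs; `default` (200k/100/20k; 30 × 400)
for analysis; `full_scale` (5M/500/500k; 1000 × 10k) reproduces the
original protocol's settings and is practical only for real runs, not the
test suite.

## Repeated-measures ANOVA

Classical within-subject sums of squares; Mauchly's W on the covariance of
normalized Helmert contrasts with its χ² approximation; Greenhouse–Geisser
ε = (Σλ)²/((k−1)Σλ²) over the contrast-covariance eigenvalues, clipped to
[1/(k−1), 1]; the omnibus F is evaluated at ε-scaled degrees of freedom.
Pairwise paired t-tests are Bonferroni-adjusted (the adjustment is a package
choice; the analyses this models report unadjusted-looking pairwise values).
At k=2 the procedure reduces exactly to a paired t-test (F = t²). This test
is not phylogenetically corrected, by design. Implemented in-package
(~40 lines of closed-form algebra) and cross-checked in the test suite
against pingouin to 1e-9.

## Pipeline

`pipeline.run_analysis` executes the stages in order — complexity table →
phylogenetic signal → Mk/simmap regime model selection → PGLS regressions
(testes mass + body mass covariate) → coevolution vs normalized testes mass
→ regional RM-ANOVA and tip-complexity regressions — from a single seeded
config. Missing values drop species *per analysis* (complete cases for each
regression), so each stage reports its own n, and a species-exclusion list
reruns everything on the reduced set for sensitivity checks. The synthetic
profile generates specimens whose 3D features are driven by their simulated
social-system regime, so the full chain from voxel-free geometry to model
selection is exercised end to end; the reproduction profile ingests a
ready-made trait CSV (converting testes volume to mass at density
0.81 g/cm³, with converted rows flagged) plus Newick trees and skips the
shape stage. Reports carry a provenance block (config, seeds, hash)
sufficient to regenerate the run bit-identically.

## Problem sizes

Simulation scales are the package's analysis profile: shape fixtures
15k–50k points; recovery studies 64–128 tips with 40–200 replicates;
MCMC calibrations at the `fast` profile with 40–100 replicates;
model-selection patterns at 128 tips × 40–50 replicates over 5 models.
`scripts/acceptance.py` prints per-stage timings and writes every headline
quantity to JSON.

## Known limitations

* Complexity at the sampling ceiling depends on point density; compare
  ceiling-flagged values only across equal-n clouds.
* The OU root convention (start at the root-regime optimum) differs from
  implementations that estimate a free root state; lnL values are not
  directly comparable across conventions, though model rankings usually are.
* Stepping-stone logBF at the `fast` profile carries Monte-Carlo error of
  roughly ±2; borderline weak/positive calls need the `default` profile or
  better.
* The Mauchly χ² approximation is poor below ~10 subjects; the GG-corrected
  F itself remains valid.
* No measurement-error model on traits; no OUMA/OUMVA (regime-specific
  pull) variants.
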