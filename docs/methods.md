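# Methods

This note records the statistical procedures implemented in `metabeta`,
the defaults and their rationale, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Coverage-standardized Hill numbers

**Sample coverage.** The reference-sample estimator is
Ĉ = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁+2f₂)] (1 when f₁ = 0).  Expected
coverage at other sample sizes uses the standard
rarefaction/extrapolation estimator: for m < n,
Ĉ(m) = 1 − Σᵢ (xᵢ/n)·C(n−xᵢ, m)/C(n−1, m), which equals one minus the
probability that the (m+1)-th individual drawn without replacement
belongs to a previously unseen species — the identity our enumeration
tests exploit; for m > n, Ĉ(m) = 1 − (1−Ĉ)·A^(m−n) with
A = n·f₀/(n·f₀+f₁) and the Chao1-style undetected-species estimate
f₀ = ((n−1)/n)·f₁²/(2f₂), falling back to ((n−1)/n)·f₁(f₁−1)/2 when
f₂ = 0 (avoids division by zero; standard bias-corrected form).

**Standardization.** The coverage curve is inverted by integer bisection
with linear interpolation between adjacent integer sizes (fractional m
is defined by that interpolation throughout).  Expected Hill numbers at
size m: q = 0 via exact hypergeometric detection probabilities; q = 1
via exact expected frequency counts (and the analytic q → 1 limit at the
reference point — no numeric q → 1 approach, which is unstable); q = 2
via the closed form valid on both sides of n.  For q = 1 extrapolation
the entropy is blended as Ĥ(n+t) = n/(n+t)·Ĥ_obs + t/(n+t)·Ĥ∞ with the
Chao–Wang–Jost asymptotic entropy estimator: exact at t = 0, tends to
the asymptotic estimate, monotone in t.  Extrapolation is capped at 2n
(conventional reliability bound); a target above the cap's coverage is
computed at the cap and flagged, never silently truncated.

**Default target.** "0.95 of the maximum of the observed distribution"
is operationalized as 0.95 × the minimum, over every compared assemblage
(pooled and joint distributions alike), of expected coverage at the cap.
This makes the target always reachable and shared within each
comparison; both the multiplier and the cap are configurable.  This is a
convention choice, flagged as such: other operational readings exist.

## Diversity partitioning

γ is the standardized Hill number of the pooled district assemblage; α
is 1/N times the standardized Hill number of the joint (species, patch)
category distribution — the only α that keeps β = γ/α within [1, N] for
all q in this framework.  β is reported as the exact ratio (so
γ = α·β holds identically); because γ and α are standardized
independently, estimator noise can push the ratio marginally below 1,
in which case the 1−S transform uses the clipped value and the result is
flagged.  1−S = (1−1/β)/(1−1/N) is the only dissimilarity surfaced by
default (it reproduces Jaccard dissimilarity in the equal-abundance
census case).  Pairwise patch dissimilarities are N = 2 decompositions
at a coverage target shared across all pairs of a district;
cross-district pairs are out of scope.

**Functional facet.** Species distances are Gower (range-normalized
numeric, 0/1 categorical, averaged over mutually observed traits) with
τ defaulting to the mean off-diagonal distance ("dmean"); the
attribute-diversity form aᵢ = Σⱼ (1 − min(dᵢⱼ, τ)/τ)·pⱼ makes FD reduce
to TD when all distances reach τ and to 1 when all are zero.  For the
joint (α) distribution, cells in different patches are fully distinct,
so each patch contributes its own attribute values.  FD has no printed
analytic rarefaction here; standardized FD is a Monte-Carlo expectation
(hypergeometric subsampling below n; multinomial resampling of observed
proportions above n, since undetected species carry no trait
information), seedable, 30 replicates by default.  This is the main
approximation of the package; its noise is visible in FD bootstrap SEs.

**Bootstrap.** Chao-calibrated: detected probabilities are shrunk by the
coverage deficit, f₀ undetected species share the remainder, and each
patch is resampled multinomially at its observed size (B = 200 default).
Undetected species are treated as patch-private in the pooled matrix (a
simplification relative to allocating a shared pool-level f₀), and FD
bootstrap stays within the detected pool.

## Meta-analysis

Per site and case, Δ = estimate(ESBC) − estimate(control); the SE of Δ
is the SD of replicate-wise bootstrap differences when replicate streams
are available, else √(SE²_E + SE²_C).  Sites are combined by
fixed-effect inverse-variance weighting (wₛ ∝ 1/SEₛ²), CI = Δ̂ ± 1.96·SE;
a heterogeneity model is deliberately not the default because the
weighting is described only through district-wise bootstrap CIs.  Zero
SEs are floored at a configurable ε with a warning; a single site is
returned as-is and flagged.  Significance = CI excluding 0.

## Null models

**Individual shuffle.** All individuals of a site are reallocated
uniformly at random to the site's patches with patch totals fixed
(sequential multivariate-hypergeometric allocation — exactly uniform
conditional on both margins).  Site-level species totals, patch totals
and site γ are conserved exactly.  β-deviation = observed pairwise 1−S
minus the null mean over R replicates (R = 100 default; averaging over
R stabilizes the deviation relative to a single randomized data set,
which remains available as the single-replicate mode and is flagged).
Null replicates are standardized to the same coverage target as the
observed pair, so deviation does not conflate sampling depth.  The
shuffle spans both districts of a site by default; a within-district
mode exists as a sensitivity flag.  Note that deviations of pairs
sharing patches are correlated; Monte-Carlo error of summaries over
pairs should be estimated from independent runs, not per-pair SDs.

**Trait shuffle.** Species labels are permuted across whole trait rows
(equivalently, a simultaneous row/column permutation of the Gower
matrix, which is computed once); the abundance matrix is untouched.
SES = (observed mean pairwise functional 1−S − null mean)/null SD;
|SES| > 1.96 flags significance; a zero null SD yields a flagged
undefined SES.  Because the shuffle leaves abundances unchanged,
sampling-depth artefacts cancel between observed and null, so SES is
evaluated on the reference sample by default (a coverage option
exists); this also makes R = 100–500 replicates affordable.

## Distance predictors and mixed models

Structural distance: Euclidean on z-standardized (canopy density,
deadwood volume); abiotic: Euclidean on z-standardized Ellenberg
indicator means (light excluded upstream); spatial: planar meters.
Standardization is pooled across all patches by default (comparable
effect sizes across sites; per-site scaling available).  Canopy and
deadwood are combined into one structural predictor by default; raw
per-attribute differences are also emitted.

The β-deviation model has treatment-specific intercepts and slopes
(Control/ESBC × Structure/Abiotic/Spatial; no pooled main effects) and
a site random intercept, fitted by REML (statsmodels MixedLM); the site
effect is the only correction for the pseudo-replication of pairwise
observations, by design.  Predictors are z-standardized before fitting
so Wald z values are comparable across terms (configurable).  Marginal
and conditional R² follow the variance-components form
(var_fixed, +var_random over total).  The full-interaction recoding
spans the same column space (fitted values identical, verified in
tests) and its interaction z tests slope differences.  Collinear
designs (e.g. constant distances) are rejected, not fitted.  The SES
treatment comparison is a Gaussian mixed model of SES on treatment with
a site random intercept (the family is unstated in the source methods;
Gaussian is the default here).

## Synthetic landscapes

The generator emulates the paired design: n sites (default 11), each
with an ESBC and a control district of 9 or 15 patches on a jittered
100 m grid (~20 ha footprint).  Control districts have high canopy
(0.88 ± 0.02) and little deadwood; ESBC districts spread canopy targets
over 0.35–0.92 (gaps) and carry elevated, variable deadwood, and the
per-site variance contrast is enforced deterministically whenever the
treatment effect is on.  Five Ellenberg-style indicator axes add mild
patch-level abiotic structure, with one axis responding to canopy
openness.  The species pool (default 1308 species, matching the scale
of a large beetle inventory) has lognormal expected per-patch
intensities (meanlog −0.7, sdlog 1.5 → realistic patch totals and many
rare species), niche optima on every environmental axis, lognormal
dispersal abilities, and a mixed trait block (two niche/dispersal-linked
numeric traits at configurable correlation r = 0.7, one free numeric
trait, one guild category).

Assembly archetypes act on species × patch intensity profiles mixed
additively by weight (so expected composition stays analytically
checkable): species sorting = Gaussian niche match; mass effect =
suitability diffused by an exponential kernel exp(−d/dispersal_scale);
patch dynamics = occupancy from a seeded contact process
(distance-decaying colonization, random extinction, regional reseeding
on global extinction); neutral = equal shares.  Each term is normalized
at the district level (the abundance-weighted total intensity matches
the regional abundance mass) rather than per species: this preserves
absolute habitat filtering — a species matching nothing in a district
stays rare there — which is what lets the heterogenization treatment
raise γ and, under an interconnected mass-effect regime (long dispersal,
sharp niches), α; the neutral term is exactly unchanged by the
normalization, so pure-neutral landscapes have exactly equal expected
shares across a site's patches.  Latent counts are Poisson draws from the mixture intensity and
detection is binomial thinning (default fraction 0.2), separating
assembly from sampling as the coverage correction presumes.

What a green test does **not** establish: the generator has a single
environmental snapshot (no forest growth, deadwood decay or multi-year
dynamics), no trap-type structure, binary occupancy in the
patch-dynamics term, and trait axes that are a stand-in schema rather
than a reconstruction of any real trait list.  Archetype-recovery tests
therefore demonstrate that the pipeline detects the intended signal in
a world where the archetype is expressed, not that real data will carry
signals of this strength.  For the patch-dynamics recovery suite the
world is dispersal-limited (scale 80 m against 100 m patch spacing) with
a relatively even abundance distribution (meanlog 1.5, sdlog 0.8),
because the spatial signal of colonization–extinction dynamics is
carried community-wide and would otherwise be drowned by sampling noise
on rare species; the sorting suite runs at generator defaults.

## Known limitations

* FD standardization is Monte-Carlo, hence stochastic at fixed seed
  count; TD is fully analytic.
* q = 1 extrapolation uses a blended entropy estimator rather than a
  published closed form; its behaviour is exact at the reference point
  and monotone, but extrapolated q = 1 values beyond ~2n are heuristic.
* The patch-level bootstrap treats undetected species as patch-private,
  slightly inflating pooled-level richness variance.
* Inverse-variance fixed-effect weighting is one reading of
  "weighted and combined by meta-analysis"; `combine(method="random")`
  provides the DerSimonian–Laird random-effects alternative, off by
  default because no heterogeneity model is described for the design
  this package mirrors.
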