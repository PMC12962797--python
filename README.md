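# metabeta

Statistical tooling for detecting metacommunity assembly processes from
replicated paired forest-district experiments, built around beetle-style
community samples: coverage-standardized Hill-number diversity
partitioning (taxonomic and functional), paired meta-analysis of
treatment–control differences, individual-shuffle β-deviation and
trait-shuffle SES null models, and mixed-model attribution of
β-deviation to structural, abiotic and spatial patch-pair distances.
A synthetic metacommunity generator emulating the species-sorting,
mass-effect, patch-dynamics and neutral archetypes exercises the whole
pipeline end to end.

## Who this is for

Community ecologists analysing paired-design experiments in which one
district per site was structurally heterogenized (canopy gaps, deadwood
enrichment — "ESBC", Enhancement of Structural Beta Complexity) and a
homogeneous district serves as control, with arthropod communities
sampled on a grid of 50 m × 50 m patches per district.  All methods also
apply to any replicated paired design with patch-level count data.

## The model

For an assemblage with species proportions *pᵢ*, the Hill number of
order *q* is

    qD = (Σᵢ pᵢ^q)^(1/(1−q)),    ¹D = exp(−Σᵢ pᵢ ln pᵢ)

(*q* = 0 richness, 1 Shannon-equivalent, 2 Simpson-equivalent).  Because
sampled inventories are incomplete, estimates are standardized not to a
common sample size but to a common **sample coverage**
Ĉ = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁+2f₂)], by inverting the
rarefaction/extrapolation curve of expected coverage and evaluating the
expected Hill number at the matching sample size (default target: 0.95
of the maximum coverage every compared assemblage can reach at twice its
sample size).

District (γ) diversity is decomposed multiplicatively over its N
patches: γ is the coverage-standardized Hill number of the pooled
assemblage, α is 1/N times the standardized Hill number of the joint
(species, patch) distribution, and β = γ/α ∈ [1, N] is normalized to

    1−S = (1 − 1/β) / (1 − 1/N) ∈ [0, 1]

(0 = identical patch compositions, 1 = completely disjunct).  Functional
diversity replaces species by functional neighbourhoods through a Gower
trait distance with threshold τ (attribute-diversity form).  Per-site
ESBC−control differences (positive = higher in ESBC) are combined over
sites by fixed-effect inverse-variance meta-analysis with bootstrap
(B = 200) propagation of district-level uncertainty — 18 cases:
{TD, FD} × {γ, α, β} × q ∈ {0, 1, 2}.

β-deviation compares each within-district patch-pair 1−S against its
expectation when all individuals of a site are randomly reshuffled among
the site's patches (patch totals and site-level species abundances
preserved); deviations are modelled by a linear mixed model with
treatment-specific slopes for structural, abiotic (Ellenberg) and
spatial pair distances and a site random intercept (REML, Wald z,
Nakagawa R²).  Trait-shuffle SES = (obs − null mean)/null SD tests
whether functional turnover departs from what taxonomic turnover
predicts.

## Worked example

```bash
metabeta simulate --n-sites 3 --n-species 120 --seed 3 --outdir demo
metabeta diversity-meta --community demo/community.csv --traits demo/traits.csv \
    --bootstrap 40 --facets TD --q 0 --seed 1 --outdir demo_out
```

`demo_out/meta_results.csv` from this exact run:

```
facet,scale,q,estimate,se,ci_low,ci_high,z,significant,n_sites
TD,gamma,0,2.186,17.87,-32.84,37.21,0.122,False,3
TD,alpha,0,-3.300,2.69,-8.58,1.98,-1.22,False,3
TD,beta,0,0.0556,0.0147,0.0269,0.0844,3.79,True,3
```

Reading: under the default even mixture of assembly archetypes, the
heterogenization treatment raises between-patch turnover — the β row is
the ESBC−control difference in 1−S units (+0.056, CI excluding 0,
significant) — while γ (effective species, +2.2 ± 17.9) and α are
indistinguishable from zero at three sites.  With `--facets TD,FD --q
0,1,2` the table has all 18 cases.  `metabeta beta-deviation` adds the
z-value table of the mixed models (six treatment-specific slopes plus
conditional R² per facet × q case), and `metabeta ses` the trait-shuffle
SES comparison.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a scaled-down synthetic landscape and recomputes both
headline analyses from scratch — the 18-case meta-analysis table, the
mixed-model z-table and the SES contrast — writing the requested metrics
as JSON.
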