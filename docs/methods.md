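# Methods

## The model

The package analyses a haploid, non-recombining marker system (the
male-specific region of the Y chromosome). Under the infinite-sites
assumption every variant arises once, on one branch of a single rooted
genealogy; a sample's haplotype is therefore determined by which
variant-bearing branches lie on its root path. All components are organised
around this perfect-phylogeny picture:

* the **backbone tree** is the rooted haplotype tree with variants attached
  to edges (an edge is named after the node below it);
* a **haplotype call** is the deepest node whose path is consistent with the
  sample's tested alleles;
* **haplotype diversity**, **ancestry signatures** and **clade ages** are
  read off the resulting assignment tables.

## Rooted compatibility test

Two binary variants fit on one rooted tree with a known all-ancestral root
iff their carrier sets are disjoint or nested. Operationally the builder
flags a pair as incompatible when the joint genotype patterns 01, 10 and 11
all occur; the 00 pattern is taken as given at the root. (This is the rooted
form of the classical four-gamete test; with the ancestral state known the
fourth gamete carries no information.) The builder's check and the test
suite's oracle both use this exhaustive O(m²) pair scan, implemented
independently. The optional `drop_recurrent` mode greedily removes the column
involved in the most conflicts (ties broken lexicographically by variant id)
until the matrix is compatible; removed variants are reported, never silently
dropped. No general maximum-parsimony search is attempted.

Synthesized node names are `N<k>` in deterministic preorder (siblings ordered
by decreasing carrier count, then smallest variant id); imported backbones
keep their published labels. Junction nodes — published branch points without
a genotyped key variant — are permitted and flagged by the validator.

## Hierarchical calling and the bracketing rule

Successive genotyping tests markers top-down and skips ahead along the branch
that proved derived, so most markers of a finished sample are untested. The
caller places a sample on the deepest node whose incoming edge carries a
tested-derived variant and whose path contains no tested-ancestral edge; an
untested marker *between* two tested-derived markers on one path is treated
as derived (bracketing). Untested markers *below* the last derived one are
never assumed, which is what makes the call an ancestor-or-self of the truth
under missingness without genotyping error (verified by simulation sweep).

Internal placements reproduce the asterisk notation (`daC_Ao*`). The status
field distinguishes `inner_confirmed` (every child branch tested ancestral)
from `inner_unresolved` (at least one child branch untested); printed labels
carry the single `*` convention for both.

Conflict tolerance: one tested-derived variant off the maximal-support path
(recurrent mutation or assay error) is tolerated — the call keeps the path
with the most tested-derived support and reports the variant in `conflicts`,
and imputation retains it as derived rather than zeroing it. Two or more
off-path derived variants, or a rival path with equal support, raise an
ambiguous-call error carrying both candidate paths. Samples with fewer than
one tested variant are no-calls. These thresholds are design choices; the
source protocols do not specify behaviour under contradictory assays.

Assay planning orders the untested variants below the current consistent node
by descending prior mass of the subtree each branch leads to (ties by variant
id), and prunes branches already tested ancestral — the formalisation of
"test the haplotype most frequent in this breed first".

## Diversity estimators

Haplotype diversity uses the unbiased estimator

    Hd = n (1 − Σ p_i²) / (n − 1)

with sampling variance

    V = 2/(n(n−1)) · { 2(n−2) [Σp³ − (Σp²)²] + Σp² − (Σp²)² }

(Nei 1987, the estimator behind pegas' `hap.div`). The exact variance
estimator behind published tables of this kind is usually unstated; the Nei
form is assumed here and validated against exhaustive pair counting for the
point estimate. Asterisked internal haplotype labels count as distinct
haplotypes. Headline percentages round half-up to the integer (or one
decimal for composition tables), matching how such tables are printed.

## Ancestry signatures

A haplotype observed at least `min_count` times in exactly one
signature-defining reference group becomes that group's unique predictor; in
two or more groups it gets a varied signature listing them (displayed joined
with "/"); in none it stays unexplained. `min_count` defaults to 2 — one
observation in one reference group is weak evidence. Published predictor
lists also encode narrative history that frequencies alone cannot supply;
curated overrides (YAML) are applied last and logged with provenance
`curated`. Bases follow the signature class: Arabian/Thoroughbred/Coldblood
count as recent breeding, Spanish/West Asian as early dissemination;
non-Crown assignments are reported separately.

## Clock dating

For a clade founded at node X, ρ is the mean number of derived variants from
X to its sampled tips and the age estimate is t̂ = ρ/(μL), with μ the
per-site per-year substitution rate and L the effective callable length in
sites. The interval combines the exact (Garwood/chi-square) Poisson interval
on the total tip count T = Σ counts with the rate bounds: the lower age bound
divides the lower count bound by μ_high and vice versa. Treating tips as
independent Poisson draws is exact for a star genealogy and a good
approximation for recent-expansion clades, whose shared internal branches are
short; for deeply structured clades the interval is anticonservative, which
is why calibration is checked on expansion genealogies. This desk-scale
estimator deliberately replaces full Bayesian phylogenetic dating (an
off-the-shelf MCMC stack); acceptance is parameter recovery — on simulated
strict-clock genealogies with a true age of 1,500 years the nominal 95%
interval covers the truth in ≥90% of replicates (observed ≈94–97% across the
grid of ages 500/1,500/5,000 years and expected counts 3/13/50).

Default rate values follow the published horse Y clock: μ = 1.69e−9 per site
per year with bounds 1.41e−9 and 2.11e−9, quoted for a 10-year generation
interval. The effective callable length L has no published value in the
source study (it lives in the underlying resequencing work), so L is a
required configuration value; synthetic fixtures use L = 5.0e6 sites, a
placeholder on the order of the callable MSY chosen so that an expansion
clade of age 1,500 years accumulates ≈13 mutations per lineage. Published
clade ages therefore cannot be recomputed from this package alone, and no
attempt is made to match them.

## The synthetic-data generator

`synthdata` emulates exactly the structure the analysis assumes:

* **Genealogies** — rooted, binary, ultrametric, root age = `tmrca_years`
  exactly. Three models: `yule` (pure birth), `kingman` (constant-size
  coalescent via msprime) and `star_burst`, where all coalescence happens in
  the top 2% of the clade age — the generator's definition of a hard
  expansion burst, mimicking a recent haplogroup radiation.
* **Mutations** — Poisson(μ·L·t) per branch, infinite sites, so matrices are
  perfect-phylogeny-compatible by construction; recurrent mutation enters
  only through `genotyping_error_rate`.
* **Breeds** — every breed draws a Dirichlet(α) weight vector over the
  distinct haplotypes and tips join breeds proportionally. Small α
  concentrates each breed on few patrilines (line breeding, low Hd); large α
  recovers the cohort spectrum per breed.
* **Masking** — i.i.d. missingness plus optional allele flips, truth
  retained.

Defaults (120 tips, star-burst, TMRCA 1,500 y, μ = 1.69e−9, L = 5e6, seven
breeds, α = 0.3, 30% missingness, zero error) describe a recent expansion
clade sampled at the patriline level. Two deliberate mismatches with real
cohorts: (1) with ~13 mutations per lineage every tip is a distinct
haplotype, so haplotype *sharing* — which real breed panels show because many
horses descend from one stallion — is emulated with the `kingman` model,
whose short terminal branches leave many tips unmutated; breed-diversity
properties are therefore exercised on coalescent cohorts. (2) Missingness is
i.i.d. rather than protocol-correlated (real successive genotyping leaves
whole sub-branches untested); the caller's ancestor-safety guarantee does not
depend on the missingness pattern, but realized "*HT" rates in synthetic runs
are not calibrated to published ones. Passing tests show correctness of the
algorithms under the stated model, not demographic realism.

The whole bundle is a pure function of `SimParams` (seed included); bundle
directories are byte-identical across reruns.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: cohorts of 30–120
tips, a 10,000-sample masked calling sweep (resampled from a 120-tip cohort),
500 clock replicates of 20 tips, 200 random matrices for the builder/oracle
comparison, and pair-counting oracles up to n = 200. Published headline
percentages are recomputed from the printed marginal counts of the study's
panels (the counts are inputs; the percentages are computed). The published
per-sample supplementary tables (needed for breed-level Hd benchmarks and the
124-variant backbone counts) are external downloads and are not bundled; the
computation path they would flow through is exercised end-to-end on synthetic
cohorts instead.

Floating-point and tie-breaking conventions: percentages round half away from
zero; sibling order, node naming and plan order are fully deterministic;
variance estimates are clamped at zero before the square root; Poisson
intervals use the chi-square form with the conventional (0, χ²₀.₉₇₅(2)/2)
interval at zero counts.
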