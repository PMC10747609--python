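# Methods

`delimpy` implements a single-locus species-delimitation workflow for
plastid (or other non-recombining) sequence data: distance-based barcode-gap
partitioning, single-threshold generalized mixed Yule–coalescent (GMYC)
delimitation on an ultrametric genealogy, and a biogeographic-concordance
test of the delimited entities against regionalization subprovinces. A
synthetic-data generator with full ground truth drives all statistical
validation. This note records the models, the defaults and why, the
numerical choices, and what the tests do and do not demonstrate.

## Sequence data and distances

Alignments are restricted to `{A, C, G, T, N, -}`. Identical sequences are
collapsed to haplotypes either under strict string equality or under an
`n_wildcard` policy in which mismatches confined to `N` positions merge into
the first matching haplotype; the strict policy is the default for distance
work so that sequencing `N`s never inflate haplotype counts. The
"populations" dataset variant re-expands haplotypes with user-chosen copy
numbers, mirroring the practice of representing haplotypes roughly in
proportion to their field frequency (a haplotype confined to a single
population is represented once).

Pairwise distances support three substitution models:

* `p` — raw proportion of differing sites;
* `JC69` — d = −(3/4)·ln(1 − 4p/3);
* `K80` — d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q), with P and Q the
  transition and transversion proportions (transitions are A↔G and C↔T).

Sites carrying a gap or `N` in either sequence are removed pair by pair
(pairwise deletion) before counting — standard barcoding practice.
Proportions outside a correction's domain raise a saturation error naming
the offending pair rather than returning NaN.

## Barcode-gap partitioning (asap-style)

Candidate partitions are the states of the single-linkage merge sequence
over the distance matrix: at threshold t the groups equal the connected
components of the graph joining all pairs at distance ≤ t, which is the
transitive-closure logic of threshold-based species grouping. Each
candidate carries:

* **threshold distance** `d_next` — the smallest pending merge distance,
  i.e. the distance at which the candidate would collapse (so finer
  partitions report smaller thresholds);
* **panmixia p-value** — a label-permutation test applied to the merge(s)
  pending at `d_next`. The statistic is mean(between-group distances) −
  mean(pooled within-group distances); labels are permuted within the
  union of the two groups. The test is exhaustive whenever the number of
  distinct splits is at most `n_perm` (default 999), otherwise Monte Carlo
  with the add-one estimator. A low p-value means the groups the candidate
  keeps apart could not plausibly be one randomly mating pool. Simultaneous
  merges at one distance combine by minimum (conservative against lumping);
  a two-singleton union has no within-group distances and returns 1.
* **relative gap width** `W = (d_next − d_cur)/d_next` — the width of the
  distance interval over which the candidate persists, relative to its own
  collapse distance. This is a dimensionless measure of the intra/inter
  discontinuity: a jump from 0.0015 to 0.0167 (W ≈ 0.91) is stronger
  evidence of a barcode gap than an absolutely wider but relatively milder
  jump higher in the hierarchy. When `d_cur = 0` — no positive merge
  distance has been applied, as for the all-singletons state or after
  merging only identical sequences — there is no observed intra-group
  scale, no gap can be claimed, and W = 0. An early design that normalized
  W by the mean pairwise distance systematically preferred the deepest
  split of nested hierarchies (deep gaps are always absolutely wider) and
  was discarded.

Candidates are ranked within each substitution model: p-value ascending and
W descending, ties receiving average ranks; the **asap-score** is the mean
of the two ranks (lower is better). The final ordering places candidates
whose threshold overpasses the **reference threshold distance** (default
0.0005 substitutions/site, a floor below which divergence is treated as
intrapopulation-level) ahead of those that do not, then sorts by asap-score,
p-value and fewer groups. The reference stratification matters in datasets
rich in identical sequences, where haplotype-level boundaries are trivially
"significant" under permutation (within-distances are all zero) yet sit at
sub-population divergences.

The permutation surrogate reproduces the described behaviour of the
published method (ranked p and W averaged into one score, lower better) but
numeric equality with the ASAP server is not claimed: the original p-value
is coalescent-model-based and resolves far below any permutation floor.

## Single-threshold GMYC

On an ultrametric genealogy with tips at height 0, branching older than a
threshold height T is modelled as a Yule process over lineages and
branching younger than T as coalescence within the entities subtended at T.
Inter-event intervals i of length x_i carry class counts: b_Y = number of
lineages when the interval lies above T, and b_C = Σ_j n_j(n_j − 1) over
entities j below it. The log-likelihood is

    lnL = Σ_i [ ln(λ_k b_{i,k}^{p_k})  −  (λ_Y b_{i,Y}^{p_Y} + λ_C b_{i,C}^{p_C}) x_i ]

with k the class of the event terminating interval i, survival terms
dropped where a count is zero, and the interval containing T split at T
(the piece touching T carries no event term). This convention yields the
textbook coalescent likelihood in the one-class limit and a closed form for
two tips: lnL(λ) = ln(2λ) − 2λt, maximized at λ̂ = 1/(2t).

**Optimization.** For fixed exponent p, the rate profile is analytic:
λ̂ = E/S(p) with E the event count and S(p) = Σ b_i^p x_i, reducing each
class fit to a 1-D search over p (17-point grid plus bounded refinement,
likelihood tolerance 1e−8). Exponent bounds are [−2, 2].

**Exponents.** By default p_Y = p_C = 1, the canonical Yule and coalescent
rate shapes; `estimate_exponents=True` frees them (the one-process null is
fitted under the same convention so it stays nested). The default was
chosen because freeing the exponents lets the threshold scan absorb noise
on null (single-population) genealogies and roughly triples the
likelihood-ratio test's type-I error, while contributing nothing measurable
to recovery on well-separated simulations.

**Threshold scan.** Candidate thresholds are midpoints between consecutive
distinct node heights, plus one below the shallowest node (every tip its
own entity) and one above the root (a single entity — exactly the null
model, whose likelihood is reused), so the scan covers every distinct
entity configuration and lnL_alt ≥ lnL_null holds by construction. Ties in
lnL resolve toward fewer entities.

**Inference outputs.** The LRT statistic 2(lnL_alt − lnL_null) is referred
to chi-square with 3 degrees of freedom — a convention inherited from the
method's common usage, not a derived asymptotic. The entity-count
confidence interval is the range of entity counts among candidates within 2
log-likelihood units of the maximum. Per-node support is the sum of Akaike
weights (all candidates share one dimension, so weights reduce to
normalized exp(lnL)) of the candidate models in which the node lies on the
diversification side of the threshold or is itself the crossing (entity
MRCA) node; under a clear two-species genealogy the root's support
approaches 1 while within-species nodes drop toward 0. "ML entities"
includes singletons; "clusters" counts entities with ≥ 2 tips. Zero-length
internal branches (identical sequences retained in a populations dataset)
are jittered by 1e−8 with a warning.

## Biogeographic concordance

Haplogroup occurrences across subprovinces are tabulated into a count
matrix; rows are normalized to relative frequencies (a haplogroup's
distribution over the biogeographic space). Subprovince columns follow the
thermal gradient: ascending mean BIO11 (mean temperature of the coldest
quarter, °C) over the occurrences, ties alphabetical. The double k-means
split clusters rows on their frequency profiles (k_rows = 3) and columns on
their column-normalized composition, transposed (k_cols = 4), with 10
k-means restarts per run; the analysis is repeated 25 times with
independently derived seeds and is reported "consistent" only if every
repeat returns the identical canonical partition (clusters relabelled by
first appearance). The defaults 3/4/25 are the study conditions of the
emulated analysis. Agreement between partitions (rows vs species
hypotheses, or any two delimitations) is scored with the Adjusted Rand
Index; 1.0 with exact label-structure match is reported as full agreement.
The k-means distance (squared Euclidean), initialization and normalization
are documented defaults — the emulated analysis does not state them.

Trait summaries report, per group, mean/min/max of the adaxial:abaxial
epidermal cell-length ratio, hair width and hydathode count, plus a flag
for the diagnostic criterion that adaxial cells are 1.5–2× the abaxial
ones (group mean ratio within [1.5, 2.0]). Single-record groups report no
dispersion.

## Synthetic-data generator

The generator reproduces the structure the analysis assumes, with truth
recorded for scoring:

* **Species tree** — Yule, constructed backwards (waiting time to the next
  join ~ Exponential(k·birth_rate) with k extant lineages). The default
  generator redraws (≤ 100×) until the shallowest divergence is ≥ 0.01
  expected substitutions/site; unconditioned draws frequently leave no room
  for any within-species gap. Default birth rate 30 per substitutions/site
  of the scenario scale.
* **Gene tree** — an independent constant-size coalescent per species
  (pairwise coalescence rate 1/θ; E[TMRCA] = θ for a pair), redrawn (≤
  100×) until its depth is below (shallowest speciation height)/
  min_gap_factor (default 5), then grafted below the species tip. The true
  threshold is the midpoint between the deepest coalescent MRCA and the
  shallowest speciation node; every simulated tree satisfies coalescent
  heights < T_true < speciation heights by construction. Default θ = 5e−4.
  No migration or introgression is simulated, matching the assumption that
  the plastid variation carries no hybridization signature.
* **Sequences** — K80 evolution (default κ = 2, 2000 sites) along the gene
  tree via the closed-form transition probabilities per branch; time is in
  expected substitutions per site throughout (the genealogy is not
  time-calibrated).
* **Occurrences** — the default scenario has three species: a
  narrow-endemic diploid confined to the single warmest of twelve
  subprovinces, a second diploid spread over four warm subprovinces, and a
  tetraploid across six colder ones; five haplogroups (1/2/2 per species),
  41 populations (6/15/20), BIO11 subprovince means on a linear −2…9 °C
  gradient with 0.5 °C observation noise, per-species occupancy profiles
  Dirichlet-perturbed once (concentration 200) before populations draw
  their subprovince. Ploidy and haplogroup are deterministic functions of
  species (tetraploid = cold-adapted), and with 6 + 10 + 14 = 30 sampled
  individuals the alignment collapses to roughly 14 haplotypes at the
  default θ and length.

All randomness derives from one master seed via per-stage, counter-indexed
`SeedSequence` children, so every artefact is bytewise reproducible.

**What the generator does not emulate:** recombination, hybridization and
chloroplast capture, rate variation among sites and lineages, tree
uncertainty (the genealogy is handed to GMYC as if known — in the emulated
workflow it comes from a Bayesian posterior), uneven sampling effort, or
spatial autocorrelation beyond the planted profiles. Passing tests
therefore show the methods are implemented correctly and behave as designed
under their own assumptions; they do not show robustness to violations of
those assumptions in real data.

## Validation experiment sizes

The statistical checks use: 100 genealogies of 4 species × 10 tips for
entity recovery, LRT power and threshold-interval coverage; 100
single-population 40-tip coalescents for LRT size; 100 two-species
alignments (8 + 8 tips, 2000 sites) for barcode-gap recovery; 1000 random
12-label matrices for the partition/connected-components identity; and the
default 41-population scenario for the concordance and end-to-end checks.
These sizes keep Monte-Carlo error a few percent while the whole suite
completes in well under a minute of likelihood work.

## Known limitations

* The panmixia p-value is a permutation surrogate with resolution bounded
  by 1/(n_perm + 1); nested hierarchies whose p-values all hit the floor
  are discriminated by W and the reference-threshold stratification alone.
* The chi-square(3) reference for the GMYC LRT is a convention; the scan
  over thresholds makes the true null distribution non-standard, and with
  freed exponents the test becomes markedly liberal.
* Node supports use equal-dimension Akaike weights over the threshold
  candidates; they are not posterior probabilities.
* The biogeographic stage treats subprovince membership and BIO11 as given
  labels/covariates; no spatial layers are processed.
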