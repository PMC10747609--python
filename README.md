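# delimpy

Single-locus species delimitation and biogeographic concordance testing for
plant (and other) species complexes with strong morphological stasis.

Groups of closely related taxa often hide cryptic species behind uniform
morphology. Given a single-locus alignment (typically several concatenated
plastid regions, inherited as one linkage block), an ultrametric genealogy
and an occurrence table, `delimpy` asks three complementary questions:

1. **Where is the barcode gap?** An automatic-partitioning analysis of
   pairwise genetic distances (p, JC69 or K80) builds every single-linkage
   candidate partition and ranks it by a panmixia p-value and a relative
   gap width W, averaged into an *asap-score* (lower is better).
2. **Where does branching switch from speciation to coalescence?** The
   single-threshold generalized mixed Yule–coalescent (GMYC) model finds
   the threshold height T̂ maximizing

   lnL = Σᵢ [ ln(λₖ b₍ᵢₖ₎^pₖ) − (λ_Y b₍ᵢY₎^{p_Y} + λ_C b₍ᵢC₎^{p_C}) xᵢ ],

   where intervals older than T follow a Yule process over b_Y lineages and
   younger intervals follow coalescence with intensity
   b_C = Σⱼ nⱼ(nⱼ−1) over the delimited entities, with a likelihood-ratio
   test against a one-process null (χ²₃), a 2-lnL entity-count confidence
   interval and Akaike-weight node supports.
3. **Do the molecular species make biogeographic sense?** Haplogroup ×
   subprovince frequencies, ordered along a BIO11 thermal gradient, are
   split by a repeated double k-means (rows k=3, columns k=4, 25 repeats);
   concordance between the biogeographic row clusters and the molecular
   delimitations is scored with the Adjusted Rand Index.

A synthetic-data generator (Yule species trees, grafted within-species
coalescents, K80 sequence evolution, species-specific subprovince occupancy
with ploidy labels) provides scenarios with full ground truth; every
statistical guarantee in the test suite is measured against it. See
`docs/methods.md` for the models, defaults and limitations.

## Worked example

```python
import delimpy as d

sc = d.make_scenario(42)                      # 3 species, 41 populations
ht = d.collapse_haplotypes(sc.alignment)
print("haplotypes:", ht.n)

est = d.AsapPartitioner(n_perm=199, random_state=42).fit(sc.alignment)
best = est.best_
print(f"best model: {est.best_model_}")
print(f"best partition: {best.n_species} species "
      f"(asap-score {best.asap_score:.2f}, p = {best.p_value:.3g}, "
      f"W = {best.W:.3f}, threshold = {best.threshold_dist:.4g})")

gm = d.GmycModel().fit(sc.tree)
print(gm.result_.summary())

F = d.build_frequency_matrix(sc.occurrences)
dk = d.DoubleKMeans(random_state=42).fit(F)
print("row clusters:", dk.row_partition_, "consistent:", dk.consistent_)
ari, _ = d.partition_concordance(dk.row_partition_, sc.truth.hap_species)
print(f"ARI vs true species-of-haplogroup: {ari:.1f}")
```

prints

```
haplotypes: 16
best model: K80
best partition: 3 species (asap-score 1.25, p = 0.005, W = 0.979, threshold = 0.07195)
ML entities: 3 (clusters: 3), confidence interval: 3-3, LRT: 57.092 (p = 2.457e-12, ***), threshold T = 0.0212389
row clusters: {'hgA': 0, 'hgB': 1, 'hgC': 1, 'hgD': 2, 'hgE': 2} consistent: True
ARI vs true species-of-haplogroup: 1.0
```

Reading the output: the 30 sampled sequences collapse to 16 haplotypes; the
distance analysis ranks a 3-species partition first (its threshold, 0.072
substitutions/site, is the distance at which it would collapse, and W≈0.98
says the gap below spans almost the whole interval up to that threshold);
GMYC independently delimits the same 3 entities with a decisive
likelihood-ratio test; and the haplogroup clusters across subprovinces
reproduce the species structure exactly (ARI = 1), stable over all 25
k-means repeats — three concordant lines of evidence for three species,
which is the generator's truth.

The estimators follow scikit-learn conventions (`fit`, `fit_predict`,
`get_params`, fitted attributes with trailing underscores). The same
workflow is scriptable from the shell:

```sh
delim simulate scenario --seed 42 --out scen/
delim run --fasta scen/alignment.fasta --tree scen/genealogy.nwk \
          --occ scen/occurrences.csv --truth scen/truth.json \
          --seed 42 --out results/
```

which writes `report.json`, flat TSVs and a plain-text summary; individual
stages are available as `delim haplotypes | distances | asap | gmyc |
biogeo` and `delim simulate yule | coalescent | gmyc-tree | sequences`.

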