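# cooccursig

Mining **signature pathways** from species co-occurrence networks in gut
metagenomes.

Microbial communities associated with a disease are rarely reproducible at
the species level across independent cohorts, but the *functions* those
communities carry often are.  `cooccursig` implements a pipeline that turns
species-level taxonomic profiles and stratified KO (KEGG Ortholog)
functional profiles into per-phenotype species co-occurrence networks,
analyzes them at three granularity levels, and reports the pathways that are
enriched in a disease phenotype, absent from the control, and replicated
across cohorts.

## Method

**Co-occurrence test.** Relative abundances are binarized (present ⇔
abundance > 0).  For two species occupying N₁ and N₂ of N samples, the
number of jointly occupied samples under random, independent placement is
hypergeometric,

    P(j) = C(N₁, j) · C(N − N₁, N₂ − j) / C(N, N₂),

and a pair is a significant positive co-occurrence when the upper tail
p_gt = P(J ≥ j_obs) < 0.05.  Tails are computed exactly in log space; pairs
with expected co-occurrence N₁N₂/N below 1 are screened out by default.
Significant pairs form an unweighted, undirected network per (dataset,
phenotype).

**Three granularity levels.**

* *Global*: the network's full species set.
* *Community*: Leiden community detection under the Constant Potts Model,
  Q = Σ_c [e_c − γ·n_c(n_c−1)/2], with resolution γ defaulting to the first
  quartile of node degree divided by (n − 1).
* *Key elements*: the top-5 species by hub (eigenvector) centrality and by
  shortest-path betweenness.

**Enrichment and signatures.** Each species set is mapped to the KOs it
contributes (any positive stratified abundance in the phenotype's samples),
and the KO query is tested per pathway with the upper-tail hypergeometric
test against the annotation universe, BH-adjusted.  Per level, the disease
phenotype's significant pathways minus the control's, intersected across
datasets, are the robust signature pathways.  Species-level Jaccard indices
quantify how little the networks themselves overlap across cohorts.

## Worked example

The package ships a synthetic-cohort generator that emulates profiling
outputs for two independent cohorts (control/CD/UC, 30 samples each, 60
background species) with a planted 5-species block per disease phenotype
whose 12-KO pathway is split across the block members:

```bash
cooccursig simulate --seed 11 --outdir example
cooccursig run-all --config example/run_config.yaml
```

prints

```
CD: robust signature pathways: ['map99001']
UC: robust signature pathways: ['map99002']
outputs written to example/run
```

`map99001`/`map99002` are the planted CD/UC signature pathways — each is
enriched in its disease phenotype's co-occurring species in *both* cohorts
and absent from the controls, even though the block species names are
disjoint between cohorts (the species-level Jaccard for these networks is
≈ 0.3–0.5).  `example/run/` contains the per-stage artifacts: presence
matrices and the filter report, pair tables with exact tail probabilities,
edge-list/GraphML networks, CPM partitions, centrality tables, per-level
enrichment tables (GeneRatio, BgRatio, p-value, BH-adjusted p-value,
geneIDs), and the signature report with per-cluster "Cluster No. / Total
Species / Contrib. Species" detail and per-species "k/K" KO counts.

The same stages are available individually (`preprocess`, `cooccur`,
`network`, `enrich`, `compare`); a SHA-256 manifest makes a downstream stage
refuse upstream outputs that changed since they were produced.  Identical
config + seed reproduce every output byte for byte.

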