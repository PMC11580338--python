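# Methods

## Scope and data model

The pipeline consumes four files per cohort: a merged species-level
taxonomic profile (rows are `|`-separated, `x__`-prefixed lineage strings;
columns are samples; values are relative abundances on either a 0–100 or 0–1
scale — only strict positivity is ever used, so no rescaling is applied), a
stratified KO abundance table (row keys `K#####` or
`K#####|g__Genus.s__Genus_species`; `UNMAPPED`/`UNGROUPED` rows are
discarded), a sample metadata table, and a two-column pathway→KO annotation.
The canonical species key everywhere is the underscored binomial carried by
the `s__` token — the one identifier shared between the two profile formats.
Species-level rows are those with an `s__` rank and no `t__` (strain) rank;
strain rows would duplicate species.

## Filter cascade

Order is fixed: (1) metadata selection — age within [18, 65] inclusive (the
exclusions are strictly younger/older), medicated samples out, only each
subject's first visit (minimal `visit_index`), duplicate sample ids dropped;
(2) kingdom filter — Archaea and Eukaryota excluded by default (viruses are
retained; the set is configurable); (3) zero-prevalence removal, computed on
the union of all phenotype samples rather than per phenotype; (4) removal of
samples with zero Shannon diversity, H = −Σ pᵢ ln pᵢ with natural log and
0·ln 0 = 0.  An all-zero sample is assigned H = 0 so the same rule removes
it without a 0/0.  The cascade is idempotent, and a per-stage survivor count
table is emitted.  "Medication" is a precomputed boolean column; the
pipeline does not interpret drug names.

## Exact co-occurrence test

For occupancies N₁, N₂ in N samples the joint-occupancy null is
hypergeometric; `p_gt`/`p_lt` are upper/lower tails **including** the
observed term (so p_gt + p_lt = 1 + P(j_obs)).  Implementation: log-factorial
(gammaln) evaluation of every feasible term, each tail accumulated from its
far end inward so the smallest terms add first.  Against an exact
rational-arithmetic oracle this is accurate to ~1e-15 absolute for N ≤ 12
and better than 1e-10 relative at N = 5000.  Pairs with expected
co-occurrence N₁N₂/N < 1 are not tested by default (`expected_threshold`,
set 0 to disable) — the usual screening of pairs whose discrete null cannot
be informative; the threshold is echoed in the run report because published
analyses are not always explicit about it.  Significance is raw
p_gt < alpha with strict inequality and no multiple-testing correction at
this stage; the network is the undirected simple graph on significant
positive pairs, with isolated species omitted (optionally retained for
diagnostics).  Negative associations (`p_lt`) are computed and reported in
the pair table but no negative-edge network is built.

## Network analysis

*Global level* is simply the node set.  *Community level* optimizes the
Constant Potts Model in edge-count form, Q = Σ_c [e_c − γ·n_c(n_c−1)/2],
with the Leiden algorithm (leidenalg).  The default resolution is the first
quartile of node degree (linear-interpolation quantile) divided by (n − 1);
on an unweighted graph strength equals degree.  Both the quantile and the
denominator are configurable because the heuristic is stated ambiguously in
the literature this follows; the choice is recorded in the run report.
Leiden is a stochastic local optimizer, so the procedure restarts from 30
seeds derived deterministically from the user seed and keeps the best
partition by an independent recomputation of Q (ties to the earliest
restart); on exhaustively searchable graphs (≤ 8 nodes) this reaches the
global CPM optimum in testing.  Cluster ids are relabeled contiguously from
1 in sorted-node order, making partitions byte-reproducible.

*Key-element level*: hub scores are the principal eigenvector of the
adjacency matrix (on undirected graphs Kleinberg's hub score coincides with
eigenvector centrality), computed per connected component by power iteration
on A + I — the spectral shift removes the ±λ oscillation on bipartite
components — to relative tolerance 1e-10.  Component scores are
max-normalized within the component, weighted by the component's spectral
radius, then globally max-normalized, so nodes outside the dominant
component remain comparable instead of being zeroed.  Betweenness is
unnormalized Brandes shortest-path betweenness with each unordered pair
counted once.  Top-k lists (k = 5 by default) break score ties by ascending
species name; no tie policy is claimed beyond determinism.

## Enrichment

A species of interest contributes every KO with positive stratified
abundance in ≥ 1 sample of its phenotype subset (presence, not magnitude;
minimum-sample count is configurable and defaults to 1).  Species with no
stratified rows are dropped with a warning.  For a query of n KOs within a
universe of M, a pathway with K annotated KOs and k query hits scores the
upper tail Σ_{i≥k} C(K,i)C(M−K,n−i)/C(M,n) (scipy's hypergeometric
survival function).  The universe defaults to all annotated KOs; an
`observed` mode restricts universe and pathways to KOs actually seen in the
cohort's profile.  Only pathways with k ≥ 1 are reported, sorted by p-value
then pathway id, with GeneRatio "k/n" and BgRatio "K/M".  Adjustment is
Benjamini–Hochberg (statsmodels; Bonferroni available); significance uses
the adjusted p-value at 0.05 with strict inequality by default, with a
raw-p mode exposed since published phrasing ("significance less than 0.05")
does not always distinguish the two.

## Signature comparison

Per analysis level and disease phenotype: the disease's significant
pathways minus the control's, then intersected across cohorts.  At the
community level the disease pool is the union over clusters with ≥ 2
species (singletons carry no co-occurrence signal); control subtraction
uses the union over control clusters and can be disabled for the pure
cross-dataset-consistency reading — the subtraction mechanics at this level
are a design choice, not an assertion about prior work.  For every robust
pathway the report records, per cohort, each contributing cluster as
(cluster id, total species, species carrying ≥ 1 pathway KO), per-species
KO counts rendered "k/K", and the union coverage |∪_s (KOs of s ∩ pathway)|.
Centrality-level signatures are computed separately for the hub and
betweenness top-5 lists and may legitimately be empty.  Cross-dataset
network overlap is the Jaccard index on species (node) sets, with edge-set
Jaccard available as a secondary metric.

## Synthetic cohorts

The generator emulates profiling outputs for paired independent cohorts so
the whole pipeline is testable without external data.  Default study
conditions: two cohorts, 30 samples per phenotype (control/CD/UC), 60
background species shared by name across cohorts, and one planted 5-species
block per disease phenotype tied to a 12-KO pathway split disjointly
(round-robin) across the block, so no single species carries the whole
pathway and only the community can light it up.

Parameter choices, made once:

* **Background occupancy** per species ~ U(0.05, 0.6): heterogeneous
  prevalence produces null networks with sporadic false-positive edges, as
  real presence/absence panels do.
* **Block co-presence** via a latent Bernoulli(q = 0.6) per-sample indicator
  with independent Bernoulli(0.9) species dropout.  q is deliberately
  moderate: a presence/absence test has no power when occupancy approaches
  1, because the hypergeometric null then predicts near-total overlap
  regardless of association — the planted p_gt is smallest at moderate
  occupancy and rises again as q → 1 (the trend test covers the monotone
  regime only).
* **Baseline block occupancy p0 = 0** by default: planted consortia are
  disease-specific.  Any positive p0 gives block species a small chance of
  a spurious significant edge in the control network, which would leak
  planted KOs into control enrichment; with p0 = 0 a control report of the
  planted pathway is structurally impossible rather than merely improbable.
  Nonzero p0 is fully supported and exercised in tests.
* **Annotation**: 60 background pathways × 12 KOs drawn from a 1000-KO
  pool; each species carries 5 background KOs (block species additionally
  their planted slice).  These sizes keep the query-to-universe ratio low
  enough that full coverage of a 12-KO pathway is a strong signal.
* **Abundances** when present are log-uniform in [1e-4, 10] percent —
  magnitude is cosmetic since only positivity propagates.  Ages are drawn
  in [20, 60] so the age filter is inert unless a test plants violations.

What the generator does **not** model: compositional correlation structure,
sequencing noise, strain-level variation, longitudinal autocorrelation, or
realistic phylogenetic signal in gene content.  Passing the planted-recovery
test therefore demonstrates that the pipeline's inference machinery is
correct and well-calibrated under its own null, not that real cohorts of
this size would yield equally clean signatures.

## Determinism and numerics

Every stochastic step (simulation, Leiden) is seeded; identical config +
seed reproduce all outputs byte for byte, and the CLI's SHA-256 manifest
lets a downstream stage refuse stale upstream files.  Tail probabilities are
capped at 1 against rounding; BH is applied only across pathways with ≥ 1
hit; empty networks, single-node graphs (no resolution heuristic), and
queries disjoint from the universe raise or degrade explicitly rather than
silently.

## Problem sizes

Default experiments run two cohorts of 90 samples × ~70 species
(≈ 1500–2500 tested pairs per phenotype); replicate counts are 100 seeds in
the recovery test and 25 in the acceptance script — sizes chosen so a full
validation pass completes on a laptop-class single core in a few minutes.
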