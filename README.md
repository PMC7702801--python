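# paleonet

Ecological co-occurrence network analysis for microbiome profiles, built for
the small-cohort regime of ancient microbiome studies — coprolites and
dental calculus — but applicable to any species-level relative-abundance
data.

Taxonomic inventories from small cohorts pose two statistical traps: the
sum-to-one constraint of relative abundances induces spurious negative
correlations, and any single network built from a handful of samples is
unstable. `paleonet` addresses both by combining a compositionally
corrected (SparCC-style) correlation estimator with heavy replication:
every network is rebuilt many times (default 100) from independent
Dirichlet resamplings of the counts, and every downstream quantity —
cluster count, modularity, transitivity, articulation points, keystone
taxa — is reported as a replicate consensus.

## What it computes

**Compositional correlations.** From the log-ratio variance matrix
*t*<sub>ij</sub> = var(log(*x*<sub>i</sub>/*x*<sub>j</sub>)), per-taxon
basis variances ω<sub>i</sub>² are obtained by solving the sparsity
approximation's linear system, giving basis correlations

ρ<sub>ij</sub> = (ω<sub>i</sub>² + ω<sub>j</sub>² − *t*<sub>ij</sub>) / (2 ω<sub>i</sub> ω<sub>j</sub>),

followed by iterative exclusion of strongly correlated pairs that violate
the sparsity assumption. Counts are resampled through a Dirichlet posterior
(pseudocount 1) and ρ is averaged over `n_inner` draws.

**Networks and their properties.** Edges retain pairs with ρ > 0.3
(strictly; positive-only by default). Communities come from greedy
modularity maximization; reported properties are the cluster count,
Newman modularity *Q*, global transitivity *C* = 3·triangles/triples, and
articulation points, each summarized as mean (s.d.) over replicates, with
*Q* and *C* categorized on a five-level scale (very low … very high) and
condensed into the network distinctness ratio mean(*Q*)/mean(*C*).

**Consensus keystones.** Per replicate, the top-5 taxa under pagerank
(damping 0.85), Wasserman–Faust closeness, and the HITS hub score; a taxon
is a keystone for a method if it appears in at least 80 of 100 replicates.

**Functional redundancy and response diversity.** For gene classes matched
in stratified gene-family tables (e.g. acetate kinase, butyrate kinase,
methylmalonyl-CoA decarboxylase, adhesins, fimbrial and flagellar
proteins): contributor richness *S*, Faith's phylogenetic diversity on a
taxonomy cladogram (unit branches; Newick override accepted), and the
Gini–Simpson index 1 − Σ*p*<sub>i</sub>², compared between groups with a
two-sided Mann–Whitney U test.

**Sample-size robustness.** Cohorts are subsampled to 5/10/20 samples,
the whole machinery re-run, and the scaling of cluster count and
distinctness ratio with size summarized by OLS *r*², together with
keystone recovery against the full cohort.

## Worked example

```python
from paleonet import (synth_abundance, two_block_spec, replicate_networks,
                      replicate_candidates, consensus_keystones)

# 30-sample cohort with two planted 8-taxon correlation blocks (basis rho 0.7)
table, truth = synth_abundance(two_block_spec(seed=11))
summary, reps = replicate_networks(table, n_replicates=100, seed=11)
print(f"clusters:     {summary.means['n_clusters']:.2f} (s.d. = {summary.sds['n_clusters']:.2f})")
print(f"modularity:   {summary.means['modularity']:.3f} -> {summary.categories['modularity']}")
print(f"transitivity: {summary.means['transitivity']:.3f} -> {summary.categories['transitivity']}")

report = consensus_keystones(replicate_candidates([n for n, _ in reps], k=5))
print(report.keystones["pagerank"][:3])
```

prints

```
clusters:     2.00 (s.d. = 0.00)
modularity:   0.499 -> very high
transitivity: 0.877 -> very high
[('Genus13_sp13', 100), ('Genus3_sp3', 100), ('Genus4_sp4', 100)]
```

The two planted blocks are recovered as exactly two clusters in all 100
replicates; block members (not a hub — this spec plants none) dominate the
centrality rankings. The high modularity/transitivity categories reflect
the clean two-clique structure of the synthetic truth, far crisper than
real calculus or coprolite networks.

The same analysis runs from the shell against profile files:

```bash
paleonet synth --spec examples/synth_spec.yaml --outdir data/ --seed 11
paleonet run --taxonomic-table data/abundance.tsv \
             --stratified-table data/genefamilies.tsv \
             --outdir results/ --seed 11
```

writing network summaries (JSON), GraphML exports, keystone reports,
gene profiles, diversity profiles, the co-occurrence table, subsampling
results and a provenance manifest from which the run can be re-executed
bit-for-bit.

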