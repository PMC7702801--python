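# Methods

## The model and its assumptions

The pipeline treats a cohort of microbiome samples as repeated observations
of an unobserved *basis* community: per sample, each taxon has a latent
positive abundance, and what is observed is the composition (relative
abundances, or counts at a sequencing depth). Correlations computed naively
on compositions are biased by the sum-to-one closure, so the estimator
works in log-ratio space. For taxa *i*, *j*,

    t_ij = var(log(x_i / x_j)) = w_i^2 + w_j^2 - 2 rho_ij w_i w_j,

where w_i^2 and rho_ij are basis variances and correlations. The system is
unidentifiable in general; under the sparsity approximation (most pairs
roughly uncorrelated), summing over j gives a linear system for w_i^2 with
design matrix (D-1) on the diagonal and 1 off it (D = number of taxa; the
system is underdetermined below D = 4, which is enforced as a
precondition). Correlations follow as
rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j), clamped to [-1, 1].

Because strongly correlated pairs violate the sparsity assumption, up to
`max_exclusion_rounds` (default 10) exclusion iterations remove, one at a
time, the active pair with the largest |rho| above `exclusion_threshold`
(default 0.1) from the linear system and re-solve. Ties are broken by the
lexicographically smallest taxon pair so runs are deterministic. Excluded
pairs are recorded in the estimate's provenance.

Counts are linked to the basis through a Dirichlet posterior with a uniform
prior: every resampling draw adds pseudocount 1 to each cell and draws
fractions per sample, keeping all entries strictly positive. The reported
correlation matrix averages `n_inner` (default 20) independent draws.
Relative-abundance inputs (the common profiler output) are first rescaled
to pseudo-counts at a configurable depth (default 10 000, rounded); this
choice affects replicate variance and is logged and recorded in provenance.

Numerical notes: log-ratio variances use the unbiased (n-1) estimator and
are computed from the covariance of log fractions; non-positive basis
variance solutions — a known small-sample pathology of the linear system —
are floored at 1e-6 with a warning rather than aborting; if exclusions
would leave a taxon with fewer than two active partners, exclusion stops
early.

## Networks, replication, and summaries

An edge joins taxa whose estimated correlation strictly exceeds the
threshold (default 0.3). The default keeps positive correlations only; an
absolute-value mode is available. Replication re-estimates the correlation
matrix `n_replicates` times (default 100) from independent RNG substreams
of a single mandatory seed and rebuilds the network each time. The sample
set is fixed across replicates: replication quantifies resampling
(count-noise) uncertainty, not sampling-of-subjects uncertainty — the
subsampling simulation addresses the latter.

Communities are detected by greedy modularity maximization on the
unweighted thresholded graph (weights are retained on edges for reporting
only); isolated nodes stay in the node set, flagged, and are excluded from
cluster counts and centrality. Modularity Q uses the standard Newman
formula on the returned partition. Transitivity is 3 x triangles /
connected triples; articulation points come from the DFS lowpoint
algorithm. Per-property summaries are the mean and sample s.d. (n-1)
over surviving replicates; edgeless replicates are recorded and skipped,
and more than 50% failures aborts the run.

Category labels for modularity (very low < 0.1, low 0.1–0.15, medium
0.15–0.2, high 0.2–0.3, very high >= 0.3) and transitivity (very low
< 0.4, low 0.4–0.5, medium 0.5–0.6, high 0.6–0.7, very high >= 0.7) treat
interior boundaries as left-closed/right-open and are computed on the
replicate means. The network distinctness ratio is mean(Q)/mean(C),
computed on the means rather than per replicate.

## Consensus keystones

Three per-replicate centralities are computed on the non-isolated,
unweighted graph: pagerank with damping 0.85 iterated to a residual below
1e-10; closeness with the Wasserman–Faust component-size correction so
scores are comparable across disconnected replicates (harmonic centrality
was the logged alternative); and the HITS hub score, which on an
undirected graph is the principal eigenvector of the adjacency matrix,
normalized to a maximum of 1. Per replicate and method the top k = 5 taxa
(cutoff ties broken lexicographically) are saved; a taxon is a consensus
keystone for a method when it appears in at least `min_count` replicates
— 80 of 100 at the defaults, scaled as ceil(0.8 n) otherwise. Consensus is
per method, not pooled, and near-misses (count >= min_count/2) are
reported for diagnostics.

A protocol property worth stating plainly: consensus over resampling
replicates filters count-noise instability only. Spurious correlations
that are present in a small fixed cohort are stable across replicates and
can therefore produce stable spurious keystones; this is the same
small-sample effect the subsampling simulation measures, and it is why the
package's null-calibration checks are run at large n (40 taxa, 500
samples), where the null estimator is well behaved.

## Functional redundancy and response diversity

Gene classes are named pattern sets matched case-insensitively against
annotation text. Per sample and class, contributors are the taxa with
positive stratified abundance (families summed per taxon within the
class). Richness S counts them; the Gini–Simpson index 1 - sum(p_i^2)
uses each taxon's share of the class's stratified total; Faith's PD sums
the branch lengths of the minimal rooted subtree spanning the
contributors. The default tree is the taxonomy cladogram built from
lineages with unit branch lengths — a rank-based proxy, labelled as such —
with an externally supplied Newick tree accepted as an override. PD is
computed by a postorder sweep marking branches whose subtree holds a
present tip (the library routine it would otherwise wrap rejects
multifurcating roots such as star trees).

Unknown/unclassified contributors are deliberately retained: they count as
a single pseudo-taxon for richness and evenness and attach to the root
with branch length 1 for PD; an exclusion flag is available. Samples with
zero contributors are flagged, reported, and excluded from group tests.

Group comparisons use the two-sided Mann–Whitney U test — exact
enumeration when both groups have at most 8 tie-free values, the normal
approximation with tie correction otherwise — reporting U, p and group
medians. p-values are reported raw by default; Benjamini–Hochberg
adjustment is available.

## Subsampling simulation

For sizes 5, 10 and 20 (configurable) and `reps_per_size` repetitions
(default 10; drawn without replacement, independent across repetitions),
taxa are re-filtered with the same thresholds (prevalence >= 0.3 of
samples and mean relative abundance >= 1e-4 by default, both recorded in
provenance) and the full replication machinery re-run. The coefficient of
determination of each property against size is computed by OLS on the
pooled (size, value) points (per-size means are available as an
alternative mode); the slope sign is reported alongside since the claims
of interest are directional. Keystone recovery compares each subsample's
consensus sets with the full cohort's per method (|sub ∩ full| / |full|,
plus Jaccard).

## Synthetic data

The generator draws correlated log-basis abundances (multivariate normal
assembled from disjoint within-block correlations plus an optional hub
whose partner-partner correlation is the square of the hub-partner value,
keeping a one-factor, positive-definite structure — verified by Cholesky
at construction), exponentiates, closes to fractions, and observes
multinomial counts at a fixed depth. The exact correlation matrix fed to
the Cholesky factor is returned as ground truth. The log-normal /
multinomial choice matches the estimator's own assumptions (positive
fractions, log-ratio structure); it is a testbed decision, not a claim
about ancient specimens, and passing recovery tests therefore demonstrate
correctness of the machinery, not robustness to ancient-DNA damage,
contamination or taxonomic misassignment, which the generator does not
model. Stratified tables plant per-class contributor sets (fixed across
samples by default so richness assertions are exact; a shuffle flag
relaxes this) with symmetric-Dirichlet shares whose concentration controls
evenness, and totals written as the exact stratified sums.

Canonical study conditions used throughout the tests: a 30-sample,
20-taxon cohort with two 8-taxon blocks at basis correlation 0.7; the same
cohort shape with a hub correlated 0.6 with 10 partners; and a 40-sample,
30-taxon cohort with four 5-taxon blocks plus a 9-partner hub for the
subsampling ladder. Sequencing depth defaults to 10 000. End-to-end checks
at these sizes (100 network replicates; subsampling with 10 repetitions
per size and 20 replicates per subsample, inner averaging reduced to 5)
complete in well under a minute each on one CPU.

## Defaults, degenerate inputs, and limitations

All tunables live in `RunConfig` and are echoed into the provenance
manifest; a seed is mandatory. Degenerate cases are explicit errors:
all-zero sample rows (cannot be resampled), fewer than 4 taxa, edgeless
networks for cluster/centrality operations, filters that remove every
taxon, subsample sizes at or above the cohort size, all-zero share vectors.
Percentage-vs-fraction input conventions are auto-detected (any abundance
value above 1.5 implies percentages) with an explicit override, and the
decision is recorded.

Known limitations: the correlation estimator has no significance
machinery (magnitude thresholds only, matching the network definition);
closeness on heavily fragmented replicates remains sensitive to component
structure even with the Wasserman–Faust correction; the taxonomy-cladogram
PD is a coarse proxy for phylogenetic breadth; and at cohort sizes below
roughly 10 samples the networks are noise-dominated — which is precisely
what the subsampling simulation is for.
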