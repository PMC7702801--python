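"""Co-occurrence networks, communities, and replicate property summaries.

A network retains the edge (i, j) iff the estimated correlation exceeds a
threshold (default 0.3, strictly greater-than), positive-only by default.
Communities come from greedy modularity maximization on the unweighted
thresholded graph; the reported properties are the cluster count, Newman
modularity Q, global transitivity C (3 x triangles / connected triples) and
the articulation points. Properties are summarized over many estimation
replicates (mean and sample s.d.), categorized on the replicate means, and
condensed into a network distinctness ratio mean(Q) / mean(C): high values
mean distinct, weakly interlinked clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .compositional import CorrelationEstimate, estimate_correlations
from .profiles_io import AbundanceTable

__all__ = [
    "EcologyNetwork",
    "ClusterAssignment",
    "NetworkProperties",
    "NetworkPropertySummary",
    "NoEdgesError",
    "build_network",
    "detect_clusters",
    "transitivity",
    "articulation_points",
    "network_properties",
    "categorize",
    "replicate_networks",
    "cluster_cooccurrence",
]

logger = logging.getLogger(__name__)


class NoEdgesError(ValueError):
    """The thresholded graph has no edges."""


@dataclass
class EcologyNetwork:
    """Thresholded undirected graph over taxa; isolated nodes kept but flagged."""

    graph: nx.Graph
    threshold: float
    sign_mode: str = "positive"

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def isolated(self) -> list[str]:
        return sorted(nx.isolates(self.graph))

    @property
    def active_subgraph(self) -> nx.Graph:
        """The graph restricted to non-isolated (edge-bearing) nodes."""
        keep = [n for n, deg in self.graph.degree if deg > 0]
        return self.graph.subgraph(keep)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ClusterAssignment:
    """Community labels for non-isolated nodes plus the partition's modularity Q."""

    labels: dict[str, int]
    modularity_q: float

    def __post_init__(self) -> None:
        if not -0.5 - 1e-9 <= self.modularity_q <= 1 + 1e-9:
            raise ValueError(f"modularity {self.modularity_q} outside [-0.5, 1]")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


@dataclass
class NetworkProperties:
    n_clusters: int
    modularity_q: float
    transitivity_c: float
    articulation_points: list[str]


@dataclass
class NetworkPropertySummary:
    """Per-property mean and sample s.d. over replicates, with categories."""

    means: dict[str, float]
    sds: dict[str, float]
    categories: dict[str, str]
    distinctness_ratio: float | None
    n_replicates: int
    n_failed: int = 0
    provenance: dict = field(default_factory=dict)


def build_network(
    corr: CorrelationEstimate, threshold: float = 0.3, sign_mode: str = "positive"
) -> EcologyNetwork:
    """Threshold a correlation matrix into an undirected taxon graph.

    ``positive`` mode keeps edges with rho > threshold; ``absolute`` mode with
    \\|rho\\| > threshold. Strictly greater-than in both modes.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if sign_mode not in ("positive", "absolute"):
        raise ValueError(f"sign_mode must be 'positive' or 'absolute', got {sign_mode!r}")
    g = nx.Graph()
    g.add_nodes_from(corr.taxa)
    d = len(corr.taxa)
    for i in range(d):
        for j in range(i + 1, d):
            rho = corr.rho[i, j]
            keep = rho > threshold if sign_mode == "positive" else abs(rho) > threshold
            if keep:
                g.add_edge(corr.taxa[i], corr.taxa[j], weight=float(rho))
    return EcologyNetwork(graph=g, threshold=threshold, sign_mode=sign_mode)


def detect_clusters(net: EcologyNetwork) -> ClusterAssignment:
    """Greedy modularity-maximization communities on the unweighted graph.

    Isolated nodes are excluded; labels are assigned in order of each
    community's lexicographically smallest member so the result is
    deterministic. Q is the standard Newman modularity of the partition.
    """
    sub = net.active_subgraph
    if sub.number_of_edges() == 0:
        raise NoEdgesError("cannot detect clusters on an edgeless network")
    communities = nx.community.greedy_modularity_communities(sub, weight=None)
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    labels = {node: k for k, comm in enumerate(communities) for node in comm}
    q = nx.community.modularity(sub, [set(c) for c in communities], weight=None)
    return ClusterAssignment(labels=labels, modularity_q=float(q))


def transitivity(net: EcologyNetwork) -> float:
    """Global clustering coefficient: 3 x triangles / connected triples."""
    sub = net.active_subgraph
    if sub.number_of_edges() == 0:
        raise NoEdgesError("network has no edges")
    return float(nx.transitivity(sub))


def articulation_points(net: EcologyNetwork) -> list:
    """Nodes whose removal disconnects their component (DFS lowpoints)."""
    sub = net.active_subgraph
    if sub.number_of_edges() == 0:
        raise NoEdgesError("network has no edges")
    return sorted(nx.articulation_points(sub))


def network_properties(net: EcologyNetwork) -> NetworkProperties:
    """Cluster count, modularity, transitivity, articulation points."""
    clusters = detect_clusters(net)
    return NetworkProperties(
        n_clusters=clusters.n_clusters,
        modularity_q=clusters.modularity_q,
        transitivity_c=transitivity(net),
        articulation_points=articulation_points(net),
    )


_MOD_BINS = ((0.1, "very low"), (0.15, "low"), (0.2, "medium"), (0.3, "high"))
_TRANS_BINS = ((0.4, "very low"), (0.5, "low"), (0.6, "medium"), (0.7, "high"))


def categorize(value: float, which: str) -> str:
    """Qualitative category for a modularity or transitivity value.

    Interior boundaries are left-closed/right-open: modularity in [0.1, 0.15)
    is "low", >= 0.3 "very high"; transitivity in [0.4, 0.5) is "low",
    >= 0.7 "very high".
    """
    if which == "modularity":
        bins, lo, hi = _MOD_BINS, -0.5, 1.0
    elif which == "transitivity":
        bins, lo, hi = _TRANS_BINS, 0.0, 1.0
    else:
        raise ValueError(f"which must be 'modularity' or 'transitivity', got {which!r}")
    if not lo <= value <= hi:
        raise ValueError(f"{which} value {value} outside [{lo}, {hi}]")
    for upper, label in bins:
        if value < upper:
            return label
    return "very high"


def replicate_networks(
    table: AbundanceTable,
    n_replicates: int = 100,
    threshold: float = 0.3,
    sign_mode: str = "positive",
    seed: int | None = 0,
    estimator: dict | None = None,
) -> tuple[NetworkPropertySummary, list[tuple[EcologyNetwork, ClusterAssignment]]]:
    """Estimate, threshold, and summarize the network ``n_replicates`` times.

    Each replicate draws its estimator seed from an independent substream of
    ``seed``. Edgeless replicates are recorded and skipped; more than 50%
    failures aborts. Means use the surviving replicates; s.d. is the sample
    standard deviation (n-1 denominator); categories are computed on the
    means; distinctness ratio = mean Q / mean C.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    estimator = dict(estimator or {})
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_replicates)
    replicates: list[tuple[EcologyNetwork, ClusterAssignment]] = []
    records: list[NetworkProperties] = []
    n_failed = 0
    for r, ss in enumerate(child_seeds):
        corr = estimate_correlations(table, seed=ss, **estimator)
        net = build_network(corr, threshold=threshold, sign_mode=sign_mode)
        if net.n_edges == 0:
            n_failed += 1
            logger.warning("replicate %d produced an edgeless network; skipped", r)
            continue
        clusters = detect_clusters(net)
        sub = net.active_subgraph
        props = NetworkProperties(
            n_clusters=clusters.n_clusters,
            modularity_q=clusters.modularity_q,
            transitivity_c=float(nx.transitivity(sub)),
            articulation_points=sorted(nx.articulation_points(sub)),
        )
        replicates.append((net, clusters))
        records.append(props)
        if (r + 1) % 10 == 0:
            logger.info("replicate %d/%d done", r + 1, n_replicates)
    if n_failed > n_replicates / 2:
        raise RuntimeError(
            f"{n_failed}/{n_replicates} replicates were edgeless; aborting"
        )
    arrays = {
        "n_clusters": np.array([p.n_clusters for p in records], dtype=float),
        "modularity": np.array([p.modularity_q for p in records]),
        "transitivity": np.array([p.transitivity_c for p in records]),
        "n_articulation_points": np.array(
            [len(p.articulation_points) for p in records], dtype=float
        ),
    }
    means = {k: float(v.mean()) for k, v in arrays.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in arrays.items()}
    categories = {
        "modularity": categorize(means["modularity"], "modularity"),
        "transitivity": categorize(means["transitivity"], "transitivity"),
    }
    ratio = (
        means["modularity"] / means["transitivity"]
        if means["transitivity"] > 0
        else None
    )
    summary = NetworkPropertySummary(
        means=means,
        sds=sds,
        categories=categories,
        distinctness_ratio=ratio,
        n_replicates=n_replicates,
        n_failed=n_failed,
        provenance={
            "threshold": threshold,
            "sign_mode": sign_mode,
            "seed": seed if isinstance(seed, int) else None,
            "estimator": estimator,
        },
    )
    return summary, replicates


def cluster_cooccurrence(
    replicates: list[ClusterAssignment],
    focal_taxa: list[str],
    other_taxa: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """How often each focal taxon shares a cluster with each other taxon.

    For a (focal, other) pair the frequency is the fraction of replicates in
    which both are non-isolated and carry the same cluster label, over the
    replicates in which both are non-isolated; the denominator is returned
    alongside. Focal taxa never non-isolated get a NaN row with a warning.
    """
    if other_taxa is None:
        seen: dict[str, None] = {}
        for rep in replicates:
            for node in rep.labels:
                seen.setdefault(node, None)
        other_taxa = sorted(seen)
    freq = pd.DataFrame(np.nan, index=list(focal_taxa), columns=other_taxa)
    denom = pd.DataFrame(0, index=list(focal_taxa), columns=other_taxa)
    for focal in focal_taxa:
        if not any(focal in rep.labels for rep in replicates):
            logger.warning("focal taxon %r absent from all replicates", focal)
            continue
        for other in other_taxa:
            both = [
                rep for rep in replicates if focal in rep.labels and other in rep.labels
            ]
            denom.loc[focal, other] = len(both)
            if both:
                same = sum(rep.labels[focal] == rep.labels[other] for rep in both)
                freq.loc[focal, other] = same / len(both)
    return freq, denom
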