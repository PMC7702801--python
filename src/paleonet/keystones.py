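"""Consensus keystone-taxon detection across network replicates.

A keystone taxon is one with disproportionate influence on community
structure, operationalized as a taxon that is consistently among the top-k
most central nodes of the co-occurrence network. Three standard centralities
are used — pagerank (damping 0.85), Wasserman–Faust component-corrected
closeness, and the HITS hub score (on an undirected graph, the principal
adjacency eigenvector) — and a taxon is declared a consensus keystone for a
method when it lands in that method's top-k in at least ``min_count`` of the
replicates (default 80 of 100, scaled as ceil(0.8 n) otherwise).
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import EcologyNetwork, NoEdgesError
from .profiles_io import StratifiedGeneTable

__all__ = [
    "METHODS",
    "CentralityScores",
    "KeystoneReport",
    "TaxonNotFoundError",
    "centrality_scores",
    "top_candidates",
    "replicate_candidates",
    "consensus_keystones",
    "keystone_gene_profile",
]

METHODS = ("pagerank", "closeness", "hubscore")


class TaxonNotFoundError(KeyError):
    """Requested taxon has no stratified gene entries."""


@dataclass
class CentralityScores:
    method: str
    scores: dict[str, float]
    parameters: dict = field(default_factory=dict)


@dataclass
class KeystoneReport:
    """Per-method consensus taxa with replicate occurrence counts.

    ``keystones[method]`` lists (taxon, count) with count >= ``min_count``,
    sorted by count descending then taxon name; ``near_misses`` holds taxa
    with count >= min_count / 2 that fell short, for diagnostics.
    """

    keystones: dict[str, list[tuple[str, int]]]
    near_misses: dict[str, list[tuple[str, int]]]
    min_count: int
    n_replicates: int

    def taxa(self, method: str) -> set[str]:
        return {t for t, _ in self.keystones[method]}


def centrality_scores(net: EcologyNetwork, method: str) -> CentralityScores:
    """Centrality of every non-isolated node under one method.

    pagerank: damping 0.85, iterated to residual < 1e-10 (scores sum to 1 over
    the non-isolated nodes). closeness: Wasserman–Faust scaling so values are
    comparable across disconnected components. hubscore: principal eigenvector
    of the adjacency matrix, rescaled to max = 1.
    """
    sub = net.active_subgraph
    if sub.number_of_edges() == 0:
        raise NoEdgesError("cannot score an edgeless network")
    if method == "pagerank":
        d = 0.85
        raw = nx.pagerank(sub, alpha=d, tol=1e-12, max_iter=10_000)
        return CentralityScores(method, {n: float(v) for n, v in raw.items()}, {"damping": d})
    if method == "closeness":
        raw = nx.closeness_centrality(sub, wf_improved=True)
        return CentralityScores(method, {n: float(v) for n, v in raw.items()}, {})
    if method == "hubscore":
        nodes = sorted(sub.nodes)
        a = nx.to_numpy_array(sub, nodelist=nodes, weight=None)
        vals, vecs = np.linalg.eigh(a)
        vec = np.abs(vecs[:, int(np.argmax(vals))])
        vec = vec / vec.max() if vec.max() > 0 else vec
        return CentralityScores(method, dict(zip(nodes, map(float, vec))), {})
    raise ValueError(f"unknown centrality method {method!r}; use one of {METHODS}")


def top_candidates(scores: CentralityScores, k: int = 5) -> list[str]:
    """The k highest-scoring taxa; ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [t for t, _ in ordered[:k]]


def replicate_candidates(
    networks: list[EcologyNetwork], k: int = 5, methods: tuple[str, ...] = METHODS
) -> dict[str, list[list[str]]]:
    """Per-method, per-replicate top-k candidate lists."""
    out: dict[str, list[list[str]]] = {m: [] for m in methods}
    for net in networks:
        for m in methods:
            out[m].append(top_candidates(centrality_scores(net, m), k))
    return out


def scaled_min_count(n_replicates: int, fraction: float = 0.8) -> int:
    """ceil(fraction x n_replicates): 80 of 100 at the defaults."""
    return math.ceil(fraction * n_replicates)


def consensus_keystones(
    replicate_cands: dict[str, list[list[str]]],
    min_count: int | None = None,
) -> KeystoneReport:
    """Taxa appearing in a method's top-k list in >= ``min_count`` replicates."""
    if not replicate_cands or any(not v for v in replicate_cands.values()):
        raise ValueError("empty candidate lists")
    n_reps = {len(v) for v in replicate_cands.values()}
    if len(n_reps) != 1:
        raise ValueError("methods disagree on replicate count")
    n_replicates = n_reps.pop()
    if min_count is None:
        min_count = scaled_min_count(n_replicates)
    if min_count > n_replicates:
        raise ValueError(f"min_count {min_count} exceeds n_replicates {n_replicates}")
    keystones: dict[str, list[tuple[str, int]]] = {}
    near: dict[str, list[tuple[str, int]]] = {}
    for method, lists in replicate_cands.items():
        counts: dict[str, int] = {}
        for cand_list in lists:
            for taxon in cand_list:
                counts[taxon] = counts.get(taxon, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        keystones[method] = [(t, c) for t, c in ranked if c >= min_count]
        near[method] = [(t, c) for t, c in ranked if min_count / 2 <= c < min_count]
    return KeystoneReport(
        keystones=keystones,
        near_misses=near,
        min_count=min_count,
        n_replicates=n_replicates,
    )


def keystone_gene_profile(
    genes: StratifiedGeneTable, taxon: str, top_n: int = 50
) -> list[tuple[str, str, float]]:
    """The taxon's ``top_n`` most abundant gene families.

    Families stratified to the taxon are ranked by abundance summed across
    samples (ties broken by family id); each result row is
    (family_id, annotation, summed_abundance).
    """
    rows = [
        (e.family_id, e.annotation, float(genes.values[i].sum()))
        for i, e in enumerate(genes.entries)
        if e.taxon == taxon
    ]
    if not rows:
        close = difflib.get_close_matches(taxon, genes.taxa(), n=5, cutoff=0.4)
        raise TaxonNotFoundError(
            f"no stratified entries for taxon {taxon!r}; close matches: {close}"
        )
    rows.sort(key=lambda r: (-r[2], r[0]))
    return rows[:top_n]
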