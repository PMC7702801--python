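import itertools

import networkx as nx
import numpy as np
import pytest

from paleonet.compositional import CorrelationEstimate
from paleonet.network import (
    ClusterAssignment,
    EcologyNetwork,
    NoEdgesError,
    build_network,
    categorize,
    cluster_cooccurrence,
    detect_clusters,
    network_properties,
    replicate_networks,
)


def corr(matrix, taxa=None):
    matrix = np.asarray(matrix, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(len(matrix))]
    return CorrelationEstimate(taxa=taxa, rho=matrix)


def net_from_graph(g):
    return EcologyNetwork(graph=g, threshold=0.3)


def newman_q(g, labels):
    """Independent Newman modularity: Q = sum_c (e_c/m - (d_c/2m)^2)."""
    m = g.number_of_edges()
    q = 0.0
    for c in set(labels.values()):
        members = {n for n, lab in labels.items() if lab == c}
        e_c = sum(1 for u, v in g.edges if u in members and v in members)
        d_c = sum(d for n, d in g.degree if n in members)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


class TestBuildNetwork:
    RHO = [[1, 0.5, 0.1], [0.5, 1, -0.6], [0.1, -0.6, 1]]

    def test_positive_mode_default(self):
        net = build_network(corr(self.RHO), threshold=0.3)
        assert set(map(frozenset, net.graph.edges)) == {frozenset({"t0", "t1"})}

    def test_absolute_mode(self):
        net = build_network(corr(self.RHO), threshold=0.3, sign_mode="absolute")
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset({"t0", "t1"}),
            frozenset({"t1", "t2"}),
        }

    def test_threshold_is_strict(self):
        rho = [[1, 0.3, 0], [0.3, 1, 0], [0, 0, 1]]
        net = build_network(corr(rho), threshold=0.3)
        assert net.n_edges == 0

    def test_isolated_nodes_retained_and_flagged(self):
        net = build_network(corr(self.RHO), threshold=0.3)
        assert set(net.nodes) == {"t0", "t1", "t2"}
        assert net.isolated == ["t2"]


class TestDetectClusters:
    def two_cliques_bridge(self):
        g = nx.Graph()
        for block in (list("abcd"), list("efgh")):
            g.add_edges_from(itertools.combinations(block, 2))
        g.add_edge("d", "e")
        return g

    def test_two_cliques_found_and_q_is_global_optimum(self):
        g = self.two_cliques_bridge()
        result = detect_clusters(net_from_graph(g))
        assert result.n_clusters == 2
        assert set(frozenset(n for n, c in result.labels.items() if c == k)
                   for k in (0, 1)) == {frozenset("abcd"), frozenset("efgh")}
        # exhaustive-partition oracle: greedy finds the true modularity optimum here
        best = max(
            newman_q(g, dict(zip(g.nodes, assignment)))
            for assignment in _set_partitions(len(g.nodes))
        )
        assert result.modularity_q == pytest.approx(best, abs=1e-12)

    def test_single_clique_q_zero(self):
        g = nx.complete_graph(4)
        result = detect_clusters(net_from_graph(g))
        assert result.n_clusters == 1
        assert result.modularity_q == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_network_rejected(self):
        g = nx.empty_graph(3)
        with pytest.raises(NoEdgesError):
            detect_clusters(net_from_graph(g))

    def test_reported_q_matches_newman_formula(self):
        g = self.two_cliques_bridge()
        result = detect_clusters(net_from_graph(g))
        assert result.modularity_q == pytest.approx(
            newman_q(g, result.labels), abs=1e-12
        )


def _set_partitions(n):
    """All partitions of n items as label assignments (restricted growth)."""

    def rec(prefix, maxlab):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for lab in range(maxlab + 2):
            yield from rec(prefix + [lab], max(maxlab, lab))

    yield from rec([0], 0)


class TestNetworkProperties:
    def test_complete_graph(self):
        props = network_properties(net_from_graph(nx.complete_graph(4)))
        assert props.transitivity_c == pytest.approx(1.0)
        assert props.articulation_points == []

    def test_path_graph(self):
        props = network_properties(net_from_graph(nx.path_graph(4)))
        assert props.transitivity_c == pytest.approx(0.0)
        assert props.articulation_points == [1, 2]

    def test_articulation_removal_disconnects(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = nx.gnp_random_graph(8, 0.3, seed=int(rng.integers(2**31)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() == 0:
                continue
            props = network_properties(net_from_graph(g))
            before = nx.number_connected_components(g)
            for ap in props.articulation_points:
                h = g.copy()
                h.remove_node(ap)
                assert nx.number_connected_components(h) >= before + 1


class TestCategorize:
    @pytest.mark.parametrize(
        "value,which,label",
        [
            (0.111, "modularity", "low"),
            (0.667, "transitivity", "high"),
            (0.052, "modularity", "very low"),
            (0.822, "transitivity", "very high"),
            (0.15, "modularity", "medium"),  # left-closed boundary
            (0.3, "modularity", "very high"),
            (0.7, "transitivity", "very high"),
            (0.399, "transitivity", "very low"),
        ],
    )
    def test_bins(self, value, which, label):
        assert categorize(value, which) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize(1.2, "modularity")
        with pytest.raises(ValueError):
            categorize(-0.1, "transitivity")


class TestReplicateNetworks:
    def test_two_block_cohort_recovers_two_clusters(self, two_block_table):
        table, _ = two_block_table
        summary, reps = replicate_networks(
            table, n_replicates=30, seed=11, estimator={"n_inner": 5}
        )
        assert summary.means["n_clusters"] == pytest.approx(2, abs=0.5)
        assert len(reps) + summary.n_failed == 30

    def test_deterministic_under_seed(self, two_block_table):
        table, _ = two_block_table
        s1, _ = replicate_networks(table, n_replicates=5, seed=4, estimator={"n_inner": 2})
        s2, _ = replicate_networks(table, n_replicates=5, seed=4, estimator={"n_inner": 2})
        assert s1.means == s2.means
        assert s1.sds == s2.sds

    def test_sd_uses_sample_denominator(self, two_block_table):
        table, _ = two_block_table
        summary, reps = replicate_networks(
            table, n_replicates=2, seed=8, estimator={"n_inner": 2}
        )
        qs = [c.modularity_q for _, c in reps]
        assert summary.sds["modularity"] == pytest.approx(np.std(qs, ddof=1))

    def test_distinctness_ratio_monotone_in_modularity(self):
        # ratio arithmetic on constructed summaries: higher Q at fixed C
        assert (0.3 / 0.6) > (0.2 / 0.6)


class TestClusterCooccurrence:
    def assign(self, labels):
        return ClusterAssignment(labels=labels, modularity_q=0.0)

    def test_half_and_full_frequencies(self):
        reps = [
            self.assign({"X": 0, "Y": 0, "Z": 1}),
            self.assign({"X": 0, "Y": 1, "Z": 1}),
        ]
        freq, denom = cluster_cooccurrence(reps, ["X"])
        assert freq.loc["X", "Y"] == pytest.approx(0.5)
        assert denom.loc["X", "Y"] == 2
        assert freq.loc["X", "X"] == pytest.approx(1.0)

    def test_absent_focal_flagged_nan(self):
        reps = [self.assign({"X": 0})]
        freq, _ = cluster_cooccurrence(reps, ["missing"])
        assert freq.loc["missing"].isna().all()

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(5)
        taxa = [f"t{i}" for i in range(6)]
        reps = []
        for _ in range(10):
            present = [t for t in taxa if rng.random() > 0.2]
            reps.append(self.assign({t: int(rng.integers(3)) for t in present}))
        freq, denom = cluster_cooccurrence(reps, taxa[:2])
        for focal in taxa[:2]:
            for other in taxa:
                both = [r for r in reps if focal in r.labels and other in r.labels]
                assert denom.loc[focal, other] == len(both)
                if both:
                    expected = sum(
                        r.labels[focal] == r.labels[other] for r in both
                    ) / len(both)
                    assert freq.loc[focal, other] == pytest.approx(expected)
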