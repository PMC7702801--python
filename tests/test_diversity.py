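import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleonet.diversity import (
    GeneClass,
    InsufficientDataError,
    TaxonomyTree,
    compare_groups,
    diversity_profile,
    faith_pd,
    gini_simpson,
    mann_whitney,
    select_gene_families,
    taxonomy_cladogram,
)
from paleonet.profiles_io import UNKNOWN_TAXON, GeneEntry, StratifiedGeneTable
from paleonet.synth import default_lineage


class TestGiniSimpson:
    def test_equal_shares(self):
        assert gini_simpson([0.25] * 4) == pytest.approx(0.75)

    def test_single_contributor(self):
        assert gini_simpson([1.0]) == pytest.approx(0.0)

    def test_unnormalized_input(self):
        assert gini_simpson([5, 3, 2]) == pytest.approx(0.62)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini_simpson([0.0, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        shares=st.lists(st.floats(0.01, 100), min_size=1, max_size=10),
        scale=st.floats(0.001, 1000),
    )
    def test_scale_invariance(self, shares, scale):
        v = np.array(shares)
        assert gini_simpson(v * scale) == pytest.approx(gini_simpson(v), abs=1e-9)


class TestTaxonomyCladogram:
    def recs(self):
        def rec(genus, species, family="F1"):
            return default_lineage(0, species=f"{genus}_{species}")._replace_family(family) if False else None

        # two species in one genus + one in another genus, same family
        from paleonet.profiles_io import TaxonRecord

        def make(genus, sp):
            return TaxonRecord(
                f"{genus}_{sp}",
                (
                    ("k", "Bacteria"),
                    ("p", "P1"),
                    ("c", "C1"),
                    ("o", "O1"),
                    ("f", "F1"),
                    ("g", genus),
                    ("s", f"{genus}_{sp}"),
                ),
            )

        return [make("GenA", "x"), make("GenA", "y"), make("GenB", "z")]

    def test_prefix_merge_topology(self):
        tree = taxonomy_cladogram(self.recs()).tree
        family = next(n for n in tree.traverse() if n.name == "f__F1")
        genus_names = sorted(c.name for c in family.children)
        assert genus_names == ["g__GenA", "g__GenB"]
        gen_a = next(c for c in family.children if c.name == "g__GenA")
        assert sorted(t.name for t in gen_a.tips()) == ["GenA_x", "GenA_y"]

    def test_single_taxon_path_length(self):
        recs = self.recs()[:1]
        tree = taxonomy_cladogram(recs)
        assert faith_pd({"GenA_x"}, tree) == pytest.approx(7.0)

    def test_conflicting_lineages_rejected(self):
        from paleonet.profiles_io import TaxonRecord

        a = self.recs()[0]
        b = TaxonRecord(a.taxon_id, (("k", "Archaea"),) + a.lineage[1:])
        with pytest.raises(ValueError, match="conflicting"):
            taxonomy_cladogram([a, b])

    def test_topology_matches_prefix_trie_oracle(self):
        taxa = [default_lineage(i) for i in range(30)]
        tree = taxonomy_cladogram(taxa).tree
        # oracle: count of distinct lineage prefixes = node count (plus root)
        prefixes = set()
        for t in taxa:
            for depth in range(1, len(t.lineage) + 1):
                prefixes.add(t.lineage[:depth])
        assert sum(1 for _ in tree.traverse(include_self=False)) == len(prefixes)


class TestFaithPD:
    def test_star_tree_closed_form(self):
        import io

        from skbio import TreeNode

        tree = TaxonomyTree(TreeNode.read(io.StringIO("(a:1,b:1,c:1)root;")))
        assert faith_pd({"a", "b", "c"}, tree) == pytest.approx(3.0)

    def test_matches_union_of_root_paths_oracle(self):
        taxa = [default_lineage(i) for i in range(20)]
        tree = taxonomy_cladogram(taxa)
        rng = np.random.default_rng(0)
        tips = {t.name: t for t in tree.tree.tips()}
        for _ in range(10):
            k = int(rng.integers(1, 20))
            present = set(rng.choice(sorted(tips), size=k, replace=False))
            # oracle: union of the edges on each present tip's path to the root
            edges = set()
            for name in present:
                node = tips[name]
                while node.parent is not None:
                    edges.add(id(node))
                    node = node.parent
            assert faith_pd(present, tree) == pytest.approx(float(len(edges)))

    def test_monotone_in_added_tips(self):
        taxa = [default_lineage(i) for i in range(10)]
        tree = taxonomy_cladogram(taxa)
        names = sorted(t.name for t in tree.tree.tips())
        pd_values = [faith_pd(set(names[: k + 1]), tree) for k in range(len(names))]
        assert all(b >= a for a, b in zip(pd_values, pd_values[1:]))

    def test_unknown_pseudo_taxon_adds_unit_branch(self):
        taxa = [default_lineage(0)]
        tree = taxonomy_cladogram(taxa)
        base = faith_pd({taxa[0].taxon_id}, tree)
        assert faith_pd({taxa[0].taxon_id, UNKNOWN_TAXON}, tree) == pytest.approx(base + 1)

    def test_missing_taxon_rejected(self):
        tree = taxonomy_cladogram([default_lineage(0)])
        with pytest.raises(ValueError, match="not in tree"):
            faith_pd({"nope"}, tree)


def make_gene_table(class_rows, sample_ids=("s1",)):
    """class_rows: list of (family, annotation, {taxon: per-sample values})."""
    entries, rows = [], []
    for fam, ann, contribs in class_rows:
        total = np.sum([v for v in contribs.values()], axis=0)
        entries.append(GeneEntry(fam, ann, None))
        rows.append(np.atleast_1d(total))
        for taxon, vals in contribs.items():
            entries.append(GeneEntry(fam, ann, taxon))
            rows.append(np.atleast_1d(np.asarray(vals, dtype=float)))
    return StratifiedGeneTable(
        sample_ids=list(sample_ids), entries=entries, values=np.vstack(rows)
    )


class TestSelectGeneFamilies:
    def test_case_insensitive_substring(self):
        table = make_gene_table(
            [("U1", "Acetate kinase (EC 2.7.2.1)", {"X_y": [1.0]})]
        )
        subset = select_gene_families(table, GeneClass("ak", ("acetate kinase",)))
        assert len(subset.entries) == 2  # total + 1 contributor

    def test_no_match_returns_empty_with_warning(self, caplog):
        table = make_gene_table([("U1", "Acetate kinase", {"X_y": [1.0]})])
        subset = select_gene_families(table, GeneClass("bk", ("butyrate kinase",)))
        assert len(subset.entries) == 0

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(4)
        rows = []
        planted = 0
        for i in range(100):
            is_match = i % 8 == 0 and planted < 12
            ann = "Flagellar hook protein" if is_match else f"Hypothetical protein {i}"
            planted += is_match
            rows.append((f"U{i}", ann, {f"T{i}": [float(rng.random())]}))
        table = make_gene_table(rows)
        subset = select_gene_families(table, GeneClass("fla", ("flagell",)))
        oracle = [
            i
            for i, e in enumerate(table.entries)
            if "flagell" in e.annotation.lower()
        ]
        assert [table.entries[i] for i in oracle] == subset.entries


class TestDiversityProfile:
    def test_composition_of_closed_forms(self):
        taxa = [default_lineage(0, species="X_a"), default_lineage(1, species="Y_b")]
        tree = taxonomy_cladogram(taxa)
        table = make_gene_table(
            [("U1", "Acetate kinase", {"X_a": [6.0], "Y_b": [2.0]})]
        )
        profiles = diversity_profile(
            table, [GeneClass("acetate kinase", ("acetate kinase",))], tree
        )
        row = profiles.iloc[0]
        assert row["richness"] == 2
        assert row["gini_simpson"] == pytest.approx(1 - 0.75**2 - 0.25**2)
        assert row["faith_pd"] == pytest.approx(faith_pd({"X_a", "Y_b"}, tree))

    def test_absent_class_flagged_zero(self):
        taxa = [default_lineage(0, species="X_a")]
        tree = taxonomy_cladogram(taxa)
        table = make_gene_table([("U1", "Acetate kinase", {"X_a": [1.0]})])
        profiles = diversity_profile(
            table, [GeneClass("bk", ("butyrate kinase",))], tree
        )
        row = profiles.iloc[0]
        assert row["richness"] == 0 and row["flagged"]
        assert row["faith_pd"] == 0.0 and row["gini_simpson"] == 0.0

    def test_richness_equals_independent_recount(self):
        rng = np.random.default_rng(9)
        taxa = [default_lineage(i) for i in range(12)]
        tree = taxonomy_cladogram(taxa)
        contribs = {
            taxa[i].taxon_id: rng.random(4) * (rng.random(4) > 0.3) for i in range(7)
        }
        table = make_gene_table(
            [("U1", "Adhesin precursor", contribs)], sample_ids=[f"s{i}" for i in range(4)]
        )
        profiles = diversity_profile(table, [GeneClass("adh", ("adhesin",))], tree)
        for s in range(4):
            expected = sum(1 for v in contribs.values() if v[s] > 0)
            got = profiles[(profiles["sample"] == f"s{s}")].iloc[0]["richness"]
            assert got == expected


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(a, a)
        assert res.p_value >= 0.99

    def test_exact_enumeration_oracle(self):
        res = mann_whitney([1, 2, 3, 4], [10, 11, 12, 13])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 70)

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([1, 2], [3, 4, 5])

    def test_ties_use_asymptotic_method(self):
        res = mann_whitney([1, 1, 2, 3], [2, 3, 3, 4])
        assert res.method == "asymptotic"

    def test_dataframe_interface_excludes_flagged(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "gene_class": ["A"] * 4 + ["B"] * 4,
                "richness": [5, 6, 7, 0, 1, 2, 1, 2],
                "flagged": [False, False, False, True, False, False, False, False],
            }
        )
        res = compare_groups(df, "richness", "A", "B")
        assert res.n_a == 3 and res.n_b == 4

    def test_planted_ordering_ranks_dominant_class_higher(self):
        """Class generated with higher richness and evenness dominates in
        group medians for all three metrics."""
        from paleonet.synth import ClassSpec, StratifiedSpec, synth_stratified

        pool = [default_lineage(i) for i in range(20)]
        spec = StratifiedSpec(
            classes=[
                ClassSpec("A", "Acetate kinase", n_contributors=12, concentration=50.0),
                ClassSpec("B", "Butyrate kinase", n_contributors=3, concentration=0.3),
            ],
            taxa_pool=pool,
            n_samples=12,
            seed=21,
        )
        table, _ = synth_stratified(spec)
        tree = taxonomy_cladogram(pool)
        profiles = diversity_profile(
            table,
            [
                GeneClass("A", ("acetate kinase",)),
                GeneClass("B", ("butyrate kinase",)),
            ],
            tree,
        )
        for metric in ("richness", "faith_pd", "gini_simpson"):
            med = profiles.groupby("gene_class")[metric].median()
            assert med["A"] > med["B"], metric
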