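"""Functional redundancy and response diversity of gene classes.

For a class of gene families (e.g. "acetate kinase", matched against
annotation text), each sample's stratified contributions are condensed into
three alpha-diversity metrics over the contributing taxa:

* richness S — the number of distinct taxa contributing to the class
  (functional redundancy: many taxa backing the same function);
* Faith's phylogenetic diversity PD — total branch length of the minimal
  subtree connecting the contributors to the root (response diversity:
  phylogenetically spread contributors respond differently to perturbation);
* Gini–Simpson index 1 - sum(p_i^2) — evenness of the contributors' shares.

The default PD tree is a taxonomy cladogram with unit branch lengths — a
rank-based proxy, labelled as such in outputs — with a Newick override
accepted for a real phylogeny. Unknown/unclassified contributors count as a
single pseudo-taxon attached to the root at branch length 1.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .profiles_io import UNKNOWN_TAXON, StratifiedGeneTable, TaxonRecord

__all__ = [
    "GeneClass",
    "DEFAULT_GENE_CLASSES",
    "TaxonomyTree",
    "InsufficientDataError",
    "GroupComparison",
    "select_gene_families",
    "gini_simpson",
    "taxonomy_cladogram",
    "faith_pd",
    "diversity_profile",
    "compare_groups",
    "mann_whitney",
    "adjust_pvalues",
]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """A comparison group has fewer than 3 usable values."""


@dataclass(frozen=True)
class GeneClass:
    """A named set of case-insensitive annotation patterns."""

    name: str
    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.patterns or any(not p for p in self.patterns):
            raise ValueError(f"gene class {self.name!r} needs >= 1 non-empty pattern")

    def matches(self, annotation: str) -> bool:
        return any(re.search(p, annotation, re.IGNORECASE) for p in self.patterns)


#: Short-chain fatty acid synthesis genes and cell-cell binding proteins.
DEFAULT_GENE_CLASSES = (
    GeneClass("acetate kinase", ("acetate kinase",)),
    GeneClass("butyrate kinase", ("butyrate kinase",)),
    GeneClass("methylmalonyl-CoA decarboxylase", ("methylmalonyl-coa decarboxylase",)),
    GeneClass("adhesin", ("adhesin",)),
    GeneClass("fimbrial", ("fimbria",)),
    GeneClass("flagellar", ("flagell",)),
)


def select_gene_families(
    genes: StratifiedGeneTable, gene_class: GeneClass
) -> StratifiedGeneTable:
    """The subset of rows whose annotation matches the class; empty subsets
    are returned with a warning, not an error."""
    idx = [i for i, e in enumerate(genes.entries) if gene_class.matches(e.annotation)]
    if not idx:
        logger.warning("gene class %r matched no rows", gene_class.name)
    return genes.subset(idx)


def gini_simpson(shares) -> float:
    """1 - sum(p_i^2) after normalizing ``shares`` to proportions."""
    v = np.asarray(shares, dtype=float)
    if np.any(v < 0):
        raise ValueError("shares must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("gini_simpson undefined for an all-zero share vector")
    p = v / total
    return float(1.0 - np.sum(p**2))


@dataclass
class TaxonomyTree:
    """A rooted tree over taxa (scikit-bio ``TreeNode``), unit branch lengths
    by default. Built from lineages (:func:`taxonomy_cladogram`) or read from
    Newick via :meth:`from_newick`."""

    tree: TreeNode

    @property
    def tip_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}

    @classmethod
    def from_newick(cls, path, default_length: float = 1.0) -> "TaxonomyTree":
        tree = TreeNode.read(str(path))
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = default_length
        return cls(tree=tree)


def taxonomy_cladogram(taxa: list[TaxonRecord]) -> TaxonomyTree:
    """Rank cladogram from lineages: shared prefixes merge, every edge has
    length 1, children are ordered lexicographically."""
    by_id: dict[str, TaxonRecord] = {}
    for rec in taxa:
        prev = by_id.get(rec.taxon_id)
        if prev is not None and prev.lineage != rec.lineage:
            raise ValueError(f"conflicting lineages for taxon {rec.taxon_id!r}")
        by_id[rec.taxon_id] = rec
    root = TreeNode(name="root")
    index: dict[tuple, TreeNode] = {(): root}
    for rec in sorted(by_id.values(), key=lambda r: r.clade_string):
        prefix: tuple = ()
        for depth, (rank, name) in enumerate(rec.lineage):
            parent = index[prefix]
            prefix = prefix + ((rank, name),)
            node = index.get(prefix)
            if node is None:
                is_tip = depth == len(rec.lineage) - 1
                label = rec.taxon_id if is_tip else f"{rank}__{name}"
                node = TreeNode(name=label, length=1.0)
                parent.append(node)
                index[prefix] = node
    return TaxonomyTree(tree=root)


def faith_pd(present_taxa, tree: TaxonomyTree) -> float:
    """Total branch length of the minimal rooted subtree spanning the tips.

    The :data:`~paleonet.profiles_io.UNKNOWN_TAXON` pseudo-taxon attaches to
    the root with branch length 1.
    """
    present = set(present_taxa)
    extra = 0.0
    if UNKNOWN_TAXON in present and UNKNOWN_TAXON not in tree.tip_names:
        present.discard(UNKNOWN_TAXON)
        extra = 1.0
    if not present:
        return extra
    missing = present - tree.tip_names
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    # postorder sweep: a branch contributes iff its subtree holds a present tip
    total = 0.0
    has_present: dict[int, bool] = {}
    for node in tree.tree.postorder(include_self=False):
        if node.is_tip():
            hit = node.name in present
        else:
            hit = any(has_present[id(c)] for c in node.children)
        has_present[id(node)] = hit
        if hit and node.length:
            total += float(node.length)
    return total + extra


def diversity_profile(
    genes: StratifiedGeneTable,
    gene_classes,
    tree: TaxonomyTree,
    include_unknown: bool = True,
) -> pd.DataFrame:
    """Per-sample, per-class richness, Faith PD and Gini–Simpson.

    Within a class and sample, p_i is taxon i's share of the class's total
    stratified abundance (families summed per taxon). Samples with no
    contributors get S = 0, PD = 0, Gini–Simpson = 0 and ``flagged=True``.
    Long-format columns: sample, gene_class, richness, faith_pd,
    gini_simpson, flagged.
    """
    records = []
    for gene_class in gene_classes:
        subset = select_gene_families(genes, gene_class)
        for s, sample in enumerate(genes.sample_ids):
            contrib: dict[str, float] = {}
            for i, e in enumerate(subset.entries):
                if e.is_total or (e.taxon == UNKNOWN_TAXON and not include_unknown):
                    continue
                val = float(subset.values[i, s])
                if val > 0:
                    contrib[e.taxon] = contrib.get(e.taxon, 0.0) + val
            if contrib:
                records.append(
                    {
                        "sample": sample,
                        "gene_class": gene_class.name,
                        "richness": len(contrib),
                        "faith_pd": faith_pd(contrib.keys(), tree),
                        "gini_simpson": gini_simpson(list(contrib.values())),
                        "flagged": False,
                    }
                )
            else:
                records.append(
                    {
                        "sample": sample,
                        "gene_class": gene_class.name,
                        "richness": 0,
                        "faith_pd": 0.0,
                        "gini_simpson": 0.0,
                        "flagged": True,
                    }
                )
    return pd.DataFrame.from_records(records)


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str  # "exact" or "asymptotic"


def mann_whitney(a, b) -> GroupComparison:
    """Two-sided Mann–Whitney U: exact enumeration when both groups have
    <= 8 tie-free values, normal approximation with tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError(
            f"each group needs >= 3 values (got {len(a)}, {len(b)})"
        )
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=len(a),
        n_b=len(b),
        method=method,
    )


def compare_groups(
    profiles: pd.DataFrame,
    metric: str,
    a: str,
    b: str,
    by: str = "gene_class",
    include_flagged: bool = False,
) -> GroupComparison:
    """Compare ``metric`` between two levels of column ``by`` (e.g. two gene
    classes, or two cohorts via a ``group`` column). Flagged zero-contributor
    rows are excluded by default, with counts logged."""
    if metric not in profiles.columns:
        raise ValueError(f"unknown metric {metric!r}")
    df = profiles if include_flagged else profiles[~profiles["flagged"]]
    n_dropped = len(profiles) - len(df)
    if n_dropped:
        logger.info("excluded %d flagged zero-contributor rows", n_dropped)
    va = df.loc[df[by] == a, metric].to_numpy()
    vb = df.loc[df[by] == b, metric].to_numpy()
    return mann_whitney(va, vb)


def adjust_pvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; raw values are the
    default reporting convention)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
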