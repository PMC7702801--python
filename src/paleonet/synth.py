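"""Synthetic microbiome data with planted, recoverable structure.

Two generators mirror the two input kinds the pipeline consumes:

* compositional count tables — per sample, correlated log-basis abundances
  are drawn from a multivariate normal (correlation assembled from disjoint
  within-block correlations plus an optional hub taxon correlated with a
  partner set), exponentiated, normalized to fractions, and observed as
  multinomial counts at a fixed sequencing depth. The exact basis
  correlation matrix used for the Cholesky factor is returned as ground
  truth for recovery tests.
* stratified gene-family tables — per gene class, a fixed contributor set of
  the requested richness whose per-sample shares follow a symmetric
  Dirichlet with a chosen concentration (low concentration = uneven), with
  exactly consistent unstratified total rows.

The log-normal/multinomial model matches the assumptions of the
basis-variance correlation estimator (strictly positive fractions,
log-ratio structure); it is a testbed choice, not a claim about real
coprolite or calculus data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles_io import (
    UNKNOWN_TAXON,
    AbundanceTable,
    GeneEntry,
    StratifiedGeneTable,
    TaxonRecord,
)

__all__ = [
    "SyntheticSpec",
    "StratifiedSpec",
    "ClassSpec",
    "synth_abundance",
    "synth_stratified",
    "default_lineage",
    "two_block_spec",
    "planted_hub_spec",
    "four_block_hub_spec",
]


def default_lineage(i: int, species: str | None = None) -> TaxonRecord:
    """A plausible full lineage for synthetic taxon ``i``; taxa are spread
    over 4 phyla and get their own genus so the cladogram has real depth."""
    phylum = f"Phylum{i % 4}"
    species = species or f"Genus{i}_sp{i}"
    genus = species.split("_", 1)[0]
    lineage = (
        ("k", "Bacteria"),
        ("p", phylum),
        ("c", f"Class{i % 4}"),
        ("o", f"Order{i % 8}"),
        ("f", f"Family{i % 8}"),
        ("g", genus),
        ("s", species),
    )
    return TaxonRecord(taxon_id=species, lineage=lineage)


@dataclass
class SyntheticSpec:
    """Generative spec for a compositional count table.

    Correlation blocks are (index set, within-block basis correlation);
    ``hub`` is (hub index, partner indices, hub-partner correlation) — the
    partner-partner correlation is set to the square of the hub-partner
    value (one-factor structure) so the matrix stays positive definite.
    """

    n_samples: int = 30
    n_taxa: int = 20
    log_mean: float | np.ndarray = 0.0
    log_sd: float | np.ndarray = 1.0
    blocks: list[tuple[list[int], float]] = field(default_factory=list)
    hub: tuple[int, list[int], float] | None = None
    depth: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        seen: set[int] = set()
        for idx, rho in self.blocks:
            if not -1 < rho < 1:
                raise ValueError(f"block correlation {rho} outside (-1, 1)")
            if seen & set(idx):
                raise ValueError("correlation blocks must be disjoint")
            seen |= set(idx)
        self.correlation_matrix()  # fail fast on non-positive-definite specs

    def correlation_matrix(self) -> np.ndarray:
        r = np.eye(self.n_taxa)
        for idx, rho in self.blocks:
            for i in idx:
                for j in idx:
                    if i != j:
                        r[i, j] = rho
        if self.hub is not None:
            h, partners, rho = self.hub
            for p in partners:
                r[h, p] = r[p, h] = rho
            for p in partners:
                for q in partners:
                    if p != q and r[p, q] == 0.0:
                        r[p, q] = r[q, p] = rho * rho
        try:
            np.linalg.cholesky(r + 1e-12 * np.eye(self.n_taxa))
        except np.linalg.LinAlgError:
            raise ValueError(
                f"implied correlation matrix not positive definite "
                f"(blocks={self.blocks}, hub={self.hub})"
            )
        return r


def synth_abundance(
    spec: SyntheticSpec, return_log_basis: bool = False
) -> tuple[AbundanceTable, np.ndarray]:
    """Draw a count table from the spec; returns (table, true basis correlation).

    With ``return_log_basis=True`` the drawn log-basis matrix is appended to
    the result for diagnostics (the observed counts are closed to fractions,
    which attenuates correlations relative to the open basis).
    """
    r = spec.correlation_matrix()
    sd = np.broadcast_to(np.asarray(spec.log_sd, dtype=float), (spec.n_taxa,))
    mu = np.broadcast_to(np.asarray(spec.log_mean, dtype=float), (spec.n_taxa,))
    cov = r * np.outer(sd, sd)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(spec.n_taxa))
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_samples, spec.n_taxa))
    log_basis = mu + z @ chol.T
    basis = np.exp(log_basis)
    fractions = basis / basis.sum(axis=1, keepdims=True)
    counts = np.array(
        [rng.multinomial(spec.depth, frac) for frac in fractions], dtype=float
    )
    taxa = [default_lineage(i) for i in range(spec.n_taxa)]
    table = AbundanceTable(
        sample_ids=[f"sample_{s}" for s in range(spec.n_samples)],
        taxa=taxa,
        values=counts,
        kind="counts",
        meta={"generator": "synth_abundance", "seed": spec.seed, "depth": spec.depth},
    )
    if return_log_basis:
        return table, r, log_basis
    return table, r


@dataclass(frozen=True)
class ClassSpec:
    """One gene class to plant: ``n_contributors`` taxa whose shares follow a
    symmetric Dirichlet(``concentration``), scaled by ``scale``."""

    name: str
    annotation: str
    n_contributors: int
    concentration: float = 1.0
    scale: float = 100.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.n_contributors < 1:
            raise ValueError("n_contributors must be >= 1")


@dataclass
class StratifiedSpec:
    classes: list[ClassSpec]
    taxa_pool: list[TaxonRecord]
    n_samples: int = 10
    seed: int = 0
    shuffle_contributors: bool = False

    def __post_init__(self) -> None:
        pool = len(self.taxa_pool)
        for c in self.classes:
            if c.n_contributors > pool:
                raise ValueError(
                    f"class {c.name!r} wants {c.n_contributors} contributors, "
                    f"pool has {pool}"
                )


def synth_stratified(
    spec: StratifiedSpec,
) -> tuple[StratifiedGeneTable, dict[str, dict]]:
    """Generate a stratified table; returns (table, ground truth per class).

    Contributor sets are fixed across samples by default so planted richness
    is exact in every sample; total rows are written as the exact sum of
    their stratified rows. Ground truth records each class's contributor
    list and the expected Gini–Simpson of equal shares.
    """
    rng = np.random.default_rng(spec.seed)
    sample_ids = [f"sample_{s}" for s in range(spec.n_samples)]
    entries: list[GeneEntry] = []
    rows: list[np.ndarray] = []
    truth: dict[str, dict] = {}
    for ci, cls in enumerate(spec.classes):
        family_id = f"UF{ci:04d}"
        base_choice = rng.choice(
            len(spec.taxa_pool), size=cls.n_contributors, replace=False
        )
        strat_values = np.zeros((cls.n_contributors, spec.n_samples))
        contributors_per_sample = []
        for s in range(spec.n_samples):
            if spec.shuffle_contributors:
                choice = rng.choice(
                    len(spec.taxa_pool), size=cls.n_contributors, replace=False
                )
            else:
                choice = base_choice
            contributors_per_sample.append(choice)
            shares = rng.dirichlet(np.full(cls.n_contributors, cls.concentration))
            strat_values[:, s] = shares * cls.scale
        if spec.shuffle_contributors:
            # one row per (taxon, sample) union; rebuild densely
            union = sorted({int(i) for ch in contributors_per_sample for i in ch})
            dense = np.zeros((len(union), spec.n_samples))
            for s, choice in enumerate(contributors_per_sample):
                for k, i in enumerate(choice):
                    dense[union.index(int(i)), s] = strat_values[k, s]
            contrib_idx, strat_values = union, dense
        else:
            contrib_idx = [int(i) for i in base_choice]
        total = strat_values.sum(axis=0)
        entries.append(GeneEntry(family_id, cls.annotation, None))
        rows.append(total)
        names = [spec.taxa_pool[i].taxon_id for i in contrib_idx]
        for name, row in zip(names, strat_values):
            entries.append(GeneEntry(family_id, cls.annotation, name))
            rows.append(row)
        truth[cls.name] = {
            "family_id": family_id,
            "contributors": names,
            "richness": cls.n_contributors,
            "equal_share_gini_simpson": 1.0 - 1.0 / cls.n_contributors,
            "concentration": cls.concentration,
        }
    table = StratifiedGeneTable(
        sample_ids=sample_ids,
        entries=entries,
        values=np.vstack(rows),
        meta={"generator": "synth_stratified", "seed": spec.seed},
    )
    return table, truth


# ---------------------------------------------------------------------------
# canonical study-condition specs used across tests and end-to-end runs
# ---------------------------------------------------------------------------


def two_block_spec(seed: int = 0) -> SyntheticSpec:
    """Two planted 8-taxon blocks (basis rho 0.7) among 20 taxa, 30 samples."""
    return SyntheticSpec(
        n_samples=30,
        n_taxa=20,
        blocks=[(list(range(0, 8)), 0.7), (list(range(8, 16)), 0.7)],
        seed=seed,
    )


def planted_hub_spec(seed: int = 0) -> SyntheticSpec:
    """One hub taxon correlated (rho 0.6) with 10 partners among 20 taxa."""
    return SyntheticSpec(
        n_samples=30,
        n_taxa=20,
        hub=(0, list(range(1, 11)), 0.6),
        seed=seed,
    )


def four_block_hub_spec(seed: int = 0) -> SyntheticSpec:
    """Four 5-taxon blocks plus a 9-partner hub over 40 samples (subsampling cohort)."""
    return SyntheticSpec(
        n_samples=40,
        n_taxa=30,
        blocks=[
            (list(range(0, 5)), 0.7),
            (list(range(5, 10)), 0.7),
            (list(range(10, 15)), 0.7),
            (list(range(15, 20)), 0.7),
        ],
        hub=(20, list(range(21, 30)), 0.6),
        seed=seed,
    )
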