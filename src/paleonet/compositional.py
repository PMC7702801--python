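"""Compositionally corrected taxon-taxon correlation estimation.

Relative-abundance data are compositional: the sum-to-one constraint alone
induces spurious negative correlations between taxa. The estimator here
follows the basis-variance (SparCC-style) approach: from the log-ratio
variance matrix

    t_ij = var(log(x_i / x_j))

it solves a sparsity-approximation linear system for per-taxon basis
variances w_i^2 and recovers basis correlations

    rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j),

then iteratively excludes the most strongly correlated pairs (which violate
the sparsity assumption) from the linear system and re-solves. Count tables
are resampled through a Dirichlet posterior (uniform prior, pseudocount 1)
so the estimate can be averaged over resampling draws; replicated estimation
with independent seeds is what makes 100-fold network replication meaningful
downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .profiles_io import AbundanceTable

__all__ = [
    "CorrelationEstimate",
    "InsufficientDimensionError",
    "DegenerateSampleError",
    "dirichlet_fractions",
    "log_ratio_variances",
    "basis_correlations",
    "estimate_correlations",
    "pearson_log_correlations",
]

logger = logging.getLogger(__name__)

#: floor applied to non-positive basis-variance solutions (small-sample pathology)
OMEGA_SQ_FLOOR = 1e-6


class InsufficientDimensionError(ValueError):
    """Fewer than 4 taxa: the sparsity linear system is underdetermined."""


class DegenerateSampleError(ValueError):
    """A sample with zero total count cannot be resampled."""


@dataclass
class CorrelationEstimate:
    """Symmetric taxa x taxa basis-correlation matrix with provenance."""

    taxa: list[str]
    rho: np.ndarray
    n_inner: int = 1
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        d = len(self.taxa)
        if self.rho.shape != (d, d):
            raise ValueError(f"rho shape {self.rho.shape} != ({d}, {d})")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValueError("rho must be symmetric")
        if np.any(np.abs(self.rho) > 1 + 1e-9):
            raise ValueError("rho entries must lie in [-1, 1]")
        if not np.allclose(np.diag(self.rho), 1.0):
            raise ValueError("rho diagonal must be 1")

    def pair(self, a: str, b: str) -> float:
        return float(self.rho[self.taxa.index(a), self.taxa.index(b)])


def dirichlet_fractions(counts: np.ndarray, seed) -> np.ndarray:
    """One posterior draw of underlying fractions per sample.

    ``seed`` may be an int, a Generator, or a SeedSequence. A uniform prior
    (pseudocount 1 in every cell) keeps all fractions strictly positive; each
    row of the result sums to 1. Fixed seed => bit-identical output.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a samples x taxa matrix")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        bad = np.where(totals <= 0)[0].tolist()
        raise DegenerateSampleError(f"all-zero sample rows at indices {bad}")
    rng = np.random.default_rng(seed)
    draws = rng.gamma(shape=counts + 1.0)  # Dirichlet via normalized gammas
    return draws / draws.sum(axis=1, keepdims=True)


def log_ratio_variances(fractions: np.ndarray, ddof: int = 1) -> np.ndarray:
    """The matrix t with t_ij = var(log(x_i / x_j)); zero diagonal, symmetric.

    Computed through the covariance of log fractions:
    var(log x_i - log x_j) = S_ii + S_jj - 2 S_ij.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions <= 0):
        raise ValueError("fractions must be strictly positive")
    logx = np.log(fractions)
    cov = np.cov(logx, rowvar=False, ddof=ddof)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    t = 0.5 * (t + t.T)
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def basis_correlations(
    fractions: np.ndarray,
    exclusion_threshold: float = 0.1,
    max_exclusion_rounds: int = 10,
    taxa: list[str] | None = None,
) -> CorrelationEstimate:
    """Basis correlations from one strictly positive fraction matrix.

    Solves M w2 = t_rowsums with M = (D-2) I + J over active pairs, then runs
    up to ``max_exclusion_rounds`` exclusion iterations: the active pair with
    the largest \\|rho\\| above ``exclusion_threshold`` is removed from the
    system (ties broken by lexicographically smallest taxon pair) and the
    system re-solved. Non-positive basis variances are floored at
    :data:`OMEGA_SQ_FLOOR` with a warning.
    """
    fractions = np.asarray(fractions, dtype=float)
    n, d = fractions.shape
    if d < 4:
        raise InsufficientDimensionError(
            f"need >= 4 taxa for the sparsity system, got {d}"
        )
    if n < 2:
        raise ValueError("need >= 2 samples")
    if taxa is None:
        taxa = [f"taxon_{i}" for i in range(d)]

    t = log_ratio_variances(fractions)
    # design matrix: diagonal = number of active partners, off-diagonal = 1 if active
    active = ~np.eye(d, dtype=bool)
    excluded: list[tuple[int, int]] = []
    rho = np.eye(d)
    floored = False
    for round_no in range(max_exclusion_rounds + 1):
        m = np.where(active, 1.0, 0.0)
        np.fill_diagonal(m, active.sum(axis=1))
        tsum = np.where(active, t, 0.0).sum(axis=1)
        omega_sq = np.linalg.solve(m, tsum)
        if np.any(omega_sq <= 0):
            floored = True
            omega_sq = np.maximum(omega_sq, OMEGA_SQ_FLOOR)
        omega = np.sqrt(omega_sq)
        rho = (omega_sq[:, None] + omega_sq[None, :] - t) / (2.0 * np.outer(omega, omega))
        np.clip(rho, -1.0, 1.0, out=rho)
        np.fill_diagonal(rho, 1.0)
        if round_no == max_exclusion_rounds:
            break
        cand = np.abs(np.where(active, rho, 0.0))
        np.fill_diagonal(cand, 0.0)
        best = cand.max()
        if best <= exclusion_threshold:
            break
        pairs = [
            (i, j) for i, j in zip(*np.where(cand >= best - 1e-15)) if i < j
        ]
        i, j = min(pairs, key=lambda p: tuple(sorted((taxa[p[0]], taxa[p[1]]))))
        active[i, j] = active[j, i] = False
        excluded.append((i, j))
        if active.sum(axis=1).min() < 2:  # system degenerating; stop excluding
            break
    if floored:
        warnings.warn(
            "non-positive basis variance floored at 1e-6 (small-sample pathology)",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("floored non-positive basis variance estimates")
    return CorrelationEstimate(
        taxa=list(taxa),
        rho=rho,
        n_inner=1,
        excluded_pairs=[tuple(sorted((taxa[i], taxa[j]))) for i, j in excluded],
        meta={"exclusion_threshold": exclusion_threshold, "floored": floored},
    )


def _as_counts(table: AbundanceTable, depth: int) -> np.ndarray:
    if table.kind == "counts":
        return np.asarray(table.values, dtype=float)
    logger.info("rescaling relative abundances to pseudo-counts at depth %d", depth)
    return np.rint(table.values * depth)


def estimate_correlations(
    table: AbundanceTable,
    n_inner: int = 20,
    exclusion_threshold: float = 0.1,
    seed: int | None = 0,
    depth: int = 10_000,
    max_exclusion_rounds: int = 10,
) -> CorrelationEstimate:
    """Average basis correlations over ``n_inner`` Dirichlet resampling draws.

    Relative tables are first rescaled to pseudo-counts at ``depth`` (rounded);
    counts are used as-is. Deterministic under a fixed ``seed``.
    """
    counts = _as_counts(table, depth)
    taxa = table.taxon_ids
    if len(taxa) < 4:
        raise InsufficientDimensionError(
            f"need >= 4 taxa for the sparsity system, got {len(taxa)}"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_inner)
    acc = np.zeros((len(taxa), len(taxa)))
    excluded: set[tuple[str, str]] = set()
    for ss in child_seeds:
        frac = dirichlet_fractions(counts, ss)
        est = basis_correlations(
            frac,
            exclusion_threshold=exclusion_threshold,
            max_exclusion_rounds=max_exclusion_rounds,
            taxa=taxa,
        )
        acc += est.rho
        excluded.update(est.excluded_pairs)
    rho = np.clip(acc / n_inner, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationEstimate(
        taxa=taxa,
        rho=rho,
        n_inner=n_inner,
        excluded_pairs=sorted(excluded),
        seed=seed if isinstance(seed, int) else None,
        meta={
            "exclusion_threshold": exclusion_threshold,
            "max_exclusion_rounds": max_exclusion_rounds,
            "depth": depth if table.kind == "relative" else None,
            "estimator": "sparcc",
        },
    )


def pearson_log_correlations(
    table: AbundanceTable, pseudo: float = 1e-6
) -> CorrelationEstimate:
    """Plain Pearson correlation of log abundances (selectable alternative
    backend; no compositional correction)."""
    x = np.log(np.asarray(table.values, dtype=float) + pseudo)
    rho = np.corrcoef(x, rowvar=False)
    rho = np.clip(0.5 * (rho + rho.T), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationEstimate(
        taxa=table.taxon_ids, rho=rho, n_inner=1, meta={"estimator": "pearson_log"}
    )
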