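"""Sample-size robustness simulation.

Cohorts are repeatedly subsampled (without replacement) to a ladder of sizes
(default 5, 10, 20), taxa re-filtered, and the whole network-replication
machinery re-run on each subsample. The outputs track how the cluster count
and the network distinctness ratio (modularity / transitivity) scale with
sample size — summarized by the OLS coefficient of determination r^2 on the
pooled (size, value) points — and how well each subsample's consensus
keystones recover the full-cohort keystones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .keystones import (
    METHODS,
    KeystoneReport,
    consensus_keystones,
    replicate_candidates,
)
from .network import NetworkPropertySummary, replicate_networks
from .profiles_io import AbundanceTable, EmptyTableError, filter_taxa

__all__ = [
    "SubsampleRecord",
    "SubsampleResult",
    "FitResult",
    "subsample_experiment",
    "fit_r2",
    "keystone_overlap",
]

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    r_squared: float
    slope: float
    n_points: int


@dataclass
class SubsampleRecord:
    size: int
    rep: int
    summary: NetworkPropertySummary | None
    keystones: KeystoneReport | None
    failed: bool = False


@dataclass
class SubsampleResult:
    sizes: list[int]
    reps_per_size: int
    records: list[SubsampleRecord]
    r_squared: dict[str, FitResult]
    keystone_overlap: dict[int, dict[str, dict[str, float]]]
    full_keystones: KeystoneReport
    provenance: dict = field(default_factory=dict)

    def values(self, prop: str) -> list[tuple[int, float]]:
        """Pooled (size, value) points for one property over non-failed reps."""
        pts = []
        for rec in self.records:
            if rec.failed or rec.summary is None:
                continue
            if prop == "distinctness_ratio":
                v = rec.summary.distinctness_ratio
            else:
                v = rec.summary.means.get(prop)
            if v is not None:
                pts.append((rec.size, float(v)))
        return pts


def fit_r2(points) -> FitResult:
    """OLS of property value on sample size: r^2 plus the slope sign.

    Needs >= 3 points over >= 2 distinct sizes.
    """
    pts = [(float(s), float(v)) for s, v in points]
    if len(pts) < 3:
        raise ValueError("need >= 3 points")
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if len(np.unique(xs)) < 2:
        raise ValueError("all sizes identical; fit undefined")
    if np.allclose(ys, ys[0]):
        return FitResult(r_squared=0.0, slope=0.0, n_points=len(pts))
    res = stats.linregress(xs, ys)
    return FitResult(
        r_squared=float(res.rvalue**2), slope=float(res.slope), n_points=len(pts)
    )


def keystone_overlap(
    sub: KeystoneReport, full: KeystoneReport
) -> dict[str, dict[str, float]]:
    """Per-method recovery |sub ∩ full| / |full| and Jaccard similarity.

    An empty full-cohort keystone set yields NaNs, flagged via the
    ``undefined`` key.
    """
    if set(sub.keystones) != set(full.keystones):
        raise ValueError(
            f"method mismatch: {sorted(sub.keystones)} vs {sorted(full.keystones)}"
        )
    out: dict[str, dict[str, float]] = {}
    for method in full.keystones:
        s, f = sub.taxa(method), full.taxa(method)
        if not f:
            out[method] = {"recovery": float("nan"), "jaccard": float("nan"),
                           "undefined": True}
            continue
        inter = len(s & f)
        union = len(s | f)
        out[method] = {
            "recovery": inter / len(f),
            "jaccard": inter / union if union else 1.0,
            "undefined": False,
        }
    return out


def subsample_experiment(
    table: AbundanceTable,
    sizes=(5, 10, 20),
    reps_per_size: int = 10,
    seed: int | None = 0,
    n_replicates: int = 20,
    threshold: float = 0.3,
    sign_mode: str = "positive",
    estimator: dict | None = None,
    filter_params: dict | None = None,
    k: int = 5,
    full_summary_replicates: int | None = None,
) -> SubsampleResult:
    """Run the subsampling ladder and compare against the full cohort.

    The full cohort is first filtered and replicated (``full_summary_replicates``
    network replicates, default the same ``n_replicates``) to fix the
    reference keystone sets. Then for each (size, rep) an independent RNG
    substream draws that many samples without replacement, taxa are
    re-filtered with the same thresholds, and the replicate-network summary
    plus consensus keystones are recorded. Degenerate subsamples (all
    replicates edgeless, or no taxa surviving the filter) are recorded as
    failed rather than fatal.
    """
    sizes = [int(s) for s in sizes]
    if any(s >= table.n_samples for s in sizes):
        raise ValueError(
            f"every subsample size must be < {table.n_samples} samples; got {sizes}"
        )
    if reps_per_size < 1:
        raise ValueError("reps_per_size must be >= 1")
    estimator = dict(estimator or {})
    filter_params = dict(filter_params or {})
    rel = _as_relative(table)

    root = np.random.SeedSequence(seed)
    full_ss, sub_ss = root.spawn(2)
    full_filtered = filter_taxa(rel, **filter_params)
    _, full_reps = replicate_networks(
        full_filtered,
        n_replicates=full_summary_replicates or n_replicates,
        threshold=threshold,
        sign_mode=sign_mode,
        seed=full_ss,
        estimator=estimator,
    )
    full_keystones = consensus_keystones(
        replicate_candidates([net for net, _ in full_reps], k=k)
    )

    records: list[SubsampleRecord] = []
    child = iter(sub_ss.spawn(len(sizes) * reps_per_size))
    for size in sizes:
        for rep in range(reps_per_size):
            ss = next(child)
            rng = np.random.default_rng(ss)
            pick = rng.choice(table.n_samples, size=size, replace=False)
            sub_table = rel.subset_samples([table.sample_ids[i] for i in sorted(pick)])
            try:
                sub_filtered = filter_taxa(sub_table, **filter_params)
                summary, reps = replicate_networks(
                    sub_filtered,
                    n_replicates=n_replicates,
                    threshold=threshold,
                    sign_mode=sign_mode,
                    seed=ss.spawn(1)[0],
                    estimator=estimator,
                )
                ks = consensus_keystones(
                    replicate_candidates([net for net, _ in reps], k=k)
                )
                records.append(SubsampleRecord(size, rep, summary, ks))
            except (EmptyTableError, RuntimeError) as exc:
                logger.warning("subsample size=%d rep=%d degenerate: %s", size, rep, exc)
                records.append(SubsampleRecord(size, rep, None, None, failed=True))

    result = SubsampleResult(
        sizes=sizes,
        reps_per_size=reps_per_size,
        records=records,
        r_squared={},
        keystone_overlap={},
        full_keystones=full_keystones,
        provenance={
            "seed": seed if isinstance(seed, int) else None,
            "n_replicates": n_replicates,
            "threshold": threshold,
            "sign_mode": sign_mode,
            "estimator": estimator,
            "filter": filter_params,
            "r2_mode": "pooled",
        },
    )
    for prop in ("n_clusters", "distinctness_ratio", "modularity", "transitivity"):
        pts = result.values(prop)
        try:
            result.r_squared[prop] = fit_r2(pts)
        except ValueError:
            logger.warning("r^2 undefined for %s (%d usable points)", prop, len(pts))
    for size in sizes:
        per_method: dict[str, list[dict[str, float]]] = {m: [] for m in METHODS}
        for rec in records:
            if rec.size != size or rec.failed or rec.keystones is None:
                continue
            for m, d in keystone_overlap(rec.keystones, full_keystones).items():
                per_method[m].append(d)
        result.keystone_overlap[size] = {
            m: {
                "recovery": float(np.mean([d["recovery"] for d in ds]))
                if ds
                else float("nan"),
                "jaccard": float(np.mean([d["jaccard"] for d in ds]))
                if ds
                else float("nan"),
                "n_reps": len(ds),
            }
            for m, ds in per_method.items()
        }
    return result


def _as_relative(table: AbundanceTable) -> AbundanceTable:
    if table.kind == "relative":
        return table
    sums = table.values.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise EmptyTableError("cannot normalize samples with zero total count")
    from dataclasses import replace

    return replace(table, values=table.values / sums, kind="relative")
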