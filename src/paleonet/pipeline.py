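"""Config-driven orchestration of the full analysis with provenance.

Stages: network replication -> consensus keystones -> keystone gene
profiles -> functional diversity -> cluster co-occurrence -> subsampling
simulation. Every effective parameter is echoed into ``manifest.json`` so a
run can be re-executed bit-for-bit from its own manifest; stage reruns reuse
cached upstream outputs keyed by a content hash of the inputs and the
relevant config subsection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import __version__
from .diversity import GeneClass, diversity_profile, taxonomy_cladogram
from .keystones import (
    KeystoneReport,
    consensus_keystones,
    keystone_gene_profile,
    TaxonNotFoundError,
)
from .network import ClusterAssignment, cluster_cooccurrence, replicate_networks
from .keystones import replicate_candidates
from .profiles_io import (
    AbundanceTable,
    filter_taxa,
    read_stratified_genefamilies,
    read_taxonomic_table,
    write_stratified_genefamilies,
    write_taxonomic_table,
)
from .subsample import subsample_experiment
from .synth import ClassSpec, StratifiedSpec, SyntheticSpec, synth_abundance, synth_stratified

__all__ = [
    "RunConfig",
    "ConfigError",
    "MissingUpstreamError",
    "run_full_analysis",
    "run_stage",
    "run_synth",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """RunConfig validation failure (CLI exit code 3)."""


class MissingUpstreamError(FileNotFoundError):
    """A dependent stage is missing its cached upstream artifact (exit 4)."""


_DEFAULT_CLASSES = [
    {"name": "acetate kinase", "patterns": ["acetate kinase"]},
    {"name": "butyrate kinase", "patterns": ["butyrate kinase"]},
    {
        "name": "methylmalonyl-CoA decarboxylase",
        "patterns": ["methylmalonyl-coa decarboxylase"],
    },
    {"name": "adhesin", "patterns": ["adhesin"]},
    {"name": "fimbrial", "patterns": ["fimbria"]},
    {"name": "flagellar", "patterns": ["flagell"]},
]


@dataclass
class RunConfig:
    """Every effective parameter of a pipeline run; the seed is mandatory."""

    taxonomic_table: str
    outdir: str
    seed: int
    stratified_table: str | None = None
    level: str = "species"
    min_prevalence: float = 0.3
    min_mean_abundance: float = 1e-4
    n_inner: int = 20
    exclusion_threshold: float = 0.1
    max_exclusion_rounds: int = 10
    depth: int = 10_000
    threshold: float = 0.3
    sign_mode: str = "positive"
    n_replicates: int = 100
    k: int = 5
    min_count: int | None = None
    top_n_genes: int = 50
    gene_classes: list = field(default_factory=lambda: [dict(c) for c in _DEFAULT_CLASSES])
    focal_taxa: list = field(default_factory=list)
    subsample_sizes: list = field(default_factory=lambda: [5, 10, 20])
    subsample_reps: int = 10
    subsample_replicates: int = 20
    run_subsample: bool = True

    def validate(self) -> None:
        errors = []
        if self.seed is None:
            errors.append("seed: required, no silent nondeterminism")
        if not 0 < self.threshold < 1:
            errors.append(f"threshold: must be in (0, 1), got {self.threshold}")
        if self.sign_mode not in ("positive", "absolute"):
            errors.append(f"sign_mode: must be positive|absolute, got {self.sign_mode}")
        if not 0 <= self.min_prevalence <= 1:
            errors.append(f"min_prevalence: must be in [0, 1], got {self.min_prevalence}")
        if self.n_replicates < 2:
            errors.append(f"n_replicates: must be >= 2, got {self.n_replicates}")
        if self.n_inner < 1:
            errors.append(f"n_inner: must be >= 1, got {self.n_inner}")
        if self.k < 1:
            errors.append(f"k: must be >= 1, got {self.k}")
        if self.depth < 100:
            errors.append(f"depth: must be >= 100, got {self.depth}")
        if self.min_count is not None and self.min_count > self.n_replicates:
            errors.append("min_count: exceeds n_replicates")
        if errors:
            raise ConfigError("; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # -- estimator / filter kwargs -------------------------------------
    @property
    def estimator_kwargs(self) -> dict:
        return {
            "n_inner": self.n_inner,
            "exclusion_threshold": self.exclusion_threshold,
            "max_exclusion_rounds": self.max_exclusion_rounds,
            "depth": self.depth,
        }

    @property
    def filter_kwargs(self) -> dict:
        return {
            "min_prevalence": self.min_prevalence,
            "min_mean_abundance": self.min_mean_abundance,
        }


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, allow_nan=True) + "\n")


def _content_key(config: RunConfig, *paths) -> str:
    h = hashlib.sha256()
    params = config.to_dict()
    params.pop("outdir", None)  # where outputs land never changes what they hold
    h.update(json.dumps(params, sort_keys=True).encode())
    for p in paths:
        if p and Path(p).exists():
            h.update(Path(p).read_bytes())
    return h.hexdigest()[:16]


def _load_filtered(config: RunConfig) -> AbundanceTable:
    path = Path(config.taxonomic_table)
    if not path.exists():
        raise FileNotFoundError(f"taxonomic table not found: {path}")
    table = read_taxonomic_table(path, level=config.level)
    return filter_taxa(table, **config.filter_kwargs)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_network(config: RunConfig, outdir: Path) -> dict:
    table = _load_filtered(config)
    summary, reps = replicate_networks(
        table,
        n_replicates=config.n_replicates,
        threshold=config.threshold,
        sign_mode=config.sign_mode,
        seed=config.seed,
        estimator=config.estimator_kwargs,
    )
    cands = replicate_candidates([net for net, _ in reps], k=config.k)
    cache = {
        "key": _content_key(config, config.taxonomic_table),
        "summary": {
            "means": summary.means,
            "sds": summary.sds,
            "categories": summary.categories,
            "distinctness_ratio": summary.distinctness_ratio,
            "n_replicates": summary.n_replicates,
            "n_failed": summary.n_failed,
        },
        "candidates": cands,
        "cluster_labels": [
            {"labels": c.labels, "modularity_q": c.modularity_q} for _, c in reps
        ],
    }
    _json_dump(cache, outdir / "cache_network.json")
    _json_dump(cache["summary"], outdir / "network_summary.json")
    net0 = reps[0][0]
    nx.write_graphml(net0.graph, outdir / "network_replicate0.graphml")
    with open(outdir / "network_edges.tsv", "w") as fh:
        fh.write("taxon_a\ttaxon_b\tweight\n")
        for a, b, d in sorted(net0.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['weight']:.6f}\n")
    return cache


def _load_network_cache(config: RunConfig, outdir: Path) -> dict:
    path = outdir / "cache_network.json"
    if not path.exists():
        raise MissingUpstreamError(f"run the network stage first: missing {path}")
    cache = json.loads(path.read_text())
    if cache.get("key") == _content_key(config, config.taxonomic_table):
        logger.info("network cache hit (%s)", cache["key"])
    else:
        logger.warning("network cache key mismatch; results may be stale")
    return cache


def _stage_keystones(config: RunConfig, outdir: Path, cache: dict | None = None) -> KeystoneReport:
    cache = cache or _load_network_cache(config, outdir)
    report = consensus_keystones(cache["candidates"], min_count=config.min_count)
    payload = {
        "min_count": report.min_count,
        "n_replicates": report.n_replicates,
        "keystones": report.keystones,
        "near_misses": report.near_misses,
    }
    _json_dump(payload, outdir / "keystones.json")
    with open(outdir / "keystones.tsv", "w") as fh:
        fh.write("method\ttaxon\tcount\n")
        for method in sorted(report.keystones):
            for taxon, count in report.keystones[method]:
                fh.write(f"{method}\t{taxon}\t{count}\n")
    return report


def _stage_gene_profiles(config: RunConfig, outdir: Path, report: KeystoneReport) -> None:
    genes = read_stratified_genefamilies(config.stratified_table)
    taxa = sorted({t for m in report.keystones.values() for t, _ in m})
    with open(outdir / "keystone_gene_profiles.tsv", "w") as fh:
        fh.write("taxon\trank\tfamily_id\tannotation\tsummed_abundance\n")
        for taxon in taxa:
            try:
                profile = keystone_gene_profile(genes, taxon, top_n=config.top_n_genes)
            except TaxonNotFoundError:
                logger.warning("keystone %r has no stratified gene entries", taxon)
                continue
            for rank, (fam, ann, ab) in enumerate(profile, start=1):
                fh.write(f"{taxon}\t{rank}\t{fam}\t{ann}\t{ab:.6f}\n")


def _stage_fdiv(config: RunConfig, outdir: Path) -> None:
    if not config.stratified_table or not Path(config.stratified_table).exists():
        raise FileNotFoundError(
            f"stratified gene-family table not found: {config.stratified_table}"
        )
    genes = read_stratified_genefamilies(config.stratified_table)
    classes = [GeneClass(c["name"], tuple(c["patterns"])) for c in config.gene_classes]
    table = read_taxonomic_table(config.taxonomic_table, level=config.level)
    known = {t.taxon_id: t for t in table.taxa}
    from .synth import default_lineage

    records = []
    for i, name in enumerate(sorted(set(genes.taxa()))):
        if name == "UNKNOWN":
            continue
        records.append(known.get(name) or default_lineage(i, species=name))
    tree = taxonomy_cladogram(records)
    profiles = diversity_profile(genes, classes, tree)
    profiles.to_csv(outdir / "diversity_profiles.tsv", sep="\t", index=False)


def _stage_cooccur(config: RunConfig, outdir: Path, cache: dict | None = None) -> None:
    cache = cache or _load_network_cache(config, outdir)
    assignments = [
        ClusterAssignment(labels=c["labels"], modularity_q=c["modularity_q"])
        for c in cache["cluster_labels"]
    ]
    focal = list(config.focal_taxa)
    if not focal:
        report = consensus_keystones(cache["candidates"], min_count=config.min_count)
        focal = sorted({t for m in report.keystones.values() for t, _ in m})
    freq, denom = cluster_cooccurrence(assignments, focal)
    freq.to_csv(outdir / "cooccurrence.tsv", sep="\t")
    denom.to_csv(outdir / "cooccurrence_denominators.tsv", sep="\t")


def _stage_subsample(config: RunConfig, outdir: Path) -> None:
    path = Path(config.taxonomic_table)
    if not path.exists():
        raise FileNotFoundError(f"taxonomic table not found: {path}")
    table = read_taxonomic_table(path, level=config.level)
    usable = [s for s in config.subsample_sizes if s < table.n_samples]
    if not usable:
        logger.warning("cohort too small for any subsample size; skipping")
        _json_dump({"skipped": True}, outdir / "subsample.json")
        return
    result = subsample_experiment(
        table,
        sizes=usable,
        reps_per_size=config.subsample_reps,
        seed=config.seed,
        n_replicates=config.subsample_replicates,
        threshold=config.threshold,
        sign_mode=config.sign_mode,
        estimator=config.estimator_kwargs,
        filter_params=config.filter_kwargs,
        k=config.k,
        full_summary_replicates=config.n_replicates,
    )
    payload = {
        "sizes": result.sizes,
        "reps_per_size": result.reps_per_size,
        "r_squared": {
            prop: {"r_squared": f.r_squared, "slope": f.slope, "n_points": f.n_points}
            for prop, f in result.r_squared.items()
        },
        "keystone_overlap": result.keystone_overlap,
        "records": [
            {
                "size": rec.size,
                "rep": rec.rep,
                "failed": rec.failed,
                "means": rec.summary.means if rec.summary else None,
                "distinctness_ratio": rec.summary.distinctness_ratio
                if rec.summary
                else None,
            }
            for rec in result.records
        ],
        "provenance": result.provenance,
    }
    _json_dump(payload, outdir / "subsample.json")


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage; returns {output name: path}. Raises on stage failure."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "network"
    try:
        cache = _stage_network(config, outdir)
        stage = "keystones"
        report = _stage_keystones(config, outdir, cache)
        if config.stratified_table:
            stage = "gene_profiles"
            _stage_gene_profiles(config, outdir, report)
            stage = "fdiv"
            _stage_fdiv(config, outdir)
        stage = "cooccur"
        _stage_cooccur(config, outdir, cache)
        if config.run_subsample:
            stage = "subsample"
            _stage_subsample(config, outdir)
    except Exception:
        logger.error("stage %r failed", stage)
        raise
    import time

    manifest = {
        "config": config.to_dict(),
        "versions": {
            "paleonet": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "networkx": nx.__version__,
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _json_dump(manifest, outdir / "manifest.json")
    return {p.name: str(p) for p in sorted(outdir.iterdir())}


_STAGES = {
    "network": _stage_network,
    "keystones": _stage_keystones,
    "fdiv": _stage_fdiv,
    "cooccur": _stage_cooccur,
    "subsample": _stage_subsample,
}


def run_stage(stage: str, config: RunConfig) -> None:
    """Run a single stage, reusing cached upstream outputs where they exist."""
    config.validate()
    if stage not in _STAGES:
        raise ConfigError(f"unknown stage {stage!r}; one of {sorted(_STAGES)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _STAGES[stage](config, outdir)


# ---------------------------------------------------------------------------
# synthetic-data stage
# ---------------------------------------------------------------------------


def run_synth(spec_path, outdir, seed: int) -> dict:
    """Generate synthetic inputs from a YAML spec, in the dialects the
    readers consume. Returns {output name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(spec_path) as fh:
        spec = yaml.safe_load(fh) or {}
    outputs = {}
    if "abundance" in spec:
        a = dict(spec["abundance"])
        a.setdefault("seed", seed)
        a["blocks"] = [(list(idx), float(r)) for idx, r in a.get("blocks", [])]
        if a.get("hub"):
            h, partners, r = a["hub"]
            a["hub"] = (int(h), list(partners), float(r))
        table, truth = synth_abundance(SyntheticSpec(**a))
        rel = table.values / table.values.sum(axis=1, keepdims=True)
        from dataclasses import replace

        write_taxonomic_table(
            replace(table, values=rel, kind="relative"), outdir / "abundance.tsv"
        )
        np.savetxt(outdir / "true_correlations.tsv", truth, delimiter="\t")
        outputs["abundance"] = str(outdir / "abundance.tsv")
    if "stratified" in spec:
        s = dict(spec["stratified"])
        s.setdefault("seed", seed)
        s["classes"] = [ClassSpec(**c) for c in s["classes"]]
        from .synth import default_lineage

        pool = s.pop("taxa_pool", None)
        if pool is None:
            pool = [default_lineage(i) for i in range(s.pop("n_taxa_pool", 20))]
        else:
            pool = [default_lineage(i, species=name) for i, name in enumerate(pool)]
        table, truth = synth_stratified(StratifiedSpec(taxa_pool=pool, **s))
        write_stratified_genefamilies(table, outdir / "genefamilies.tsv")
        _json_dump(truth, outdir / "stratified_truth.json")
        outputs["stratified"] = str(outdir / "genefamilies.tsv")
    return outputs
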