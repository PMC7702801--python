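"""Readers, writers and filters for taxonomic and stratified gene-family profiles.

Two plain-text dialects are supported, matching what the common profilers emit:

* merged taxonomic tables — one row per clade, the first column a pipe-delimited
  lineage string (``k__Bacteria|p__...|s__Genus_species``), remaining columns
  per-sample abundances, either percentages (0–100) or fractions (0–1);
* stratified gene-family tables — one row per (gene family, contributing taxon),
  the first column ``FAMILYID: annotation|g__Genus.s__Genus_species`` for
  stratified rows and ``FAMILYID: annotation`` for community totals, with
  ``UNMAPPED``/``UNGROUPED`` bookkeeping rows allowed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RANK_ORDER",
    "UNKNOWN_TAXON",
    "TaxonRecord",
    "AbundanceTable",
    "GeneEntry",
    "StratifiedGeneTable",
    "ProfileParseError",
    "EmptyTableError",
    "DuplicateEntryError",
    "parse_clade_string",
    "read_taxonomic_table",
    "write_taxonomic_table",
    "filter_taxa",
    "renormalize",
    "read_stratified_genefamilies",
    "write_stratified_genefamilies",
]

#: Canonical rank prefixes, kingdom -> strain.
RANK_ORDER = ("k", "p", "c", "o", "f", "g", "s", "t")

#: Reserved marker for unclassified / unknown contributing taxa.
UNKNOWN_TAXON = "UNKNOWN"


class ProfileParseError(ValueError):
    """A profile file violated its dialect."""


class EmptyTableError(ValueError):
    """An operation produced or received a table with no usable rows."""


class DuplicateEntryError(ValueError):
    """Duplicate taxon or (gene family, taxon) identifier."""


@dataclass(frozen=True)
class TaxonRecord:
    """A terminal clade plus its full lineage.

    ``lineage`` is an ordered tuple of ``(rank_letter, name)`` pairs in the
    canonical k,p,c,o,f,g,s(,t) order; ``taxon_id`` is the name at the
    terminal rank (a species epithet string for species-level records).
    """

    taxon_id: str
    lineage: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        letters = [r for r, _ in self.lineage]
        expected = list(RANK_ORDER[: len(letters)])
        if letters != expected:
            raise ProfileParseError(
                f"lineage ranks {letters} not in canonical order for {self.taxon_id!r}"
            )

    @property
    def terminal_rank(self) -> str:
        return self.lineage[-1][0]

    @property
    def clade_string(self) -> str:
        return "|".join(f"{r}__{n}" for r, n in self.lineage)


def parse_clade_string(clade: str) -> tuple[tuple[str, str], ...]:
    """Parse a pipe-delimited clade string into ``((rank, name), ...)``."""
    parts = clade.strip().split("|")
    lineage = []
    for part in parts:
        if len(part) < 4 or part[1:3] != "__" or part[0] not in RANK_ORDER:
            raise ProfileParseError(f"malformed clade component {part!r} in {clade!r}")
        lineage.append((part[0], part[3:]))
    return tuple(lineage)


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with lineage metadata.

    ``kind`` is ``"relative"`` (rows of fractions, each summing to at most
    ~1) or ``"counts"``. Values are validated at construction; relative rows
    are *not* renormalized implicitly — :func:`renormalize` is explicit.
    """

    sample_ids: list[str]
    taxa: list[TaxonRecord]
    values: np.ndarray
    kind: str = "relative"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxa)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.taxa)})"
            )
        if self.kind not in ("relative", "counts"):
            raise ValueError(f"kind must be 'relative' or 'counts', got {self.kind!r}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("abundance values must be finite and non-negative")
        ids = self.taxon_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({t for t in ids if ids.count(t) > 1})
            raise DuplicateEntryError(f"duplicate taxon identifiers: {dupes}")
        if self.kind == "relative":
            sums = self.values.sum(axis=1)
            if np.any(sums > 1.0 + 1e-6):
                bad = [self.sample_ids[i] for i in np.where(sums > 1.0 + 1e-6)[0]]
                raise ValueError(f"relative rows sum to > 1 for samples {bad}")

    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return replace(
            self, sample_ids=list(sample_ids), values=self.values[idx, :].copy()
        )


_LEVEL_LETTER = {
    "kingdom": "k",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
}


def read_taxonomic_table(
    path, level: str = "species", percent: bool | None = None
) -> AbundanceTable:
    """Read a merged taxonomic TSV, keeping rows terminating at ``level``.

    Percentage vs fraction convention is auto-detected (any retained value
    > 1.5 triggers percentage interpretation) unless ``percent`` is set
    explicitly; the decision is recorded in ``meta``. Strain-level (``t__``)
    rows never qualify at species level.
    """
    letter = _LEVEL_LETTER.get(level)
    if letter is None:
        raise ValueError(f"unknown taxonomic level {level!r}")
    rank_index = RANK_ORDER.index(letter)

    header: list[str] | None = None
    rows: list[tuple[tuple[tuple[str, str], ...], list[float]]] = []
    n_comment = n_other_rank = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if header is None and line.startswith("#"):
                n_comment += 1
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                continue
            lineage = _parse_clade_at(cells[0], lineno)
            try:
                values = [float(c) for c in cells[1:]]
            except ValueError as exc:
                raise ProfileParseError(f"non-numeric cell at line {lineno}: {exc}")
            if len(values) != len(header) - 1:
                raise ProfileParseError(
                    f"line {lineno}: expected {len(header) - 1} values, got {len(values)}"
                )
            if len(lineage) == rank_index + 1 and lineage[-1][0] == letter:
                rows.append((lineage, values))
            else:
                n_other_rank += 1
    if header is None:
        raise ProfileParseError(f"{path}: no header row found")
    if not rows:
        raise EmptyTableError(f"{path}: no rows at level {level!r}")

    sample_ids = header[1:]
    taxa = [TaxonRecord(lineage[-1][1], lineage) for lineage, _ in rows]
    values = np.array([v for _, v in rows], dtype=float).T  # samples x taxa
    if not values.any():
        raise EmptyTableError(f"{path}: all {level!r}-level abundances are zero")

    if percent is None:
        percent = bool((values > 1.5).any())
    if percent:
        values = values / 100.0
    table = AbundanceTable(
        sample_ids=sample_ids,
        taxa=taxa,
        values=values,
        kind="relative",
        meta={
            "source": str(path),
            "level": level,
            "percent_input": bool(percent),
            "rows_other_rank": n_other_rank,
            "rows_comment": n_comment,
        },
    )
    return table


def _parse_clade_at(clade: str, lineno: int) -> tuple[tuple[str, str], ...]:
    try:
        return parse_clade_string(clade)
    except ProfileParseError as exc:
        raise ProfileParseError(f"line {lineno}: {exc}")


def write_taxonomic_table(table: AbundanceTable, path, sidecar: bool = True) -> None:
    """Write the canonical taxa x samples TSV plus a JSON provenance sidecar."""
    with open(path, "w") as fh:
        fh.write("#clade_name\t" + "\t".join(table.sample_ids) + "\n")
        fh.write("clade_name\t" + "\t".join(table.sample_ids) + "\n")
        for j, taxon in enumerate(table.taxa):
            vals = "\t".join(repr(float(v)) for v in table.values[:, j])
            fh.write(f"{taxon.clade_string}\t{vals}\n")
    if sidecar:
        with open(str(path) + ".json", "w") as fh:
            json.dump({"kind": table.kind, **_jsonable(table.meta)}, fh, indent=1)


def _jsonable(meta: dict) -> dict:
    return json.loads(json.dumps(meta, default=str))


def renormalize(table: AbundanceTable) -> AbundanceTable:
    """Rescale each sample row of a relative table to sum to exactly 1."""
    if table.kind != "relative":
        raise ValueError("renormalize expects a relative table")
    sums = table.values.sum(axis=1)
    if np.any(sums <= 0):
        raise EmptyTableError("cannot renormalize sample rows that sum to zero")
    out = replace(table, values=table.values / sums[:, None])
    out.meta = {**table.meta, "renormalized": True}
    return out


def filter_taxa(
    table: AbundanceTable,
    min_prevalence: float = 0.3,
    min_mean_abundance: float = 1e-4,
) -> AbundanceTable:
    """Keep taxa present in >= ``min_prevalence`` of samples with mean relative
    abundance >= ``min_mean_abundance``; samples are untouched.

    Filter parameters are recorded in the result's provenance metadata.
    """
    if table.kind != "relative":
        raise ValueError("filter_taxa expects a relative table")
    prevalence = (table.values > 0).mean(axis=0)
    mean_ab = table.values.mean(axis=0)
    keep = (prevalence >= min_prevalence) & (mean_ab >= min_mean_abundance)
    if not keep.any():
        raise EmptyTableError(
            f"filter (min_prevalence={min_prevalence}, "
            f"min_mean_abundance={min_mean_abundance}) removed all taxa"
        )
    out = replace(
        table,
        taxa=[t for t, k in zip(table.taxa, keep) if k],
        values=table.values[:, keep].copy(),
    )
    out.meta = {
        **table.meta,
        "filter": {
            "min_prevalence": min_prevalence,
            "min_mean_abundance": min_mean_abundance,
            "taxa_in": table.n_taxa,
            "taxa_out": int(keep.sum()),
        },
    }
    return out


# ---------------------------------------------------------------------------
# stratified gene-family tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneEntry:
    """One row of a stratified table: a gene family, its annotation text, and
    either a contributing taxon id, :data:`UNKNOWN_TAXON`, or ``None`` for the
    community-total (unstratified) row."""

    family_id: str
    annotation: str
    taxon: str | None

    @property
    def is_total(self) -> bool:
        return self.taxon is None


@dataclass
class StratifiedGeneTable:
    """Entries x samples gene-family abundance matrix.

    Stratified rows attribute a family's abundance to a contributing taxon;
    total rows (``taxon is None``) carry the community sum. The invariant
    total >= sum(stratified) - 1e-3 (relative) is checked at construction.
    """

    sample_ids: list[str]
    entries: list[GeneEntry]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entries), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.entries)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("gene-family values must be finite and non-negative")
        keys = [(e.family_id, e.taxon) for e in self.entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise DuplicateEntryError(f"duplicate (family, taxon) rows: {dupes}")
        self._check_totals()

    def _check_totals(self) -> None:
        totals: dict[str, np.ndarray] = {}
        strat_sums: dict[str, np.ndarray] = {}
        for e, row in zip(self.entries, self.values):
            if e.is_total:
                totals[e.family_id] = row
            else:
                strat_sums[e.family_id] = strat_sums.get(e.family_id, 0) + row
        for fam, total in totals.items():
            ssum = strat_sums.get(fam)
            if ssum is None:
                continue
            tol = 1e-3 * np.maximum(ssum, 1e-12)
            if np.any(total < ssum - tol):
                raise ValueError(
                    f"family {fam!r}: total row below the sum of its stratified rows"
                )

    @property
    def stratified(self) -> list[int]:
        return [i for i, e in enumerate(self.entries) if not e.is_total]

    def contributors(self, family_id: str) -> list[tuple[str, np.ndarray]]:
        return [
            (e.taxon, self.values[i])
            for i, e in enumerate(self.entries)
            if e.family_id == family_id and not e.is_total
        ]

    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            if e.taxon is not None:
                seen.setdefault(e.taxon, None)
        return list(seen)

    def subset(self, indices: list[int]) -> "StratifiedGeneTable":
        return StratifiedGeneTable(
            sample_ids=list(self.sample_ids),
            entries=[self.entries[i] for i in indices],
            values=self.values[indices, :].copy(),
            meta=dict(self.meta),
        )


_UNCLASSIFIED_MARKERS = {"unclassified", "unknown"}


def _parse_gene_row_id(row_id: str, lineno: int) -> GeneEntry:
    if "|" in row_id:
        head, taxon_part = row_id.split("|", 1)
    else:
        head, taxon_part = row_id, None
    if ": " in head:
        family_id, annotation = head.split(": ", 1)
    else:
        family_id, annotation = head, ""
    family_id = family_id.strip()
    if not family_id:
        raise ProfileParseError(f"line {lineno}: empty gene-family identifier")
    taxon: str | None = None
    if taxon_part is not None:
        tp = taxon_part.strip()
        if tp.lower() in _UNCLASSIFIED_MARKERS:
            taxon = UNKNOWN_TAXON
        elif ".s__" in tp:
            taxon = tp.split(".s__", 1)[1]
        elif tp.startswith("g__"):
            taxon = tp[3:]
        elif tp.startswith("s__"):
            taxon = tp[3:]
        else:
            taxon = tp
    return GeneEntry(family_id=family_id, annotation=annotation.strip(), taxon=taxon)


def read_stratified_genefamilies(path) -> StratifiedGeneTable:
    """Read a stratified gene-family TSV (totals and per-taxon rows)."""
    header: list[str] | None = None
    entries: list[GeneEntry] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if header is None:
                if len(cells) < 2:
                    raise ProfileParseError(f"{path}: missing header row")
                header = cells
                continue
            entry = _parse_gene_row_id(cells[0], lineno)
            try:
                values = [float(c) for c in cells[1:]]
            except ValueError as exc:
                raise ProfileParseError(f"non-numeric cell at line {lineno}: {exc}")
            entries.append(entry)
            rows.append(values)
    if header is None:
        raise ProfileParseError(f"{path}: missing header row")
    if not entries:
        raise EmptyTableError(f"{path}: no gene-family rows")
    return StratifiedGeneTable(
        sample_ids=header[1:],
        entries=entries,
        values=np.array(rows, dtype=float),
        meta={"source": str(path)},
    )


def write_stratified_genefamilies(table: StratifiedGeneTable, path) -> None:
    """Write the stratified dialect back out (totals then stratified rows as stored)."""
    with open(path, "w") as fh:
        fh.write("# Gene Family\t" + "\t".join(table.sample_ids) + "\n")
        for e, row in zip(table.entries, table.values):
            head = f"{e.family_id}: {e.annotation}" if e.annotation else e.family_id
            if e.taxon is not None:
                if e.taxon == UNKNOWN_TAXON:
                    head += "|unclassified"
                else:
                    genus = e.taxon.split("_", 1)[0]
                    head += f"|g__{genus}.s__{e.taxon}"
            fh.write(head + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
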