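"""Ingestion and harmonization of miRNA-target interaction catalogs.

Experimentally supported miRNA->mRNA and miRNA->lncRNA interactions come from
several public databases with differing column layouts, identifier case
conventions and heavy mutual redundancy.  This module reads such tables,
normalizes identifiers, optionally maps them through an alias table, and
merges everything into a single deduplicated catalog whose edges carry the
union of their evidence-source labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

MRNA = "mRNA"
LNCRNA = "lncRNA"
TARGET_CLASSES = (MRNA, LNCRNA)

__all__ = [
    "InteractionEdge",
    "InteractionCatalog",
    "LoadReport",
    "normalize_mirna_id",
    "normalize_gene_id",
    "read_interaction_table",
    "read_alias_map",
    "harmonize_and_merge",
    "write_catalog",
    "read_catalog",
]


def normalize_mirna_id(raw: str) -> str:
    # catalogs mix e.g. "hsa-miR-484" / "hsa-mir-484"; compare case-insensitively
    return str(raw).strip().lower()


def normalize_gene_id(raw: str) -> str:
    return str(raw).strip().upper()


@dataclass(frozen=True)
class InteractionEdge:
    """One miRNA -> target interaction with its evidence sources."""

    mirna_id: str
    target_id: str
    target_class: str
    sources: frozenset

    def __post_init__(self):
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(f"target_class must be one of {TARGET_CLASSES}")
        if not self.sources:
            raise ValueError("sources must be non-empty")


@dataclass
class LoadReport:
    """Row accounting for one ingestion or merge step."""

    rows: int = 0
    kept: int = 0
    dropped_blank: int = 0
    duplicates: int = 0
    unmapped: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class InteractionCatalog:
    """Deduplicated collection of miRNA-target edges plus the miRNA background.

    ``n_mirna_universe`` is the background size N_T used by the competition
    test.  It defaults to the number of distinct miRNAs present in the merged
    catalog but may be set to a genome-wide count by the caller.
    """

    edges: list = field(default_factory=list)
    n_mirna_universe: int | None = None

    def __post_init__(self):
        n_distinct = len({e.mirna_id for e in self.edges})
        if self.n_mirna_universe is None:
            self.n_mirna_universe = n_distinct
        if self.n_mirna_universe < n_distinct:
            raise ValueError(
                f"n_mirna_universe={self.n_mirna_universe} smaller than the "
                f"{n_distinct} distinct miRNAs in the catalog"
            )
        keys = [(e.mirna_id, e.target_id, e.target_class) for e in self.edges]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (mirna, target, class) edges in catalog")

    def mirnas(self) -> set:
        return {e.mirna_id for e in self.edges}

    def targets(self, target_class: str) -> set:
        return {e.target_id for e in self.edges if e.target_class == target_class}

    def mirna_sets(self, target_class: str) -> dict:
        """Map target id -> set of miRNAs regulating it, for one class."""
        out: dict = {}
        for e in self.edges:
            if e.target_class == target_class:
                out.setdefault(e.target_id, set()).add(e.mirna_id)
        return out


def read_interaction_table(
    path,
    target_class: str,
    source_label: str,
    mirna_col: str = "mirna",
    target_col: str = "target",
    sep: str | None = None,
) -> tuple[list, LoadReport]:
    """Read one interaction table into edge fragments tagged with a source.

    ``sep=None`` sniffs tab versus comma.  Rows with a blank miRNA or target
    are dropped and counted; duplicated (miRNA, target) rows are collapsed and
    counted.  Missing mandatory columns raise ``ValueError`` naming the column.
    """
    if target_class not in TARGET_CLASSES:
        raise ValueError(f"target_class must be one of {TARGET_CLASSES}")
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    report = LoadReport(rows=len(df))
    for col in (mirna_col, target_col):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    if df.empty:
        warnings.warn(f"empty interaction table: {path}")
        return [], report
    sub = df[[mirna_col, target_col]].copy()
    sub.columns = ["mirna", "target"]
    for c in sub.columns:
        sub[c] = sub[c].fillna("").str.strip()
    blank = (sub["mirna"] == "") | (sub["target"] == "")
    report.dropped_blank = int(blank.sum())
    sub = sub[~blank]
    sub["mirna"] = sub["mirna"].map(normalize_mirna_id)
    sub["target"] = sub["target"].map(normalize_gene_id)
    n_before = len(sub)
    sub = sub.drop_duplicates()
    report.duplicates = n_before - len(sub)
    report.kept = len(sub)
    srcs = frozenset([source_label])
    edges = [
        InteractionEdge(m, t, target_class, srcs)
        for m, t in sub.itertuples(index=False)
    ]
    return edges, report


def read_alias_map(path) -> dict:
    """Read a two-column raw->canonical alias TSV into a dict.

    A raw identifier mapped to two different canonical symbols is an ambiguous
    alias and raises ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["raw", "canonical"])
    mapping: dict = {}
    for raw, canon in df.itertuples(index=False):
        raw = normalize_gene_id(raw)
        canon = normalize_gene_id(canon)
        if raw in mapping and mapping[raw] != canon:
            raise ValueError(f"ambiguous alias: {raw!r} -> {mapping[raw]!r} and {canon!r}")
        mapping[raw] = canon
    return mapping


def harmonize_and_merge(
    fragments: Iterable,
    aliases: Mapping | None = None,
    n_mirna_universe: int | None = None,
) -> tuple[InteractionCatalog, LoadReport]:
    """Merge edge fragments into one deduplicated catalog.

    If an alias map is given, every target identifier must map through it;
    edges whose target is unmapped are excluded and counted in the report.
    Duplicate (miRNA, target, class) edges are collapsed with sources unioned.
    A target appearing in both classes is kept in both with a warning (biotype
    assignments drift across annotation versions).
    """
    report = LoadReport()
    merged: dict = {}
    for frag in fragments:
        for e in frag:
            report.rows += 1
            target = e.target_id
            if aliases is not None:
                if target not in aliases:
                    report.unmapped += 1
                    continue
                target = aliases[target]
            key = (e.mirna_id, target, e.target_class)
            if key in merged:
                report.duplicates += 1
                merged[key] = merged[key] | e.sources
            else:
                merged[key] = e.sources
    both = {(m, t) for m, t, c in merged if c == MRNA} & {
        (m, t) for m, t, c in merged if c == LNCRNA
    }
    if both:
        warnings.warn(
            f"{len(both)} miRNA-target pairs occur as both mRNA and lncRNA "
            "targets; kept in both classes"
        )
    edges = [
        InteractionEdge(m, t, c, frozenset(srcs))
        for (m, t, c), srcs in sorted(merged.items())
    ]
    report.kept = len(edges)
    catalog = InteractionCatalog(edges, n_mirna_universe)
    return catalog, report


def write_catalog(catalog: InteractionCatalog, path) -> None:
    df = pd.DataFrame(
        [
            (e.mirna_id, e.target_id, e.target_class, ";".join(sorted(e.sources)))
            for e in catalog.edges
        ],
        columns=["mirna_id", "target_id", "target_class", "sources"],
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path, n_mirna_universe: int | None = None) -> InteractionCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    edges = [
        InteractionEdge(r.mirna_id, r.target_id, r.target_class,
                        frozenset(r.sources.split(";")))
        for r in df.itertuples(index=False)
    ]
    return InteractionCatalog(edges, n_mirna_universe)
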