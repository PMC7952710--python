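"""The two-level knowledge base linking sources, patterns and entities.

The Summary section has one row per disentangled unit (DSU): the union of
the unit's pattern AVs, and for every entity the number of the unit's
patterns it contains.  The Comprehensive section has one row per individual
pattern with 0/1 containment flags per entity.  A summary count at
(DSU, entity) always equals the number of 1-flags for that entity among the
DSU's comprehensive rows.  Entities with no patterns at all stay as
all-zero columns — that is exactly what makes outliers visible.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .disentanglement import DSUCode, DSUnit
from .pattern_mining import Pattern, summarize_patterns
from .tabular_io import RelationalTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PatternRow:
    """One comprehensive-section row: a pattern detached from live objects."""

    dsu: DSUCode
    avs: tuple[tuple[str, str], ...]  # sorted (attribute, value) pairs
    significance: float
    eids: frozenset
    class_label: Optional[str] = None
    confidence: Optional[float] = None
    tie: bool = False

    def render_avs(self) -> str:
        return "; ".join(f"{a}={v}" for a, v in self.avs)


@dataclass(frozen=True)
class SummaryRow:
    """One summary-section row: a DSU's union pattern and entity counts."""

    dsu: DSUCode
    av_union: tuple[tuple[str, str], ...]
    counts: tuple[tuple[str, int], ...]  # (entity, count>0), entity order

    def count_map(self) -> dict:
        return dict(self.counts)


@dataclass
class PDDKB:
    """Summary + Comprehensive knowledge base over one table."""

    entity_ids: list[str]
    summary: list[SummaryRow]
    comprehensive: list[PatternRow]
    labels: Optional[dict] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.check_consistency()

    # -- invariants -------------------------------------------------------
    def check_consistency(self) -> None:
        by_dsu: dict[DSUCode, list[PatternRow]] = {}
        for row in self.comprehensive:
            by_dsu.setdefault(row.dsu, []).append(row)
        for srow in self.summary:
            rows = by_dsu.get(srow.dsu, [])
            if not rows:
                raise ValueError(f"summary DSU {srow.dsu} has no patterns")
            counts = srow.count_map()
            for e in self.entity_ids:
                want = sum(1 for r in rows if e in r.eids)
                if counts.get(e, 0) != want:
                    raise ValueError(
                        f"count/flag mismatch at ({srow.dsu.render()}, {e}): "
                        f"summary {counts.get(e, 0)} vs flags {want}"
                    )

    # -- accessors --------------------------------------------------------
    @property
    def dsus(self) -> list[DSUCode]:
        return [row.dsu for row in self.summary]

    def counts_for(self, entity: str) -> dict:
        """Per-DSU pattern count for one entity."""
        return {
            row.dsu: row.count_map().get(entity, 0) for row in self.summary
        }

    def patterns_of(self, dsu: DSUCode) -> list[PatternRow]:
        return [r for r in self.comprehensive if r.dsu == dsu]

    def matched_patterns(self, entity: str) -> list[PatternRow]:
        return [r for r in self.comprehensive if entity in r.eids]

    def is_empty(self) -> bool:
        return not self.comprehensive

    # -- equality for round-trip checks ----------------------------------
    def to_comparable(self) -> tuple:
        return (
            tuple(self.entity_ids),
            tuple(self.summary),
            tuple(
                (
                    r.dsu,
                    r.avs,
                    round(r.significance, 9),
                    tuple(sorted(r.eids)),
                    r.class_label,
                    None if r.confidence is None else round(r.confidence, 9),
                    r.tie,
                )
                for r in self.comprehensive
            ),
            tuple(sorted((self.labels or {}).items())),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PDDKB):
            return NotImplemented
        return self.to_comparable() == other.to_comparable()


def build_kb(
    units: Sequence[DSUnit],
    patterns_by_unit: Mapping[DSUCode, Sequence[Pattern]],
    table: RelationalTable,
    metadata: Optional[dict] = None,
) -> PDDKB:
    """Assemble the KB from discovered units and their patterns.

    DSUs with zero patterns are dropped (logged).  Rows are ordered DSU
    lexicographic, then significance descending, for deterministic diffs.
    """
    codes = [u.code for u in units]
    if len(codes) != len(set(codes)):
        raise ValueError("duplicate DSU codes")
    unit_codes = set(codes)
    for code in patterns_by_unit:
        if code not in unit_codes:
            raise ValueError(f"patterns supplied for unknown DSU {code}")
    labels = None
    if table.labels is not None:
        labels = {
            e: (None if table.labels.at[e] is None else str(table.labels.at[e]))
            for e in table.entity_ids
        }
    summary: list[SummaryRow] = []
    comprehensive: list[PatternRow] = []
    for unit in sorted(units, key=lambda u: u.code):
        pats = list(patterns_by_unit.get(unit.code, []))
        if not pats:
            logger.info("DSU %s has no patterns; dropped", unit.code.render())
            continue
        for p in pats:
            if p.dsu != unit.code:
                raise ValueError(
                    f"pattern {p.render()} mapped to {unit.code} but tagged {p.dsu}"
                )
        sp = summarize_patterns(pats, unit.code, table)
        summary.append(
            SummaryRow(
                dsu=unit.code,
                av_union=sp.av_union,
                counts=tuple(
                    (e, sp.per_entity_counts[e])
                    for e in table.entity_ids
                    if sp.per_entity_counts.get(e, 0) > 0
                ),
            )
        )
        for p in sorted(pats, key=lambda p: (-p.significance, p.av_keys and tuple(sorted(p.av_keys)))):
            ca = p.class_association
            comprehensive.append(
                PatternRow(
                    dsu=unit.code,
                    avs=tuple(sorted(av.key for av in p.avs)),
                    significance=p.significance,
                    eids=p.eids,
                    class_label=None if ca is None else ca.label,
                    confidence=None if ca is None else ca.confidence,
                    tie=False if ca is None else ca.tie,
                )
            )
    kb = PDDKB(
        entity_ids=list(table.entity_ids),
        summary=summary,
        comprehensive=comprehensive,
        labels=labels,
        metadata=dict(metadata or {}),
    )
    logger.info(
        "knowledge base: %d DSUs, %d patterns, %d entities",
        len(summary),
        len(comprehensive),
        len(kb.entity_ids),
    )
    return kb


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def export_kb(kb: PDDKB, directory, format: str = "csv") -> list[str]:
    """Write the KB to ``directory``; returns the file manifest.

    CSV: summary.csv, comprehensive.csv, metadata.json.  JSON: kb.json with
    the same content nested.  Export then import round-trips losslessly.
    """
    os.makedirs(directory, exist_ok=True)
    if format == "csv":
        return _export_csv(kb, directory)
    if format == "json":
        path = os.path.join(directory, "kb.json")
        with open(path, "w") as fh:
            json.dump(_kb_to_dict(kb), fh, indent=1, sort_keys=True)
        return [path]
    raise ValueError(f"unknown format {format!r}")


def import_kb(directory, format: str = "csv") -> PDDKB:
    if format == "csv":
        return _import_csv(directory)
    if format == "json":
        with open(os.path.join(directory, "kb.json")) as fh:
            return _kb_from_dict(json.load(fh))
    raise ValueError(f"unknown format {format!r}")


def _kb_to_dict(kb: PDDKB) -> dict:
    return {
        "entity_ids": kb.entity_ids,
        "labels": kb.labels,
        "metadata": kb.metadata,
        "summary": [
            {
                "dsu": row.dsu.render(),
                "av_union": [[a, v] for a, v in row.av_union],
                "counts": {e: c for e, c in row.counts},
            }
            for row in kb.summary
        ],
        "comprehensive": [
            {
                "dsu": row.dsu.render(),
                "avs": [[a, v] for a, v in row.avs],
                "significance": row.significance,
                "eids": sorted(row.eids),
                "class_label": row.class_label,
                "confidence": row.confidence,
                "tie": row.tie,
            }
            for row in kb.comprehensive
        ],
    }


def _kb_from_dict(d: dict) -> PDDKB:
    summary = [
        SummaryRow(
            dsu=DSUCode.parse(row["dsu"]),
            av_union=tuple((a, v) for a, v in row["av_union"]),
            counts=tuple(
                (e, int(row["counts"][e]))
                for e in d["entity_ids"]
                if e in row["counts"]
            ),
        )
        for row in d["summary"]
    ]
    comprehensive = [
        PatternRow(
            dsu=DSUCode.parse(row["dsu"]),
            avs=tuple((a, v) for a, v in row["avs"]),
            significance=float(row["significance"]),
            eids=frozenset(row["eids"]),
            class_label=row["class_label"],
            confidence=row["confidence"],
            tie=bool(row["tie"]),
        )
        for row in d["comprehensive"]
    ]
    return PDDKB(
        entity_ids=list(d["entity_ids"]),
        summary=summary,
        comprehensive=comprehensive,
        labels=d["labels"],
        metadata=d["metadata"],
    )


def _export_csv(kb: PDDKB, directory) -> list[str]:
    spath = os.path.join(directory, "summary.csv")
    cpath = os.path.join(directory, "comprehensive.csv")
    mpath = os.path.join(directory, "metadata.json")
    with open(spath, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["dsu", "av_union"] + kb.entity_ids)
        if kb.labels is not None:
            w.writerow(
                ["[class]", ""]
                + [kb.labels.get(e) or "" for e in kb.entity_ids]
            )
        for row in kb.summary:
            cm = row.count_map()
            w.writerow(
                [row.dsu.render(), "; ".join(f"{a}={v}" for a, v in row.av_union)]
                + [cm.get(e, 0) for e in kb.entity_ids]
            )
    with open(cpath, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            ["dsu", "avs", "significance", "class_label", "confidence", "tie"]
            + kb.entity_ids
        )
        for row in kb.comprehensive:
            w.writerow(
                [
                    row.dsu.render(),
                    row.render_avs(),
                    repr(row.significance),
                    "" if row.class_label is None else row.class_label,
                    "" if row.confidence is None else repr(row.confidence),
                    int(row.tie),
                ]
                + [int(e in row.eids) for e in kb.entity_ids]
            )
    with open(mpath, "w") as fh:
        json.dump(
            {"metadata": kb.metadata, "has_labels": kb.labels is not None},
            fh,
            indent=1,
            sort_keys=True,
        )
    return [spath, cpath, mpath]


def _import_csv(directory) -> PDDKB:
    spath = os.path.join(directory, "summary.csv")
    cpath = os.path.join(directory, "comprehensive.csv")
    mpath = os.path.join(directory, "metadata.json")
    with open(spath, newline="") as fh:
        srows = list(csv.reader(fh))
    header = srows[0]
    entity_ids = header[2:]
    labels = None
    body = srows[1:]
    if body and body[0][0] == "[class]":
        labels = {
            e: (v if v != "" else None)
            for e, v in zip(entity_ids, body[0][2:])
        }
        body = body[1:]
    summary = []
    for row in body:
        av_union = tuple(
            tuple(part.split("=", 1)) for part in row[1].split("; ") if part
        )
        counts = tuple(
            (e, int(c)) for e, c in zip(entity_ids, row[2:]) if int(c) > 0
        )
        summary.append(
            SummaryRow(dsu=DSUCode.parse(row[0]), av_union=av_union, counts=counts)
        )
    with open(cpath, newline="") as fh:
        crows = list(csv.reader(fh))
    comprehensive = []
    for row in crows[1:]:
        avs = tuple(tuple(part.split("=", 1)) for part in row[1].split("; ") if part)
        flags = row[6:]
        eids = frozenset(e for e, f in zip(entity_ids, flags) if f == "1")
        comprehensive.append(
            PatternRow(
                dsu=DSUCode.parse(row[0]),
                avs=avs,
                significance=float(row[2]),
                eids=eids,
                class_label=row[3] if row[3] != "" else None,
                confidence=float(row[4]) if row[4] != "" else None,
                tie=bool(int(row[5])),
            )
        )
    with open(mpath) as fh:
        meta = json.load(fh)
    return PDDKB(
        entity_ids=entity_ids,
        summary=summary,
        comprehensive=comprehensive,
        labels=labels,
        metadata=meta["metadata"],
    )


def table_digest(table: RelationalTable) -> str:
    """Stable content digest of a table's CSV rendering."""
    return hashlib.sha1(table.to_csv_string().encode()).hexdigest()
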