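"""Relational-table input/output and quantization.

A relational table holds N entities (rows) by M mixed-mode attributes
(columns).  Categorical cells are value symbols; numeric cells are floats.
Entities are addressed ``E1 … EN`` (1-based, in input order).  Numeric
attributes are discretized into interval categories before any association
statistics are computed, so that every attribute value (AV) is a discrete
event.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORICAL = "categorical"
NUMERIC = "numeric"


class TableParseError(ValueError):
    """Structured parse failure (ragged row, duplicate id, empty input)."""


@dataclass(frozen=True)
class Attribute:
    name: str
    mode: str  # CATEGORICAL or NUMERIC

    def __post_init__(self) -> None:
        if self.mode not in (CATEGORICAL, NUMERIC):
            raise ValueError(f"unknown attribute mode {self.mode!r}")


@dataclass
class RelationalTable:
    """Entities x mixed-mode attributes, with optional per-entity class labels.

    ``values`` is indexed by ``entity_ids`` with one column per attribute;
    numeric columns are float64 (NaN = missing), categorical columns hold
    strings (None = missing).
    """

    entity_ids: list[str]
    attributes: list[Attribute]
    values: pd.DataFrame
    labels: Optional[pd.Series] = None
    missing_marker: str = "?"
    label_name: str = "class"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.entity_ids)
        if len(set(self.entity_ids)) != n:
            raise TableParseError("duplicate entity ids")
        if list(self.values.index) != list(self.entity_ids):
            raise ValueError("values index must equal entity_ids")
        if list(self.values.columns) != [a.name for a in self.attributes]:
            raise ValueError("values columns must match attribute order")
        if self.labels is not None and list(self.labels.index) != list(self.entity_ids):
            raise ValueError("labels must cover every entity in order")
        for attr in self.attributes:
            if attr.mode == NUMERIC:
                col = pd.to_numeric(self.values[attr.name], errors="coerce")
                if not np.isfinite(col.to_numpy(dtype=float)).any():
                    raise ValueError(
                        f"numeric attribute {attr.name!r} has no finite value"
                    )

    # -- basic accessors --------------------------------------------------
    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def mode_of(self, name: str) -> str:
        for a in self.attributes:
            if a.name == name:
                return a.mode
        raise KeyError(name)

    def is_missing(self, entity: str, attribute: str) -> bool:
        v = self.values.at[entity, attribute]
        return _cell_is_missing(v)

    def subset(self, entity_ids: Sequence[str]) -> "RelationalTable":
        """Row subset preserving attribute schema and label column."""
        ids = list(entity_ids)
        vals = self.values.loc[ids]
        labels = self.labels.loc[ids] if self.labels is not None else None
        return RelationalTable(
            entity_ids=ids,
            attributes=list(self.attributes),
            values=vals,
            labels=labels,
            missing_marker=self.missing_marker,
            label_name=self.label_name,
            provenance=self.provenance,
        )

    # -- serialization ----------------------------------------------------
    def to_csv_string(self) -> str:
        import io

        buf = io.StringIO()
        self.write_csv(buf)
        return buf.getvalue()

    def write_csv(self, path_or_buf) -> None:
        """Mirror of :func:`read_table`: round trips values, ids and modes."""
        close = False
        if isinstance(path_or_buf, (str, bytes)):
            fh = open(path_or_buf, "w", newline="")
            close = True
        else:
            fh = path_or_buf
        try:
            w = csv.writer(fh, lineterminator="\n")
            header = ["id"] + self.attribute_names
            if self.labels is not None:
                header.append(self.label_name)
            w.writerow(header)
            for eid in self.entity_ids:
                row = [eid]
                for attr in self.attributes:
                    v = self.values.at[eid, attr.name]
                    if _cell_is_missing(v):
                        row.append(self.missing_marker)
                    elif attr.mode == NUMERIC:
                        row.append(repr(float(v)))
                    else:
                        row.append(str(v))
                if self.labels is not None:
                    lab = self.labels.at[eid]
                    row.append(self.missing_marker if lab is None else str(lab))
                w.writerow(row)
        finally:
            if close:
                fh.close()


def _cell_is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return False


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_table(
    path,
    label_column: Optional[str] = None,
    missing_marker: str = "?",
    id_column: Optional[str] = "id",
    provenance: str = "",
) -> RelationalTable:
    """Read a CSV file (header required) into a :class:`RelationalTable`.

    A column whose non-missing cells all parse as numbers is inferred
    numeric; everything else is categorical.  ``label_column`` is removed
    from the attribute set and stored as per-entity class labels.
    ``id_column`` (if present in the header) supplies entity identifiers;
    otherwise entities are numbered ``E1 … EN``.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r]  # drop fully blank lines
    if not rows:
        raise TableParseError(f"{path}: empty file")
    header = rows[0]
    width = len(header)
    data = rows[1:]
    if not data:
        raise TableParseError(f"{path}: no data rows")
    for i, row in enumerate(data, start=2):  # file line number, header = 1
        if len(row) != width:
            raise TableParseError(
                f"{path}: row {i} has {len(row)} cells, expected {width}"
            )
    if label_column is not None and label_column not in header:
        raise TableParseError(f"label column {label_column!r} not in header")

    columns: dict[str, list[str]] = {h: [] for h in header}
    if len(columns) != width:
        raise TableParseError(f"{path}: duplicate column names in header")
    for row in data:
        for h, cell in zip(header, row):
            columns[h].append(cell)

    # entity ids
    if id_column is not None and id_column in header:
        entity_ids = columns.pop(id_column)
        if len(set(entity_ids)) != len(entity_ids):
            dupes = sorted({e for e in entity_ids if entity_ids.count(e) > 1})
            raise TableParseError(f"duplicate entity ids: {dupes}")
    else:
        entity_ids = [f"E{i}" for i in range(1, len(data) + 1)]

    labels = None
    if label_column is not None:
        raw = columns.pop(label_column)
        labels = pd.Series(
            [None if c == missing_marker or c == "" else c for c in raw],
            index=entity_ids,
        )

    attributes: list[Attribute] = []
    series: dict[str, pd.Series] = {}
    for name, cells in columns.items():
        present = [c for c in cells if c != missing_marker and c != ""]
        numeric = bool(present) and all(_parses_float(c) for c in present)
        if numeric:
            vals = [
                float(c) if (c != missing_marker and c != "") else np.nan
                for c in cells
            ]
            series[name] = pd.Series(vals, index=entity_ids, dtype=float)
            attributes.append(Attribute(name, NUMERIC))
        else:
            vals = [
                None if (c == missing_marker or c == "") else c for c in cells
            ]
            series[name] = pd.Series(vals, index=entity_ids, dtype=object)
            attributes.append(Attribute(name, CATEGORICAL))

    values = pd.DataFrame({a.name: series[a.name] for a in attributes})
    return RelationalTable(
        entity_ids=entity_ids,
        attributes=attributes,
        values=values,
        labels=labels,
        missing_marker=missing_marker,
        label_name=label_column or "class",
        provenance=provenance or str(path),
    )


def _parses_float(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def read_alignment(
    path,
    start: int = 1,
    site_prefix: str = "S",
    provenance: str = "",
) -> RelationalTable:
    """Read an aligned FASTA file (or one-sequence-per-line text) as a table.

    Each aligned site becomes a categorical attribute named by its ordinal
    (``S<start> … S<start+L-1>``) and the residue characters — including the
    gap character ``-`` — become its value symbols.
    """
    names: list[str] = []
    seqs: list[str] = []
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if not stripped:
        raise TableParseError(f"{path}: empty alignment")
    if stripped.startswith(">"):
        from Bio import SeqIO
        import io

        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
    else:
        for line in text.splitlines():
            line = line.strip()
            if line:
                names.append(f"seq{len(names) + 1}")
                seqs.append(line)
    if len(seqs) < 2:
        raise TableParseError(f"{path}: need at least 2 aligned sequences")
    length = len(seqs[0])
    for name, s in zip(names, seqs):
        if len(s) != length:
            raise TableParseError(
                f"{path}: sequence {name!r} has length {len(s)}, expected {length}"
            )
    entity_ids = [f"E{i}" for i in range(1, len(seqs) + 1)]
    attributes = [
        Attribute(f"{site_prefix}{start + j}", CATEGORICAL) for j in range(length)
    ]
    values = pd.DataFrame(
        {
            attributes[j].name: pd.Series(
                [s[j] for s in seqs], index=entity_ids, dtype=object
            )
            for j in range(length)
        }
    )
    return RelationalTable(
        entity_ids=entity_ids,
        attributes=attributes,
        values=values,
        provenance=provenance or str(path),
    )


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

EQUAL_WIDTH = "equal_width"
EQUAL_FREQUENCY = "equal_frequency"


@dataclass
class QuantizationScheme:
    """Per-numeric-attribute bin edges, fit on training data and reusable.

    Edges are ascending with first = min and last = max of the fitted data.
    Intervals are left-closed / right-open except the last, which is closed.
    Out-of-range values at apply time clip into the first/last bin.
    """

    edges: dict[str, list[float]] = field(default_factory=dict)
    method: str = EQUAL_WIDTH
    bins: int = 3

    def __bool__(self) -> bool:
        return bool(self.edges)

    def labels_for(self, attribute: str) -> list[str]:
        e = self.edges[attribute]
        if len(e) == 1:  # constant column
            return [f"[{_fmt(e[0])},{_fmt(e[0])}]"]
        out = []
        for k in range(len(e) - 1):
            last = k == len(e) - 2
            out.append(
                f"[{_fmt(e[k])},{_fmt(e[k + 1])}{']' if last else ')'}"
            )
        return out

    def assign(self, attribute: str, value: float) -> str:
        e = self.edges[attribute]
        labels = self.labels_for(attribute)
        if len(e) == 1:
            return labels[0]
        k = int(np.searchsorted(e, value, side="right")) - 1
        k = min(max(k, 0), len(e) - 2)
        return labels[k]

    def apply(self, table: RelationalTable) -> RelationalTable:
        """Quantize a table using the stored edges (train-fit, test-apply)."""
        return _quantize_with(table, self)

    def to_dict(self) -> dict:
        return {"method": self.method, "bins": self.bins, "edges": self.edges}

    @classmethod
    def from_dict(cls, d: Mapping) -> "QuantizationScheme":
        return cls(
            edges={k: [float(x) for x in v] for k, v in d["edges"].items()},
            method=d["method"],
            bins=int(d["bins"]),
        )


def _fmt(x: float) -> str:
    return format(float(x), "g")


def quantize(
    table: RelationalTable,
    bins: int = 3,
    method: str = EQUAL_WIDTH,
) -> tuple[RelationalTable, QuantizationScheme]:
    """Replace every numeric attribute by an interval-label categorical one.

    Equal-width edges are ``min + k*(max-min)/bins``; equal-frequency edges
    are the empirical quantiles (duplicate edges are collapsed with a
    warning, so fewer bins than requested may result).  Categorical
    attributes pass through untouched; an all-categorical table is returned
    unchanged with an empty scheme.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if method not in (EQUAL_WIDTH, EQUAL_FREQUENCY):
        raise ValueError(f"unknown quantization method {method!r}")
    numeric = [a for a in table.attributes if a.mode == NUMERIC]
    scheme = QuantizationScheme(method=method, bins=bins)
    if not numeric:
        return table, scheme
    for attr in numeric:
        col = table.values[attr.name].to_numpy(dtype=float)
        finite = col[np.isfinite(col)]
        lo, hi = float(finite.min()), float(finite.max())
        if lo == hi:
            scheme.edges[attr.name] = [lo]
            continue
        if method == EQUAL_WIDTH:
            edges = [lo + k * (hi - lo) / bins for k in range(bins + 1)]
        else:
            qs = np.quantile(finite, np.linspace(0.0, 1.0, bins + 1))
            edges = list(np.unique(qs))
            if len(edges) < bins + 1:
                warnings.warn(
                    f"{attr.name}: equal-frequency bins collapsed to "
                    f"{len(edges) - 1} (ties in the data)",
                    stacklevel=2,
                )
        edges[0], edges[-1] = lo, hi
        scheme.edges[attr.name] = [float(e) for e in edges]
    return _quantize_with(table, scheme), scheme


def _quantize_with(
    table: RelationalTable, scheme: QuantizationScheme
) -> RelationalTable:
    attributes = []
    columns = {}
    for attr in table.attributes:
        if attr.mode == NUMERIC and attr.name in scheme.edges:
            col = table.values[attr.name].to_numpy(dtype=float)
            out = [
                None if not np.isfinite(v) else scheme.assign(attr.name, float(v))
                for v in col
            ]
            attributes.append(Attribute(attr.name, CATEGORICAL))
            columns[attr.name] = pd.Series(
                out, index=table.entity_ids, dtype=object
            )
        else:
            attributes.append(attr)
            columns[attr.name] = table.values[attr.name]
    return RelationalTable(
        entity_ids=list(table.entity_ids),
        attributes=attributes,
        values=pd.DataFrame(columns),
        labels=table.labels,
        missing_marker=table.missing_marker,
        label_name=table.label_name,
        provenance=table.provenance,
    )
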