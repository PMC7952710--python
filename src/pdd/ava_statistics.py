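"""Attribute-value catalog and adjusted standardized residuals.

Every (attribute, value) event in a table is an AV with a marginal count n
and an EID set (the entities carrying it).  The association between two AVs
a and b with co-occurrence o, marginals n_a, n_b and table size N is scored
by the adjusted standardized residual

    d = ((o - e) / sqrt(e)) / sqrt((1 - n_a/N)(1 - n_b/N)),  e = n_a*n_b/N,

which is approximately standard normal under independence, so |d| >= 1.96
marks two-sided 95% significance.  The same form extends to AV sets of any
order with e = N * prod(n_i/N) and variance factor prod(1 - n_i/N).  The SR
matrix collects the pairwise residual over all cross-attribute AV pairs;
same-attribute pairs are mutually exclusive events and are structurally 0.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .tabular_io import NUMERIC, RelationalTable

logger = logging.getLogger(__name__)


class DegenerateMarginalError(ValueError):
    """An AV marginal of 0 or N makes the residual variance vanish."""


@dataclass(frozen=True)
class AV:
    """One attribute-value event: marginal count and entity (EID) set."""

    attr_index: int
    attribute: str
    value: str
    n: int
    eids: frozenset
    index: int  # position in the owning catalog

    def __str__(self) -> str:
        return f"{self.attribute}={self.value}"

    @property
    def key(self) -> tuple[str, str]:
        return (self.attribute, self.value)


@dataclass
class AVCatalog:
    """Ordered AV list over a table, attribute-then-value order."""

    avs: list[AV]
    N: int
    entity_ids: tuple
    attribute_names: tuple

    def __len__(self) -> int:
        return len(self.avs)

    def __iter__(self):
        return iter(self.avs)

    def __getitem__(self, i: int) -> AV:
        return self.avs[i]

    def lookup(self, attribute: str, value: str) -> AV:
        for av in self.avs:
            if av.attribute == attribute and av.value == value:
                return av
        raise KeyError((attribute, value))

    @property
    def attr_indices(self) -> np.ndarray:
        return np.array([av.attr_index for av in self.avs], dtype=int)

    @property
    def n_attributes_present(self) -> int:
        return len({av.attr_index for av in self.avs})

    def by_attribute(self, attribute: str) -> list[AV]:
        return [av for av in self.avs if av.attribute == attribute]


def build_av_catalog(table: RelationalTable) -> AVCatalog:
    """One AV per (attribute, observed non-missing value).

    Missing cells are excluded from the AV catalog and from every statistic.
    Constant attributes (a value carried by all N entities) are dropped with
    a warning: their residual variance is zero and they carry no association
    information.  Numeric attributes must be quantized first.
    """
    numeric = [a.name for a in table.attributes if a.mode == NUMERIC]
    if numeric:
        raise ValueError(
            f"numeric attributes {numeric} must be quantized before cataloging"
        )
    avs: list[AV] = []
    N = table.n_entities
    for ai, attr in enumerate(table.attributes):
        col = table.values[attr.name]
        eids_by_value: dict[str, set] = {}
        for eid in table.entity_ids:
            v = col.at[eid]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            eids_by_value.setdefault(str(v), set()).add(eid)
        if not eids_by_value:
            raise ValueError(
                f"attribute {attr.name!r} has zero non-missing values"
            )
        for value in sorted(eids_by_value):
            eids = frozenset(eids_by_value[value])
            if len(eids) == N:
                warnings.warn(
                    f"dropping constant AV {attr.name}={value} (n = N = {N})",
                    stacklevel=2,
                )
                continue
            avs.append(
                AV(
                    attr_index=ai,
                    attribute=attr.name,
                    value=value,
                    n=len(eids),
                    eids=eids,
                    index=len(avs),
                )
            )
    return AVCatalog(
        avs=avs,
        N=N,
        entity_ids=tuple(table.entity_ids),
        attribute_names=tuple(table.attribute_names),
    )


def eid_intersection(avs: Iterable[AV], catalog: Optional[AVCatalog] = None) -> frozenset:
    """Entities carrying every AV of the set (the AV set's frequency support).

    At most one AV per attribute: two values of the same attribute are
    mutually exclusive and their intersection is structurally empty.
    """
    avs = list(avs)
    if not avs:
        raise ValueError("empty AV set")
    seen: dict[int, AV] = {}
    for av in avs:
        if av.attr_index in seen and seen[av.attr_index].value != av.value:
            raise ValueError(
                f"AVs {seen[av.attr_index]} and {av} share an attribute "
                "(mutually exclusive events)"
            )
        seen[av.attr_index] = av
    out = set(avs[0].eids)
    for av in avs[1:]:
        out &= av.eids
    return frozenset(out)


def adjusted_residual(o: float, n_a: int, n_b: int, N: int) -> float:
    """Adjusted standardized residual of a 2x2 AV-pair contingency margin."""
    _check_marginal(n_a, N)
    _check_marginal(n_b, N)
    if not (0 <= o <= min(n_a, n_b)):
        raise ValueError(f"impossible co-occurrence o={o} for marginals ({n_a},{n_b})")
    e = n_a * n_b / N
    return ((o - e) / math.sqrt(e)) / math.sqrt((1 - n_a / N) * (1 - n_b / N))


def compound_residual_from_counts(o: float, marginals: Sequence[int], N: int) -> float:
    """High-order residual: e = N*prod(n_i/N), variance prod(1 - n_i/N)."""
    if len(marginals) < 2:
        raise ValueError("compound residual needs >= 2 marginals")
    var = 1.0
    e = float(N)
    for n_i in marginals:
        _check_marginal(n_i, N)
        e *= n_i / N
        var *= 1 - n_i / N
    return ((o - e) / math.sqrt(e)) / math.sqrt(var)


def compound_residual(avs: Iterable[AV], catalog: Optional[AVCatalog] = None, N: Optional[int] = None) -> float:
    """Compound residual of an AV set, o taken from its EID-intersection."""
    avs = list(avs)
    if N is None:
        if catalog is not None:
            N = catalog.N
        else:
            raise ValueError("need catalog or N")
    o = len(eid_intersection(avs))
    return compound_residual_from_counts(o, [av.n for av in avs], N)


def _check_marginal(n: int, N: int) -> None:
    if not (0 < n < N):
        raise DegenerateMarginalError(
            f"marginal n={n} out of (0, N={N}): residual variance vanishes"
        )


@dataclass
class SRMatrix:
    """Square symmetric matrix of pairwise adjusted residuals over a catalog."""

    values: np.ndarray
    catalog: AVCatalog

    def __post_init__(self) -> None:
        A = len(self.catalog)
        if self.values.shape != (A, A):
            raise ValueError("SR matrix shape must match catalog size")

    @property
    def cross_attribute_mask(self) -> np.ndarray:
        """True where the two AVs belong to different attributes."""
        ai = self.catalog.attr_indices
        return ai[:, None] != ai[None, :]

    def entry(self, av_a: AV, av_b: AV) -> float:
        return float(self.values[av_a.index, av_b.index])

    def to_csv(self, path) -> None:
        import csv as _csv

        names = [str(av) for av in self.catalog]
        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh, lineterminator="\n")
            w.writerow([""] + names)
            for name, row in zip(names, self.values):
                w.writerow([name] + [repr(float(x)) for x in row])


def build_sr_matrix(catalog: AVCatalog) -> SRMatrix:
    """Pairwise adjusted residuals for all cross-attribute AV pairs.

    Same-attribute entries and the diagonal are fixed at 0; the result is
    symmetric and finite everywhere.
    """
    if catalog.n_attributes_present < 2:
        raise ValueError("SR matrix needs AVs from >= 2 attributes")
    A = len(catalog)
    N = catalog.N
    eid_pos = {e: i for i, e in enumerate(catalog.entity_ids)}
    B = np.zeros((N, A), dtype=float)
    for av in catalog:
        for e in av.eids:
            B[eid_pos[e], av.index] = 1.0
    O = B.T @ B
    n = np.array([av.n for av in catalog], dtype=float)
    if np.any((n <= 0) | (n >= N)):
        bad = [str(av) for av in catalog if not (0 < av.n < N)]
        raise DegenerateMarginalError(f"degenerate marginals for {bad}")
    E = np.outer(n, n) / N
    f = 1.0 - n / N
    D = (O - E) / np.sqrt(E) / np.sqrt(np.outer(f, f))
    ai = catalog.attr_indices
    D[ai[:, None] == ai[None, :]] = 0.0  # same attribute incl. diagonal
    D = (D + D.T) / 2.0  # exact symmetry against float noise
    expected_below_one = int(((E < 1.0) & (ai[:, None] != ai[None, :])).sum()) // 2
    if expected_below_one:
        logger.info(
            "SR matrix: %d cross-attribute pairs with expected count < 1",
            expected_below_one,
        )
    return SRMatrix(values=D, catalog=catalog)
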