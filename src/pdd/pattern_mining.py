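"""Growing significant high-order patterns inside each disentangled unit.

A pattern is an AV set (>= 2 AVs, at most one per attribute) whose compound
residual reaches the significance threshold and whose EID-intersection
meets a minimum occurrence.  Candidates are grown levelwise inside one
SubPG: a candidate is extended only while its EID-intersection is non-empty
(support is anti-monotone), but significance itself never prunes supersets
(it is not anti-monotone), and every qualifying subset is kept — the
comprehensive view — rather than only maximal ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

from .ava_statistics import (
    AV,
    AVCatalog,
    compound_residual_from_counts,
    eid_intersection,
)
from .disentanglement import DEFAULT_THRESHOLD, DSUCode, DSUnit
from .tabular_io import RelationalTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_OCCURRENCE = 2
DEFAULT_MAX_ORDER = 8


@dataclass(frozen=True)
class ClassAssociation:
    label: str
    confidence: float
    tie: bool = False


@dataclass(frozen=True)
class Pattern:
    """A significant AV set with its entity support and DSU address."""

    avs: tuple[AV, ...]  # sorted by catalog index
    eids: frozenset
    significance: float
    dsu: Optional[DSUCode] = None
    class_association: Optional[ClassAssociation] = None

    @property
    def order(self) -> int:
        return len(self.avs)

    @property
    def av_keys(self) -> frozenset:
        return frozenset(av.key for av in self.avs)

    def render(self) -> str:
        return ", ".join(str(av) for av in self.avs)


@dataclass
class SummaryPattern:
    """Per-DSU union super-pattern with per-entity member-pattern counts."""

    dsu: DSUCode
    av_union: tuple[tuple[str, str], ...]  # sorted (attribute, value) pairs
    per_entity_counts: dict  # entity -> #member patterns it contains (> 0 only)


@dataclass
class PatternSearchResult:
    patterns: list[Pattern]
    repulsive: list[Pattern]  # significance <= -threshold, kept out of the KB
    truncated: bool = False


def grow_patterns(
    subpg: Sequence[AV] | DSUnit,
    catalog: AVCatalog,
    threshold: float = DEFAULT_THRESHOLD,
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
    max_order: int = DEFAULT_MAX_ORDER,
    dsu: Optional[DSUCode] = None,
) -> PatternSearchResult:
    """Levelwise search for all significant patterns within one SubPG.

    Returns every AV subset (one AV per attribute, order >= 2) with
    compound residual >= threshold and support >= min_occurrence, plus —
    separately — repulsive sets with residual <= -threshold.  Search depth
    is capped at max_order with a logged warning.
    """
    if isinstance(subpg, DSUnit):
        dsu = dsu or subpg.code
        avs = list(subpg.avs)
    else:
        avs = list(subpg)
    avs.sort(key=lambda av: av.index)
    N = catalog.N
    patterns: list[Pattern] = []
    repulsive: list[Pattern] = []
    truncated = False

    def evaluate(members: tuple[AV, ...], eids: frozenset) -> None:
        d = compound_residual_from_counts(len(eids), [a.n for a in members], N)
        if d >= threshold and len(eids) >= min_occurrence:
            patterns.append(
                Pattern(avs=members, eids=eids, significance=d, dsu=dsu)
            )
        elif d <= -threshold:
            repulsive.append(
                Pattern(avs=members, eids=eids, significance=d, dsu=dsu)
            )

    # level 2 seeds
    frontier: list[tuple[tuple[AV, ...], frozenset]] = []
    for a, b in combinations(avs, 2):
        if a.attr_index == b.attr_index:
            continue
        eids = a.eids & b.eids
        evaluate((a, b), frozenset(eids))
        if eids:
            frontier.append(((a, b), frozenset(eids)))

    order = 2
    while frontier:
        if order >= max_order:
            if any(True for _ in frontier):
                truncated = True
                logger.warning(
                    "pattern growth truncated at max_order=%d in DSU %s",
                    max_order,
                    dsu.render() if dsu else "?",
                )
            break
        nxt: list[tuple[tuple[AV, ...], frozenset]] = []
        for members, eids in frontier:
            last = members[-1].index
            used_attrs = {m.attr_index for m in members}
            for av in avs:
                if av.index <= last or av.attr_index in used_attrs:
                    continue
                new_eids = eids & av.eids
                new_members = members + (av,)
                evaluate(new_members, frozenset(new_eids))
                if new_eids:
                    nxt.append((new_members, frozenset(new_eids)))
        frontier = nxt
        order += 1
    return PatternSearchResult(
        patterns=patterns, repulsive=repulsive, truncated=truncated
    )


def enumerate_patterns_bruteforce(
    avs: Sequence[AV],
    catalog: AVCatalog,
    threshold: float = DEFAULT_THRESHOLD,
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
    max_order: Optional[int] = None,
) -> list[Pattern]:
    """Exhaustive enumeration over all legal AV subsets (oracle, small inputs)."""
    avs = sorted(avs, key=lambda av: av.index)
    out: list[Pattern] = []
    top = max_order if max_order is not None else len(avs)
    for k in range(2, min(len(avs), top) + 1):
        for combo in combinations(avs, k):
            attrs = {a.attr_index for a in combo}
            if len(attrs) != k:
                continue
            eids = eid_intersection(combo)
            d = compound_residual_from_counts(
                len(eids), [a.n for a in combo], catalog.N
            )
            if d >= threshold and len(eids) >= min_occurrence:
                out.append(Pattern(avs=tuple(combo), eids=eids, significance=d))
    return out


def summarize_patterns(
    patterns: Sequence[Pattern],
    dsu: DSUCode,
    table: Optional[RelationalTable] = None,
) -> SummaryPattern:
    """Union super-pattern of a DSU with per-entity member-pattern counts."""
    for p in patterns:
        if p.dsu != dsu:
            raise ValueError(
                f"pattern {p.render()} belongs to {p.dsu}, not {dsu}"
            )
    union = sorted({av.key for p in patterns for av in p.avs})
    counts: dict = {}
    for p in patterns:
        for e in p.eids:
            counts[e] = counts.get(e, 0) + 1
    return SummaryPattern(
        dsu=dsu, av_union=tuple(union), per_entity_counts=counts
    )


def associate_class(
    pattern: Pattern, labels: Mapping
) -> Optional[ClassAssociation]:
    """Majority class over the pattern's covered labeled entities.

    Confidence is the majority fraction of the labeled coverage; ties break
    lexicographically and are flagged.  Returns None when no covered entity
    is labeled.
    """
    tally: dict[str, int] = {}
    for e in pattern.eids:
        lab = labels.get(e)
        if lab is not None:
            tally[str(lab)] = tally.get(str(lab), 0) + 1
    if not tally:
        return None
    best = max(tally.values())
    winners = sorted(c for c, k in tally.items() if k == best)
    return ClassAssociation(
        label=winners[0],
        confidence=best / sum(tally.values()),
        tie=len(winners) > 1,
    )


def associate_all(
    patterns: Iterable[Pattern], labels: Mapping
) -> list[Pattern]:
    """Attach class associations to a pattern list (labels are reference-only)."""
    return [
        replace(p, class_association=associate_class(p, labels))
        for p in patterns
    ]
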