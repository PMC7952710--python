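"""Disentangling the SR matrix into statistical source spaces.

The symmetric SR matrix is eigendecomposed; each eigenpair (lambda, v) is a
Disentangled Space (DS) whose re-projected residual space (RSRV) is the
rank-one matrix lambda * v v^T.  Summed over all spaces the RSRVs
reconstruct SR exactly, so each DS carries the share of every pairwise
association attributable to one statistical source.  A DS is retained when
its RSRV still contains at least one significant cross-attribute entry
(|entry| >= threshold, default 1.96).  Within a retained DS the significant
AVs split by the sign of their principal-component loading into two Pattern
Groups (PGs), and each PG splits into SubPGs — connected components under
positive significant RSRV association.  A (DS, PG, SubPG) triple is a
disentangled unit addressed by its DSU code, e.g. ``[2 1 2]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import networkx as nx
import numpy as np

from .ava_statistics import AV, AVCatalog, SRMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.96


class DSUCode(NamedTuple):
    """Address of one disentangled unit: (DS ordinal, PG ordinal, SubPG ordinal)."""

    ds: int
    pg: int
    subpg: int

    def render(self) -> str:
        return f"[{self.ds} {self.pg} {self.subpg}]"

    @classmethod
    def parse(cls, s: str) -> "DSUCode":
        parts = s.strip().strip("[]").split()
        if len(parts) != 3:
            raise ValueError(f"bad DSU code {s!r}")
        return cls(*(int(p) for p in parts))


@dataclass
class DisentangledSpace:
    """One principal component of the SR matrix with its rank-one RSRV."""

    ordinal: int  # 1-based, by descending |eigenvalue|
    eigenvalue: float
    vector: np.ndarray  # unit principal component over catalog AVs
    catalog: AVCatalog
    owned: Optional[np.ndarray] = None  # AVs whose dominant space this is
    significant: list[AV] = field(default_factory=list)
    retained: bool = False

    @property
    def rsrv(self) -> np.ndarray:
        return self.eigenvalue * np.outer(self.vector, self.vector)

    def loading(self, av: AV) -> float:
        return float(self.vector[av.index])


@dataclass
class PatternGroup:
    """AVs on one sign side of a DS's principal component."""

    space: DisentangledSpace
    ordinal: int  # 1 = positive loadings, 2 = negative
    side: str  # "positive" | "negative"
    members: list[AV]
    subpgs: list[list[AV]] = field(default_factory=list)


@dataclass
class DSUnit:
    """One SubPG with its DSU address; the granule patterns are grown in."""

    code: DSUCode
    avs: list[AV]
    space: DisentangledSpace

    def render(self) -> str:
        return self.code.render()


# ---------------------------------------------------------------------------


def decompose(sr: SRMatrix) -> list[DisentangledSpace]:
    """Full eigendecomposition of SR, spaces ordered by |eigenvalue| desc.

    Negative eigenvalues are kept and ranked by magnitude.  Each
    eigenvector's sign is fixed so its largest-magnitude loading is
    positive, which makes PG numbering deterministic across runs.

    Every AV is additionally assigned to its *dominant* space — the
    eigenpair carrying the largest share |lambda| * loading^2 of the AV's
    association mass (ties to the higher-ranked space).  Downstream, an AV
    contributes significant structure only in its dominant space, so each
    statistical source claims its AVs exactly once and entangled AVs shared
    between sources are resolved to the space that explains them best.
    """
    M = sr.values
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("SR matrix must be symmetric")
    evals, evecs = np.linalg.eigh(M)
    # |eigenvalue| descending; magnitude ties (to float tolerance) prefer
    # the positive member of a +/- pair, then the original eigh position
    scale = max(float(np.abs(evals).max()), 1.0)
    mag = np.round(np.abs(evals) / scale, 9)
    order = sorted(
        range(len(evals)), key=lambda k: (-mag[k], evals[k] < 0, k)
    )
    spaces: list[DisentangledSpace] = []
    for rank, k in enumerate(order, start=1):
        v = evecs[:, k].copy()
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
        spaces.append(
            DisentangledSpace(
                ordinal=rank,
                eigenvalue=float(evals[k]),
                vector=v,
                catalog=sr.catalog,
            )
        )
    # Dominant-space assignment: energy of AV i in space s is lambda_s*v_s[i]^2.
    # Only positive-eigenvalue spaces compete: sources are positively
    # co-occurring AV blocks, while negative eigenpairs encode the exclusion
    # structure between sources and can host no co-occurrence pattern.
    energy = np.stack(
        [max(s.eigenvalue, 0.0) * s.vector**2 for s in spaces], axis=1
    )
    owner = np.argmax(energy, axis=1)  # first max wins -> higher-ranked space
    claimed = energy[np.arange(energy.shape[0]), owner] > 0
    for si, space in enumerate(spaces):
        space.owned = (owner == si) & claimed
    return spaces


def select_spaces(
    spaces: Sequence[DisentangledSpace],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[DisentangledSpace]:
    """Retain spaces whose RSRV still holds significant cross-attribute mass.

    A space is retained iff its RSRV has >= 1 cross-attribute entry of
    magnitude >= threshold and >= 2 significant AVs spanning >= 2
    attributes; a significant AV is one this space owns (it is the AV's
    dominant space) with at least one such entry in its row.  Retention is
    per space, so non-contiguous selections (e.g. DS1, DS2, DS3, DS5 with
    DS4 dropped) arise naturally.

    AVs whose dominant space is not retained are then re-projected: each is
    reassigned to the retained positive space where it carries the most
    energy, so a source AV is not lost merely because a weak echo space
    claimed it first.
    """

    def significant_rows(space: DisentangledSpace, owned: np.ndarray):
        catalog = space.catalog
        ai = catalog.attr_indices
        cross = ai[:, None] != ai[None, :]
        sig_entries = (np.abs(space.rsrv) >= threshold) & cross
        rows = sig_entries.any(axis=1) & owned
        return sig_entries, np.where(rows)[0]

    retained: list[DisentangledSpace] = []
    for space in spaces:
        owned = (
            space.owned
            if space.owned is not None
            else np.ones(len(space.vector), dtype=bool)
        )
        sig_entries, sig_rows = significant_rows(space, owned)
        space.significant = [space.catalog[int(i)] for i in sig_rows]
        n_attrs = len({space.catalog[int(i)].attr_index for i in sig_rows})
        space.retained = bool(
            sig_entries.any() and len(sig_rows) >= 2 and n_attrs >= 2
        )
        if space.retained:
            retained.append(space)

    if retained and any(s.owned is not None and not s.retained for s in spaces):
        # re-project orphaned AVs onto the retained positive spaces
        n_avs = len(spaces[0].vector)
        orphan = np.zeros(n_avs, dtype=bool)
        for s in spaces:
            if s.owned is not None and not s.retained:
                orphan |= s.owned
        if orphan.any():
            energy = np.stack(
                [max(s.eigenvalue, 0.0) * s.vector**2 for s in retained], axis=1
            )
            best = np.argmax(energy, axis=1)
            claimed = energy[np.arange(n_avs), best] > 0
            for ri, space in enumerate(retained):
                gained = orphan & (best == ri) & claimed
                if not gained.any():
                    continue
                owned = space.owned | gained
                space.owned = owned
                _, sig_rows = significant_rows(space, owned)
                space.significant = [space.catalog[int(i)] for i in sig_rows]
    logger.info(
        "retained %d/%d disentangled spaces at threshold %.3g: %s",
        len(retained),
        len(spaces),
        threshold,
        [s.ordinal for s in retained],
    )
    return retained


def form_pattern_groups(
    space: DisentangledSpace,
) -> tuple[PatternGroup, PatternGroup]:
    """Split significant AVs by PC-loading sign: PG1 positive, PG2 negative.

    Zero loadings are excluded; an empty PG is emitted with no SubPGs.
    """
    pos = [av for av in space.significant if space.vector[av.index] > 0]
    neg = [av for av in space.significant if space.vector[av.index] < 0]
    return (
        PatternGroup(space=space, ordinal=1, side="positive", members=pos),
        PatternGroup(space=space, ordinal=2, side="negative", members=neg),
    )


def form_subpgs(
    pg: PatternGroup,
    space: Optional[DisentangledSpace] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[list[AV]]:
    """Partition a PG into SubPGs: connected components under positive edges.

    Two members are linked when their RSRV entry is >= +threshold (positive
    association only); components are ordered by size descending, ties by
    smallest AV index.  Singletons are allowed.
    """
    space = space or pg.space
    if not pg.members:
        pg.subpgs = []
        return []
    R = space.rsrv
    g = nx.Graph()
    g.add_nodes_from(av.index for av in pg.members)
    idx = [av.index for av in pg.members]
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if R[idx[a], idx[b]] >= threshold:
                g.add_edge(idx[a], idx[b])
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    catalog = space.catalog
    pg.subpgs = [[catalog[i] for i in comp] for comp in comps]
    return pg.subpgs


def enumerate_units(
    retained: Sequence[DisentangledSpace],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[DSUnit]:
    """All nonempty SubPGs of the retained spaces, addressed by DSU codes."""
    units: list[DSUnit] = []
    for space in retained:
        for pg in form_pattern_groups(space):
            subpgs = form_subpgs(pg, space, threshold)
            for k, avs in enumerate(subpgs, start=1):
                units.append(
                    DSUnit(
                        code=DSUCode(space.ordinal, pg.ordinal, k),
                        avs=avs,
                        space=space,
                    )
                )
    codes = [u.code for u in units]
    if len(codes) != len(set(codes)):
        raise AssertionError("duplicate DSU codes")
    logger.info("enumerated %d disentangled units", len(units))
    return units


def export_spaces(
    retained: Sequence[DisentangledSpace],
    directory,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[str]:
    """Per-DS CSV: PC loadings and significant RSRV entries, one file per DS."""
    import csv
    import os

    paths = []
    for space in retained:
        path = os.path.join(directory, f"ds_{space.ordinal}.csv")
        R = space.rsrv
        catalog = space.catalog
        ai = catalog.attr_indices
        cross = ai[:, None] != ai[None, :]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["eigenvalue", repr(space.eigenvalue)])
            w.writerow(["av", "loading", "significant"])
            for av in catalog:
                w.writerow(
                    [
                        str(av),
                        repr(float(space.vector[av.index])),
                        int(av in space.significant),
                    ]
                )
            w.writerow(["av_a", "av_b", "rsrv"])
            for i in range(len(catalog)):
                for j in range(i + 1, len(catalog)):
                    if cross[i, j] and abs(R[i, j]) >= threshold:
                        w.writerow(
                            [str(catalog[i]), str(catalog[j]), repr(float(R[i, j]))]
                        )
        paths.append(path)
    return paths
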