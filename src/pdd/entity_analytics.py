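"""Entity-level analytics on the knowledge base.

Clustering assigns each covered entity to the disentangled unit holding
most of its patterns, then merges units whose entity coverage overlaps.
Outliers are entities carrying no discovered pattern at the significance
threshold; mislabeled entities carry patterns, but every one of them is
associated with a class other than the entity's own label.  The classifier
scores a new record by the significance-weighted, confidence-weighted vote
of the training patterns it contains.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import RunConfig
from .disentanglement import DSUCode
from .knowledge_base import PDDKB, PatternRow
from .pipeline import DiscoveryResult, run_discovery
from .tabular_io import QuantizationScheme, RelationalTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class EntityClustering:
    """Entity -> cluster id; clusters carry their dominant DSUs."""

    assignments: dict  # entity -> cluster id (int, 1-based)
    cluster_dsus: dict  # cluster id -> sorted list of DSUCode
    unassigned: list  # entities with zero pattern counts, entity order

    def n_clusters(self) -> int:
        return len(self.cluster_dsus)

    def members(self, cluster: int) -> list:
        return [e for e, c in self.assignments.items() if c == cluster]


def cluster_entities(kb: PDDKB, merge_overlap: float = 0.5) -> EntityClustering:
    """Max-count DSU assignment followed by transitive overlap merging.

    Each covered entity goes to the DSU with its maximal summary count
    (ties to the lower DSU code); DSU clusters whose covered-entity Jaccard
    overlap reaches ``merge_overlap`` are merged transitively.  Zero-count
    entities are unassigned (outliers).
    """
    if not kb.summary:
        return EntityClustering(
            assignments={}, cluster_dsus={}, unassigned=list(kb.entity_ids)
        )
    coverage = {row.dsu: set(row.count_map()) for row in kb.summary}
    dsu_of: dict = {}
    for e in kb.entity_ids:
        counts = kb.counts_for(e)
        best = max(counts.values())
        if best <= 0:
            continue
        dsu_of[e] = min(d for d, c in counts.items() if c == best)
    g = nx.Graph()
    dsus = sorted(coverage)
    g.add_nodes_from(dsus)
    for i in range(len(dsus)):
        for j in range(i + 1, len(dsus)):
            a, b = coverage[dsus[i]], coverage[dsus[j]]
            union = len(a | b)
            if union and len(a & b) / union >= merge_overlap:
                g.add_edge(dsus[i], dsus[j])
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    cluster_of_dsu = {}
    cluster_dsus = {}
    for cid, comp in enumerate(comps, start=1):
        cluster_dsus[cid] = comp
        for d in comp:
            cluster_of_dsu[d] = cid
    assignments = {e: cluster_of_dsu[d] for e, d in dsu_of.items()}
    unassigned = [e for e in kb.entity_ids if e not in assignments]
    logger.info(
        "clustered %d entities into %d clusters (%d unassigned)",
        len(assignments),
        len(cluster_dsus),
        len(unassigned),
    )
    return EntityClustering(
        assignments=assignments, cluster_dsus=cluster_dsus, unassigned=unassigned
    )


# ---------------------------------------------------------------------------
# Anomalies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MislabelEntry:
    entity: str
    given_label: str
    inferred_class: str
    supporting: tuple  # PatternRow tuple, all of a class != given_label


@dataclass
class AnomalyReport:
    """Outliers (no patterns) and mislabeled entities (only foreign patterns)."""

    outliers: list
    mislabeled: list  # of MislabelEntry

    def __post_init__(self) -> None:
        if set(self.outliers) & {m.entity for m in self.mislabeled}:
            raise ValueError("outlier and mislabeled sets must be disjoint")

    @property
    def flagged(self) -> set:
        return set(self.outliers) | {m.entity for m in self.mislabeled}

    def to_json(self, path) -> None:
        doc = {
            "outliers": list(self.outliers),
            "mislabeled": [
                {
                    "entity": m.entity,
                    "given_label": m.given_label,
                    "inferred_class": m.inferred_class,
                    "supporting_patterns": [
                        {
                            "dsu": r.dsu.render(),
                            "avs": [f"{a}={v}" for a, v in r.avs],
                            "significance": r.significance,
                            "class": r.class_label,
                        }
                        for r in m.supporting
                    ],
                }
                for m in self.mislabeled
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def detect_outliers(kb: PDDKB) -> list:
    """Entities whose comprehensive column is all zero, in entity order."""
    covered = set()
    for row in kb.comprehensive:
        covered |= row.eids
    return [e for e in kb.entity_ids if e not in covered]


def detect_mislabeled(
    kb: PDDKB,
    labels: Optional[Mapping] = None,
    patterns: Optional[Sequence[PatternRow]] = None,
) -> list:
    """Entities all of whose matched patterns belong to a foreign class.

    The inferred class is the significance-weighted majority over the
    matched patterns.  Entities matching no pattern are outliers, never
    mislabeled.  Patterns without a class association do not count either
    way.
    """
    labels = labels if labels is not None else (kb.labels or {})
    rows = list(patterns) if patterns is not None else kb.comprehensive
    entries: list[MislabelEntry] = []
    for e in kb.entity_ids:
        given = labels.get(e)
        if given is None:
            continue
        matched = [r for r in rows if e in r.eids and r.class_label is not None]
        if not matched:
            continue
        if any(r.class_label == given for r in matched):
            continue
        weight: dict[str, float] = {}
        for r in matched:
            weight[r.class_label] = weight.get(r.class_label, 0.0) + abs(
                r.significance
            )
        best = max(weight.values())
        inferred = sorted(c for c, w in weight.items() if w == best)[0]
        entries.append(
            MislabelEntry(
                entity=e,
                given_label=str(given),
                inferred_class=inferred,
                supporting=tuple(matched),
            )
        )
    return entries


def detect_anomalies(kb: PDDKB, labels: Optional[Mapping] = None) -> AnomalyReport:
    """Outlier check then abnormal-entity (mislabel) check on one KB."""
    outliers = detect_outliers(kb)
    mislabeled = detect_mislabeled(kb, labels)
    return AnomalyReport(outliers=outliers, mislabeled=mislabeled)


# ---------------------------------------------------------------------------
# Supervised classification
# ---------------------------------------------------------------------------

@dataclass
class ClassifierModel:
    """Pattern-based classifier fit by running discovery on training rows."""

    kb: PDDKB
    scheme: QuantizationScheme
    config: RunConfig
    priors: dict  # class -> prior fraction on training rows
    majority_class: str
    attribute_modes: dict  # attribute name -> mode at fit time

    @property
    def scoring_patterns(self) -> list:
        return [r for r in self.kb.comprehensive if r.class_label is not None]


def fit_classifier(
    table: RelationalTable,
    config: Optional[RunConfig] = None,
    discovery: Optional[DiscoveryResult] = None,
) -> ClassifierModel:
    """Run the full pipeline on labeled training rows and keep the KB.

    Requires >= 2 classes, each with at least ``config.min_class_size``
    members.  The quantization scheme fit here is reapplied to test rows.
    """
    config = config or RunConfig()
    if table.labels is None:
        raise ValueError("fit_classifier needs a labeled table")
    counts: dict[str, int] = {}
    for e in table.entity_ids:
        lab = table.labels.at[e]
        if lab is not None:
            counts[str(lab)] = counts.get(str(lab), 0) + 1
    if len(counts) < 2:
        raise ValueError(f"need >= 2 classes, got {sorted(counts)}")
    small = {c: n for c, n in counts.items() if n < config.min_class_size}
    if small:
        raise ValueError(f"classes below min size {config.min_class_size}: {small}")
    result = discovery or run_discovery(table, config)
    total = sum(counts.values())
    priors = {c: n / total for c, n in counts.items()}
    majority = sorted(counts, key=lambda c: (-counts[c], c))[0]
    return ClassifierModel(
        kb=result.kb,
        scheme=result.scheme,
        config=config,
        priors=priors,
        majority_class=majority,
        attribute_modes={a.name: a.mode for a in table.attributes},
    )


@dataclass(frozen=True)
class Prediction:
    label: str
    scores: dict
    abstained: bool
    tie: bool = False


def classify(model: ClassifierModel, row: Mapping) -> Prediction:
    """Score one record: sum of significance x confidence per class.

    ``row`` maps attribute name to raw value (numeric attributes are
    quantized with the stored scheme).  Unseen values match nothing.  With
    zero matches the model abstains and falls back to the training-majority
    class; score ties break lexicographically.
    """
    cells: dict[str, str] = {}
    for attr, mode in model.attribute_modes.items():
        if attr not in row:
            continue
        v = row[attr]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if mode == "numeric" and attr in model.scheme.edges:
            cells[attr] = model.scheme.assign(attr, float(v))
        else:
            cells[attr] = str(v)
    scores: dict[str, float] = {}
    for r in model.scoring_patterns:
        if all(cells.get(a) == v for a, v in r.avs):
            scores[r.class_label] = scores.get(r.class_label, 0.0) + (
                r.significance * (r.confidence or 0.0)
            )
    if not scores:
        return Prediction(
            label=model.majority_class, scores={}, abstained=True
        )
    best = max(scores.values())
    winners = sorted(c for c, s in scores.items() if s == best)
    if len(winners) > 1:
        logger.info("score tie between %s; picking %s", winners, winners[0])
    return Prediction(
        label=winners[0], scores=scores, abstained=False, tie=len(winners) > 1
    )


# ---------------------------------------------------------------------------
# Clustering evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClusteringMetrics:
    accuracy: float
    f_measure: float  # macro-averaged harmonic mean of per-class P/R
    precision: dict  # per class
    recall: dict
    mapping: dict  # cluster id -> class


def evaluate_clustering(
    predicted: EntityClustering, truth: Mapping
) -> ClusteringMetrics:
    """Score a clustering against per-entity class ground truth.

    Clusters are mapped to classes by the optimal one-to-one assignment
    maximizing total agreement; accuracy is the matched fraction over all
    entities in ``truth`` (unassigned entities count as errors).
    """
    entities = list(truth)
    classes = sorted({str(truth[e]) for e in entities})
    clusters = sorted(predicted.cluster_dsus)
    if not clusters or not predicted.assignments:
        logger.warning("empty clustering: all-zero metrics")
        return ClusteringMetrics(
            accuracy=0.0,
            f_measure=0.0,
            precision={c: 0.0 for c in classes},
            recall={c: 0.0 for c in classes},
            mapping={},
        )
    cont = np.zeros((len(clusters), len(classes)), dtype=float)
    cpos = {c: i for i, c in enumerate(clusters)}
    kpos = {k: j for j, k in enumerate(classes)}
    for e in entities:
        cid = predicted.assignments.get(e)
        if cid is not None:
            cont[cpos[cid], kpos[str(truth[e])]] += 1
    ri, cj = linear_sum_assignment(-cont)
    mapping = {clusters[i]: classes[j] for i, j in zip(ri, cj)}
    matched = cont[ri, cj].sum()
    accuracy = float(matched) / len(entities)
    precision, recall, f_parts = {}, {}, []
    class_sizes = {k: sum(1 for e in entities if str(truth[e]) == k) for k in classes}
    for cid, k in mapping.items():
        tp = cont[cpos[cid], kpos[k]]
        cluster_size = cont[cpos[cid]].sum()
        precision[k] = float(tp / cluster_size) if cluster_size else 0.0
        recall[k] = float(tp / class_sizes[k]) if class_sizes[k] else 0.0
    for k in classes:
        p, r = precision.get(k, 0.0), recall.get(k, 0.0)
        precision.setdefault(k, 0.0)
        recall.setdefault(k, 0.0)
        f_parts.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
    return ClusteringMetrics(
        accuracy=accuracy,
        f_measure=float(np.mean(f_parts)),
        precision=precision,
        recall=recall,
        mapping=mapping,
    )


# ---------------------------------------------------------------------------
# Repeated-split experiment
# ---------------------------------------------------------------------------

@dataclass
class SplitRecord:
    repeat: int
    accuracy: float
    n_train: int
    n_test: int
    n_removed: int
    n_abstained: int


@dataclass
class ExperimentResult:
    records: list
    mean_accuracy: float
    variance: float
    remove_anomalies: bool


def run_split_experiment(
    table: RelationalTable,
    config: Optional[RunConfig] = None,
    remove_anomalies: bool = False,
    seed: Optional[int] = None,
) -> ExperimentResult:
    """Repeated stratified train/test splits with optional anomaly removal.

    Each repeat draws a stratified ``train_fraction`` split; with
    ``remove_anomalies`` the outlier and mislabel checks run on the
    training portion and flagged rows are dropped before refitting.
    Identical seeds give identical records.
    """
    config = config or RunConfig()
    if table.labels is None:
        raise ValueError("experiment needs a labeled table")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    by_class: dict[str, list] = {}
    for e in table.entity_ids:
        lab = table.labels.at[e]
        if lab is not None:
            by_class.setdefault(str(lab), []).append(e)
    records: list[SplitRecord] = []
    for rep in range(config.repeats):
        train_ids: list = []
        test_ids: list = []
        for c in sorted(by_class):
            members = list(by_class[c])
            perm = rng.permutation(len(members))
            k = max(1, int(round(config.train_fraction * len(members))))
            if k == len(members):  # keep >= 1 test row per class when possible
                k = len(members) - 1
            train_ids += [members[i] for i in perm[:k]]
            test_ids += [members[i] for i in perm[k:]]
        train_ids = [e for e in table.entity_ids if e in set(train_ids)]
        test_ids = [e for e in table.entity_ids if e in set(test_ids)]
        train = table.subset(train_ids)
        n_removed = 0
        if remove_anomalies:
            pre_model = fit_classifier(train, config)
            report = detect_anomalies(pre_model.kb)
            keep = [e for e in train_ids if e not in report.flagged]
            # never drop a class below the fit threshold
            kept_counts: dict[str, int] = {}
            for e in keep:
                kept_counts[str(table.labels.at[e])] = (
                    kept_counts.get(str(table.labels.at[e]), 0) + 1
                )
            if len(kept_counts) >= 2 and all(
                v >= config.min_class_size for v in kept_counts.values()
            ):
                n_removed = len(train_ids) - len(keep)
                train = table.subset(keep)
        model = fit_classifier(train, config)
        correct = 0
        abstained = 0
        for e in test_ids:
            row = {
                a.name: table.values.at[e, a.name] for a in table.attributes
            }
            pred = classify(model, row)
            abstained += int(pred.abstained)
            if pred.label == str(table.labels.at[e]):
                correct += 1
        records.append(
            SplitRecord(
                repeat=rep,
                accuracy=correct / len(test_ids) if test_ids else 0.0,
                n_train=train.n_entities,
                n_test=len(test_ids),
                n_removed=n_removed,
                n_abstained=abstained,
            )
        )
    accs = [r.accuracy for r in records]
    return ExperimentResult(
        records=records,
        mean_accuracy=float(np.mean(accs)),
        variance=float(np.var(accs, ddof=1)) if len(accs) > 1 else 0.0,
        remove_anomalies=remove_anomalies,
    )
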