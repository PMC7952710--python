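"""Synthetic relational tables with planted, entangled multi-source structure.

The generator plants one AV block per class: at each blocked attribute a
class member shows the block's value with probability ``fidelity`` and a
uniformly random other value otherwise; non-blocked attributes are uniform.
Blocks may deliberately share AVs across classes (entanglement).  On top of
that it supports background cell noise, all-uniform noise entities recorded
under a random class label, planted mislabels (the recorded label is
flipped, the true one kept in the ground truth), and stochastic transition
groups that interpolate per attribute between two class blocks.  Each
component (blocks, noise, mislabels, transitions) draws from its own
seed-split stream, so changing one rate never perturbs the others' draws.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .ava_statistics import AV
from .disentanglement import DSUnit
from .entity_analytics import (
    AnomalyReport,
    ClusteringMetrics,
    EntityClustering,
    evaluate_clustering,
)
from .knowledge_base import table_digest
from .tabular_io import Attribute, CATEGORICAL, NUMERIC, RelationalTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AttributeSpec:
    name: str
    values: tuple  # category symbols; for numeric attributes, latent levels
    numeric: bool = False


@dataclass(frozen=True)
class ClassSpec:
    name: str
    size: int
    block: Mapping  # attribute name -> planted value symbol


@dataclass(frozen=True)
class TransitionSpec:
    """A small group interpolating between two class blocks.

    ``fractions`` maps attribute name -> probability of taking the target
    class's AV there (else the source class's); attributes outside the map
    use ``default_fraction``.
    """

    name: str
    source: str
    target: str
    size: int
    fractions: Mapping = field(default_factory=dict)
    default_fraction: float = 0.5


@dataclass
class SyntheticSpec:
    """Full description of one synthetic study condition."""

    attributes: list
    classes: list
    fidelity: float = 1.0
    noise_rate: float = 0.0
    mislabel_rate: float = 0.0
    n_noise_entities: int = 0
    transitions: list = field(default_factory=list)
    seed: int = 0

    @property
    def n_entities(self) -> int:
        return (
            sum(c.size for c in self.classes)
            + sum(t.size for t in self.transitions)
            + self.n_noise_entities
        )

    def validate(self) -> None:
        for r, nm in [
            (self.fidelity, "fidelity"),
            (self.noise_rate, "noise_rate"),
            (self.mislabel_rate, "mislabel_rate"),
        ]:
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{nm} must be in [0, 1], got {r}")
        names = {a.name for a in self.attributes}
        class_names = {c.name for c in self.classes}
        for c in self.classes:
            for attr in c.block:
                if attr not in names:
                    raise ValueError(
                        f"class {c.name!r} block references unknown attribute {attr!r}"
                    )
                spec = next(a for a in self.attributes if a.name == attr)
                if c.block[attr] not in spec.values:
                    raise ValueError(
                        f"class {c.name!r} block value {c.block[attr]!r} "
                        f"not in alphabet of {attr!r}"
                    )
        for t in self.transitions:
            if t.source not in class_names or t.target not in class_names:
                raise ValueError(
                    f"transition {t.name!r} references unknown class"
                )

    def to_dict(self) -> dict:
        return {
            "attributes": [
                {"name": a.name, "values": list(a.values), "numeric": a.numeric}
                for a in self.attributes
            ],
            "classes": [
                {"name": c.name, "size": c.size, "block": dict(c.block)}
                for c in self.classes
            ],
            "fidelity": self.fidelity,
            "noise_rate": self.noise_rate,
            "mislabel_rate": self.mislabel_rate,
            "n_noise_entities": self.n_noise_entities,
            "transitions": [
                {
                    "name": t.name,
                    "source": t.source,
                    "target": t.target,
                    "size": t.size,
                    "fractions": dict(t.fractions),
                    "default_fraction": t.default_fraction,
                }
                for t in self.transitions
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticSpec":
        return cls(
            attributes=[
                AttributeSpec(a["name"], tuple(a["values"]), bool(a["numeric"]))
                for a in d["attributes"]
            ],
            classes=[
                ClassSpec(c["name"], int(c["size"]), dict(c["block"]))
                for c in d["classes"]
            ],
            fidelity=float(d["fidelity"]),
            noise_rate=float(d["noise_rate"]),
            mislabel_rate=float(d["mislabel_rate"]),
            n_noise_entities=int(d["n_noise_entities"]),
            transitions=[
                TransitionSpec(
                    t["name"],
                    t["source"],
                    t["target"],
                    int(t["size"]),
                    dict(t["fractions"]),
                    float(t["default_fraction"]),
                )
                for t in d["transitions"]
            ],
            seed=int(d["seed"]),
        )


@dataclass
class GroundTruth:
    """Sidecar truth for a generated table; never embedded in the table."""

    true_labels: dict  # entity -> true group (class, transition or "noise")
    blocks: dict  # class name -> {attribute: value}
    mislabeled: list  # entities whose recorded label was flipped
    noise_entities: list
    transition_entities: dict  # group name -> entity list
    table_digest: str
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "true_labels": self.true_labels,
                    "blocks": self.blocks,
                    "mislabeled": self.mislabeled,
                    "noise_entities": self.noise_entities,
                    "transition_entities": self.transition_entities,
                    "table_digest": self.table_digest,
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def generate(spec: SyntheticSpec) -> tuple[RelationalTable, GroundTruth]:
    """Draw one table from the spec; fixed seed gives byte-identical output."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_blocks, rng_noise, rng_mislabel, rng_transition = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    attr_specs = list(spec.attributes)
    blocks = {c.name: dict(c.block) for c in spec.classes}
    rows: list[dict] = []
    true_labels: dict = {}
    recorded: list = []
    noise_entities: list = []
    transition_entities: dict = {t.name: [] for t in spec.transitions}

    def uniform_value(a: AttributeSpec, rng) -> str:
        return a.values[int(rng.integers(len(a.values)))]

    def other_value(a: AttributeSpec, not_this: str, rng) -> str:
        rest = [v for v in a.values if v != not_this]
        if not rest:
            return not_this
        return rest[int(rng.integers(len(rest)))]

    eid = 0
    for c in spec.classes:
        for _ in range(c.size):
            eid += 1
            e = f"E{eid}"
            row = {}
            for a in attr_specs:
                if a.name in c.block:
                    if rng_blocks.random() < spec.fidelity:
                        row[a.name] = c.block[a.name]
                    else:
                        row[a.name] = other_value(a, c.block[a.name], rng_blocks)
                else:
                    row[a.name] = uniform_value(a, rng_blocks)
            rows.append(row)
            true_labels[e] = c.name
            recorded.append(c.name)
    for t in spec.transitions:
        src = blocks[t.source]
        tgt = blocks[t.target]
        t_attrs = sorted(set(src) | set(tgt))
        for _ in range(t.size):
            eid += 1
            e = f"E{eid}"
            row = {}
            for a in attr_specs:
                if a.name in t_attrs:
                    frac = t.fractions.get(a.name, t.default_fraction)
                    take_target = rng_transition.random() < frac
                    pick = tgt if take_target else src
                    if a.name in pick:
                        row[a.name] = pick[a.name]
                    else:
                        row[a.name] = uniform_value(a, rng_transition)
                else:
                    row[a.name] = uniform_value(a, rng_transition)
            rows.append(row)
            true_labels[e] = t.name
            recorded.append(t.name)
            transition_entities[t.name].append(e)
    class_names = sorted(c.name for c in spec.classes)
    for _ in range(spec.n_noise_entities):
        eid += 1
        e = f"E{eid}"
        rows.append({a.name: uniform_value(a, rng_noise) for a in attr_specs})
        true_labels[e] = "noise"
        # noise entities masquerade under a random class label
        recorded.append(
            class_names[int(rng_noise.integers(len(class_names)))]
            if class_names
            else "noise"
        )
        noise_entities.append(e)

    entity_ids = [f"E{i}" for i in range(1, eid + 1)]

    # background cell noise, applied uniformly after structure
    if spec.noise_rate > 0:
        for i, e in enumerate(entity_ids):
            for a in attr_specs:
                if rng_noise.random() < spec.noise_rate:
                    rows[i][a.name] = uniform_value(a, rng_noise)

    # planted mislabels among class entities only
    mislabeled: list = []
    if spec.mislabel_rate > 0 and len(class_names) >= 2:
        class_entities = [
            e for e in entity_ids if true_labels[e] in class_names
        ]
        k = int(round(spec.mislabel_rate * len(class_entities)))
        picks = rng_mislabel.choice(len(class_entities), size=k, replace=False)
        for p in sorted(int(x) for x in picks):
            e = class_entities[p]
            idx = entity_ids.index(e)
            wrong = [c for c in class_names if c != true_labels[e]]
            recorded[idx] = wrong[int(rng_mislabel.integers(len(wrong)))]
            mislabeled.append(e)

    # materialize the table; numeric attributes map latent level k to a
    # jittered value in [k+0.05, k+0.95] so equal-width binning recovers it
    columns = {}
    attributes = []
    for a in attr_specs:
        if a.numeric:
            level = {v: k for k, v in enumerate(a.values)}
            vals = [
                level[rows[i][a.name]] + 0.05 + 0.9 * rng_blocks.random()
                for i in range(len(entity_ids))
            ]
            columns[a.name] = pd.Series(vals, index=entity_ids, dtype=float)
            attributes.append(Attribute(a.name, NUMERIC))
        else:
            columns[a.name] = pd.Series(
                [rows[i][a.name] for i in range(len(entity_ids))],
                index=entity_ids,
                dtype=object,
            )
            attributes.append(Attribute(a.name, CATEGORICAL))
    labels = pd.Series(recorded, index=entity_ids, dtype=object)
    table = RelationalTable(
        entity_ids=entity_ids,
        attributes=attributes,
        values=pd.DataFrame(columns),
        labels=labels,
        provenance=f"synthetic(seed={spec.seed})",
    )
    truth = GroundTruth(
        true_labels=true_labels,
        blocks=blocks,
        mislabeled=mislabeled,
        noise_entities=noise_entities,
        transition_entities=transition_entities,
        table_digest=table_digest(table),
        seed=spec.seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Presets: study conditions mirroring the shapes of the validation datasets
# ---------------------------------------------------------------------------

def _alphabet(block_values: Sequence[str], pad: Sequence[str], size: int) -> tuple:
    out = list(dict.fromkeys(block_values))
    for p in pad:
        if len(out) >= size:
            break
        if p not in out:
            out.append(p)
    return tuple(sorted(out))


def preset(name: str, seed: int = 0) -> SyntheticSpec:
    """Named study conditions.

    apc1_like: 80 entities, 9 categorical site attributes, imbalanced
    classes 30/25/20/5, class blocks with two deliberately shared AVs.
    cancer_transition_like: two major classes (447/235) plus two
    30-entity transition groups interpolating between their blocks.
    heart_like: 270 entities, 13 mixed-mode attributes, 2 classes.
    two_class_mislabel: 500 entities, 2 balanced classes with disjoint
    blocks and 5% planted mislabels.
    entangled_mislabel: low-volume noisy clinical shape — 120 entities,
    2 balanced classes whose blocks share two AVs, fidelity 0.65, 10%
    planted mislabels.
    """
    presets = {
        "apc1_like": _apc1_like,
        "cancer_transition_like": _cancer_transition_like,
        "heart_like": _heart_like,
        "two_class_mislabel": _two_class_mislabel,
        "entangled_mislabel": _entangled_mislabel,
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name](seed)


def _apc1_like(seed: int) -> SyntheticSpec:
    # site alphabets hold each class's residue plus fillers; Mammal/Plant
    # share S1=L and Mammal/Fungi share S6=E (planted entanglement)
    blocks = {
        "Mammal": {"S1": "L", "S2": "A", "S3": "K", "S4": "T", "S5": "V", "S6": "E", "S7": "G"},
        "Plant": {"S1": "L", "S2": "P", "S3": "D", "S4": "S", "S5": "I", "S6": "Q", "S7": "W"},
        "Fungi": {"S1": "M", "S2": "R", "S3": "H", "S4": "Y", "S5": "C", "S6": "E", "S7": "F"},
        "Insect": {"S4": "E", "S5": "F", "S8": "N", "S9": "D"},
    }
    pad = "GASTV"
    attrs = []
    for j in range(1, 10):
        name = f"S{j}"
        bv = [b[name] for b in blocks.values() if name in b]
        attrs.append(AttributeSpec(name, _alphabet(bv, pad, 5)))
    classes = [
        ClassSpec("Mammal", 30, blocks["Mammal"]),
        ClassSpec("Plant", 25, blocks["Plant"]),
        ClassSpec("Fungi", 20, blocks["Fungi"]),
        ClassSpec("Insect", 5, blocks["Insect"]),
    ]
    return SyntheticSpec(
        attributes=attrs, classes=classes, fidelity=0.9, seed=seed
    )


def _cancer_transition_like(seed: int) -> SyntheticSpec:
    attrs = [
        AttributeSpec(f"A{j}", ("low", "mid", "high")) for j in range(1, 10)
    ]
    benign = {f"A{j}": "low" for j in range(1, 10)}
    malignant = {f"A{j}": "high" for j in range(1, 10)}
    classes = [
        ClassSpec("Benign", 447, benign),
        ClassSpec("Malignant", 235, malignant),
    ]
    t1 = TransitionSpec(
        "Transition1",
        source="Benign",
        target="Malignant",
        size=30,
        fractions={f"A{j}": (0.9 if j <= 4 else 0.1) for j in range(1, 10)},
    )
    t2 = TransitionSpec(
        "Transition2",
        source="Benign",
        target="Malignant",
        size=30,
        fractions={f"A{j}": (0.1 if j <= 4 else 0.9) for j in range(1, 10)},
    )
    return SyntheticSpec(
        attributes=attrs,
        classes=classes,
        fidelity=0.9,
        transitions=[t1, t2],
        seed=seed,
    )


def _heart_like(seed: int) -> SyntheticSpec:
    attrs = []
    for j in range(1, 6):  # 5 numeric attributes with 3 latent levels
        attrs.append(
            AttributeSpec(f"N{j}", ("l0", "l1", "l2"), numeric=True)
        )
    for j in range(1, 9):  # 8 categorical attributes
        attrs.append(AttributeSpec(f"C{j}", ("a", "b", "c")))
    absence = {"N1": "l0", "N2": "l0", "N3": "l0", "C1": "a", "C2": "a", "C3": "a", "C4": "a"}
    presence = {"N1": "l2", "N2": "l2", "N3": "l2", "C1": "c", "C2": "c", "C3": "c", "C4": "c"}
    classes = [
        ClassSpec("Absence", 150, absence),
        ClassSpec("Presence", 120, presence),
    ]
    return SyntheticSpec(
        attributes=attrs, classes=classes, fidelity=0.85, seed=seed
    )


def _two_class_mislabel(seed: int) -> SyntheticSpec:
    attrs = [AttributeSpec(f"A{j}", ("u", "v", "w")) for j in range(1, 9)]
    block_a = {f"A{j}": "u" for j in range(1, 7)}
    block_b = {f"A{j}": "w" for j in range(1, 7)}
    classes = [ClassSpec("ClassA", 250, block_a), ClassSpec("ClassB", 250, block_b)]
    return SyntheticSpec(
        attributes=attrs,
        classes=classes,
        fidelity=0.9,
        mislabel_rate=0.05,
        seed=seed,
    )


def _entangled_mislabel(seed: int) -> SyntheticSpec:
    # low-volume, high-noise regime: pattern coverages are small and mixed,
    # so planted mislabels can flip pattern-class associations — the regime
    # where anomaly removal before training pays off
    attrs = [AttributeSpec(f"A{j}", ("u", "v", "w")) for j in range(1, 9)]
    block_a = {f"A{j}": "u" for j in range(1, 7)}
    block_b = {f"A{j}": ("u" if j <= 2 else "w") for j in range(1, 7)}
    classes = [ClassSpec("ClassA", 60, block_a), ClassSpec("ClassB", 60, block_b)]
    return SyntheticSpec(
        attributes=attrs,
        classes=classes,
        fidelity=0.65,
        mislabel_rate=0.10,
        seed=seed,
    )


def independent_table(
    n_entities: int, n_attributes: int, n_values: int = 4, seed: int = 0
) -> RelationalTable:
    """Mutually independent uniform attributes (type-I error control runs)."""
    spec = SyntheticSpec(
        attributes=[
            AttributeSpec(f"A{j}", tuple(f"v{k}" for k in range(n_values)))
            for j in range(1, n_attributes + 1)
        ],
        classes=[],
        n_noise_entities=n_entities,
        seed=seed,
    )
    table, _ = generate(spec)
    return RelationalTable(
        entity_ids=table.entity_ids,
        attributes=table.attributes,
        values=table.values,
        labels=None,
        provenance=table.provenance,
    )


# ---------------------------------------------------------------------------
# Scoring discovered structure against the planted truth
# ---------------------------------------------------------------------------

def _check_digest(truth: GroundTruth, table: Optional[RelationalTable]) -> None:
    if table is not None and table_digest(table) != truth.table_digest:
        raise ValueError("table digest does not match ground truth")


def av_block_ari(
    units: Sequence[DSUnit],
    truth: GroundTruth,
    table: Optional[RelationalTable] = None,
) -> float:
    """ARI between planted block membership and discovered SubPG membership.

    Each planted AV that is unique to one class block is assigned to the
    unit where it carries the most spectral energy (|eigenvalue| x
    loading^2); AVs shared by several blocks have no unique truth and are
    excluded.  Unrecovered AVs form one extra cluster.
    """
    _check_digest(truth, table)
    owners: dict = {}
    shared = set()
    for cls, block in truth.blocks.items():
        for attr, value in block.items():
            key = (attr, str(value))
            if key in owners and owners[key] != cls:
                shared.add(key)
            owners[key] = cls
    keys = sorted(k for k in owners if k not in shared)
    best_unit: dict = {}
    best_energy: dict = {}
    for u in units:
        lam = abs(u.space.eigenvalue)
        for av in u.avs:
            k = av.key
            energy = lam * float(u.space.vector[av.index]) ** 2
            if energy > best_energy.get(k, 0.0):
                best_energy[k] = energy
                best_unit[k] = u.code
    unit_ids = {code: i for i, code in enumerate(sorted({c for c in best_unit.values()}))}
    truth_labels = [owners[k] for k in keys]
    pred_labels = [
        unit_ids[best_unit[k]] if k in best_unit else -1 for k in keys
    ]
    return float(adjusted_rand_score(truth_labels, pred_labels))


def clustering_score(
    clustering: EntityClustering,
    truth: GroundTruth,
    table: Optional[RelationalTable] = None,
    include_noise: bool = False,
) -> ClusteringMetrics:
    """Entity-cluster quality against true group labels."""
    _check_digest(truth, table)
    ref = {
        e: g
        for e, g in truth.true_labels.items()
        if include_noise or g != "noise"
    }
    return evaluate_clustering(clustering, ref)


def classes_recovered(
    clustering: EntityClustering,
    truth: GroundTruth,
    min_recall: float = 0.5,
) -> set:
    """Groups that dominate some cluster and have > min_recall of their
    members inside it."""
    sizes: dict = {}
    for e, g in truth.true_labels.items():
        if g != "noise":
            sizes[g] = sizes.get(g, 0) + 1
    recovered = set()
    for cid in clustering.cluster_dsus:
        members = clustering.members(cid)
        if not members:
            continue
        tally: dict = {}
        for e in members:
            g = truth.true_labels.get(e)
            if g and g != "noise":
                tally[g] = tally.get(g, 0) + 1
        if not tally:
            continue
        top = max(tally, key=lambda g: (tally[g], g))
        if tally[top] > min_recall * sizes[top]:
            recovered.add(top)
    return recovered


def anomaly_score(
    report: AnomalyReport,
    truth: GroundTruth,
    table: Optional[RelationalTable] = None,
) -> dict:
    """Precision/recall of mislabel and outlier detection vs planted truth."""
    _check_digest(truth, table)
    planted_mis = set(truth.mislabeled)
    found_mis = {m.entity for m in report.mislabeled}
    planted_out = set(truth.noise_entities)
    found_out = set(report.outliers)

    def pr(found: set, planted: set) -> tuple[float, float]:
        tp = len(found & planted)
        p = tp / len(found) if found else (1.0 if not planted else 0.0)
        r = tp / len(planted) if planted else 1.0
        return p, r

    mp, mr = pr(found_mis, planted_mis)
    op, orr = pr(found_out, planted_out)
    return {
        "mislabel_precision": mp,
        "mislabel_recall": mr,
        "outlier_precision": op,
        "outlier_recall": orr,
    }
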