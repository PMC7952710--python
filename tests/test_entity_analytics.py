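import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdd.config import RunConfig
from pdd.disentanglement import DSUCode
from pdd.entity_analytics import (
    AnomalyReport,
    EntityClustering,
    MislabelEntry,
    classify,
    cluster_entities,
    detect_anomalies,
    detect_mislabeled,
    detect_outliers,
    evaluate_clustering,
    fit_classifier,
    run_split_experiment,
)
from pdd.knowledge_base import PDDKB, PatternRow, SummaryRow
from pdd.pipeline import run_discovery
from pdd.synthetic_data import generate, preset


def kb_from_rows(entity_ids, rows, labels=None):
    """Assemble a consistent PDDKB from (dsu, avs, significance, eids, cls)."""
    patterns = [
        PatternRow(
            dsu=d, avs=a, significance=s, eids=frozenset(e), class_label=c,
            confidence=None if c is None else 1.0,
        )
        for d, a, s, e, c in rows
    ]
    by_dsu = {}
    for p in patterns:
        by_dsu.setdefault(p.dsu, []).append(p)
    summary = []
    for d in sorted(by_dsu):
        counts = {}
        union = set()
        for p in by_dsu[d]:
            union |= set(p.avs)
            for e in p.eids:
                counts[e] = counts.get(e, 0) + 1
        summary.append(
            SummaryRow(
                dsu=d,
                av_union=tuple(sorted(union)),
                counts=tuple((e, counts[e]) for e in entity_ids if e in counts),
            )
        )
    return PDDKB(
        entity_ids=list(entity_ids),
        summary=summary,
        comprehensive=patterns,
        labels=labels,
    )


D1, D2 = DSUCode(1, 1, 1), DSUCode(2, 1, 1)
AV1 = (("A", "x"), ("B", "y"))
AV2 = (("C", "z"), ("D", "w"))


class TestClusterEntities:
    def test_max_count_assignment(self):
        # E1 holds 2 patterns of D1 and 1 of D2 -> cluster of D1
        kb = kb_from_rows(
            ["E1", "E2", "E3"],
            [
                (D1, AV1, 3.0, {"E1", "E2"}, None),
                (D1, (("A", "x"), ("C", "z")), 2.5, {"E1"}, None),
                (D2, AV2, 4.0, {"E1", "E3"}, None),
            ],
        )
        cl = cluster_entities(kb, merge_overlap=1.0)
        assert cl.assignments["E1"] == cl.assignments["E2"]
        assert cl.assignments["E3"] != cl.assignments["E1"]

    def test_zero_count_unassigned(self):
        kb = kb_from_rows(
            ["E1", "E2", "E3"], [(D1, AV1, 3.0, {"E1", "E2"}, None)]
        )
        cl = cluster_entities(kb)
        assert cl.unassigned == ["E3"]
        assert set(cl.assignments) | set(cl.unassigned) == {"E1", "E2", "E3"}

    def test_identical_coverage_merges(self):
        kb = kb_from_rows(
            ["E1", "E2"],
            [
                (D1, AV1, 3.0, {"E1", "E2"}, None),
                (D2, AV2, 2.0, {"E1", "E2"}, None),
            ],
        )
        cl = cluster_entities(kb, merge_overlap=0.5)
        assert cl.n_clusters() == 1

    def test_full_overlap_needed_at_one(self):
        kb = kb_from_rows(
            ["E1", "E2", "E3"],
            [
                (D1, AV1, 3.0, {"E1", "E2"}, None),
                (D2, AV2, 2.0, {"E1", "E2", "E3"}, None),
            ],
        )
        cl = cluster_entities(kb, merge_overlap=1.0)
        assert cl.n_clusters() == 2


class TestAnomalies:
    def test_outliers_are_zero_columns(self):
        kb = kb_from_rows(
            ["E1", "E2", "E3"], [(D1, AV1, 3.0, {"E2"}, None)]
        )
        assert detect_outliers(kb) == ["E1", "E3"]

    def test_no_outliers_when_all_covered(self):
        kb = kb_from_rows(
            ["E1", "E2"], [(D1, AV1, 3.0, {"E1", "E2"}, None)]
        )
        assert detect_outliers(kb) == []

    def test_foreign_only_patterns_flagged(self):
        labels = {"E1": "Benign", "E2": "Malignant"}
        kb = kb_from_rows(
            ["E1", "E2"],
            [(D1, AV1, 3.0, {"E1", "E2"}, "Malignant")],
            labels=labels,
        )
        entries = detect_mislabeled(kb)
        assert [m.entity for m in entries] == ["E1"]
        assert entries[0].inferred_class == "Malignant"
        assert entries[0].supporting

    def test_own_class_match_not_flagged(self):
        labels = {"E1": "Benign"}
        kb = kb_from_rows(
            ["E1"],
            [
                (D1, AV1, 3.0, {"E1"}, "Benign"),
                (D2, AV2, 5.0, {"E1"}, "Malignant"),
            ],
            labels=labels,
        )
        assert detect_mislabeled(kb) == []

    def test_outlier_never_mislabeled(self):
        labels = {"E1": "Benign", "E2": "Benign"}
        kb = kb_from_rows(
            ["E1", "E2"], [(D1, AV1, 3.0, {"E1"}, "Malignant")], labels=labels
        )
        rep = detect_anomalies(kb)
        assert rep.outliers == ["E2"]
        assert [m.entity for m in rep.mislabeled] == ["E1"]

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            AnomalyReport(
                outliers=["E1"],
                mislabeled=[
                    MislabelEntry("E1", "A", "B", (object(),))
                ],
            )


@pytest.fixture(scope="module")
def model():
    table, _ = generate(preset("two_class_mislabel", seed=1))
    return fit_classifier(table, RunConfig())


class TestClassifier:

    def test_refit_deterministic(self):
        table, _ = generate(preset("two_class_mislabel", seed=1))
        m1 = fit_classifier(table, RunConfig())
        m2 = fit_classifier(table, RunConfig())
        assert m1.kb == m2.kb and m1.priors == m2.priors

    def test_single_class_error(self, toy_table):
        t = toy_table
        t.labels = pd.Series(["P"] * 6, index=t.entity_ids, dtype=object)
        with pytest.raises(ValueError, match="2 classes"):
            fit_classifier(t, RunConfig(min_class_size=2))

    def test_block_row_classified_correctly(self, model):
        row = {f"A{j}": "u" for j in range(1, 9)}
        pred = classify(model, row)
        assert pred.label == "ClassA" and not pred.abstained

    def test_unmatched_row_abstains_to_majority(self, model):
        row = {f"A{j}": "zz" for j in range(1, 9)}  # unseen values
        pred = classify(model, row)
        assert pred.abstained and pred.label == model.majority_class

    def test_priors_sum_to_one(self, model):
        assert sum(model.priors.values()) == pytest.approx(1.0)


class TestEvaluateClustering:
    @staticmethod
    def clustering(assignments, n_clusters):
        return EntityClustering(
            assignments=assignments,
            cluster_dsus={i: [DSUCode(i, 1, 1)] for i in range(1, n_clusters + 1)},
            unassigned=[],
        )

    def test_perfect(self):
        truth = {"E1": "X", "E2": "X", "E3": "Y", "E4": "Y"}
        cl = self.clustering({"E1": 1, "E2": 1, "E3": 2, "E4": 2}, 2)
        m = evaluate_clustering(cl, truth)
        assert m.accuracy == 1.0 and m.f_measure == 1.0

    def test_printed_confusion_toy(self):
        # clusters (3 X, 1 Y) and (1 X, 3 Y) -> optimal mapping accuracy 0.75
        truth = {f"E{i}": ("X" if i <= 4 else "Y") for i in range(1, 9)}
        assignments = {
            "E1": 1, "E2": 1, "E3": 1, "E5": 1,
            "E4": 2, "E6": 2, "E7": 2, "E8": 2,
        }
        m = evaluate_clustering(self.clustering(assignments, 2), truth)
        assert m.accuracy == pytest.approx(0.75)

    def test_unassigned_count_as_errors(self):
        truth = {"E1": "X", "E2": "X", "E3": "Y", "E4": "Y"}
        cl = EntityClustering(
            assignments={"E1": 1, "E2": 1, "E3": 2},
            cluster_dsus={1: [D1], 2: [D2]},
            unassigned=["E4"],
        )
        m = evaluate_clustering(cl, truth)
        assert m.accuracy == pytest.approx(0.75)

    @given(perm_seed=st.integers(0, 100))
    @settings(derandomize=True, max_examples=20)
    def test_relabel_invariance(self, perm_seed):
        rng = np.random.default_rng(perm_seed)
        truth = {f"E{i}": f"C{rng.integers(3)}" for i in range(1, 21)}
        base = {f"E{i}": int(rng.integers(1, 4)) for i in range(1, 21)}
        m1 = evaluate_clustering(self.clustering(base, 3), truth)
        relabel = dict(zip([1, 2, 3], rng.permutation([1, 2, 3])))
        permuted = {e: int(relabel[c]) for e, c in base.items()}
        m2 = evaluate_clustering(self.clustering(permuted, 3), truth)
        assert m1.accuracy == pytest.approx(m2.accuracy)
        assert m1.f_measure == pytest.approx(m2.f_measure)

    def test_empty_clustering_zero_metrics(self):
        cl = EntityClustering(assignments={}, cluster_dsus={}, unassigned=["E1"])
        m = evaluate_clustering(cl, {"E1": "X"})
        assert m.accuracy == 0.0 and m.f_measure == 0.0


@pytest.fixture(scope="module")
def small_table():
    import dataclasses

    spec = preset("two_class_mislabel", seed=3)
    spec = dataclasses.replace(
        spec,
        classes=[dataclasses.replace(c, size=40) for c in spec.classes],
        mislabel_rate=0.0,
    )
    return generate(spec)[0]


class TestSplitExperiment:

    def test_fixed_seed_reproducible(self, small_table):
        cfg = RunConfig(seed=9, repeats=3)
        r1 = run_split_experiment(small_table, cfg)
        r2 = run_split_experiment(small_table, cfg)
        assert [x.accuracy for x in r1.records] == [x.accuracy for x in r2.records]

    def test_no_anomalies_removal_is_noop(self, small_table):
        cfg = RunConfig(seed=9, repeats=3)
        base = run_split_experiment(small_table, cfg, remove_anomalies=False)
        clean = run_split_experiment(small_table, cfg, remove_anomalies=True)
        for b, c in zip(base.records, clean.records):
            if c.n_removed == 0:
                assert b.accuracy == pytest.approx(c.accuracy)

    def test_records_shape(self, small_table):
        cfg = RunConfig(seed=1, repeats=2)
        res = run_split_experiment(small_table, cfg)
        assert len(res.records) == 2
        for r in res.records:
            assert 0.0 <= r.accuracy <= 1.0
            assert r.n_train + r.n_test == small_table.n_entities
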