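import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdd.ava_statistics import (
    DegenerateMarginalError,
    adjusted_residual,
    build_av_catalog,
    build_sr_matrix,
    compound_residual,
    compound_residual_from_counts,
    eid_intersection,
)

from .conftest import make_table, random_table


def bruteforce_pair_residual(table, attr_a, val_a, attr_b, val_b):
    """Independent 2x2 contingency oracle: scan raw rows, no catalog reuse."""
    N = table.n_entities
    o = na = nb = 0
    for e in table.entity_ids:
        a = table.values.at[e, attr_a] == val_a
        b = table.values.at[e, attr_b] == val_b
        na += a
        nb += b
        o += a and b
    e_ = na * nb / N
    return ((o - e_) / math.sqrt(e_)) / math.sqrt((1 - na / N) * (1 - nb / N))


class TestCatalog:
    def test_direct_counts(self):
        t = make_table({"A": ["x", "x", "y", "y"], "B": ["p", "q", "p", "q"]})
        cat = build_av_catalog(t)
        av = cat.lookup("A", "x")
        assert av.n == 2 and av.eids == frozenset({"E1", "E2"})

    def test_single_entity_rejected_by_sr_but_counts_ok(self):
        t = make_table({"A": ["x", "y"], "B": ["p", "q"]})
        cat = build_av_catalog(t)
        assert all(av.n == 1 for av in cat)

    def test_marginals_match_column_scan(self, toy_table):
        cat = build_av_catalog(toy_table)
        for av in cat:
            col = toy_table.values[av.attribute]
            assert av.n == sum(col.at[e] == av.value for e in toy_table.entity_ids)

    def test_constant_attribute_dropped_with_warning(self):
        t = make_table({"A": ["x", "x", "x"], "B": ["p", "q", "p"]})
        with pytest.warns(UserWarning, match="constant"):
            cat = build_av_catalog(t)
        assert all(av.attribute != "A" for av in cat)

    def test_same_attribute_disjoint_eids(self, toy_table):
        cat = build_av_catalog(toy_table)
        for a in toy_table.attribute_names:
            avs = cat.by_attribute(a)
            for i in range(len(avs)):
                for j in range(i + 1, len(avs)):
                    assert not (avs[i].eids & avs[j].eids)


class TestEIDIntersection:
    def test_single_av_is_own_eids(self, toy_table):
        cat = build_av_catalog(toy_table)
        av = cat.lookup("A", "x")
        assert eid_intersection([av]) == av.eids

    def test_same_attribute_error(self, toy_table):
        cat = build_av_catalog(toy_table)
        with pytest.raises(ValueError, match="share an attribute"):
            eid_intersection([cat.lookup("A", "x"), cat.lookup("A", "y")])

    def test_matches_row_scan(self, toy_table):
        cat = build_av_catalog(toy_table)
        avs = [cat.lookup("A", "x"), cat.lookup("B", "p"), cat.lookup("C", "m")]
        scan = {
            e
            for e in toy_table.entity_ids
            if toy_table.values.at[e, "A"] == "x"
            and toy_table.values.at[e, "B"] == "p"
            and toy_table.values.at[e, "C"] == "m"
        }
        assert eid_intersection(avs) == frozenset(scan)

    def test_disjoint_sets_empty(self, toy_table):
        cat = build_av_catalog(toy_table)
        # A=x is E1-E3, C=n is E4,E5 -> empty
        assert eid_intersection([cat.lookup("A", "x"), cat.lookup("C", "n")]) == frozenset()


class TestResiduals:
    def test_zero_when_observed_equals_expected(self):
        assert adjusted_residual(10, 20, 25, 50) == pytest.approx(0.0)

    def test_pair_example(self):
        assert adjusted_residual(20, 20, 25, 50) == pytest.approx(5.7735, abs=1e-4)

    def test_compound_example(self):
        d = compound_residual_from_counts(10, (50, 40, 20), 100)
        assert d == pytest.approx(6.1237, abs=1e-4)

    def test_degenerate_marginal_error(self):
        with pytest.raises(DegenerateMarginalError):
            adjusted_residual(5, 10, 10, 10)

    def test_pair_consistency_of_two_forms(self, toy_table):
        cat = build_av_catalog(toy_table)
        a, b = cat.lookup("A", "x"), cat.lookup("B", "p")
        o = len(a.eids & b.eids)
        assert compound_residual([a, b], cat) == pytest.approx(
            adjusted_residual(o, a.n, b.n, cat.N), abs=1e-12
        )

    @given(o=st.integers(0, 20))
    @settings(derandomize=True, max_examples=30)
    def test_monotone_in_observed(self, o):
        # with marginals fixed, d strictly increases in o
        d1 = adjusted_residual(o, 20, 30, 60)
        d2 = adjusted_residual(o + 1, 20, 30, 60) if o < 20 else None
        if d2 is not None:
            assert d2 > d1


class TestSRMatrix:
    def test_concordant_values(self, concordant_table):
        cat = build_av_catalog(concordant_table)
        sr = build_sr_matrix(cat)
        a1, b1, b2 = cat.lookup("A", "a1"), cat.lookup("B", "b1"), cat.lookup("B", "b2")
        assert sr.entry(a1, b1) == pytest.approx(10.0, abs=1e-9)
        assert sr.entry(a1, b2) == pytest.approx(-10.0, abs=1e-9)

    def test_symmetric_zero_diag_and_blocks(self, toy_table):
        cat = build_av_catalog(toy_table)
        sr = build_sr_matrix(cat)
        assert np.allclose(sr.values, sr.values.T)
        assert np.all(sr.values[~sr.cross_attribute_mask] == 0)

    def test_matches_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            t = random_table(rng, int(rng.integers(10, 50)), int(rng.integers(2, 5)))
            try:
                cat = build_av_catalog(t)
            except ValueError:
                continue
            sr = build_sr_matrix(cat)
            for a in cat:
                for b in cat:
                    if a.attr_index == b.attr_index:
                        continue
                    want = bruteforce_pair_residual(
                        t, a.attribute, a.value, b.attribute, b.value
                    )
                    assert sr.values[a.index, b.index] == pytest.approx(
                        want, abs=1e-9
                    )

    def test_entity_permutation_invariance(self, toy_table):
        cat = build_av_catalog(toy_table)
        sr = build_sr_matrix(cat)
        perm = [3, 0, 5, 1, 4, 2]
        ids = [toy_table.entity_ids[i] for i in perm]
        shuffled = toy_table.subset(ids)
        shuffled = make_table(
            {
                a: [shuffled.values.at[e, a] for e in shuffled.entity_ids]
                for a in shuffled.attribute_names
            }
        )
        sr2 = build_sr_matrix(build_av_catalog(shuffled))
        assert np.allclose(sr.values, sr2.values)
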