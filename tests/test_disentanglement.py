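import numpy as np
import pytest

from pdd.ava_statistics import build_av_catalog, build_sr_matrix
from pdd.disentanglement import (
    DSUCode,
    decompose,
    enumerate_units,
    form_pattern_groups,
    form_subpgs,
    select_spaces,
)

from .conftest import make_table


@pytest.fixture
def concordant_sr(concordant_table):
    return build_sr_matrix(build_av_catalog(concordant_table))


class TestDecompose:
    def test_rsrv_sum_reconstructs_sr(self, concordant_sr):
        spaces = decompose(concordant_sr)
        total = sum(s.rsrv for s in spaces)
        assert np.allclose(total, concordant_sr.values, atol=1e-8)

    def test_leading_pc_separates_concordant_pairs(self, concordant_sr):
        spaces = decompose(concordant_sr)
        cat = concordant_sr.catalog
        v = spaces[0].vector
        s = {av.value: np.sign(v[av.index]) for av in cat}
        assert s["a1"] == s["b1"] and s["a2"] == s["b2"] and s["a1"] != s["a2"]

    def test_order_by_abs_eigenvalue(self, concordant_sr):
        spaces = decompose(concordant_sr)
        mags = [abs(s.eigenvalue) for s in spaces]
        tol = 1e-6 * max(mags + [1.0])
        assert all(mags[i] >= mags[i + 1] - tol for i in range(len(mags) - 1))

    def test_sign_convention_largest_loading_positive(self, concordant_sr):
        for s in decompose(concordant_sr):
            j = int(np.argmax(np.abs(s.vector)))
            assert s.vector[j] >= 0

    def test_unit_vectors(self, concordant_sr):
        for s in decompose(concordant_sr):
            assert np.linalg.norm(s.vector) == pytest.approx(1.0)

    def test_nonsymmetric_error(self, concordant_sr):
        bad = concordant_sr
        bad.values[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            decompose(bad)

    def test_decompose_of_reconstruction_reproduces_eigenvalues(
        self, concordant_sr
    ):
        import copy

        spaces = decompose(concordant_sr)
        rebuilt = copy.deepcopy(concordant_sr)
        rebuilt.values = sum(s.rsrv for s in spaces)
        rebuilt.values = (rebuilt.values + rebuilt.values.T) / 2
        spaces2 = decompose(rebuilt)
        for a, b in zip(spaces, spaces2):
            assert a.eigenvalue == pytest.approx(b.eigenvalue, abs=1e-8)


class TestSelect:
    def test_below_threshold_dropped(self):
        # weak concordance: max |SR| entry < 1.96 -> nothing retained
        t = make_table(
            {
                "A": ["a1"] * 5 + ["a2"] * 5,
                "B": ["b1"] * 3 + ["b2"] * 2 + ["b1"] * 2 + ["b2"] * 3,
            }
        )
        sr = build_sr_matrix(build_av_catalog(t))
        assert np.abs(sr.values).max() < 1.96
        assert select_spaces(decompose(sr)) == []

    def test_strong_pair_retained_with_both_avs(self, pair_table):
        sr = build_sr_matrix(build_av_catalog(pair_table))
        retained = select_spaces(decompose(sr))
        assert retained
        lead = retained[0]
        sig = {str(av) for av in lead.significant}
        assert {"A=a1", "B=b1"} <= sig or {"A=a2", "B=b2"} <= sig

    def test_non_contiguous_retention_representable(self, concordant_sr):
        spaces = decompose(concordant_sr)
        retained = select_spaces(spaces)
        # ordinals are those of the full decomposition, not renumbered
        assert all(s.ordinal == spaces[s.ordinal - 1].ordinal for s in retained)


class TestPatternGroups:
    def test_sign_partition(self, concordant_sr):
        retained = select_spaces(decompose(concordant_sr))
        pg1, pg2 = form_pattern_groups(retained[0])
        vals1 = {av.value for av in pg1.members}
        vals2 = {av.value for av in pg2.members}
        assert vals1 in ({"a1", "b1"}, {"a2", "b2"})
        assert vals1 | vals2 == {"a1", "a2", "b1", "b2"} and not (vals1 & vals2)

    def test_all_positive_gives_empty_pg2(self, pair_table):
        retained = select_spaces(decompose(build_sr_matrix(build_av_catalog(pair_table))))
        space = retained[0]
        pg1, pg2 = form_pattern_groups(space)
        assert len(pg1.members) + len(pg2.members) == len(space.significant)

    def test_subpgs_partition_pg(self, concordant_sr):
        retained = select_spaces(decompose(concordant_sr))
        for space in retained:
            for pg in form_pattern_groups(space):
                subpgs = form_subpgs(pg)
                flat = [av for s in subpgs for av in s]
                assert sorted(av.index for av in flat) == sorted(
                    av.index for av in pg.members
                )

    def test_unconnected_members_are_singletons(self, concordant_sr):
        retained = select_spaces(decompose(concordant_sr))
        space = retained[0]
        pg1, _ = form_pattern_groups(space)
        subpgs = form_subpgs(pg1, space, threshold=1e9)  # no edges possible
        assert all(len(s) == 1 for s in subpgs)


class TestUnits:
    def test_dsu_codes_unique_and_nonempty(self, concordant_sr):
        retained = select_spaces(decompose(concordant_sr))
        units = enumerate_units(retained)
        codes = [u.code for u in units]
        assert len(codes) == len(set(codes))
        assert all(u.avs for u in units)

    def test_dsu_rendering(self):
        assert DSUCode(2, 1, 2).render() == "[2 1 2]"
        assert DSUCode.parse("[2 1 2]") == DSUCode(2, 1, 2)


class TestPlantedSources:
    def test_orthogonal_blocks_recovered_exactly_at_full_fidelity(self):
        from pdd.synthetic_data import AttributeSpec, ClassSpec, SyntheticSpec, generate

        # every attribute is blocked, so at fidelity 1.0 there is no random
        # background and each SubPG must equal a planted block exactly
        attrs = [AttributeSpec(f"A{j}", ("p", "q", "r", "s")) for j in range(1, 7)]
        classes = [
            ClassSpec("C1", 30, {f"A{j}": "p" for j in range(1, 7)}),
            ClassSpec("C2", 30, {f"A{j}": "q" for j in range(1, 7)}),
        ]
        spec = SyntheticSpec(attributes=attrs, classes=classes, fidelity=1.0, seed=5)
        table, truth = generate(spec)
        cat = build_av_catalog(table)
        retained = select_spaces(decompose(build_sr_matrix(cat)))
        units = enumerate_units(retained)
        discovered = [frozenset(str(av) for av in u.avs) for u in units]
        assert frozenset(f"A{j}=p" for j in range(1, 7)) in discovered
        assert frozenset(f"A{j}=q" for j in range(1, 7)) in discovered
        assert len(discovered) == 2
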