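import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_space
from vbstruct.ranking import (
    CriteriaConfig,
    bond_stretch_measure,
    merge_scores,
    rank_by_bond_length,
    rank_structures,
    score_intra_atomic,
    score_symmetry,
    score_user_bonds,
    score_user_radicals,
)
from vbstruct.vb_space import VBStructure, enumerate_structures


def covalent(pairs, unpaired=(), vacant=()):
    return VBStructure(frozenset(), frozenset(vacant), frozenset(pairs), tuple(unpaired))


class FakeGeometry:
    """Minimal geometry stub: explicit distances, uniform covalent radius sum."""

    def __init__(self, distances, cov=1.0):
        self._d = {frozenset(k): v for k, v in distances.items()}
        self._cov = cov

    def distance(self, a, b):
        return self._d[frozenset((a, b))]

    def covalent_sum(self, a, b):
        return self._cov


class TestCriteriaConfig:
    def test_requires_priorities(self):
        with pytest.raises(ValueError):
            CriteriaConfig(())

    def test_rejects_duplicates(self):
        with pytest.raises(ValueError):
            CriteriaConfig(("symmetry", "symmetry"))

    def test_rejects_unknown(self):
        with pytest.raises(ValueError):
            CriteriaConfig(("charge",))

    def test_user_bonds_criterion_needs_bonds(self):
        with pytest.raises(ValueError):
            CriteriaConfig(("user_bonds",))

    def test_user_radicals_criterion_needs_radicals(self):
        with pytest.raises(ValueError):
            CriteriaConfig(("user_radicals",))


class TestUserBonds:
    def test_all_bonds_user_defined(self):
        s = covalent({(1, 2), (5, 6)}, vacant=(3, 4))
        assert score_user_bonds(s, {(1, 2), (5, 6)}) == 1

    def test_no_user_bond_present(self):
        s = covalent({(1, 6), (4, 5)}, vacant=(2, 3))
        assert score_user_bonds(s, {(1, 2), (5, 6)}) == 3

    def test_one_of_two(self):
        s = covalent({(1, 2), (4, 5)}, vacant=(3, 6))
        assert score_user_bonds(s, {(1, 2)}) == 2

    def test_empty_udb_error(self):
        with pytest.raises(ValueError):
            score_user_bonds(covalent({(1, 2)}), set())

    def test_orientation_ignored(self):
        s = covalent({(1, 2)})
        assert score_user_bonds(s, {(2, 1)}) == 1


class TestUserRadicals:
    def test_matching_radical(self):
        s = covalent({(1, 2), (5, 6)}, unpaired=(4,), vacant=(3,))
        assert score_user_radicals(s, {4}) == 1

    def test_non_matching_radical(self):
        s = covalent({(1, 2)}, unpaired=(3,), vacant=(4, 5, 6))
        assert score_user_radicals(s, {4, 6}) == 2

    def test_singlet_no_radicals_scores_one(self):
        s = covalent({(1, 2), (3, 4)})
        assert score_user_radicals(s, {1}) == 1


class TestIntraAtomic:
    ATOMS = {1: "A", 2: "B", 3: "C", 4: "D", 5: "D", 6: "E"}

    def test_none(self):
        assert score_intra_atomic(covalent({(1, 2), (3, 6)}, vacant=(4, 5)), self.ATOMS) == 1

    def test_one(self):
        assert score_intra_atomic(covalent({(4, 5), (1, 2)}, vacant=(3, 6)), self.ATOMS) == 2

    def test_two(self):
        atoms = {1: "A", 2: "A", 3: "B", 4: "B"}
        assert score_intra_atomic(covalent({(1, 2), (3, 4)}), atoms) == 3


class TestSymmetry:
    LABELS = {1: "sigma", 2: "pi", 3: "pi", 4: None, 5: None}

    def test_same_symmetry_bond(self):
        assert score_symmetry(covalent({(2, 3)}, vacant=(1, 4, 5)), self.LABELS) == 1

    def test_cross_symmetry_bond(self):
        assert score_symmetry(covalent({(1, 3)}, vacant=(2, 4, 5)), self.LABELS) == 2

    def test_no_bonds(self):
        assert score_symmetry(covalent(set(), unpaired=(1, 2), vacant=(3, 4, 5)), self.LABELS) == 1

    def test_wildcard_unlabeled_same(self):
        assert score_symmetry(covalent({(4, 5)}, vacant=(1, 2, 3)), self.LABELS) == 1

    def test_wildcard_vs_labeled_different(self):
        assert score_symmetry(covalent({(1, 4)}, vacant=(2, 3, 5)), self.LABELS) == 2


class TestBondLength:
    def test_shorter_bond_ranked_first(self):
        # linear A-B...C: bonding A-B beats bonding A-C
        space = make_space(3, 2, 0)
        geometry = FakeGeometry({("A1", "A2"): 1.0, ("A1", "A3"): 3.0, ("A2", "A3"): 2.0})
        short = covalent({(1, 2)}, vacant=(3,))
        long = covalent({(1, 3)}, vacant=(2,))
        ranks = rank_by_bond_length([long, short], geometry, space.atom_map)
        assert ranks[short] == 1 and ranks[long] == 2

    def test_ties_share_dense_rank(self):
        space = make_space(4, 4, 0)
        geometry = FakeGeometry(
            {(f"A{i}", f"A{j}"): 1.0 for i in range(1, 5) for j in range(i + 1, 5)}
        )
        structures = enumerate_structures(space, n_double=0)
        ranks = rank_by_bond_length(structures, geometry, space.atom_map)
        assert set(ranks.values()) == {1}

    def test_neighboring_bonds_contribute_zero(self):
        space = make_space(2, 2, 0)
        geometry = FakeGeometry({("A1", "A2"): 0.9}, cov=1.0)
        s = covalent({(1, 2)})
        assert bond_stretch_measure(s, geometry, space.atom_map) == 0.0

    def test_intra_atomic_contributes_zero(self):
        atom_map = {1: "A", 2: "A"}
        geometry = FakeGeometry({})
        assert bond_stretch_measure(covalent({(1, 2)}), geometry, atom_map) == 0.0

    def test_missing_atom_named(self):
        space = make_space(2, 2, 0)
        geometry = FakeGeometry({})
        with pytest.raises(KeyError):
            rank_by_bond_length([covalent({(1, 2)})], geometry, space.atom_map)


class TestMerge:
    def test_single_criterion_identity(self):
        assert merge_scores([[3, 1, 2]]) == [3, 1, 2]

    def test_worked_example(self):
        assert merge_scores([[1, 2], [2, 1]]) == [2, 3]

    def test_tie_broken_by_next_criterion(self):
        assert merge_scores([[1, 1], [3, 1]]) == [3, 1]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            merge_scores([[1, 2], [1]])

    def test_scores_below_one_rejected(self):
        with pytest.raises(ValueError):
            merge_scores([[0, 1]])

    @settings(max_examples=150, deadline=None)
    @given(
        st.integers(1, 6).flatmap(
            lambda k: st.lists(
                st.lists(st.integers(1, 9), min_size=k, max_size=k),
                min_size=1,
                max_size=5,
            )
        )
    )
    def test_merge_is_lexicographic(self, table):
        """Merged order == lexicographic order of the per-criterion tuples."""
        unified = merge_scores(table)
        n = len(table[0])
        tuples = [tuple(vec[i] for vec in table) for i in range(n)]
        for i in range(n):
            for j in range(n):
                if tuples[i] < tuples[j]:
                    assert unified[i] < unified[j]
                elif tuples[i] == tuples[j]:
                    assert unified[i] == unified[j]

    def test_unified_always_at_least_one(self):
        assert min(merge_scores([[1, 4], [2, 2], [3, 1]])) >= 1


class TestRankStructures:
    def test_permutation_equivariance(self):
        """Relabeling orbitals consistently leaves every score unchanged."""
        space = make_space(4, 4, 1)
        structures = enumerate_structures(space, n_double=0)
        config = CriteriaConfig(
            ("user_bonds", "user_radicals", "intra_atomic"),
            user_bonds={(1, 2)},
            user_radicals={3},
        )
        ranked = rank_structures(space, structures, config)
        relabel = {1: 3, 2: 4, 3: 1, 4: 2}
        space2 = make_space(4, 4, 1)  # atoms A1..A4 follow indices, so remap configs
        config2 = CriteriaConfig(
            ("user_bonds", "user_radicals", "intra_atomic"),
            user_bonds={(relabel[1], relabel[2])},
            user_radicals={relabel[3]},
        )
        by_structure = {r.structure: r for r in ranked}
        ranked2 = rank_structures(space2, enumerate_structures(space2, n_double=0), config2)
        for r2 in ranked2:
            back = VBStructure(
                frozenset(),
                frozenset(),
                frozenset(
                    tuple(sorted((inv[a], inv[b]))) for a, b in r2.structure.pairs
                ),
                tuple(sorted(inv[i] for i in r2.structure.unpaired)),
            ) if (inv := {v: k for k, v in relabel.items()}) else None
            assert by_structure[back].scores == r2.scores

    def test_bond_length_requires_geometry(self):
        space = make_space(4, 4, 0)
        config = CriteriaConfig(("bond_length",))
        with pytest.raises(ValueError):
            rank_structures(space, enumerate_structures(space, n_double=0), config)

    def test_scores_integral_and_positive(self):
        space = make_space(4, 4, 0)
        config = CriteriaConfig(("intra_atomic", "symmetry"))
        for r in rank_structures(space, enumerate_structures(space, n_double=0), config):
            assert r.unified >= 1
            assert all(isinstance(v, int) and v >= 1 for v in r.scores.values())

    def test_d_nab_recorded(self, c5h5):
        space, geometry, _ = c5h5
        config = CriteriaConfig(("bond_length",))
        ranked = rank_structures(
            space, enumerate_structures(space, n_double=0), config, geometry
        )
        assert all(r.d_nab is not None and r.d_nab >= 0 for r in ranked)
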