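"""Descriptors, fingerprints, Tanimoto similarity and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scaffold_screen.descriptors import (Fingerprint, compute_descriptors,
                                         fingerprint, hierarchical_cluster,
                                         similarity_matrix,
                                         similarity_to_reference, tanimoto,
                                         SimilarityMatrix)


def _fp(bits, length=16):
    values = np.zeros(length, dtype=np.uint8)
    values[list(bits)] = 1
    return Fingerprint("path", values)


class TestDescriptors:
    def test_methane_molecular_weight(self, record_factory):
        d = compute_descriptors(record_factory("C"))
        assert d.mw == pytest.approx(16.04, abs=0.01)  # 12.011 + 4*1.008

    def test_ethane_has_no_polar_features(self, record_factory):
        d = compute_descriptors(record_factory("CC"))
        assert (d.hba, d.hbd, d.psa) == (0, 0, 0.0)

    def test_invariants_on_real_structures(self, hit_library):
        for rec in hit_library.records:
            d = compute_descriptors(rec)
            assert d.mw > 0
            assert d.hba >= 0 and d.hbd >= 0
            assert d.psa >= 0
            assert 0 <= d.qed <= 1

    def test_invariant_to_atom_ordering(self, record_factory):
        a = compute_descriptors(record_factory("CC(=O)NCCCS(=O)(=O)O"))
        b = compute_descriptors(record_factory("OS(=O)(=O)CCCNC(C)=O"))
        assert (a.hba, a.hbd) == (b.hba, b.hbd)
        for field in ("mw", "alogp", "psa", "qed"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-9)

    def test_menadione_bisulfite_descriptors_are_in_range(self, record_factory):
        # published panel: MW 253.25, AlogP 0.98, PSA 88.18, QED 0.76;
        # exactness is not contracted across descriptor software lineages,
        # so only generous windows are asserted here
        rec = record_factory("CC1(S(=O)(=O)[O-])CC(=O)c2ccccc2C1=O")
        d = compute_descriptors(rec)
        assert d.mw == pytest.approx(253.25, abs=1.0)
        assert d.psa == pytest.approx(88.18, abs=25.0)
        assert 0 < d.qed < 1


class TestTanimoto:
    def test_identical_nonzero_is_one(self):
        a = _fp({1, 5, 9})
        assert tanimoto(a, a) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(_fp({0, 1}), _fp({2, 3})) == 0.0

    def test_one_shared_of_three(self):
        assert tanimoto(_fp({1, 2}), _fp({1, 3})) == pytest.approx(1 / 3)

    def test_scheme_mismatch_raises(self, record_factory):
        rec = record_factory("CCO")
        with pytest.raises(ValueError, match="scheme"):
            tanimoto(fingerprint(rec, "estate"), fingerprint(rec, "path"))

    def test_all_zero_pair_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert tanimoto(_fp(set()), _fp(set())) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(a=st.sets(st.integers(0, 15)), b=st.sets(st.integers(0, 15)))
    def test_symmetry_and_bounds(self, a, b):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = tanimoto(_fp(a), _fp(b))
            tba = tanimoto(_fp(b), _fp(a))
        assert tab == tba
        assert 0.0 <= tab <= 1.0
        if a:
            assert tanimoto(_fp(a), _fp(a)) == 1.0


class TestSimilarityMatrix:
    def test_matches_pairwise_reference_calls(self, hit_library):
        records = hit_library.records[:5]
        matrix = similarity_matrix(records)
        for i, rec in enumerate(records):
            pairs = dict(similarity_to_reference(records, rec))
            for j, other in enumerate(records):
                assert matrix.values[i, j] == pytest.approx(pairs[other.id])

    def test_unit_diagonal_and_symmetry(self, hit_library):
        matrix = similarity_matrix(hit_library.records)
        assert np.allclose(np.diag(matrix.values), 1.0)
        assert np.allclose(matrix.values, matrix.values.T)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityMatrix(ids=["a", "b"], values=bad)

    def test_reference_similarity_in_unit_interval(self, hit_library, record_factory):
        scaffold = record_factory("CCCS(=O)(=O)O", "scaffold")
        sims = similarity_to_reference(hit_library.records, scaffold)
        assert all(0.0 <= t <= 1.0 for _, t in sims)
        self_sim = similarity_to_reference([scaffold], scaffold)
        assert self_sim == [("scaffold", 1.0)]


class TestHierarchicalCluster:
    def _matrix(self, values, ids=None):
        values = np.asarray(values, dtype=float)
        return SimilarityMatrix(ids=ids or [f"m{i}" for i in range(len(values))],
                                values=values)

    def test_two_singletons(self):
        tree = hierarchical_cluster(self._matrix([[1.0, 0.3], [0.3, 1.0]]))
        assert sorted(tree.cut(2).values()) == [1, 2]

    def test_forced_merge_of_similar_pair(self):
        matrix = self._matrix([[1.0, 0.9, 0.1],
                               [0.9, 1.0, 0.1],
                               [0.1, 0.1, 1.0]])
        groups = hierarchical_cluster(matrix).cut(2)
        assert groups["m0"] == groups["m1"] != groups["m2"]

    def test_cut_extremes(self, hit_library):
        tree = hierarchical_cluster(similarity_matrix(hit_library.records))
        n = len(hit_library.records)
        assert set(tree.cut(1).values()) == {1}
        assert sorted(tree.cut(n).values()) == list(range(1, n + 1))

    def test_k_out_of_range(self):
        tree = hierarchical_cluster(self._matrix([[1.0, 0.5], [0.5, 1.0]]))
        with pytest.raises(ValueError):
            tree.cut(3)

    def test_leads_co_cluster_at_k4(self, hit_library):
        # the two lead candidates (menadione bisulfite, camphotamide) land
        # in the same of the four structural groups of the hit set
        tree = hierarchical_cluster(similarity_matrix(hit_library.records))
        groups = tree.cut(4)
        assert groups["4"] == groups["6"]

    def test_newick_contains_all_leaves(self, hit_library):
        records = hit_library.records[:6]
        tree = hierarchical_cluster(similarity_matrix(records))
        newick = tree.to_newick()
        assert newick.endswith(";")
        for rec in records:
            assert rec.id in newick

    def test_deterministic(self, hit_library):
        m1 = similarity_matrix(hit_library.records)
        m2 = similarity_matrix(hit_library.records)
        t1, t2 = hierarchical_cluster(m1), hierarchical_cluster(m2)
        assert np.array_equal(t1.linkage_matrix, t2.linkage_matrix)
        assert t1.cut(4) == t2.cut(4)
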