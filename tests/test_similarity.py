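import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import birwnet as bw
from birwnet.similarity import SimilarityMatrix


def spearman_rank_formula(x, y):
    """Oracle: 1 - 6*sum(d^2)/(n(n^2-1)) for untied vectors."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    return 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))


class TestGipKernel:
    def test_unit_diagonal_and_hand_value(self, diag2_assoc):
        kl = bw.gip_kernel(diag2_assoc, "lncrna", 1.0)
        # identity adjacency: mean squared column norm 1, so gamma = 1 and
        # the off-diagonal distance^2 is 2
        np.testing.assert_allclose(np.diag(kl.values), 1.0)
        assert kl.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)
        kd = bw.gip_kernel(diag2_assoc, "disease", 1.0)
        assert kd.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_all_zero_matrix_rejected(self):
        assoc = bw.AssociationMatrix(np.zeros((2, 2)), ("D1", "D2"), ("L1", "L2"))
        with pytest.raises(ValueError, match="bandwidth"):
            bw.gip_kernel(assoc, "lncrna")

    def test_invariant_to_permuting_non_axis_dimension(self):
        rng = np.random.default_rng(3)
        values = (rng.random((5, 4)) < 0.5).astype(float)
        values[0, 0] = 1.0
        ids_d = tuple(f"D{i}" for i in range(5))
        ids_l = tuple(f"L{j}" for j in range(4))
        assoc = bw.AssociationMatrix(values, ids_d, ids_l)
        perm = rng.permutation(5)
        shuffled = bw.AssociationMatrix(values[perm], tuple(ids_d[i] for i in perm), ids_l)
        kl = bw.gip_kernel(assoc, "lncrna")
        kl_perm = bw.gip_kernel(shuffled, "lncrna")
        np.testing.assert_allclose(kl.values, kl_perm.values, atol=1e-12)

    def test_strictly_decreasing_in_hamming_distance(self):
        # brute force over all binary profile pairs of length <= 4 at fixed gamma
        for n in (2, 3, 4):
            gamma = 0.7
            for x, y, u, v in itertools.product(
                itertools.product((0, 1), repeat=n), repeat=4
            ):
                hx = sum(a != b for a, b in zip(x, y))
                hu = sum(a != b for a, b in zip(u, v))
                kx = np.exp(-gamma * np.sum((np.array(x) - np.array(y)) ** 2))
                ku = np.exp(-gamma * np.sum((np.array(u) - np.array(v)) ** 2))
                if hx > hu:
                    assert kx < ku

    def test_entries_in_unit_interval_and_symmetric(self):
        rng = np.random.default_rng(11)
        values = (rng.random((6, 7)) < 0.4).astype(float)
        values[0, 0] = 1.0
        assoc = bw.AssociationMatrix(
            values, tuple(f"D{i}" for i in range(6)), tuple(f"L{j}" for j in range(7))
        )
        for axis in ("lncrna", "disease"):
            k = bw.gip_kernel(assoc, axis)
            assert ((k.values > 0) & (k.values <= 1)).all()
            np.testing.assert_allclose(k.values, k.values.T, atol=1e-12)


class TestSpearmanSimilarity:
    def make(self, profiles, ids, universe):
        expr = bw.ExpressionData(np.array(profiles, float), ids, tuple(f"T{t}" for t in range(len(profiles[0]))))
        return bw.spearman_similarity(expr, universe)

    def test_identical_reversed_and_formula_oracle(self):
        spc = self.make([[1, 2, 3], [1, 2, 3]], ("L1", "L2"), ("L1", "L2"))
        assert spc.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        spc = self.make([[1, 2, 3], [3, 2, 1]], ("L1", "L2"), ("L1", "L2"))
        assert spc.values[0, 1] == pytest.approx(-1.0, abs=1e-12)
        spc = self.make([[1, 2, 3, 4], [2, 1, 4, 3]], ("L1", "L2"), ("L1", "L2"))
        assert spc.values[0, 1] == pytest.approx(0.6, abs=1e-12)

    @given(
        st.lists(
            st.lists(st.floats(-100, 100, allow_nan=False), min_size=4, max_size=4),
            min_size=2,
            max_size=5,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_rank_formula_on_untied_vectors(self, rows):
        arr = np.array(rows)
        # keep only examples where every vector is tie-free
        if any(len(set(r)) != len(r) for r in rows):
            return
        ids = tuple(f"L{i}" for i in range(len(rows)))
        spc = self.make(arr, ids, ids)
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                expected = spearman_rank_formula(arr[i], arr[j])
                assert spc.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_zero_pattern_outside_profiled_set(self):
        spc = self.make([[1, 2, 3]], ("L2",), ("L1", "L2", "L3"))
        assert spc.values[1, 1] == 1.0  # profiled: unit self-similarity
        assert spc.values[0, 0] == 0.0 and spc.values[2, 2] == 0.0
        assert (spc.values[0, :] == 0).all() and (spc.values[:, 2] == 0).all()

    def test_constant_profile_correlates_zero(self):
        spc = self.make([[5, 5, 5], [1, 2, 3]], ("L1", "L2"), ("L1", "L2"))
        assert spc.values[0, 1] == 0.0


class TestCombineLncrnaSimilarity:
    def setup_method(self):
        ids = ("L1", "L2")
        self.spc = SimilarityMatrix(np.array([[1.0, 0.6], [0.6, 1.0]]), ids, "SPC")
        self.kl = SimilarityMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]), ids, "KL")

    def test_weighted_mean_when_both_profiled(self):
        sl = bw.combine_lncrna_similarity(self.spc, self.kl, np.array([True, True]), 0.5)
        assert sl.values[0, 1] == pytest.approx(0.5)

    def test_kernel_branch_when_one_unprofiled(self):
        sl = bw.combine_lncrna_similarity(self.spc, self.kl, np.array([True, False]), 0.5)
        assert sl.values[0, 1] == 0.4

    def test_degenerate_weights_are_exact(self):
        sl0 = bw.combine_lncrna_similarity(self.spc, self.kl, np.array([True, True]), 0.0)
        assert (sl0.values == self.kl.values).all()  # bit-identical
        sl1 = bw.combine_lncrna_similarity(self.spc, self.kl, np.array([True, True]), 1.0)
        assert (sl1.values == self.spc.values).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bw.combine_lncrna_similarity(self.spc, self.kl, np.array([True]), 0.5)


class TestLogisticDiseaseSimilarity:
    def test_hand_values_at_default_parameters(self):
        ids = ("D1", "D2")
        kd = SimilarityMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), ids, "KD")
        sd = bw.logistic_disease_similarity(kd)
        assert sd.values[0, 1] == pytest.approx(1.0 / (1.0 + 9999.0), abs=1e-15)
        assert sd.values[0, 0] == pytest.approx(
            1.0 / (1.0 + 9999.0 * np.exp(-15.0)), abs=1e-12
        )

    def test_strictly_increasing_in_kernel_when_c_negative(self):
        grid = np.linspace(0, 1, 21)
        kd = SimilarityMatrix(
            np.outer(np.ones(21), grid) / 2 + np.outer(grid, np.ones(21)) / 2,
            tuple(f"D{i}" for i in range(21)),
            "KD",
        )
        sd = bw.logistic_disease_similarity(kd)
        # along a row, KD increases with the column grid, so SD must too
        assert (np.diff(sd.values[0]) > 0).all()

    def test_symmetry_preserved_and_role_checked(self):
        rng = np.random.default_rng(5)
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        kd = SimilarityMatrix(m, tuple(f"D{i}" for i in range(4)), "KD")
        sd = bw.logistic_disease_similarity(kd)
        np.testing.assert_allclose(sd.values, sd.values.T, atol=1e-12)
        assert ((sd.values > 0) & (sd.values < 1)).all()
        with pytest.raises(ValueError, match="KD"):
            bw.logistic_disease_similarity(sd)
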