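"""Unit tests for the entropy and WLD similarity features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scmfuse import (
    PatchSpec,
    SimilarityConstants,
    SimilarityMap,
    differential_excitation,
    entropy_similarity,
    patch_entropy_series,
    wld_similarity,
)
from scmfuse.features import binary_entropy

from _oracles import entropy_scalar, excitation_scalar

SPEC = PatchSpec(l_p=1)
CONST = SimilarityConstants.defaults(n_max=20)


class TestPatchEntropy:
    def test_homogeneous_patches_give_exact_zero(self):
        for fill in (0, 1):
            stack = np.full((3, 8, 8), fill, dtype=np.uint8)
            assert not patch_entropy_series(stack, SPEC).any()

    def test_one_third_ones_patch(self):
        # a uniform column pattern puts exactly 3 ones in every 3x3 patch
        frame = np.zeros((6, 6), dtype=np.uint8)
        frame[:, ::3] = 1
        ent = patch_entropy_series(frame[None, :, :], SPEC)
        expected = -(1 / 3) * np.log2(1 / 3) - (2 / 3) * np.log2(2 / 3)
        assert ent[0, 1:-1, 1:-1] == pytest.approx(expected)
        assert expected == pytest.approx(0.9183, abs=1e-4)

    def test_near_balanced_patch_is_lattice_maximum(self):
        h49 = binary_entropy(np.array(4 / 9))
        assert h49 == pytest.approx(0.99108, abs=1e-5)
        counts = np.arange(10) / 9.0
        assert binary_entropy(counts).max() == pytest.approx(h49)
        # symmetry of the attainable maximum: H(4/9) == H(5/9)
        assert binary_entropy(np.array(5 / 9)) == pytest.approx(h49)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_counting(self, seed):
        rng = np.random.default_rng(seed)
        stack = (rng.random((5, 16, 16)) < 0.4).astype(np.uint8)
        fast = patch_entropy_series(stack, SPEC)
        slow = entropy_scalar(stack, l_p=1)
        assert np.allclose(fast, slow, atol=1e-12)

    def test_symmetric_under_bit_complement(self, rng):
        stack = (rng.random((4, 12, 12)) < 0.5).astype(np.uint8)
        assert np.allclose(
            patch_entropy_series(stack, SPEC),
            patch_entropy_series(1 - stack, SPEC),
        )

    @given(st.integers(0, 9))
    @settings(deadline=None)
    def test_entropy_bounded_in_unit_interval(self, k):
        h = binary_entropy(np.array(k / 9.0))
        assert 0.0 <= h <= 1.0


class TestEntropySimilarity:
    def test_identical_fields_score_one(self, rng):
        field = rng.random((20, 8, 8))
        s = entropy_similarity(field, field, CONST)
        assert s.kind == "entropy"
        assert np.all(s.values == 1.0)

    def test_single_one_bit_difference(self):
        va = np.zeros((20, 4, 4))
        vb = va.copy()
        vb[0, 2, 2] = 1.0
        s = entropy_similarity(va, vb, CONST).values
        assert s[2, 2] == pytest.approx(1 - 1 / 60)
        assert s[0, 0] == 1.0

    def test_worst_case_bound_under_defaults(self, rng):
        va = rng.random((20, 10, 10))
        vb = rng.random((20, 10, 10))
        s = entropy_similarity(va, vb, CONST).values
        lower = 1 - np.sqrt(20) / 60
        assert np.all(s >= lower) and np.all(s <= 1.0)
        # the bound is attained by maximally different feature vectors
        worst = entropy_similarity(np.zeros((20, 1, 1)), np.ones((20, 1, 1)), CONST)
        assert worst.values[0, 0] == pytest.approx(lower)
        assert lower == pytest.approx(0.9255, abs=1e-4)

    def test_symmetric_in_arguments(self, rng):
        va, vb = rng.random((5, 6, 6)), rng.random((5, 6, 6))
        assert np.allclose(
            entropy_similarity(va, vb, CONST).values,
            entropy_similarity(vb, va, CONST).values,
        )

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            entropy_similarity(np.zeros((5, 4, 4)), np.zeros((5, 3, 3)), CONST)


class TestDifferentialExcitation:
    def test_constant_map_gives_zero(self):
        xi = differential_excitation(np.full((6, 6), 5), SPEC)
        assert not xi.any()

    def test_direct_evaluation_at_interior_pixel(self):
        # centre 2 surrounded by values summing to R = 6 over the patch
        T = np.full((5, 5), 2.0)
        T[1:4, 1:4] = [[3, 3, 3], [3, 2, 3], [3, 2, 2]]
        xi = differential_excitation(T, SPEC)
        assert xi[2, 2] == pytest.approx(np.arctan(3.0), abs=1e-12)
        assert np.arctan(3.0) == pytest.approx(1.249, abs=1e-3)

    def test_scale_invariant_where_center_positive(self, rng):
        T = rng.integers(1, 20, size=(10, 10)).astype(float)
        assert np.allclose(
            differential_excitation(T, SPEC),
            differential_excitation(3.0 * T, SPEC),
        )

    def test_values_inside_arctangent_range(self, rng):
        T = rng.integers(0, 21, size=(12, 12))
        xi = differential_excitation(T, SPEC)
        assert np.all(np.abs(xi) < np.pi / 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_loop(self, seed):
        rng = np.random.default_rng(seed)
        T = rng.integers(0, 21, size=(12, 12))
        assert np.allclose(
            differential_excitation(T, SPEC), excitation_scalar(T, l_p=1), atol=1e-12
        )


class TestWldSimilarity:
    def test_identical_fields_score_one(self, rng):
        xi = rng.uniform(-1.5, 1.5, size=(8, 8))
        s = wld_similarity(xi, xi, CONST)
        assert s.kind == "wld"
        assert np.all(s.values == 1.0)

    def test_direct_evaluation_and_bounds(self):
        xa = np.array([[np.pi / 2]])
        xb = np.array([[0.0]])
        s = wld_similarity(xa, xb, CONST).values
        assert s[0, 0] == pytest.approx(0.9)
        # supremum of |dxi| is pi, so values stay above 1 - pi/cs2 = 0.8
        sup = wld_similarity(np.array([[np.pi / 2]]), np.array([[-np.pi / 2]]), CONST)
        assert sup.values[0, 0] == pytest.approx(0.8)

    def test_symmetric_in_arguments(self, rng):
        xa, xb = rng.uniform(-1, 1, (6, 6)), rng.uniform(-1, 1, (6, 6))
        assert np.allclose(
            wld_similarity(xa, xb, CONST).values, wld_similarity(xb, xa, CONST).values
        )

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            wld_similarity(np.zeros((4, 4)), np.zeros((5, 5)), CONST)


class TestSimilarityMap:
    def test_rejects_unknown_kind(self):
        with pytest.raises(ValueError):
            SimilarityMap(values=np.ones((2, 2)), kind="cosine")
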