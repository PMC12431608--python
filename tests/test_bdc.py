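"""Image metric branch: BDC representations, prototypes, trace similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bdcc.bdc import (
    BDCMatrix,
    FeatureMap,
    bdc_representation,
    class_prototype,
    double_center,
    image_branch_probabilities,
    pairwise_distance_matrix,
    reshape_feature_map,
    trace_similarity,
)


def naive_bdc(vectors: np.ndarray) -> np.ndarray:
    """Independent triple-loop reference for distance matrix + double-centering."""
    m = len(vectors)
    ahat = np.zeros((m, m))
    for k in range(m):
        for l in range(m):
            ahat[k, l] = np.sqrt(np.sum((vectors[k] - vectors[l]) ** 2))
    out = np.zeros((m, m))
    for k in range(m):
        for l in range(m):
            out[k, l] = (
                ahat[k, l]
                - sum(ahat[i, l] for i in range(m)) / m
                - sum(ahat[k, j] for j in range(m)) / m
                + sum(ahat[i, j] for i in range(m) for j in range(m)) / m**2
            )
    return out


class TestReshape:
    def test_channel_axis_shape(self):
        f = FeatureMap(np.arange(6.0).reshape(2, 1, 3))
        assert reshape_feature_map(f, "channel").shape == (3, 2)

    def test_spatial_axis_shape(self):
        f = FeatureMap(np.arange(8.0).reshape(2, 2, 2))
        assert reshape_feature_map(f, "spatial").shape == (4, 2)

    def test_axes_are_transposes(self, rng):
        f = FeatureMap(rng.normal(size=(3, 3, 4)))
        np.testing.assert_array_equal(
            reshape_feature_map(f, "channel"), reshape_feature_map(f, "spatial").T
        )

    def test_nonfinite_rejected(self):
        vals = np.ones((2, 2, 2))
        vals[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            FeatureMap(vals)


class TestDistances:
    def test_hand_example(self):
        dm = pairwise_distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        np.testing.assert_allclose(dm.values, [[0, 5], [5, 0]])

    def test_identical_vectors_zero(self):
        dm = pairwise_distance_matrix(np.ones((4, 3)))
        np.testing.assert_array_equal(dm.values, np.zeros((4, 4)))

    def test_matches_double_loop(self, rng):
        x = rng.normal(size=(5, 7))
        dm = pairwise_distance_matrix(x)
        for k in range(5):
            for l in range(5):
                assert dm.values[k, l] == pytest.approx(
                    np.linalg.norm(x[k] - x[l]), abs=1e-12
                )

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance_matrix([np.zeros(2), np.zeros(3)])


class TestDoubleCenter:
    def test_hand_example(self):
        dm = pairwise_distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        out = double_center(dm)
        np.testing.assert_allclose(out.values, [[-2.5, 2.5], [2.5, -2.5]])

    def test_zero_matrix_fixed_point(self):
        out = double_center(pairwise_distance_matrix(np.ones((3, 2))))
        np.testing.assert_array_equal(out.values, np.zeros((3, 3)))

    def test_row_and_column_sums_vanish(self, rng):
        x = rng.normal(size=(6, 4))
        out = double_center(pairwise_distance_matrix(x))
        assert np.abs(out.values.sum(axis=0)).max() < 1e-10
        assert np.abs(out.values.sum(axis=1)).max() < 1e-10


class TestBDCRepresentation:
    def test_constant_tensor_gives_zero(self):
        f = FeatureMap(np.full((2, 2, 3), 7.0))
        np.testing.assert_allclose(bdc_representation(f).values, 0.0, atol=1e-12)

    def test_spatial_axis_hand_example(self):
        f = FeatureMap(np.array([[[0.0, 0.0], [3.0, 4.0]]]))  # 1 x 2 x 2
        out = bdc_representation(f, axis="spatial")
        np.testing.assert_allclose(out.values, [[-2.5, 2.5], [2.5, -2.5]])

    @pytest.mark.parametrize("axis", ["channel", "spatial"])
    def test_matches_naive_triple_loop(self, rng, axis):
        for _ in range(50):
            h, w = rng.integers(2, 6, size=2)
            d = rng.integers(2, 9)
            f = FeatureMap(rng.normal(size=(h, w, d)))
            obs = reshape_feature_map(f, axis)
            got = bdc_representation(f, axis=axis).values
            np.testing.assert_allclose(got, naive_bdc(obs), atol=1e-10)

    def test_translation_invariance(self, rng):
        base = rng.normal(size=(3, 3, 4))
        f1 = FeatureMap(base)
        # shifting every spatial observation by a constant vector leaves
        # pairwise distances, hence the BDC matrix, unchanged
        f2 = FeatureMap(base + rng.normal(size=(1, 1, 4)))
        a1 = bdc_representation(f1, axis="spatial").values
        a2 = bdc_representation(f2, axis="spatial").values
        np.testing.assert_allclose(a1, a2, atol=1e-8)


class TestPrototype:
    def test_mean_of_identical_is_identity(self, rng):
        a = bdc_representation(FeatureMap(rng.normal(size=(2, 2, 3))))
        p = class_prototype([a, a], class_id="x")
        np.testing.assert_allclose(p.matrix.values, a.values)
        assert p.support_count == 2

    def test_elementwise_mean(self):
        m1 = BDCMatrix(np.array([[-1.0, 1.0], [1.0, -1.0]]))
        m2 = BDCMatrix(np.array([[-3.0, 3.0], [3.0, -3.0]]))
        p = class_prototype([m1, m2])
        np.testing.assert_allclose(p.matrix.values, [[-2, 2], [2, -2]])

    def test_mean_preserves_centering(self, rng):
        mats = [
            bdc_representation(FeatureMap(rng.normal(size=(3, 2, 4))))
            for _ in range(5)
        ]
        p = class_prototype(mats)
        assert np.abs(p.matrix.values.sum(axis=0)).max() < 1e-10

    def test_duplication_invariance(self, rng):
        mats = [
            bdc_representation(FeatureMap(rng.normal(size=(2, 2, 3))))
            for _ in range(3)
        ]
        p1 = class_prototype(mats)
        p2 = class_prototype(mats + mats)
        np.testing.assert_allclose(p1.matrix.values, p2.matrix.values, atol=1e-12)

    def test_empty_and_mismatched_rejected(self, rng):
        with pytest.raises(ValueError):
            class_prototype([])
        a = bdc_representation(FeatureMap(rng.normal(size=(2, 2, 3))))
        b = bdc_representation(FeatureMap(rng.normal(size=(2, 2, 4))))
        with pytest.raises(ValueError):
            class_prototype([a, b])


class TestTraceSimilarity:
    def test_zero_prototype(self, rng):
        a = bdc_representation(FeatureMap(rng.normal(size=(2, 2, 3))))
        zero = class_prototype([BDCMatrix(np.zeros((3, 3)))])
        assert trace_similarity(a, zero) == 0.0

    def test_self_similarity_is_squared_norm(self):
        a = BDCMatrix(np.array([[-2.5, 2.5], [2.5, -2.5]]))
        assert trace_similarity(a, class_prototype([a])) == pytest.approx(25.0)

    def test_frobenius_inner_product(self, rng):
        a = bdc_representation(FeatureMap(rng.normal(size=(2, 3, 4))))
        b = bdc_representation(FeatureMap(rng.normal(size=(3, 2, 4))))
        got = trace_similarity(a, class_prototype([b]))
        assert got == pytest.approx(np.trace(a.values.T @ b.values), abs=1e-12)


class TestImageBranchProbabilities:
    def _protos(self, rng, n, size=4):
        return [
            class_prototype(
                [bdc_representation(FeatureMap(rng.normal(size=(2, 2, size))))]
            )
            for _ in range(n)
        ]

    def test_equal_similarities_uniform(self):
        q = BDCMatrix(np.zeros((3, 3)))
        protos = [class_prototype([BDCMatrix(np.zeros((3, 3)))]) for _ in range(4)]
        np.testing.assert_allclose(
            image_branch_probabilities(q, protos), np.full(4, 0.25), atol=1e-12
        )

    def test_sums_to_one_and_argmax_preserved(self, rng):
        for _ in range(20):
            q = bdc_representation(FeatureMap(rng.normal(size=(2, 2, 4))))
            protos = self._protos(rng, 5)
            sims = [trace_similarity(q, p) for p in protos]
            probs = image_branch_probabilities(q, protos)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert probs.argmax() == np.argmax(sims)

    def test_invalid_temperature(self, rng):
        q = bdc_representation(FeatureMap(rng.normal(size=(2, 2, 4))))
        with pytest.raises(ValueError):
            image_branch_probabilities(q, self._protos(rng, 3), temperature=0.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_bdc_centering_property(seed):
    """Every produced BDC matrix is symmetric with vanishing row/column sums."""
    rng = np.random.default_rng(seed)
    h, w = rng.integers(2, 5, size=2)
    d = int(rng.integers(2, 7))
    out = bdc_representation(FeatureMap(rng.normal(size=(h, w, d)))).values
    assert np.allclose(out, out.T, atol=1e-8)
    assert np.abs(out.sum(axis=0)).max() < 1e-8
    assert np.abs(out.sum(axis=1)).max() < 1e-8
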