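"""Weighted DTW: oracle equivalence, matrix construction, AXB decisions."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from songsim.dtw import (
    DissimilarityMatrix,
    WeightVector,
    axb_decide,
    dissimilarity_matrix,
    dtw_dissimilarity,
    standardize_contours,
)


def brute_force_dtw(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    """Exhaustive enumeration of all monotone alignments (lengths <= 5)."""
    n, m = a.shape[0], b.shape[0]

    def cost(i, j):
        return float(np.sqrt(np.sum(w * (a[i] - b[j]) ** 2)))

    best_total, best_len = None, None
    stack = [(0, 0, cost(0, 0), 1)]
    while stack:
        i, j, tot, length = stack.pop()
        if (i, j) == (n - 1, m - 1):
            # minimal total; among equal totals the longest path (so the
            # mean over the alignment is well defined)
            if (best_total is None or tot < best_total
                    or (tot == best_total and length > best_len)):
                best_total, best_len = tot, length
            continue
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                stack.append((ni, nj, tot + cost(ni, nj), length + 1))
    return best_total / best_len


contour = st.integers(1, 5).flatmap(
    lambda n: st.lists(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=2),
        min_size=n, max_size=n,
    )
)


class TestDTWCore:
    def test_identical_contours_give_zero(self, rng):
        a = rng.normal(size=(7, 3))
        w = WeightVector.equal(("x", "y", "z"))
        assert dtw_dissimilarity(a, a, w) == 0.0

    def test_single_cell_case(self):
        w = WeightVector(features=("f",), weights=np.array([1.0]))
        assert dtw_dissimilarity(np.array([[0.0]]), np.array([[3.0]]), w) == 3.0

    def test_empty_contour_rejected(self):
        w = WeightVector(features=("f",), weights=np.array([1.0]))
        with pytest.raises(ValueError):
            dtw_dissimilarity(np.empty((0, 1)), np.array([[1.0]]), w)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=contour, b=contour, wraw=st.lists(st.floats(0.1, 3), min_size=2,
                                               max_size=2))
    def test_matches_exhaustive_enumeration(self, a, b, wraw):
        a, b = np.array(a), np.array(b)
        w = WeightVector(features=("x", "y"), weights=np.array(wraw))
        got = dtw_dissimilarity(a, b, w)
        expected = brute_force_dtw(a, b, w.weights)
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_symmetry(self, rng):
        w = WeightVector.equal(("x", "y"))
        for _ in range(20):
            a = rng.normal(size=(rng.integers(2, 10), 2))
            b = rng.normal(size=(rng.integers(2, 10), 2))
            assert dtw_dissimilarity(a, b, w) == pytest.approx(
                dtw_dissimilarity(b, a, w), rel=1e-12
            )

    def test_upweighting_differing_feature_increases_distance(self, rng):
        # statistical trend: raising the weight of the feature on which two
        # contours differ should typically increase their dissimilarity
        up = 0
        n_pairs = 60
        for _ in range(n_pairs):
            base = rng.normal(size=(6, 2))
            other = base.copy()
            other[:, 0] += rng.normal(2.0, 0.5, size=6)  # differ on feature 0
            w_lo = WeightVector(features=("x", "y"), weights=np.array([0.2, 0.8]))
            w_hi = WeightVector(features=("x", "y"), weights=np.array([0.8, 0.2]))
            if dtw_dissimilarity(base, other, w_hi) > dtw_dissimilarity(
                base, other, w_lo
            ):
                up += 1
        assert up > 0.9 * n_pairs


class TestWeightVector:
    def test_normalised_to_sum_one(self):
        w = WeightVector(features=("a", "b"), weights=np.array([2.0, 6.0]))
        assert w.weights.sum() == pytest.approx(1.0)
        assert w.weights[1] == pytest.approx(0.75)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            WeightVector(features=("a",), weights=np.array([-1.0]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            WeightVector(features=("a", "b"), weights=np.zeros(2))


class TestDissimilarityMatrix:
    def test_identical_syllables_zero_offdiagonal(self):
        c = np.ones((4, 2))
        w = WeightVector.equal(("x", "y"))
        m = dissimilarity_matrix({"a": c, "b": c.copy(), "c": c.copy()}, w,
                                 standardize=False)
        assert np.all(m.values == 0.0)

    def test_symmetric_and_matches_pairwise_calls(self, rng):
        w = WeightVector.equal(("x", "y"))
        contours = {f"s{i}": rng.normal(size=(rng.integers(3, 8), 2))
                    for i in range(5)}
        m = dissimilarity_matrix(contours, w)
        assert np.array_equal(m.values, m.values.T)
        arrays = standardize_contours(contours, ("x", "y"))
        for i, j in itertools.combinations(range(5), 2):
            expected = dtw_dissimilarity(arrays[f"s{i}"], arrays[f"s{j}"], w)
            assert m.values[i, j] == pytest.approx(expected, rel=1e-12)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DissimilarityMatrix(ids=["a", "a"], values=np.zeros((2, 2)))

    def test_asymmetric_rejected(self):
        v = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(ids=["a", "b"], values=v)

    def test_csv_roundtrip(self, tmp_path, rng):
        x = rng.random((4, 4))
        v = (x + x.T) / 2
        np.fill_diagonal(v, 0.0)
        m = DissimilarityMatrix(ids=list("abcd"), values=v)
        m.to_csv(tmp_path / "m.csv")
        back = DissimilarityMatrix.from_csv(tmp_path / "m.csv")
        assert back.ids == m.ids
        assert np.allclose(back.values, m.values, atol=1e-12)


class TestAxbDecide:
    @pytest.fixture()
    def simple_matrix(self):
        #     x    a    b
        # x   0    2    6
        v = np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 1.0], [6.0, 1.0, 0.0]])
        return DissimilarityMatrix(ids=["x", "a", "b"], values=v)

    def test_relative_distance_arithmetic(self, simple_matrix):
        side, xp = axb_decide(simple_matrix, "x", ["a"], ["b"])
        assert side == "A"
        assert xp == pytest.approx(-0.5)

    def test_equal_distances_tie_to_side_a(self):
        v = np.array([[0.0, 3.0, 3.0], [3.0, 0.0, 1.0], [3.0, 1.0, 0.0]])
        m = DissimilarityMatrix(ids=["x", "a", "b"], values=v)
        side, xp = axb_decide(m, "x", ["a"], ["b"])
        assert xp == 0.0 and side == "A"

    def test_degenerate_zero_distances_abstain(self):
        v = np.zeros((3, 3))
        m = DissimilarityMatrix(ids=["x", "a", "b"], values=v)
        side, xp = axb_decide(m, "x", ["a"], ["b"])
        assert side is None

    def test_xp_always_within_unit_interval(self, rng):
        for _ in range(30):
            x = rng.random((6, 6)) + 0.01
            v = (x + x.T) / 2
            np.fill_diagonal(v, 0.0)
            m = DissimilarityMatrix(ids=[f"s{i}" for i in range(6)], values=v)
            _, xp = axb_decide(m, "s0", ["s1", "s2"], ["s3", "s4", "s5"])
            assert -1.0 <= xp <= 1.0

    def test_min_and_exemplar_aggregation(self, rng):
        x = rng.random((5, 5)) + 0.1
        v = (x + x.T) / 2
        np.fill_diagonal(v, 0.0)
        m = DissimilarityMatrix(ids=list("pabcd"), values=v)
        assert m.side_distance("p", ["a", "b"], "min") == min(
            m.loc("p", "a"), m.loc("p", "b")
        )
        assert m.side_distance("p", ["a", "b"], "exemplar") == m.loc("p", "a")

    def test_mean_aggregation_over_sides(self, rng):
        x = rng.random((5, 5)) + 0.1
        v = (x + x.T) / 2
        np.fill_diagonal(v, 0.0)
        m = DissimilarityMatrix(ids=list("pabcd"), values=v)
        _, xp = axb_decide(m, "p", ["a", "b"], ["c", "d"])
        da = (m.loc("p", "a") + m.loc("p", "b")) / 2
        db = (m.loc("p", "c") + m.loc("p", "d")) / 2
        assert xp == pytest.approx((da - db) / (da + db))
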