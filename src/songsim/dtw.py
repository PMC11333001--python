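"""Weighted dynamic-time-warping dissimilarity over acoustic feature contours.

Each syllable is a multivariate time series of z-scored acoustic features
(time included, so warping is penalised).  The point cost between frame i
of one syllable and frame j of another is the weighted Euclidean distance
``sqrt(sum_f w_f (a[i,f] - b[j,f])^2)`` with non-negative feature weights
normalised to sum to one.  A monotone alignment (diagonal / insert /
delete steps) minimising the summed point cost is found by dynamic
programming, and the dissimilarity is the mean point cost along the
optimal path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .audio import CONTOUR_FEATURES, FeatureContours

__all__ = [
    "WeightVector",
    "DissimilarityMatrix",
    "dtw_dissimilarity",
    "dissimilarity_matrix",
    "axb_decide",
    "standardize_contours",
]


@dataclass
class WeightVector:
    """Non-negative per-feature weights, normalised to sum to one."""

    features: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (len(self.features),):
            raise ValueError("one weight per feature required")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and non-negative")
        s = w.sum()
        if s <= 0:
            raise ValueError("weights must not all be zero")
        self.weights = w / s

    @classmethod
    def equal(cls, features: tuple[str, ...] = CONTOUR_FEATURES) -> "WeightVector":
        return cls(features=tuple(features), weights=np.ones(len(features)))


@dataclass
class DissimilarityMatrix:
    """Symmetric non-negative pairwise dissimilarities with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate syllable ids")
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite dissimilarities")
        if np.any(v < 0):
            raise ValueError("negative dissimilarities")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("matrix not symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("diagonal must be zero")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        self._index = {s: i for i, s in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def side_distance(self, probe: str, side_ids: list[str],
                      aggregate: str = "mean") -> float:
        """Probe-to-side distance: mean (default), min, or exemplar-only
        (the side's first stimulus; sides are stored exemplar-first)."""
        if aggregate == "exemplar":
            return self.loc(probe, side_ids[0])
        d = np.array([self.loc(probe, s) for s in side_ids])
        if aggregate == "mean":
            return float(d.mean())
        if aggregate == "min":
            return float(d.min())
        raise ValueError(f"unknown aggregate {aggregate!r}")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column ids differ")
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(dtype=np.float64))


# ---------------------------------------------------------------------------
# Numba kernels


@njit(cache=True)
def _dtw_core(cost: np.ndarray) -> tuple[float, int]:
    """Min-total-cost monotone alignment of a point-cost matrix.

    Returns (total cost, path length).  When several alignments share the
    minimal total cost, the longest such path is reported so the mean path
    cost is well defined (the smallest mean among optimal alignments).
    """
    n, m = cost.shape
    acc = np.empty((n, m))
    plen = np.empty((n, m), dtype=np.int64)
    acc[0, 0] = cost[0, 0]
    plen[0, 0] = 1
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        plen[i, 0] = i + 1
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
        plen[0, j] = j + 1
    for i in range(1, n):
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            blen = plen[i - 1, j - 1]
            if acc[i - 1, j] < best or (acc[i - 1, j] == best
                                        and plen[i - 1, j] > blen):
                best = acc[i - 1, j]
                blen = plen[i - 1, j]
            if acc[i, j - 1] < best or (acc[i, j - 1] == best
                                        and plen[i, j - 1] > blen):
                best = acc[i, j - 1]
                blen = plen[i, j - 1]
            acc[i, j] = cost[i, j] + best
            plen[i, j] = blen + 1
    return acc[n - 1, m - 1], plen[n - 1, m - 1]


@njit(cache=True)
def _weighted_cost(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> np.ndarray:
    n, m = a.shape[0], b.shape[0]
    f = w.shape[0]
    cost = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            s = 0.0
            for k in range(f):
                d = a[i, k] - b[j, k]
                s += w[k] * d * d
            cost[i, j] = np.sqrt(s)
    return cost


@njit(cache=True)
def _dtw_weighted(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    cost = _weighted_cost(a, b, w)
    total, length = _dtw_core(cost)
    return total / length


@njit(cache=True)
def dtw_batch_from_sqdiff(
    flat: np.ndarray,
    offsets: np.ndarray,
    shapes: np.ndarray,
    w: np.ndarray,
) -> np.ndarray:
    """Mean-path DTW for many pairs from cached per-feature squared diffs.

    ``flat`` concatenates, per pair, an (n1, n2, F) tensor of per-feature
    squared differences; ``offsets[p]`` is the pair's start index and
    ``shapes[p] = (n1, n2)``.  Used by the MCMC weight tuner, where only
    the weights change between likelihood evaluations.
    """
    n_pairs = offsets.shape[0]
    f = w.shape[0]
    out = np.empty(n_pairs)
    for p in range(n_pairs):
        n1 = shapes[p, 0]
        n2 = shapes[p, 1]
        base = offsets[p]
        cost = np.empty((n1, n2))
        for i in range(n1):
            for j in range(n2):
                s = 0.0
                idx = base + (i * n2 + j) * f
                for k in range(f):
                    s += w[k] * flat[idx + k]
                cost[i, j] = np.sqrt(s)
        total, length = _dtw_core(cost)
        out[p] = total / length
    return out


# ---------------------------------------------------------------------------
# Public operations


def _as_array(c, features: tuple[str, ...]) -> np.ndarray:
    if isinstance(c, FeatureContours):
        return c.to_array(features)
    a = np.asarray(c, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None]
    return a


def dtw_dissimilarity(c1, c2, w: WeightVector) -> float:
    """Mean-path weighted DTW dissimilarity between two contour sets.

    Inputs may be :class:`FeatureContours` or (frames, features) arrays and
    are expected to be standardised per feature (corpus z-scores) so that
    the weights are comparable across features.
    """
    a = _as_array(c1, w.features)
    b = _as_array(c2, w.features)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty contour")
    if a.shape[1] != len(w.features) or b.shape[1] != len(w.features):
        raise ValueError("contour feature count does not match weight vector")
    return float(_dtw_weighted(a, b, w.weights))


def standardize_contours(
    contours: dict[str, FeatureContours] | dict[str, np.ndarray],
    features: tuple[str, ...] = CONTOUR_FEATURES,
) -> dict[str, np.ndarray]:
    """Z-score each feature over all frames of all syllables.

    Constant features are left centred (unit denominator) rather than
    amplified by a near-zero standard deviation.
    """
    arrays = {k: _as_array(v, features) for k, v in contours.items()}
    stacked = np.concatenate(list(arrays.values()), axis=0)
    mean = stacked.mean(axis=0)
    std = stacked.std(axis=0)
    std[std < 1e-12] = 1.0
    return {k: (v - mean) / std for k, v in arrays.items()}


def dissimilarity_matrix(
    contours: dict[str, FeatureContours] | dict[str, np.ndarray],
    w: WeightVector,
    standardize: bool = True,
) -> DissimilarityMatrix:
    """All-pairs DTW dissimilarity matrix (each unordered pair computed once)."""
    if len(contours) < 2:
        raise ValueError("need at least 2 syllables")
    arrays = (
        standardize_contours(contours, w.features)
        if standardize
        else {k: _as_array(v, w.features) for k, v in contours.items()}
    )
    ids = list(arrays)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _dtw_weighted(arrays[ids[i]], arrays[ids[j]], w.weights)
            values[i, j] = values[j, i] = d
    return DissimilarityMatrix(ids=ids, values=values)


def axb_decide(
    D: DissimilarityMatrix,
    probe: str,
    side_A_ids: list[str],
    side_B_ids: list[str],
    aggregate: str = "mean",
) -> tuple[str | None, float]:
    """AXB decision of a dissimilarity matrix on one probe.

    ``Xp = (D_probeA - D_probeB) / (D_probeA + D_probeB)`` with the
    probe-to-side distances aggregated (mean by default) over each side's
    stimuli.  Side A is chosen when ``Xp < 0``, side B when ``Xp > 0``; an
    exact tie deterministically returns side A.  When both side distances
    are zero the decision abstains (side ``None``).
    """
    da = D.side_distance(probe, side_A_ids, aggregate)
    db = D.side_distance(probe, side_B_ids, aggregate)
    if da + db == 0:
        return None, 0.0
    xp = (da - db) / (da + db)
    return ("A" if xp <= 0 else "B"), float(xp)
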