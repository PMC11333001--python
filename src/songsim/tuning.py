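"""Metropolis-Hastings calibration of DTW feature weights from bird decisions.

Given a set of unambiguous behavioural triplets, the sampler explores the
simplex of DTW feature weights.  For each triplet the signed relative
dissimilarity ``Xp = (D_pos - D_neg) / (D_pos + D_neg)`` is computed under
the proposed weights (oriented so the bird-chosen side is the positive
side, hence Xp < 0 when the metric agrees with the bird), and the decision
log-likelihood ``log(1 / (1 + exp(4 Xp)))`` is summed over all triplets.
The chain starts from equal weights, proposes multiplicative log-Gaussian
steps (sd 0.1) renormalised to sum to one, and runs 10,000 iterations of
which the first 1,000 are discarded; the posterior mean of the remaining
draws is the tuned weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dtw import (
    DissimilarityMatrix,
    WeightVector,
    axb_decide,
    dtw_batch_from_sqdiff,
    standardize_contours,
)
from .trials import StimulusSet, Triplet

__all__ = [
    "MCMCResult",
    "decision_log_likelihood",
    "mcmc_tune",
    "generate_machine_triplets",
]

_LIKELIHOOD_SLOPE = 4.0


def decision_log_likelihood(xp) -> np.ndarray | float:
    """Log-likelihood ``log(1 / (1 + exp(4 Xp)))`` of one oriented decision.

    ``Xp`` is oriented so that the bird-chosen side is the positive side:
    Xp < 0 means the metric agrees with the bird and the likelihood
    approaches 1; Xp = 0 gives probability 0.5.
    """
    return -np.logaddexp(0.0, _LIKELIHOOD_SLOPE * np.asarray(xp, dtype=np.float64))


@dataclass
class MCMCResult:
    """Weight-calibration chain output."""

    features: tuple[str, ...]
    samples: np.ndarray  # (n_iter, n_features) chain states
    accepted: np.ndarray  # (n_iter,) bool
    log_likelihood_trace: np.ndarray  # (n_iter,)
    burn_in: int

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean())

    @property
    def posterior_mean(self) -> WeightVector:
        post = self.samples[self.burn_in:]
        return WeightVector(features=self.features, weights=post.mean(axis=0))


class _TripletXp:
    """Caches per-pair squared feature differences for fast re-weighting."""

    def __init__(self, triplets, arrays, aggregate):
        if aggregate != "mean":
            raise ValueError("only mean probe-to-side aggregation is supported here")
        pair_index: dict[tuple[str, str], int] = {}
        pair_list: list[tuple[str, str]] = []

        def pair_id(a: str, b: str) -> int:
            key = (a, b) if a <= b else (b, a)
            if key not in pair_index:
                pair_index[key] = len(pair_list)
                pair_list.append(key)
            return pair_index[key]

        pos_idx, pos_ptr = [], [0]
        neg_idx, neg_ptr = [], [0]
        for t in triplets:
            for p in t.positive_ids:
                pos_idx.append(pair_id(t.anchor_id, p))
            pos_ptr.append(len(pos_idx))
            for nn in t.negative_ids:
                neg_idx.append(pair_id(t.anchor_id, nn))
            neg_ptr.append(len(neg_idx))
        self.pos_idx = np.array(pos_idx, dtype=np.int64)
        self.pos_ptr = np.array(pos_ptr, dtype=np.int64)
        self.neg_idx = np.array(neg_idx, dtype=np.int64)
        self.neg_ptr = np.array(neg_ptr, dtype=np.int64)
        self.pos_counts = np.diff(self.pos_ptr).astype(np.float64)
        self.neg_counts = np.diff(self.neg_ptr).astype(np.float64)

        n_feat = next(iter(arrays.values())).shape[1]
        chunks, offsets, shapes = [], [], []
        offset = 0
        for a, b in pair_list:
            xa, xb = arrays[a], arrays[b]
            sq = (xa[:, None, :] - xb[None, :, :]) ** 2
            chunks.append(sq.ravel())
            offsets.append(offset)
            shapes.append((xa.shape[0], xb.shape[0]))
            offset += sq.size
        self.flat = np.concatenate(chunks)
        self.offsets = np.array(offsets, dtype=np.int64)
        self.shapes = np.array(shapes, dtype=np.int64)
        self.n_features = n_feat

    def xp(self, weights: np.ndarray) -> np.ndarray:
        dists = dtw_batch_from_sqdiff(self.flat, self.offsets, self.shapes, weights)
        d_pos = np.add.reduceat(dists[self.pos_idx], self.pos_ptr[:-1]) / self.pos_counts
        d_neg = np.add.reduceat(dists[self.neg_idx], self.neg_ptr[:-1]) / self.neg_counts
        denom = d_pos + d_neg
        denom[denom == 0] = 1.0
        return (d_pos - d_neg) / denom


def mcmc_tune(
    triplets: list[Triplet],
    contours,
    features: tuple[str, ...],
    n_iter: int = 10_000,
    burn_in: int = 1_000,
    proposal_sd: float = 0.1,
    seed: int = 0,
    proposal_correction: bool = True,
    standardize: bool = True,
) -> MCMCResult:
    """Calibrate DTW feature weights against unambiguous bird triplets.

    Parameters follow the procedure described in the module docstring.
    ``proposal_correction`` includes the log-proposal-ratio term of the
    asymmetric multiplicative proposal in the acceptance rule (the
    corrected sampler is the default; the uncorrected variant is kept for
    comparison).  Deterministic given ``seed``.
    """
    triplets = [t for t in triplets if t.u == 1]
    if not triplets:
        raise ValueError("need at least one unambiguous triplet")
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    arrays = (
        standardize_contours(contours, features)
        if standardize
        else {k: np.asarray(v, dtype=np.float64) for k, v in contours.items()}
    )
    needed = {t.anchor_id for t in triplets}
    for t in triplets:
        needed.update(t.positive_ids)
        needed.update(t.negative_ids)
    missing = needed - set(arrays)
    if missing:
        raise ValueError(f"contours missing for syllables: {sorted(missing)[:5]} ...")

    cache = _TripletXp(triplets, arrays, aggregate="mean")
    n_feat = len(features)
    rng = np.random.default_rng(seed)

    def loglik(w: np.ndarray) -> float:
        ll = float(np.sum(decision_log_likelihood(cache.xp(w))))
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite likelihood at weights {w}")
        return ll

    w = np.full(n_feat, 1.0 / n_feat)
    ll = loglik(w)
    samples = np.empty((n_iter, n_feat))
    accepted = np.zeros(n_iter, dtype=bool)
    trace = np.empty(n_iter)
    for it in range(n_iter):
        prop = w * np.exp(rng.normal(0.0, proposal_sd, size=n_feat))
        prop = prop / prop.sum()
        ll_prop = loglik(prop)
        log_alpha = ll_prop - ll
        if proposal_correction:
            log_alpha += float(np.sum(np.log(prop) - np.log(w)))
        if np.log(rng.random()) < log_alpha:
            w, ll = prop, ll_prop
            accepted[it] = True
        samples[it] = w
        trace[it] = ll
    return MCMCResult(
        features=tuple(features), samples=samples, accepted=accepted,
        log_likelihood_trace=trace, burn_in=burn_in,
    )


def generate_machine_triplets(
    D: DissimilarityMatrix,
    stimulus_sets: list[StimulusSet],
    min_margin: float = 0.0,
    aggregate: str = "mean",
) -> list[Triplet]:
    """Machine-labelled triplets from a tuned metric.

    For every probe x stimulus-set pair the metric's AXB decision labels a
    u=1 triplet; only coarse ('easy') distinctions with ``|Xp| >=
    min_margin`` are kept, and exact ties or degenerate decisions are
    always dropped.
    """
    if not 0.0 <= min_margin <= 1.0:
        raise ValueError("min_margin must lie in [0, 1]")
    out: list[Triplet] = []
    for sset in stimulus_sets:
        for probe in sset.probe_ids:
            side, xp = axb_decide(D, probe, sset.side_A_ids, sset.side_B_ids,
                                  aggregate=aggregate)
            if side is None or xp == 0.0 or abs(xp) < min_margin:
                continue
            pos = sset.side_A_ids if side == "A" else sset.side_B_ids
            neg = sset.side_B_ids if side == "A" else sset.side_A_ids
            out.append(
                Triplet(anchor_id=probe, positive_ids=list(pos),
                        negative_ids=list(neg), u=1, weight=1,
                        cycle_id=sset.set_id)
            )
    return out
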