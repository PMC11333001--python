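"""Scoring similarity methods against behavioural AXB decisions.

Any method that produces a dissimilarity matrix (DTW, a learnt embedding,
or an ingested matrix from external software) can be scored by the degree
to which its AXB decisions agree with the birds' consolidated majority
decisions, with bootstrap confidence intervals, attainable-accuracy
bounds derived from cycle accuracy and decision consistency, a
disagreement-based multidimensional scaling of methods, and a binned
choice-calibration curve relating relative rank distance to choice
log-odds (adjusted for the dataset-wide side bias).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dtw import DissimilarityMatrix, axb_decide
from .trials import ProbeDecision, Triplet, TrialRecord, all_cycle_accuracies

__all__ = [
    "EvaluationReport",
    "decide_triplets",
    "axb_accuracy",
    "attainable_bounds",
    "disagreement_mds",
    "choice_calibration",
    "ingest_external_matrix",
    "flag_zero_similarity_triplets",
]


@dataclass
class EvaluationReport:
    method: str
    n_scored: int
    n_abstained: int
    accuracy: float
    ci_low: float
    ci_high: float
    bound_cycle: float | None = None
    bound_consistency: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy outside [0, 1]")
        if not self.ci_low <= self.accuracy <= self.ci_high:
            raise ValueError("accuracy outside its confidence interval")


def decide_triplets(
    D: DissimilarityMatrix,
    triplets: list[Triplet],
    aggregate: str = "mean",
    exclude_ties: bool = True,
) -> list[str | None]:
    """Per-triplet method decisions, oriented to the bird's choice.

    Returns "P" when the method picks the bird-chosen (positive) side, "N"
    when it picks the opposite side, None for abstentions (degenerate
    distances, and exact ties when ``exclude_ties``).
    """
    out: list[str | None] = []
    for t in triplets:
        side, xp = axb_decide(D, t.anchor_id, t.positive_ids, t.negative_ids,
                              aggregate=aggregate)
        if side is None or (exclude_ties and xp == 0.0):
            out.append(None)
        else:
            out.append("P" if side == "A" else "N")
    return out


def axb_accuracy(
    method_decisions: list[str | None],
    triplets: list[Triplet],
    method: str = "method",
    n_boot: int = 1000,
    seed: int = 0,
) -> EvaluationReport:
    """Agreement of a method's AXB decisions with the birds' majority labels.

    Accuracy = agreements / scored triplets; abstentions (None) are
    excluded from both numerator and denominator and counted separately.
    The 95% CI is a percentile bootstrap over scored triplets.
    """
    if len(method_decisions) != len(triplets):
        raise ValueError("one decision per triplet required")
    scored = np.array([d == "P" for d in method_decisions if d is not None],
                      dtype=np.float64)
    n_abst = sum(d is None for d in method_decisions)
    if scored.size == 0:
        raise ValueError("no scorable triplets")
    acc = float(scored.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, scored.size, size=(n_boot, scored.size))
    boots = scored[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EvaluationReport(
        method=method, n_scored=int(scored.size), n_abstained=n_abst,
        accuracy=acc, ci_low=min(float(lo), acc), ci_high=max(float(hi), acc),
    )


def attainable_bounds(
    trials: list[TrialRecord],
    decisions: list[ProbeDecision],
    weight_by_decisions: bool = False,
) -> tuple[float, float | None]:
    """Attainable-accuracy estimates from the behavioural data itself.

    ``bound_cycle`` is the mean cycle accuracy over the (bird, cycle)
    pairs contributing decisions — unweighted by default, weighted by each
    pair's decision count when ``weight_by_decisions``; ``bound_consistency``
    is the mean, over decisions with more than one recorded choice, of the
    fraction of choices agreeing with the majority side (None when no
    multi-decision triplets exist).
    """
    accs = all_cycle_accuracies(trials)
    counts: dict[tuple[str, str], int] = {}
    for d in decisions:
        key = (d.bird_id, d.cycle_id)
        counts[key] = counts.get(key, 0) + d.n_decisions
    contributing = sorted(k for k in counts if k in accs)
    if not contributing:
        raise ValueError("no contributing cycles with training trials")
    if weight_by_decisions:
        total = sum(counts[k] for k in contributing)
        bound_cycle = sum(accs[k] * counts[k] for k in contributing) / total
    else:
        bound_cycle = float(np.mean([accs[k] for k in contributing]))
    multi = [d.consistency for d in decisions if d.n_decisions >= 2]
    bound_consistency = float(np.mean(multi)) if multi else None
    return float(bound_cycle), bound_consistency


def disagreement_mds(
    decisions_by_method: dict[str, list[str | None]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classical MDS of methods from pairwise disagreement fractions.

    The distance between two methods is the fraction of commonly scored
    triplets on which they chose different sides.  Classical (Torgerson)
    scaling of the squared-distance matrix gives 2-D coordinates.
    Returns (coordinates, distance matrix), both indexed by method name.
    """
    names = list(decisions_by_method)
    if len(names) < 3:
        raise ValueError("need at least 3 methods")
    n = len(names)
    lengths = {len(v) for v in decisions_by_method.values()}
    if len(lengths) != 1:
        raise ValueError("methods must cover a common triplet set")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = decisions_by_method[names[i]]
            b = decisions_by_method[names[j]]
            common = [(x, y) for x, y in zip(a, b) if x is not None and y is not None]
            if not common:
                raise ValueError(
                    f"methods {names[i]} and {names[j]} share no scored triplets"
                )
            dist[i, j] = dist[j, i] = sum(x != y for x, y in common) / len(common)
    # Torgerson: double-centre -0.5 * D^2, embed with the top eigenpairs
    d2 = dist**2
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b_mat = -0.5 * j_mat @ d2 @ j_mat
    evals, evecs = np.linalg.eigh(b_mat)
    order = np.argsort(evals)[::-1][:2]
    coords = evecs[:, order] * np.sqrt(np.maximum(evals[order], 0.0))
    return (
        pd.DataFrame(coords, index=names, columns=["mds1", "mds2"]),
        pd.DataFrame(dist, index=names, columns=names),
    )


def _rank_distances(D: DissimilarityMatrix) -> dict[str, dict[str, int]]:
    """Rank of every other syllable in each syllable's sorted row (1 = most
    similar); ties broken by id order via a stable sort."""
    ranks: dict[str, dict[str, int]] = {}
    vals = D.values
    for i, sid in enumerate(D.ids):
        order = np.argsort(vals[i], kind="stable")
        order = order[order != i]
        ranks[sid] = {D.ids[j]: r for r, j in enumerate(order, start=1)}
    return ranks


def choice_calibration(
    trials: list[TrialRecord],
    D: DissimilarityMatrix,
    left_right_stimuli: dict[str, tuple[str, str]],
    n_bins: int = 20,
) -> pd.DataFrame:
    """Binned choice-calibration curve from relative rank distances.

    For each answered probe trial the relative rank distance
    ``(RD_left - RD_right) / (RD_left + RD_right)`` is computed, where
    ``RD_side`` is the rank of the side's training stimulus in the probe's
    sorted dissimilarity row.  Trials are sorted and split into ``n_bins``
    equal-count bins; each bin reports the log-odds of choosing the right
    perch minus the dataset-wide side-bias log-odds.  Log-odds use the
    Haldane-Anscombe 0.5 correction so empty cells stay finite.
    """
    ranks = _rank_distances(D)
    xs, right = [], []
    for t in trials:
        if t.role != "probe" or t.chosen_side == "none":
            continue
        lr = left_right_stimuli.get(t.cycle_id)
        if lr is None:
            continue
        rd_l = ranks[t.stimulus_id][lr[0]]
        rd_r = ranks[t.stimulus_id][lr[1]]
        xs.append((rd_l - rd_r) / (rd_l + rd_r))
        right.append(t.chosen_side == "R")
    if len(xs) < n_bins:
        raise ValueError(f"only {len(xs)} probe trials for {n_bins} bins")
    xs_arr = np.array(xs)
    right_arr = np.array(right, dtype=np.float64)
    n_r, n_l = right_arr.sum(), (1 - right_arr).sum()
    side_bias = math.log((n_r + 0.5) / (n_l + 0.5))
    order = np.argsort(xs_arr, kind="stable")
    rows = []
    for chunk in np.array_split(order, n_bins):
        r = right_arr[chunk].sum()
        l = len(chunk) - r
        rows.append(
            {
                "bin_centre": float(xs_arr[chunk].mean()),
                "n_trials": int(len(chunk)),
                "log_odds_right": math.log((r + 0.5) / (l + 0.5)) - side_bias,
            }
        )
    return pd.DataFrame(rows)


def ingest_external_matrix(path, kind: str = "dissimilarity") -> DissimilarityMatrix:
    """Read a square delimited (dis)similarity matrix from another tool.

    Similarities are converted to dissimilarities as ``max(s) - s``.  The
    returned matrix carries a ``zero_similarity`` boolean array marking
    the pairs the source scored exactly zero (meaningful for tools with a
    similarity floor); see :func:`flag_zero_similarity_triplets`.
    """
    if kind not in ("similarity", "dissimilarity"):
        raise ValueError(f"unknown kind {kind!r}")
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column ids differ")
    v = df.to_numpy(dtype=np.float64)
    if not np.allclose(v, v.T, atol=1e-6):
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance")
    v = (v + v.T) / 2.0
    zero = np.zeros_like(v, dtype=bool)
    if kind == "similarity":
        zero = v == 0.0
        v = v.max() - v
    np.fill_diagonal(v, 0.0)
    out = DissimilarityMatrix(ids=[str(i) for i in df.index], values=v)
    out.zero_similarity = zero  # type: ignore[attr-defined]
    return out


def flag_zero_similarity_triplets(
    D: DissimilarityMatrix, triplets: list[Triplet]
) -> list[bool]:
    """Mark triplets whose probe scored zero similarity against both sides.

    Such triplets are candidates for exclusion in a sensitivity analysis:
    the source tool judged all three sounds too dissimilar to compare.
    Requires a matrix ingested from a similarity source.
    """
    zero = getattr(D, "zero_similarity", None)
    if zero is None:
        return [False] * len(triplets)
    idx = {s: i for i, s in enumerate(D.ids)}
    flags = []
    for t in triplets:
        a = idx[t.anchor_id]
        all_pos = all(zero[a, idx[p]] for p in t.positive_ids)
        all_neg = all(zero[a, idx[n]] for n in t.negative_ids)
        flags.append(all_pos and all_neg)
    return flags
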