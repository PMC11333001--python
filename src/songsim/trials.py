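"""Operant AXB trial logs, decision consolidation and triplet construction.

A trial log records one row per operant response.  Consolidation groups the
repeated presentations of one probe to one bird within one testing cycle
into a single decision with a side-consistency statistic; the triplet
builder then applies the data-quality filters — minimum cycle accuracy on
training stimuli, device-fault exclusion, and the consistency windows that
split decisions into unambiguous (consistency > 70%, at least two
decisions) and ambiguous (50-70%) triplet datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "ProbeDecision",
    "Triplet",
    "StimulusSet",
    "parse_trials",
    "write_trials",
    "cycle_accuracy",
    "all_cycle_accuracies",
    "consolidate_probe_decisions",
    "build_triplet_datasets",
    "select_stimulus_set",
    "split_triplets",
    "write_triplets",
    "read_triplets",
]

_SIDES = ("L", "R", "none")
TRIAL_COLUMNS = [
    "bird_id", "cycle_id", "stimulus_id", "role", "correct_side",
    "chosen_side", "rewarded", "timestamp", "device_ok",
]


@dataclass
class TrialRecord:
    """One operant response (training or probe)."""

    bird_id: str
    cycle_id: str
    stimulus_id: str
    role: str  # training | probe
    correct_side: str  # L | R | none
    chosen_side: str  # L | R | none (none = unanswered)
    rewarded: bool
    timestamp: float
    device_ok: bool = True

    def __post_init__(self) -> None:
        if self.role not in ("training", "probe"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.correct_side not in _SIDES or self.chosen_side not in _SIDES:
            raise ValueError("unknown side token")
        if self.role == "training" and self.correct_side == "none":
            raise ValueError("training trial must have a correct side")
        if self.role == "probe" and self.correct_side != "none":
            raise ValueError("probe trial cannot have a correct side")


@dataclass
class ProbeDecision:
    """Consolidated decision of one bird on one probe within one cycle."""

    bird_id: str
    cycle_id: str
    probe_id: str
    n_decisions: int
    majority_side: str
    consistency: float
    stimulus_set_id: str
    device_ok: bool = True

    def __post_init__(self) -> None:
        if not 0.5 <= self.consistency <= 1.0:
            raise ValueError("consistency must lie in [0.5, 1]")


@dataclass
class Triplet:
    """Set-valued triplet: probe anchor vs. the two training-stimulus sides.

    ``u = 1`` marks an unambiguous decision, ``u = 0`` an ambiguous one;
    ``weight`` carries the number of underlying raw decisions.
    """

    anchor_id: str
    positive_ids: list[str]
    negative_ids: list[str]
    u: int
    weight: int = 1
    bird_id: str = ""
    cycle_id: str = ""

    def __post_init__(self) -> None:
        if self.u not in (0, 1):
            raise ValueError("u must be 0 or 1")
        if not self.positive_ids or not self.negative_ids:
            raise ValueError("positive and negative sets must be non-empty")
        if set(self.positive_ids) & set(self.negative_ids):
            raise ValueError("positive and negative sets must be disjoint")
        if self.anchor_id in self.positive_ids or self.anchor_id in self.negative_ids:
            raise ValueError("anchor cannot appear in either side")


@dataclass
class StimulusSet:
    """Two 8-stimulus training sides built around a pair of exemplars."""

    set_id: str
    exemplar_A: str
    exemplar_B: str
    side_A_ids: list[str]
    side_B_ids: list[str]
    probe_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.side_A_ids) & set(self.side_B_ids):
            raise ValueError("stimulus sides must be disjoint")
        if self.exemplar_A not in self.side_A_ids or self.exemplar_B not in self.side_B_ids:
            raise ValueError("exemplars must belong to their sides")
        overlap = set(self.probe_ids) & (set(self.side_A_ids) | set(self.side_B_ids))
        if overlap:
            raise ValueError(f"probes overlap training sides: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# Trial log I/O


def parse_trials(path) -> list[TrialRecord]:
    """Read a comma-delimited trial log, validating every row.

    Malformed rows are reported with their line number (header = line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    errors = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                TrialRecord(
                    bird_id=row.bird_id,
                    cycle_id=row.cycle_id,
                    stimulus_id=row.stimulus_id,
                    role=row.role,
                    correct_side=row.correct_side,
                    chosen_side=row.chosen_side,
                    rewarded=str(row.rewarded).strip().lower() in ("1", "true", "yes"),
                    timestamp=float(row.timestamp),
                    device_ok=str(row.device_ok).strip().lower() in ("1", "true", "yes"),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {i}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed rows\n" + "\n".join(errors))
    return records


def write_trials(path, trials: list[TrialRecord]) -> None:
    df = pd.DataFrame([asdict(t) for t in trials], columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Accuracy and consolidation


def cycle_accuracy(trials: list[TrialRecord], bird_id: str, cycle_id: str) -> float:
    """Fraction of correct answered training responses in one bird's cycle."""
    n_correct = n_answered = 0
    for t in trials:
        if (t.bird_id == bird_id and t.cycle_id == cycle_id
                and t.role == "training" and t.chosen_side != "none"):
            n_answered += 1
            if t.chosen_side == t.correct_side:
                n_correct += 1
    if n_answered == 0:
        raise ValueError(f"no answered training trials for {bird_id}/{cycle_id}")
    return n_correct / n_answered


def all_cycle_accuracies(trials: list[TrialRecord]) -> dict[tuple[str, str], float]:
    """Cycle accuracy for every (bird, cycle) with answered training trials."""
    counts: dict[tuple[str, str], list[int]] = {}
    for t in trials:
        if t.role == "training" and t.chosen_side != "none":
            c = counts.setdefault((t.bird_id, t.cycle_id), [0, 0])
            c[1] += 1
            c[0] += int(t.chosen_side == t.correct_side)
    return {k: c[0] / c[1] for k, c in counts.items()}


def consolidate_probe_decisions(trials: list[TrialRecord]) -> list[ProbeDecision]:
    """One consolidated decision per (bird, cycle, probe).

    Unanswered trials are ignored.  A tie in side counts gives consistency
    0.5 with the lexicographically first side as majority (such decisions
    are by definition ambiguous).  A decision touched by any device-fault
    trial is flagged ``device_ok=False``.
    """
    groups: dict[tuple[str, str, str], list[TrialRecord]] = {}
    for t in trials:
        if t.role == "probe" and t.chosen_side != "none":
            groups.setdefault((t.bird_id, t.cycle_id, t.stimulus_id), []).append(t)
    decisions = []
    for (bird, cycle, probe), ts in sorted(groups.items()):
        sides = [t.chosen_side for t in ts]
        n = len(sides)
        n_l = sides.count("L")
        n_r = n - n_l
        if n_l > n_r:
            majority = "L"
        elif n_r > n_l:
            majority = "R"
        else:
            majority = "L"  # tie: lexicographically first side
        decisions.append(
            ProbeDecision(
                bird_id=bird, cycle_id=cycle, probe_id=probe, n_decisions=n,
                majority_side=majority, consistency=max(n_l, n_r) / n,
                stimulus_set_id=cycle, device_ok=all(t.device_ok for t in ts),
            )
        )
    return decisions


# ---------------------------------------------------------------------------
# Triplet datasets


def _training_sides(trials: list[TrialRecord]) -> dict[tuple[str, str], dict[str, list[str]]]:
    """Per (bird, cycle): training stimulus ids by rewarded side."""
    out: dict[tuple[str, str], dict[str, list[str]]] = {}
    for t in trials:
        if t.role == "training":
            sides = out.setdefault((t.bird_id, t.cycle_id), {"L": [], "R": []})
            if t.stimulus_id not in sides[t.correct_side]:
                sides[t.correct_side].append(t.stimulus_id)
    return out


def build_triplet_datasets(
    decisions: list[ProbeDecision],
    cycle_accuracies: dict[tuple[str, str], float],
    training_sides: dict[tuple[str, str], dict[str, list[str]]] | list[TrialRecord],
    min_cycle_accuracy: float = 0.65,
    unambiguous_consistency: float = 0.70,
    ambiguous_range: tuple[float, float] = (0.50, 0.70),
    eval_accuracy: float | None = None,
) -> tuple[list[Triplet], list[Triplet]]:
    """Apply the quality filters and split decisions into triplet datasets.

    Filters, in order: decisions from (bird, cycle) pairs with cycle
    accuracy below ``min_cycle_accuracy`` are discarded; decisions touched
    by device faults are discarded; unambiguous = at least two decisions
    with consistency strictly above ``unambiguous_consistency`` (u=1,
    positives = training stimuli rewarded on the majority side); ambiguous
    = consistency within ``ambiguous_range`` inclusive (u=0).  Exactly-70%
    consistency is therefore ambiguous.  When ``eval_accuracy`` is given
    (e.g. 0.77 for a stricter evaluation split) only decisions from cycles
    at or above it are kept.
    """
    for thr in (min_cycle_accuracy, unambiguous_consistency, *ambiguous_range):
        if not 0.5 <= thr <= 1.0:
            raise ValueError(f"threshold {thr} outside [0.5, 1]")
    if isinstance(training_sides, list):
        training_sides = _training_sides(training_sides)
    unamb: list[Triplet] = []
    amb: list[Triplet] = []
    for d in decisions:
        key = (d.bird_id, d.cycle_id)
        acc = cycle_accuracies.get(key)
        if acc is None or acc < min_cycle_accuracy:
            continue
        if eval_accuracy is not None and acc < eval_accuracy:
            continue
        if not d.device_ok:
            continue
        sides = training_sides.get(key)
        if sides is None or not sides["L"] or not sides["R"]:
            continue
        pos = sides[d.majority_side]
        neg = sides["R" if d.majority_side == "L" else "L"]
        if d.probe_id in pos or d.probe_id in neg:
            continue
        if d.n_decisions >= 2 and d.consistency > unambiguous_consistency:
            unamb.append(
                Triplet(anchor_id=d.probe_id, positive_ids=list(pos),
                        negative_ids=list(neg), u=1, weight=d.n_decisions,
                        bird_id=d.bird_id, cycle_id=d.cycle_id)
            )
        elif ambiguous_range[0] <= d.consistency <= ambiguous_range[1]:
            amb.append(
                Triplet(anchor_id=d.probe_id, positive_ids=list(pos),
                        negative_ids=list(neg), u=0, weight=d.n_decisions,
                        bird_id=d.bird_id, cycle_id=d.cycle_id)
            )
    return unamb, amb


def split_triplets(
    triplets: list[Triplet], eval_fraction: float, seed: int
) -> tuple[list[Triplet], list[Triplet]]:
    """Train/evaluation split, stratified by cycle, anchors never shared.

    All triplets of one anchor go to the same split; within each cycle the
    anchors are shuffled and the first ``eval_fraction`` assigned to the
    evaluation split.
    """
    if not 0 < eval_fraction < 1:
        raise ValueError("eval_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    by_cycle: dict[str, list[str]] = {}
    for t in triplets:
        anchors = by_cycle.setdefault(t.cycle_id, [])
        if t.anchor_id not in anchors:
            anchors.append(t.anchor_id)
    eval_anchors: set[tuple[str, str]] = set()
    for cycle in sorted(by_cycle):
        anchors = sorted(by_cycle[cycle])
        rng.shuffle(anchors)
        n_eval = int(round(eval_fraction * len(anchors)))
        eval_anchors.update((cycle, a) for a in anchors[:n_eval])
    train = [t for t in triplets if (t.cycle_id, t.anchor_id) not in eval_anchors]
    evaluation = [t for t in triplets if (t.cycle_id, t.anchor_id) in eval_anchors]
    return train, evaluation


def write_triplets(path, triplets: list[Triplet]) -> None:
    """JSON-lines: one triplet object per line."""
    with open(path, "w") as fh:
        for t in triplets:
            fh.write(json.dumps(asdict(t)) + "\n")


def read_triplets(path) -> list[Triplet]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(Triplet(**json.loads(line)))
    return out


# ---------------------------------------------------------------------------
# Rank-based stimulus-set selection


def select_stimulus_set(
    dissim,
    seed: int,
    side_size: int = 8,
    b_rank_window: tuple[int, int] = (50, 150),
    probe_rank_window: tuple[int, int] = (20, 200),
    set_id: str = "set000",
) -> StimulusSet:
    """Construct one stimulus set by similarity rank.

    Exemplar A is uniform-random; exemplar B is uniform among the syllables
    ranked within ``b_rank_window`` of A's similarity ranking (rank 1 = most
    similar).  Each side is its exemplar plus the ``side_size - 1`` most
    similar syllables; if the sides would overlap, B is resampled.  Probes
    are all syllables ranked within ``probe_rank_window`` of *both*
    exemplars that are not themselves training stimuli.
    """
    ids = list(dissim.ids)
    n = len(ids)
    if n < probe_rank_window[1] + 1:
        raise ValueError(
            f"corpus of {n} syllables too small for rank window {probe_rank_window}"
        )
    values = np.asarray(dissim.values)
    rng = np.random.default_rng(seed)

    def ranks_for(i: int) -> np.ndarray:
        # rank of every syllable w.r.t. i: 1 = most similar, self excluded
        order = np.argsort(values[i], kind="stable")
        order = order[order != i]
        r = np.empty(n, dtype=int)
        r[i] = 0
        r[order] = np.arange(1, n)
        return r

    for _ in range(1000):
        a = int(rng.integers(n))
        ranks_a = ranks_for(a)
        candidates = np.where(
            (ranks_a >= b_rank_window[0]) & (ranks_a <= b_rank_window[1])
        )[0]
        if candidates.size == 0:
            continue
        b = int(candidates[rng.integers(candidates.size)])
        side_a = [a] + list(np.argsort(values[a], kind="stable")[1:side_size])
        side_b = [b] + list(np.argsort(values[b], kind="stable")[1:side_size])
        if set(side_a) & set(side_b):
            continue
        ranks_b = ranks_for(b)
        probe_idx = [
            j for j in range(n)
            if j not in set(side_a) | set(side_b)
            and probe_rank_window[0] <= ranks_a[j] <= probe_rank_window[1]
            and probe_rank_window[0] <= ranks_b[j] <= probe_rank_window[1]
        ]
        return StimulusSet(
            set_id=set_id,
            exemplar_A=ids[a],
            exemplar_B=ids[b],
            side_A_ids=[ids[j] for j in side_a],
            side_B_ids=[ids[j] for j in side_b],
            probe_ids=[ids[j] for j in probe_idx],
        )
    raise RuntimeError("could not build disjoint stimulus sides")
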