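"""Trial-log parsing, consolidation, filtering and stimulus-set selection."""

import numpy as np
import pytest

from songsim.dtw import DissimilarityMatrix
from songsim.trials import (
    ProbeDecision,
    StimulusSet,
    TrialRecord,
    Triplet,
    all_cycle_accuracies,
    build_triplet_datasets,
    consolidate_probe_decisions,
    cycle_accuracy,
    parse_trials,
    read_triplets,
    select_stimulus_set,
    split_triplets,
    write_trials,
    write_triplets,
)


def _trial(bird="b1", cycle="c1", stim="s1", role="training", correct="L",
           chosen="L", t=0.0, ok=True):
    return TrialRecord(bird_id=bird, cycle_id=cycle, stimulus_id=stim,
                       role=role, correct_side=correct, chosen_side=chosen,
                       rewarded=chosen == correct, timestamp=t, device_ok=ok)


def _probe(bird="b1", cycle="c1", stim="x1", chosen="L", t=0.0, ok=True):
    return _trial(bird, cycle, stim, role="probe", correct="none",
                  chosen=chosen, t=t, ok=ok)


class TestTrialRecord:
    def test_probe_cannot_have_correct_side(self):
        with pytest.raises(ValueError):
            _trial(role="probe", correct="L")

    def test_training_needs_correct_side(self):
        with pytest.raises(ValueError):
            _trial(role="training", correct="none")

    def test_unknown_side_token_rejected(self):
        with pytest.raises(ValueError, match="side"):
            _trial(chosen="X")


class TestParseTrials:
    def test_roundtrip_lossless(self, tmp_path):
        trials = [_trial(t=float(i)) for i in range(5)]
        trials += [_probe(t=float(i + 5), chosen=("L" if i % 2 else "R"))
                   for i in range(5)]
        path = tmp_path / "log.csv"
        write_trials(path, trials)
        back = parse_trials(path)
        assert back == trials

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "log.csv"
        write_trials(path, [])
        assert parse_trials(path) == []

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text(
            "bird_id,cycle_id,stimulus_id,role,correct_side,chosen_side,"
            "rewarded,timestamp,device_ok\n"
            "b1,c1,s1,probe,L,L,1,0.0,1\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            parse_trials(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text("bird_id,cycle_id\nb1,c1\n")
        with pytest.raises(ValueError, match="missing required columns"):
            parse_trials(path)


class TestCycleAccuracy:
    def test_seven_of_ten(self):
        trials = [_trial(chosen="L" if i < 7 else "R", t=i) for i in range(10)]
        assert cycle_accuracy(trials, "b1", "c1") == pytest.approx(0.7)

    def test_probe_trials_excluded(self):
        trials = [_trial(chosen="L", t=i) for i in range(4)]
        trials += [_probe(chosen="R", t=10 + i) for i in range(6)]
        assert cycle_accuracy(trials, "b1", "c1") == 1.0

    def test_unanswered_trials_excluded(self):
        trials = [_trial(chosen="L"), _trial(chosen="none", t=1.0)]
        assert cycle_accuracy(trials, "b1", "c1") == 1.0

    def test_no_training_trials_rejected(self):
        with pytest.raises(ValueError):
            cycle_accuracy([_probe()], "b1", "c1")


class TestConsolidate:
    def test_majority_and_consistency(self):
        trials = [_probe(chosen=c, t=i) for i, c in enumerate("LLR")]
        (d,) = consolidate_probe_decisions(trials)
        assert (d.n_decisions, d.majority_side) == (3, "L")
        assert d.consistency == pytest.approx(2 / 3)

    def test_tie_goes_to_lexicographic_side(self):
        trials = [_probe(chosen=c, t=i) for i, c in enumerate("LR")]
        (d,) = consolidate_probe_decisions(trials)
        assert d.majority_side == "L"
        assert d.consistency == 0.5

    def test_single_decision(self):
        (d,) = consolidate_probe_decisions([_probe(chosen="R")])
        assert (d.n_decisions, d.consistency) == (1, 1.0)


def _make_log(cycle_acc_frac, probe_choices, bird="b1", cycle="c1", ok=True):
    """Training trials realising an exact cycle accuracy + one probe."""
    n = len(cycle_acc_frac)
    trials = [
        _trial(bird, cycle, "tL", role="training", correct="L",
               chosen="L" if c else "R", t=i, ok=ok)
        for i, c in enumerate(cycle_acc_frac)
    ]
    # ensure both sides have training stimuli
    trials.append(_trial(bird, cycle, "tR", correct="R", chosen="R", t=n, ok=ok))
    trials += [
        _probe(bird, cycle, "x1", chosen=c, t=n + 1 + i, ok=ok)
        for i, c in enumerate(probe_choices)
    ]
    return trials


class TestBuildTripletDatasets:
    def test_known_composition_counts(self):
        # bird A: accuracy 8/10 -> kept; probe LLLR (cons 0.75, n=4) -> unambiguous
        log = _make_log([1] * 8 + [0] * 2, "LLLR", bird="bA")
        # bird B: accuracy 7/10 -> kept; probe LLR (cons 2/3) -> ambiguous
        log += _make_log([1] * 7 + [0] * 3, "LLR", bird="bB")
        # bird C: accuracy 6/10 < 0.65 -> everything discarded
        log += _make_log([1] * 6 + [0] * 4, "LLLL", bird="bC")
        # bird D: single decision -> in neither set (n >= 2 rule)
        log += _make_log([1] * 9 + [0], "L", bird="bD")
        decisions = consolidate_probe_decisions(log)
        accs = all_cycle_accuracies(log)
        unamb, amb = build_triplet_datasets(decisions, accs, log)
        assert len(unamb) == 1 and len(amb) == 1
        assert unamb[0].bird_id == "bA" and unamb[0].u == 1
        assert amb[0].bird_id == "bB" and amb[0].u == 0
        assert unamb[0].positive_ids == ["tL"] and unamb[0].negative_ids == ["tR"]

    def test_exactly_70_percent_consistency_is_ambiguous(self):
        # 7 of 10 choices on one side: consistency exactly 0.70
        log = _make_log([1] * 8 + [0] * 2, "L" * 7 + "R" * 3)
        unamb, amb = build_triplet_datasets(
            consolidate_probe_decisions(log), all_cycle_accuracies(log), log
        )
        assert len(unamb) == 0 and len(amb) == 1

    def test_device_fault_discards_decision(self):
        log = _make_log([1] * 8 + [0] * 2, "LLLL", ok=False)
        unamb, amb = build_triplet_datasets(
            consolidate_probe_decisions(log), all_cycle_accuracies(log), log
        )
        assert len(unamb) == 0 and len(amb) == 0

    def test_eval_accuracy_filter_is_stricter(self):
        log = _make_log([1] * 7 + [0] * 3, "LLLL", bird="b1")  # 0.70
        log += _make_log([1] * 8 + [0] * 2, "LLLL", bird="b2")  # 0.80
        decisions = consolidate_probe_decisions(log)
        accs = all_cycle_accuracies(log)
        unamb, _ = build_triplet_datasets(decisions, accs, log)
        unamb_eval, _ = build_triplet_datasets(decisions, accs, log,
                                               eval_accuracy=0.77)
        assert len(unamb) == 2 and len(unamb_eval) == 1
        assert unamb_eval[0].bird_id == "b2"

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        log = []
        for b in range(6):
            acc = rng.integers(5, 11)
            choices = "".join(rng.choice(["L", "R"], size=rng.integers(1, 6)))
            log += _make_log([1] * acc + [0] * (10 - acc), choices,
                             bird=f"b{b}")
        decisions = consolidate_probe_decisions(log)
        accs = all_cycle_accuracies(log)
        unamb, amb = build_triplet_datasets(decisions, accs, log)
        keys_u = {(t.bird_id, t.cycle_id, t.anchor_id) for t in unamb}
        keys_a = {(t.bird_id, t.cycle_id, t.anchor_id) for t in amb}
        assert not keys_u & keys_a

    def test_filter_monotonicity_in_accuracy_threshold(self):
        rng = np.random.default_rng(1)
        log = []
        for b in range(8):
            acc = rng.integers(5, 11)
            log += _make_log([1] * acc + [0] * (10 - acc), "LLR", bird=f"b{b}")
        decisions = consolidate_probe_decisions(log)
        accs = all_cycle_accuracies(log)
        sizes = []
        for thr in (0.5, 0.65, 0.8, 0.95):
            u, a = build_triplet_datasets(decisions, accs, log,
                                          min_cycle_accuracy=thr)
            sizes.append(len(u) + len(a))
        assert sizes == sorted(sizes, reverse=True)

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_triplet_datasets([], {}, [], min_cycle_accuracy=0.3)


@pytest.fixture(scope="module")
def matrix():
    rng = np.random.default_rng(42)
    x = rng.normal(size=(210, 3))
    d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(ids=[f"s{i}" for i in range(210)], values=d)


class TestSelectStimulusSet:
    def test_deterministic(self, matrix):
        a = select_stimulus_set(matrix, seed=3)
        b = select_stimulus_set(matrix, seed=3)
        assert a == b

    def test_probe_ranks_within_window(self, matrix):
        sset = select_stimulus_set(matrix, seed=3)
        idx = {s: i for i, s in enumerate(matrix.ids)}

        def rank(anchor, other):
            row = matrix.values[idx[anchor]]
            order = np.argsort(row, kind="stable")
            order = order[order != idx[anchor]]
            return int(np.where(order == idx[other])[0][0]) + 1

        assert 50 <= rank(sset.exemplar_A, sset.exemplar_B) <= 150
        for probe in sset.probe_ids:
            assert 20 <= rank(sset.exemplar_A, probe) <= 200
            assert 20 <= rank(sset.exemplar_B, probe) <= 200

    def test_sides_disjoint_with_8_each(self, matrix):
        sset = select_stimulus_set(matrix, seed=7)
        assert len(sset.side_A_ids) == 8 and len(sset.side_B_ids) == 8
        assert not set(sset.side_A_ids) & set(sset.side_B_ids)

    def test_too_small_corpus_rejected(self):
        d = np.abs(np.subtract.outer(np.arange(50.0), np.arange(50.0)))
        small = DissimilarityMatrix(ids=[f"s{i}" for i in range(50)], values=d)
        with pytest.raises(ValueError, match="too small"):
            select_stimulus_set(small, seed=0)


class TestTripletContainer:
    def test_sides_must_be_disjoint(self):
        with pytest.raises(ValueError):
            Triplet(anchor_id="x", positive_ids=["a"], negative_ids=["a"], u=1)

    def test_anchor_not_in_sides(self):
        with pytest.raises(ValueError):
            Triplet(anchor_id="a", positive_ids=["a"], negative_ids=["b"], u=1)

    def test_jsonl_roundtrip(self, tmp_path):
        trips = [
            Triplet(anchor_id=f"x{i}", positive_ids=["a", "b"],
                    negative_ids=["c"], u=i % 2, weight=i + 1, cycle_id="c1")
            for i in range(4)
        ]
        path = tmp_path / "t.jsonl"
        write_triplets(path, trips)
        assert read_triplets(path) == trips


def test_split_never_shares_anchors():
    trips = [
        Triplet(anchor_id=f"x{i % 10}", positive_ids=["a"], negative_ids=["b"],
                u=1, cycle_id=f"c{i % 3}")
        for i in range(30)
    ]
    train, ev = split_triplets(trips, eval_fraction=0.3, seed=0)
    assert len(train) + len(ev) == 30 and ev
    shared = {(t.cycle_id, t.anchor_id) for t in train} & \
             {(t.cycle_id, t.anchor_id) for t in ev}
    assert not shared
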