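"""Evaluation harness: accuracy, bounds, MDS, calibration, matrix ingestion."""

import numpy as np
import pytest

from songsim.dtw import DissimilarityMatrix
from songsim.evaluation import (
    attainable_bounds,
    axb_accuracy,
    choice_calibration,
    decide_triplets,
    disagreement_mds,
    flag_zero_similarity_triplets,
    ingest_external_matrix,
)
from songsim.trials import ProbeDecision, TrialRecord, Triplet


def _triplets(n):
    return [
        Triplet(anchor_id=f"x{i}", positive_ids=["a"], negative_ids=["b"], u=1)
        for i in range(n)
    ]


class TestAxbAccuracy:
    def test_self_agreement_is_one(self):
        trips = _triplets(10)
        rep = axb_accuracy(["P"] * 10, trips, method="birds")
        assert rep.accuracy == 1.0 and rep.ci_low <= 1.0 <= rep.ci_high

    def test_fixture_arithmetic(self):
        trips = _triplets(5)
        rep = axb_accuracy(["P", "P", "P", "N", None], trips)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.n_scored == 4 and rep.n_abstained == 1

    def test_coin_flip_scores_near_chance(self, rng):
        n = 2000
        trips = _triplets(n)
        decisions = [("P" if rng.random() < 0.5 else "N") for _ in range(n)]
        rep = axb_accuracy(decisions, trips, n_boot=200, seed=1)
        assert abs(rep.accuracy - 0.5) < 4 * np.sqrt(0.25 / n)
        assert rep.ci_low < 0.5 < rep.ci_high

    def test_no_scorable_triplets_rejected(self):
        with pytest.raises(ValueError):
            axb_accuracy([None, None], _triplets(2))


def _trial(bird, cycle, stim, role, correct, chosen, t):
    return TrialRecord(bird_id=bird, cycle_id=cycle, stimulus_id=stim,
                       role=role, correct_side=correct, chosen_side=chosen,
                       rewarded=True, timestamp=t)


class TestAttainableBounds:
    def test_hand_computed_values(self):
        trials = []
        # cycle 1 accuracy 0.7, cycle 2 accuracy 0.8
        for i in range(10):
            trials.append(_trial("b1", "c1", "t1", "training", "L",
                                 "L" if i < 7 else "R", i))
            trials.append(_trial("b2", "c2", "t2", "training", "R",
                                 "R" if i < 8 else "L", 100 + i))
        decisions = [
            ProbeDecision("b1", "c1", "x1", 3, "L", 2 / 3, "c1"),
            ProbeDecision("b2", "c2", "x2", 1, "R", 1.0, "c2"),
        ]
        bound_cycle, bound_cons = attainable_bounds(trials, decisions)
        assert bound_cycle == pytest.approx(0.75)  # unweighted mean
        assert bound_cons == pytest.approx(2 / 3)  # only the n>=2 decision

    def test_decision_count_weighted_variant(self):
        trials = []
        for i in range(10):
            trials.append(_trial("b1", "c1", "t1", "training", "L",
                                 "L" if i < 7 else "R", i))
            trials.append(_trial("b2", "c2", "t2", "training", "R",
                                 "R" if i < 8 else "L", 100 + i))
        decisions = [
            ProbeDecision("b1", "c1", "x1", 3, "L", 2 / 3, "c1"),
            ProbeDecision("b2", "c2", "x2", 1, "R", 1.0, "c2"),
        ]
        bound, _ = attainable_bounds(trials, decisions, weight_by_decisions=True)
        assert bound == pytest.approx((0.7 * 3 + 0.8 * 1) / 4)

    def test_perfect_consistency(self):
        trials = [_trial("b1", "c1", "t", "training", "L", "L", i)
                  for i in range(4)]
        decisions = [ProbeDecision("b1", "c1", "x", 4, "L", 1.0, "c1")]
        _, bound_cons = attainable_bounds(trials, decisions)
        assert bound_cons == 1.0

    def test_no_multi_decision_triplets_reported_missing(self):
        trials = [_trial("b1", "c1", "t", "training", "L", "L", 0)]
        decisions = [ProbeDecision("b1", "c1", "x", 1, "L", 1.0, "c1")]
        _, bound_cons = attainable_bounds(trials, decisions)
        assert bound_cons is None


class TestDisagreementMds:
    def test_duplicate_methods_coincide(self):
        dec = ["P", "N", "P", "N"]
        coords, dist = disagreement_mds(
            {"m1": dec, "m2": list(dec), "m3": ["N", "P", "N", "P"]}
        )
        assert dist.loc["m1", "m2"] == 0.0
        assert np.linalg.norm(coords.loc["m1"] - coords.loc["m2"]) < 1e-6

    def test_label_flip_gives_maximal_distance(self):
        dec = ["P", "N", "P", "N"]
        flipped = ["N", "P", "N", "P"]
        _, dist = disagreement_mds({"m": dec, "flip": flipped, "half": ["P", "P", "P", "N"]})
        assert dist.loc["m", "flip"] == 1.0

    def test_matches_eigendecomposition_oracle(self):
        # hand-built 3x3 disagreement matrix via three 10-triplet methods
        a = ["P"] * 10
        b = ["P"] * 7 + ["N"] * 3
        c = ["N"] * 4 + ["P"] * 6
        coords, dist = disagreement_mds({"a": a, "b": b, "c": c})
        d = dist.to_numpy()
        # oracle: classical MDS by double-centring + eigendecomposition
        n = 3
        j = np.eye(n) - np.ones((n, n)) / n
        bmat = -0.5 * j @ (d**2) @ j
        evals, evecs = np.linalg.eigh(bmat)
        order = np.argsort(evals)[::-1][:2]
        oracle = evecs[:, order] * np.sqrt(np.maximum(evals[order], 0))
        got = coords.to_numpy()
        # distances between points must match exactly (configuration is
        # unique up to rotation/reflection)
        def pdist(x):
            return np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        assert np.allclose(pdist(got), pdist(oracle), atol=1e-10)
        # 3 points embed exactly: reconstructed distances = input distances
        assert np.allclose(pdist(got), d, atol=1e-10)

    def test_fewer_than_three_methods_rejected(self):
        with pytest.raises(ValueError):
            disagreement_mds({"a": ["P"], "b": ["P"]})


def _chain_matrix(n):
    """Distances on a line: syllable i at coordinate i."""
    idx = np.arange(n, dtype=float)
    v = np.abs(idx[:, None] - idx[None, :])
    return DissimilarityMatrix(ids=[f"s{i}" for i in range(n)], values=v)


class TestChoiceCalibration:
    def _probe_trial(self, cycle, stim, chosen, t):
        return _trial("b1", cycle, stim, "probe", "none", chosen, t)

    def test_equal_count_bins(self):
        D = _chain_matrix(50)
        lr = {"c1": ("s0", "s49")}
        trials = [self._probe_trial("c1", f"s{i}", "L" if i < 25 else "R", i)
                  for i in range(5, 45)]
        table = choice_calibration(trials, D, lr, n_bins=20)
        assert len(table) == 20
        assert (table["n_trials"] == 2).all()

    def test_zero_noise_monotone_log_odds(self):
        D = _chain_matrix(60)
        lr = {"c1": ("s0", "s59")}
        # deterministic choices: nearer side always chosen
        trials = [
            self._probe_trial("c1", f"s{i}", "L" if i < 30 else "R", i)
            for i in range(10, 50)
        ]
        table = choice_calibration(trials, D, lr, n_bins=8)
        assert np.all(np.diff(table["log_odds_right"]) >= 0)
        assert table["log_odds_right"].iloc[0] < 0 < table["log_odds_right"].iloc[-1]

    def test_symmetric_unbiased_centre_near_zero(self, rng):
        D = _chain_matrix(60)
        lr = {"c1": ("s20", "s40")}
        trials = [self._probe_trial("c1", "s30", "L" if rng.random() < 0.5 else "R", t)
                  for t in range(200)]
        table = choice_calibration(trials, D, lr, n_bins=4)
        # probe equidistant, unbiased choices: adjusted log-odds ~ 0
        assert np.abs(table["log_odds_right"]).max() < 0.5

    def test_fewer_trials_than_bins_rejected(self):
        D = _chain_matrix(30)
        trials = [self._probe_trial("c1", "s5", "L", 0)]
        with pytest.raises(ValueError):
            choice_calibration(trials, D, {"c1": ("s0", "s29")}, n_bins=20)


class TestIngestExternalMatrix:
    def test_identity_similarity_zero_self_dissimilarity(self, tmp_path):
        import pandas as pd

        sim = np.eye(3)
        ids = ["a", "b", "c"]
        path = tmp_path / "sim.csv"
        pd.DataFrame(sim, index=ids, columns=ids).to_csv(path)
        D = ingest_external_matrix(path, kind="similarity")
        assert np.all(np.diag(D.values) == 0)
        assert D.values[0, 1] == 1.0  # max(s) - 0

    def test_zero_similarity_triplets_flagged(self, tmp_path):
        import pandas as pd

        ids = ["x", "a", "b", "c"]
        sim = np.array(
            [
                [1.0, 0.0, 0.0, 0.8],
                [0.0, 1.0, 0.5, 0.2],
                [0.0, 0.5, 1.0, 0.3],
                [0.8, 0.2, 0.3, 1.0],
            ]
        )
        path = tmp_path / "sim.csv"
        pd.DataFrame(sim, index=ids, columns=ids).to_csv(path)
        D = ingest_external_matrix(path, kind="similarity")
        trips = [
            Triplet(anchor_id="x", positive_ids=["a"], negative_ids=["b"], u=1),
            Triplet(anchor_id="x", positive_ids=["a"], negative_ids=["c"], u=1),
        ]
        flags = flag_zero_similarity_triplets(D, trips)
        assert flags == [True, False]
        assert sum(flags) == 1

    def test_roundtrip_full_precision(self, tmp_path, rng):
        x = rng.random((4, 4))
        v = (x + x.T) / 2
        np.fill_diagonal(v, 0.0)
        m = DissimilarityMatrix(ids=list("abcd"), values=v)
        m.to_csv(tmp_path / "d.csv")
        back = ingest_external_matrix(tmp_path / "d.csv", kind="dissimilarity")
        assert np.allclose(back.values, m.values, atol=1e-12)

    def test_asymmetric_rejected(self, tmp_path):
        import pandas as pd

        v = np.array([[0.0, 1.0], [2.0, 0.0]])
        path = tmp_path / "bad.csv"
        pd.DataFrame(v, index=["a", "b"], columns=["a", "b"]).to_csv(path)
        with pytest.raises(ValueError, match="asymmetric"):
            ingest_external_matrix(path)

    def test_non_square_rejected(self, tmp_path):
        import pandas as pd

        path = tmp_path / "bad.csv"
        pd.DataFrame(np.zeros((2, 3)), index=["a", "b"],
                     columns=["a", "b", "c"]).to_csv(path)
        with pytest.raises(ValueError, match="square"):
            ingest_external_matrix(path)


def test_decide_triplets_orientation():
    v = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 2.0], [4.0, 2.0, 0.0]])
    D = DissimilarityMatrix(ids=["x", "a", "b"], values=v)
    t_agree = Triplet(anchor_id="x", positive_ids=["a"], negative_ids=["b"], u=1)
    t_disagree = Triplet(anchor_id="x", positive_ids=["b"], negative_ids=["a"], u=1)
    assert decide_triplets(D, [t_agree, t_disagree]) == ["P", "N"]
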