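"""Synthetic syllable corpora and simulated operant AXB decision logs.

The generator provides ground truth for every downstream stage: syllables
are harmonic stacks with a time-varying fundamental and a controllable
broadband-noise share, and each syllable's position in a low-dimensional
latent "perceptual" space is a deterministic function of its acoustic
parameters.  Simulated birds answer AXB probe trials through a logistic
choice model on latent-space distances, so the planted metric, the decision
logs and the audio all share one ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .audio import Syllable
from .trials import TrialRecord, StimulusSet

__all__ = [
    "SyllableParams",
    "PlantedSpace",
    "generate_syllable",
    "generate_corpus",
    "simulate_trials",
    "planted_stimulus_sets",
]

RATE = 48_000

# sampling ranges for corpus generation
_RANGES = {
    "duration": (0.05, 0.3),
    "f0_start": (400.0, 1500.0),
    "f0_end": (400.0, 1500.0),
    "f0_mod_depth": (0.0, 80.0),
    "f0_mod_rate": (10.0, 40.0),
    "harmonic_rolloff": (2.0, 12.0),
    "noise_fraction": (0.0, 0.6),
}


@dataclass(frozen=True)
class SyllableParams:
    """Parameters of one synthetic harmonic-stack syllable."""

    duration: float = 0.15
    f0_start: float = 600.0
    f0_end: float = 600.0
    f0_mod_depth: float = 0.0
    f0_mod_rate: float = 25.0
    n_harmonics: int = 5
    harmonic_rolloff: float = 6.0
    noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.duration:
            raise ValueError("duration must be positive")
        for name in ("f0_start", "f0_end"):
            f = getattr(self, name)
            if not 100.0 <= f < RATE / 2:
                raise ValueError(f"{name}={f} outside [100, Nyquist)")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must lie in [0, 1]")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.harmonic_rolloff < 0:
            raise ValueError("harmonic_rolloff must be >= 0")
        if self.f0_mod_depth < 0:
            raise ValueError("f0_mod_depth must be >= 0")
        if self.f0_mod_rate <= 0:
            raise ValueError("f0_mod_rate must be positive")


@dataclass
class PlantedSpace:
    """Latent perceptual coordinates per syllable plus a decision temperature.

    ``noise_scale`` is the logistic temperature of simulated choices: the
    probability of choosing side A given the signed relative distance
    ``Xp`` is ``1 / (1 + exp(4 * Xp / noise_scale))``, so smaller values
    give more deterministic birds and ``noise_scale -> 0`` recovers the
    planted metric exactly.
    """

    coords: dict[str, np.ndarray]
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        self.coords = {k: np.asarray(v, dtype=np.float64) for k, v in self.coords.items()}

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.coords[a] - self.coords[b]))

    def side_distance(self, probe: str, side_ids: list[str]) -> float:
        return float(np.mean([self.distance(probe, s) for s in side_ids]))

    def xp(self, probe: str, side_a: list[str], side_b: list[str]) -> float:
        da = self.side_distance(probe, side_a)
        db = self.side_distance(probe, side_b)
        if da + db == 0:
            return 0.0
        return (da - db) / (da + db)


def generate_syllable(params: SyllableParams, rate: int = RATE) -> Syllable:
    """Render one syllable: decaying harmonic stack + vibrato + noise.

    The fundamental ramps linearly from ``f0_start`` to ``f0_end`` with a
    sinusoidal modulation of depth ``f0_mod_depth`` Hz at ``f0_mod_rate``
    Hz.  Harmonic ``h`` has amplitude ``10**(-(h-1)*harmonic_rolloff/20)``;
    harmonics above Nyquist are dropped.  Gaussian noise carries a
    ``noise_fraction`` share of total power.  Deterministic given the seed.
    """
    n = max(2, int(round(params.duration * rate)))
    t = np.arange(n) / rate
    f0 = (
        params.f0_start
        + (params.f0_end - params.f0_start) * t / params.duration
        + params.f0_mod_depth * np.sin(2 * np.pi * params.f0_mod_rate * t)
    )
    phase = 2 * np.pi * np.cumsum(f0) / rate
    tone = np.zeros(n)
    for h in range(1, params.n_harmonics + 1):
        if h * max(params.f0_start, params.f0_end) + h * params.f0_mod_depth >= rate / 2:
            break
        amp = 10.0 ** (-(h - 1) * params.harmonic_rolloff / 20.0)
        tone += amp * np.sin(h * phase)
    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal(n)

    def _unit_power(x: np.ndarray) -> np.ndarray:
        p = np.sqrt(np.mean(x**2))
        return x / p if p > 0 else x

    nf = params.noise_fraction
    mix = np.sqrt(1.0 - nf) * _unit_power(tone) + np.sqrt(nf) * _unit_power(noise)
    peak = np.max(np.abs(mix))
    if peak > 0:
        mix = 0.9 * mix / peak
    return Syllable(id=f"syl{params.seed}", samples=mix, rate=rate)


def latent_coords(params: SyllableParams) -> np.ndarray:
    """Deterministic 3-D latent coordinates from acoustic parameters.

    Axes: scaled log mean fundamental, scaled log duration, scaled noise
    fraction.  Scales put each axis on a roughly unit range over the
    sampling ranges so no single parameter dominates the planted metric.
    """
    f0_mean = 0.5 * (params.f0_start + params.f0_end)
    return np.array(
        [
            np.log(f0_mean / 400.0) / np.log(1500.0 / 400.0),
            np.log(params.duration / 0.05) / np.log(0.3 / 0.05),
            params.noise_fraction,
        ]
    )


def generate_corpus(
    n: int, seed: int, noise_scale: float = 1.0, render_audio: bool = True
) -> tuple[list[Syllable], pd.DataFrame, PlantedSpace]:
    """Sample ``n`` syllables and their planted perceptual space.

    Returns the rendered syllables (empty list when ``render_audio`` is
    False), a parameter table (one row per syllable), and the planted
    space whose coordinates derive deterministically from the parameters.
    """
    if n < 2:
        raise ValueError("corpus needs at least 2 syllables")
    rng = np.random.default_rng(seed)
    rows = []
    coords = {}
    syllables = []
    for i in range(n):
        kw = {k: float(rng.uniform(*lohi)) for k, lohi in _RANGES.items()}
        params = SyllableParams(
            n_harmonics=int(rng.integers(1, 9)),
            seed=int(rng.integers(0, 2**31 - 1)),
            **kw,
        )
        sid = f"s{i:04d}"
        if render_audio:
            syl = generate_syllable(params)
            syl.id = sid
            syllables.append(syl)
        rows.append({"id": sid, **{f: getattr(params, f) for f in (
            "duration", "f0_start", "f0_end", "f0_mod_depth", "f0_mod_rate",
            "n_harmonics", "harmonic_rolloff", "noise_fraction", "seed")}})
        coords[sid] = latent_coords(params)
    table = pd.DataFrame(rows).set_index("id")
    return syllables, table, PlantedSpace(coords=coords, noise_scale=noise_scale)


def planted_stimulus_sets(
    space: PlantedSpace,
    n_sets: int,
    probes_per_set: int,
    seed: int,
    side_size: int = 8,
) -> list[StimulusSet]:
    """Build stimulus sets directly from the planted space.

    A light-weight counterpart of rank-based selection on a measured
    dissimilarity matrix: exemplars are drawn at random, each side is the
    exemplar plus its ``side_size - 1`` nearest latent neighbours, and
    probes are syllables intermediate in latent distance to both exemplars.
    """
    rng = np.random.default_rng(seed)
    ids = sorted(space.coords)
    X = np.stack([space.coords[i] for i in ids])
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    sets = []
    for k in range(n_sets):
        a = int(rng.integers(len(ids)))
        order_a = np.argsort(d[a])
        b = int(order_a[min(len(ids) - 1, max(2 * side_size, len(ids) // 4))])
        side_a_idx = [a] + [int(j) for j in order_a[1:] if j != b][: side_size - 1]
        order_b = np.argsort(d[b])
        side_b_idx = [b] + [
            int(j) for j in order_b[1:] if j not in side_a_idx
        ][: side_size - 1]
        used = set(side_a_idx) | set(side_b_idx)
        rest = [j for j in range(len(ids)) if j not in used]
        # probes: intermediate syllables (not extreme outliers to both sides),
        # sampled so the signed relative distance Xp spans a realistic range
        both = np.array([d[a, j] + d[b, j] for j in rest])
        keep = np.array(rest)[both <= np.quantile(both, 0.75)]
        rng.shuffle(keep)
        probe_idx = [int(j) for j in keep[:probes_per_set]]
        sets.append(
            StimulusSet(
                set_id=f"set{k:03d}",
                exemplar_A=ids[a],
                exemplar_B=ids[b],
                side_A_ids=[ids[j] for j in side_a_idx],
                side_B_ids=[ids[j] for j in side_b_idx],
                probe_ids=[ids[j] for j in probe_idx],
            )
        )
    return sets


def simulate_trials(
    space: PlantedSpace,
    stimulus_sets: list[StimulusSet],
    n_birds: int,
    bird_accuracies: list[float],
    probes_per_set: int,
    repeats: int,
    seed: int,
    training_trials_per_cycle: int = 100,
    side_bias: float = 0.0,
    start_time: float = 0.0,
) -> list[TrialRecord]:
    """Simulate an operant AXB decision log against the planted metric.

    Each bird runs one cycle per stimulus set.  Training trials are correct
    with probability equal to the bird's accuracy.  On probe trials the
    probability of choosing side A (mapped to the left perch) is
    ``1 / (1 + exp(4 * Xp / noise_scale + side_bias))`` with ``Xp`` the
    signed relative latent distance of the probe to the two sides; each
    probe is re-presented ``repeats`` times.  Deterministic given the seed.
    """
    if len(bird_accuracies) != n_birds:
        raise ValueError("need one accuracy per bird")
    for acc in bird_accuracies:
        if not 0.5 < acc <= 1.0:
            raise ValueError(f"bird accuracy {acc} outside (0.5, 1]")
    rng = np.random.default_rng(seed)
    k = 4.0 / space.noise_scale
    records: list[TrialRecord] = []
    t = start_time
    for b in range(n_birds):
        bird = f"bird{b:02d}"
        acc = bird_accuracies[b]
        for sset in stimulus_sets:
            if not sset.side_A_ids or not sset.side_B_ids:
                raise ValueError(f"{sset.set_id}: empty stimulus side")
            cycle = sset.set_id
            for _ in range(training_trials_per_cycle):
                on_a = rng.random() < 0.5
                stim_ids = sset.side_A_ids if on_a else sset.side_B_ids
                stim = stim_ids[int(rng.integers(len(stim_ids)))]
                correct = "L" if on_a else "R"
                chosen = correct if rng.random() < acc else ("R" if on_a else "L")
                t += 1.0
                records.append(
                    TrialRecord(
                        bird_id=bird, cycle_id=cycle, stimulus_id=stim,
                        role="training", correct_side=correct, chosen_side=chosen,
                        rewarded=chosen == correct, timestamp=t, device_ok=True,
                    )
                )
            probes = sset.probe_ids[:probes_per_set]
            for probe in probes:
                xp = space.xp(probe, sset.side_A_ids, sset.side_B_ids)
                p_a = 1.0 / (1.0 + np.exp(np.clip(k * xp + side_bias, -500, 500)))
                for _ in range(repeats):
                    chosen = "L" if rng.random() < p_a else "R"
                    t += 1.0
                    records.append(
                        TrialRecord(
                            bird_id=bird, cycle_id=cycle, stimulus_id=probe,
                            role="probe", correct_side="none", chosen_side=chosen,
                            rewarded=True, timestamp=t, device_ok=True,
                        )
                    )
    return records
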