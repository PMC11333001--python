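"""Triplet losses and the embedding training loop.

Two loss regimes are supported.  The standard hinge triplet loss
``[D_ap - D_an + delta]_+`` applies when only unambiguous triplets are
trained on.  When ambiguous triplets participate, the mixed loss

    [u (1 - e^{p_u}) + (1 - u)(1 - e^{-|p_a|})]_+ ,
    p_u = D_an^2 - D_ap^2 - delta,   p_a = D_an^2 - D_ap^2,

treats unambiguous triplets (u=1) as a soft margin constraint
``D_an^2 - D_ap^2 >= delta`` and ambiguous triplets (u=0) as the
constraint that the two sides be equidistant from the anchor.

Training pools the selected triplet sources (U = unambiguous bird
decisions, A = ambiguous bird decisions, L = machine triplets from the
tuned DTW metric) into one stream; set-valued triplets are expanded each
epoch by sampling one positive and one negative exemplar uniformly from
their sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dtw import DissimilarityMatrix, axb_decide
from .network import NetworkConfig, TripletNet
from .trials import Triplet

__all__ = [
    "TrainConfig",
    "EmbeddingMatrix",
    "triplet_loss",
    "mixed_loss",
    "train_model",
    "embedding_axb",
]


def triplet_loss(D_ap, D_an, delta: float):
    """Standard hinge triplet loss ``max(0, D_ap - D_an + delta)``."""
    if delta < 0:
        raise ValueError("margin delta must be non-negative")
    return np.maximum(0.0, np.asarray(D_ap) - np.asarray(D_an) + delta)


def mixed_loss(D_ap, D_an, delta: float, u):
    """Ambiguity-aware loss on squared Euclidean embedding distances.

    See the module docstring; ``u`` is 1 for unambiguous and 0 for
    ambiguous triplets.  Per-triplet values lie in [0, 1) for u=0 and
    [0, 1] for u=1; the batch loss is their sum.
    """
    if delta < 0:
        raise ValueError("margin delta must be non-negative")
    D_ap = np.asarray(D_ap, dtype=np.float64)
    D_an = np.asarray(D_an, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    if np.any((u != 0) & (u != 1)):
        raise ValueError("u must be 0 or 1")
    p_u = D_an**2 - D_ap**2 - delta
    p_a = D_an**2 - D_ap**2
    val = u * (1.0 - np.exp(np.clip(p_u, None, 700.0))) + (1.0 - u) * (
        1.0 - np.exp(-np.abs(p_a))
    )
    return np.maximum(0.0, val)


@dataclass
class TrainConfig:
    """Training-run configuration (one of the Table-style source mixes)."""

    sources: str = "U"  # subset of {U, A, L}, e.g. "LUA"
    pretrain_on_L: bool = False
    margin: float = 0.2
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    pretrain_epochs: int = 20
    seed: int = 0
    squared_distances: bool = True
    loss: str = "auto"  # auto | hinge | mixed

    def __post_init__(self) -> None:
        if not self.sources or any(s not in "UAL" for s in self.sources):
            raise ValueError("sources must be a non-empty subset of {U, A, L}")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")


@dataclass
class EmbeddingMatrix:
    """Per-syllable d-dimensional embeddings."""

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("one vector per id required")
        self._index = {s: i for i, s in enumerate(self.ids)}

    def vector(self, id: str) -> np.ndarray:
        return self.vectors[self._index[id]]

    def distance_matrix(self) -> DissimilarityMatrix:
        """Pairwise Euclidean distances as a dissimilarity matrix."""
        sq = np.sum(self.vectors**2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * self.vectors @ self.vectors.T
        d = np.sqrt(np.maximum(d2, 0.0))
        np.fill_diagonal(d, 0.0)
        return DissimilarityMatrix(ids=list(self.ids), values=d)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.vectors, index=self.ids).to_csv(path, header=False)

    @classmethod
    def from_csv(cls, path) -> "EmbeddingMatrix":
        df = pd.read_csv(path, index_col=0, header=None)
        return cls(ids=[str(i) for i in df.index],
                   vectors=df.to_numpy(dtype=np.float64))


def _mel_values(mel) -> np.ndarray:
    v = np.asarray(getattr(mel, "values", mel), dtype=np.float64)
    # dB in [-80, 0] -> roughly [0, 1] input scale
    return v / 80.0 + 1.0


def _loss_and_grads(a, p, n, u, delta, squared, use_mixed):
    """Per-triplet losses and gradients w.r.t. the three embedding blocks."""
    dap_vec = a - p
    dan_vec = a - n
    dap2 = np.sum(dap_vec**2, axis=1)
    dan2 = np.sum(dan_vec**2, axis=1)
    if use_mixed:
        p_u = dan2 - dap2 - delta
        p_a = dan2 - dap2
        val = u * (1.0 - np.exp(np.clip(p_u, None, 700.0))) + (1.0 - u) * (
            1.0 - np.exp(-np.abs(p_a))
        )
        losses = np.maximum(0.0, val)
        active = (val > 0).astype(np.float64)
        # d loss / d (dan2 - dap2)
        ddiff = active * (
            u * (-np.exp(np.clip(p_u, None, 700.0)))
            + (1.0 - u) * np.sign(p_a) * np.exp(-np.abs(p_a))
        )
        g_dap2 = -ddiff
        g_dan2 = ddiff
    else:
        if squared:
            margin_term = dap2 - dan2 + delta
            losses = np.maximum(0.0, margin_term)
            active = (margin_term > 0).astype(np.float64)
            g_dap2 = active
            g_dan2 = -active
        else:
            dap = np.sqrt(np.maximum(dap2, 1e-24))
            dan = np.sqrt(np.maximum(dan2, 1e-24))
            margin_term = dap - dan + delta
            losses = np.maximum(0.0, margin_term)
            active = (margin_term > 0).astype(np.float64)
            g_dap2 = active / (2.0 * dap)
            g_dan2 = -active / (2.0 * dan)
    # d dap2 / d a = 2 (a - p), etc.
    da = 2.0 * (g_dap2[:, None] * dap_vec + g_dan2[:, None] * dan_vec)
    dp = -2.0 * g_dap2[:, None] * dap_vec
    dn = -2.0 * g_dan2[:, None] * dan_vec
    return losses, da, dp, dn


def _run_phase(model, triplets, inputs, index, cfg, rng, use_mixed, epochs, log, phase):
    order = np.arange(len(triplets))
    for epoch in range(epochs):
        rng.shuffle(order)
        total = 0.0
        n_seen = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = [triplets[i] for i in order[start : start + cfg.batch_size]]
            if not batch:
                continue
            a_idx = [index[t.anchor_id] for t in batch]
            p_idx = [index[t.positive_ids[rng.integers(len(t.positive_ids))]]
                     for t in batch]
            n_idx = [index[t.negative_ids[rng.integers(len(t.negative_ids))]]
                     for t in batch]
            u = np.array([t.u for t in batch], dtype=np.float64)
            # anchors/positives/negatives heavily repeat within a batch
            # (sides are shared per cycle): embed each unique image once
            all_idx = np.concatenate([a_idx, p_idx, n_idx])
            uniq, inverse = np.unique(all_idx, return_inverse=True)
            emb_u = model.forward(inputs[uniq], train=True)
            emb = emb_u[inverse]
            b = len(batch)
            a, p, n = emb[:b], emb[b : 2 * b], emb[2 * b :]
            losses, da, dp, dn = _loss_and_grads(
                a, p, n, u, cfg.margin, cfg.squared_distances, use_mixed
            )
            scale = 1.0 / b
            dflat = np.concatenate([da, dp, dn], axis=0) * scale
            d_uniq = np.zeros_like(emb_u)
            np.add.at(d_uniq, inverse, dflat.astype(emb_u.dtype))
            model.backward(d_uniq)
            model.adam_step(lr=cfg.lr)
            total += losses.sum()
            n_seen += b
        log.append({"phase": phase, "epoch": epoch, "loss": total / max(n_seen, 1)})


def train_model(
    datasets: dict[str, list[Triplet]],
    mels: dict,
    net: NetworkConfig,
    cfg: TrainConfig,
) -> tuple[TripletNet, EmbeddingMatrix, pd.DataFrame]:
    """Train the embedding network on the configured triplet sources.

    ``datasets`` maps source codes (U, A, L) to triplet lists; ``mels``
    maps syllable ids to their mel spectrograms.  Sources named in
    ``cfg.sources`` are pooled into one training stream (with an optional
    pre-training phase on L); the loss is the mixed, ambiguity-aware form
    whenever source A is active (or ``cfg.loss='mixed'``), otherwise the
    hinge triplet loss on squared distances by default.  Returns the
    model, final embeddings of every syllable in ``mels`` and a training
    log with a per-phase source audit.
    """
    pooled: list[Triplet] = []
    used_sources = []
    for code in "LUA":
        if code in cfg.sources and datasets.get(code):
            pooled.extend(datasets[code])
            used_sources.append(code)
    if not pooled:
        raise ValueError(f"no triplets found for sources {cfg.sources!r}")
    referenced: set[str] = set()
    for t in pooled:
        referenced.add(t.anchor_id)
        referenced.update(t.positive_ids)
        referenced.update(t.negative_ids)
    missing = referenced - set(mels)
    if missing:
        raise ValueError(f"mel spectrograms missing for {sorted(missing)[:5]} ...")

    ids = list(mels)
    index = {s: i for i, s in enumerate(ids)}
    inputs = np.stack([_mel_values(mels[s]) for s in ids])

    if cfg.loss == "mixed":
        use_mixed = True
    elif cfg.loss == "hinge":
        use_mixed = False
    else:
        use_mixed = "A" in cfg.sources and bool(datasets.get("A"))

    model = TripletNet(net, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    log: list[dict] = []

    if cfg.pretrain_on_L:
        if not datasets.get("L"):
            raise ValueError("pretrain_on_L requires machine (L) triplets")
        _run_phase(model, datasets["L"], inputs, index, cfg, rng,
                   use_mixed=False, epochs=cfg.pretrain_epochs, log=log,
                   phase="pretrain:L")

    _run_phase(model, pooled, inputs, index, cfg, rng, use_mixed,
               epochs=cfg.epochs, log=log, phase="train:" + "".join(used_sources))

    vectors = np.concatenate(
        [model.forward(inputs[i : i + 64]) for i in range(0, len(ids), 64)]
    )
    return model, EmbeddingMatrix(ids=ids, vectors=vectors), pd.DataFrame(log)


def embedding_axb(
    embeddings: EmbeddingMatrix,
    probe: str,
    side_A_ids: list[str],
    side_B_ids: list[str],
    aggregate: str = "mean",
) -> tuple[str | None, float]:
    """AXB decision in the learnt space: delegate to the distance comparator."""
    ids = [probe, *side_A_ids, *side_B_ids]
    sub = EmbeddingMatrix(
        ids=list(dict.fromkeys(ids)),
        vectors=np.stack([embeddings.vector(s) for s in dict.fromkeys(ids)]),
    )
    return axb_decide(sub.distance_matrix(), probe, side_A_ids, side_B_ids,
                      aggregate=aggregate)
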