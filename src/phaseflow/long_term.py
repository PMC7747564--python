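"""Sequence-level (long-term) phase smoother.

The per-second probability rows emitted by the clip classifier are noisy
and temporally inconsistent.  The long-term model treats the whole video
as one sequence: each second's phase id is embedded (dimension 32), fed
through a single bidirectional LSTM layer with 128 hidden-state features
per direction, and mapped back to the seven phases by a linear head.

Because one training sample is an entire video, training data is scarce;
the augmentation that makes this workable is temperature softening of the
probability rows (T = 11) followed by a fresh categorical draw of one
phase per second at every epoch, so the model sees a different corrupted
phase sequence each pass.  Inference is deterministic: the per-second
argmax ids are fed through the network once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._nn import SGD, BiLSTMSequenceClassifier, softmax
from .ontology import N_PHASES, AnnotationTrack
from .short_term import ProbabilitySequence

__all__ = [
    "LongTermConfig",
    "PhaseIdSequence",
    "LongTermModel",
    "soften",
    "sample_phase_sequence",
    "train_long_term",
    "smooth",
]

#: Floor applied to zero probabilities before the 1/T power, so the
#: temperature map is defined on the closed simplex.
EPS_FLOOR = 1e-12


@dataclass(frozen=True)
class LongTermConfig:
    """Hyperparameters of the sequence smoother.

    Defaults are the published configuration: temperature 11, embedding
    32, 128 hidden features, bidirectional, SGD with fixed lr 0.1 and
    momentum 0.9, mini-batch of one video, 30 epochs.
    """

    temperature_T: float = 11.0
    embed_dim: int = 32
    hidden_dim: int = 128
    bidirectional: bool = True
    lr: float = 0.1
    momentum: float = 0.9
    epochs: int = 30
    batch_videos: int = 1
    augment: bool = True  # per-epoch categorical resampling; off = argmax inputs
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.temperature_T > 0:
            raise ValueError("temperature_T must be > 0")
        if self.embed_dim < 1 or self.hidden_dim < 1:
            raise ValueError("embed_dim and hidden_dim must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_videos != 1:
            raise ValueError("mini-batch is one video (sequences have different lengths)")


@dataclass(frozen=True)
class PhaseIdSequence:
    """One sampled phase id per second of a video."""

    video_id: str
    ids: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=np.int64)
        if ids.ndim != 1 or ids.size == 0:
            raise ValueError(f"{self.video_id}: ids must be a non-empty 1-D sequence")
        if ids.min() < 0 or ids.max() >= N_PHASES:
            raise ValueError(f"{self.video_id}: ids must lie in 0..{N_PHASES - 1}")
        object.__setattr__(self, "ids", ids)


def soften(prob_row: np.ndarray, T: float) -> np.ndarray:
    """Temperature-soften a probability vector: ``q_i = p_i^(1/T) / sum``.

    This is the distillation temperature map restricted to the simplex
    (exponent 1/T on probabilities equals dividing log-probabilities by
    T); it is the identity at T = 1, softens towards uniform-on-support as
    T grows, and preserves the ordering of entries for every T > 0.
    Zero entries are floored at 1e-12 before exponentiation.
    """
    if not T > 0:
        raise ValueError("temperature must be > 0")
    p = np.asarray(prob_row, dtype=np.float64)
    if p.min() < 0:
        raise ValueError("probabilities must be non-negative")
    q = np.clip(p, EPS_FLOOR, None) ** (1.0 / T)
    return q / q.sum(axis=-1, keepdims=True)


def sample_phase_sequence(
    probs: ProbabilitySequence, T: float, rng: np.random.Generator
) -> PhaseIdSequence:
    """Draw one phase per second from the temperature-softened rows.

    Each call produces fresh draws; this is the training-time
    augmentation that turns one L x 7 matrix into an unbounded family of
    corrupted phase sequences.
    """
    q = soften(probs.rows, T)
    u = rng.random((q.shape[0], 1))
    ids = (q.cumsum(axis=1) > u).argmax(axis=1)
    return PhaseIdSequence(video_id=probs.video_id, ids=ids)


@dataclass
class LongTermModel:
    """A trained sequence smoother plus its training configuration."""

    net: BiLSTMSequenceClassifier
    config: LongTermConfig
    loss_history: list[float]


def _as_pairs(
    cases: Sequence,
) -> list[tuple[ProbabilitySequence, AnnotationTrack]]:
    pairs = []
    for c in cases:
        if isinstance(c, tuple):
            probs, truth = c
        else:
            probs, truth = c.probs, c.truth
        if probs.rows.shape[0] != truth.length_s:
            raise ValueError(
                f"{truth.video_id}: probability rows ({probs.rows.shape[0]}) do not "
                f"match truth length ({truth.length_s})"
            )
        pairs.append((probs, truth))
    return pairs


def train_long_term(
    cases: Sequence,
    config: LongTermConfig = LongTermConfig(),
    init: LongTermModel | None = None,
) -> LongTermModel:
    """Train the smoother on (probability sequence, truth track) pairs.

    One optimization step per video per epoch (mini-batch of one, since
    every video has a different length); the per-second cross-entropy is
    averaged over the video.  With ``config.augment`` the input ids are
    resampled from the softened rows each epoch; otherwise the argmax ids
    are used (the ablation without sampling augmentation).  Pass ``init``
    to continue training from an existing model (fine-tuning).
    """
    pairs = _as_pairs(cases)
    if not pairs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    if init is not None:
        net = BiLSTMSequenceClassifier(
            n_classes=N_PHASES, embed_dim=config.embed_dim,
            hidden_dim=config.hidden_dim, bidirectional=config.bidirectional, rng=rng,
        )
        net.params = {k: v.copy() for k, v in init.net.params.items()}
    else:
        net = BiLSTMSequenceClassifier(
            n_classes=N_PHASES, embed_dim=config.embed_dim,
            hidden_dim=config.hidden_dim, bidirectional=config.bidirectional, rng=rng,
        )
    opt = SGD(net.params, lr=config.lr, momentum=config.momentum)
    loss_history: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        epoch_losses = []
        for i in order:
            probs, truth = pairs[i]
            if config.augment:
                ids = sample_phase_sequence(probs, config.temperature_T, rng).ids
            else:
                ids = probs.argmax_track().labels
            loss, grads = net.loss_and_grads(ids, truth.labels)
            opt.step(grads)
            epoch_losses.append(loss)
        loss_history.append(float(np.mean(epoch_losses)))
    return LongTermModel(net=net, config=config, loss_history=loss_history)


def smooth(model: LongTermModel, probs: ProbabilitySequence) -> AnnotationTrack:
    """Smooth one probability sequence into a final per-second track.

    Deterministic inference: the per-row argmax ids (no temperature, no
    sampling) pass once through the embedding, the bidirectional LSTM and
    the linear head; the output is the per-second argmax phase.
    """
    if probs.rows.shape[0] == 0:
        raise ValueError("empty probability sequence")
    ids = probs.argmax_track().labels
    pred = model.net.predict(ids)
    return AnnotationTrack(video_id=probs.video_id, labels=pred)


def smooth_sampled(
    model: LongTermModel, probs: ProbabilitySequence, k: int, rng: np.random.Generator
) -> AnnotationTrack:
    """Alternative inference: average logits over ``k`` sampled sequences."""
    if k < 1:
        raise ValueError("k must be >= 1")
    acc = None
    for _ in range(k):
        ids = sample_phase_sequence(probs, model.config.temperature_T, rng).ids
        logits = model.net.forward(ids)
        acc = logits if acc is None else acc + logits
    return AnnotationTrack(video_id=probs.video_id, labels=np.argmax(acc, axis=1))
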