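"""Clip-level (short-term) classifier contract.

The short-term model views each second of video as an independent sample:
a 2.56 s clip of 64 frames (at 25 FPS) centred on that second is
classified into one of the seven phases.  This module implements the
geometry of clip extraction, frame preprocessing and augmentation, the
Second Duration Ratio (SDR) progress feature, the SGD training schedule
with validation-iteration learning-rate drops, per-video probability
sequence emission, and out-of-body trimming.

The full-scale backbone is an inflated ResNet-50 with non-local blocks,
pre-trained on large image/video corpora; that configuration is recorded
in :class:`BackboneSpec` for documentation, while the instantiable
default is a small 3D-convolutional network suited to CPU-scale
experiments on synthetic frames.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from ._nn import SGD, TinyConv3D, TinyConv3DConfig, softmax
from .ontology import N_PHASES, AnnotationTrack

__all__ = [
    "ClipSpec",
    "PreprocessConfig",
    "ShortTermTrainConfig",
    "BackboneSpec",
    "ProbabilitySequence",
    "FrameCase",
    "ShortTermModel",
    "clip_frame_indices",
    "compute_sdr",
    "preprocess_clip",
    "lr_at",
    "training_samples_seen",
    "train_short_term",
    "predict_probability_sequence",
    "detect_out_of_body",
    "trim_bounds",
]


@dataclass(frozen=True)
class ClipSpec:
    """Geometry of the per-second clip: 2.56 s at 25 FPS -> 64 frames."""

    fps: int = 25
    clip_duration_s: float = 2.56
    n_frames: int = 64
    anchor_policy: str = "middle-of-second"  # or "random-in-second" (train)

    def __post_init__(self) -> None:
        if self.n_frames != round(self.fps * self.clip_duration_s):
            raise ValueError(
                f"n_frames ({self.n_frames}) must equal round(fps * clip_duration_s) "
                f"= {round(self.fps * self.clip_duration_s)}"
            )
        if self.anchor_policy not in ("middle-of-second", "random-in-second"):
            raise ValueError(f"unknown anchor_policy {self.anchor_policy!r}")


@dataclass(frozen=True)
class PreprocessConfig:
    """Spatial preprocessing: short-side resize, crop, channel standardization.

    Defaults are the full-scale values (256-px short side, 224 crop,
    ImageNet channel statistics); desk-scale runs on tiny synthetic frames
    pass smaller sizes.
    """

    resize_short_side: int = 256
    crop: int = 224
    channel_mean: tuple[float, float, float] = (0.485, 0.456, 0.406)
    channel_sd: tuple[float, float, float] = (0.229, 0.224, 0.225)

    def __post_init__(self) -> None:
        if self.crop > self.resize_short_side:
            raise ValueError("crop must not exceed the resized short side")


@dataclass(frozen=True)
class ShortTermTrainConfig:
    """SGD schedule: lr 0.01, momentum 0.9, batches of 16 clips; the
    validation set is evaluated every ``eval_every_samples`` training
    samples and the learning rate drops by ``lr_drop_factor`` after
    validation iterations 10, 20 and 25, stopping after 30."""

    batch_clips: int = 16
    lr_init: float = 0.01
    momentum: float = 0.9
    eval_every_samples: int = 250_000
    lr_drop_after_validations: tuple[int, ...] = (10, 20, 25)
    stop_after_validations: int = 30
    lr_drop_factor: float = 10.0
    sdr_enabled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        drops = self.lr_drop_after_validations
        if any(b <= a for a, b in zip(drops, drops[1:])):
            raise ValueError("lr_drop_after_validations must be strictly increasing")
        if drops and drops[-1] >= self.stop_after_validations:
            raise ValueError("lr drops must occur before stop_after_validations")


@dataclass(frozen=True)
class BackboneSpec:
    """Which clip backbone to build.

    ``inflated-residual-50-nonlocal`` documents the full-scale
    architecture (an ImageNet-initialized ResNet-50 inflated to 3D with
    non-local attention blocks, pre-trained for action recognition); it is
    not instantiable here.  ``tiny-3d`` is the CPU-scale default.
    """

    kind: str = "tiny-3d"
    n_classes: int = N_PHASES
    sdr_concat_at_head: bool = False
    tiny: TinyConv3DConfig | None = None

    def build(self, in_channels: int = 3, rng: np.random.Generator | None = None) -> TinyConv3D:
        if self.kind == "tiny-3d":
            cfg = self.tiny or TinyConv3DConfig()
            cfg = TinyConv3DConfig(
                kernel1=cfg.kernel1, channels1=cfg.channels1,
                kernel2=cfg.kernel2, channels2=cfg.channels2,
                n_classes=self.n_classes, use_sdr=self.sdr_concat_at_head,
            )
            return TinyConv3D(cfg, in_channels=in_channels, rng=rng)
        if self.kind == "inflated-residual-50-nonlocal":
            raise NotImplementedError(
                "the full-scale inflated ResNet-50 backbone is documented but not "
                "instantiable at desk scale; use kind='tiny-3d'"
            )
        raise ValueError(f"unknown backbone kind {self.kind!r}")


@dataclass(frozen=True)
class ProbabilitySequence:
    """L x 7 matrix of per-second phase probabilities for one video."""

    video_id: str
    rows: np.ndarray

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=np.float64)
        if rows.ndim != 2 or rows.shape[1] != N_PHASES or rows.shape[0] == 0:
            raise ValueError(f"{self.video_id}: rows must be a non-empty L x {N_PHASES} matrix")
        if rows.min() < 0:
            raise ValueError(f"{self.video_id}: probabilities must be non-negative")
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.video_id}: each row must sum to 1")
        object.__setattr__(self, "rows", rows)

    @property
    def length_s(self) -> int:
        return int(self.rows.shape[0])

    def argmax_track(self) -> AnnotationTrack:
        """Per-second argmax prediction; ties break to the lowest phase id."""
        return AnnotationTrack(video_id=self.video_id, labels=np.argmax(self.rows, axis=1))


@dataclass(frozen=True)
class FrameCase:
    """A video available as a decoded frame array plus per-second labels."""

    video_id: str
    frames: np.ndarray  # (L * fps, H, W, 3), uint8
    labels: np.ndarray  # (L,), phase ids

    @property
    def length_s(self) -> int:
        return int(np.asarray(self.labels).size)


# ---------------------------------------------------------------------------
# Clip geometry and analytic features
# ---------------------------------------------------------------------------


def clip_frame_indices(
    anchor_second: int, anchor_frame: int, video_len_s: int, spec: ClipSpec = ClipSpec()
) -> np.ndarray:
    """Frame indices of the clip centred on an anchor frame.

    The window spans ``n_frames`` consecutive frames centred on the anchor
    (32 before, 31 after for 64 frames) and is clamped at video
    boundaries, repeating edge frames so the clip length is invariant.
    """
    if not 0 <= anchor_second < video_len_s:
        raise ValueError(f"anchor second {anchor_second} outside video of {video_len_s}s")
    if not 0 <= anchor_frame < spec.fps:
        raise ValueError(f"anchor frame {anchor_frame} outside 0..{spec.fps - 1}")
    a = anchor_second * spec.fps + anchor_frame
    half = spec.n_frames // 2
    idx = np.arange(a - half, a - half + spec.n_frames)
    return np.clip(idx, 0, video_len_s * spec.fps - 1)


def compute_sdr(second: int, video_len_s: int) -> float:
    """Second Duration Ratio: the sample second over the video length.

    A progress feature in [0, 1) concatenated before the classification
    head; it suppresses predictions of temporally distant phases.
    """
    if video_len_s <= 0:
        raise ValueError("video length must be positive")
    if not 0 <= second < video_len_s:
        raise ValueError(f"second {second} outside video of {video_len_s}s")
    return second / video_len_s


def resized_dims(h: int, w: int, short_side: int) -> tuple[int, int]:
    """Output (height, width) after resizing the shorter side to ``short_side``."""
    if h <= 0 or w <= 0:
        raise ValueError("frame dimensions must be positive")
    if h <= w:
        return short_side, int(round(w * short_side / h))
    return int(round(h * short_side / w)), short_side


def preprocess_clip(
    frames: np.ndarray,
    train_mode: bool = False,
    config: PreprocessConfig = PreprocessConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Resize (short side), crop and standardize a frame stack.

    uint8 input is mapped to [0, 1] before per-channel standardization
    with the configured mean/sd.  Cropping is random in train mode and
    centred in eval mode.
    """
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError("frames must have shape (T, H, W, 3)")
    x = frames.astype(np.float64)
    if frames.dtype == np.uint8:
        x /= 255.0
    T, H, W, _ = x.shape
    if min(H, W) != config.resize_short_side:
        out_h, out_w = resized_dims(H, W, config.resize_short_side)
        x = ndimage.zoom(x, (1, out_h / H, out_w / W, 1), order=1, grid_mode=True,
                         mode="nearest")
        H, W = x.shape[1], x.shape[2]
    c = config.crop
    if H < c or W < c:
        raise ValueError(f"resized frame {H}x{W} smaller than {c}x{c} crop")
    if train_mode:
        if rng is None:
            raise ValueError("train-mode preprocessing needs an rng for the random crop")
        top = int(rng.integers(0, H - c + 1))
        left = int(rng.integers(0, W - c + 1))
    else:
        top = (H - c) // 2
        left = (W - c) // 2
    x = x[:, top : top + c, left : left + c, :]
    mean = np.asarray(config.channel_mean)
    sd = np.asarray(config.channel_sd)
    return (x - mean) / sd


def lr_at(validation_iter: int, config: ShortTermTrainConfig = ShortTermTrainConfig()) -> float:
    """Learning rate in effect after ``validation_iter`` validation iterations."""
    if validation_iter < 0:
        raise ValueError("validation_iter must be >= 0")
    n_drops = sum(validation_iter >= d for d in config.lr_drop_after_validations)
    return config.lr_init / config.lr_drop_factor**n_drops


def training_samples_seen(validation_iters: int, eval_every_samples: int) -> int:
    """Total training samples after a number of validation iterations."""
    if validation_iters < 0 or eval_every_samples < 0:
        raise ValueError("arguments must be >= 0")
    return validation_iters * eval_every_samples


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------


@dataclass
class ShortTermModel:
    """A trained clip classifier bundled with its preprocessing contract."""

    net: TinyConv3D
    clip_spec: ClipSpec
    preprocess: PreprocessConfig
    sdr_enabled: bool
    history: list = field(default_factory=list)


def _gather_clip(frames: np.ndarray, second: int, anchor_frame: int, video_len_s: int,
                 spec: ClipSpec) -> np.ndarray:
    idx = clip_frame_indices(second, anchor_frame, video_len_s, spec)
    return frames[idx]


def _evaluate_cases(model_net: TinyConv3D, cases: Sequence[FrameCase], spec: ClipSpec,
                    prep: PreprocessConfig, sdr_enabled: bool, max_seconds: int = 200,
                    rng: np.random.Generator | None = None) -> float:
    """Per-second argmax accuracy over (a subsample of) validation seconds."""
    pairs = [(ci, s) for ci, c in enumerate(cases) for s in range(c.length_s)]
    if len(pairs) > max_seconds:
        rng = rng if rng is not None else np.random.default_rng(0)
        keep = rng.choice(len(pairs), size=max_seconds, replace=False)
        pairs = [pairs[i] for i in keep]
    correct = 0
    for ci, s in pairs:
        case = cases[ci]
        clip = _gather_clip(case.frames, s, spec.fps // 2, case.length_s, spec)
        x = preprocess_clip(clip, train_mode=False, config=prep)[None]
        sdr = np.array([compute_sdr(s, case.length_s)]) if sdr_enabled else None
        pred = int(np.argmax(model_net.forward(x, sdr=sdr)[0]))
        correct += pred == int(case.labels[s])
    return correct / len(pairs)


def train_short_term(
    train_cases: Sequence[FrameCase],
    val_cases: Sequence[FrameCase],
    backbone: BackboneSpec = BackboneSpec(),
    config: ShortTermTrainConfig = ShortTermTrainConfig(),
    clip_spec: ClipSpec = ClipSpec(),
    preprocess: PreprocessConfig = PreprocessConfig(),
) -> ShortTermModel:
    """Train the clip classifier with the per-second sampling scheme.

    Mini-batches are formed by repeatedly selecting a random training
    video and a random second within it; the anchor frame within the
    second is random during training.  When the training pool holds fewer
    than ``eval_every_samples`` seconds, validation runs once per epoch
    (one pass worth of samples) instead.
    """
    if not train_cases:
        raise ValueError("empty training set")
    if backbone.n_classes != N_PHASES:
        raise ValueError(f"backbone must have {N_PHASES} classes")
    rng = np.random.default_rng(config.seed)
    net = backbone.build(in_channels=3, rng=rng)
    opt = SGD(net.params, lr=config.lr_init, momentum=config.momentum)
    total_seconds = sum(c.length_s for c in train_cases)
    eval_every = config.eval_every_samples
    if total_seconds < config.eval_every_samples:
        eval_every = total_seconds  # small-dataset rule: validate every epoch
    model = ShortTermModel(net=net, clip_spec=clip_spec, preprocess=preprocess,
                           sdr_enabled=config.sdr_enabled, history=[])
    samples_seen = 0
    validations = 0
    since_eval = 0
    running_loss: list[float] = []
    while validations < config.stop_after_validations:
        vids = rng.integers(0, len(train_cases), size=config.batch_clips)
        clips, targets, sdrs = [], [], []
        for vi in vids:
            case = train_cases[int(vi)]
            s = int(rng.integers(0, case.length_s))
            anchor = int(rng.integers(0, clip_spec.fps))
            clip = _gather_clip(case.frames, s, anchor, case.length_s, clip_spec)
            clips.append(preprocess_clip(clip, train_mode=True, config=preprocess, rng=rng))
            targets.append(int(case.labels[s]))
            sdrs.append(compute_sdr(s, case.length_s))
        batch = np.stack(clips)
        sdr = np.asarray(sdrs) if config.sdr_enabled else None
        loss, grads = net.loss_and_grads(batch, np.asarray(targets), sdr=sdr)
        opt.lr = lr_at(validations, config)
        opt.step(grads)
        running_loss.append(loss)
        samples_seen += config.batch_clips
        since_eval += config.batch_clips
        if since_eval >= eval_every:
            since_eval = 0
            validations += 1
            val_acc = (
                _evaluate_cases(net, val_cases, clip_spec, preprocess, config.sdr_enabled,
                                rng=np.random.default_rng(config.seed + validations))
                if val_cases else float("nan")
            )
            model.history.append(
                {
                    "validation_iter": validations,
                    "samples_seen": samples_seen,
                    "lr": lr_at(validations, config),
                    "train_loss": float(np.mean(running_loss)),
                    "val_accuracy": val_acc,
                    "checkpoint": {k: v.copy() for k, v in net.params.items()},
                }
            )
            running_loss = []
    return model


def predict_probability_sequence(
    model: ShortTermModel, case: FrameCase, batch_seconds: int = 32
) -> ProbabilitySequence:
    """Emit the L x 7 per-second probability matrix for one video.

    Evaluation anchors at the middle frame of each second; rows are
    SoftMax outputs stacked in temporal order.
    """
    if model.net.n_classes != N_PHASES:
        raise ValueError(f"model must have {N_PHASES} classes")
    L = case.length_s
    if L < 1:
        raise ValueError("video must be at least 1 s long")
    spec = model.clip_spec
    anchor = spec.fps // 2
    rows = np.empty((L, N_PHASES))
    for start in range(0, L, batch_seconds):
        seconds = range(start, min(start + batch_seconds, L))
        clips = np.stack(
            [
                preprocess_clip(
                    _gather_clip(case.frames, s, anchor, L, spec),
                    train_mode=False, config=model.preprocess,
                )
                for s in seconds
            ]
        )
        sdr = (
            np.array([compute_sdr(s, L) for s in seconds]) if model.sdr_enabled else None
        )
        rows[list(seconds)] = model.net.predict_proba(clips, sdr=sdr)
    return ProbabilitySequence(video_id=case.video_id, rows=rows)


# ---------------------------------------------------------------------------
# Out-of-body trimming
# ---------------------------------------------------------------------------


def detect_out_of_body(
    frames: np.ndarray,
    classifier: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Classify per-second frames as in-body (True) or out-of-body (False).

    ``frames`` holds one representative frame per second, shape
    (L, H, W, 3).  The default heuristic marks a frame in-body when it is
    red-dominant and of intermediate brightness, which separates the
    endoscopic view from dark/grey out-of-body footage; a trained
    classifier can be plugged in instead.
    """
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError("frames must have shape (L, H, W, 3)")
    if classifier is not None:
        return np.asarray(classifier(frames), dtype=bool)
    x = frames.astype(np.float64)
    if frames.dtype != np.uint8 and x.max() <= 1.0:
        x = x * 255.0
    means = x.mean(axis=(1, 2))  # (L, 3)
    r, g, b = means[:, 0], means[:, 1], means[:, 2]
    brightness = means.mean(axis=1)
    red_dominant = (r > g + 5) & (r > b + 5)
    mid_brightness = (brightness > 30) & (brightness < 230)
    return red_dominant & mid_brightness


def trim_bounds(mask: np.ndarray) -> tuple[int, int]:
    """Longest contiguous in-body run as half-open second bounds."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 1 or mask.size == 0:
        raise ValueError("mask must be a non-empty 1-D boolean array")
    if not mask.any():
        raise ValueError("no in-body frames found in video")
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    best = int(np.argmax(ends - starts))
    return int(starts[best]), int(ends[best])
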