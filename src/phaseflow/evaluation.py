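"""Evaluation metrics for per-second phase predictions.

Per-second accuracy is the headline metric; because phases have very
uneven durations it is complemented by mean phase accuracy (unweighted
mean of per-phase recalls), the truth-by-prediction confusion matrix,
phase-transition accuracy at temporal thresholds, percentile subsetting
of per-video scores, and per-group (medical center / surgeon) boxplot
breakdowns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ontology import AnnotationTrack, CaseMetadata, N_PHASES, Segmentation

__all__ = [
    "ConfusionMatrix",
    "TransitionAccuracyTable",
    "VideoScore",
    "GroupStats",
    "DEFAULT_TAUS",
    "per_second_accuracy",
    "mean_phase_accuracy",
    "confusion_matrix",
    "row_normalize",
    "transition_offsets",
    "transition_accuracy",
    "percentile_filter",
    "group_accuracy",
]

#: Temporal thresholds (seconds) of the transition-accuracy table.
DEFAULT_TAUS: tuple[int, ...] = (15, 30, 45, 60, 90, 120, 150, 180, 270, 360)


@dataclass(frozen=True)
class ConfusionMatrix:
    """7x7 counts; rows are truth phases, columns are predicted phases."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_PHASES, N_PHASES) or c.min() < 0:
            raise ValueError(f"counts must be a non-negative {N_PHASES}x{N_PHASES} matrix")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TransitionAccuracyTable:
    """Percentage of phase starts predicted within +-tau seconds of truth."""

    taus: tuple[int, ...]
    percent_within: tuple[float, ...]
    n_phases_evaluated: int

    def __post_init__(self) -> None:
        if len(self.taus) != len(self.percent_within):
            raise ValueError("taus and percent_within must align")
        pw = self.percent_within
        if any(b < a - 1e-9 for a, b in zip(pw, pw[1:])):
            raise ValueError("percent_within must be non-decreasing in tau")


@dataclass(frozen=True)
class VideoScore:
    """Per-video accuracy with provenance metadata."""

    video_id: str
    accuracy: float
    meta: CaseMetadata = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if self.meta is None:
            object.__setattr__(self, "meta", CaseMetadata(video_id=self.video_id))


@dataclass(frozen=True)
class GroupStats:
    """Boxplot statistics of per-video accuracy within one group."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]


def _check_lengths(pred: AnnotationTrack, truth: AnnotationTrack) -> None:
    if pred.length_s != truth.length_s:
        raise ValueError(
            f"length mismatch for {truth.video_id}: "
            f"pred {pred.length_s}s vs truth {truth.length_s}s"
        )


def per_second_accuracy(pred: AnnotationTrack, truth: AnnotationTrack) -> float:
    """Fraction of seconds whose predicted phase matches the annotation."""
    _check_lengths(pred, truth)
    return float(np.mean(pred.labels == truth.labels))


def mean_phase_accuracy(pred: AnnotationTrack, truth: AnnotationTrack) -> float:
    """Unweighted mean of per-phase recalls over phases present in truth.

    Compensates for uneven phase durations; phases absent from the truth
    track are excluded (recall over empty support is undefined).
    """
    _check_lengths(pred, truth)
    recalls = []
    for p in range(N_PHASES):
        support = truth.labels == p
        if support.any():
            recalls.append(float(np.mean(pred.labels[support] == p)))
    return float(np.mean(recalls))


def confusion_matrix(
    pairs: Iterable[tuple[AnnotationTrack, AnnotationTrack]]
) -> ConfusionMatrix:
    """Tally truth-vs-predicted seconds over (pred, truth) track pairs."""
    counts = np.zeros((N_PHASES, N_PHASES), dtype=np.int64)
    for pred, truth in pairs:
        _check_lengths(pred, truth)
        np.add.at(counts, (truth.labels, pred.labels), 1)
    return ConfusionMatrix(counts=counts)


def row_normalize(cm: ConfusionMatrix) -> np.ndarray:
    """Per-truth-phase rates; the diagonal is each phase's recall.

    Rows with no truth seconds are left as zeros.
    """
    counts = cm.counts.astype(np.float64)
    sums = counts.sum(axis=1, keepdims=True)
    return np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)


def transition_offsets(
    pred: Segmentation, truth: Segmentation
) -> list[tuple[int, float]]:
    """Start-time offsets |pred_start - true_start| per truth phase.

    For each phase present in the truth segmentation, its true start is
    the start of its first segment and its predicted start the start of
    the phase's first segment in the prediction.  A phase absent from the
    prediction is a miss, recorded as an infinite offset (outside every
    finite threshold).
    """
    if pred.length_s != truth.length_s:
        raise ValueError(
            f"length mismatch for {truth.video_id}: "
            f"pred {pred.length_s}s vs truth {truth.length_s}s"
        )
    first_pred: dict[int, int] = {}
    for s in pred.segments:
        first_pred.setdefault(s.phase, s.start_s)
    offsets: list[tuple[int, float]] = []
    seen: set[int] = set()
    for s in truth.segments:
        if s.phase in seen:
            continue
        seen.add(s.phase)
        if s.phase in first_pred:
            offsets.append((s.phase, abs(first_pred[s.phase] - s.start_s)))
        else:
            offsets.append((s.phase, float("inf")))
    return offsets


def transition_accuracy(
    pairs: Sequence[tuple[Segmentation, Segmentation]] | Segmentation,
    truth: Segmentation | None = None,
    taus: Sequence[int] = DEFAULT_TAUS,
    per_video: bool = False,
) -> TransitionAccuracyTable:
    """Percentage of phase starts within +-tau of the true start.

    Accepts either a list of (pred, truth) segmentation pairs or one
    pred/truth pair directly.  By default all phase instances are pooled
    across videos; with ``per_video`` the per-video percentages are
    macro-averaged instead.
    """
    if isinstance(pairs, Segmentation):
        if not isinstance(truth, Segmentation):
            raise ValueError("a prediction segmentation needs a truth segmentation")
        pairs = [(pairs, truth)]
    elif isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(pairs[0], Segmentation):
        pairs = [pairs]  # a single (pred, truth) pair
    per_pair_offsets = [
        np.array([d for _, d in transition_offsets(p, t)]) for p, t in pairs
    ]
    if not per_pair_offsets or all(o.size == 0 for o in per_pair_offsets):
        raise ValueError("no truth phases to evaluate")
    taus = tuple(int(t) for t in taus)
    if per_video:
        percents = tuple(
            float(np.mean([np.mean(o <= t) * 100.0 for o in per_pair_offsets if o.size]))
            for t in taus
        )
    else:
        pooled = np.concatenate(per_pair_offsets)
        percents = tuple(float(np.mean(pooled <= t) * 100.0) for t in taus)
    n = int(sum(o.size for o in per_pair_offsets))
    return TransitionAccuracyTable(taus=taus, percent_within=percents, n_phases_evaluated=n)


def percentile_filter(scores: Sequence[VideoScore], percentile: float) -> list[VideoScore]:
    """Videos with accuracy strictly above the given accuracy percentile.

    Percentiles use linear interpolation of order statistics, so
    ``percentile=50`` keeps videos above the median.
    """
    if not scores:
        raise ValueError("empty score list")
    accs = np.array([s.accuracy for s in scores])
    cut = float(np.percentile(accs, percentile))
    return [s for s in scores if s.accuracy > cut]


def group_accuracy(
    scores: Sequence[VideoScore], key: str, min_n: int = 10
) -> dict[str, GroupStats]:
    """Boxplot statistics of per-video accuracy per metadata group.

    Only groups with more than ``min_n`` videos are reported.  Whiskers
    extend to the most extreme values within 1.5 IQR of the quartiles;
    values beyond are listed as outliers.
    """
    if key not in ("medical_center", "surgeon"):
        raise ValueError(f"unknown group key {key!r}")
    groups: dict[str, list[float]] = {}
    for s in scores:
        groups.setdefault(getattr(s.meta, key), []).append(s.accuracy)
    out: dict[str, GroupStats] = {}
    for g, vals in sorted(groups.items()):
        if len(vals) <= min_n:
            continue
        a = np.array(vals)
        q1, med, q3 = np.percentile(a, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = a[(a >= lo_fence) & (a <= hi_fence)]
        outliers = tuple(sorted(float(v) for v in a[(a < lo_fence) | (a > hi_fence)]))
        out[g] = GroupStats(
            n=len(vals), median=float(med), q1=float(q1), q3=float(q3),
            whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
            outliers=outliers,
        )
    return out
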