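"""Seeded synthetic phase-sequence data.

Real cholecystectomy videos are restricted, so this module generates the
two artifacts every downstream stage consumes: ground-truth per-second
phase tracks with the workflow's structural quirks (optional phases,
Dissection/Division alternation, Packaging-after-Final-inspection
reordering), and noisy per-second 7-way probability sequences emulating
the output of a trained clip classifier.

The emission model reproduces the three error types seen in clip
classifiers on this task: temporal shifts of phase boundaries, confusion
of temporally adjacent phases, and sporadic distant-phase errors, the
last optionally attenuated by the video-progress (SDR) feature.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .ontology import (
    N_PHASES,
    AnnotationTrack,
    CaseMetadata,
    PhaseSegment,
    Segmentation,
    segments_from_track,
    track_from_segments,
)
from .short_term import ProbabilitySequence

__all__ = [
    "EmissionConfig",
    "SimulationConfig",
    "SyntheticCase",
    "generate_truth_track",
    "emit_probability_sequence",
    "generate_dataset",
    "render_phase_frames",
    "PHASE_COLORS",
]

#: Per-phase duration (mean_s, sd_s) of the log-normal duration model.
#: Chosen to yield ~30-60 min procedures with Dissection and Separation
#: dominating, Adhesiolysis/Packaging short and often absent.
DEFAULT_DURATIONS: dict[int, tuple[float, float]] = {
    0: (180.0, 90.0),
    1: (240.0, 150.0),
    2: (900.0, 420.0),
    3: (240.0, 120.0),
    4: (600.0, 300.0),
    5: (180.0, 90.0),
    6: (240.0, 120.0),
}


@dataclass(frozen=True)
class EmissionConfig:
    """Noise model for per-second classifier probability rows.

    adjacent_confusion
        Probability mass leaked from the true phase to its temporally
        adjacent phase ids.
    distant_error_rate
        Per-second probability that the row is centred on a distant
        (non-adjacent) phase instead of the true one.
    sdr_attenuation
        When on, distant error phases are drawn preferentially near the
        current video progress, mimicking the suppression of
        progress-inconsistent errors by the SDR feature.
    boundary_jitter_sd_s
        Gaussian sd (seconds) of the shift applied to each emitted phase
        transition.
    boundary_shift_mean_s
        Mean of that Gaussian: a systematic temporal bias of emitted
        transitions (positive = the classifier flags transitions late), as
        opposed to the zero-mean jitter.
    concentration
        Dirichlet sharpness of each probability row; ``np.inf`` gives the
        deterministic noiseless limit.
    overconfidence
        Exponent applied to each Dirichlet draw (then renormalized).
        Dirichlet rows are roughly calibrated, whereas softmax outputs of
        trained deep networks are sharply overconfident, with
        log-probability margins of tens of nats between the predicted and
        the competing phases; the exponent reproduces that sharpness.  It
        is a monotone per-row transform, so per-second argmax accuracy is
        unaffected, but the behaviour of temperature sampling (which
        divides log-probabilities by T) depends directly on it.
    """

    adjacent_confusion: float = 0.2
    distant_error_rate: float = 0.03
    sdr_attenuation: bool = True
    boundary_jitter_sd_s: float = 3.0
    boundary_shift_mean_s: float = 0.0
    concentration: float = 15.0
    overconfidence: float = 8.0

    def __post_init__(self) -> None:
        for name in ("adjacent_confusion", "distant_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.boundary_jitter_sd_s < 0:
            raise ValueError("boundary_jitter_sd_s must be >= 0")
        if not self.concentration > 0:
            raise ValueError("concentration must be > 0")
        if not self.overconfidence > 0:
            raise ValueError("overconfidence must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_videos: int = 100
    durations: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DURATIONS)
    )
    p_skip_phase0: float = 0.1
    p_skip_phase1: float = 0.5
    p_skip_phase5: float = 0.15
    p_alternate_23: float = 0.2
    p_reorder_56: float = 0.1
    emission: EmissionConfig = field(default_factory=EmissionConfig)
    n_centers: int = 6
    n_surgeons: int = 12
    center_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_skip_phase0", "p_skip_phase1", "p_skip_phase5",
                     "p_alternate_23", "p_reorder_56"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if set(self.durations) != set(range(N_PHASES)):
            raise ValueError("durations must cover phase ids 0..6")
        for pid, (m, s) in self.durations.items():
            if m <= 0 or s <= 0:
                raise ValueError(f"phase {pid}: duration mean/sd must be positive")
        if self.n_centers < 1 or self.n_surgeons < 1:
            raise ValueError("n_centers and n_surgeons must be >= 1")
        if self.center_weights is not None and len(self.center_weights) != self.n_centers:
            raise ValueError("center_weights length must equal n_centers")

    def scaled(self, factor: float) -> "SimulationConfig":
        """Return a copy with all phase durations scaled by ``factor``.

        Used for desk-scale runs where full-length procedures would be
        needlessly slow; the structure of the tracks is unchanged.
        """
        durations = {p: (m * factor, s * factor) for p, (m, s) in self.durations.items()}
        return replace(self, durations=durations)


@dataclass(frozen=True)
class SyntheticCase:
    """One simulated video: truth track, emitted probabilities, metadata."""

    truth: AnnotationTrack
    probs: ProbabilitySequence
    meta: CaseMetadata

    def __post_init__(self) -> None:
        if self.probs.rows.shape[0] != self.truth.length_s:
            raise ValueError(
                f"{self.truth.video_id}: probability rows ({self.probs.rows.shape[0]}) "
                f"do not match track length ({self.truth.length_s})"
            )


def _lognormal_duration(mean: float, sd: float, rng: np.random.Generator) -> int:
    # method-of-moments parameterization of the log-normal
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return max(1, int(round(rng.lognormal(mu, np.sqrt(sigma2)))))


def generate_truth_track(
    config: SimulationConfig, rng: np.random.Generator, video_id: str = "video0000"
) -> AnnotationTrack:
    """Draw one ground-truth phase track.

    Base order is 0..6.  Preparation, Adhesiolysis and Packaging are
    independently skipped with their configured probabilities; with
    probability ``p_alternate_23`` a short Dissection/Division
    back-and-forth is inserted after Division; with probability
    ``p_reorder_56`` Packaging moves after Final inspection.  Phases 2, 3,
    4 and 6 are always present.  Durations are log-normal, rounded to at
    least one second.
    """
    order: list[int] = [0, 1, 2, 3, 4, 5, 6]
    if rng.random() < config.p_skip_phase0:
        order.remove(0)
    if rng.random() < config.p_skip_phase1:
        order.remove(1)
    skip5 = rng.random() < config.p_skip_phase5
    if skip5:
        order.remove(5)
    elif rng.random() < config.p_reorder_56:
        order.remove(5)
        order.append(5)  # gallbladder packed only at the very end
    alternate = rng.random() < config.p_alternate_23

    labels: list[np.ndarray] = []
    for pid in order:
        m, s = config.durations[pid]
        dur = _lognormal_duration(m, s, rng)
        labels.append(np.full(dur, pid, dtype=np.int64))
        if pid == 3 and alternate:
            # brief return to Dissection before completing Division
            for extra in (2, 3):
                em, es = config.durations[extra]
                dur = _lognormal_duration(0.3 * em, 0.3 * es, rng)
                labels.append(np.full(dur, extra, dtype=np.int64))
    return AnnotationTrack(video_id=video_id, labels=np.concatenate(labels))


def _jitter_boundaries(
    track: AnnotationTrack, sd: float, rng: np.random.Generator, mean: float = 0.0
) -> AnnotationTrack:
    """Shift each phase transition by a rounded Gaussian offset."""
    if sd == 0 and mean == 0:
        return track
    seg = segments_from_track(track)
    L = track.length_s
    bounds = [s.start_s for s in seg.segments[1:]]
    jittered: list[int] = []
    lo = 1
    n_rest = len(bounds)
    for b in bounds:
        n_rest -= 1
        hi = L - 1 - n_rest
        bj = int(np.clip(int(round(b + rng.normal(mean, sd))), lo, hi))
        jittered.append(bj)
        lo = bj + 1
    phases = [s.phase for s in seg.segments]
    edges = [0] + jittered + [L]
    segs = []
    for p, s, e in zip(phases, edges[:-1], edges[1:]):
        if segs and segs[-1][0] == p:
            segs[-1] = (p, segs[-1][1], e)
        else:
            segs.append((p, s, e))
    return track_from_segments(
        Segmentation(
            video_id=track.video_id,
            segments=tuple(PhaseSegment(p, s, e) for p, s, e in segs),
        )
    )


def _distant_phase(
    true_phase: int, sdr: float, attenuate: bool, rng: np.random.Generator
) -> int:
    candidates = np.array(
        [p for p in range(N_PHASES) if abs(p - true_phase) >= 2], dtype=np.int64
    )
    if attenuate:
        # errors inconsistent with current progress are suppressed
        centers = (candidates + 0.5) / N_PHASES
        w = np.exp(-((sdr - centers) ** 2) / (2 * 0.15**2))
        w = w / w.sum() if w.sum() > 0 else np.full(candidates.size, 1.0 / candidates.size)
    else:
        w = np.full(candidates.size, 1.0 / candidates.size)
    return int(rng.choice(candidates, p=w))


def emit_probability_sequence(
    truth: AnnotationTrack, config: EmissionConfig, rng: np.random.Generator
) -> ProbabilitySequence:
    """Emulate per-second probability rows from a clip classifier.

    Each row is centred on the (boundary-jittered) true phase with
    ``adjacent_confusion`` mass leaked to phase ids +-1; with probability
    ``distant_error_rate`` the row is instead centred on a distant phase.
    Rows are Dirichlet draws with the configured concentration and always
    sum to 1.
    """
    jittered = _jitter_boundaries(truth, config.boundary_jitter_sd_s, rng,
                                  mean=config.boundary_shift_mean_s)
    L = truth.length_s
    rows = np.empty((L, N_PHASES))
    alpha_floor = 0.02
    for t in range(L):
        p = int(jittered.labels[t])
        center = p
        if config.distant_error_rate > 0 and rng.random() < config.distant_error_rate:
            center = _distant_phase(p, t / L, config.sdr_attenuation, rng)
        m = np.zeros(N_PHASES)
        neighbors = [q for q in (center - 1, center + 1) if 0 <= q < N_PHASES]
        m[center] = 1.0 - config.adjacent_confusion
        for q in neighbors:
            m[q] = config.adjacent_confusion / len(neighbors)
        if np.isinf(config.concentration):
            rows[t] = m if m.sum() > 0 else np.full(N_PHASES, 1.0 / N_PHASES)
        else:
            d = rng.dirichlet(config.concentration * m + alpha_floor)
            d = np.clip(d, 1e-30, None) ** config.overconfidence
            rows[t] = d / d.sum()
    return ProbabilitySequence(video_id=truth.video_id, rows=rows)


def _assign_groups(
    n: int,
    n_groups: int,
    weights: tuple[float, ...] | None,
    rng: np.random.Generator,
    prefix: str,
) -> list[str]:
    """Round-robin with 10% random reassignment, or weighted draws."""
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        idx = rng.choice(n_groups, size=n, p=w / w.sum())
    else:
        idx = np.arange(n) % n_groups
        flip = rng.random(n) < 0.1
        idx = np.where(flip, rng.integers(0, n_groups, size=n), idx)
    return [f"{prefix}{int(i) + 1}" for i in idx]


def generate_dataset(config: SimulationConfig) -> list[SyntheticCase]:
    """Generate a full synthetic dataset, deterministic under the seed."""
    if config.n_videos < 1:
        raise ValueError("n_videos must be >= 1")
    rng = np.random.default_rng(config.seed)
    centers = _assign_groups(config.n_videos, config.n_centers, config.center_weights, rng, "MC")
    surgeons = _assign_groups(config.n_videos, config.n_surgeons, None, rng, "surgeon")
    cases = []
    for i in range(config.n_videos):
        vid = f"video{i:04d}"
        truth = generate_truth_track(config, rng, video_id=vid)
        probs = emit_probability_sequence(truth, config.emission, rng)
        meta = CaseMetadata(video_id=vid, medical_center=centers[i], surgeon=surgeons[i])
        cases.append(SyntheticCase(truth=truth, probs=probs, meta=meta))
    return cases


# ---------------------------------------------------------------------------
# Toy frame rendering for the clip-classifier path
# ---------------------------------------------------------------------------

#: Distinct RGB anchors (uint8) for the seven phases; body-cavity reds and
#: oranges dominate, as in laparoscopic footage.
PHASE_COLORS: np.ndarray = np.array(
    [
        [150, 40, 40],
        [180, 90, 40],
        [200, 60, 90],
        [120, 60, 140],
        [200, 140, 60],
        [90, 120, 170],
        [170, 170, 80],
    ],
    dtype=np.uint8,
)


def render_phase_frames(
    track: AnnotationTrack,
    fps: int = 25,
    size: tuple[int, int] = (24, 24),
    noise_sd: float = 10.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render synthetic color-coded frames for a track (test stand-in).

    Produces a (L*fps, H, W, 3) uint8 array in which every frame of a
    second is the phase's anchor color plus pixel noise.  This is a
    deliberately crude synthetic stand-in that makes phases visually
    separable so the clip-classifier path can be trained and evaluated
    without real videos; it does not attempt to emulate surgical imagery.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    H, W = size
    per_frame = np.repeat(track.labels, fps)
    frames = PHASE_COLORS[per_frame][:, None, None, :].astype(np.float64)
    frames = np.broadcast_to(frames, (per_frame.size, H, W, 3)).copy()
    frames += rng.normal(0.0, noise_sd, size=frames.shape)
    return np.clip(frames, 0, 255).astype(np.uint8)
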