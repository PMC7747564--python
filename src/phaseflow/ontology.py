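"""Phase vocabulary and per-second annotation data model.

Laparoscopic cholecystectomy workflow is described with seven phases, one
label per second of video.  Phases follow a typical order (Preparation,
Adhesiolysis, Dissection, Division, Separation, Packaging, Final
inspection) but the order may vary: Adhesiolysis and Packaging are
optional, Packaging can follow Final inspection, and the surgeon may
alternate between Dissection and Division.

Time is handled at 1-second resolution, 0-based, with half-open
``[start_s, end_s)`` segments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASE_NAMES",
    "N_PHASES",
    "phase_name",
    "phase_id",
    "AnnotationTrack",
    "PhaseSegment",
    "Segmentation",
    "CaseMetadata",
    "segments_from_track",
    "track_from_segments",
    "read_annotations",
    "write_annotations",
    "read_segmentations_json",
    "write_segmentations_json",
]

#: The seven workflow phases, indexed by phase id 0..6.
PHASE_NAMES: tuple[str, ...] = (
    "Preparation",
    "Adhesiolysis",
    "Dissection",
    "Division",
    "Separation",
    "Packaging",
    "Final inspection",
)

N_PHASES: int = len(PHASE_NAMES)

_NAME_TO_ID = {name: i for i, name in enumerate(PHASE_NAMES)}


def phase_name(pid: int) -> str:
    """Return the canonical name of a phase id."""
    if not 0 <= int(pid) < N_PHASES:
        raise ValueError(f"phase id must be in 0..{N_PHASES - 1}, got {pid}")
    return PHASE_NAMES[int(pid)]


def phase_id(name: str) -> int:
    """Return the phase id for a canonical phase name."""
    try:
        return _NAME_TO_ID[name]
    except KeyError:
        raise ValueError(f"unknown phase name {name!r}") from None


@dataclass(frozen=True)
class AnnotationTrack:
    """Per-second ground-truth phase labels for one video.

    ``labels[t]`` is the phase id of second ``t``; every second of the
    video carries exactly one label.
    """

    video_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError(f"{self.video_id}: labels must be a non-empty 1-D sequence")
        if labels.min() < 0 or labels.max() >= N_PHASES:
            raise ValueError(f"{self.video_id}: labels must lie in 0..{N_PHASES - 1}")
        object.__setattr__(self, "labels", labels)

    @property
    def length_s(self) -> int:
        return int(self.labels.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTrack):
            return NotImplemented
        return self.video_id == other.video_id and np.array_equal(self.labels, other.labels)

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.video_id, self.labels.tobytes()))


@dataclass(frozen=True)
class PhaseSegment:
    """A maximal run of one phase, as a half-open interval of seconds."""

    phase: int
    start_s: int
    end_s: int

    def __post_init__(self) -> None:
        if not 0 <= self.phase < N_PHASES:
            raise ValueError(f"phase id {self.phase} out of range")
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(f"invalid segment bounds [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Segmentation:
    """Ordered contiguous phase segments covering one video."""

    video_id: str
    segments: tuple[PhaseSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ValueError(f"{self.video_id}: segmentation must contain >= 1 segment")
        if segs[0].start_s != 0:
            raise ValueError(f"{self.video_id}: first segment must start at 0")
        for prev, cur in zip(segs, segs[1:]):
            if cur.start_s != prev.end_s:
                raise ValueError(
                    f"{self.video_id}: gap or overlap between seconds "
                    f"{prev.end_s} and {cur.start_s}"
                )
            if cur.phase == prev.phase:
                raise ValueError(f"{self.video_id}: adjacent segments share phase {cur.phase}")
        object.__setattr__(self, "segments", segs)

    @property
    def length_s(self) -> int:
        return self.segments[-1].end_s


@dataclass(frozen=True)
class CaseMetadata:
    """Provenance of one video; unknown groups use the literal "unknown"."""

    video_id: str
    medical_center: str = "unknown"
    surgeon: str = "unknown"


def segments_from_track(track: AnnotationTrack) -> Segmentation:
    """Run-length encode a per-second track into contiguous phase segments.

    Inverse of :func:`track_from_segments`; a phase that recurs (e.g.
    Packaging after Final inspection) yields multiple segments.
    """
    labels = track.labels
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [labels.size]))
    segs = tuple(
        PhaseSegment(phase=int(labels[s]), start_s=int(s), end_s=int(e))
        for s, e in zip(starts, ends)
    )
    return Segmentation(video_id=track.video_id, segments=segs)


def track_from_segments(seg: Segmentation) -> AnnotationTrack:
    """Expand contiguous phase segments back into a per-second track."""
    labels = np.empty(seg.length_s, dtype=np.int64)
    for s in seg.segments:
        labels[s.start_s : s.end_s] = s.phase
    return AnnotationTrack(video_id=seg.video_id, labels=labels)


# ---------------------------------------------------------------------------
# Annotation I/O
#
# CSV format: header `video_id,second,phase_id`, one row per second, seconds
# dense 0..L-1 per video.  JSON variant stores run-length segments.
# ---------------------------------------------------------------------------


def write_annotations(tracks: Iterable[AnnotationTrack], path: str | Path) -> None:
    """Write tracks to a per-second annotation CSV."""
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "video_id": t.video_id,
                    "second": np.arange(t.length_s),
                    "phase_id": t.labels,
                }
            )
        )
    if not frames:
        raise ValueError("no tracks to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[AnnotationTrack]:
    """Read per-second annotation CSV, validating label range and coverage."""
    df = pd.read_csv(path, dtype={"video_id": str, "second": np.int64, "phase_id": np.int64})
    required = {"video_id", "second", "phase_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    bad = df.index[(df["phase_id"] < 0) | (df["phase_id"] >= N_PHASES)]
    if len(bad):
        # +2: 1-based line numbers plus header row
        raise ValueError(f"{path}: phase_id out of 0..{N_PHASES - 1} at line {bad[0] + 2}")
    tracks = []
    for vid, group in df.groupby("video_id", sort=False):
        seconds = group["second"].to_numpy()
        order = np.argsort(seconds)
        seconds = seconds[order]
        if not np.array_equal(seconds, np.arange(seconds.size)):
            raise ValueError(f"{path}: video {vid} does not densely cover seconds 0..L-1")
        tracks.append(AnnotationTrack(video_id=str(vid), labels=group["phase_id"].to_numpy()[order]))
    return tracks


def write_segmentations_json(segs: Iterable[Segmentation], path: str | Path) -> None:
    payload = [
        {
            "video_id": s.video_id,
            "length_s": s.length_s,
            "segments": [
                {"phase": seg.phase, "start": seg.start_s, "end": seg.end_s}
                for seg in s.segments
            ],
        }
        for s in segs
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_segmentations_json(path: str | Path) -> list[Segmentation]:
    payload = json.loads(Path(path).read_text())
    out = []
    for entry in payload:
        segs = tuple(
            PhaseSegment(phase=d["phase"], start_s=d["start"], end_s=d["end"])
            for d in entry["segments"]
        )
        s = Segmentation(video_id=entry["video_id"], segments=segs)
        if s.length_s != entry["length_s"]:
            raise ValueError(f"{entry['video_id']}: stored length_s disagrees with segments")
        out.append(s)
    return out
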