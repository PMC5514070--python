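"""Segmentation of a pen trace into strokes, words and letters.

A *stroke* is a maximal run of pen-down samples (pressure above threshold).
Strokes shorter than the artifact threshold (40 ms) are dropped.  Strokes
separated by an in-air gap of at most 5 s belong to the same word; a longer
detachment ends the word.  Within a word, letter boundaries fall at local
minima of the (smoothed) speed profile — the natural slow points of the pen
in the transitions between letters — for cursive writing, or at pen lifts
for block capitals where each letter is a separate stroke cluster.

Automatic boundaries can be replaced per trial by an annotation-override
file, the programmatic analogue of an experimenter's manual correction.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import SmoothingConfig, SpeedSeries, path_length
from .trace_io import Trace


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentationParams:
    pen_down_threshold: float = 0.0      # strict >: pressure 0 is pen-up
    max_gap: float = 5.0                 # s; longer in-air detachment ends a word
    min_segment_duration: float = 0.040  # s; shorter pen-down runs are artifacts
    letter_min_duration: float = 0.050   # s; guard against degenerate letters
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)

    def __post_init__(self):
        if not (self.min_segment_duration > 0 and self.letter_min_duration > 0):
            raise ValueError("durations must be positive")
        if not self.max_gap > self.min_segment_duration:
            raise ValueError("max_gap must exceed min_segment_duration")


@dataclass(frozen=True)
class Stroke:
    """A maximal pen-down run: inclusive sample span plus its duration/length."""

    trace_ref: str
    start_idx: int
    end_idx: int
    duration: float      # s
    path_length: float   # cm


@dataclass(frozen=True)
class LetterSegment:
    """One letter's inclusive sample span; duration counts pen-down time only."""

    label: str
    start_idx: int
    end_idx: int
    duration: float
    source: str = "auto"    # "auto" | "override"


def extract_strokes(trace: Trace,
                    params: SegmentationParams = SegmentationParams()) -> list[Stroke]:
    """Maximal runs of pressure > threshold, dropping sub-40 ms artifacts."""
    down = trace.pressure > params.pen_down_threshold
    if not down.any():
        warnings.warn(f"trace {trace.meta.trial_id!r} has no pen-down sample")
        return []
    padded = np.concatenate(([False], down, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2] - 1   # inclusive spans
    strokes = []
    for s, e in zip(starts, stops):
        duration = trace.t[e] - trace.t[s]
        # tolerance keeps exactly-threshold runs despite float subtraction
        if duration < params.min_segment_duration - 1e-9:
            continue
        strokes.append(Stroke(
            trace_ref=trace.meta.trial_id,
            start_idx=int(s), end_idx=int(e),
            duration=float(duration),
            path_length=path_length(trace, int(s), int(e)),
        ))
    return strokes


def group_words(strokes: list[Stroke], trace: Trace,
                params: SegmentationParams = SegmentationParams()) -> list[list[Stroke]]:
    """Group time-ordered strokes into words at in-air gaps > max_gap."""
    if not strokes:
        return []
    groups: list[list[Stroke]] = [[strokes[0]]]
    for prev, cur in zip(strokes, strokes[1:]):
        gap = trace.t[cur.start_idx] - trace.t[prev.end_idx]
        if gap > params.max_gap + 1e-9:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    return groups


def _pen_down_duration(trace: Trace, strokes: list[Stroke],
                       start: int, end: int) -> float:
    """Pen-down time over sample intervals [j, j+1] with start <= j < end,
    counting an interval when it lies inside a stroke."""
    total = 0.0
    for s in strokes:
        lo = max(start, s.start_idx)
        hi = min(end, s.end_idx)
        if hi > lo:
            total += trace.t[hi] - trace.t[lo]
    return total


def _local_minima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local minima (both neighbours strictly larger)."""
    v = values
    idx = np.flatnonzero((v[1:-1] < v[:-2]) & (v[1:-1] < v[2:])) + 1
    return idx


def _cursive_boundaries(word_group, trace, n_letters, speed, params):
    """Pick n_letters-1 boundary samples at the lowest in-stroke speed
    minima, subject to each resulting letter lasting >= letter_min_duration;
    ties broken by earlier time."""
    candidates = []
    for s in word_group:
        seg = speed.values[s.start_idx:s.end_idx + 1]
        for i in _local_minima(seg):
            candidates.append((float(seg[i]), s.start_idx + int(i)))
    candidates.sort(key=lambda c: (c[0], c[1]))

    start = word_group[0].start_idx
    end = word_group[-1].end_idx
    chosen: list[int] = []

    def feasible(b):
        pts = sorted(chosen + [b])
        edges = [start] + pts + [end]
        return all(
            _pen_down_duration(trace, word_group, a, z) >= params.letter_min_duration
            for a, z in zip(edges, edges[1:]))

    for _, b in candidates:
        if len(chosen) == n_letters - 1:
            break
        if feasible(b):
            chosen.append(b)
    if len(chosen) < n_letters - 1:
        raise SegmentationError(
            f"trace {trace.meta.trial_id!r}: found {len(chosen)} qualifying "
            f"speed minima but need {n_letters - 1}; supply a boundary "
            f"override for this trial")
    return sorted(chosen)


def _block_boundaries(word_group, trace, n_letters):
    """Cluster strokes into n_letters temporal clusters by cutting the
    n_letters-1 largest inter-stroke gaps; boundary = first sample of the
    stroke that opens each new cluster."""
    gaps = [trace.t[b.start_idx] - trace.t[a.end_idx]
            for a, b in zip(word_group, word_group[1:])]
    order = np.argsort(gaps)[::-1][:n_letters - 1]
    return sorted(word_group[int(i) + 1].start_idx for i in order)


def segment_letters(
    word_group: list[Stroke],
    trace: Trace,
    n_letters: int,
    speed: SpeedSeries,
    params: SegmentationParams = SegmentationParams(),
    overrides: list[int] | None = None,
) -> list[LetterSegment]:
    """Split a word group into n_letters letter segments.

    Block path (>= n_letters strokes): strokes are clustered into letters
    at the largest pen-lift gaps.  Cursive path (fewer strokes than
    letters): boundaries at speed minima inside the strokes.  ``overrides``
    (boundary sample indices, length n_letters-1) replaces the automatic
    boundaries and marks the output ``source="override"``.

    Letter spans are inclusive and consecutive; the boundary sample starts
    the next letter.  Durations count pen-down time only and partition the
    word's pen-down duration exactly.
    """
    if n_letters < 1:
        raise SegmentationError("n_letters must be >= 1")
    if not word_group:
        raise SegmentationError("empty word group")
    start = word_group[0].start_idx
    end = word_group[-1].end_idx
    if end - start + 1 < 2 * n_letters:
        raise SegmentationError(
            f"word span has {end - start + 1} samples, fewer than "
            f"2*{n_letters}")

    source = "auto"
    if overrides is not None:
        boundaries = sorted(int(b) for b in overrides)
        if len(boundaries) != n_letters - 1:
            raise SegmentationError(
                f"override supplies {len(boundaries)} boundaries, "
                f"need {n_letters - 1}")
        if boundaries and not (start < boundaries[0] and boundaries[-1] <= end):
            raise SegmentationError("override boundary outside word span")
        source = "override"
    elif n_letters == 1:
        boundaries = []
    elif len(word_group) >= n_letters:
        boundaries = _block_boundaries(word_group, trace, n_letters)
    else:
        boundaries = _cursive_boundaries(word_group, trace, n_letters,
                                         speed, params)

    word = trace.meta.word
    labels = list(word) if len(word) == n_letters else [
        str(i) for i in range(n_letters)]
    edges = [start] + boundaries + [end + 1]
    segments = []
    for label, a, b in zip(labels, edges, edges[1:]):
        dur = _pen_down_duration(trace, word_group, a, min(b, end))
        segments.append(LetterSegment(
            label=label, start_idx=int(a), end_idx=int(b - 1),
            duration=float(dur), source=source))
    return segments


def read_overrides(path: str | os.PathLike) -> dict[str, list[int]]:
    """Read a boundary-override CSV (trial_id, letter_index, boundary_sample_index)
    into {trial_id: sorted boundary indices}."""
    df = pd.read_csv(path, dtype={"trial_id": str})
    needed = {"trial_id", "letter_index", "boundary_sample_index"}
    if not needed.issubset(df.columns):
        raise SegmentationError(
            f"override file {path} must have columns {sorted(needed)}")
    out: dict[str, list[int]] = {}
    for tid, grp in df.groupby("trial_id"):
        out[str(tid)] = (grp.sort_values("letter_index")
                         ["boundary_sample_index"].astype(int).tolist())
    return out


__all__ = [
    "SegmentationParams", "Stroke", "LetterSegment", "SegmentationError",
    "extract_strokes", "group_words", "segment_letters", "read_overrides",
]
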