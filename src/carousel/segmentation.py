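"""Two-stage trajectory segmentation.

Stage 1 splits each session at shock-sector entries/exits: a segment starts
at the first sample after leaving the sector and ends at the last sample
before the next entrance, so segments contain only out-of-sector samples.

Stage 2 (*subsegmentation*) splits stage-1 segments at abrupt changes of
angular speed.  The scan processes a segment sample by sample; once a
growing subsegment is older than a 1 s warm-up its running median angular
speed is defined, and a sample whose local angular speed deviates from that
median by more than the cut-off (default 0.6 rad/s) terminates the
subsegment and starts a fresh one.  Subsegments shorter than 5 s are
discarded.  The cut-off itself can be derived from the data with
:func:`estimate_cutoff` (boxplot upper-outlier rule applied twice).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .io import ArenaConfig, Segment, Trajectory, in_sector, to_arena_frame

__all__ = [
    "SegmentationParams",
    "SegmentationStats",
    "CutoffEstimate",
    "segment_by_sector",
    "local_angular_speed",
    "subsegment",
    "estimate_cutoff",
    "cutoff_from_differences",
    "segmentation_stats",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the stage-2 angular-speed split rule.

    ``angular_speed_cutoff`` defaults to 0.6 rad/s (0.5 and 0.55 are the
    standard sensitivity alternates); the running median becomes active
    after ``warmup`` seconds; candidates shorter than
    ``min_subsegment_duration`` are dropped; ``smoothing_window`` is a
    centred moving average (odd number of samples, 1 disables) applied to
    the angular-speed series before thresholding.
    """

    angular_speed_cutoff: float = 0.6
    warmup: float = 1.0
    min_subsegment_duration: float = 5.0
    smoothing_window: int = 5

    def __post_init__(self):
        if self.angular_speed_cutoff <= 0:
            raise ValueError("angular_speed_cutoff must be positive")
        if self.warmup <= 0:
            raise ValueError("warmup must be positive")
        if self.min_subsegment_duration <= self.warmup:
            raise ValueError("min_subsegment_duration must exceed warmup")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")


@dataclass
class SegmentationStats:
    """Summary of a segmentation step (lengths in the arena frame, cm)."""

    n_segments: int
    median_length: float
    min_length: float
    max_length: float
    relative_length: float  # % of the input length retained


@dataclass
class CutoffEstimate:
    """Diagnostics of the data-driven cut-off derivation.

    ``outlier_threshold`` is Q3 + 1.5*IQR of all |median - local| angular
    speed differences; ``q1_outliers``/``q3_outliers`` are the quartiles of
    the upper-outlier subsample; ``suggested_cutoff`` is their midpoint
    rounded to 0.05 rad/s.  ``degenerate`` is set when no upper outliers
    exist (e.g. all differences equal).
    """

    outlier_threshold: float
    q1_outliers: float | None
    q3_outliers: float | None
    suggested_cutoff: float | None
    differences: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Stage 1: shock-sector segmentation
# ---------------------------------------------------------------------------

def segment_by_sector(traj: Trajectory, config: ArenaConfig,
                      min_duration: float = 5.0,
                      max_gap_intervals: float = 3.0) -> list[Segment]:
    """Split a session into maximal runs of out-of-sector samples.

    Tracking gaps longer than ``max_gap_intervals`` sampling intervals break
    contiguity and force a segment boundary.  Runs shorter than
    ``min_duration`` seconds are discarded (pass 0 to keep everything).
    """
    n = len(traj)
    if n == 0:
        return []
    outside = ~in_sector(traj.x, traj.y, config)
    # break contiguity at sector samples and at tracking gaps
    gap_after = np.zeros(n, dtype=bool)
    if n > 1:
        gap_after[:-1] = np.diff(traj.t) > max_gap_intervals / config.sampling_rate

    segments: list[Segment] = []
    i = 0
    while i < n:
        if not outside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and outside[j + 1] and not gap_after[j]:
            j += 1
        seg = Segment(traj, i, j, config, stage=1)
        if seg.duration >= min_duration:
            segments.append(seg)
        i = j + 1
    return segments


# ---------------------------------------------------------------------------
# Angular speed
# ---------------------------------------------------------------------------

def _smooth(series: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(series) < 2:
        return series
    w = min(window, len(series) - (1 - len(series) % 2))
    if w <= 1:
        return series
    pad = w // 2
    padded = np.pad(series, pad, mode="edge")
    kernel = np.ones(w) / w
    return np.convolve(padded, kernel, mode="valid")


def unwrapped_angle(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unwrapped polar angle of a path; centre samples inherit the previous
    valid angle (angle undefined at the origin)."""
    r = np.hypot(x, y)
    phi = np.arctan2(y, x)
    bad = r < 1e-9
    if bad.any():
        idx = np.where(~bad, np.arange(len(phi)), -1)
        np.maximum.accumulate(idx, out=idx)
        first = np.argmax(~bad) if (~bad).any() else 0
        idx[idx < 0] = first
        phi = phi[idx]
    return np.unwrap(phi)


def local_angular_speed(seg: Segment, params: SegmentationParams | None = None) -> np.ndarray:
    """Per-sample angular speed (rad/s, magnitude) about the arena centre,
    in the arena frame, from finite differences of the unwrapped angle."""
    params = params or SegmentationParams()
    x, y = seg.xy_arena()
    t = seg.t
    if len(t) < 2:
        raise ValueError("segment needs at least 2 samples")
    phi = unwrapped_angle(x, y)
    omega = np.abs(np.gradient(phi, t))
    return _smooth(omega, params.smoothing_window)


# ---------------------------------------------------------------------------
# Stage 2: running-median subsegmentation
# ---------------------------------------------------------------------------

class _RunningMedian:
    """Insert-only running median via two heaps."""

    __slots__ = ("lo", "hi")

    def __init__(self):
        self.lo: list[float] = []  # max-heap (negated)
        self.hi: list[float] = []  # min-heap

    def add(self, v: float) -> None:
        if self.lo and v > -self.lo[0]:
            heapq.heappush(self.hi, v)
        else:
            heapq.heappush(self.lo, -v)
        if len(self.lo) > len(self.hi) + 1:
            heapq.heappush(self.hi, -heapq.heappop(self.lo))
        elif len(self.hi) > len(self.lo):
            heapq.heappush(self.lo, -heapq.heappop(self.hi))

    def median(self) -> float:
        if len(self.lo) > len(self.hi):
            return -self.lo[0]
        return 0.5 * (-self.lo[0] + self.hi[0])


def split_points(omega: np.ndarray, t: np.ndarray, cutoff: float, warmup: float,
                 collect_differences: bool = False):
    """Sequential running-median scan.

    Returns the list of candidate ``(start, end)`` index pairs (inclusive,
    local to the input arrays) and, optionally, the sample of
    |running median - local| differences evaluated after each warm-up.
    """
    n = len(omega)
    bounds: list[tuple[int, int]] = []
    diffs: list[float] = [] if collect_differences else None
    i0 = 0
    rm = _RunningMedian()
    for i in range(n):
        if i > i0 and (t[i - 1] - t[i0]) > warmup:
            d = abs(omega[i] - rm.median())
            if collect_differences:
                diffs.append(d)
            if d > cutoff:
                bounds.append((i0, i - 1))
                i0 = i
                rm = _RunningMedian()
        rm.add(omega[i])
    bounds.append((i0, n - 1))
    if collect_differences:
        return bounds, np.asarray(diffs)
    return bounds


def subsegment(seg: Segment, params: SegmentationParams | None = None) -> list[Segment]:
    """Stage-2 split of a stage-1 segment at abrupt angular-speed changes."""
    params = params or SegmentationParams()
    if len(seg) < 2:
        return []
    omega = local_angular_speed(seg, params)
    bounds = split_points(omega, seg.t, params.angular_speed_cutoff, params.warmup)
    out = []
    for i0, i1 in bounds:
        sub = Segment(seg.trajectory, seg.start + i0, seg.start + i1, seg.config, stage=2)
        if sub.duration >= params.min_subsegment_duration:
            out.append(sub)
    return out


def subsegment_all(segments: list[Segment], params: SegmentationParams | None = None) -> list[Segment]:
    """Stage-2 segmentation of a list of stage-1 segments."""
    out: list[Segment] = []
    for seg in segments:
        out.extend(subsegment(seg, params))
    return out


# ---------------------------------------------------------------------------
# Data-driven cut-off derivation
# ---------------------------------------------------------------------------

def estimate_cutoff(segments: list[Segment], params: SegmentationParams | None = None) -> CutoffEstimate:
    """Derive the angular-speed cut-off from the data.

    Collects |running median - local| angular-speed differences from an
    unsplit scan of every segment, then applies the two-stage boxplot rule
    of :func:`cutoff_from_differences`.
    """
    params = params or SegmentationParams()
    all_diffs = []
    for seg in segments:
        if len(seg) < 2:
            continue
        omega = local_angular_speed(seg, params)
        _, d = split_points(omega, seg.t, math.inf, params.warmup, collect_differences=True)
        all_diffs.append(d)
    if not all_diffs:
        raise ValueError("no angular-speed differences could be collected")
    return cutoff_from_differences(np.concatenate(all_diffs))


def cutoff_from_differences(diffs: np.ndarray) -> CutoffEstimate:
    """Two-stage boxplot rule on a sample of angular-speed differences:
    upper outliers are values above Q3 + 1.5*IQR; the suggested cut-off is
    the midpoint of the outlier subsample's own quartiles, rounded to the
    nearest 0.05 rad/s."""
    diffs = np.asarray(diffs, dtype=float)
    q1, q3 = np.percentile(diffs, [25, 75])
    threshold = q3 + 1.5 * (q3 - q1)
    outliers = diffs[diffs > threshold]
    if outliers.size == 0:
        return CutoffEstimate(
            outlier_threshold=float(threshold), q1_outliers=None, q3_outliers=None,
            suggested_cutoff=None, differences=diffs, degenerate=True,
        )
    oq1, oq3 = np.percentile(outliers, [25, 75])
    suggested = round(((oq1 + oq3) / 2.0) / 0.05) * 0.05
    return CutoffEstimate(
        outlier_threshold=float(threshold),
        q1_outliers=float(oq1),
        q3_outliers=float(oq3),
        suggested_cutoff=float(suggested),
        differences=diffs,
    )


def segmentation_stats(segments: list[Segment], input_length: float) -> SegmentationStats:
    """Count/length summary of a segmentation step (arena-frame lengths)."""
    if not segments:
        return SegmentationStats(0, math.nan, math.nan, math.nan, 0.0)
    lengths = np.array([s.arc_length("arena") for s in segments])
    rel = 100.0 * lengths.sum() / input_length if input_length > 0 else math.nan
    return SegmentationStats(
        n_segments=len(segments),
        median_length=float(np.median(lengths)),
        min_length=float(lengths.min()),
        max_length=float(lengths.max()),
        relative_length=float(rel),
    )
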