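"""The 11-feature descriptor of a trajectory subsegment.

Each subsegment is summarised by positional and kinematic features that
separate the stereotyped behaviours: where the animal is relative to the
shock sector (room frame), how angularly spread the path is in either
frame, how far from the wall it runs (log-radius, centrality), and how fast
and how erratically it moves (speed and angular-speed statistics, speed
change frequency — all in the arena frame, the animal's true locomotion
frame).

Quartiles follow the linear-interpolation ("type 7") convention throughout;
the logarithm is natural.  Angular dispersion is computed on the unwrapped
angle sequence in time order, so multi-lap paths yield dispersions above
2*pi instead of wrapping artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import numpy as np
import pandas as pd

from .io import ArenaConfig, Segment, wrap_angle
from .segmentation import unwrapped_angle

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "angular_distance_to_sector",
    "angular_dispersion",
    "log_radius_stats",
    "centrality",
    "speed_stats",
    "angular_speed_stats",
    "speed_change_frequency",
    "compute_features",
    "features_table",
]

#: Radius fraction of the concentric circle used by the centrality feature.
CENTRAL_REGION_FRACTION = 0.75

#: Speed-level fraction used by the speed-change-frequency feature.
SPEED_CROSSING_FRACTION = 0.25


@dataclass(frozen=True)
class FeatureVector:
    angular_distance_to_sector: float  # rad, [0, 2*pi), room frame
    angular_dispersion_room: float     # rad
    angular_dispersion_arena: float    # rad
    median_log_radius: float
    iqr_log_radius: float
    centrality: float                  # fraction of arc length in the inner 75% disc
    median_speed: float                # cm/s, arena frame
    iqr_speed: float
    median_angular_speed: float        # rad/s, arena frame
    iqr_angular_speed: float
    speed_change_frequency: float      # 1/s

    def to_dict(self) -> dict:
        return asdict(self)


FEATURE_NAMES = tuple(f.name for f in fields(FeatureVector))


def _iqr(values: np.ndarray) -> float:
    q1, q3 = np.percentile(values, [25, 75])
    return float(q3 - q1)


def angular_distance_to_sector(seg: Segment, config: ArenaConfig) -> float:
    """Angle of the segment's summed room-frame position vectors relative to
    the sector centre, mapped to [0, 2*pi).  A near-zero resultant (perfectly
    balanced path) is defined as 0."""
    x, y = seg.xy_room()
    sx, sy = x.sum(), y.sum()
    if np.hypot(sx, sy) < 1e-9:
        return 0.0
    return float(wrap_angle(np.arctan2(sy, sx) - config.sector_centre))


def angular_dispersion(seg: Segment, frame: str = "room") -> float:
    """Max minus min of the unwrapped polar-angle sequence (rad)."""
    x, y = seg.xy_room() if frame == "room" else seg.xy_arena()
    if len(x) < 2:
        return 0.0
    phi = unwrapped_angle(x, y)
    return float(phi.max() - phi.min())


def log_radius_stats(seg: Segment) -> tuple[float, float]:
    """Median and IQR of the natural log of the distance to the arena
    centre.  Frame-independent (rotation preserves radius); samples at the
    exact centre are offset by machine epsilon."""
    r = seg.radius()
    r = np.maximum(r, np.finfo(float).tiny)
    logr = np.log(r)
    return float(np.median(logr)), _iqr(logr)


def centrality(seg: Segment, config: ArenaConfig) -> float:
    """Fraction of the arena-frame arc length inside the concentric circle of
    radius 0.75*R.  Steps crossing the circle are apportioned by linear
    interpolation of the crossing point along the chord."""
    x, y = seg.xy_arena()
    if len(x) < 2:
        return 0.0
    rc = CENTRAL_REGION_FRACTION * config.radius
    p0 = np.column_stack([x[:-1], y[:-1]])
    d = np.column_stack([np.diff(x), np.diff(y)])
    step_len = np.hypot(d[:, 0], d[:, 1])
    total = step_len.sum()
    if total == 0:
        return 0.0
    # fraction of each chord with |p0 + s d| < rc, s in [0, 1]
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", p0, d)
    c = np.einsum("ij,ij->i", p0, p0) - rc * rc
    inside_frac = np.zeros(len(a))
    degenerate = a < 1e-18          # zero-length steps: point in or out
    inside_frac[degenerate] = (c[degenerate] < 0).astype(float)
    ok = ~degenerate
    disc = b[ok] ** 2 - 4 * a[ok] * c[ok]
    s1 = np.where(disc > 0, (-b[ok] - np.sqrt(np.maximum(disc, 0))) / (2 * a[ok]), np.inf)
    s2 = np.where(disc > 0, (-b[ok] + np.sqrt(np.maximum(disc, 0))) / (2 * a[ok]), -np.inf)
    frac = np.clip(s2, 0.0, 1.0) - np.clip(s1, 0.0, 1.0)
    inside_frac[ok] = np.where(disc > 0, np.maximum(frac, 0.0), (c[ok] < 0).astype(float))
    return float((inside_frac * step_len).sum() / total)


def _speeds(seg: Segment) -> np.ndarray:
    x, y = seg.xy_arena()
    t = seg.t
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    return np.hypot(vx, vy)


def _angular_speeds(seg: Segment) -> np.ndarray:
    x, y = seg.xy_arena()
    phi = unwrapped_angle(x, y)
    return np.abs(np.gradient(phi, seg.t))


def speed_stats(seg: Segment) -> tuple[float, float]:
    """Median and IQR of the per-sample speed (cm/s, arena frame)."""
    v = _speeds(seg)
    return float(np.median(v)), _iqr(v)


def angular_speed_stats(seg: Segment) -> tuple[float, float]:
    """Median and IQR of the per-sample angular speed about the arena centre
    (rad/s, arena frame)."""
    w = _angular_speeds(seg)
    return float(np.median(w)), _iqr(w)


def speed_change_frequency(seg: Segment) -> float:
    """Rate (1/s) of crossings of the 25%-of-median speed level.

    Counts strict sign changes of ``speed - 0.25*median_speed`` between
    consecutive samples; samples exactly at the level attach to the previous
    side.  A zero median speed yields 0.
    """
    v = _speeds(seg)
    med = np.median(v)
    if med <= 0:
        return 0.0
    rel = v - SPEED_CROSSING_FRACTION * med
    sign = np.sign(rel)
    # zeros inherit the previous side
    for i in range(len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1] if i > 0 else 1.0
    crossings = int(np.sum(sign[1:] != sign[:-1]))
    duration = seg.duration
    return crossings / duration if duration > 0 else 0.0


def compute_features(seg: Segment, config: ArenaConfig | None = None) -> FeatureVector:
    """All 11 features of one stage-2 subsegment.  Pure and deterministic."""
    config = config or seg.config
    med_logr, iqr_logr = log_radius_stats(seg)
    med_v, iqr_v = speed_stats(seg)
    med_w, iqr_w = angular_speed_stats(seg)
    return FeatureVector(
        angular_distance_to_sector=angular_distance_to_sector(seg, config),
        angular_dispersion_room=angular_dispersion(seg, "room"),
        angular_dispersion_arena=angular_dispersion(seg, "arena"),
        median_log_radius=med_logr,
        iqr_log_radius=iqr_logr,
        centrality=centrality(seg, config),
        median_speed=med_v,
        iqr_speed=iqr_v,
        median_angular_speed=med_w,
        iqr_angular_speed=iqr_w,
        speed_change_frequency=speed_change_frequency(seg),
    )


def features_table(segments: list[Segment], config: ArenaConfig | None = None) -> pd.DataFrame:
    """One row per subsegment: identifiers plus the 11 feature columns."""
    rows = []
    for i, seg in enumerate(segments):
        tr = seg.trajectory
        row = {
            "animal_id": tr.animal_id,
            "group": tr.group,
            "session": tr.session,
            "segment_id": i,
            "stage": seg.stage,
            "start_index": seg.start,
            "end_index": seg.end,
        }
        row.update(compute_features(seg, config).to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
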