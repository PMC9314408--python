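"""Trajectory containers, arena geometry and reference-frame transforms.

The Carousel maze (active allothetic place-avoidance, AAPA) records an
animal on a slowly rotating circular arena.  Two coordinate systems matter:

* the **room frame**, fixed to the laboratory, in which the shock sector is
  stationary;
* the **arena frame**, co-rotating with the arena surface, in which the
  animal's true locomotion takes place.

Positions are stored in the room frame; the arena frame is obtained by
rotating each sample back by the arena orientation at its timestamp.  The
arena orientation is reconstructed analytically from the rotation rate
(``rotation_sign * rotation_rate * t + arena_phase0``) unless a measured
per-sample orientation is supplied (``arena_angle`` column), which takes
precedence and supports recordings where the rotation was tracked.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ArenaConfig",
    "Trajectory",
    "Segment",
    "FormatError",
    "DataError",
    "wrap_angle",
    "circular_difference",
    "in_sector",
    "to_arena_frame",
    "read_trajectories",
    "write_trajectories",
]

#: Canonical CSV columns for trajectory files (long form, one row per sample).
CSV_COLUMNS = ("animal_id", "group", "session", "t_s", "x_cm", "y_cm", "shock")
OPTIONAL_COLUMNS = ("arena_angle_rad",)


class FormatError(ValueError):
    """A trajectory file does not conform to the documented CSV layout."""


class DataError(ValueError):
    """A trajectory file parses but violates a data invariant."""


def wrap_angle(theta):
    """Map angles to ``[0, 2*pi)`` (counterclockwise-positive, atan2 convention)."""
    return np.mod(theta, 2.0 * np.pi)


def circular_difference(a, b):
    """Signed circular difference ``a - b`` mapped to ``(-pi, pi]``."""
    d = np.mod(np.asarray(a) - np.asarray(b), 2.0 * np.pi)
    return np.where(d > np.pi, d - 2.0 * np.pi, d)


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and dynamics of the rotating arena.

    Defaults reproduce the standard setup: an 80 cm diameter arena rotating
    at one revolution per minute, with a 60 degree shock sector fixed in the
    room frame, 25 Hz tracking, and 0.5 s shock pulses repeated every 1.5 s
    while the animal stays inside the sector.
    """

    radius: float = 40.0                       # cm
    rotation_rate: float = 2.0 * math.pi / 60.0  # rad/s (1 rpm)
    rotation_sign: int = 1                     # +1 counterclockwise, -1 clockwise
    sector_centre: float = 0.0                 # rad, room frame
    sector_width: float = math.pi / 3.0        # rad (60 degrees)
    sampling_rate: float = 25.0                # Hz
    shock_pulse: float = 0.5                   # s
    shock_interval: float = 1.5                # s
    arena_phase0: float = 0.0                  # rad, arena orientation at t=0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0 < self.sector_width < 2 * math.pi):
            raise ValueError("sector_width must lie in (0, 2*pi)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.shock_interval <= 0:
            raise ValueError("shock_interval must be positive")
        if self.rotation_sign not in (-1, 1):
            raise ValueError("rotation_sign must be +1 or -1")

    def arena_angle_at(self, t):
        """Arena orientation (rad) at time(s) ``t`` under the analytic model."""
        return self.rotation_sign * self.rotation_rate * np.asarray(t, dtype=float) + self.arena_phase0

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ArenaConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))


def in_sector(x, y, config: ArenaConfig):
    """Is a room-frame point inside the shock sector?

    Membership depends only on the polar angle: a point is inside iff the
    circular distance between ``atan2(y, x)`` and the sector centre falls in
    the half-open interval ``[-width/2, +width/2)``.  The arena centre
    (angle undefined) is defined to be outside.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = circular_difference(np.arctan2(y, x), config.sector_centre)
    half = config.sector_width / 2.0
    # tiny tolerance keeps the half-open boundary stable under the
    # cos/sin/atan2 round trip (1e-9 rad ~ 4e-8 cm at the rim)
    eps = 1e-9
    inside = (d >= -half - eps) & (d < half - eps)
    return inside & ((x != 0) | (y != 0))


def _rotate(x, y, theta):
    c, s = np.cos(theta), np.sin(theta)
    return x * c + y * s, -x * s + y * c


def to_arena_frame(traj: "Trajectory", config: ArenaConfig):
    """Room-frame positions rotated into the co-rotating arena frame.

    Returns ``(x_arena, y_arena)``.  Per-sample radius is preserved exactly
    (rotation about the origin).  A measured ``arena_angle`` on the
    trajectory overrides the analytic rotation model.
    """
    theta = traj.arena_angle if traj.arena_angle is not None else config.arena_angle_at(traj.t)
    return _rotate(traj.x, traj.y, theta)


def to_room_frame(x_arena, y_arena, t, config: ArenaConfig, arena_angle=None):
    """Inverse of :func:`to_arena_frame` for raw coordinate arrays."""
    theta = arena_angle if arena_angle is not None else config.arena_angle_at(t)
    return _rotate(np.asarray(x_arena, float), np.asarray(y_arena, float), -np.asarray(theta, float))


@dataclass
class Trajectory:
    """One animal-session time series of room-frame positions and shock flags."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    shock: np.ndarray
    animal_id: str = "animal"
    group: str = ""
    session: int = 1
    arena_angle: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.shock = np.asarray(self.shock, dtype=bool)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.shock)):
            raise DataError("t, x, y, shock must have equal length")
        if self.arena_angle is not None:
            self.arena_angle = np.asarray(self.arena_angle, dtype=float)
            if len(self.arena_angle) != len(self.t):
                raise DataError("arena_angle length mismatch")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise DataError(f"time must be strictly increasing ({self.animal_id}, session {self.session})")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def radius(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    def arena_xy(self, config: ArenaConfig):
        return to_arena_frame(self, config)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "group": self.group,
                "session": self.session,
                "t_s": self.t,
                "x_cm": self.x,
                "y_cm": self.y,
                "shock": self.shock.astype(int),
            }
        )
        if self.arena_angle is not None:
            df["arena_angle_rad"] = self.arena_angle
        return df


@dataclass
class Segment:
    """A contiguous index range ``[start, end]`` (inclusive) of a trajectory.

    ``stage`` is 1 for sector-delimited segments and 2 for angular-speed
    subsegments.  Views in either reference frame are available through the
    attached arena configuration.
    """

    trajectory: Trajectory
    start: int
    end: int
    config: ArenaConfig
    stage: int = 1

    def __post_init__(self):
        n = len(self.trajectory)
        if not (0 <= self.start <= self.end < n):
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end}] for n={n}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def t(self) -> np.ndarray:
        return self.trajectory.t[self.start : self.end + 1]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def xy_room(self):
        s = slice(self.start, self.end + 1)
        return self.trajectory.x[s], self.trajectory.y[s]

    def xy_arena(self):
        xa, ya = to_arena_frame(self.trajectory, self.config)
        s = slice(self.start, self.end + 1)
        return xa[s], ya[s]

    def radius(self) -> np.ndarray:
        x, y = self.xy_room()
        return np.hypot(x, y)

    def arc_length(self, frame: str = "arena") -> float:
        """Total path length (cm) in the requested frame."""
        x, y = self.xy_arena() if frame == "arena" else self.xy_room()
        return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_trajectories(path, config: ArenaConfig, outside: str = "clamp",
                      radius_tolerance: float = 1.0) -> list[Trajectory]:
    """Read a long-form trajectory CSV into one :class:`Trajectory` per
    animal-session.

    Parameters
    ----------
    outside:
        Policy for samples farther than ``radius + radius_tolerance`` from
        the centre: ``"clamp"`` rescales them onto the rim with a warning,
        ``"reject"`` raises :class:`DataError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    out: list[Trajectory] = []
    for (animal, session), g in df.groupby(["animal_id", "session"], sort=True):
        g = g.sort_values("t_s")
        x = g["x_cm"].to_numpy(float)
        y = g["y_cm"].to_numpy(float)
        r = np.hypot(x, y)
        far = r > config.radius + radius_tolerance
        if far.any():
            if outside == "reject":
                raise DataError(
                    f"{int(far.sum())} samples outside the arena for {animal} session {session}"
                )
            warnings.warn(
                f"{int(far.sum())} samples outside the arena radius for {animal} "
                f"session {session}; clamped to the rim"
            )
            scale = np.where(far, config.radius / np.where(r > 0, r, 1.0), 1.0)
            x, y = x * scale, y * scale
        out.append(
            Trajectory(
                t=g["t_s"].to_numpy(float),
                x=x,
                y=y,
                shock=g["shock"].to_numpy(),
                animal_id=str(animal),
                group=str(g["group"].iloc[0]),
                session=int(session),
                arena_angle=g["arena_angle_rad"].to_numpy(float)
                if "arena_angle_rad" in g.columns
                else None,
            )
        )
    return out


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    """Write trajectories to the canonical long-form CSV."""
    pd.concat([tr.to_frame() for tr in trajectories], ignore_index=True).to_csv(path, index=False)
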