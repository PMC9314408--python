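"""Synthetic place-avoidance cohorts with planted strategy structure.

Generates 25 Hz tracking sessions on the rotating arena in which every
sample carries a ground-truth strategy code, so the whole pipeline
(segmentation, features, clustering, classification, group statistics) is
testable without recorded data.

Each session is a sequence of behavioural *bouts* drawn from a per-group
strategy mix.  The archetypes realise the field's verbal definitions:

* ``thigmotaxis`` — a correlated wall-following walk confined to the outer
  band of the arena (arena frame);
* ``incursion`` — wall-following interleaved with inward excursions that
  reach well inside the 75 % circle;
* ``focused`` — a mean-reverting walk about a fixed room-frame anchor kept
  outside the shock sector;
* ``chaining`` — a near-stationary animal (small positional jitter in the
  arena frame) carried passively by the rotation, drifting toward the inner
  arena;
* ``avoidance`` — idling in the arena frame until the rotation carries the
  animal close to the sector edge, then an active angular retreat.

Bouts join continuously (each starts at the previous endpoint and relaxes
into its regime); consecutive bouts are linked by a brief (~0.6 s)
reorientation turn, mimicking the abrupt heading change animals show when
switching behaviour.  Gaussian position jitter emulates tracking noise, and
shock flags follow the pulse-timing rule whenever the animal is inside the
sector during a shock-on session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .io import ArenaConfig, Segment, Trajectory, circular_difference, to_room_frame
from .labels import AVOIDANCE, CHAINING, FOCUSED, INCURSION, STRATEGIES, THIGMOTAXIS

__all__ = [
    "CohortSpec",
    "CONTROL_MIX",
    "TREATED_MIX",
    "NULL_MIX",
    "generate_bout",
    "generate_session",
    "generate_cohort",
    "truth_label",
    "truth_labels_table",
]

#: Default strategy mixes: the treated group leans on thigmotaxis/incursion,
#: the control group on focused/avoidance, chaining comparable — the planted
#: group contrast mirrors the direction of reported group differences.
CONTROL_MIX = {THIGMOTAXIS: 0.20, INCURSION: 0.15, FOCUSED: 0.30,
               CHAINING: 0.10, AVOIDANCE: 0.25}
TREATED_MIX = {THIGMOTAXIS: 0.40, INCURSION: 0.25, FOCUSED: 0.10,
               CHAINING: 0.15, AVOIDANCE: 0.10}
#: Equal-usage mix for null (no group difference) cohorts.
NULL_MIX = {s: 0.2 for s in STRATEGIES}

CODE = {s: i for i, s in enumerate(STRATEGIES)}


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults emulate the standard protocol: 10 animals per group, five
    20-minute shock-on sessions plus one retrieval session without shocks,
    and 0.3 cm tracking jitter.
    """

    n_per_group: int = 10
    n_sessions: int = 6
    session_duration: float = 1200.0     # s
    strategy_mix: dict = field(default_factory=lambda: {
        "control": CONTROL_MIX, "treated": TREATED_MIX})
    shock_sessions: tuple = (1, 2, 3, 4, 5)
    bout_duration: tuple = (15.0, 60.0)  # s, uniform draw
    walk_speed: float = 8.0              # cm/s, locomotor speed scale
    wall_band: tuple = (0.85, 1.0)       # thigmotaxis radial band (fractions of R)
    incursion_depth: tuple = (0.40, 0.55)  # excursion minimum radius (fractions of R)
    focused_spread: float = 4.0          # cm, stationary sd about the anchor
    avoidance_margin: float = 0.30       # rad, retreat trigger distance to sector edge
    avoidance_retreat_rate: float = 0.35  # rad/s, room-frame retreat speed
    chaining_jitter: float = 0.10        # cm, stationary sd of arena-frame jitter
    turn_duration: float = 0.6           # s, reorientation between bouts
    turn_rate: float = 1.8               # rad/s during reorientation
    noise_sd: float = 0.3                # cm, tracking jitter
    seed: int = 0

    def __post_init__(self):
        for g, mix in self.strategy_mix.items():
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"strategy mix for {g!r} sums to {total}, not 1")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")


def _ou(rng, n, dt, tau, sigma, x0, mean):
    """Exact-discretisation Ornstein-Uhlenbeck path via an AR(1) filter.

    ``sigma`` is the stationary standard deviation; ``mean`` may be an
    array (time-varying target).
    """
    a = math.exp(-dt / tau)
    e = rng.normal(0.0, sigma * math.sqrt(1.0 - a * a), size=n)
    u = e + (1.0 - a) * np.broadcast_to(np.asarray(mean, float), (n,))
    y, _ = lfilter([1.0], [1.0, -a], u, zi=np.array([a * x0]))
    return y


def _smooth_xy(x, y, window):
    if window <= 1 or len(x) < window:
        return x, y
    pad = window // 2
    kern = np.ones(window) / window
    sm = lambda v: np.convolve(np.pad(v, pad, mode="edge"), kern, mode="valid")
    return sm(x), sm(y)


def _polar(xy):
    x, y = xy
    return math.hypot(x, y), math.atan2(y, x)


# ---------------------------------------------------------------------------
# Bout archetypes (all return arena-frame coordinates)
# ---------------------------------------------------------------------------

def _wall_walk(rng, spec, config, m, dt, start, r_target):
    """Shared machinery of thigmotaxis/incursion: a correlated walk whose
    radius tracks ``r_target`` while the heading advances tangentially."""
    r0, phi0 = _polar(start)
    r = _ou(rng, m, dt, tau=1.2, sigma=1.2, x0=r0, mean=r_target)
    lo, hi = spec.wall_band[0] * config.radius * 0.35, config.radius * 0.995
    r = np.clip(r, lo, hi)
    v = _ou(rng, m, dt, tau=2.0, sigma=2.0, x0=spec.walk_speed, mean=spec.walk_speed)
    v = np.clip(v, 1.0, 3.0 * spec.walk_speed)
    flips = rng.random(m) < 0.004  # heading reversal roughly every 10 s
    direction = (1 if rng.random() < 0.5 else -1) * np.cumprod(1 - 2 * flips.astype(int))
    phi = phi0 + np.cumsum(direction * v / r * dt)
    x, y = r * np.cos(phi), r * np.sin(phi)
    return _smooth_xy(x, y, 7)


def _thigmotaxis(rng, spec, config, m, dt, start, t0):
    R = config.radius
    band_mid = 0.5 * (spec.wall_band[0] + spec.wall_band[1])
    x, y = _wall_walk(rng, spec, config, m, dt, start,
                      r_target=np.full(m, band_mid * R))
    r = np.hypot(x, y)
    lo = spec.wall_band[0] * R
    scale = np.where(r < lo, lo / np.maximum(r, 1e-9), 1.0)
    return x * scale, y * scale


def _incursion(rng, spec, config, m, dt, start, t0):
    R = config.radius
    wall = 0.92 * R
    target = np.full(m, wall)
    i = int(rng.uniform(1.0, 4.0) / dt)  # first excursion onset
    while i < m:
        dur = int(rng.uniform(3.0, 6.0) / dt)
        depth = rng.uniform(*spec.incursion_depth) * R
        u = np.linspace(0.0, 1.0, min(dur, m - i))
        target[i : i + len(u)] = wall - (wall - depth) * np.sin(np.pi * u) ** 2
        i += dur + int(rng.uniform(2.0, 5.0) / dt)
    return _wall_walk(rng, spec, config, m, dt, start, r_target=target)


def _focused(rng, spec, config, m, dt, start, t0):
    R = config.radius
    t = t0 + np.arange(m) * dt
    # anchor: the current room-frame position, pulled to a comfortable radius
    # and pushed outside the sector
    x0r, y0r = to_room_frame(start[0], start[1], t0, config)
    r_a, phi_a = math.hypot(x0r, y0r), math.atan2(y0r, x0r)
    r_a = min(max(r_a, 0.45 * R), 0.80 * R)
    half = config.sector_width / 2.0
    margin = 0.5
    d = float(circular_difference(phi_a, config.sector_centre))
    if abs(d) < half + margin:
        phi_a = config.sector_centre + math.copysign(half + margin + 0.2, d if d != 0 else 1.0)
    ax, ay = r_a * math.cos(phi_a), r_a * math.sin(phi_a)
    xr = _ou(rng, m, dt, tau=3.0, sigma=spec.focused_spread, x0=x0r, mean=ax)
    yr = _ou(rng, m, dt, tau=3.0, sigma=spec.focused_spread, x0=y0r, mean=ay)
    xr, yr = _smooth_xy(xr, yr, 9)
    theta = config.arena_angle_at(t)
    return xr * np.cos(theta) + yr * np.sin(theta), -xr * np.sin(theta) + yr * np.cos(theta)


def _chaining(rng, spec, config, m, dt, start, t0):
    R = config.radius
    r0, phi0 = _polar(start)
    r_a = min(r0, 0.55 * R)  # passive sitting happens in the inner arena
    ax, ay = r_a * math.cos(phi0), r_a * math.sin(phi0)
    x = _ou(rng, m, dt, tau=25.0, sigma=spec.chaining_jitter, x0=start[0], mean=ax)
    y = _ou(rng, m, dt, tau=25.0, sigma=spec.chaining_jitter, x0=start[1], mean=ay)
    return _smooth_xy(x, y, 5)


def _avoidance(rng, spec, config, m, dt, start, t0):
    """Arena-frame idling punctuated by room-frame angular retreats just
    before the rotation would carry the animal into the sector."""
    R = config.radius
    sign = config.rotation_sign
    half = config.sector_width / 2.0
    entry_edge = config.sector_centre - sign * half
    trigger = entry_edge - sign * spec.avoidance_margin

    t = t0 + np.arange(m) * dt
    x0r, y0r = to_room_frame(start[0], start[1], t0, config)
    r0, phi = math.hypot(x0r, y0r), math.atan2(y0r, x0r)
    r = np.clip(_ou(rng, m, dt, tau=4.0, sigma=2.0, x0=r0, mean=0.78 * R),
                0.3 * R, 0.97 * R)
    omega = np.empty(m)
    i = 0
    while i < m:
        # forward (with-rotation) angular distance already past the trigger;
        # inside the danger zone the animal retreats at once instead of being
        # carried through the sector
        past = (sign * (phi - trigger)) % (2.0 * math.pi)
        if past >= spec.avoidance_margin + config.sector_width:
            dist = 2.0 * math.pi - past
            n_idle = min(max(1, int(dist / (config.rotation_rate * dt))), m - i)
            omega[i : i + n_idle] = sign * config.rotation_rate
            phi += sign * config.rotation_rate * n_idle * dt
            i += n_idle
            if i >= m:
                break
        # retreat: run back against the rotation
        n_run = min(int(rng.uniform(2.0, 3.2) / dt), m - i)
        omega[i : i + n_run] = -sign * spec.avoidance_retreat_rate
        phi += -sign * spec.avoidance_retreat_rate * n_run * dt
        i += n_run
    phi_series = math.atan2(y0r, x0r) + np.cumsum(omega * dt)
    phi_series += np.cumsum(rng.normal(0, 0.002, m))  # heading jitter
    xr, yr = r * np.cos(phi_series), r * np.sin(phi_series)
    xr, yr = _smooth_xy(xr, yr, 5)
    theta = config.arena_angle_at(t)
    return xr * np.cos(theta) + yr * np.sin(theta), -xr * np.sin(theta) + yr * np.cos(theta)


_GENERATORS = {
    THIGMOTAXIS: _thigmotaxis,
    INCURSION: _incursion,
    FOCUSED: _focused,
    CHAINING: _chaining,
    AVOIDANCE: _avoidance,
}


def generate_bout(strategy: str, duration: float, config: ArenaConfig,
                  spec: CohortSpec | None = None, rng=None,
                  start_xy_arena=None, t0: float = 0.0):
    """Arena-frame samples of one behavioural bout (noise-free).

    Returns ``(x_arena, y_arena)`` at the configured sampling rate.  When no
    start point is given a random one inside the arena is drawn.
    """
    if strategy not in _GENERATORS:
        raise ValueError(f"unknown strategy {strategy!r}")
    spec = spec or CohortSpec()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    dt = 1.0 / config.sampling_rate
    m = max(2, int(round(duration * config.sampling_rate)))
    if start_xy_arena is None:
        r = rng.uniform(0.5, 0.9) * config.radius
        a = rng.uniform(0, 2 * math.pi)
        start_xy_arena = (r * math.cos(a), r * math.sin(a))
    return _GENERATORS[strategy](rng, spec, config, m, dt, start_xy_arena, t0)


def _turn(rng, spec, config, m, dt, start):
    """Reorientation arc between bouts: a quick rotation about the centre."""
    r0, phi0 = _polar(start)
    r0 = min(max(r0, 0.15 * config.radius), 0.95 * config.radius)
    sign = 1 if rng.random() < 0.5 else -1
    phi = phi0 + sign * spec.turn_rate * np.arange(1, m + 1) * dt
    return r0 * np.cos(phi), r0 * np.sin(phi)


def generate_session(animal_id: str, group: str, session: int,
                     spec: CohortSpec, config: ArenaConfig, rng):
    """One session: bout sequence, tracking noise, shocks, truth codes.

    Returns ``(Trajectory, codes)`` where ``codes[i]`` indexes
    :data:`carousel.labels.STRATEGIES` for sample ``i``.
    """
    from .stats import simulate_shock_flags  # deferred: avoids an import cycle

    fs = config.sampling_rate
    dt = 1.0 / fs
    n = int(round(spec.session_duration * fs))
    mix = spec.strategy_mix[group]
    if isinstance(next(iter(mix.values())), dict):  # per-session mixes
        mix = mix[session]
    names = list(mix)
    probs = np.array([mix[s] for s in names])

    xs, ys, codes = [], [], []
    r = rng.uniform(0.5, 0.85) * config.radius
    a = rng.uniform(0, 2 * math.pi)
    pos = (r * math.cos(a), r * math.sin(a))
    filled = 0
    first = True
    n_turn = max(2, int(round(spec.turn_duration * fs)))
    while filled < n:
        strat = names[rng.choice(len(names), p=probs)]
        code = CODE[strat]
        if not first:
            tx, ty = _turn(rng, spec, config, n_turn, dt, pos)
            xs.append(tx); ys.append(ty)
            codes.append(np.full(len(tx), code, dtype=np.int8))
            pos = (tx[-1], ty[-1])
            filled += len(tx)
        dur = rng.uniform(*spec.bout_duration)
        bx, by = generate_bout(strat, dur, config, spec, rng,
                               start_xy_arena=pos, t0=filled * dt)
        xs.append(bx); ys.append(by)
        codes.append(np.full(len(bx), code, dtype=np.int8))
        pos = (bx[-1], by[-1])
        filled += len(bx)
        first = False

    xa = np.concatenate(xs)[:n]
    ya = np.concatenate(ys)[:n]
    code_arr = np.concatenate(codes)[:n]
    t = np.arange(n) * dt
    x, y = to_room_frame(xa, ya, t, config)
    x = x + rng.normal(0, spec.noise_sd, n)
    y = y + rng.normal(0, spec.noise_sd, n)
    rr = np.hypot(x, y)
    over = rr > config.radius
    if over.any():
        scale = np.where(over, config.radius / rr, 1.0)
        x, y = x * scale, y * scale

    traj = Trajectory(t=t, x=x, y=y, shock=np.zeros(n, dtype=bool),
                      animal_id=animal_id, group=group, session=session)
    if session in spec.shock_sessions:
        traj.shock = simulate_shock_flags(traj, config)
    return traj, code_arr


def generate_cohort(spec: CohortSpec | None = None,
                    config: ArenaConfig | None = None):
    """Full cohort: a list of trajectories and per-sample ground truth.

    Returns ``(trajectories, truth)`` with ``truth[(animal_id, session)]``
    the strategy-code array of that session.  Deterministic given
    ``spec.seed``.
    """
    spec = spec or CohortSpec()
    config = config or ArenaConfig()
    rng = np.random.default_rng(spec.seed)
    trajectories: list[Trajectory] = []
    truth: dict[tuple[str, int], np.ndarray] = {}
    for group in sorted(spec.strategy_mix):
        for i in range(spec.n_per_group):
            animal = f"{group[:4]}{i + 1:02d}"
            for session in range(1, spec.n_sessions + 1):
                traj, codes = generate_session(animal, group, session, spec, config, rng)
                trajectories.append(traj)
                truth[(animal, session)] = codes
    return trajectories, truth


def truth_label(truth: dict, seg: Segment) -> str:
    """Plurality ground-truth strategy of a segment's samples."""
    codes = truth[(seg.trajectory.animal_id, seg.trajectory.session)]
    counts = np.bincount(codes[seg.start : seg.end + 1], minlength=len(STRATEGIES))
    return STRATEGIES[int(np.argmax(counts))]


def truth_labels_table(segments, truth):
    """Tidy frame of ground-truth labels, one row per segment."""
    import pandas as pd

    rows = [{
        "animal_id": s.trajectory.animal_id,
        "group": s.trajectory.group,
        "session": s.trajectory.session,
        "segment_id": i,
        "label": truth_label(truth, s),
    } for i, s in enumerate(segments)]
    return pd.DataFrame(rows)
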