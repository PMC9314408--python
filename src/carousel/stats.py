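"""Session performance measures, strategy-usage tables, and Friedman group
comparisons.

Standard place-avoidance performance measures per session: number of
entrances to the shock sector, number of shocks, time to first shock,
maximum time avoided (longest continuous out-of-sector interval, including
the spans before the first entrance and after the last exit), arena-frame
path length and average speed.

Group differences are tested with the Friedman rank test.  Because group
comparisons involve exactly two treatments (and SciPy's implementation
requires three), the tie-corrected closed form is implemented here; it
matches SciPy for three or more treatments.  The default design ranks all
animals jointly within each session, aggregates to per-group mean ranks,
and blocks over the five training sessions; the retrieval session is
reported in tables but excluded from tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ArenaConfig, Trajectory, in_sector, to_arena_frame
from .labels import ALL_LABELS

__all__ = [
    "SessionSummary",
    "FriedmanResult",
    "performance_measures",
    "summarize_sessions",
    "strategy_percentages",
    "friedman_test",
    "friedman_group_test",
    "group_report",
]

#: Sessions used for hypothesis tests (the shock-on training sessions).
TRAINING_SESSIONS = (1, 2, 3, 4, 5)


@dataclass
class SessionSummary:
    animal_id: str
    group: str
    session: int
    n_entrances: int
    n_shocks: int
    time_to_first_shock: float
    max_time_avoided: float
    path_length: float      # cm, arena frame
    average_speed: float    # cm/s


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    p_value: float


def simulate_shock_flags(traj: Trajectory, config: ArenaConfig) -> np.ndarray:
    """Shock flags from the timing rule: first pulse at the entry sample,
    further pulses every ``shock_interval`` while the animal stays inside.
    Samples within ``shock_pulse`` of a pulse onset are flagged."""
    inside = in_sector(traj.x, traj.y, config)
    flags = np.zeros(len(traj), dtype=bool)
    t = traj.t
    i = 0
    n = len(traj)
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and inside[j + 1]:
            j += 1
        onset = t[i]
        while onset <= t[j]:
            flags |= (t >= onset) & (t < onset + config.shock_pulse) & inside
            onset += config.shock_interval
        i = j + 1
    return flags


def performance_measures(traj: Trajectory, config: ArenaConfig,
                         simulate_shocks: bool | None = None) -> SessionSummary:
    """Standard per-session performance measures.

    ``simulate_shocks=None`` uses recorded shock flags when any are present
    and falls back to the timing rule otherwise; True/False force either.
    An animal starting inside the sector counts as one entrance.
    """
    inside = in_sector(traj.x, traj.y, config)
    t = traj.t
    duration = traj.duration

    entries = int(np.sum(~inside[:-1] & inside[1:]))
    if len(inside) and inside[0]:
        entries += 1

    if simulate_shocks is None:
        simulate_shocks = not traj.shock.any()
    shock = simulate_shock_flags(traj, config) if simulate_shocks else traj.shock
    onsets = np.flatnonzero(np.diff(np.concatenate([[False], shock]).astype(int)) == 1)
    n_shocks = len(onsets)
    t_first = float(t[onsets[0]]) if n_shocks else duration

    # longest contiguous out-of-sector interval (session start/end included)
    max_avoided = 0.0
    i, n = 0, len(inside)
    while i < n:
        if inside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not inside[j + 1]:
            j += 1
        # an avoided interval runs until the moment of (re-)entry
        start = t[i]
        end = t[j + 1] if j < n - 1 else t[-1]
        max_avoided = max(max_avoided, end - start)
        i = j + 1

    xa, ya = to_arena_frame(traj, config)
    path = float(np.sum(np.hypot(np.diff(xa), np.diff(ya))))
    return SessionSummary(
        animal_id=traj.animal_id,
        group=traj.group,
        session=traj.session,
        n_entrances=entries,
        n_shocks=n_shocks,
        time_to_first_shock=t_first,
        max_time_avoided=float(max_avoided),
        path_length=path,
        average_speed=path / duration if duration > 0 else 0.0,
    )


MEASURES = ("n_entrances", "n_shocks", "time_to_first_shock",
            "max_time_avoided", "path_length", "average_speed")


def summarize_sessions(trajectories: list[Trajectory], config: ArenaConfig,
                       simulate_shocks: bool | None = None) -> pd.DataFrame:
    """Performance-measure table, one row per animal-session."""
    rows = [performance_measures(tr, config, simulate_shocks).__dict__
            for tr in trajectories]
    return pd.DataFrame(rows)


def strategy_percentages(labels: pd.DataFrame) -> pd.DataFrame:
    """Per animal-session percentage of subsegments under each strategy.

    ``labels`` needs columns ``animal_id``, ``group``, ``session``,
    ``label``.  Every label (including ``unidentified``) gets a column;
    rows sum to 100.
    """
    required = {"animal_id", "group", "session", "label"}
    if not required.issubset(labels.columns):
        raise ValueError(f"labels frame needs columns {sorted(required)}")
    counts = (labels.groupby(["animal_id", "group", "session", "label"], observed=True)
              .size().unstack(fill_value=0))
    for lab in ALL_LABELS:
        if lab not in counts.columns:
            counts[lab] = 0
    counts = counts[list(ALL_LABELS)]
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct.reset_index()


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------

def _friedman_statistic(data: np.ndarray) -> float | None:
    """Tie-corrected Friedman chi-square of a blocks x treatments table;
    None when every block is fully tied (correction factor 0)."""
    n, k = data.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums ** 2) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts ** 3 - counts)
    correction = 1.0 - ties / (n * k * (k * k - 1))
    if correction <= 0:
        return None
    return max(float(chi2 / correction), 0.0)


def friedman_test(matrix, method: str = "chisq") -> FriedmanResult:
    """Tie-corrected Friedman rank test on a blocks x treatments table.

    Rows are blocks (e.g. sessions), columns are treatments (e.g. groups).
    Values are ranked within each block with average ranks for ties; the
    chi-square statistic is divided by the tie-correction factor
    ``1 - sum(t^3 - t) / (n k (k^2 - 1))``.  All blocks fully tied yields
    statistic 0, p 1.

    ``method="chisq"`` takes p from the chi-square upper tail (the usual
    large-sample reference); ``method="exact"`` enumerates every within-block
    permutation (feasible for small tables only) and reports the exact
    fraction of permuted statistics at least as large as the observed one.
    """
    data = np.asarray(matrix, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    n, k = data.shape
    chi2 = _friedman_statistic(data)
    if chi2 is None:
        return FriedmanResult(statistic=0.0, df=k - 1, p_value=1.0)
    if method == "chisq":
        p = float(sps.chi2.sf(chi2, k - 1))
    elif method == "exact":
        from itertools import permutations, product

        n_perms = math.factorial(k) ** n
        if n_perms > 2_000_000:
            raise ValueError(f"exact null with {n_perms} permutations is infeasible")
        perms = list(permutations(range(k)))
        count = 0
        for combo in product(perms, repeat=n):
            permuted = np.stack([data[i, list(p_)] for i, p_ in enumerate(combo)])
            stat = _friedman_statistic(permuted)
            stat = 0.0 if stat is None else stat
            if stat >= chi2 - 1e-12:
                count += 1
        p = count / n_perms
    else:
        raise ValueError(f"unknown method {method!r}")
    return FriedmanResult(statistic=float(chi2), df=k - 1, p_value=float(p))


def friedman_group_test(values: pd.DataFrame, value_col: str,
                        sessions=TRAINING_SESSIONS) -> FriedmanResult:
    """Group comparison of a per-animal per-session quantity.

    Within each session all animals are ranked jointly; the mean rank per
    group forms one block row, and the Friedman test runs over the session
    blocks with groups as treatments.  Needs columns ``animal_id``,
    ``group``, ``session`` and ``value_col``.
    """
    df = values[values["session"].isin(sessions)]
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    blocks = []
    for s in sorted(df["session"].unique()):
        sub = df[df["session"] == s]
        ranks = sps.rankdata(sub[value_col].to_numpy())
        row = [ranks[(sub["group"] == g).to_numpy()].mean() for g in groups]
        blocks.append(row)
    return friedman_test(np.asarray(blocks))


def group_report(summaries: pd.DataFrame, percentages: pd.DataFrame | None = None,
                 sessions=TRAINING_SESSIONS):
    """Per-session group medians/IQRs and Friedman p-values.

    Returns a dict with ``measures`` / ``strategies`` tidy tables (median,
    q1, q3 per group per session, retrieval session included) and
    ``friedman`` (one row per quantity, training sessions only).
    """
    def tidy(df, cols):
        rows = []
        for (g, s), sub in df.groupby(["group", "session"]):
            for c in cols:
                v = sub[c].to_numpy(float)
                q1, med, q3 = np.percentile(v, [25, 50, 75])
                rows.append({"group": g, "session": s, "measure": c,
                             "median": med, "q1": q1, "q3": q3,
                             "min": v.min(), "max": v.max()})
        return pd.DataFrame(rows)

    report = {"measures": tidy(summaries, [c for c in MEASURES if c in summaries])}
    fried = [{"measure": c,
              **friedman_group_test(summaries, c, sessions).__dict__}
             for c in MEASURES if c in summaries]
    if percentages is not None:
        strat_cols = [c for c in percentages.columns if c in ALL_LABELS]
        report["strategies"] = tidy(percentages, strat_cols)
        fried += [{"measure": c,
                   **friedman_group_test(percentages, c, sessions).__dict__}
                  for c in strat_cols]
    report["friedman"] = pd.DataFrame(fried)
    return report


def plot_group_boxes(df: pd.DataFrame, columns, path=None):
    """Side-by-side per-session group box plots (whiskers = min/max)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(df["group"].unique())
    sessions = sorted(df["session"].unique())
    fig, axes = plt.subplots(1, len(columns), figsize=(3.2 * len(columns), 3.2),
                             squeeze=False)
    for ax, col in zip(axes[0], columns):
        width = 0.35
        for gi, g in enumerate(groups):
            data = [df[(df["group"] == g) & (df["session"] == s)][col].to_numpy()
                    for s in sessions]
            pos = [s + (gi - (len(groups) - 1) / 2) * width for s in sessions]
            ax.boxplot(data, positions=pos, widths=width * 0.9, whis=(0, 100),
                       patch_artist=True,
                       boxprops={"facecolor": "white" if gi == 0 else "0.4"})
        ax.set_title(col, fontsize=9)
        ax.set_xticks(sessions)
        ax.set_xticklabels(sessions)
        ax.set_xlabel("session")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
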