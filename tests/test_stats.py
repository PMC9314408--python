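"""Performance measures, strategy percentages, Friedman tests, reports."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from carousel import ArenaConfig, performance_measures, strategy_percentages
from carousel.stats import (
    friedman_group_test,
    friedman_test,
    group_report,
    simulate_shock_flags,
    summarize_sessions,
)
from carousel.io import in_sector

from conftest import make_trajectory


def stationary_in_arena(config, duration, start_angle, radius=20.0):
    """Animal carried passively by the arena from a given room-frame angle."""
    t = np.arange(int(duration * config.sampling_rate)) / config.sampling_rate
    ang = start_angle + config.rotation_sign * config.rotation_rate * t
    return make_trajectory(t, radius * np.cos(ang), radius * np.sin(ang), config)


class TestPerformanceMeasures:
    def test_never_entering_sector(self, config):
        traj = stationary_in_arena(config, 60.0,
                                   config.sector_centre + math.pi, radius=0.0)
        # radius 0 is always outside; use a fixed point opposite the sector
        t = np.arange(1500) / 25.0
        traj = make_trajectory(t, np.full(1500, -20.0), np.zeros(1500), config)
        # a room-fixed point never moves relative to the sector
        s = performance_measures(traj, config)
        assert s.n_entrances == 0
        assert s.n_shocks == 0
        assert s.time_to_first_shock == traj.duration
        assert s.max_time_avoided == pytest.approx(traj.duration)

    def test_passive_rotation_oracle(self, config):
        # stationary (arena frame) animal starting just outside the sector's
        # leading edge: one entrance per 60 s revolution, 10 s dwell each
        # (60 of 360 degrees), 7 shock pulses per dwell (entry + every 1.5 s)
        half = config.sector_width / 2
        eps = 1e-4
        start = config.sector_centre - config.rotation_sign * (half + eps)
        traj = stationary_in_arena(config, 1200.0, start)
        s = performance_measures(traj, config, simulate_shocks=True)
        assert s.n_entrances == 20
        assert s.n_shocks == 20 * 7
        assert s.max_time_avoided == pytest.approx(50.0, abs=0.1)
        assert s.path_length == pytest.approx(0.0, abs=1e-6)

    def test_single_entrance_interval_arithmetic(self, static_config):
        fs = static_config.sampling_rate
        t = np.arange(int(1200 * fs)) / fs
        ang = np.full(len(t), math.pi)
        ang[(t >= 300) & (t < 310)] = static_config.sector_centre
        traj = make_trajectory(t, 20 * np.cos(ang), 20 * np.sin(ang), static_config)
        s = performance_measures(traj, static_config, simulate_shocks=True)
        assert s.n_entrances == 1
        assert s.time_to_first_shock == pytest.approx(300.0, abs=0.05)
        # the avoided span from exit (310) to session end (~1200)
        assert s.max_time_avoided == pytest.approx(890.0, abs=0.1)

    def test_starting_inside_counts_as_entrance(self, static_config):
        t = np.arange(250) / 25.0
        ang = np.full(250, static_config.sector_centre)
        ang[125:] = math.pi
        traj = make_trajectory(t, 20 * np.cos(ang), 20 * np.sin(ang), static_config)
        assert performance_measures(traj, static_config).n_entrances == 1

    def test_average_speed_is_path_over_duration(self, static_config):
        t = np.arange(0, 100, 0.04)
        x = -30 + 3.0 * t * 60 / 100  # straight line
        traj = make_trajectory(t, x, np.full(len(t), 10.0), static_config)
        s = performance_measures(traj, static_config)
        assert s.average_speed == pytest.approx(s.path_length / traj.duration)

    def test_shock_conservation_rule(self, config, small_cohort):
        # total simulated shocks = sum over dwells of 1 + floor(dwell/interval)
        _, trajectories, _ = small_cohort
        traj = trajectories[0]
        flags = simulate_shock_flags(traj, config)
        onsets = int(np.sum(np.diff(np.concatenate([[0], flags.astype(int)])) == 1))
        inside = in_sector(traj.x, traj.y, config)
        expected = 0
        i, n = 0, len(inside)
        while i < n:
            if inside[i]:
                j = i
                while j + 1 < n and inside[j + 1]:
                    j += 1
                expected += 1 + int((traj.t[j] - traj.t[i]) / config.shock_interval)
                i = j + 1
            else:
                i += 1
        assert onsets == expected

    def test_max_time_avoided_at_least_first_entrance_latency(self, config,
                                                              small_cohort):
        _, trajectories, _ = small_cohort
        for traj in trajectories:
            s = performance_measures(traj, config)
            inside = in_sector(traj.x, traj.y, config)
            first_in = traj.t[np.argmax(inside)] if inside.any() else traj.duration
            assert s.max_time_avoided >= first_in - traj.t[0] - 1e-9


class TestStrategyPercentages:
    def frame(self, labels, animal="a1", group="g", session=1):
        return pd.DataFrame({"animal_id": animal, "group": group,
                             "session": session, "label": labels})

    def test_single_class_is_100(self):
        pct = strategy_percentages(self.frame(["thigmotaxis"] * 4))
        assert pct.loc[0, "thigmotaxis"] == pytest.approx(100.0)

    def test_three_to_one_split(self):
        pct = strategy_percentages(self.frame(["thigmotaxis"] * 3 + ["avoidance"]))
        assert pct.loc[0, "thigmotaxis"] == pytest.approx(75.0)
        assert pct.loc[0, "avoidance"] == pytest.approx(25.0)

    def test_rows_sum_to_100_random(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["thigmotaxis", "incursion", "focused", "chaining",
                             "avoidance", "unidentified"], size=200)
        animals = rng.choice(["a1", "a2", "a3"], size=200)
        sessions = rng.integers(1, 4, size=200)
        df = pd.DataFrame({"animal_id": animals, "group": "g",
                           "session": sessions, "label": labels})
        pct = strategy_percentages(df)
        label_cols = [c for c in pct.columns if c not in ("animal_id", "group", "session")]
        assert np.allclose(pct[label_cols].sum(axis=1), 100.0)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            strategy_percentages(pd.DataFrame({"label": ["x"]}))


def exhaustive_permutation_p(data, observed):
    """Exact within-block permutation null computed independently."""
    data = np.asarray(data, float)
    n, k = data.shape
    perms = list(itertools.permutations(range(k)))
    count, total = 0, 0
    for combo in itertools.product(perms, repeat=n):
        permuted = np.stack([data[i, list(p)] for i, p in enumerate(combo)])
        stat = friedman_test(permuted).statistic
        if stat >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


class TestFriedman:
    def test_identical_columns_null(self):
        res = friedman_test(np.ones((5, 3)))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_ordered_table_closed_form(self):
        # 3 treatments x 4 blocks, strictly ordered within every block:
        # rank sums (4, 8, 12) give chi2 = 12/(4*3*4)*(16+64+144) - 3*4*4 = 8
        data = np.tile([1.0, 2.0, 3.0], (4, 1)) + np.arange(4)[:, None] * 10
        res = friedman_test(data)
        assert res.statistic == pytest.approx(8.0)
        assert res.df == 2
        assert res.p_value == pytest.approx(float(sps.chi2.sf(8.0, 2)))

    def test_matches_scipy_with_and_without_ties(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            data = rng.integers(0, 5, size=(8, 4)).astype(float)  # many ties
            ours = friedman_test(data)
            ref = sps.friedmanchisquare(*data.T)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-9)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_p_matches_independent_enumeration(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(4, 3))
        res = friedman_test(data, method="exact")
        assert res.p_value == pytest.approx(exhaustive_permutation_p(data,
                                                                     res.statistic))

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(6, 3))
        a = friedman_test(data)
        b = friedman_test(np.exp(data))
        assert a.statistic == pytest.approx(b.statistic)

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            friedman_test(np.ones((1, 3)))
        with pytest.raises(ValueError):
            friedman_test(np.ones((3, 1)))


class TestGroupComparison:
    def cohort_frame(self, rng, shift=0.0):
        rows = []
        for g, delta in (("control", 0.0), ("treated", shift)):
            for a in range(8):
                for s in range(1, 7):
                    rows.append({"animal_id": f"{g}{a}", "group": g, "session": s,
                                 "value": rng.normal(delta, 1.0)})
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(4)
        df = self.cohort_frame(rng, shift=0.0)
        res = friedman_group_test(df, "value")
        assert res.p_value > 0.05

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        df = self.cohort_frame(rng, shift=3.0)
        res = friedman_group_test(df, "value")
        assert res.p_value < 0.05

    def test_session_six_excluded_from_tests(self):
        rng = np.random.default_rng(6)
        df = self.cohort_frame(rng, shift=0.0)
        # plant a huge difference only in the retrieval session
        df.loc[(df["session"] == 6) & (df["group"] == "treated"), "value"] += 100
        res = friedman_group_test(df, "value")
        assert res.p_value > 0.05  # session 6 cannot drive the result

    def test_group_report_tables(self, config, small_cohort):
        _, trajectories, _ = small_cohort
        summaries = summarize_sessions(trajectories, config)
        rng = np.random.default_rng(7)
        labels = pd.DataFrame({
            "animal_id": rng.choice(summaries["animal_id"].unique(), 120),
            "group": "control", "session": rng.integers(1, 3, 120),
            "label": rng.choice(["thigmotaxis", "avoidance"], 120),
        })
        labels["group"] = labels["animal_id"].str[:4].map(
            {"cont": "control", "trea": "treated"})
        rep = group_report(summaries, strategy_percentages(labels),
                           sessions=(1, 2))
        assert {"measures", "strategies", "friedman"} <= set(rep)
        assert set(rep["measures"]["session"]) == {1, 2}
        assert (rep["friedman"]["p_value"] <= 1).all()
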