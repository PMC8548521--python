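"""Analysis battery: tortuosity, trial metrics, curves, heat maps, tests."""

import math
import warnings

import numpy as np
import pytest

from apivr.geometry import ArenaConfig
from apivr.metrics import (
    learning_curves,
    occupancy_heatmap,
    paired_fixation_test,
    fixation_times,
    tortuosity,
    trial_metrics,
)
from apivr.protocol import BeeLog, Choice, Phase, TrialLog


def _path_length_oracle(xy):
    total = 0.0
    for a, b in zip(xy, xy[1:]):
        total += math.hypot(b[0] - a[0], b[1] - a[1])
    return total


class TestTortuosity:
    def test_straight_path_is_exactly_one(self):
        xy = np.column_stack([np.zeros(10), np.linspace(0, 9, 10)])
        assert tortuosity(xy) == 1.0

    def test_half_circle_is_pi_over_two(self):
        theta = np.linspace(0, np.pi, 50_001)
        xy = np.column_stack([np.cos(theta), np.sin(theta)])
        expected = _path_length_oracle(xy) / 2.0
        val = tortuosity(xy)
        assert val == pytest.approx(expected, abs=1e-9)
        assert val == pytest.approx(math.pi / 2, abs=1e-6)

    def test_closed_loop_flagged_undefined(self):
        xy = [(0, 0), (1, 0), (1, 1), (0, 0)]
        with pytest.warns(UserWarning):
            assert tortuosity(xy) is None

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            tortuosity([(0.0, 0.0)])

    def test_matches_brute_force_oracle_on_random_paths(self, rng):
        for _ in range(300):
            n = rng.integers(2, 12)
            xy = rng.normal(size=(n, 2)) * 10
            chord = math.hypot(*(xy[-1] - xy[0]))
            if chord < 1e-6:
                continue
            expected = _path_length_oracle(xy) / chord
            assert tortuosity(xy) == pytest.approx(expected, rel=1e-12)
            assert tortuosity(xy) >= 1.0 - 1e-12

    def test_equality_only_for_collinear_monotone_paths(self, rng):
        for _ in range(200):
            xy = rng.normal(size=(5, 2)) * 5
            val = tortuosity(xy)
            if val is None:
                continue
            steps = np.diff(xy, axis=0)
            collinear_monotone = np.allclose(
                np.sqrt((steps**2).sum(1)).sum(),
                math.hypot(*(xy[-1] - xy[0])),
                atol=1e-9,
            )
            assert (abs(val - 1.0) < 1e-9) == collinear_monotone


def _straight_log(speed=2.0, duration=10.0, tick=0.017):
    n = int(round(duration / tick))
    log = TrialLog(phase=Phase.TRAIN, trial_index=0, choice=Choice.NC)
    for k in range(n):
        log.t.append((k + 1) * tick)
        log.x.append(0.0)
        log.y.append(speed * (k + 1) * tick)
        log.heading.append(0.0)
        log.locked.append(False)
        log.fix_plus.append(False)
        log.fix_minus.append(False)
    return log


class TestTrialMetrics:
    def test_scripted_straight_walk(self):
        log = _straight_log(speed=2.0, duration=10.0)
        m = trial_metrics(log)
        # 10 s at a 0.017 s tick is 588 whole ticks (9.996 s of motion)
        assert m.distance == pytest.approx(2.0 * 10.0, abs=0.05)
        assert m.mean_speed == pytest.approx(2.0, rel=1e-9)
        assert m.tortuosity == pytest.approx(1.0)
        assert m.cumulative_turning == 0.0

    def test_nc_trial_has_no_latency(self):
        m = trial_metrics(_straight_log())
        assert m.choice is Choice.NC and m.latency is None

    def test_constant_left_spin_accumulates_turning(self):
        tick = 0.017
        n = int(round(60.0 / tick))
        log = TrialLog(phase=Phase.TRAIN, trial_index=0)
        h = 0.0
        for k in range(n):
            h += 10.0 * tick  # 10 deg/s leftward
            log.t.append((k + 1) * tick)
            log.x.append(0.0)
            log.y.append(0.0)
            log.heading.append((h + 180.0) % 360.0 - 180.0)
            log.locked.append(False)
            log.fix_plus.append(False)
            log.fix_minus.append(False)
        m = trial_metrics(log, tick)
        assert m.cumulative_turning == pytest.approx(10.0 * n * tick, rel=1e-9)

    def test_locked_portion_excluded(self):
        log = _straight_log(duration=10.0)
        # append a frozen lock tail
        for k in range(100):
            log.t.append(log.t[-1] + 0.017)
            log.x.append(log.x[-1])
            log.y.append(log.y[-1])
            log.heading.append(0.0)
            log.locked.append(True)
            log.fix_plus.append(False)
            log.fix_minus.append(False)
        m = trial_metrics(log)
        assert m.distance == pytest.approx(20.0, abs=0.05)
        assert m.mean_speed == pytest.approx(2.0, rel=1e-9)


class TestFixationTimes:
    def test_tick_counting(self, arena):
        log = TrialLog(phase=Phase.TEST, trial_index=0)
        for k in range(1000):
            log.t.append((k + 1) * arena.tick)
            log.x.append(0.0)
            log.y.append(0.0)
            log.heading.append(0.0)
            log.locked.append(False)
            log.fix_plus.append(k < 100)
            log.fix_minus.append(False)
        t_plus, t_minus = fixation_times(log, arena)
        assert t_plus == pytest.approx(1.7)
        assert t_minus == 0.0
        assert t_plus + t_minus <= 60.0

    def test_requires_test_phase(self, arena):
        log = TrialLog(phase=Phase.TRAIN, trial_index=0)
        with pytest.raises(ValueError):
            fixation_times(log, arena)


def _bee(choices, bee_id=0):
    trials = [
        TrialLog(phase=Phase.TRAIN, trial_index=i, choice=c) for i, c in enumerate(choices)
    ]
    return BeeLog(bee_id, "blue", "green", trials, None, 0)


class TestLearningCurves:
    def test_degenerate_cohort_has_unit_proportion_and_ci(self):
        bees = [_bee([Choice.CS_PLUS] * 3, i) for i in range(8)]
        df = learning_curves(bees, n_boot=200, seed=0)
        plus = df[df["category"] == "cs_plus"]
        assert (plus["proportion"] == 1.0).all()
        assert (plus["ci_low"] == 1.0).all() and (plus["ci_high"] == 1.0).all()

    def test_proportions_sum_to_one_and_cis_bracket_estimate(self, rng):
        cats = [Choice.CS_PLUS, Choice.CS_MINUS, Choice.NC]
        bees = [
            _bee([cats[rng.integers(3)] for _ in range(10)], i) for i in range(30)
        ]
        df = learning_curves(bees, n_boot=500, seed=1)
        sums = df.groupby("trial")["proportion"].sum()
        assert np.allclose(sums, 1.0)
        assert (df["ci_low"] <= df["proportion"] + 1e-12).all()
        assert (df["ci_high"] >= df["proportion"] - 1e-12).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            learning_curves([], n_boot=200)


class TestOccupancy:
    def _stationary_log(self, n=100, x=3.2, y=7.8, side="right"):
        log = TrialLog(phase=Phase.TRAIN, trial_index=0, cs_plus_side=side)
        for k in range(n):
            log.t.append((k + 1) * 0.017)
            log.x.append(x)
            log.y.append(y)
            log.heading.append(0.0)
            log.locked.append(False)
            log.fix_plus.append(False)
            log.fix_minus.append(False)
        return log

    def test_single_occupied_bin_and_cap(self):
        grid = occupancy_heatmap([self._stationary_log(100)])
        assert grid.counts.max() == 100
        assert (grid.counts > 0).sum() == 1
        assert grid.display_cap == pytest.approx(10.0)

    def test_counts_conserve_samples(self, rng):
        logs = [self._stationary_log(50, rng.uniform(-40, 40), rng.uniform(-40, 40)) for _ in range(5)]
        grid = occupancy_heatmap(logs)
        assert grid.counts.sum() == 250

    def test_side_reflection_mirrors_grid(self):
        left = occupancy_heatmap([self._stationary_log(10, x=3.0, side="left")])
        right = occupancy_heatmap([self._stationary_log(10, x=-3.0, side="right")])
        assert np.array_equal(left.counts, right.counts)


class TestPairedFixationTest:
    def test_identical_arrays_flagged_with_p_one(self):
        with pytest.warns(UserWarning):
            stat, p = paired_fixation_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p == 1.0

    def test_constant_shift_exact_p(self):
        t_minus = np.arange(10, dtype=float)
        stat, p = paired_fixation_test(t_minus + 1.0, t_minus)
        assert stat == 55.0
        assert p == pytest.approx(2.0 / 2**10, abs=1e-9)

    def test_swapping_arrays_preserves_p(self, rng):
        a = rng.uniform(0, 10, 12)
        b = rng.uniform(0, 10, 12)
        _, p1 = paired_fixation_test(a, b)
        _, p2 = paired_fixation_test(b, a)
        assert p1 == pytest.approx(p2)

    def test_requires_five_pairs(self):
        with pytest.raises(ValueError):
            paired_fixation_test([1, 2], [3, 4])
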