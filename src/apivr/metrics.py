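"""Trajectory and choice analytics.

Implements the full descriptive battery of the paradigm: per-trial motor
metrics (distance, speed, tortuosity, cumulative turning, choice latency),
per-test fixation times, learning curves as per-trial category proportions
with percentile-bootstrap confidence intervals, occupancy heat maps binned
at 1 cm^2 with the display colour scale capped at 10% of the maximum bin,
and the paired signed-rank comparison of fixation times.

Cohort-level inference is deliberately descriptive (proportions, bootstrap
CIs, signed-rank tests); no mixed-model machinery lives here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ArenaConfig
from .protocol import BeeLog, Choice, Phase, TrialLog

__all__ = [
    "TrialMetrics",
    "OccupancyGrid",
    "tortuosity",
    "trial_metrics",
    "fixation_times",
    "learning_curves",
    "occupancy_heatmap",
    "paired_fixation_test",
    "metrics_table",
]

CATEGORIES = (Choice.CS_PLUS, Choice.CS_MINUS, Choice.NC)


@dataclass(frozen=True)
class TrialMetrics:
    """Per-trial summary: choice category, latency (s; None for NC),
    distance walked (cm), mean speed (cm/s), tortuosity (>= 1; None when the
    path closes on itself) and signed cumulative turning (deg, leftward
    positive)."""

    choice: Choice
    latency: Optional[float]
    distance: float
    mean_speed: float
    tortuosity: Optional[float]
    cumulative_turning: float


@dataclass(frozen=True)
class OccupancyGrid:
    """Binned spatial occupancy. ``counts`` holds raw per-bin sample counts;
    ``display_cap`` is the colour-scale ceiling (10% of the max bin) applied
    at render time only."""

    bin_size: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    display_cap: float


def tortuosity(xy: np.ndarray, eps: float = 1e-9) -> Optional[float]:
    """Path length divided by the straight-line distance between the first
    and last point. 1 for a straight path, pi/2 for a half circle; None
    (with a warning) when the trajectory closes on itself."""
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[0] < 2 or xy.shape[1] != 2:
        raise ValueError("need at least two 2-D points")
    steps = np.diff(xy, axis=0)
    path = float(np.sqrt((steps**2).sum(axis=1)).sum())
    chord = float(np.hypot(*(xy[-1] - xy[0])))
    if chord < eps:
        warnings.warn("closed-loop trajectory: tortuosity undefined", stacklevel=2)
        return None
    return path / chord


def _heading_increments(heading: Sequence[float]) -> np.ndarray:
    """Signed per-tick heading changes (deg), unwrapped across the +/-180
    seam, leftward positive."""
    h = np.asarray(heading, dtype=float)
    if h.size < 2:
        return np.zeros(0)
    d = np.diff(h)
    d = (d + 180.0) % 360.0 - 180.0
    return d


def trial_metrics(
    log: TrialLog,
    tick: float = 0.017,
    start: Tuple[float, float] = (0.0, 0.0),
    start_heading: float = 0.0,
) -> TrialMetrics:
    """Summarise one trial log over its pre-lock portion.

    The trajectory starts at the arena start pose (origin by default), which
    precedes the first logged sample by one tick of motion.
    """
    locked = np.asarray(log.locked, dtype=bool)
    n_free = int(np.argmax(locked)) if locked.any() else len(log.t)
    if n_free < 1:
        return TrialMetrics(log.choice, log.latency, 0.0, 0.0, None, 0.0)
    xy = np.column_stack(
        [
            np.concatenate([[start[0]], log.x[:n_free]]),
            np.concatenate([[start[1]], log.y[:n_free]]),
        ]
    )
    steps = np.diff(xy, axis=0)
    distance = float(np.sqrt((steps**2).sum(axis=1)).sum())
    elapsed = n_free * tick
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tort = tortuosity(xy)
    heading = np.concatenate([[start_heading], log.heading[:n_free]])
    turning = float(_heading_increments(heading).sum())
    return TrialMetrics(
        choice=log.choice,
        latency=log.latency,
        distance=distance,
        mean_speed=distance / elapsed if elapsed > 0 else 0.0,
        tortuosity=tort,
        cumulative_turning=turning,
    )


def fixation_times(log: TrialLog, arena: ArenaConfig) -> Tuple[float, float]:
    """Seconds spent with the CS+ (resp. CS-) centre inside the screen-centre
    window during a test, as tick counts times the tick length."""
    if log.phase is not Phase.TEST:
        raise ValueError("fixation times are defined for test logs only")
    t_plus = arena.tick * sum(log.fix_plus)
    t_minus = arena.tick * sum(log.fix_minus)
    return (t_plus, t_minus)


def learning_curves(
    bees: Sequence[BeeLog],
    n_boot: int = 10_000,
    seed: int = 0,
    n_trials: Optional[int] = None,
) -> pd.DataFrame:
    """Per-trial category proportions with 95% percentile-bootstrap CIs.

    Each bee contributes a one-hot (CS+, CS-, NC) vector per trial, so the
    three proportions sum to 1 in every trial and every bootstrap replicate.
    Bees are resampled with replacement; CIs are the 2.5/97.5 percentiles.
    """
    if not bees:
        raise ValueError("empty cohort")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    n_trials = n_trials or max(len(b.trials) for b in bees)
    n = len(bees)
    onehot = np.zeros((n, n_trials, len(CATEGORIES)))
    for i, bee in enumerate(bees):
        for j, tr in enumerate(bee.trials[:n_trials]):
            onehot[i, j, CATEGORIES.index(tr.choice)] = 1.0
    props = onehot.mean(axis=0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = onehot[idx].mean(axis=1)  # (n_boot, n_trials, 3)
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    rows = []
    for j in range(n_trials):
        for k, cat in enumerate(CATEGORIES):
            rows.append(
                {
                    "trial": j + 1,
                    "category": cat.value,
                    "proportion": props[j, k],
                    "ci_low": lo[j, k],
                    "ci_high": hi[j, k],
                }
            )
    return pd.DataFrame(rows)


def occupancy_heatmap(
    logs: Sequence[TrialLog],
    bin_size: float = 1.0,
    cap_fraction: float = 0.10,
    extent: float = 50.0,
    reflect_cs_plus_to: Optional[str] = "right",
) -> OccupancyGrid:
    """Accumulate pose samples into ``bin_size`` cm bins.

    When ``reflect_cs_plus_to`` is set, logs whose CS+ sat on the other side
    are mirrored about the x = 0 axis first, so the rewarded stimulus ends
    up on a fixed side by convention. Raw counts are preserved; the 10% cap
    applies to the rendering colour scale only.
    """
    xs: List[np.ndarray] = []
    ys: List[np.ndarray] = []
    for log in logs:
        x = np.asarray(log.x, dtype=float)
        y = np.asarray(log.y, dtype=float)
        if (
            reflect_cs_plus_to is not None
            and log.cs_plus_side is not None
            and log.cs_plus_side != reflect_cs_plus_to
        ):
            x = -x
        xs.append(x)
        ys.append(y)
    if not xs:
        raise ValueError("no logs supplied")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    edges = np.arange(-extent, extent + bin_size, bin_size)
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=(edges, edges))
    counts = counts.astype(np.int64)
    return OccupancyGrid(
        bin_size=bin_size,
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        display_cap=cap_fraction * counts.max() if counts.size else 0.0,
    )


def paired_fixation_test(
    t_plus: Sequence[float], t_minus: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired fixation times.

    Exact null distribution for n <= 25 pairs, normal approximation with
    tie correction otherwise. Returns (V statistic, p value); a degenerate
    all-zero difference vector raises a ValueError.
    """
    a = np.asarray(t_plus, dtype=float)
    b = np.asarray(t_minus, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need at least 5 paired observations")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero: test degenerate", stacklevel=2)
        return 0.0, 1.0
    n_nonzero = int(np.count_nonzero(d))
    method = "exact" if n_nonzero <= 25 else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method, zero_method="wilcox")
    # report V as the positive-rank sum (R's convention), not scipy's min(R+, R-)
    nz = d[d != 0]
    ranks = stats.rankdata(np.abs(nz))
    v_stat = float(ranks[nz > 0].sum())
    return v_stat, float(res.pvalue)


def metrics_table(bees: Sequence[BeeLog], tick: float = 0.017) -> pd.DataFrame:
    """Per-bee per-trial metrics as a tidy DataFrame."""
    rows = []
    for bee in bees:
        for tr in bee.trials:
            m = trial_metrics(tr, tick)
            rows.append(
                {
                    "bee_id": bee.bee_id,
                    "trial": tr.trial_index + 1,
                    "cs_plus_color": bee.cs_plus_color,
                    "choice": m.choice.value,
                    "latency_s": m.latency,
                    "distance_cm": m.distance,
                    "mean_speed_cm_s": m.mean_speed,
                    "tortuosity": m.tortuosity,
                    "cumulative_turning_deg": m.cumulative_turning,
                }
            )
    return pd.DataFrame(rows)
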