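"""Gait-event detection and summary statistics.

Events are extracted from the decimated trajectory log: a touchdown is a
downward crossing of the ground level (z = 0) by a foot, a liftoff an
upward crossing; chatter faster than a debounce window is merged away.  A
"step" is a touchdown event.  The statistical helpers (Pearson
correlation, Student's pooled-variance t-test) are thin wrappers around
scipy that also report the degrees of freedom used throughout the
analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .state import LEFT, RIGHT
from .trajectory import Trajectory

__all__ = [
    "FootEvents", "GaitEvents", "StepIntervalStats",
    "detect_events", "step_intervals", "count_steps", "peak_heights",
    "pearson", "unpaired_t", "mean_velocity",
]


@dataclass
class FootEvents:
    """Ordered touchdown and liftoff times of one foot [s]."""

    touchdowns: np.ndarray
    liftoffs: np.ndarray
    initially_grounded: bool

    def __post_init__(self) -> None:
        events = [(t, "td") for t in self.touchdowns] + [
            (t, "lo") for t in self.liftoffs
        ]
        events.sort()
        kinds = [k for _, k in events]
        if any(a == b for a, b in zip(kinds, kinds[1:])):
            raise ValueError("touchdowns and liftoffs must strictly alternate")


@dataclass
class GaitEvents:
    right: FootEvents
    left: FootEvents

    def foot(self, index: int) -> FootEvents:
        if index == RIGHT:
            return self.right
        if index == LEFT:
            return self.left
        raise ValueError("foot index must be RIGHT (1) or LEFT (2)")


def _drop_short_regimes(trans: list[tuple[float, bool]], debounce: float,
                        leading_td: bool) -> list[tuple[float, bool]]:
    """Remove adjacent transition pairs enclosing a regime shorter than the
    debounce window; ``leading_td`` selects which pair type to drop."""
    out: list[tuple[float, bool]] = []
    i = 0
    while i < len(trans):
        if (
            i + 1 < len(trans)
            and trans[i][1] is leading_td
            and trans[i + 1][1] is (not leading_td)
            and trans[i + 1][0] - trans[i][0] < debounce
        ):
            i += 2
            continue
        out.append(trans[i])
        i += 1
    return out


def _detect_foot(t: np.ndarray, z: np.ndarray, debounce: float) -> FootEvents:
    grounded = z <= 0.0
    change = np.flatnonzero(grounded[1:] != grounded[:-1]) + 1
    trans = [(float(t[i]), bool(grounded[i])) for i in change]
    # merge contact across short bounces first, then drop short taps
    trans = _drop_short_regimes(trans, debounce, leading_td=False)
    trans = _drop_short_regimes(trans, debounce, leading_td=True)
    touchdowns = np.array([ti for ti, td in trans if td])
    liftoffs = np.array([ti for ti, td in trans if not td])
    return FootEvents(touchdowns, liftoffs, bool(grounded[0]))


def detect_events(traj: Trajectory, debounce: float = 0.02) -> GaitEvents:
    """Extract per-foot touchdown/liftoff times from a trajectory.

    ``debounce`` [s] merges contact chatter: a pair of opposite transitions
    closer than the window cancels out.  Event times are the first sample
    of the new contact regime, so crossing times are recovered to one
    sample of the decimated log.
    """
    if len(traj) < 2:
        return GaitEvents(
            FootEvents(np.array([]), np.array([]), True),
            FootEvents(np.array([]), np.array([]), True),
        )
    return GaitEvents(
        right=_detect_foot(traj.t, traj.foot_height(RIGHT), debounce),
        left=_detect_foot(traj.t, traj.foot_height(LEFT), debounce),
    )


@dataclass
class StepIntervalStats:
    """Step-interval series of one foot with summary statistics."""

    intervals: np.ndarray
    mean: float
    sd: float

    @property
    def cv(self) -> float:
        """Coefficient of variation (sd / mean)."""
        return self.sd / self.mean


def step_intervals(
    events: FootEvents, step_range: tuple[int, int] | None = None
) -> StepIntervalStats:
    """Intervals between successive touchdowns of the same foot.

    The k-th step is the k-th touchdown (1-indexed) and its interval is
    the time since the previous touchdown, so ``step_range=(11, 100)``
    selects the 90 intervals ending at touchdowns 11 through 100.  A
    trajectory with fewer touchdowns than the requested range raises a
    shortfall error.
    """
    td = np.asarray(events.touchdowns)
    if step_range is None:
        if td.size < 2:
            raise ValueError(f"need >= 2 touchdowns, got {td.size}")
        intervals = np.diff(td)
    else:
        first, last = step_range
        if first < 2 or last < first:
            raise ValueError("step_range must satisfy 2 <= first <= last")
        if td.size < last:
            raise ValueError(
                f"requested steps {first}..{last} but only {td.size} touchdowns available"
            )
        intervals = np.diff(td)[first - 2 : last - 1]
    mean = float(intervals.mean())
    sd = float(intervals.std(ddof=1)) if intervals.size > 1 else 0.0
    return StepIntervalStats(intervals, mean, sd)


def count_steps(events: GaitEvents, window: tuple[float, float]) -> dict[int, int]:
    """Touchdowns per foot inside the half-open window [t0, t1)."""
    t0, t1 = window
    out = {}
    for foot in (RIGHT, LEFT):
        td = events.foot(foot).touchdowns
        out[foot] = int(np.count_nonzero((td >= t0) & (td < t1)))
    return out


def peak_heights(
    traj: Trajectory,
    events: GaitEvents,
    normalization: float | None = None,
) -> dict[int, np.ndarray]:
    """Maximum foot height per flight phase, optionally trunk-normalized.

    A flight phase runs from a liftoff to the next touchdown (or the end
    of the trajectory).  Returns per-foot arrays of peak heights; with
    ``normalization`` (the trunk height) the peaks are expressed as a
    fraction of it.
    """
    out = {}
    for foot in (RIGHT, LEFT):
        ev = events.foot(foot)
        z = traj.foot_height(foot)
        peaks = []
        for lo in ev.liftoffs:
            later_td = ev.touchdowns[ev.touchdowns > lo]
            t1 = later_td[0] if later_td.size else traj.t[-1] + np.inf
            mask = (traj.t >= lo) & (traj.t < t1)
            if mask.any():
                peaks.append(float(z[mask].max()))
        arr = np.array(peaks)
        if normalization is not None:
            arr = arr / normalization
        out[foot] = arr
    return out


def pearson(x, y) -> tuple[float, int, float]:
    """Pearson correlation with (r, df, two-sided p), df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in an input sample")
    res = stats.pearsonr(x, y)
    return float(res.statistic), x.size - 2, float(res.pvalue)


def unpaired_t(x, y) -> tuple[float, int, float]:
    """Student's pooled-variance unpaired t-test: (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), x.size + y.size - 2, float(res.pvalue)


def mean_velocity(traj: Trajectory, window: tuple[float, float]) -> float:
    """|net lateral trunk displacement| / duration over a time window."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive duration")
    if t0 < traj.t[0] - 1e-12 or t1 > traj.t[-1] + 1e-12:
        raise ValueError("window outside trajectory")
    x0 = float(np.interp(t0, traj.t, traj.trunk_x))
    x1 = float(np.interp(t1, traj.t, traj.trunk_x))
    return abs(x1 - x0) / (t1 - t0)
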