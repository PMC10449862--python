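"""Live-betting ("Slot or Not") behavioral analysis.

Participants can switch between a sure amount (state 0) and the slot machine
(state 1) at any moment while the reel spins, up to 750 ms after it stops.
The switch record of each trial is converted to a binary timeseries on a
50-ms stop-locked grid; per-outcome means of these series are the behavioral
expectation trajectories.

Window-membership convention (shared with the ERP module): each of the six
500-ms deceleration windows is half-open [a, b), except the last window
[-0.5, 0] which is closed at 0 so the standstill sample is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outcomes import CONDITION_ORDER, OutcomeClass

__all__ = [
    "GRID_STEP",
    "DECEL_WINDOWS",
    "ChoiceEvent",
    "ChoiceTimeseries",
    "ConditionCurves",
    "events_to_timeseries",
    "exclude_participants",
    "condition_curves",
    "group_curves",
    "behavior_window_means",
    "window_mask",
    "slope_stat",
    "SlopeResult",
    "read_event_log",
    "write_event_log",
]

#: Grid spacing of the betting timeseries (seconds).
GRID_STEP = 0.050

#: The six 500-ms deceleration analysis windows, stop-locked (seconds).
DECEL_WINDOWS: tuple[tuple[float, float], ...] = (
    (-3.0, -2.5),
    (-2.5, -2.0),
    (-2.0, -1.5),
    (-1.5, -1.0),
    (-1.0, -0.5),
    (-0.5, 0.0),
)


@dataclass(frozen=True)
class ChoiceEvent:
    """A single choice (or choice switch): at ``time`` the participant's
    selected option becomes ``new_state`` (0 = sure amount, 1 = machine)."""

    participant: str
    trial: int
    time: float  # seconds, stop-locked
    new_state: int

    def __post_init__(self) -> None:
        if self.new_state not in (0, 1):
            raise ValueError(f"new_state must be 0 or 1, got {self.new_state}")


@dataclass
class ChoiceTimeseries:
    """Binary bet-state series on a fixed 50-ms stop-locked grid."""

    grid: np.ndarray
    values: np.ndarray
    outcome: OutcomeClass
    sure_amount: float
    participant: str = ""
    trial: int = -1
    n_switches: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same shape")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("values must be binary")


def events_to_timeseries(
    events: list[ChoiceEvent],
    trial_span: tuple[float, float],
    grid_step: float = GRID_STEP,
) -> ChoiceTimeseries:
    """Sample-and-hold conversion of a trial's switch events to a binary
    series: the value at grid time tau is the state set by the latest event
    with time <= tau.  Simultaneous events: the last one wins.

    The first event must sit at (or before) the trial start; it defines the
    initial state.  ``trial_span`` is (start, end) in stop-locked seconds.
    """
    if not events:
        raise ValueError("no events: an initial state is required")
    times = np.array([e.time for e in events], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("events must be sorted by time")
    start, end = trial_span
    if times[0] > start:
        raise ValueError(
            f"no initial state: first event at {times[0]:.3f}s is after trial start {start:.3f}s"
        )
    n = int(round((end - start) / grid_step)) + 1
    grid = start + grid_step * np.arange(n)
    states = np.array([e.new_state for e in events])
    # latest event with time <= tau; ties resolved by taking the last index
    idx = np.searchsorted(times, grid + 1e-12, side="right") - 1
    values = states[idx]
    n_switches = int(np.sum(np.diff(states) != 0))  # actual state changes
    return ChoiceTimeseries(
        grid=grid,
        values=values,
        outcome=OutcomeClass.FULL_AWAY,  # caller overwrites via metadata below
        sure_amount=np.nan,
        n_switches=n_switches,
    )


@dataclass
class ConditionCurves:
    """Per-outcome mean bet-probability curves on a common stop-locked grid.

    ``level`` records the unit of aggregation: 'participant' (mean over that
    participant's trials) or 'group' (unweighted mean of participant curves).
    """

    grid: np.ndarray
    curves: dict[OutcomeClass, np.ndarray]
    level: str = "participant"
    missing: tuple[OutcomeClass, ...] = field(default_factory=tuple)

    def curve(self, outcome: OutcomeClass) -> np.ndarray:
        return self.curves[outcome]


def _series_dataframe(series: list[ChoiceTimeseries]) -> pd.DataFrame:
    rows = []
    for s in series:
        rows.append(
            {
                "participant": s.participant,
                "trial": s.trial,
                "outcome": s.outcome,
                "n_switches": s.n_switches,
            }
        )
    return pd.DataFrame(rows)


def exclude_participants(
    sessions: dict[str, list[ChoiceTimeseries]], threshold: float = 0.90
) -> tuple[list[str], pd.DataFrame]:
    """Exclusion rule: a participant is dropped iff the fraction of their
    trials with zero switch events (over the whole trial, including the
    750 ms after the stop) is >= ``threshold``.

    Returns the retained participant ids and a per-participant report.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    retained: list[str] = []
    report_rows = []
    for pid, trials in sessions.items():
        if not trials:
            raise ValueError(f"participant {pid!r} has an empty session")
        n_zero = sum(1 for t in trials if t.n_switches == 0)
        frac = n_zero / len(trials)
        excluded = frac >= threshold
        if not excluded:
            retained.append(pid)
        report_rows.append(
            {
                "participant": pid,
                "n_trials": len(trials),
                "n_no_switch": n_zero,
                "fraction_no_switch": frac,
                "excluded": excluded,
            }
        )
    return retained, pd.DataFrame(report_rows)


def _common_grid(series: list[ChoiceTimeseries]) -> np.ndarray:
    grid = series[0].grid
    for s in series[1:]:
        if s.grid.shape != grid.shape or not np.allclose(s.grid, grid):
            raise ValueError("all series must share one stop-locked grid")
    return grid


def condition_curves(series: list[ChoiceTimeseries]) -> ConditionCurves:
    """Participant-level curves: mean over one participant's trials per
    outcome class.  Classes with zero trials are flagged and omitted."""
    if not series:
        raise ValueError("no series")
    grid = _common_grid(series)
    curves: dict[OutcomeClass, np.ndarray] = {}
    missing = []
    for oc in CONDITION_ORDER:
        vals = [s.values for s in series if s.outcome is oc]
        if not vals:
            missing.append(oc)
            continue
        curves[oc] = np.mean(np.asarray(vals, dtype=float), axis=0)
    return ConditionCurves(
        grid=grid, curves=curves, level="participant", missing=tuple(missing)
    )


def group_curves(participant_curves: list[ConditionCurves]) -> ConditionCurves:
    """Group-level curves: unweighted mean of participant-level curves
    (mean of means — the repeated-measures unit of analysis)."""
    if not participant_curves:
        raise ValueError("no participant curves")
    grid = participant_curves[0].grid
    curves: dict[OutcomeClass, np.ndarray] = {}
    missing = []
    for oc in CONDITION_ORDER:
        per = [pc.curves[oc] for pc in participant_curves if oc in pc.curves]
        if not per:
            missing.append(oc)
            continue
        curves[oc] = np.mean(np.asarray(per), axis=0)
    return ConditionCurves(grid=grid, curves=curves, level="group", missing=tuple(missing))


def window_mask(grid: np.ndarray, window: tuple[float, float], closed_end: bool) -> np.ndarray:
    """Grid-sample membership for a time window: [a, b) normally, [a, b]
    when ``closed_end`` (used for the final window ending at 0)."""
    a, b = window
    tol = 1e-9
    if closed_end:
        return (grid >= a - tol) & (grid <= b + tol)
    return (grid >= a - tol) & (grid < b - tol)


def behavior_window_means(
    participant_curves: dict[str, ConditionCurves],
    windows: tuple[tuple[float, float], ...] = DECEL_WINDOWS,
) -> pd.DataFrame:
    """Tidy table of per-participant, per-class, per-window curve means.

    The last window of ``windows`` is treated as closed at its right edge;
    all others are half-open [a, b).
    """
    rows = []
    for pid, pc in participant_curves.items():
        grid = pc.grid
        for wi, win in enumerate(windows):
            mask = window_mask(grid, win, closed_end=(wi == len(windows) - 1))
            if not mask.any():
                raise ValueError(f"window {win} contains no grid samples")
            for oc in CONDITION_ORDER:
                if oc not in pc.curves:
                    continue
                rows.append(
                    {
                        "participant": pid,
                        "outcome": str(oc),
                        "window_start": win[0],
                        "window_end": win[1],
                        "mean": float(pc.curves[oc][mask].mean()),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SlopeResult:
    """Per-participant OLS slopes of the bet tendency over a window, and the
    paired t contrast between two outcome classes."""

    slopes: pd.DataFrame  # columns: participant, outcome, slope
    class_a: OutcomeClass
    class_b: OutcomeClass
    t: float
    df: int
    p: float


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    t = t - t.mean()
    denom = float(np.dot(t, t))
    if denom == 0:
        raise ValueError("degenerate time axis")
    return float(np.dot(t, y - y.mean()) / denom)


def slope_stat(
    participant_curves: dict[str, ConditionCurves],
    window: tuple[float, float],
    class_a: OutcomeClass,
    class_b: OutcomeClass,
) -> SlopeResult:
    """Slope analysis: per participant and class, the OLS slope of the
    expectation curve regressed on time within ``window`` (closed interval),
    then a paired t-test on the ``class_a`` vs ``class_b`` slopes."""
    from .stats import paired_ttest

    if len(participant_curves) < 2:
        raise ValueError("need at least 2 participants")
    rows = []
    for pid, pc in participant_curves.items():
        mask = window_mask(pc.grid, window, closed_end=True)
        if mask.sum() < 2:
            raise ValueError(f"window {window} has fewer than 2 grid points")
        tt = pc.grid[mask]
        for oc in CONDITION_ORDER:
            if oc not in pc.curves:
                continue
            rows.append(
                {"participant": pid, "outcome": str(oc), "slope": _ols_slope(tt, pc.curves[oc][mask])}
            )
    slopes = pd.DataFrame(rows)
    wide = slopes.pivot(index="participant", columns="outcome", values="slope")
    a = wide[str(class_a)].to_numpy()
    b = wide[str(class_b)].to_numpy()
    if np.ptp(a - b) == 0 and (a - b)[0] == 0:
        t, df, p = 0.0, a.size - 1, 1.0
    else:
        t, df, p = paired_ttest(a, b)
    return SlopeResult(slopes=slopes, class_a=class_a, class_b=class_b, t=t, df=df, p=p)


# ---------------------------------------------------------------------------
# event-log IO (CSV columns: participant, trial, outcome, sure_amount,
# time_s, state)
# ---------------------------------------------------------------------------

LOG_COLUMNS = ["participant", "trial", "outcome", "sure_amount", "time_s", "state"]


def write_event_log(events: pd.DataFrame, path) -> None:
    missing = set(LOG_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event log missing columns: {sorted(missing)}")
    events[LOG_COLUMNS].to_csv(path, index=False)


def read_event_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event log {path} missing columns: {sorted(missing)}")
    return df


def log_to_sessions(
    log: pd.DataFrame, trial_span: tuple[float, float], grid_step: float = GRID_STEP
) -> dict[str, list[ChoiceTimeseries]]:
    """Convert a tidy event log into per-participant lists of binary
    timeseries, one per trial."""
    sessions: dict[str, list[ChoiceTimeseries]] = {}
    for (pid, trial), g in log.groupby(["participant", "trial"], sort=True):
        g = g.sort_values("time_s", kind="stable")
        events = [
            ChoiceEvent(str(pid), int(trial), float(r.time_s), int(r.state))
            for r in g.itertuples()
        ]
        ts = events_to_timeseries(events, trial_span, grid_step)
        ts.outcome = OutcomeClass(g["outcome"].iloc[0])
        ts.sure_amount = float(g["sure_amount"].iloc[0])
        ts.participant = str(pid)
        ts.trial = int(trial)
        sessions.setdefault(str(pid), []).append(ts)
    return sessions
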