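"""Synthetic slot-machine cohorts: trial schedules, reel kinematics, latent
expectation trajectories, live-betting choice logs and stop-locked EEG epochs.

The generator states a complete world with the structure the analyses assume:

* Trial designs and timing follow the task: a fast constant-speed spin
  (uniform over 850–1950 ms) followed by a linearly decelerating phase
  (uniform over 2533–4050 ms) that ends with the reel at a standstill (0 s).
  With linear deceleration the item that is ``j`` positions before the stop
  item crosses the payline at  t_j = -sqrt(2 j D / v0)  (D = deceleration
  duration, v0 = fast-spin speed in items/s); v0 is calibrated so the
  one-before-last item enters the payline at -0.685 s on average.
* Each outcome class has a latent unsigned match-expectation trajectory
  p(t) in [0, 1]: MATCH and NEAR_BEFORE rise monotonically toward the stop,
  NEAR_AFTER rises until the penultimate item enters the payline and then
  collapses (the player sees their item leave), FULL_AWAY decays early (the
  player's item passed the payline while the reel was still fast).
* Betting behavior is a discrete-time hazard process on a 50-ms grid: the
  player switches toward the option favored by the lagged trajectory at a
  rate proportional to how decisively it beats the sure amount.
* EEG epochs carry a CNV-like fronto-central ramp -gain * (p(t) - p0) on the
  midline channels (maximal at Cz) plus outcome-dependent post-stop FRN/P3
  bumps and Gaussian sensor noise.  The ramp tracks the *unsigned* match
  expectation, so gain and loss framings produce the same pre-stop signal.

One master seed determines everything; per-subject and per-trial substreams
are spawned deterministically from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import GRID_STEP
from .erp import Epoch, EpochSet
from .outcomes import (
    CONDITION_ORDER,
    GAIN_FRAMING,
    LOSS_FRAMING,
    STOP_DISTANCES,
    DomainFraming,
    OutcomeClass,
)

__all__ = [
    "SPIN_RANGE",
    "DECEL_RANGE",
    "PENULTIMATE_ENTRY",
    "STUDY_DESIGNS",
    "SimulationConfig",
    "TrialTiming",
    "TrialSchedule",
    "LatentTrajectory",
    "build_trial_schedule",
    "sample_trial_timing",
    "latent_expectation",
    "certainty_signal",
    "simulate_choices",
    "simulate_epochs",
    "simulate_behavioral_cohort",
    "simulate_coupled_curves",
    "fast_speed_for_calibration",
]

# Printed task timing (seconds).
SPIN_RANGE = (0.850, 1.950)
DECEL_RANGE = (2.533, 4.050)
#: Calibration constant: average payline-entry time of the one-before-last
#: item (seconds before the standstill).
PENULTIMATE_ENTRY = -0.685

#: Per-class trial counts of the four studies (EEG studies 1/3: 150 trials in
#: 3 blocks; behavioral studies 2/4: 36 trials).
STUDY_DESIGNS: dict[int, dict[OutcomeClass, int]] = {
    1: {
        OutcomeClass.MATCH: 25,
        OutcomeClass.NEAR_BEFORE: 25,
        OutcomeClass.NEAR_AFTER: 25,
        OutcomeClass.FULL_AWAY: 75,
    },
    2: {
        OutcomeClass.MATCH: 6,
        OutcomeClass.NEAR_BEFORE: 6,
        OutcomeClass.NEAR_AFTER: 6,
        OutcomeClass.FULL_AWAY: 18,
    },
}
STUDY_DESIGNS[3] = dict(STUDY_DESIGNS[1])
STUDY_DESIGNS[4] = dict(STUDY_DESIGNS[2])
STUDY_BLOCKS = {1: 3, 2: 1, 3: 3, 4: 1}

SURE_AMOUNTS = (1, 5, 10, 15, 20, 25)

#: Midline channels carried by synthetic epochs; scalp gain of the CNV-like
#: ramp per channel (maximal at the vertex).
CHANNELS = ("Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz")
RAMP_TOPOGRAPHY = {"Fz": 0.6, "FCz": 0.8, "Cz": 1.0, "CPz": 0.7, "Pz": 0.4, "POz": 0.2, "Oz": 0.1}

# Latent-trajectory shape constants (documented in the methods note).
# The pre-evidence expectation equals the objective match base rate of every
# study design (25/150 = 6/36 = 1/6), so mid-range sure amounts genuinely
# compete with the machine early in the trial.
P0 = 1.0 / 6.0
RISE_TAU = 0.25  # s, steepness of the pre-stop rise
DECAY_TAU = 0.15  # s, collapse rate once the outcome is visibly decided
P_FLOOR = 0.03  # residual expectation once a miss is certain
MATCH_HALF, MATCH_MAX = -1.00, 0.95
NB_HALF, NB_MAX = -0.85, 0.90

# Post-outcome component amplitudes (μV) by class: FRN (negative, fronto-
# central, ~250 ms) larger for a match; P3 (positive, centro-parietal,
# ~373 ms) largest for a match, then the near-before outcome.
FRN_AMP = {
    OutcomeClass.MATCH: -4.0,
    OutcomeClass.NEAR_BEFORE: -2.5,
    OutcomeClass.NEAR_AFTER: -1.5,
    OutcomeClass.FULL_AWAY: -1.5,
}
P3_AMP = {
    OutcomeClass.MATCH: 8.0,
    OutcomeClass.NEAR_BEFORE: 5.0,
    OutcomeClass.NEAR_AFTER: 3.0,
    OutcomeClass.FULL_AWAY: 3.0,
}
FRN_LATENCY, FRN_WIDTH = 0.250, 0.030
P3_LATENCY, P3_WIDTH = 0.373, 0.050
FRN_TOPO = {"Fz": 0.9, "FCz": 1.0, "Cz": 0.9, "CPz": 0.5, "Pz": 0.3, "POz": 0.1, "Oz": 0.05}
P3_TOPO = {"Fz": 0.3, "FCz": 0.5, "Cz": 0.8, "CPz": 1.0, "Pz": 0.9, "POz": 0.6, "Oz": 0.4}


def fast_speed_for_calibration(
    entry_time: float = PENULTIMATE_ENTRY, decel_range: tuple[float, float] = DECEL_RANGE
) -> float:
    """Fast-spin speed v0 (items/s) such that the mean payline-entry time of
    the one-before-last item over uniformly distributed deceleration
    durations equals ``entry_time``.

    With linear deceleration, t_1 = -sqrt(2 D / v0), so
    v0 = 2 (E[sqrt D])^2 / entry_time^2 where for D ~ U[a, b]
    E[sqrt D] = (2/3)(b^{3/2} - a^{3/2}) / (b - a).
    """
    a, b = decel_range
    mean_sqrt_d = (2.0 / 3.0) * (b**1.5 - a**1.5) / (b - a)
    return 2.0 * mean_sqrt_d**2 / entry_time**2


@dataclass(frozen=True)
class TrialTiming:
    """Kinematic timing of one trial, stop-locked (stop at 0 s)."""

    spin_duration: float
    decel_duration: float
    item_passages: tuple[tuple[int, float], ...]  # (items before stop, entry time)
    penultimate_entry: float
    selected_entry: float | None  # payline entry of the chosen item; None if never

    @property
    def spin_onset(self) -> float:
        return -(self.spin_duration + self.decel_duration)

    @property
    def decel_onset(self) -> float:
        return -self.decel_duration


@dataclass
class TrialSchedule:
    trials: list[tuple[int, OutcomeClass, float, TrialTiming]]
    blocks: int
    framing: DomainFraming = GAIN_FRAMING

    def counts(self) -> dict[OutcomeClass, int]:
        out = {oc: 0 for oc in CONDITION_ORDER}
        for _, oc, _, _ in self.trials:
            out[oc] += 1
        return out


@dataclass
class LatentTrajectory:
    """Unsigned match-expectation p(t) on a stop-locked grid (t <= 0)."""

    grid: np.ndarray
    expectation: np.ndarray
    outcome: OutcomeClass


@dataclass
class SimulationConfig:
    """All generator knobs; the defaults are the stated world.

    eeg_ramp_gain is in μV per unit expectation change; eeg_noise_sd is the
    single-trial Gaussian sensor noise in μV; choice_lag is the latency of
    the behavioral readout behind the latent trajectory; switch_hazard is
    the per-second switching rate per unit of decision gap.
    """

    n_subjects: int = 36
    design: dict[OutcomeClass, int] = field(default_factory=lambda: dict(STUDY_DESIGNS[1]))
    blocks: int = 3
    framing: DomainFraming = GAIN_FRAMING
    eeg_ramp_gain: float = 10.0
    eeg_noise_sd: float = 10.0
    choice_lag: float = 0.20
    switch_hazard: float = 10.0
    sampling_rate_eeg: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eeg_noise_sd < 0 or self.switch_hazard < 0 or self.eeg_ramp_gain < 0:
            raise ValueError("rates, gains and SDs must be nonnegative")
        if self.sampling_rate_eeg <= 0:
            raise ValueError("sampling rate must be positive")

    @classmethod
    def for_study(cls, study: int, n_subjects: int, seed: int, **kw) -> "SimulationConfig":
        if study not in STUDY_DESIGNS:
            raise ValueError(f"unknown study {study}; expected 1-4")
        framing = GAIN_FRAMING if study in (1, 2) else LOSS_FRAMING
        return cls(
            n_subjects=n_subjects,
            design=dict(STUDY_DESIGNS[study]),
            blocks=STUDY_BLOCKS[study],
            framing=framing,
            seed=seed,
            **kw,
        )


# ---------------------------------------------------------------------------
# schedules and timing
# ---------------------------------------------------------------------------


def build_trial_schedule(
    design: dict[OutcomeClass, int],
    blocks: int,
    seed: int,
    framing: DomainFraming = GAIN_FRAMING,
    sure_amounts: tuple[float, ...] | None = None,
) -> TrialSchedule:
    """Seeded random trial order with exactly the requested per-class counts.

    ``blocks`` must divide the total trial count.  Sure amounts (behavioral
    studies) are drawn uniformly from the configured set per trial; EEG
    studies pass None and get 0.
    """
    counts = {oc: int(design.get(oc, 0)) for oc in CONDITION_ORDER}
    if any(c < 0 for c in counts.values()):
        raise ValueError("trial counts must be nonnegative")
    total = sum(counts.values())
    if total == 0:
        return TrialSchedule(trials=[], blocks=blocks, framing=framing)
    if blocks < 1 or total % blocks != 0:
        raise ValueError(f"blocks={blocks} does not divide the {total}-trial design")
    rng = np.random.default_rng(seed)
    labels: list[OutcomeClass] = []
    for oc in CONDITION_ORDER:
        labels.extend([oc] * counts[oc])
    order = rng.permutation(total)
    trials = []
    for idx, pos in enumerate(order):
        oc = labels[pos]
        sure = float(rng.choice(sure_amounts)) if sure_amounts else 0.0
        timing = sample_trial_timing(oc, rng)
        trials.append((idx, oc, sure, timing))
    return TrialSchedule(trials=trials, blocks=blocks, framing=framing)


def sample_trial_timing(outcome: OutcomeClass, rng: np.random.Generator) -> TrialTiming:
    """Draw one trial's kinematics.

    Durations are uniform over the printed ranges (only mean and range are
    known; the uniform mean 3291.5 ms differs from the printed 3307 ms by
    <0.5%, accepted).  Item passage times follow the linear-deceleration
    model; the stop distance of the selected item is drawn from the class
    definition (FULL_AWAY: 2 or 3, equiprobable).
    """
    spin = float(rng.uniform(*SPIN_RANGE))
    decel = float(rng.uniform(*DECEL_RANGE))
    v0 = fast_speed_for_calibration()
    distances = STOP_DISTANCES[outcome]
    d = int(distances[0] if len(distances) == 1 else rng.choice(distances))
    # items before the stop item that cross the payline during deceleration
    max_j = int(math.floor(v0 * decel / 2.0))
    passages = []
    for j in range(max_j, 0, -1):
        t_j = -math.sqrt(2.0 * j * decel / v0)
        if t_j >= -decel:
            passages.append((j, t_j))
    penultimate = -math.sqrt(2.0 * decel / v0)
    # selected item crosses the payline d items before the stop (d > 0:
    # the reel overshot it); d <= 0 means it never reaches the payline.
    selected_entry = -math.sqrt(2.0 * d * decel / v0) if d > 0 else None
    return TrialTiming(
        spin_duration=spin,
        decel_duration=decel,
        item_passages=tuple(passages),
        penultimate_entry=penultimate,
        selected_entry=selected_entry,
    )


# ---------------------------------------------------------------------------
# latent trajectories
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _rise(t: np.ndarray, half: float, p_max: float) -> np.ndarray:
    return P0 + (p_max - P0) * _sigmoid((t - half) / RISE_TAU)


def latent_expectation(
    outcome: OutcomeClass, timing: TrialTiming, grid: np.ndarray
) -> LatentTrajectory:
    """Class-shaped unsigned match-expectation trajectory on ``grid``.

    MATCH rises slightly earlier/higher than NEAR_BEFORE (the approaching
    alignment is visible); NEAR_AFTER mirrors the NEAR_BEFORE rise until the
    penultimate item enters the payline (that item *is* the selected one)
    and then collapses toward the floor; FULL_AWAY decays once the selected
    item crosses the payline while the reel is clearly not stopping.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < -3.0 - 1e-9 or grid.max() > 1e-9):
        raise ValueError("grid must lie within the deceleration epoch [-3, 0]")
    t_p = timing.penultimate_entry
    if outcome is OutcomeClass.MATCH:
        p = _rise(grid, MATCH_HALF, MATCH_MAX)
    elif outcome is OutcomeClass.NEAR_BEFORE:
        p = _rise(grid, NB_HALF, NB_MAX)
    elif outcome is OutcomeClass.NEAR_AFTER:
        p = _rise(grid, NB_HALF, NB_MAX)
        peak = P0 + (NB_MAX - P0) * float(_sigmoid((t_p - NB_HALF) / RISE_TAU))
        after = grid > t_p
        p[after] = P_FLOOR + (peak - P_FLOOR) * np.exp(-(grid[after] - t_p) / DECAY_TAU)
    elif outcome is OutcomeClass.FULL_AWAY:
        t_real = timing.selected_entry if timing.selected_entry is not None else -1.0
        p = P_FLOOR + (P0 - P_FLOOR) * _sigmoid(-(grid - t_real) / 0.2)
        p = np.minimum.accumulate(p)  # certainty of the miss only grows
    else:  # pragma: no cover
        raise ValueError(outcome)
    return LatentTrajectory(grid=grid, expectation=np.clip(p, 0.0, 1.0), outcome=outcome)


def certainty_signal(traj: LatentTrajectory) -> np.ndarray:
    """The CNV driver: expectation build-up relative to the pre-evidence
    level, p(t) - p0.  Identical across gain and loss framings (the ramp
    tracks match certainty, not value)."""
    return traj.expectation - P0


# ---------------------------------------------------------------------------
# choices
# ---------------------------------------------------------------------------


def simulate_choices(
    traj: LatentTrajectory,
    sure_amount: float,
    timing: TrialTiming,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete-time hazard model of live betting on the 50-ms grid.

    The grid runs from the (snapped) spin onset to +0.750 s.  At each step
    the lagged expectation e = p(t - lag) (held at p0 before deceleration,
    at the realized outcome after the stop) defines the favored option
    (machine iff e > sure_amount/100); if the current state disagrees, a
    switch occurs with probability 1 - exp(-hazard * |e - sure/100| * dt).

    Returns (grid, values).
    """
    if sure_amount not in SURE_AMOUNTS:
        raise ValueError(f"sure_amount must be one of {SURE_AMOUNTS}")
    start = -GRID_STEP * math.ceil(-timing.spin_onset / GRID_STEP)
    n = int(round((0.750 - start) / GRID_STEP)) + 1
    grid = start + GRID_STEP * np.arange(n)
    target_value = sure_amount / 100.0
    outcome_value = 1.0 if traj.outcome is OutcomeClass.MATCH else 0.0

    lagged = grid - cfg.choice_lag
    e = np.empty_like(grid)
    pre = lagged < traj.grid[0]
    post = lagged > 0
    mid = ~pre & ~post
    e[pre] = P0
    e[post] = outcome_value
    e[mid] = np.interp(lagged[mid], traj.grid, traj.expectation)

    state = int(rng.random() < 0.5)  # pre-spin selection
    values = np.empty(n, dtype=int)
    gap = e - target_value
    target = (gap > 0).astype(int)
    p_switch = 1.0 - np.exp(-cfg.switch_hazard * np.abs(gap) * GRID_STEP)
    u = rng.random(n)
    for i in range(n):
        if state != target[i] and u[i] < p_switch[i]:
            state = target[i]
        values[i] = state
    return grid, values


def simulate_behavioral_cohort(cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate a full live-betting cohort and return a tidy event log
    (columns: participant, trial, outcome, sure_amount, time_s, state) in
    the format the behavior module reads.

    Each trial contributes the initial selection event plus one event per
    state change of the simulated series.
    """
    master = np.random.SeedSequence(cfg.seed)
    subject_seeds = master.spawn(cfg.n_subjects)
    rows = []
    for si, sseq in enumerate(subject_seeds):
        pid = f"S{si + 1:02d}"
        rng = np.random.default_rng(sseq)
        schedule = build_trial_schedule(
            cfg.design,
            cfg.blocks,
            seed=rng.integers(2**31),
            framing=cfg.framing,
            sure_amounts=SURE_AMOUNTS,
        )
        for idx, oc, sure, timing in schedule.trials:
            decel_grid = np.arange(-3.0, 1e-9, GRID_STEP)
            traj = latent_expectation(oc, timing, decel_grid)
            grid, values = simulate_choices(traj, sure, timing, cfg, rng)
            rows.append(
                {
                    "participant": pid,
                    "trial": idx,
                    "outcome": str(oc),
                    "sure_amount": sure,
                    "time_s": round(float(grid[0]), 4),
                    "state": int(values[0]),
                }
            )
            changes = np.flatnonzero(np.diff(values) != 0) + 1
            for ci in changes:
                rows.append(
                    {
                        "participant": pid,
                        "trial": idx,
                        "outcome": str(oc),
                        "sure_amount": sure,
                        "time_s": round(float(grid[ci]), 4),
                        "state": int(values[ci]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EEG epochs
# ---------------------------------------------------------------------------

EPOCH_START = -6.2  # covers max spin+decel (6.0 s) plus the 200-ms baseline
EPOCH_END = 1.0


def _epoch_times(sfreq: float) -> np.ndarray:
    n = int(math.ceil((EPOCH_END - EPOCH_START) * sfreq)) + 1
    return EPOCH_START + np.arange(n) / sfreq


def _gaussian_bump(times: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((times - center) / width) ** 2)


def simulate_epochs(
    schedule: TrialSchedule, cfg: SimulationConfig, rng: np.random.Generator, subject: str = "S01"
) -> EpochSet:
    """Simulate one subject's stop-locked epochs for a trial schedule.

    Channel traces = ramp_topography * (-gain * certainty(t)) during the
    deceleration, plus post-stop FRN/P3 bumps, plus white Gaussian noise of
    sd ``eeg_noise_sd``.  Epochs span [-6.2, +1.0] s so the pre-spin 200-ms
    baseline of every admissible trial is covered.
    """
    times = _epoch_times(cfg.sampling_rate_eeg)
    epochs = []
    ramp_gains = np.array([RAMP_TOPOGRAPHY[c] for c in CHANNELS])[:, None]
    frn_gains = np.array([FRN_TOPO[c] for c in CHANNELS])[:, None]
    p3_gains = np.array([P3_TOPO[c] for c in CHANNELS])[:, None]
    for idx, oc, _sure, timing in schedule.trials:
        decel_mask = (times >= -3.0) & (times <= 0.0)
        traj = latent_expectation(oc, timing, times[decel_mask])
        signal = np.zeros_like(times)
        signal[decel_mask] = certainty_signal(traj)
        # hold the final certainty level through the outcome phase
        if decel_mask.any():
            signal[times > 0] = signal[decel_mask][-1]
        base = -cfg.eeg_ramp_gain * ramp_gains * signal[None, :]
        frn = FRN_AMP[oc] * frn_gains * _gaussian_bump(times, FRN_LATENCY, FRN_WIDTH)[None, :]
        p3 = P3_AMP[oc] * p3_gains * _gaussian_bump(times, P3_LATENCY, P3_WIDTH)[None, :]
        data = base + frn + p3
        if cfg.eeg_noise_sd > 0:
            data = data + rng.normal(0.0, cfg.eeg_noise_sd, size=data.shape)
        epochs.append(
            Epoch(data=data, times=times, outcome=oc, spin_onset=timing.spin_onset, trial=idx)
        )
    return EpochSet(
        subject=subject, epochs=epochs, sfreq=cfg.sampling_rate_eeg, channels=list(CHANNELS)
    )


# ---------------------------------------------------------------------------
# coupled-curve fixture for parameter recovery
# ---------------------------------------------------------------------------


def _recovery_fixture_curves(grid: np.ndarray) -> dict[OutcomeClass, np.ndarray]:
    """Behavior-side curves of the recovery fixture.

    Window-start recovery is only well-posed when the condition-
    discriminative variance of the coupled content is concentrated *inside*
    the injected window rather than at its end: for an exact-copy injection
    the search objective tracks the per-point pattern variance of the curves
    over [t, 0], so monotone saturating trajectories make every sub-window
    as good as the injected one.  These curves therefore use the crossing
    geometry of the final deceleration second — a NEAR_AFTER hump and a
    NEAR_BEFORE dip around -0.75 s with partial reconvergence at the stop —
    which peaks the pattern variance at the injected window start.
    """
    bump = np.exp(-0.5 * ((grid + 0.85) / 0.30) ** 2)
    rise = _sigmoid((grid + 0.5) / 0.12)
    return {
        OutcomeClass.MATCH: 0.40 + 0.12 * rise,
        OutcomeClass.NEAR_BEFORE: 0.40 - 0.18 * bump + 0.08 * rise,
        OutcomeClass.NEAR_AFTER: 0.40 + 0.30 * bump + 0.05 * rise,
        OutcomeClass.FULL_AWAY: 0.40 - 0.22 * bump - 0.03 * rise,
    }


def simulate_coupled_curves(
    n_subjects: int = 12,
    noise_sd: float = 0.05,
    coupling_window: tuple[float, float] = (-1.0, 0.0),
    seed: int = 0,
):
    """Per-subject EEG curve sets coupled to group behavioral curves *only*
    inside ``coupling_window``; outside it the EEG curves are smooth
    condition-independent noise.  Used for parameter recovery of the window
    search: the recovered window start should sit at the injected start.

    Behavioral curves are the dedicated recovery-fixture set (see
    ``_recovery_fixture_curves`` for why their dispersion is concentrated
    mid-window) on the 50-ms grid; EEG curves are their negatives inside the
    window plus white noise of sd ``noise_sd`` everywhere (curves live on
    [0, 1], so 0.05 is a moderate 5%-of-range distortion).

    Returns (eeg_sets, beh) as coupling.CurveSet objects.
    """
    from .coupling import CurveSet

    rng = np.random.default_rng(seed)
    grid = np.arange(-3.0, 1e-9, GRID_STEP)
    beh_curves = _recovery_fixture_curves(grid)
    beh = CurveSet(times=grid, curves=dict(beh_curves), side="behavioral-group")
    lo, hi = coupling_window
    inside = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    eeg_sets = []
    for _ in range(n_subjects):
        curves = {}
        for oc in CONDITION_ORDER:
            trace = np.zeros_like(grid)
            # outside the window: smooth wander, shared structure-free
            wander = np.cumsum(rng.normal(0, 0.02, size=grid.size))
            trace[~inside] = wander[~inside] - wander[~inside].mean()
            trace[inside] = -beh_curves[oc][inside]
            trace = trace + rng.normal(0, noise_sd, size=grid.size)
            curves[oc] = trace
        eeg_sets.append(CurveSet(times=grid, curves=curves, side="eeg-subject"))
    return eeg_sets, beh
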