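"""ERP analysis of stop-locked slot-machine epochs.

Epochs are channel × sample matrices in μV on a uniform time axis spanning at
least [-3, +1] s around the machine standstill (0 s), and reaching back far
enough to cover a 200-ms baseline immediately before the spin onset of that
trial.  Operations: baseline correction, per-outcome condition averaging with
an optional 30-Hz zero-phase low-pass on the averages, mean amplitudes in the
six 500-ms deceleration windows at a chosen electrode, and extraction of the
post-outcome FRN and P3 components by the peak-anchored 80-ms-window rule.

The CNV-like quantity of interest is the slow fronto-central negativity that
builds up before the standstill; its analysis electrode is Cz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as spsig

from .behavior import DECEL_WINDOWS, window_mask
from .outcomes import CONDITION_ORDER, OutcomeClass

__all__ = [
    "Epoch",
    "EpochSet",
    "ConditionAverage",
    "ComponentWindow",
    "COMPONENT_DEFS",
    "baseline_correct",
    "average_by_condition",
    "eeg_window_means",
    "peak_window",
    "component_mean",
    "grand_average",
]

BASELINE_DURATION = 0.200  # seconds before spin onset


@dataclass
class Epoch:
    data: np.ndarray  # (n_channels, n_samples), μV
    times: np.ndarray  # seconds, stop-locked, uniform
    outcome: OutcomeClass
    spin_onset: float  # seconds (< -3): start of the fast spin
    trial: int = -1
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != self.times.size:
            raise ValueError("data must be (n_channels, n_samples) matching times")


@dataclass
class EpochSet:
    subject: str
    epochs: list[Epoch]
    sfreq: float
    channels: list[str]

    def __post_init__(self) -> None:
        n_ch = len(self.channels)
        for ep in self.epochs:
            if ep.data.shape[0] != n_ch:
                raise ValueError("inconsistent channel count across epochs")

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {self.channels}"
            ) from None


def baseline_correct(epoch: Epoch) -> Epoch:
    """Subtract, per channel, the mean over the 200 ms preceding the spin
    onset of this trial.  Idempotent up to floating point (the corrected
    baseline mean is ~0, so a second application subtracts ~0)."""
    t0 = epoch.spin_onset - BASELINE_DURATION
    t1 = epoch.spin_onset
    mask = (epoch.times >= t0 - 1e-9) & (epoch.times < t1 - 1e-9)
    if not mask.any():
        raise ValueError(
            f"baseline interval [{t0:.3f}, {t1:.3f}) s not covered by the stored "
            f"data ({epoch.times[0]:.3f}..{epoch.times[-1]:.3f} s)"
        )
    means = epoch.data[:, mask].mean(axis=1, keepdims=True)
    return replace(epoch, data=epoch.data - means, baseline_corrected=True)


@dataclass
class ConditionAverage:
    """Per-outcome mean channel × sample matrices for one subject (or the
    group, when built from subject averages)."""

    times: np.ndarray
    channels: list[str]
    averages: dict[OutcomeClass, np.ndarray]
    n_trials: dict[OutcomeClass, int] = field(default_factory=dict)
    smoothed: bool = False

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {self.channels}"
            ) from None

    def collapse_classes(self) -> np.ndarray:
        """Unweighted mean across the available outcome classes."""
        return np.mean([self.averages[oc] for oc in CONDITION_ORDER if oc in self.averages], axis=0)


def _lowpass(data: np.ndarray, sfreq: float, cutoff: float = 30.0, order: int = 4) -> np.ndarray:
    sos = spsig.butter(order, cutoff, btype="low", fs=sfreq, output="sos")
    return spsig.sosfiltfilt(sos, data, axis=-1)


def average_by_condition(epochs: EpochSet, smooth: bool = False) -> ConditionAverage:
    """Samplewise mean per outcome class, after baseline correction.

    ``smooth`` applies a zero-phase (forward-backward) 4th-order Butterworth
    low-pass at 30 Hz to the *averages* only — never to single trials.
    Classes with no epochs are omitted with a warning.
    """
    if not epochs.epochs:
        raise ValueError("empty epoch set")
    if not all(ep.baseline_corrected for ep in epochs.epochs):
        raise ValueError("epochs must be baseline-corrected before averaging")
    times = epochs.epochs[0].times
    averages: dict[OutcomeClass, np.ndarray] = {}
    n_trials: dict[OutcomeClass, int] = {}
    for oc in CONDITION_ORDER:
        mats = [ep.data for ep in epochs.epochs if ep.outcome is oc]
        if not mats:
            warnings.warn(f"no epochs for outcome {oc}; class omitted", stacklevel=2)
            continue
        avg = np.mean(mats, axis=0)
        if smooth:
            avg = _lowpass(avg, epochs.sfreq)
        averages[oc] = avg
        n_trials[oc] = len(mats)
    return ConditionAverage(
        times=times,
        channels=list(epochs.channels),
        averages=averages,
        n_trials=n_trials,
        smoothed=smooth,
    )


def eeg_window_means(
    avg: ConditionAverage,
    channel: str = "Cz",
    windows: tuple[tuple[float, float], ...] = DECEL_WINDOWS,
) -> dict[OutcomeClass, np.ndarray]:
    """Mean amplitude (μV) per class and 500-ms window at one electrode.

    Same window-membership convention as the behavioral module: [a, b) for
    every window except the last, which is closed at its right edge.
    """
    ci = avg.channel_index(channel)
    out: dict[OutcomeClass, np.ndarray] = {}
    for oc, mat in avg.averages.items():
        vals = []
        for wi, win in enumerate(windows):
            mask = window_mask(avg.times, win, closed_end=(wi == len(windows) - 1))
            if not mask.any():
                raise ValueError(f"window {win} contains no samples")
            vals.append(float(mat[ci, mask].mean()))
        out[oc] = np.array(vals)
    return out


@dataclass(frozen=True)
class ComponentWindow:
    """A peak-anchored measurement window for a post-outcome component."""

    component: str  # "FRN" or "P3"
    cluster: tuple[str, ...]
    search_window: tuple[float, float]  # seconds post-outcome
    peak: float  # seconds
    measure_window: tuple[float, float]  # seconds, width 0.080 before rounding
    polarity: str  # "negative" | "positive"


#: Component definitions: electrode cluster, search window, polarity.
#: FRN: most negative point of the fronto-central cluster average in
#: 200–350 ms; P3: most positive point of the centro-parietal cluster
#: average in 300–500 ms.
COMPONENT_DEFS = {
    "FRN": (("Fz", "FCz", "Cz"), (0.200, 0.350), "negative"),
    "P3": (("Cz", "CPz", "Pz", "POz", "Oz"), (0.300, 0.500), "positive"),
}


def _round_to(x: float, step: float) -> float:
    return round(x / step) * step


def peak_window(grand_avg: ConditionAverage, component: str) -> ComponentWindow:
    """Find a component's peak on the across-class grand average and anchor
    its 80-ms measurement window there.

    The peak is the extremum of the cluster-averaged, class-collapsed grand
    average inside the component's search window (earliest sample on ties /
    flat signals, with a warning).  The measurement window is peak ± 40 ms
    with each edge rounded to the nearest 10 ms.
    """
    if component not in COMPONENT_DEFS:
        raise ValueError(f"unknown component {component!r}; expected FRN or P3")
    cluster, search, polarity = COMPONENT_DEFS[component]
    idxs = [grand_avg.channel_index(c) for c in cluster]
    collapsed = grand_avg.collapse_classes()
    trace = collapsed[idxs, :].mean(axis=0)
    mask = (grand_avg.times >= search[0] - 1e-9) & (grand_avg.times <= search[1] + 1e-9)
    if not mask.any():
        raise ValueError(f"search window {search} not covered by the data")
    seg = trace[mask]
    seg_times = grand_avg.times[mask]
    if np.ptp(seg) == 0:
        warnings.warn(
            f"flat signal in {component} search window; using earliest sample",
            stacklevel=2,
        )
        peak_i = 0
    else:
        peak_i = int(np.argmin(seg)) if polarity == "negative" else int(np.argmax(seg))
    peak_t = float(seg_times[peak_i])
    lo = _round_to(peak_t - 0.040, 0.010)
    hi = _round_to(peak_t + 0.040, 0.010)
    return ComponentWindow(
        component=component,
        cluster=cluster,
        search_window=search,
        peak=peak_t,
        measure_window=(lo, hi),
        polarity=polarity,
    )


def component_mean(avg: ConditionAverage, win: ComponentWindow) -> dict[OutcomeClass, float]:
    """Cluster-averaged mean amplitude (μV) in the component's measurement
    window, per outcome class, for one subject's condition averages."""
    lo, hi = win.measure_window
    if lo < avg.times[0] - 1e-9 or hi > avg.times[-1] + 1e-9:
        raise ValueError(
            f"measure window [{lo}, {hi}] s exceeds the stored data span"
        )
    idxs = [avg.channel_index(c) for c in win.cluster]
    mask = (avg.times >= lo - 1e-9) & (avg.times <= hi + 1e-9)
    out = {}
    for oc, mat in avg.averages.items():
        out[oc] = float(mat[np.ix_(idxs, np.flatnonzero(mask))].mean())
    return out


def grand_average(subject_avgs: list[ConditionAverage]) -> ConditionAverage:
    """Group-level condition averages: unweighted mean of subject averages
    per class (and the same channels/time axis)."""
    if not subject_avgs:
        raise ValueError("no subject averages")
    ref = subject_avgs[0]
    averages: dict[OutcomeClass, np.ndarray] = {}
    n_trials: dict[OutcomeClass, int] = {}
    for oc in CONDITION_ORDER:
        mats = [sa.averages[oc] for sa in subject_avgs if oc in sa.averages]
        if not mats:
            continue
        averages[oc] = np.mean(mats, axis=0)
        n_trials[oc] = len(mats)
    return ConditionAverage(
        times=ref.times,
        channels=list(ref.channels),
        averages=averages,
        n_trials=n_trials,
        smoothed=ref.smoothed,
    )
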