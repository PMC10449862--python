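"""Session-bundle formats.

A session bundle is a directory holding one simulated (or converted) study:

* ``schedule.csv`` — trial, outcome, sure_amount, spin_duration,
  decel_duration, penultimate_entry (one row per trial of a reference
  schedule; behavioral logs and epoch metadata must cross-reference it).
* ``events.csv`` — behavioral event log (behavior.LOG_COLUMNS), if the
  bundle carries behavior.
* ``epochs_<subject>.npy`` + ``epochs_<subject>.json`` — per-subject epoch
  stacks (trials × channels × samples, float64) with a JSON sidecar holding
  channel names, sampling rate, the stop-locked time axis origin and
  per-trial metadata (trial index, outcome, spin onset), if the bundle
  carries EEG.
* ``config.json`` — provenance: seed, package version, study number.

Time is stop-locked seconds everywhere (0 = machine standstill).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import LOG_COLUMNS
from .erp import Epoch, EpochSet
from .outcomes import OutcomeClass
from .synthdata import TrialSchedule

__all__ = [
    "BundleError",
    "SessionBundle",
    "write_schedule",
    "write_epoch_set",
    "read_epoch_set",
    "load_session_bundle",
]


class BundleError(ValueError):
    """Typed error for malformed or inconsistent session bundles."""


SCHEDULE_COLUMNS = [
    "trial",
    "outcome",
    "sure_amount",
    "spin_duration",
    "decel_duration",
    "penultimate_entry",
]


def write_schedule(schedule: TrialSchedule, path: Path) -> None:
    rows = []
    for idx, oc, sure, timing in schedule.trials:
        rows.append(
            {
                "trial": idx,
                "outcome": str(oc),
                "sure_amount": sure,
                "spin_duration": timing.spin_duration,
                "decel_duration": timing.decel_duration,
                "penultimate_entry": timing.penultimate_entry,
            }
        )
    pd.DataFrame(rows, columns=SCHEDULE_COLUMNS).to_csv(path, index=False)


def write_epoch_set(es: EpochSet, directory: Path) -> None:
    directory = Path(directory)
    stack = np.stack([ep.data for ep in es.epochs])
    np.save(directory / f"epochs_{es.subject}.npy", stack)
    sidecar = {
        "subject": es.subject,
        "sfreq": es.sfreq,
        "channels": es.channels,
        "t0": float(es.epochs[0].times[0]),
        "n_samples": int(es.epochs[0].times.size),
        "trials": [
            {"trial": ep.trial, "outcome": str(ep.outcome), "spin_onset": ep.spin_onset}
            for ep in es.epochs
        ],
    }
    (directory / f"epochs_{es.subject}.json").write_text(json.dumps(sidecar, indent=1))


def read_epoch_set(directory: Path, subject: str) -> EpochSet:
    directory = Path(directory)
    npy = directory / f"epochs_{subject}.npy"
    sidecar_path = directory / f"epochs_{subject}.json"
    if not npy.exists() or not sidecar_path.exists():
        raise BundleError(f"missing epoch files for subject {subject!r} in {directory}")
    meta = json.loads(sidecar_path.read_text())
    stack = np.load(npy)
    times = meta["t0"] + np.arange(meta["n_samples"]) / meta["sfreq"]
    if stack.shape[0] != len(meta["trials"]):
        raise BundleError(f"{npy.name}: trial count mismatch with sidecar")
    epochs = [
        Epoch(
            data=stack[i],
            times=times,
            outcome=OutcomeClass(tr["outcome"]),
            spin_onset=tr["spin_onset"],
            trial=tr["trial"],
        )
        for i, tr in enumerate(meta["trials"])
    ]
    return EpochSet(
        subject=meta["subject"], epochs=epochs, sfreq=meta["sfreq"], channels=meta["channels"]
    )


@dataclass
class SessionBundle:
    path: Path
    schedule: pd.DataFrame
    events: pd.DataFrame | None = None
    epoch_subjects: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def epoch_set(self, subject: str) -> EpochSet:
        return read_epoch_set(self.path, subject)


def load_session_bundle(path) -> SessionBundle:
    """Load and validate a bundle directory.

    Checks: the schedule exists and is well-formed; every trial referenced
    by the event log and every epoch's metadata outcome exists in / matches
    the schedule.
    """
    path = Path(path)
    sched_path = path / "schedule.csv"
    if not sched_path.exists():
        raise BundleError(f"{path}: missing schedule (schedule.csv)")
    schedule = pd.read_csv(sched_path)
    missing_cols = set(SCHEDULE_COLUMNS) - set(schedule.columns)
    if missing_cols:
        raise BundleError(f"schedule.csv missing columns: {sorted(missing_cols)}")
    known = dict(zip(schedule["trial"], schedule["outcome"]))

    events = None
    events_path = path / "events.csv"
    if events_path.exists():
        events = pd.read_csv(events_path)
        missing_cols = set(LOG_COLUMNS) - set(events.columns)
        if missing_cols:
            raise BundleError(f"events.csv missing columns: {sorted(missing_cols)}")
        for trial in events["trial"].unique():
            if trial not in known:
                raise BundleError(f"events.csv references unknown trial {trial}")

    subjects = sorted(p.stem.replace("epochs_", "") for p in path.glob("epochs_*.json"))
    for subject in subjects:
        meta = json.loads((path / f"epochs_{subject}.json").read_text())
        for tr in meta["trials"]:
            if tr["trial"] not in known:
                raise BundleError(
                    f"epochs_{subject}: unknown trial {tr['trial']} in metadata"
                )
            if known[tr["trial"]] != tr["outcome"]:
                raise BundleError(
                    f"epochs_{subject}: outcome mismatch on trial {tr['trial']} "
                    f"({tr['outcome']} vs schedule {known[tr['trial']]})"
                )

    config = {}
    cfg_path = path / "config.json"
    if cfg_path.exists():
        config = json.loads(cfg_path.read_text())
    return SessionBundle(
        path=path, schedule=schedule, events=events, epoch_subjects=subjects, config=config
    )


def write_provenance(path: Path, study: int, seed: int, extra: dict | None = None) -> None:
    payload = {"study": study, "seed": seed, "version": __version__}
    if extra:
        payload.update(extra)
    (Path(path) / "config.json").write_text(json.dumps(payload, indent=1))
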