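"""End-to-end study runners.

``run_behavioral_study`` (studies 2/4): simulate or load a betting event log,
convert to 50-ms binary series, apply the no-switch exclusion rule, build
participant and group expectation curves, run the six-window repeated-measures
ANOVA at the Šidák-corrected threshold with Tukey follow-ups, and the
NEAR_BEFORE vs NEAR_AFTER slope contrast on the final 500 ms.

``run_eeg_study`` (studies 1/3): simulate per-subject epoch sets, baseline-
correct, average by outcome, compute Cz deceleration-window means, the same
window ANOVA/Tukey stack, and FRN/P3 amplitudes by the peak-anchored rule.

``run_coupling`` ties a paired EEG + behavioral study together through the
window-search + permutation analysis.

All outputs are CSV/JSON with the seed and configuration embedded; everything
is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, coupling, erp, stats
from . import io as bundle_io
from . import synthdata
from .outcomes import CONDITION_ORDER, OutcomeClass

__all__ = [
    "TRIAL_SPAN",
    "BehavioralStudyResult",
    "EEGStudyResult",
    "run_behavioral_study",
    "run_eeg_study",
    "run_coupling",
    "run_study_pipeline",
]

#: Stop-locked analysis span of a behavioral trial: the last 3 s of
#: deceleration through the 750-ms post-stop response window.
TRIAL_SPAN = (-3.0, 0.750)

ALPHA = 0.05
N_WINDOWS = len(behavior.DECEL_WINDOWS)


def _window_anovas(window_means: pd.DataFrame) -> pd.DataFrame:
    """Six-window RM-ANOVA table from a tidy participant × outcome × window
    means frame, with the Šidák per-window threshold applied."""
    threshold = stats.report_threshold(ALPHA, N_WINDOWS)
    rows = []
    for (w0, w1), g in window_means.groupby(["window_start", "window_end"], sort=True):
        table = (
            g.pivot(index="participant", columns="outcome", values="mean")
            .reindex(columns=[str(oc) for oc in CONDITION_ORDER])
            .to_numpy()
        )
        res = stats.rm_anova_gg(table)
        rows.append(
            {
                "window_start": w0,
                "window_end": w1,
                "F": res.F,
                "df1": res.df1,
                "df2": res.df2,
                "epsilon_gg": res.epsilon_gg,
                "p_uncorrected": res.p_uncorrected,
                "p_gg": res.p_gg,
                "p_primary": res.p_primary,
                "threshold": threshold,
                "significant": res.p_primary < threshold,
            }
        )
    return pd.DataFrame(rows)


def _window_tukeys(window_means: pd.DataFrame, anovas: pd.DataFrame) -> pd.DataFrame:
    rows = []
    sig = {
        (r.window_start, r.window_end)
        for r in anovas.itertuples()
        if r.significant
    }
    for (w0, w1), g in window_means.groupby(["window_start", "window_end"], sort=True):
        if (w0, w1) not in sig:
            continue
        table = (
            g.pivot(index="participant", columns="outcome", values="mean")
            .reindex(columns=[str(oc) for oc in CONDITION_ORDER])
            .to_numpy()
        )
        for cmp in stats.tukey_pairwise(table):
            rows.append(
                {
                    "window_start": w0,
                    "window_end": w1,
                    "class_a": str(CONDITION_ORDER[cmp.i]),
                    "class_b": str(CONDITION_ORDER[cmp.j]),
                    "mean_diff": cmp.mean_diff,
                    "t": cmp.t,
                    "p_adjusted": cmp.p_adjusted,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BehavioralStudyResult:
    study: int
    retained: list[str]
    exclusion_report: pd.DataFrame
    participant_curves: dict[str, behavior.ConditionCurves]
    group: behavior.ConditionCurves
    window_means: pd.DataFrame
    anovas: pd.DataFrame
    tukeys: pd.DataFrame
    slopes: behavior.SlopeResult


def run_behavioral_study(
    study: int,
    n_subjects: int,
    seed: int,
    out_dir: Path | None = None,
    log: pd.DataFrame | None = None,
    **cfg_kw,
) -> BehavioralStudyResult:
    if log is None:
        cfg = synthdata.SimulationConfig.for_study(study, n_subjects, seed, **cfg_kw)
        log = synthdata.simulate_behavioral_cohort(cfg)
    sessions = behavior.log_to_sessions(log, TRIAL_SPAN)
    retained, report = behavior.exclude_participants(sessions, threshold=0.90)
    pcurves = {pid: behavior.condition_curves(sessions[pid]) for pid in retained}
    group = behavior.group_curves(list(pcurves.values()))
    wmeans = behavior.behavior_window_means(pcurves)
    anovas = _window_anovas(wmeans)
    tukeys = _window_tukeys(wmeans, anovas)
    slopes = behavior.slope_stat(
        pcurves, (-0.5, 0.0), OutcomeClass.NEAR_BEFORE, OutcomeClass.NEAR_AFTER
    )
    result = BehavioralStudyResult(
        study=study,
        retained=retained,
        exclusion_report=report,
        participant_curves=pcurves,
        group=group,
        window_means=wmeans,
        anovas=anovas,
        tukeys=tukeys,
        slopes=slopes,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        behavior.write_event_log(log, out_dir / "events.csv")
        report.to_csv(out_dir / "exclusions.csv", index=False)
        wmeans.to_csv(out_dir / "window_means.csv", index=False)
        anovas.to_csv(out_dir / "window_anovas.csv", index=False)
        tukeys.to_csv(out_dir / "window_tukeys.csv", index=False)
        slopes.slopes.to_csv(out_dir / "slopes.csv", index=False)
        _write_json(
            out_dir / "summary.json",
            {
                "study": study,
                "seed": seed,
                "version": __version__,
                "n_retained": len(retained),
                "slope_t": slopes.t,
                "slope_df": slopes.df,
                "slope_p": slopes.p,
                "threshold": stats.report_threshold(ALPHA, N_WINDOWS),
            },
        )
    return result


@dataclass
class EEGStudyResult:
    study: int
    subject_averages: list[erp.ConditionAverage]
    grand: erp.ConditionAverage
    window_means: pd.DataFrame
    anovas: pd.DataFrame
    tukeys: pd.DataFrame
    component_windows: dict[str, erp.ComponentWindow]
    component_amplitudes: pd.DataFrame
    component_anovas: pd.DataFrame


def run_eeg_study(
    study: int,
    n_subjects: int,
    seed: int,
    out_dir: Path | None = None,
    smooth: bool = True,
    **cfg_kw,
) -> EEGStudyResult:
    cfg = synthdata.SimulationConfig.for_study(study, n_subjects, seed, **cfg_kw)
    master = np.random.SeedSequence(cfg.seed)
    subject_seeds = master.spawn(cfg.n_subjects)
    subject_avgs: list[erp.ConditionAverage] = []
    subject_ids: list[str] = []
    for si, sseq in enumerate(subject_seeds):
        pid = f"S{si + 1:02d}"
        rng = np.random.default_rng(sseq)
        schedule = synthdata.build_trial_schedule(
            cfg.design, cfg.blocks, seed=rng.integers(2**31), framing=cfg.framing
        )
        es = synthdata.simulate_epochs(schedule, cfg, rng, subject=pid)
        es.epochs = [erp.baseline_correct(ep) for ep in es.epochs]
        subject_avgs.append(erp.average_by_condition(es, smooth=smooth))
        subject_ids.append(pid)
    grand = erp.grand_average(subject_avgs)

    rows = []
    for pid, sa in zip(subject_ids, subject_avgs):
        means = erp.eeg_window_means(sa, channel="Cz")
        for oc, vals in means.items():
            for (w0, w1), v in zip(behavior.DECEL_WINDOWS, vals):
                rows.append(
                    {
                        "participant": pid,
                        "outcome": str(oc),
                        "window_start": w0,
                        "window_end": w1,
                        "mean": v,
                    }
                )
    wmeans = pd.DataFrame(rows)
    anovas = _window_anovas(wmeans)
    tukeys = _window_tukeys(wmeans, anovas)

    comp_windows = {c: erp.peak_window(grand, c) for c in ("FRN", "P3")}
    comp_rows = []
    for pid, sa in zip(subject_ids, subject_avgs):
        for cname, cw in comp_windows.items():
            for oc, amp in erp.component_mean(sa, cw).items():
                comp_rows.append(
                    {
                        "participant": pid,
                        "component": cname,
                        "outcome": str(oc),
                        "amplitude": amp,
                    }
                )
    comp_amp = pd.DataFrame(comp_rows)
    comp_anova_rows = []
    for cname, g in comp_amp.groupby("component"):
        table = (
            g.pivot(index="participant", columns="outcome", values="amplitude")
            .reindex(columns=[str(oc) for oc in CONDITION_ORDER])
            .to_numpy()
        )
        res = stats.rm_anova_gg(table)
        comp_anova_rows.append(
            {
                "component": cname,
                "F": res.F,
                "df1": res.df1,
                "df2": res.df2,
                "epsilon_gg": res.epsilon_gg,
                "p_gg": res.p_gg,
                "p_primary": res.p_primary,
            }
        )
    comp_anovas = pd.DataFrame(comp_anova_rows)

    result = EEGStudyResult(
        study=study,
        subject_averages=subject_avgs,
        grand=grand,
        window_means=wmeans,
        anovas=anovas,
        tukeys=tukeys,
        component_windows=comp_windows,
        component_amplitudes=comp_amp,
        component_anovas=comp_anovas,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        wmeans.to_csv(out_dir / "window_means.csv", index=False)
        anovas.to_csv(out_dir / "window_anovas.csv", index=False)
        tukeys.to_csv(out_dir / "window_tukeys.csv", index=False)
        comp_amp.to_csv(out_dir / "component_amplitudes.csv", index=False)
        comp_anovas.to_csv(out_dir / "component_anovas.csv", index=False)
        _write_json(
            out_dir / "summary.json",
            {
                "study": study,
                "seed": seed,
                "version": __version__,
                "n_subjects": n_subjects,
                "component_windows": {
                    c: {"peak": w.peak, "measure_window": list(w.measure_window)}
                    for c, w in comp_windows.items()
                },
            },
        )
    return result


def _eeg_curve_sets(
    eeg_result: EEGStudyResult, channel: str = "Cz"
) -> list[coupling.CurveSet]:
    """Per-subject Cz condition curves restricted to the deceleration span."""
    sets = []
    for sa in eeg_result.subject_averages:
        ci = sa.channel_index(channel)
        # small margin on both sides so interpolation at the exact window
        # edges (-3 and 0) never falls outside the sampled support
        mask = (sa.times >= -3.05) & (sa.times <= 0.05)
        sets.append(
            coupling.CurveSet(
                times=sa.times[mask],
                curves={oc: sa.averages[oc][ci, mask] for oc in sa.averages},
                side="eeg-subject",
            )
        )
    return sets


def run_coupling(
    eeg_result: EEGStudyResult,
    beh_result: BehavioralStudyResult,
    cfg: coupling.CouplingConfig,
    out_dir: Path | None = None,
) -> coupling.CouplingResult:
    mask = (beh_result.group.grid >= -3.0 - 1e-9) & (beh_result.group.grid <= 1e-9)
    beh_set = coupling.CurveSet(
        times=beh_result.group.grid[mask],
        curves={oc: c[mask] for oc, c in beh_result.group.curves.items()},
        side="behavioral-group",
    )
    res = coupling.couple(_eeg_curve_sets(eeg_result), beh_set, cfg)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_json(
            out_dir / "coupling.json",
            {
                "t_star": res.t_star,
                "mean_abs_r": res.mean_abs_r,
                "p_value": res.p_value,
                "per_outcome_mean_r": {str(k): v for k, v in res.per_outcome_mean_r.items()},
                "per_subject_r": res.per_subject_r.tolist(),
                "n_permutations": cfg.n_permutations,
                "seed": cfg.seed,
                "version": __version__,
            },
        )
        pd.DataFrame({"null_max_mean_abs_r": res.null_distribution}).to_csv(
            out_dir / "coupling_null.csv", index=False
        )
    return res


def run_study_pipeline(
    study_pair: tuple[int, int],
    n_subjects_eeg: int,
    n_subjects_beh: int,
    seed: int,
    out_dir: Path,
    n_permutations: int = 499,
    **cfg_kw,
):
    """Full paired-study pipeline: EEG study + behavioral study + coupling.

    ``study_pair`` is (1, 2) for the gain framing or (3, 4) for the loss
    framing.  Returns (eeg_result, beh_result, coupling_result).
    """
    eeg_study, beh_study = study_pair
    out_dir = Path(out_dir)
    eeg_res = run_eeg_study(
        eeg_study, n_subjects_eeg, seed, out_dir=out_dir / f"study{eeg_study}", **cfg_kw
    )
    beh_res = run_behavioral_study(
        beh_study, n_subjects_beh, seed + 1, out_dir=out_dir / f"study{beh_study}", **cfg_kw
    )
    ccfg = coupling.CouplingConfig(n_permutations=n_permutations, seed=seed + 2)
    cres = run_coupling(eeg_res, beh_res, ccfg, out_dir=out_dir)
    return eeg_res, beh_res, cres


def simulate_bundle(study: int, n_subjects: int, seed: int, out_dir: Path) -> Path:
    """Simulate a study and write it as a session bundle (CLI backend)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = synthdata.SimulationConfig.for_study(study, n_subjects, seed)
    if study in (2, 4):
        log = synthdata.simulate_behavioral_cohort(cfg)
        ref = synthdata.build_trial_schedule(
            cfg.design, cfg.blocks, seed=seed, framing=cfg.framing,
            sure_amounts=synthdata.SURE_AMOUNTS,
        )
        bundle_io.write_schedule(ref, out_dir / "schedule.csv")
        behavior.write_event_log(log, out_dir / "events.csv")
    else:
        # one shared reference schedule for all subjects keeps epoch metadata
        # cross-references resolvable against a single schedule.csv
        schedule = synthdata.build_trial_schedule(
            cfg.design, cfg.blocks, seed=seed, framing=cfg.framing
        )
        bundle_io.write_schedule(schedule, out_dir / "schedule.csv")
        master = np.random.SeedSequence(seed)
        for si, sseq in enumerate(master.spawn(n_subjects)):
            rng = np.random.default_rng(sseq)
            es = synthdata.simulate_epochs(schedule, cfg, rng, subject=f"S{si + 1:02d}")
            bundle_io.write_epoch_set(es, out_dir)
    bundle_io.write_provenance(out_dir, study=study, seed=seed)
    return out_dir


def _write_json(path: Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
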