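"""EEG–behavior coupling via data-driven time-window search.

The question: do per-outcome EEG averages in the final stretch of the reel's
deceleration parallel the group-level behavioral expectation trajectories?
For a candidate window [t, 0] (t in [-3, -0.5] s; windows always end at the
standstill and are at least 500 ms long), the four per-outcome curves on each
side are linearly resampled to ``m`` points (default 100), concatenated in
the fixed condition order into two 4m-vectors, and Pearson-correlated — once
per subject, against the single group behavioral curve set.  The statistic is
the absolute value of the subject-averaged correlation, and the selected
window is the one maximizing it.

Significance is assessed by outcome-label permutation: each permutation
shuffles the four condition labels of every subject's EEG curves (independent
per-subject shuffles by default), re-runs the full window search, and records
the maximized statistic.  Because the null re-runs the maximization, the
selection step's optimism is built into the null distribution.

The reference search mode is a deterministic 10-ms lattice over window starts
(reproducible, no local optima); an optional ``grid+refine`` mode polishes the
observed optimum with a bounded scalar optimizer.  Permutations always use
the lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .outcomes import CONDITION_ORDER, OutcomeClass

__all__ = [
    "CouplingConfig",
    "CouplingResult",
    "CurveSet",
    "to_grid",
    "concat_pearson",
    "mean_abs_corr",
    "search_window",
    "permutation_pvalue",
    "couple",
]


@dataclass
class CurveSet:
    """Four per-outcome real-valued curves on one time axis.

    ``side`` documents provenance: 'behavioral-group' or 'eeg-subject'.
    """

    times: np.ndarray
    curves: dict[OutcomeClass, np.ndarray]
    side: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        missing = [oc for oc in CONDITION_ORDER if oc not in self.curves]
        if missing:
            raise ValueError(f"curve set missing outcome classes: {missing}")
        for oc, c in self.curves.items():
            c = np.asarray(c, dtype=float)
            if c.shape != self.times.shape:
                raise ValueError(f"curve for {oc} does not match the time axis")
            self.curves[oc] = c

    def stacked(self) -> np.ndarray:
        """(4, n_times) array in the fixed condition order."""
        return np.stack([self.curves[oc] for oc in CONDITION_ORDER])


@dataclass
class CouplingConfig:
    """Search and permutation settings.

    ``t_bounds`` bounds the window *start* (the window always ends at 0 s);
    the upper bound -0.5 enforces the 500-ms minimum window.  ``lag`` shifts
    the EEG time axis by that many seconds relative to behavior before the
    search (positive = EEG delayed); default 0.
    """

    t_bounds: tuple[float, float] = (-3.0, -0.5)
    min_window: float = 0.5
    grid_points: int = 100
    n_permutations: int = 10_000
    seed: int = 0
    lag: float = 0.0
    mode: str = "grid"  # "grid" | "grid+refine"
    shared_shuffle: bool = False
    lattice_step: float = 0.010

    def __post_init__(self) -> None:
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.t_bounds[1] - self.t_bounds[0] < 0:
            raise ValueError("invalid t_bounds")
        if -self.t_bounds[1] < self.min_window:
            raise ValueError("t_bounds upper edge violates the minimum window length")
        if self.mode not in ("grid", "grid+refine"):
            raise ValueError(f"unknown search mode {self.mode!r}")

    def lattice(self) -> np.ndarray:
        """Ascending lattice of candidate window starts."""
        lo, hi = self.t_bounds
        n = int(round((hi - lo) / self.lattice_step))
        return lo + self.lattice_step * np.arange(n + 1)


@dataclass
class CouplingResult:
    t_star: float
    mean_abs_r: float
    per_subject_r: np.ndarray
    per_outcome_mean_r: dict[OutcomeClass, float]
    p_value: float | None = None
    null_distribution: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def to_grid(times: np.ndarray, values: np.ndarray, t_start: float, m: int) -> np.ndarray:
    """Linearly resample a curve at ``m`` equally spaced points spanning
    [t_start, 0] inclusive."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times[0] > t_start + 1e-9 or times[-1] < -1e-9:
        raise ValueError(
            f"curve support [{times[0]:.3f}, {times[-1]:.3f}] does not cover "
            f"[{t_start:.3f}, 0]"
        )
    grid = np.linspace(t_start, 0.0, m)
    return np.interp(grid, times, values)


def _resample_set(cs: CurveSet, t_start: float, m: int, shift: float = 0.0) -> np.ndarray:
    """(4, m) resampled curves; ``shift`` translates the curve's time axis."""
    times = cs.times + shift
    return np.stack([to_grid(times, cs.curves[oc], t_start, m) for oc in CONDITION_ORDER])


def concat_pearson(
    eeg: np.ndarray, beh: np.ndarray
) -> tuple[float, dict[OutcomeClass, float]]:
    """Pearson r between the two 4m-length condition concatenations, plus the
    per-condition r on each m-length pair.

    Both inputs are (4, m) arrays in the fixed condition order.
    """
    eeg = np.asarray(eeg, dtype=float)
    beh = np.asarray(beh, dtype=float)
    if eeg.shape != beh.shape or eeg.ndim != 2 or eeg.shape[0] != 4:
        raise ValueError("expected two (4, m) arrays on a shared grid")
    x = eeg.ravel()
    y = beh.ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: concatenated correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    per: dict[OutcomeClass, float] = {}
    for ci, oc in enumerate(CONDITION_ORDER):
        xc, yc = eeg[ci], beh[ci]
        if np.ptp(xc) == 0 or np.ptp(yc) == 0:
            per[oc] = np.nan
        else:
            per[oc] = float(np.corrcoef(xc, yc)[0, 1])
    return r, per


def mean_abs_corr(per_subject_r: np.ndarray) -> float:
    """|mean over subjects of r| — the absolute value of the *average*, not
    the average of absolute values: opposite-signed subjects cancel."""
    per_subject_r = np.asarray(per_subject_r, dtype=float)
    if per_subject_r.size == 0:
        raise ValueError("empty correlation list")
    return float(abs(per_subject_r.mean()))


# ---------------------------------------------------------------------------
# lattice machinery
# ---------------------------------------------------------------------------


class _LatticeCache:
    """Per-lattice-point sufficient statistics for fast relabeled
    correlations.

    For each window start t, the Pearson r between the concatenated EEG and
    behavior vectors depends on outcome relabeling only through the block
    cross-products  D[s, c, d] = <E_sc, B_d>:  the concatenated sums and
    sums-of-squares are label-invariant.  This lets every permutation reuse
    one interpolation pass.
    """

    def __init__(
        self, eeg_sets: list[CurveSet], beh: CurveSet, cfg: CouplingConfig
    ) -> None:
        self.cfg = cfg
        self.lattice = cfg.lattice()
        m = cfg.grid_points
        n_t = self.lattice.size
        n_s = len(eeg_sets)
        if n_s == 0:
            raise ValueError("no EEG subjects")
        self.n_subjects = n_s
        N = 4 * m
        self.N = N
        self.D = np.empty((n_t, n_s, 4, 4))
        self.sumE = np.empty((n_t, n_s))
        self.QE = np.empty((n_t, n_s))
        self.sumB = np.empty(n_t)
        self.QB = np.empty(n_t)
        self.B = []  # (4, m) per t, kept for per-outcome reporting
        self.E = []  # (n_s, 4, m) per t
        for ti, t in enumerate(self.lattice):
            B = _resample_set(beh, t, m)
            E = np.stack([_resample_set(cs, t, m, shift=cfg.lag) for cs in eeg_sets])
            self.B.append(B)
            self.E.append(E)
            self.sumB[ti] = B.sum()
            self.QB[ti] = (B**2).sum()
            self.sumE[ti] = E.sum(axis=(1, 2))
            self.QE[ti] = (E**2).sum(axis=(1, 2))
            # D[s, c, d] = dot(E[s, c, :], B[d, :])
            self.D[ti] = np.einsum("scm,dm->scd", E, B)
        self._var_b = N * self.QB - self.sumB**2
        self._var_e = N * self.QE - self.sumE**2
        if np.any(self._var_b <= 0):
            raise ValueError("behavioral curves have zero variance in some window")
        if np.any(self._var_e <= 0):
            raise ValueError("EEG curves have zero variance in some window")
        self._denom = np.sqrt(self._var_e * self._var_b[:, None])
        self._identity = np.tile(np.arange(4), (n_s, 1))

    def profile(self, assignment: np.ndarray | None = None) -> np.ndarray:
        """|mean-over-subjects r| at every lattice point.

        ``assignment`` is an (n_subjects, 4) integer array: assignment[s, d]
        is the EEG condition index paired with behavior condition d.  None
        means the identity labeling.
        """
        if assignment is None:
            assignment = self._identity
        s_idx = np.arange(self.n_subjects)[:, None]
        d_idx = np.arange(4)[None, :]
        cross = self.D[:, s_idx, assignment, d_idx].sum(axis=-1)  # (n_t, n_s)
        r = (self.N * cross - self.sumE * self.sumB[:, None]) / self._denom
        return np.abs(r.mean(axis=1))

    def best(self, assignment: np.ndarray | None = None) -> tuple[int, float]:
        """Lattice argmax; ties (within 1e-12, i.e. float noise on exact
        ties) resolved toward the later window start (smaller |t|): the last
        maximal index of the ascending lattice."""
        prof = self.profile(assignment)
        best_val = prof.max()
        ti = int(np.flatnonzero(prof >= best_val - 1e-12)[-1])
        return ti, float(prof[ti])

    def subject_r(self, ti: int) -> np.ndarray:
        """Signed per-subject concatenated correlations at lattice point ti."""
        cross = np.einsum("scm,cm->s", self.E[ti], self.B[ti])
        return (self.N * cross - self.sumE[ti] * self.sumB[ti]) / self._denom[ti]


def _objective(t: float, eeg_sets: list[CurveSet], beh: CurveSet, cfg: CouplingConfig) -> float:
    m = cfg.grid_points
    B = _resample_set(beh, t, m)
    rs = []
    for cs in eeg_sets:
        E = _resample_set(cs, t, m, shift=cfg.lag)
        r, _ = concat_pearson(E, B)
        rs.append(r)
    return mean_abs_corr(np.array(rs))


def search_window(
    eeg_sets: list[CurveSet],
    beh: CurveSet,
    cfg: CouplingConfig,
    _cache: _LatticeCache | None = None,
) -> tuple[float, float]:
    """Find the window start maximizing |mean-over-subjects r|.

    Returns (t_star, mean_abs_r).  In ``grid`` mode the answer is the best
    point of the 10-ms lattice; ``grid+refine`` additionally polishes with a
    bounded local optimizer and never returns less than the lattice optimum
    (minus 1e-9).
    """
    cache = _cache if _cache is not None else _LatticeCache(eeg_sets, beh, cfg)
    ti, best = cache.best()
    t_star = float(cache.lattice[ti])
    if cfg.mode == "grid+refine":
        lo = max(cfg.t_bounds[0], t_star - cfg.lattice_step)
        hi = min(cfg.t_bounds[1], t_star + cfg.lattice_step)
        res = optimize.minimize_scalar(
            lambda t: -_objective(t, eeg_sets, beh, cfg),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-5},
        )
        if -res.fun > best - 1e-9:
            if -res.fun > best:
                t_star, best = float(res.x), float(-res.fun)
    return t_star, best


def _draw_assignments(
    rng: np.random.Generator, n_subjects: int, shared: bool
) -> np.ndarray:
    if shared:
        perm = rng.permutation(4)
        return np.tile(perm, (n_subjects, 1))
    return rng.permuted(np.tile(np.arange(4), (n_subjects, 1)), axis=1)


def permutation_pvalue(
    eeg_sets: list[CurveSet],
    beh: CurveSet,
    cfg: CouplingConfig,
    observed: float,
    _cache: _LatticeCache | None = None,
) -> tuple[float, np.ndarray]:
    """Outcome-label permutation test of the searched statistic.

    Each permutation shuffles the four outcome labels of every subject's EEG
    curves (independently per subject unless ``cfg.shared_shuffle``), re-runs
    the lattice window search, and records the maximized |mean r|.  The
    p-value uses the add-one estimator
    p = (1 + #{null >= observed}) / (1 + n_permutations), never exactly 0.
    """
    cache = _cache if _cache is not None else _LatticeCache(eeg_sets, beh, cfg)
    rng = np.random.default_rng(cfg.seed)
    null = np.empty(cfg.n_permutations)
    for k in range(cfg.n_permutations):
        assignment = _draw_assignments(rng, cache.n_subjects, cfg.shared_shuffle)
        null[k] = cache.profile(assignment).max()
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + cfg.n_permutations)
    return float(p), null


def couple(
    eeg_sets: list[CurveSet], beh: CurveSet, cfg: CouplingConfig
) -> CouplingResult:
    """Full coupling analysis: window search, per-subject and per-outcome
    correlations at the selected window, and the permutation p-value."""
    cache = _LatticeCache(eeg_sets, beh, cfg)
    t_star, best = search_window(eeg_sets, beh, cfg, _cache=cache)
    ti = int(np.argmin(np.abs(cache.lattice - t_star)))
    per_subject = cache.subject_r(ti)
    per_outcome: dict[OutcomeClass, list[float]] = {oc: [] for oc in CONDITION_ORDER}
    for si in range(cache.n_subjects):
        _, per = concat_pearson(cache.E[ti][si], cache.B[ti])
        for oc in CONDITION_ORDER:
            per_outcome[oc].append(per[oc])
    per_outcome_mean = {}
    for oc, v in per_outcome.items():
        finite = [x for x in v if np.isfinite(x)]
        per_outcome_mean[oc] = float(np.mean(finite)) if finite else float("nan")
    p, null = permutation_pvalue(eeg_sets, beh, cfg, best, _cache=cache)
    return CouplingResult(
        t_star=t_star,
        mean_abs_r=best,
        per_subject_r=per_subject,
        per_outcome_mean_r=per_outcome_mean,
        p_value=p,
        null_distribution=null,
    )
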