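"""Inferential layer: Šidák window thresholds, one-way repeated-measures
ANOVA with Greenhouse–Geisser correction, Tukey pairwise comparisons on the
within-subject error term, and paired t-tests.

The ANOVA and Tukey routines are implemented from first principles (sums of
squares and the sample covariance of the condition scores) so that they can be
cross-validated against independent references rather than delegating to one.
All tables are "subject × condition" matrices: one row per subject, one column
per condition, complete (no missing cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "sidak_threshold",
    "report_threshold",
    "AnovaResult",
    "rm_anova_gg",
    "TukeyComparison",
    "tukey_pairwise",
    "paired_ttest",
]


def sidak_threshold(alpha: float, k: int) -> float:
    """Per-test threshold alpha' = 1 - (1 - alpha)^(1/k) controlling the
    family-wise error rate over ``k`` tests.

    Parameters
    ----------
    alpha : family-wise level, in (0, 1).
    k : number of tests, >= 1.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


def report_threshold(alpha: float, k: int, decimals: int = 3) -> float:
    """Šidák threshold truncated (not rounded) to ``decimals`` places, the
    convention used when quoting per-window significance levels."""
    scale = 10.0**decimals
    return math.floor(sidak_threshold(alpha, k) * scale) / scale


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA summary.

    ``p_gg`` is the Greenhouse–Geisser corrected p-value; it is the primary
    p-value whenever ``epsilon_gg < 1`` and more than two conditions are
    compared, since the uncorrected F test assumes sphericity.
    """

    F: float
    df1: int
    df2: int
    epsilon_gg: float
    p_uncorrected: float
    p_gg: float
    ms_error: float
    means: np.ndarray = field(repr=False)
    sds: np.ndarray = field(repr=False)
    n_subjects: int = 0
    n_conditions: int = 0

    @property
    def p_primary(self) -> float:
        if self.n_conditions > 2 and self.epsilon_gg < 1.0:
            return self.p_gg
        return self.p_uncorrected


def _validate_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D (subjects x conditions)")
    if np.isnan(table).any():
        raise ValueError("table has missing cells; a complete design is required")
    return table


def rm_anova_gg(table: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse–Geisser correction.

    Parameters
    ----------
    table : (n_subjects, k) array
        Per-subject condition means; every subject contributes every
        condition.

    Notes
    -----
    F = MS_condition / MS_error with df (k-1, (k-1)(n-1)), where the error
    term is the subject-by-condition interaction.  The Greenhouse–Geisser
    epsilon is computed from the double-centered sample covariance S* of the
    condition scores::

        eps = (sum_i S*_ii)^2 / ((k-1) * sum_ij S*_ij^2)

    and the corrected p-value uses an F distribution with eps-scaled degrees
    of freedom.  eps is clipped to its theoretical range [1/(k-1), 1].
    """
    table = _validate_table(table)
    n, k = table.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 3:
        raise ValueError("need at least 3 subjects")

    grand = table.mean()
    cond_means = table.mean(axis=0)
    subj_means = table.mean(axis=1)

    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_error = ss_total - ss_cond - ss_subj

    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_error = ss_error / df2

    if ms_error <= 0:
        f_stat = np.inf if ms_cond > 0 else 0.0
    else:
        f_stat = ms_cond / ms_error

    # Greenhouse-Geisser epsilon from the double-centered covariance matrix.
    cov = np.cov(table, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    row_mean = cov.mean(axis=1, keepdims=True)
    col_mean = cov.mean(axis=0, keepdims=True)
    dc = cov - row_mean - col_mean + cov.mean()
    denom = df1 * np.sum(dc**2)
    if denom <= 0:
        eps = 1.0
    else:
        eps = float(np.trace(dc) ** 2 / denom)
    eps = float(np.clip(eps, 1.0 / df1, 1.0))

    p_unc = float(sps.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    p_gg = float(sps.f.sf(f_stat, eps * df1, eps * df2)) if np.isfinite(f_stat) else 0.0

    return AnovaResult(
        F=float(f_stat),
        df1=df1,
        df2=df2,
        epsilon_gg=eps,
        p_uncorrected=p_unc,
        p_gg=p_gg,
        ms_error=float(ms_error),
        means=cond_means,
        sds=table.std(axis=0, ddof=1),
        n_subjects=n,
        n_conditions=k,
    )


@dataclass(frozen=True)
class TukeyComparison:
    """One pairwise comparison from a within-subject Tukey test."""

    i: int
    j: int
    mean_diff: float
    t: float
    q: float
    p_adjusted: float


def tukey_pairwise(table: np.ndarray) -> list[TukeyComparison]:
    """All pairwise comparisons with studentized-range (Tukey) adjustment.

    Uses the omnibus within-subject mean-square error with df (k-1)(n-1) as
    the common error term (one of several defensible repeated-measures
    conventions; documented).  Returns comparisons for every ordered pair
    (i, j), i < j, in condition-column order; mean_diff = mean_i - mean_j.
    """
    table = _validate_table(table)
    n, k = table.shape
    res = rm_anova_gg(table)
    se = math.sqrt(res.ms_error / n)
    out: list[TukeyComparison] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(res.means[i] - res.means[j])
            if se == 0:
                q = 0.0 if diff == 0 else math.inf
            else:
                q = abs(diff) / se
            t = q / math.sqrt(2.0) * (1 if diff >= 0 else -1)
            p_adj = float(sps.studentized_range.sf(q, k, res.df2))
            out.append(
                TukeyComparison(
                    i=i,
                    j=j,
                    mean_diff=diff,
                    t=t,
                    q=q * (1 if diff >= 0 else -1),
                    p_adjusted=min(p_adj, 1.0),
                )
            )
    return out


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Classical paired t-test; returns (t, df, p) with df = n - 1.

    Raises on degenerate input (all differences identical), where the t
    statistic is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    d = a - b
    if np.ptp(d) == 0 and d[0] != 0:
        raise ValueError("zero variance of differences: paired t undefined")
    if np.ptp(d) == 0:  # all differences exactly zero -> t = 0, p = 1
        return 0.0, n - 1, 1.0
    t, p = sps.ttest_rel(a, b)
    return float(t), n - 1, float(p)
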