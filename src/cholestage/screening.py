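"""Dimension reduction: per-factor ANOVA across time points and Welch t-tests.

A one-way fixed-effects ANOVA with time point as (unordered) grouping factor
screens each measured factor for significant regulation over the disease
time course; p-values are adjusted for multiplicity over the whole factor
family with the Holm step-down procedure.  A two-tailed unpaired Welch
t-test between the 0 h (sham) and 6 h groups targets the initial response
specifically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import TimeCourseDataset


@dataclass
class ScreeningResult:
    """Per-factor test outcome with family-wise adjusted significance."""

    factor_id: str
    statistic: float
    p_raw: float
    p_adj: float
    significant: bool


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control).

    Sorted ascending, p_(i) is multiplied by (m - i + 1), the sequence is
    made monotone non-decreasing by a cumulative maximum and capped at 1;
    values are returned in the original input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _significant(p_adj: float, alpha: float) -> bool:
    # alpha >= 1 disables the screen: Holm caps adjusted p-values at 1,
    # so the strict inequality could never admit anything otherwise
    return bool(alpha >= 1.0 or p_adj < alpha)


def _group_values(block: np.ndarray) -> list[np.ndarray]:
    """Finite per-time-point replicate groups of one factor."""
    return [row[np.isfinite(row)] for row in block]


def _one_way_p(groups) -> tuple[float, float]:
    """(F, p) for one-way ANOVA with degenerate-input conventions.

    Zero between- and within-group variance (all values identical) yields
    p = 1 by convention; zero within- but positive between-group variance
    yields p = 0 (infinite F).
    """
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # zero within-group variance
        return np.inf, 0.0
    return float(f), float(p)


def anova_screen(
    data: TimeCourseDataset, alpha: float = 0.05
) -> list[ScreeningResult]:
    """One-way ANOVA over time points for every factor, Holm-adjusted.

    Factors with fewer than two usable groups (>= 1 finite value each) are
    skipped with a warning and excluded from the Holm family.  Results are
    sorted by adjusted p-value.
    """
    results = []
    for meta in data.factors:
        groups = [
            g for g in _group_values(data.factor_values(meta.factor_id))
            if g.size >= 1
        ]
        if len(groups) < 2:
            warnings.warn(
                f"factor {meta.factor_id!r}: fewer than 2 usable time groups; "
                "skipped",
                stacklevel=2,
            )
            continue
        f, p = _one_way_p(groups)
        results.append((meta.factor_id, f, p))

    p_adj = holm_adjust([p for _, _, p in results])
    screened = [
        ScreeningResult(fid, f, p, pa, _significant(pa, alpha))
        for (fid, f, p), pa in zip(results, p_adj)
    ]
    screened.sort(key=lambda r: (r.p_adj, r.p_raw, r.factor_id))
    return screened


def welch_initial_test(
    data: TimeCourseDataset,
    time_a: float = 0.0,
    time_b: float = 6.0,
    alpha: float = 0.05,
) -> list[ScreeningResult]:
    """Two-tailed unpaired Welch t-test between two time points per factor.

    Defaults compare the sham control (0 h) with the 6 h group to probe the
    initial response.  Uses the Welch-Satterthwaite degrees of freedom; the
    family of factors is Holm-adjusted like the ANOVA screen.  Two constant,
    equal groups give t = 0, p = 1 by convention.
    """
    times = list(data.times)
    for t in (time_a, time_b):
        if t not in times:
            raise ValueError(f"time point {t} h not in dataset grid {times}")
    ia, ib = times.index(time_a), times.index(time_b)

    results = []
    for meta in data.factors:
        block = data.factor_values(meta.factor_id)
        a = block[ia][np.isfinite(block[ia])]
        b = block[ib][np.isfinite(block[ib])]
        if a.size < 2 or b.size < 2:
            warnings.warn(
                f"factor {meta.factor_id!r}: <2 finite values in a group; "
                "skipped",
                stacklevel=2,
            )
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            t_stat, p = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t_stat, p = stats.ttest_ind(a, b, equal_var=False)
            if not np.isfinite(p):
                t_stat, p = (np.inf if not np.isfinite(t_stat) else t_stat, 0.0)
        results.append((meta.factor_id, float(t_stat), float(p)))

    p_adj = holm_adjust([p for _, _, p in results])
    screened = [
        ScreeningResult(fid, t, p, pa, _significant(pa, alpha))
        for (fid, t, p), pa in zip(results, p_adj)
    ]
    screened.sort(key=lambda r: (r.p_adj, r.p_raw, r.factor_id))
    return screened


def significant_ids(results: list[ScreeningResult]) -> list[str]:
    """Factor ids passing the screen, in result order."""
    return [r.factor_id for r in results if r.significant]
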