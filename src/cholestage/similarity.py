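"""YS3 time-course similarity: a rank-based measure for short replicated series.

The similarity between two factor time courses is a weighted combination of
three components, each mapped to [0, 1]:

* ``S*`` — Spearman rank correlation of the individual data points (all
  N_t x N_r cells, paired by (time, replicate) index), mapped by (S + 1)/2;
* ``A*`` — Spearman correlation of the consecutive differences of the
  per-time mean courses, capturing similarity of *changes*;
* ``M*`` — agreement of the locations (time indices) of the minimum and the
  maximum of the mean courses:
  ``M* = 1 - (|pmax_i - pmax_j| + |pmin_i - pmin_j|) / (2 (N_t - 1))``.

The combined score is ``y = w1 S* + w2 A* + w3 M*`` with default weights
(0.5, 0.3, 0.2) and is reported rescaled to [-1, 1] as ``y_rescaled =
2 (y - 0.5)``.  Spearman (rather than Pearson) is used throughout for
robustness against outliers.  Degenerate inputs (constant series, constant
mean course) receive the neutral component value 0.5 and are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import NormalizedDataset, TimeCourseDataset

DEFAULT_WEIGHTS = (0.5, 0.3, 0.2)


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson of midranks), pairwise complete.

    Returns 0 when undefined (a constant sequence or < 3 complete pairs);
    use :func:`spearman_flagged` to observe the degeneracy flag.
    """
    return spearman_flagged(x, y)[0]


def spearman_flagged(x, y) -> tuple[float, bool]:
    """(rho, defined) — Spearman correlation and whether it was computable."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("sequences must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, False
    rho = stats.spearmanr(x, y).statistic
    return float(rho), True


@dataclass
class YS3Components:
    """Decomposition of one YS3 similarity evaluation."""

    s_star: float
    a_star: float
    m_star: float
    y: float
    y_rescaled: float
    degenerate: list[str] = field(default_factory=list)


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of rescaled YS3 values in [-1, 1], unit diagonal."""

    factor_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.factor_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape inconsistent with factor ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.factor_ids, columns=self.factor_ids
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def reorder(self, factor_ids) -> "SimilarityMatrix":
        idx = [self.factor_ids.index(f) for f in factor_ids]
        return SimilarityMatrix(list(factor_ids), self.values[np.ix_(idx, idx)])


def _mean_course(block: np.ndarray) -> np.ndarray:
    """Per-time mean over replicates (NaN-aware)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(block, axis=1)


def _extremum_positions(mean_course: np.ndarray) -> tuple[int, int]:
    """(argmax, argmin) time indices; earliest index on ties."""
    return int(np.nanargmax(mean_course)), int(np.nanargmin(mean_course))


def ys3(xi, xj, weights=DEFAULT_WEIGHTS) -> YS3Components:
    """YS3 similarity components between two factors.

    Parameters
    ----------
    xi, xj:
        Value blocks of shape ``(n_times, n_replicates)`` on a common time
        grid.  ``S*`` is computed on the individual cells; ``A*`` and ``M*``
        on the replicate-averaged mean courses.
    weights:
        Non-negative (w1, w2, w3) summing to 1.
    """
    w = np.asarray(weights, dtype=float)
    if w.size != 3 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be 3 non-negative numbers summing to 1")
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    xj = np.atleast_2d(np.asarray(xj, dtype=float))
    if xi.shape != xj.shape:
        raise ValueError("factors must share the same (time, replicate) grid")
    n_t = xi.shape[0]
    degenerate: list[str] = []

    s_rho, s_ok = spearman_flagged(xi.ravel(), xj.ravel())
    if not s_ok:
        degenerate.append("S*")
        s_star = 0.5
    else:
        s_star = (s_rho + 1.0) / 2.0

    mi, mj = _mean_course(xi), _mean_course(xj)
    di, dj = np.diff(mi), np.diff(mj)
    a_rho, a_ok = spearman_flagged(di, dj)
    if not a_ok:
        degenerate.append("A*")
        a_star = 0.5
    else:
        a_star = (a_rho + 1.0) / 2.0

    if np.ptp(mi[np.isfinite(mi)]) == 0 or np.ptp(mj[np.isfinite(mj)]) == 0:
        degenerate.append("M*")
        m_star = 0.5
    else:
        pmax_i, pmin_i = _extremum_positions(mi)
        pmax_j, pmin_j = _extremum_positions(mj)
        m_star = 1.0 - (abs(pmax_i - pmax_j) + abs(pmin_i - pmin_j)) / (
            2.0 * (n_t - 1)
        )

    y = float(w[0] * s_star + w[1] * a_star + w[2] * m_star)
    return YS3Components(s_star, a_star, m_star, y, 2.0 * (y - 0.5), degenerate)


def _rank_rows(a: np.ndarray) -> np.ndarray:
    """Midrank transform along axis 1."""
    return np.apply_along_axis(stats.rankdata, 1, a)


def similarity_matrix(
    data: TimeCourseDataset,
    subset=None,
    weights=DEFAULT_WEIGHTS,
) -> SimilarityMatrix:
    """All pairwise rescaled YS3 values for a factor subset.

    Factors with fewer than 3 usable individual data points are excluded
    with a warning.  For complete data the computation is vectorised
    (rank transform + correlation matrix); with missing cells it falls back
    to pairwise :func:`ys3` calls on pairwise-complete observations.
    """
    ids = list(subset) if subset is not None else data.factor_ids
    usable = []
    for f in ids:
        if np.isfinite(data.factor_values(f)).sum() >= 3:
            usable.append(f)
        else:
            warnings.warn(
                f"factor {f!r}: <3 usable points; excluded from similarity",
                stacklevel=2,
            )
    ids = usable
    if len(ids) < 2:
        raise ValueError("need at least 2 usable factors")

    sub = data.subset(ids)
    blocks = sub.values  # (K, N_t, N_r)
    if not np.isnan(blocks).any():
        mat = _similarity_matrix_complete(blocks, np.asarray(weights, float))
    else:
        k = len(ids)
        mat = np.eye(k)
        for a in range(k):
            for b in range(a + 1, k):
                mat[a, b] = mat[b, a] = ys3(
                    blocks[a], blocks[b], weights
                ).y_rescaled
    np.fill_diagonal(mat, 1.0)
    return SimilarityMatrix(ids, mat)


def _similarity_matrix_complete(
    blocks: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Vectorised YS3 matrix for complete data (no NaN)."""
    k, n_t, _ = blocks.shape
    flat = blocks.reshape(k, -1)

    def _corr(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        const = np.ptp(rows, axis=1) == 0
        ranks = _rank_rows(rows)
        sd = ranks.std(axis=1)
        sd[sd == 0] = 1.0
        z = (ranks - ranks.mean(axis=1, keepdims=True)) / sd[:, None]
        c = z @ z.T / rows.shape[1]
        return np.clip(c, -1.0, 1.0), const

    s_corr, s_const = _corr(flat)
    s_star = (s_corr + 1.0) / 2.0
    s_star[s_const, :] = 0.5
    s_star[:, s_const] = 0.5

    means = blocks.mean(axis=2)
    diffs = np.diff(means, axis=1)
    a_corr, a_const = _corr(diffs)
    a_star = (a_corr + 1.0) / 2.0
    a_star[a_const, :] = 0.5
    a_star[:, a_const] = 0.5

    m_const = np.ptp(means, axis=1) == 0
    pmax = means.argmax(axis=1)
    pmin = means.argmin(axis=1)
    m_star = 1.0 - (
        np.abs(pmax[:, None] - pmax[None, :])
        + np.abs(pmin[:, None] - pmin[None, :])
    ) / (2.0 * (n_t - 1))
    m_star[m_const, :] = 0.5
    m_star[:, m_const] = 0.5

    y = w[0] * s_star + w[1] * a_star + w[2] * m_star
    mat = 2.0 * (y - 0.5)
    return (mat + mat.T) / 2.0


def read_similarity_csv(path) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return SimilarityMatrix(list(df.index), df.to_numpy())


def plot_similarity_heatmap(sim: SimilarityMatrix, path) -> None:
    """Minimal heatmap of the similarity matrix (values only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(sim.values, vmin=-1, vmax=1, cmap="RdBu")
    ax.set_xticks(range(len(sim.factor_ids)))
    ax.set_yticks(range(len(sim.factor_ids)))
    ax.set_xticklabels(sim.factor_ids, rotation=90, fontsize=5)
    ax.set_yticklabels(sim.factor_ids, fontsize=5)
    fig.colorbar(im, ax=ax, label="YS3 (rescaled)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
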