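"""Search factor combinations that best predict disease phase.

The regression tree is fitted once on the cluster mean courses; candidate
marker panels substitute, per cluster, an individual factor (or the average
of a factor pair) for the cluster mean at prediction time.  Panels are
scored with the distance

    d(<f_1>, ..., <f_k>) = (1/N_S) * sqrt( sum_i (t_i^pre - t_i^exp)^2 )

evaluated on the log time scale, smaller is better.  Note the 1/N_S sits
outside the square root — a ``conventional_rms`` switch provides the
usual sqrt-of-mean RMS instead, and ``log_scale=False`` scores raw hours.

All one-factor-per-cluster combinations are enumerable exactly (their count
is the product of cluster sizes); two-factor-per-cluster combinations are
sampled uniformly at random.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .clustering import ClusterSet
from .dataset import NormalizedDataset
from .phase_tree import RegressionTree, SampleTable, predict_matrix


def count_single_combinations(cluster_sizes) -> int:
    """Product of cluster sizes = number of one-factor-per-cluster panels."""
    sizes = list(cluster_sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("every cluster must contain at least one factor")
    return math.prod(sizes)


def _ordered_members(clusters: ClusterSet) -> list[list[str]]:
    """Per-cluster member lists, clusters ascending, factors sorted."""
    return [sorted(clusters.members(c)) for c in clusters.cluster_labels]


def enumerate_single_combinations(clusters: ClusterSet):
    """Lexicographic stream of one-factor-per-cluster tuples (exhaustive)."""
    members = _ordered_members(clusters)
    if any(not m for m in members):
        raise ValueError("every cluster must be non-empty")
    return product(*members)


def sample_double_combinations(
    clusters: ClusterSet, n: int = 10000, seed: int = 0
):
    """Random distinct tuples of one unordered factor *pair* per cluster.

    If the total pair-combination space holds fewer than ``n`` tuples, the
    whole space is enumerated instead (with a warning).  Reproducible under
    ``seed``.
    """
    members = _ordered_members(clusters)
    if any(len(m) < 2 for m in members):
        raise ValueError("every cluster needs >= 2 factors to form pairs")
    space = math.prod(math.comb(len(m), 2) for m in members)
    if space <= n:
        warnings.warn(
            f"pair-combination space ({space}) <= requested n ({n}); "
            "enumerating exhaustively",
            stacklevel=2,
        )
        pair_lists = [
            [(a, b) for i, a in enumerate(m) for b in m[i + 1 :]]
            for m in members
        ]
        return list(product(*pair_lists))
    rng = np.random.default_rng(seed)
    seen: set = set()
    out = []
    while len(out) < n:
        combo = tuple(
            tuple(sorted(rng.choice(len(m), size=2, replace=False)))
            for m in members
        )
        if combo in seen:
            continue
        seen.add(combo)
        out.append(
            tuple((m[i], m[j]) for m, (i, j) in zip(members, combo))
        )
    return out


@dataclass
class CombinationScore:
    """One scored marker panel: chosen factors per cluster and distance d."""

    combo: tuple
    d: float
    predictions: pd.DataFrame  # per-sample predicted vs true times

    def __post_init__(self):
        self.d = float(self.d)


def _combo_matrix(
    data: NormalizedDataset, combo, table: SampleTable
) -> np.ndarray:
    """Predictor matrix with the combo's factor values per sample.

    Each combo slot is a factor id or a tuple of ids (averaged).  Sample
    rows follow the table's (time, replicate) order.
    """
    n_r = data.n_replicates
    cols = []
    for slot in combo:
        ids = (slot,) if isinstance(slot, str) else tuple(slot)
        block = np.mean(
            [data.factor_values(f) for f in ids], axis=0
        )  # (N_t, N_r)
        flat = block.ravel()  # row-major (time, rep) matches build_sample_table
        cols.append(flat)
    X_full = np.column_stack(cols)
    # align with the table's retained rows
    time_pos = {t: i for i, t in enumerate(data.times)}
    rows = [
        time_pos[t] * n_r + (r - 1)
        for t, r in zip(table.times_h, table.replicates)
    ]
    return X_full[rows]


def combination_distance(
    pred_log: np.ndarray,
    true_log: np.ndarray,
    conventional_rms: bool = False,
) -> float:
    """The d score: (1/N) sqrt(sum r^2), or sqrt(mean r^2) if conventional."""
    resid = np.asarray(pred_log) - np.asarray(true_log)
    n = resid.size
    if n == 0:
        raise ValueError("no predictions to score")
    if conventional_rms:
        return float(np.sqrt((resid**2).mean()))
    return float(np.sqrt((resid**2).sum()) / n)


def score_combination(
    tree: RegressionTree,
    data: NormalizedDataset,
    table: SampleTable,
    combo,
    log_scale: bool = True,
    conventional_rms: bool = False,
) -> CombinationScore:
    """Score one panel by routing its factor values through the fitted tree.

    Samples with a missing substituted predictor value are skipped (N_S
    adjusted) with a warning.
    """
    X = _combo_matrix(data, combo, table)
    ok = ~np.isnan(X).any(axis=1)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} samples skipped for combo {combo} "
            "(missing factor values)",
            stacklevel=2,
        )
    pred_log = predict_matrix(tree, X[ok])
    true_log = table.y[ok]
    if log_scale:
        d = combination_distance(pred_log, true_log, conventional_rms)
    else:
        d = combination_distance(
            np.exp(pred_log) - 1, np.exp(true_log) - 1, conventional_rms
        )
    predictions = pd.DataFrame(
        {
            "time_h": table.times_h[ok],
            "replicate": table.replicates[ok],
            "true_log": true_log,
            "pred_log": pred_log,
            "pred_hours": np.exp(pred_log) - 1,
        }
    )
    return CombinationScore(tuple(combo), d, predictions)


def score_all_single_combinations(
    tree: RegressionTree,
    data: NormalizedDataset,
    clusters: ClusterSet,
    table: SampleTable,
    conventional_rms: bool = False,
    chunk_size: int = 50_000,
) -> pd.DataFrame:
    """Vectorised d scores for *all* one-factor-per-cluster panels.

    Returns a DataFrame with one row per combination, columns per cluster
    slot plus ``d``, sorted ascending by (d, combo).  Requires complete
    (non-missing) normalized data for the clustered factors.  The
    combination space is processed in chunks of ``chunk_size`` to bound
    peak memory.
    """
    members = _ordered_members(clusters)
    sizes = [len(m) for m in members]
    n_combos = count_single_combinations(sizes)
    n_s = table.n_samples

    # per-cluster factor value matrices aligned to table rows: (size_j, N_S)
    value_mats = []
    for m in members:
        vm = np.stack(
            [_combo_matrix(data, (f,), table)[:, 0] for f in m]
        )
        if np.isnan(vm).any():
            raise ValueError(
                "vectorised scoring requires complete data; use "
                "score_combination for datasets with missing cells"
            )
        value_mats.append(vm)

    d = np.empty(n_combos)
    idx_cols = np.empty((len(sizes), n_combos), dtype=np.int32)
    for start in range(0, n_combos, chunk_size):
        stop = min(start + chunk_size, n_combos)
        # lexicographic combo index for this chunk
        idx = np.unravel_index(np.arange(start, stop), sizes)
        # predictor planes (chunk, N_S), routed through the tree with masks
        planes = [vm[ix] for vm, ix in zip(value_mats, idx)]
        pred = np.empty((stop - start, n_s))

        def _assign(node, mask: np.ndarray):
            if node.is_leaf:
                pred[mask] = node.prediction
                return
            le = planes[node.predictor] <= node.threshold
            _assign(node.left, mask & le)
            _assign(node.right, mask & ~le)

        _assign(tree.root, np.ones((stop - start, n_s), dtype=bool))
        resid = pred - table.y[None, :]
        if conventional_rms:
            d[start:stop] = np.sqrt((resid**2).mean(axis=1))
        else:
            d[start:stop] = np.sqrt((resid**2).sum(axis=1)) / n_s
        for j, ix in enumerate(idx):
            idx_cols[j, start:stop] = ix

    cluster_names = [f"c{c}" for c in clusters.cluster_labels]
    out = {
        name: np.array(m)[ix]
        for name, m, ix in zip(cluster_names, members, idx_cols)
    }
    out["d"] = d
    df = pd.DataFrame(out)
    slot_cols = [c for c in df.columns if c != "d"]
    return df.sort_values(["d"] + slot_cols, kind="stable").reset_index(
        drop=True
    )


def rank_combinations(scores, k: int) -> list[CombinationScore]:
    """Top-k scored combinations by ascending (d, lexicographic combo)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    items = list(scores)
    items.sort(key=lambda s: (s.d, s.combo))
    return items[:k]
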