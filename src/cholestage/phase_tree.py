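"""Regression tree predicting disease phase (log-time) from cluster means.

A binary regression tree is grown by recursive partitioning in the style of
CART/rpart: samples are the N_t x N_r animals, predictors are the per-sample
cluster mean values of the normalized factors, and the response is the
log-transformed sacrifice time

    t_tilde = log(t + 1)        (t in hours, natural log)

which renders the study's geometric time grid approximately equidistant.
At each node with at least ``minsplit`` samples the split maximising the
sum-of-squares reduction

    S_T - (S_L + S_R),   S = sum((t_tilde - mean)^2)

over all predictors and all midpoint thresholds is taken, provided both
children keep at least ``minbucket`` samples and the reduction is at least
``cp * S_root`` (complexity-parameter pruning; enforced during growth and by
a bottom-up pass, which for a fixed cp yield the same tree).  Leaves predict
the mean response of their training samples; back-transformed leaf means
``exp(t_tilde) - 1`` name the time classes.  Ties in the split search are
broken deterministically by lowest predictor index, then lowest threshold.

Robustness is assessed leave-one-out: the tree is refitted N_S times, each
time predicting the held-out animal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterSet
from .dataset import NormalizedDataset


def log_time(t_hours) -> np.ndarray:
    """The response transform t_tilde = log(t + 1), natural log, t in hours."""
    return np.log(np.asarray(t_hours, dtype=float) + 1.0)


def inverse_log_time(t_tilde) -> np.ndarray:
    return np.exp(np.asarray(t_tilde, dtype=float)) - 1.0


def format_time_class(hours: float) -> str:
    """Human-readable class label for a back-transformed leaf mean."""
    if hours < 48.0:
        return f"{hours:.0f} h"
    return f"{hours / 24.0:.0f} d"


@dataclass
class SampleTable:
    """Per-animal predictor/response table for tree fitting.

    One row per (time point, replicate); ``X`` holds the predictor values
    (cluster means or individual factors), ``y`` the log-transformed times.
    """

    X: np.ndarray
    y: np.ndarray
    predictor_names: list[str]
    times_h: np.ndarray
    replicates: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be (n_samples, n_predictors)")
        if self.X.shape[1] != len(self.predictor_names):
            raise ValueError("predictor_names inconsistent with X")

    @property
    def n_samples(self) -> int:
        return self.y.size

    def drop_rows(self, rows) -> "SampleTable":
        keep = np.ones(self.n_samples, dtype=bool)
        keep[list(np.atleast_1d(rows))] = False
        return SampleTable(
            self.X[keep],
            self.y[keep],
            list(self.predictor_names),
            self.times_h[keep],
            self.replicates[keep],
        )


def build_sample_table(
    clusters: ClusterSet, data: NormalizedDataset
) -> SampleTable:
    """One row per (time, replicate) with cluster-mean predictors.

    Predictor ``c<j>`` at sample (t_i, r) is the mean of cluster j's
    normalized member factors at that cell.  Rows whose predictors are all
    missing are excluded with a warning.
    """
    import warnings

    if not clusters.mean_courses:
        from .clustering import cluster_mean_courses

        clusters.mean_courses, clusters.mean_profile = cluster_mean_courses(
            clusters, data
        )
    labels = clusters.cluster_labels
    n_t, n_r = data.n_times, data.n_replicates
    X = np.empty((n_t * n_r, len(labels)))
    for j, c in enumerate(labels):
        X[:, j] = clusters.mean_courses[c].ravel()  # (time, rep) row-major
    times = np.repeat(data.times, n_r)
    reps = np.tile(np.arange(1, n_r + 1), n_t)
    bad = np.isnan(X).all(axis=1)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} fully-missing sample rows excluded",
            stacklevel=2,
        )
    keep = ~bad
    return SampleTable(
        X[keep],
        log_time(times[keep]),
        [f"c{c}" for c in labels],
        times[keep],
        reps[keep],
    )


@dataclass
class TreeNode:
    """Internal split node (``<= threshold`` goes left/'yes') or leaf."""

    n: int
    prediction: float  # mean response (t_tilde) of training samples
    time_range: tuple[float, float]  # [min, max] training hours
    pct: float  # fraction of root samples
    predictor: int | None = None
    predictor_name: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def predicted_hours(self) -> float:
        return float(np.exp(self.prediction) - 1.0)

    @property
    def class_label(self) -> str:
        return format_time_class(self.predicted_hours)


@dataclass
class RegressionTree:
    root: TreeNode
    predictor_names: list[str]
    minsplit: int
    minbucket: int
    cp: float
    s_root: float

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self._walk() if n.is_leaf)

    def _walk(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.extend([node.right, node.left])

    def leaves(self) -> list[TreeNode]:
        return [n for n in self._walk() if n.is_leaf]

    def used_predictors(self) -> list[str]:
        names = []
        for n in self._walk():
            if not n.is_leaf and n.predictor_name not in names:
                names.append(n.predictor_name)
        return names

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def _node(n: TreeNode) -> dict:
            d = {
                "n": n.n,
                "prediction_log": n.prediction,
                "prediction_hours": n.predicted_hours,
                "class": n.class_label,
                "time_range_h": list(n.time_range),
                "pct": n.pct,
            }
            if not n.is_leaf:
                d.update(
                    predictor=n.predictor_name,
                    threshold=n.threshold,
                    left=_node(n.left),
                    right=_node(n.right),
                )
            return d

        return {
            "minsplit": self.minsplit,
            "minbucket": self.minbucket,
            "cp": self.cp,
            "root": _node(self.root),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def render(self) -> str:
        """Indented text rendering; left branch = 'yes' (<= threshold)."""
        lines: list[str] = []

        def _rec(n: TreeNode, depth: int, tag: str):
            pad = "  " * depth
            if n.is_leaf:
                lines.append(
                    f"{pad}{tag}leaf: class {n.class_label} "
                    f"(mean {n.predicted_hours:.1f} h, range "
                    f"[{n.time_range[0]:.0f}, {n.time_range[1]:.0f}] h, "
                    f"n={n.n}, {100 * n.pct:.0f}%)"
                )
            else:
                lines.append(
                    f"{pad}{tag}{n.predictor_name} <= {n.threshold:.4g}?"
                )
                _rec(n.left, depth + 1, "yes: ")
                _rec(n.right, depth + 1, "no:  ")

        _rec(self.root, 0, "")
        return "\n".join(lines)


def _sum_sq(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if y.size else 0.0


def best_split(
    X: np.ndarray, y: np.ndarray, minbucket: int
) -> tuple[int, float, float] | None:
    """(predictor, threshold, SS reduction) of the best admissible split.

    Thresholds are midpoints between consecutive distinct sorted predictor
    values; both children must keep >= minbucket samples.  Ties are broken
    by lowest predictor index, then lowest threshold.  Returns None if no
    admissible split exists or none reduces the sum of squares.
    """
    n = y.size
    s_t = _sum_sq(y)
    best: tuple[float, int, float] | None = None  # (-reduction proxy ordering)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        if np.isnan(xs).any():
            raise ValueError("missing predictor values are not supported")
        # cumulative sums for O(n) evaluation of all split positions
        csum = np.cumsum(ys)
        csq = np.cumsum(ys**2)
        total, total_sq = csum[-1], csq[-1]
        sizes_l = np.arange(1, n)
        valid = (
            (xs[:-1] < xs[1:])
            & (sizes_l >= minbucket)
            & (n - sizes_l >= minbucket)
        )
        if not valid.any():
            continue
        s_l = csq[:-1] - csum[:-1] ** 2 / sizes_l
        with np.errstate(invalid="ignore"):
            s_r = (total_sq - csq[:-1]) - (total - csum[:-1]) ** 2 / (
                n - sizes_l
            )
        reduction = s_t - (s_l + s_r)
        reduction[~valid] = -np.inf
        pos = int(np.argmax(reduction))
        # argmax returns earliest index; with ascending xs that is also the
        # lowest threshold among tied reductions for this predictor
        red = float(reduction[pos])
        if red <= 0:
            continue
        thr = float((xs[pos] + xs[pos + 1]) / 2.0)
        if best is None or red > best[0] + 1e-12:
            best = (red, j, thr)
    if best is None:
        return None
    return best[1], best[2], best[0]


def fit_tree(
    table: SampleTable,
    minsplit: int = 6,
    minbucket: int = 2,
    cp: float = 0.01,
) -> RegressionTree:
    """Grow (and prune) a regression tree on the sample table.

    Defaults mirror the study's settings: a node is considered for splitting
    only with >= 6 samples, terminal nodes keep >= 2 samples, and a split
    must reduce the root sum of squares by at least the fraction cp = 0.01.
    """
    if table.n_samples < 1:
        raise ValueError("empty sample table")
    s_root = _sum_sq(table.y)
    n_root = table.n_samples
    min_gain = cp * s_root

    def _grow(rows: np.ndarray) -> TreeNode:
        y = table.y[rows]
        node = TreeNode(
            n=rows.size,
            prediction=float(y.mean()),
            time_range=(
                float(table.times_h[rows].min()),
                float(table.times_h[rows].max()),
            ),
            pct=rows.size / n_root,
        )
        if rows.size < minsplit or np.ptp(y) == 0:
            return node
        found = best_split(table.X[rows], y, minbucket)
        if found is None:
            return node
        j, thr, red = found
        if s_root > 0 and red < min_gain:
            return node
        go_left = table.X[rows, j] <= thr
        node.predictor = j
        node.predictor_name = table.predictor_names[j]
        node.threshold = thr
        node.left = _grow(rows[go_left])
        node.right = _grow(rows[~go_left])
        return node

    root = _grow(np.arange(table.n_samples))
    tree = RegressionTree(
        root, list(table.predictor_names), minsplit, minbucket, cp, s_root
    )
    _prune(tree)
    return tree


def _prune(tree: RegressionTree) -> None:
    """Bottom-up collapse of splits below the cp gain threshold.

    With the same gain filter already applied during growth this is a
    no-op for a fixed cp; it guards re-pruning a tree grown with a looser
    parameter.
    """
    min_gain = tree.cp * tree.s_root

    def _collapse(node: TreeNode) -> None:
        if node.is_leaf:
            return
        _collapse(node.left)
        _collapse(node.right)
        if node.left.is_leaf and node.right.is_leaf:
            nl, nr = node.left.n, node.right.n
            ml, mr = node.left.prediction, node.right.prediction
            mean = node.prediction
            red = nl * (ml - mean) ** 2 + nr * (mr - mean) ** 2
            if red < min_gain:
                node.predictor = node.predictor_name = node.threshold = None
                node.left = node.right = None

    _collapse(tree.root)


def route(tree: RegressionTree, x) -> TreeNode:
    """Leaf reached by predictor vector ``x`` (<= threshold goes left)."""
    x = np.asarray(x, dtype=float)
    node = tree.root
    while not node.is_leaf:
        v = x[node.predictor]
        if np.isnan(v):
            raise ValueError(
                f"missing value for predictor {node.predictor_name!r} "
                "(no surrogate splits)"
            )
        node = node.left if v <= node.threshold else node.right
    return node


def predict_time(tree: RegressionTree, predictors) -> tuple[float, float, str]:
    """(predicted t_tilde, predicted hours, class label) for one sample.

    ``predictors`` is either a vector ordered like the tree's predictors or
    a mapping from predictor name to value.
    """
    if isinstance(predictors, dict):
        x = np.array([predictors[p] for p in tree.predictor_names])
    else:
        x = np.asarray(predictors, dtype=float)
    leaf = route(tree, x)
    return leaf.prediction, leaf.predicted_hours, leaf.class_label


def predict_matrix(tree: RegressionTree, X: np.ndarray) -> np.ndarray:
    """Vectorised leaf predictions (t_tilde) for rows of X."""
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape[0])

    def _rec(node: TreeNode, idx: np.ndarray):
        if node.is_leaf:
            out[idx] = node.prediction
            return
        go_left = X[idx, node.predictor] <= node.threshold
        _rec(node.left, idx[go_left])
        _rec(node.right, idx[~go_left])

    _rec(tree.root, np.arange(X.shape[0]))
    return out


@dataclass
class LOOReport:
    """Held-out predictions of the leave-one-out refits."""

    records: pd.DataFrame  # one row per left-out sample
    d: float  # (1/N) * sqrt(sum of squared log-scale residuals)
    confusion: pd.DataFrame  # true time x predicted nearest time counts
    class_accuracy: dict[float, float]  # per true time point

    @property
    def n_samples(self) -> int:
        return len(self.records)


def loo_evaluate(
    table: SampleTable,
    minsplit: int = 6,
    minbucket: int = 2,
    cp: float = 0.01,
) -> LOOReport:
    """Leave-one-out refits with held-out prediction per animal.

    Each of the N_S samples is predicted by a tree fitted on the remaining
    N_S - 1.  Because refits may merge time points into different classes,
    held-out predictions are mapped to the nearest experimental time point
    on the log scale for the confusion matrix and per-time accuracy.
    """
    if table.n_samples < minsplit + 1:
        raise ValueError("too few samples for leave-one-out")
    grid = np.unique(table.times_h)
    grid_log = log_time(grid)
    rows = []
    for i in range(table.n_samples):
        sub = table.drop_rows(i)
        tree = fit_tree(sub, minsplit, minbucket, cp)
        pred_log, pred_h, label = predict_time(tree, table.X[i])
        nearest = grid[int(np.argmin(np.abs(grid_log - pred_log)))]
        rows.append(
            {
                "sample": i,
                "time_h": float(table.times_h[i]),
                "replicate": int(table.replicates[i]),
                "true_log": float(table.y[i]),
                "pred_log": pred_log,
                "pred_hours": pred_h,
                "pred_class": label,
                "pred_nearest_time_h": float(nearest),
            }
        )
    records = pd.DataFrame(rows)
    resid = records["pred_log"] - records["true_log"]
    d = float(np.sqrt((resid**2).sum()) / len(records))
    confusion = pd.crosstab(
        records["time_h"], records["pred_nearest_time_h"]
    )
    accuracy = {
        float(t): float(
            (sub["pred_nearest_time_h"] == t).mean()
        )
        for t, sub in records.groupby("time_h")
    }
    return LOOReport(records, d, confusion, accuracy)
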