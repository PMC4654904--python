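"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's code paths (and scipy shortcuts where
feasible) so that agreement is a genuine two-route check.
"""

import numpy as np


def midranks(values):
    """Average ranks (midranks for ties), built by explicit enumeration."""
    values = list(values)
    out = []
    for v in values:
        smaller = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        # ranks occupied by the tie group: smaller+1 .. smaller+equal
        out.append(smaller + (equal + 1) / 2.0)
    return np.array(out)


def pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def naive_spearman(x, y):
    return pearson(midranks(x), midranks(y))


def naive_ys3(xi, xj, weights=(0.5, 0.3, 0.2)):
    """Straight-line reimplementation of the three YS3 components."""
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    n_t = xi.shape[0]
    s_star = (naive_spearman(xi.ravel(), xj.ravel()) + 1) / 2
    mi, mj = xi.mean(axis=1), xj.mean(axis=1)
    di = [mi[t + 1] - mi[t] for t in range(n_t - 1)]
    dj = [mj[t + 1] - mj[t] for t in range(n_t - 1)]
    a_star = (naive_spearman(di, dj) + 1) / 2
    pmax_i = int(np.argmax(mi))
    pmin_i = int(np.argmin(mi))
    pmax_j = int(np.argmax(mj))
    pmin_j = int(np.argmin(mj))
    m_star = 1 - (abs(pmax_i - pmax_j) + abs(pmin_i - pmin_j)) / (2 * (n_t - 1))
    w1, w2, w3 = weights
    y = w1 * s_star + w2 * a_star + w3 * m_star
    return s_star, a_star, m_star, y, 2 * (y - 0.5)


def naive_anova_f(groups):
    """Textbook one-way ANOVA F from between/within sums of squares."""
    pooled = np.concatenate(groups)
    grand = pooled.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(pooled) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def naive_welch(a, b):
    """Welch t statistic and Welch-Satterthwaite df, from the closed forms."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def _node_sse(y):
    y = np.asarray(y, float)
    return float(((y - y.mean()) ** 2).sum())


def naive_best_split(X, y, minbucket):
    """Exhaustive (predictor, threshold) scan by direct SSE evaluation."""
    n, p = X.shape
    s_t = _node_sse(y)
    best = None
    for j in range(p):
        uniq = sorted(set(X[:, j]))
        for a, b in zip(uniq, uniq[1:]):
            thr = (a + b) / 2.0
            left = X[:, j] <= thr
            if left.sum() < minbucket or (~left).sum() < minbucket:
                continue
            red = s_t - (_node_sse(y[left]) + _node_sse(y[~left]))
            if best is None or red > best[0] + 1e-12:
                best = (red, j, thr)
    if best is None or best[0] <= 0:
        return None
    return best[1], best[2], best[0]


def naive_tree(X, y, minsplit, minbucket, cp, s_root=None):
    """Recursive-partitioning reference: nested dict of splits and leaves."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if s_root is None:
        s_root = _node_sse(y)
    node = {"n": len(y), "prediction": float(y.mean())}
    if len(y) < minsplit or _node_sse(y) == 0:
        return node
    found = naive_best_split(X, y, minbucket)
    if found is None:
        return node
    j, thr, red = found
    if s_root > 0 and red < cp * s_root:
        return node
    left = X[:, j] <= thr
    node.update(
        predictor=j,
        threshold=thr,
        left=naive_tree(X[left], y[left], minsplit, minbucket, cp, s_root),
        right=naive_tree(X[~left], y[~left], minsplit, minbucket, cp, s_root),
    )
    return node
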