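"""Bootstrap regression forests for tiny sample sizes.

Gradient-forest modelling fits one regression forest per SNP, with the
number of SNPs in the tens of thousands and the number of observations
equal to the number of sampled populations (often < 20).  General-purpose
forest implementations carry per-tree overhead that dominates at this
scale, so the per-SNP forest is implemented here as a compact
numba-compiled CART ensemble:

* bootstrap resampling per tree, ``mtry`` features tried per node;
* variance-reduction (CART) split criterion, thresholds at midpoints of
  adjacent sorted values;
* out-of-bag R² per forest;
* every accepted split is recorded as ``(feature, threshold,
  impurity_improvement)`` — the raw material for cumulative-importance
  aggregation.

The implementation is cross-validated against scikit-learn's
RandomForestRegressor in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["SmallForest", "fit_forest"]

_U64_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_U64_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_U64_MIX2 = np.uint64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _next_u64(state):
    # splitmix64: fast, seedable, platform-independent
    state[0] = state[0] + _U64_GOLDEN
    z = state[0]
    z = (z ^ (z >> np.uint64(30))) * _U64_MIX1
    z = (z ^ (z >> np.uint64(27))) * _U64_MIX2
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _randint(state, k):
    return np.int64(_next_u64(state) % np.uint64(k))


@njit(cache=True)
def _fit_forest_kernel(X, y, n_trees, mtry, min_leaf, seed):
    n, p = X.shape
    max_nodes = 2 * n + 1
    node_feature = np.full(n_trees * max_nodes, -1, dtype=np.int64)
    node_threshold = np.zeros(n_trees * max_nodes)
    node_left = np.full(n_trees * max_nodes, -1, dtype=np.int64)
    node_right = np.full(n_trees * max_nodes, -1, dtype=np.int64)
    node_value = np.zeros(n_trees * max_nodes)
    tree_offset = np.zeros(n_trees + 1, dtype=np.int64)

    max_splits = n_trees * n
    split_feature = np.empty(max_splits, dtype=np.int64)
    split_threshold = np.empty(max_splits)
    split_improvement = np.empty(max_splits)
    n_splits = 0

    state = np.empty(1, dtype=np.uint64)
    state[0] = np.uint64(seed) * np.uint64(2654435761) + np.uint64(1)

    idx = np.empty(n, dtype=np.int64)
    in_bag = np.empty(n, dtype=np.int64)
    perm = np.empty(p, dtype=np.int64)
    vals = np.empty(n)
    ys = np.empty(n)
    order = np.empty(n, dtype=np.int64)
    scratch = np.empty(n, dtype=np.int64)
    # explicit stack: (node_id, a, b)
    stack = np.empty((2 * n + 2, 3), dtype=np.int64)

    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=np.int64)

    base = 0
    for t in range(n_trees):
        tree_offset[t] = base
        for i in range(n):
            in_bag[i] = 0
        for i in range(n):
            j = _randint(state, n)
            idx[i] = j
            in_bag[j] += 1

        n_nodes = 1
        stack[0, 0] = 0
        stack[0, 1] = 0
        stack[0, 2] = n
        top = 1
        while top > 0:
            top -= 1
            node = stack[top, 0]
            a = stack[top, 1]
            b = stack[top, 2]
            m = b - a
            s = 0.0
            sq = 0.0
            for i in range(a, b):
                v = y[idx[i]]
                s += v
                sq += v * v
            mean = s / m
            ss_node = sq - s * s / m
            node_value[base + node] = mean
            if m < 2 * min_leaf or ss_node <= 1e-300:
                continue

            # sample mtry distinct features (partial Fisher-Yates)
            for j in range(p):
                perm[j] = j
            best_gain = -1.0
            best_feat = -1
            best_thr = 0.0
            best_pos = -1
            n_try = mtry if mtry < p else p
            for j in range(n_try):
                k = j + _randint(state, p - j)
                tmp = perm[j]
                perm[j] = perm[k]
                perm[k] = tmp
                f = perm[j]
                for i in range(m):
                    vals[i] = X[idx[a + i], f]
                # insertion sort of order by vals (m is tiny)
                for i in range(m):
                    order[i] = i
                for i in range(1, m):
                    o = order[i]
                    v = vals[o]
                    k2 = i - 1
                    while k2 >= 0 and vals[order[k2]] > v:
                        order[k2 + 1] = order[k2]
                        k2 -= 1
                    order[k2 + 1] = o
                for i in range(m):
                    ys[i] = y[idx[a + order[i]]]
                # scan valid split positions
                left_s = 0.0
                left_sq = 0.0
                for i in range(m - 1):
                    v = ys[i]
                    left_s += v
                    left_sq += v * v
                    nl = i + 1
                    nr = m - nl
                    if nl < min_leaf or nr < min_leaf:
                        continue
                    lo = vals[order[i]]
                    hi = vals[order[i + 1]]
                    if hi <= lo:
                        continue
                    ss_l = left_sq - left_s * left_s / nl
                    rs = s - left_s
                    ss_r = (sq - left_sq) - rs * rs / nr
                    gain = ss_node - ss_l - ss_r
                    if gain > best_gain:
                        best_gain = gain
                        best_feat = f
                        best_thr = 0.5 * (lo + hi)
                        best_pos = nl
            if best_feat < 0 or best_gain <= 1e-300:
                continue

            # partition idx[a:b] by threshold (stable)
            nl = 0
            nr = 0
            for i in range(a, b):
                if X[idx[i], best_feat] <= best_thr:
                    idx[a + nl] = idx[i]
                    nl += 1
                else:
                    scratch[nr] = idx[i]
                    nr += 1
            for i in range(nr):
                idx[a + nl + i] = scratch[i]

            left_id = n_nodes
            right_id = n_nodes + 1
            n_nodes += 2
            node_feature[base + node] = best_feat
            node_threshold[base + node] = best_thr
            node_left[base + node] = left_id
            node_right[base + node] = right_id
            split_feature[n_splits] = best_feat
            split_threshold[n_splits] = best_thr
            split_improvement[n_splits] = best_gain
            n_splits += 1

            stack[top, 0] = left_id
            stack[top, 1] = a
            stack[top, 2] = a + nl
            top += 1
            stack[top, 0] = right_id
            stack[top, 1] = a + nl
            stack[top, 2] = b
            top += 1

        # out-of-bag predictions for this tree
        for i in range(n):
            if in_bag[i] == 0:
                node = 0
                while node_feature[base + node] >= 0:
                    if X[i, node_feature[base + node]] <= node_threshold[base + node]:
                        node = node_left[base + node]
                    else:
                        node = node_right[base + node]
                oob_sum[i] += node_value[base + node]
                oob_cnt[i] += 1
        base += n_nodes
    tree_offset[n_trees] = base

    # OOB R^2 over samples that received at least one OOB prediction
    cnt = 0
    ysum = 0.0
    ymin = y[0]
    ymax = y[0]
    for i in range(n):
        if y[i] < ymin:
            ymin = y[i]
        if y[i] > ymax:
            ymax = y[i]
        if oob_cnt[i] > 0:
            cnt += 1
            ysum += y[i]
    oob_r2 = 0.0
    if cnt >= 2 and ymax > ymin:  # constant responses stay at R^2 = 0
        ymean = ysum / cnt
        ss_res = 0.0
        ss_tot = 0.0
        for i in range(n):
            if oob_cnt[i] > 0:
                pred = oob_sum[i] / oob_cnt[i]
                ss_res += (y[i] - pred) ** 2
                ss_tot += (y[i] - ymean) ** 2
        if ss_tot > 0.0:
            oob_r2 = 1.0 - ss_res / ss_tot

    return (
        node_feature[:base],
        node_threshold[:base],
        node_left[:base],
        node_right[:base],
        node_value[:base],
        tree_offset,
        split_feature[:n_splits].copy(),
        split_threshold[:n_splits].copy(),
        split_improvement[:n_splits].copy(),
        oob_r2,
    )


@njit(cache=True)
def _predict_kernel(
    X, node_feature, node_threshold, node_left, node_right, node_value, tree_offset
):
    n = X.shape[0]
    n_trees = tree_offset.shape[0] - 1
    out = np.zeros(n)
    for t in range(n_trees):
        base = tree_offset[t]
        for i in range(n):
            node = 0
            while node_feature[base + node] >= 0:
                if X[i, node_feature[base + node]] <= node_threshold[base + node]:
                    node = node_left[base + node]
                else:
                    node = node_right[base + node]
            out[i] += node_value[base + node]
    return out / n_trees


@dataclass
class SmallForest:
    """A fitted per-response regression forest.

    ``splits`` holds every accepted split as parallel arrays
    (feature index, threshold, impurity improvement in sum-of-squares
    units of the bootstrap sample).
    """

    n_features: int
    node_feature: np.ndarray
    node_threshold: np.ndarray
    node_left: np.ndarray
    node_right: np.ndarray
    node_value: np.ndarray
    tree_offset: np.ndarray
    split_feature: np.ndarray
    split_threshold: np.ndarray
    split_improvement: np.ndarray
    oob_r2: float

    @property
    def n_trees(self) -> int:
        return len(self.tree_offset) - 1

    @property
    def n_splits(self) -> int:
        return len(self.split_feature)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        return _predict_kernel(
            X,
            self.node_feature,
            self.node_threshold,
            self.node_left,
            self.node_right,
            self.node_value,
            self.tree_offset,
        )


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    mtry: int | None = None,
    min_leaf: int = 2,
    seed: int = 0,
) -> SmallForest:
    """Fit a bootstrap CART forest of ``y`` on ``X``.

    Parameters
    ----------
    X : (n, p) predictor matrix.
    y : (n,) response.
    n_trees : ensemble size.
    mtry : features tried per split; default ``ceil(p / 3)``.
    min_leaf : minimum samples per leaf.
    seed : RNG seed (any non-negative integer).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) and y (n,) with matching n")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be finite")
    p = X.shape[1]
    if mtry is None:
        mtry = int(np.ceil(p / 3))
    mtry = max(1, min(mtry, p))
    out = _fit_forest_kernel(X, y, int(n_trees), int(mtry), int(min_leaf), int(seed))
    return SmallForest(p, *out)
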