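"""Numba kernel for feature-weighted CART growth.

Implements the forest variant needed for iterative random forests: at
every split, ``mtry`` candidate features are drawn *without replacement
with probability proportional to a weight vector* (ordinary RF is the
uniform-weight special case).  Splits minimize Gini impurity of binary y;
both children must contain at least ``min_leaf`` samples.

Trees are grown iteratively over an in-place partitioned index array into
flat node arrays (feature == -1 marks a leaf, value = class-1 fraction).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _draw_candidates(weights, mtry, out):
    """Weighted sampling without replacement; zero-weight features are
    never drawn.  Returns the number of candidates written to ``out``."""
    p = weights.shape[0]
    w = weights.copy()
    total = 0.0
    for k in range(p):
        total += w[k]
    count = 0
    for _ in range(mtry):
        if total <= 1e-300:
            break
        u = np.random.random() * total
        j = -1
        c = 0.0
        for k in range(p):
            if w[k] > 0.0:
                c += w[k]
                if u < c:
                    j = k
                    break
        if j < 0:  # numerical slack: take the last positive weight
            for k in range(p - 1, -1, -1):
                if w[k] > 0.0:
                    j = k
                    break
        if j < 0:
            break
        out[count] = j
        count += 1
        total -= w[j]
        w[j] = 0.0
    return count


@njit(cache=True)
def _grow_tree(X, y, weights, mtry, min_leaf, max_depth, seed,
               feature, threshold, left, right, value, n_samples, n_pos,
               importance):
    """Grow one tree; returns the number of nodes written."""
    np.random.seed(seed)
    n, p = X.shape
    idx = np.arange(n)
    max_nodes = feature.shape[0]

    stack_node = np.empty(max_nodes, dtype=np.int64)
    stack_start = np.empty(max_nodes, dtype=np.int64)
    stack_end = np.empty(max_nodes, dtype=np.int64)
    stack_depth = np.empty(max_nodes, dtype=np.int64)

    cand = np.empty(p, dtype=np.int64)
    vals = np.empty(n, dtype=np.float64)
    scratch = np.empty(n, dtype=np.int64)

    node_count = 1
    top = 0
    stack_node[0] = 0
    stack_start[0] = 0
    stack_end[0] = n
    stack_depth[0] = 0
    top = 1

    while top > 0:
        top -= 1
        node = stack_node[top]
        start = stack_start[top]
        end = stack_end[top]
        depth = stack_depth[top]
        m = end - start

        pos = 0
        for i in range(start, end):
            pos += y[idx[i]]
        feature[node] = -1
        threshold[node] = np.nan
        left[node] = -1
        right[node] = -1
        n_samples[node] = m
        n_pos[node] = pos
        value[node] = pos / m

        if depth >= max_depth or m < 2 * min_leaf or pos == 0 or pos == m:
            continue
        if node_count + 2 > max_nodes:
            continue

        n_cand = _draw_candidates(weights, mtry, cand)
        if n_cand == 0:
            continue

        parent_gini = 1.0 - (pos / m) ** 2 - ((m - pos) / m) ** 2
        best_score = np.inf  # weighted child impurity, to minimize
        best_f = -1
        best_thr = 0.0

        for ci in range(n_cand):
            f = cand[ci]
            for i in range(m):
                vals[i] = X[idx[start + i], f]
            order = np.argsort(vals[:m], kind="mergesort")
            run_pos = 0
            prev_val = vals[order[0]]
            for i in range(m):
                run_pos += y[idx[start + order[i]]]
                if i + 1 < min_leaf or m - (i + 1) < min_leaf:
                    continue
                if i + 1 >= m:
                    break
                vi = vals[order[i]]
                vnext = vals[order[i + 1]]
                if vi == vnext:
                    continue
                nl = i + 1.0
                nr = m - nl
                pl = run_pos
                pr = pos - pl
                score = (
                    nl * (1.0 - (pl / nl) ** 2 - ((nl - pl) / nl) ** 2)
                    + nr * (1.0 - (pr / nr) ** 2 - ((nr - pr) / nr) ** 2)
                ) / m
                if score < best_score - 1e-15:
                    best_score = score
                    best_f = f
                    best_thr = 0.5 * (vi + vnext)

        if best_f < 0 or best_score >= parent_gini:
            continue

        # stable in-place partition on the chosen split
        n_left = 0
        for i in range(start, end):
            if X[idx[i], best_f] <= best_thr:
                scratch[n_left] = idx[i]
                n_left += 1
        if n_left == 0 or n_left == m:
            # midpoint threshold collapsed onto a value (float rounding)
            continue
        n_right = 0
        for i in range(start, end):
            if X[idx[i], best_f] > best_thr:
                scratch[n_left + n_right] = idx[i]
                n_right += 1
        for i in range(m):
            idx[start + i] = scratch[i]

        lid = node_count
        rid = node_count + 1
        node_count += 2
        feature[node] = best_f
        threshold[node] = best_thr
        left[node] = lid
        right[node] = rid
        importance[best_f] += (m / n) * (parent_gini - best_score)

        stack_node[top] = lid
        stack_start[top] = start
        stack_end[top] = start + n_left
        stack_depth[top] = depth + 1
        top += 1
        stack_node[top] = rid
        stack_start[top] = start + n_left
        stack_end[top] = end
        stack_depth[top] = depth + 1
        top += 1

    return node_count
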