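"""Numba kernels for growing and evaluating Gini-split decision trees.

The tree builder is CART restricted to binary classification with
non-negative feature values (occurrence counts or weighted counts):

* at every node a set of ``mtry`` distinct candidate features is drawn
  *without replacement*, each successive draw proportional to the remaining
  sampling probabilities (features with probability zero are never drawn);
* for each candidate, thresholds are midpoints between consecutive distinct
  sorted values; the split maximizing the Gini impurity decrease wins, with
  ties broken by the lower column index, then the lower threshold;
* growth stops when a node is pure, smaller than twice the minimum node
  size, or no candidate yields a positive decrease.

All randomness flows through an explicit splitmix64 state so that a tree is
a pure function of (data, probabilities, parameters, seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53

# node array layout: feature == -1 marks a leaf
LEAF = -1


@njit(cache=False)
def _next_u64(state):
    state = state + _GOLDEN
    z = state
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(cache=False)
def _next_uniform(state):
    state, z = _next_u64(state)
    return state, (z >> np.uint64(11)) * _INV53


@njit(cache=False)
def _next_below(state, n):
    """Uniform integer in [0, n) by rejection from the top 53 bits."""
    state, u = _next_uniform(state)
    return state, int(u * n)


@njit(cache=False)
def derive_substream(seed, index):
    """Deterministic per-tree RNG state from (seed, tree index)."""
    state = np.uint64(seed) * np.uint64(0x2545F4914F6CDD1D) + np.uint64(index)
    state, _ = _next_u64(state)
    return state


@njit(cache=False)
def sample_candidates_kernel(probs, cumsum, nnz, mtry, state, chosen, taken):
    """Draw ``min(mtry, nnz)`` distinct feature indices into ``chosen``.

    Rejection sampling against the fixed cumulative distribution is
    distributionally identical to successive draws proportional to the
    remaining probabilities.  ``taken`` is a scratch boolean array (reset on
    exit).  Returns (count, new_state).
    """
    p = probs.shape[0]
    k = mtry if mtry < nnz else nnz
    total = cumsum[p - 1]
    count = 0
    rejections = 0
    while count < k:
        state, u = _next_uniform(state)
        target = u * total
        idx = np.searchsorted(cumsum, target, side="right")
        if idx >= p:
            idx = p - 1
        while probs[idx] <= 0.0 and idx + 1 < p:
            idx += 1
        if probs[idx] <= 0.0 or taken[idx]:
            rejections += 1
            if rejections > 32 * (k + 8):
                # remaining mass is tiny: fall back to an O(p) renormalized draw
                rem = 0.0
                for j in range(p):
                    if probs[j] > 0.0 and not taken[j]:
                        rem += probs[j]
                state, u2 = _next_uniform(state)
                target2 = u2 * rem
                acc = 0.0
                pick = -1
                for j in range(p):
                    if probs[j] > 0.0 and not taken[j]:
                        acc += probs[j]
                        if acc >= target2:
                            pick = j
                            break
                if pick < 0:
                    for j in range(p - 1, -1, -1):
                        if probs[j] > 0.0 and not taken[j]:
                            pick = j
                            break
                chosen[count] = pick
                taken[pick] = True
                count += 1
                rejections = 0
            continue
        chosen[count] = idx
        taken[idx] = True
        count += 1
    for i in range(count):
        taken[chosen[i]] = False
    return count, state


@njit(cache=False)
def _gini(n0, n1):
    n = n0 + n1
    if n == 0:
        return 0.0
    p0 = n0 / n
    p1 = n1 / n
    return 1.0 - p0 * p0 - p1 * p1


@njit(cache=False)
def grow_tree(X, y, probs, cumsum, nnz, mtry, min_node_size, bootstrap, seed):
    """Grow one fully deterministic CART tree.

    Returns (feature, threshold, left, right, n0, n1, importance, n_nodes):
    flat node arrays (feature == -1 for leaves, children as node indices) and
    the un-normalized Gini importance accumulated over this tree's splits,
    where each split contributes
    ``(n_node/n_root)·[G_node − (n_L/n_node)·G_L − (n_R/n_node)·G_R]``.
    """
    n_samples, p = X.shape
    state = derive_substream(seed, 0)

    # bootstrap replicate (indices into X rows)
    idx_buf = np.empty(n_samples, dtype=np.int64)
    if bootstrap:
        for i in range(n_samples):
            state, r = _next_below(state, n_samples)
            idx_buf[i] = r
    else:
        for i in range(n_samples):
            idx_buf[i] = i

    max_nodes = 2 * n_samples + 1
    feature = np.full(max_nodes, LEAF, dtype=np.int64)
    threshold = np.zeros(max_nodes, dtype=np.float64)
    left = np.full(max_nodes, -1, dtype=np.int64)
    right = np.full(max_nodes, -1, dtype=np.int64)
    n0_arr = np.zeros(max_nodes, dtype=np.int64)
    n1_arr = np.zeros(max_nodes, dtype=np.int64)
    importance = np.zeros(p, dtype=np.float64)

    chosen = np.empty(p, dtype=np.int64)
    taken = np.zeros(p, dtype=np.bool_)
    vals = np.empty(n_samples, dtype=np.float64)
    labs = np.empty(n_samples, dtype=np.int64)
    order = np.empty(n_samples, dtype=np.int64)

    # stack of (node_id, start, end) over idx_buf segments
    stack_node = np.empty(max_nodes, dtype=np.int64)
    stack_lo = np.empty(max_nodes, dtype=np.int64)
    stack_hi = np.empty(max_nodes, dtype=np.int64)
    top = 0
    n_nodes = 1
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n_samples
    top = 1

    while top > 0:
        top -= 1
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        n_node = hi - lo

        c1 = 0
        for i in range(lo, hi):
            c1 += y[idx_buf[i]]
        c0 = n_node - c1
        n0_arr[node] = c0
        n1_arr[node] = c1

        if c0 == 0 or c1 == 0 or n_node < 2 * min_node_size:
            continue

        k, state = sample_candidates_kernel(probs, cumsum, nnz, mtry, state, chosen, taken)

        g_node = _gini(c0, c1)
        best_score = 0.0  # nL*GL + nR*GR deficit form: maximize n_node*G - (…)
        best_f = -1
        best_thr = 0.0
        base = n_node * g_node
        for ci in range(k):
            f = chosen[ci]
            # gather nonzero values; zeros form an implicit leading block
            nz = 0
            z1 = 0  # positives among zero-valued samples
            nzero = 0
            for i in range(lo, hi):
                v = X[idx_buf[i], f]
                if v != 0.0:
                    vals[nz] = v
                    labs[nz] = y[idx_buf[i]]
                    nz += 1
                else:
                    nzero += 1
                    z1 += y[idx_buf[i]]
            if nz == 0:
                continue
            ord_nz = np.argsort(vals[:nz], kind="mergesort")
            # scan thresholds: first between the zero block and smallest nonzero
            # (if a zero block exists), then between consecutive distinct nonzeros
            ln0 = nzero - z1
            ln1 = z1
            prev_v = 0.0
            if nzero == 0:
                first = ord_nz[0]
                prev_v = vals[first]
                ln0 += 1 - labs[first]
                ln1 += labs[first]
                start_j = 1
            else:
                start_j = 0
            for j in range(start_j, nz):
                o = ord_nz[j]
                v = vals[o]
                if v != prev_v:
                    nL = ln0 + ln1
                    nR = n_node - nL
                    if nL >= min_node_size and nR >= min_node_size:
                        gl = _gini(ln0, ln1)
                        r0 = c0 - ln0
                        r1 = c1 - ln1
                        gr = _gini(r0, r1)
                        score = base - (nL * gl + nR * gr)
                        thr = 0.5 * (prev_v + v)
                        if score > 1e-12 and (
                            score > best_score
                            or (
                                score == best_score
                                and (f < best_f or (f == best_f and thr < best_thr))
                            )
                        ):
                            best_score = score
                            best_f = f
                            best_thr = thr
                    prev_v = v
                ln0 += 1 - labs[o]
                ln1 += labs[o]

        if best_f < 0:
            continue  # no candidate gives a positive decrease → leaf

        # partition idx_buf[lo:hi] in place: <= threshold to the front
        mid = lo
        i = lo
        j = hi - 1
        while i <= j:
            if X[idx_buf[i], best_f] <= best_thr:
                i += 1
            else:
                tmp = idx_buf[i]
                idx_buf[i] = idx_buf[j]
                idx_buf[j] = tmp
                j -= 1
        mid = i

        feature[node] = best_f
        threshold[node] = best_thr
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        left[node] = lid
        right[node] = rid
        # importance contribution, relative to the bootstrap root size
        importance[best_f] += best_score / n_samples

        stack_node[top] = lid
        stack_lo[top] = lo
        stack_hi[top] = mid
        top += 1
        stack_node[top] = rid
        stack_lo[top] = mid
        stack_hi[top] = hi
        top += 1

    return (
        feature[:n_nodes],
        threshold[:n_nodes],
        left[:n_nodes],
        right[:n_nodes],
        n0_arr[:n_nodes],
        n1_arr[:n_nodes],
        importance,
        n_nodes,
    )


@njit(cache=False)
def tree_votes(feature, threshold, left, right, n0, n1, X):
    """Route samples to leaves; vote 1 iff the leaf's positive count wins (tie → 0)."""
    n = X.shape[0]
    votes = np.zeros(n, dtype=np.int64)
    for i in range(n):
        node = 0
        while feature[node] != LEAF:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        if n1[node] > n0[node]:
            votes[i] = 1
    return votes
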