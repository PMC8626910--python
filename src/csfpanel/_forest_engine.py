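"""Compiled random-forest engine with per-tree out-of-bag permutation importance.

The importance statistic needed here -- for every tree, the drop in
out-of-bag (OOB) accuracy when one feature's OOB values are permuted,
accumulated into a per-feature mean and standard deviation across trees --
requires access to each tree's bootstrap sample.  General-purpose forest
implementations expose only aggregate importances, so the forest is built
directly: fully grown CART trees (Gini impurity, ``mtry`` features tried
per split, bootstrap of n samples with replacement, minimum node size 1),
matching the classic classification random forest.

Bootstrap duplicates are handled as integer sample weights on the unique
in-bag samples, which halves the sorting work per node without changing
the fitted trees.

All routines are deterministic given ``seed``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forest_oob_run"]


@njit(cache=False)
def _sort_by_value(vals, ys, m):
    """Sort (vals, ys) pairs by vals: insertion sort for node-sized arrays,
    argsort above the crossover where NumPy's introsort wins."""
    if m < 64:
        for i in range(1, m):
            v = vals[i]
            yv = ys[i]
            j = i - 1
            while j >= 0 and vals[j] > v:
                vals[j + 1] = vals[j]
                ys[j + 1] = ys[j]
                j -= 1
            vals[j + 1] = v
            ys[j + 1] = yv
    else:
        order = np.argsort(vals[:m])
        tmpv = vals[:m].copy()
        tmpy = ys[:m].copy()
        for i in range(m):
            vals[i] = tmpv[order[i]]
            ys[i] = tmpy[order[i]]


@njit(cache=False)
def forest_oob_run(X, y, n_trees, mtry, seed):
    """Fit a bootstrap forest and accumulate OOB permutation importance.

    Parameters
    ----------
    X : (n, p) float64, C-contiguous
    y : (n,) int64 with values in {0, 1}
    n_trees, mtry : forest size and features tried per split
    seed : RNG seed (one stream drives bootstraps, feature draws and
        permutations)

    Returns
    -------
    mean_d : (p,) mean over trees of the OOB accuracy decrease
    sd_d : (p,) population standard deviation of the per-tree decreases
    vote1 : (p,) -- actually (n,) summed OOB votes for class 1
    n_oob : (n,) number of trees for which each sample was OOB
    """
    np.random.seed(seed)
    n, p = X.shape
    max_nodes = 4 * n + 8
    d_sum = np.zeros(p)
    d_sq = np.zeros(p)
    vote1 = np.zeros(n)
    n_oob = np.zeros(n)
    feature = np.empty(max_nodes, np.int64)
    threshold = np.empty(max_nodes, np.float64)
    left = np.empty(max_nodes, np.int64)
    right = np.empty(max_nodes, np.int64)
    leaf_val = np.empty(max_nodes, np.int64)
    cnt = np.empty(n, np.int64)
    work = np.empty(n, np.int64)
    stack_lo = np.empty(2 * n + 64, np.int64)
    stack_hi = np.empty(2 * n + 64, np.int64)
    stack_node = np.empty(2 * n + 64, np.int64)
    perm = np.empty(p, np.int64)
    vals = np.empty(n)
    packed = np.empty(n, np.int64)
    # presorted per-feature sample order: large nodes gather their members
    # by one linear scan of this order instead of sorting
    gorder = np.empty((p, n), np.int64)
    for j in range(p):
        gorder[j] = np.argsort(X[:, j])
    stamp = np.zeros(n, np.int64)
    stamp_ctr = 0

    for _t in range(n_trees):
        # bootstrap as per-sample multiplicities
        for i in range(n):
            cnt[i] = 0
        for i in range(n):
            cnt[np.random.randint(0, n)] += 1
        nu = 0
        for i in range(n):
            if cnt[i] > 0:
                work[nu] = i
                nu += 1
        m = n - nu
        if m == 0:  # degenerate bootstrap; no OOB information
            continue
        oob = np.empty(m, np.int64)
        k = 0
        for i in range(n):
            if cnt[i] == 0:
                oob[k] = i
                k += 1

        # grow the tree (iterative depth-first)
        n_nodes = 1
        stack_lo[0] = 0
        stack_hi[0] = nu
        stack_node[0] = 0
        sp = 1
        while sp > 0:
            sp -= 1
            lo = stack_lo[sp]
            hi = stack_hi[sp]
            node = stack_node[sp]
            wtot = 0
            w1 = 0
            for ii in range(lo, hi):
                c = cnt[work[ii]]
                wtot += c
                w1 += c * y[work[ii]]
            if w1 == 0 or w1 == wtot or hi - lo < 2:
                feature[node] = -1
                leaf_val[node] = 1 if 2 * w1 > wtot else 0
                continue
            mm = hi - lo
            for j in range(p):
                perm[j] = j
            best_imp = 1e-12
            best_f = -1
            best_thr = 0.0
            parent = 1.0 - ((w1 / wtot) ** 2 + ((wtot - w1) / wtot) ** 2)
            use_scan = mm * 5 > n  # filter-scan beats sorting on big nodes
            if use_scan:
                stamp_ctr += 1
                for ii in range(lo, hi):
                    stamp[work[ii]] = stamp_ctr
            for kk in range(mtry):
                rr = kk + np.random.randint(0, p - kk)
                tmp = perm[kk]
                perm[kk] = perm[rr]
                perm[rr] = tmp
                f = perm[kk]
                # packed companion: cnt | (cnt*y << 20)
                if use_scan:
                    k2 = 0
                    for q in range(n):
                        s = gorder[f, q]
                        if stamp[s] == stamp_ctr:
                            vals[k2] = X[s, f]
                            packed[k2] = cnt[s] | (cnt[s] * y[s] << 20)
                            k2 += 1
                else:
                    for ii in range(mm):
                        s = work[lo + ii]
                        vals[ii] = X[s, f]
                        packed[ii] = cnt[s] | (cnt[s] * y[s] << 20)
                    _sort_by_value(vals, packed, mm)
                wl = 0
                w1l = 0
                for ii in range(mm - 1):
                    wl += packed[ii] & 0xFFFFF
                    w1l += packed[ii] >> 20
                    v0 = vals[ii]
                    v1 = vals[ii + 1]
                    if v1 == v0:
                        continue
                    wr = wtot - wl
                    w1r = w1 - w1l
                    p1l = w1l / wl
                    p1r = w1r / wr
                    gl = 1.0 - (p1l * p1l + (1.0 - p1l) * (1.0 - p1l))
                    gr = 1.0 - (p1r * p1r + (1.0 - p1r) * (1.0 - p1r))
                    imp = parent - (wl * gl + wr * gr) / wtot
                    if imp > best_imp:
                        best_imp = imp
                        best_f = f
                        best_thr = 0.5 * (v0 + v1)
            if best_f < 0:
                feature[node] = -1
                leaf_val[node] = 1 if 2 * w1 > wtot else 0
                continue
            i2 = lo
            jj = hi - 1
            while i2 <= jj:
                if X[work[i2], best_f] <= best_thr:
                    i2 += 1
                else:
                    tmp2 = work[i2]
                    work[i2] = work[jj]
                    work[jj] = tmp2
                    jj -= 1
            mid = i2
            if mid == lo or mid == hi:
                feature[node] = -1
                leaf_val[node] = 1 if 2 * w1 > wtot else 0
                continue
            feature[node] = best_f
            threshold[node] = best_thr
            left[node] = n_nodes
            right[node] = n_nodes + 1
            n_nodes += 2
            stack_lo[sp] = lo
            stack_hi[sp] = mid
            stack_node[sp] = n_nodes - 2
            sp += 1
            stack_lo[sp] = mid
            stack_hi[sp] = hi
            stack_node[sp] = n_nodes - 1
            sp += 1

        # baseline OOB predictions; record which features lie on each
        # row's decision path (a permuted feature can only change a row's
        # prediction if the baseline traversal tests that feature)
        pred = np.empty(m, np.int64)
        path_feat = np.empty(m * 64, np.int64)  # flattened per-row paths
        path_start = np.empty(m + 1, np.int64)
        pf = 0
        for ii in range(m):
            path_start[ii] = pf
            nd = 0
            while feature[nd] >= 0:
                ff = feature[nd]
                seen = False
                for q in range(path_start[ii], pf):
                    if path_feat[q] == ff:
                        seen = True
                        break
                if not seen and pf < m * 64:
                    path_feat[pf] = ff
                    pf += 1
                if X[oob[ii], ff] <= threshold[nd]:
                    nd = left[nd]
                else:
                    nd = right[nd]
            pred[ii] = leaf_val[nd]
        path_start[m] = pf
        acc0 = 0.0
        for ii in range(m):
            if pred[ii] == y[oob[ii]]:
                acc0 += 1.0
            vote1[oob[ii]] += pred[ii]
            n_oob[oob[ii]] += 1.0
        acc0 /= m

        # invert: feature -> rows whose path tests it (CSR layout)
        used = np.zeros(p, np.bool_)
        fcount = np.zeros(p, np.int64)
        for q in range(pf):
            fcount[path_feat[q]] += 1
            used[path_feat[q]] = True
        fstart = np.empty(p + 1, np.int64)
        fstart[0] = 0
        for f in range(p):
            fstart[f + 1] = fstart[f] + fcount[f]
        frows = np.empty(pf, np.int64)
        fpos = fstart[:p].copy()
        for ii in range(m):
            for q in range(path_start[ii], path_start[ii + 1]):
                f = path_feat[q]
                frows[fpos[f]] = ii
                fpos[f] += 1

        # permutation importance: permute the full OOB column, but only
        # re-predict rows whose baseline path tests the feature
        pv = np.empty(m)
        for f in range(p):
            if not used[f]:
                continue
            for ii in range(m):
                pv[ii] = X[oob[ii], f]
            for ii in range(m - 1, 0, -1):
                rr = np.random.randint(0, ii + 1)
                tv = pv[ii]
                pv[ii] = pv[rr]
                pv[rr] = tv
            delta = 0.0  # change in number of correct predictions
            for q in range(fstart[f], fstart[f + 1]):
                ii = frows[q]
                nd = 0
                while feature[nd] >= 0:
                    ff = feature[nd]
                    v = pv[ii] if ff == f else X[oob[ii], ff]
                    if v <= threshold[nd]:
                        nd = left[nd]
                    else:
                        nd = right[nd]
                newp = leaf_val[nd]
                if newp != pred[ii]:
                    if newp == y[oob[ii]]:
                        delta += 1.0
                    else:
                        delta -= 1.0
            d = -delta / m  # accuracy decrease
            d_sum[f] += d
            d_sq[f] += d * d

    mean_d = d_sum / n_trees
    var_d = d_sq / n_trees - mean_d ** 2
    sd_d = np.sqrt(np.maximum(var_d, 0.0))
    return mean_d, sd_d, vote1, n_oob
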