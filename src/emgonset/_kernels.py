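"""Numba kernels for two-sample change-detection statistics.

Every statistic compares ``x[0:k]`` against ``x[k:t]`` and is standardized
(null mean/SD or likelihood-ratio form), so that a single Monte-Carlo
calibrated threshold per (model, t) applies.

Model codes (shared across the package):
0 Student, 1 Bartlett, 2 GLR, 3 GLR_Exponential,
4 GLR_Exponential_FiniteCorrection, 5 MannWhitney, 6 Mood,
7 KolmogorovSmirnov, 8 CramerVonMises.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STUDENT, BARTLETT, GLR, GLR_EXP, GLR_EXP_FC, MW, MOOD, KS, CVM = range(9)

#: name -> integer model code used by the kernels
MODEL_CODES = {
    "Student": STUDENT,
    "Bartlett": BARTLETT,
    "GLR": GLR,
    "GLR_Exponential": GLR_EXP,
    "GLR_Exponential_FiniteCorrection": GLR_EXP_FC,
    "MannWhitney": MW,
    "Mood": MOOD,
    "KolmogorovSmirnov": KS,
    "CramerVonMises": CVM,
}

_TINY = 1e-300


@njit(cache=True)
def _param_stat(cumx, cumxx, t, k, model):
    """Standardized parametric statistic for split k of x[0:t] (from prefix
    sums). Returns 0.0 for degenerate inputs."""
    l = t - k
    s1 = cumx[k]
    s2 = cumx[t] - cumx[k]
    q1 = cumxx[k]
    q2 = cumxx[t] - cumxx[k]
    if model == STUDENT:
        w1 = q1 - s1 * s1 / k
        w2 = q2 - s2 * s2 / l
        sp2 = (w1 + w2) / (t - 2)
        if sp2 <= _TINY:
            return 0.0
        return abs(s1 / k - s2 / l) / np.sqrt(sp2 * (1.0 / k + 1.0 / l))
    elif model == BARTLETT:
        if k < 2 or l < 2:
            return 0.0
        w1 = q1 - s1 * s1 / k
        w2 = q2 - s2 * s2 / l
        v1 = w1 / (k - 1)
        v2 = w2 / (l - 1)
        vp = (w1 + w2) / (t - 2)
        if v1 <= _TINY or v2 <= _TINY or vp <= _TINY:
            return 0.0
        m = (t - 2) * np.log(vp) - (k - 1) * np.log(v1) - (l - 1) * np.log(v2)
        c = 1.0 + (1.0 / (k - 1) + 1.0 / (l - 1) - 1.0 / (t - 2)) / 3.0
        return m / c
    elif model == GLR:
        w1 = q1 - s1 * s1 / k
        w2 = q2 - s2 * s2 / l
        w0 = cumxx[t] - cumx[t] * cumx[t] / t
        if w1 <= _TINY or w2 <= _TINY or w0 <= _TINY:
            return 0.0
        return t * np.log(w0 / t) - k * np.log(w1 / k) - l * np.log(w2 / l)
    else:  # exponential GLR variants; data must be positive
        s0 = cumx[t]
        if s1 <= _TINY or s2 <= _TINY:
            return 0.0
        g = 2.0 * (k * np.log(k / s1) + l * np.log(l / s2) - t * np.log(t / s0))
        if model == GLR_EXP_FC:
            g /= 1.0 + (1.0 / k + 1.0 / l - 1.0 / t) / 6.0
        return g


@njit(cache=True)
def _param_max(cumx, cumxx, t, kmin, kmax, model):
    best = -1.0
    bestk = -1
    for k in range(kmin, kmax + 1):
        s = _param_stat(cumx, cumxx, t, k, model)
        if s > best:
            best = s
            bestk = k
    return best, bestk


@njit(cache=True)
def _rank_max(r, t, kmin, kmax, model):
    """Max standardized rank statistic over splits; r[i] = rank (1..t) of
    x[i] among x[0:t]."""
    best = -1.0
    bestk = -1
    center = (t + 1) / 2.0
    acc = 0.0
    for i in range(t):
        if model == MW:
            acc += r[i]
        else:
            d = r[i] - center
            acc += d * d
        k = i + 1
        if k < kmin or k > kmax:
            continue
        l = t - k
        if model == MW:
            mu = k * (t + 1) / 2.0
            sd = np.sqrt(k * l * (t + 1) / 12.0)
        else:
            mu = k * (t * t - 1) / 12.0
            sd = np.sqrt(k * l * (t + 1.0) * (t * t - 4.0) / 180.0)
        if sd <= _TINY:
            continue
        z = abs(acc - mu) / sd
        if z > best:
            best = z
            bestk = k
    return best, bestk


@njit(cache=True)
def _ranks_inplace(x, t, r):
    """Naive O(t^2) ranks of x[0:t] into r (1-based; ties broken by order)."""
    for i in range(t):
        cnt = 1
        for j in range(t):
            if x[j] < x[i] or (x[j] == x[i] and j < i):
                cnt += 1
        r[i] = cnt


# ---------------------------------------------------------------------------
# Fenwick (binary indexed tree) helpers for the Cramer-von Mises scan.

@njit(cache=True)
def _fen_add(tree, i, v):
    while i < tree.shape[0]:
        tree[i] += v
        i += i & (-i)


@njit(cache=True)
def _fen_sum(tree, i):
    s = 0.0
    while i > 0:
        s += tree[i]
        i -= i & (-i)
    return s


@njit(cache=True)
def _cvm_scan(order_time, t, kmin, kmax):
    """Max standardized two-sample CvM statistic over splits k in
    [kmin, kmax] for a series of length t.

    ``order_time[m]`` is the time index of the m-th smallest value
    (m = 0..t-1). Runs in O(t log t) by growing the first sample one
    element at a time and maintaining sum moments of the prefix counts
    c_m = #{first-sample values <= z_m} with Fenwick trees.
    """
    # rank (1-based) of each time index
    rr = np.empty(t, dtype=np.int64)
    for m in range(t):
        rr[order_time[m]] = m + 1
    cnt_tree = np.zeros(t + 1)
    rsum_tree = np.zeros(t + 1)
    s1 = 0.0  # sum_m c_m
    s2 = 0.0  # sum_m c_m^2
    sm = 0.0  # sum_m c_m * m
    q = t * (t + 1.0) * (2.0 * t + 1.0) / 6.0
    best = -1.0
    bestk = -1
    for i in range(t):
        r_i = rr[i]
        # moments update using the state BEFORE inserting element i
        c_lt = _fen_sum(cnt_tree, r_i - 1)
        c_ge = i - c_lt
        sr_ge = (_fen_sum(rsum_tree, t) - _fen_sum(rsum_tree, r_i - 1))
        s_ge = (t - r_i + 1) * c_lt + (t + 1.0) * c_ge - sr_ge
        ntail = t - r_i + 1.0
        s2 += 2.0 * s_ge + ntail
        s1 += ntail
        sm += (t * (t + 1.0) - (r_i - 1.0) * r_i) / 2.0
        _fen_add(cnt_tree, r_i, 1.0)
        _fen_add(rsum_tree, r_i, float(r_i))
        k = i + 1
        if k < kmin or k > kmax:
            continue
        l = t - k
        ssq = t * t * s2 - 2.0 * t * k * sm + k * k * q
        tstat = ssq / (k * l * float(t) * t)
        mu = (t + 1.0) / (6.0 * t)
        var = ((t + 1.0) / (45.0 * t * t)) * (
            (4.0 * k * l * t - 3.0 * (k * k + l * l) - 2.0 * k * l) / (4.0 * k * l)
        )
        if var <= _TINY:
            continue
        z = (tstat - mu) / np.sqrt(var)
        if z > best:
            best = z
            bestk = k
    return best, bestk


@njit(cache=True)
def _ks_scan(xs, order_time, t, kmin, kmax):
    """Max standardized two-sample KS statistic over splits, O(t^2).

    ``xs`` are the sorted values; the CDF difference is only evaluated at
    the end of tie groups, so identical empirical distributions give D=0.
    """
    member = np.zeros(t, dtype=np.uint8)  # sorted-order membership of sample A
    # rank position of each time index
    pos = np.empty(t, dtype=np.int64)
    for m in range(t):
        pos[order_time[m]] = m
    best = -1.0
    bestk = -1
    for i in range(t):
        member[pos[i]] = 1
        k = i + 1
        if k < kmin or k > kmax:
            continue
        l = t - k
        c = 0
        dmax = 0.0
        for m in range(t):
            c += member[m]
            if m + 1 < t and xs[m + 1] == xs[m]:
                continue
            d = abs(c / float(k) - (m + 1 - c) / float(l))
            if d > dmax:
                dmax = d
        z = np.sqrt(k * l / float(t)) * dmax
        if z > best:
            best = z
            bestk = k
    return best, bestk


# ---------------------------------------------------------------------------
# batch and sequential drivers

@njit(cache=True)
def batch_scan(x, model, startup):
    """(max standardized statistic, earliest argmax split) over splits
    [startup, n-startup] of the whole series."""
    n = x.shape[0]
    kmin = startup
    kmax = n - startup
    if kmax < kmin:
        return -1.0, -1
    if model <= GLR_EXP_FC:
        cumx = np.zeros(n + 1)
        cumxx = np.zeros(n + 1)
        for i in range(n):
            cumx[i + 1] = cumx[i] + x[i]
            cumxx[i + 1] = cumxx[i] + x[i] * x[i]
        return _param_max(cumx, cumxx, n, kmin, kmax, model)
    order = np.argsort(x, kind="mergesort")
    if model == KS:
        return _ks_scan(x[order], order, n, kmin, kmax)
    if model == CVM:
        return _cvm_scan(order, n, kmin, kmax)
    r = np.empty(n, dtype=np.float64)
    for m in range(n):
        r[order[m]] = m + 1
    return _rank_max(r, n, kmin, kmax, model)


@njit(cache=True)
def seq_scan(x, model, startup, h, tmax, record):
    """Sequential monitoring of x with per-t thresholds h (length >= n).

    At each t >= 2*startup computes D_t = max split statistic on x[0:t];
    signals when D_t > h[t-1]. Returns (signal_t, changepoint_estimate,
    trajectory) where signal_t = -1 if the stream ends unsignalled. If
    ``record`` is nonzero the trajectory array holds D_t at index t-1
    (NaN before monitoring starts); otherwise it is empty.
    """
    n = min(x.shape[0], tmax)
    traj = np.full(n if record else 0, np.nan)
    t0 = 2 * startup
    if model <= GLR_EXP_FC:
        cumx = np.zeros(n + 1)
        cumxx = np.zeros(n + 1)
        for i in range(n):
            cumx[i + 1] = cumx[i] + x[i]
            cumxx[i + 1] = cumxx[i] + x[i] * x[i]
        for t in range(t0, n + 1):
            d, kk = _param_max(cumx, cumxx, t, startup, t - startup, model)
            if record:
                traj[t - 1] = d
            if d > h[t - 1]:
                return t, kk, traj
        return -1, -1, traj
    if model == CVM:
        for t in range(t0, n + 1):
            order = np.argsort(x[:t], kind="mergesort")
            d, kk = _cvm_scan(order, t, startup, t - startup)
            if record:
                traj[t - 1] = d
            if d > h[t - 1]:
                return t, kk, traj
        return -1, -1, traj
    # rank statistics with incremental rank maintenance
    r = np.zeros(n, dtype=np.float64)
    nt = 0
    for t in range(1, n + 1):
        xv = x[t - 1]
        rk = 1.0
        for j in range(t - 1):
            if x[j] > xv:
                r[j] += 1.0
            else:
                rk += 1.0
        r[t - 1] = rk
        nt = t
        if t < t0:
            continue
        d, kk = _rank_max(r, t, startup, t - startup, model)
        if record:
            traj[t - 1] = d
        if d > h[t - 1]:
            return t, kk, traj
    return -1, -1, traj
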