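"""Compiled inner loops for the rank scores and pairwise U-statistics.

Everything here operates on plain float64 arrays already reduced to
per-subject residual quantities; parameter handling, artificial-censoring
offsets and normalization conventions live in the public modules.  The
functions are deliberately scalar-loop style so numba can compile them:
the solvers evaluate these scores tens of thousands of times per fit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rank_score", "rank_influence", "unp_score", "w3_rows"]


@njit(cache=True)
def _risk_means(e, Z):
    """Risk-set sizes and covariate sums over {j : e_j >= e_i} (ties included).

    Returns (riskN, riskZ) with riskN[i] = #{j: e_j >= e_i} and
    riskZ[i] = sum of Z_j over that set.
    """
    n, k = Z.shape
    order = np.argsort(-e)  # descending residuals
    riskN = np.empty(n)
    riskZ = np.empty((n, k))
    cum = np.zeros(k)
    a = 0
    while a < n:
        b = a
        val = e[order[a]]
        while b < n and e[order[b]] == val:
            for m in range(k):
                cum[m] += Z[order[b], m]
            b += 1
        for t in range(a, b):
            i = order[t]
            riskN[i] = b
            for m in range(k):
                riskZ[i, m] = cum[m]
        a = b
    return riskN, riskZ


@njit(cache=True)
def rank_score(e, d, Z):
    """Unweighted (log-rank form) rank score n^{-1/2} Σ_i d_i (Z_i - Zbar(e_i)).

    Zbar(t) is the covariate average over the at-risk set {j: e_j >= t}.
    """
    n, k = Z.shape
    riskN, riskZ = _risk_means(e, Z)
    out = np.zeros(k)
    for i in range(n):
        if d[i] != 0.0:
            for m in range(k):
                out[m] += d[i] * (Z[i, m] - riskZ[i, m] / riskN[i])
    return out / np.sqrt(n)


@njit(cache=True)
def rank_influence(e, d, Z):
    """Per-subject influence terms of the rank score (martingale decomposition).

    Row i is  d_i (Z_i - Zbar(e_i)) - Σ_l d_l I{e_i >= e_l} (Z_i - Zbar(e_l)) / N_l,
    with N_l the at-risk count at e_l.  Rows sum to n^{1/2} times the score.
    """
    n, k = Z.shape
    riskN, riskZ = _risk_means(e, Z)
    # cumulative hazard-type sums over l with e_l <= e_i, ties included
    order = np.argsort(e)  # ascending
    A = np.empty(n)            # Σ d_l / N_l
    B = np.empty((n, k))       # Σ d_l Zbar(e_l) / N_l
    cumA = 0.0
    cumB = np.zeros(k)
    a = 0
    while a < n:
        b = a
        val = e[order[a]]
        while b < n and e[order[b]] == val:
            l = order[b]
            if d[l] != 0.0:
                cumA += d[l] / riskN[l]
                for m in range(k):
                    cumB[m] += d[l] * riskZ[l, m] / (riskN[l] * riskN[l])
            b += 1
        for t in range(a, b):
            i = order[t]
            A[i] = cumA
            for m in range(k):
                B[i, m] = cumB[m]
        a = b
    W = np.empty((n, k))
    for i in range(n):
        for m in range(k):
            W[i, m] = d[i] * (Z[i, m] - riskZ[i, m] / riskN[i]) - (Z[i, m] * A[i] - B[i, m])
    return W


@njit(cache=True)
def unp_score(e, b, v, delta, Z):
    """Pairwise (Gehan-type) artificial-censoring U-statistic score.

    Inputs per subject: e_i = y_x_i - Z_i'theta (event residual),
    b_i = y_d_i - Z_i'eta (censoring-bound residual before offset),
    v_i = max(0, Z_i'(theta - eta)), delta_i the event indicator.
    The pair offset is g_ij = max(v_i, v_j); the pair transform censors
    e at b - g_ij.  Returns 2 n^{1/2} / (n(n-1)) Σ_{i<j} (Z_i - Z_j) φ_ij.
    """
    n, k = Z.shape
    acc = np.zeros(k)
    for i in range(n):
        ei = e[i]
        bi = b[i]
        vi = v[i]
        di = delta[i]
        for j in range(i + 1, n):
            g = vi if vi >= v[j] else v[j]
            ci = bi - g
            cj = b[j] - g
            if di != 0.0 and ei <= ci:
                dsi = True
                xi = ei
            else:
                dsi = False
                xi = ci
            if delta[j] != 0.0 and e[j] <= cj:
                dsj = True
                xj = e[j]
            else:
                dsj = False
                xj = cj
            phi = 0
            if dsi and xi <= xj:
                phi += 1
            if dsj and xj <= xi:
                phi -= 1
            if phi != 0:
                for m in range(k):
                    acc[m] += phi * (Z[i, m] - Z[j, m])
    return acc * (2.0 * np.sqrt(n) / (n * (n - 1.0)))


@njit(cache=True)
def w3_rows(e, b, v, delta, Z):
    """Per-subject influence rows of the pairwise score.

    Row i is (2/(n-1)) Σ_{j != i} (Z_i - Z_j) φ_ij; by antisymmetry of φ the
    (i, j) pair contributes the same vector to rows i and j.
    """
    n, k = Z.shape
    W = np.zeros((n, k))
    for i in range(n):
        ei = e[i]
        bi = b[i]
        vi = v[i]
        di = delta[i]
        for j in range(i + 1, n):
            g = vi if vi >= v[j] else v[j]
            ci = bi - g
            cj = b[j] - g
            if di != 0.0 and ei <= ci:
                dsi = True
                xi = ei
            else:
                dsi = False
                xi = ci
            if delta[j] != 0.0 and e[j] <= cj:
                dsj = True
                xj = e[j]
            else:
                dsj = False
                xj = cj
            phi = 0
            if dsi and xi <= xj:
                phi += 1
            if dsj and xj <= xi:
                phi -= 1
            if phi != 0:
                for m in range(k):
                    c = phi * (Z[i, m] - Z[j, m])
                    W[i, m] += c
                    W[j, m] += c
    return W * (2.0 / (n - 1.0))
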