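"""Numba kernels for photon-by-photon HMM recursions.

The hidden chain evolves at every clock tick; photons are observed only at
their arrival ticks, so the transition operator between consecutive
photons separated by ``dt`` ticks is ``A**dt``.  The kernels below consume
per-unique-``dt`` precomputed operator tables:

* ``P[u]``   = A**dt_u                        (forward/backward/Viterbi)
* ``H[u]``   = the tick-resolved transition-count tensor such that the
               expected number of i->j tick transitions inside an interval
               with boundary posteriors u (left) and v (right) is
               sum_pq u_p v_q H[u, p, i, j, q], up to the per-interval
               normalization sum_ij C_ij = dt.

``H`` folds in the eigendecomposition divided-difference identity
sum_{d=0}^{dt-1} lam_k^d lam_l^{dt-1-d} = (lam_k^dt - lam_l^dt)/(lam_k - lam_l)
and the factor A_ij, making the E-step exact (and hence EM monotone) while
costing O(K^4) per photon regardless of ``dt``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=True)
def forward_ll(colors, didx, ptr, P, B, pi):
    """Total scaled-forward log-likelihood over all bursts."""
    K = B.shape[0]
    nb = ptr.size - 1
    ll = 0.0
    for b in range(nb):
        s, e = ptr[b], ptr[b + 1]
        n = e - s
        alpha = np.empty(K)
        for i in range(K):
            alpha[i] = pi[i] * B[i, colors[s]]
        c = alpha.sum()
        if c <= 0.0:
            c = _TINY
        ll += np.log(c)
        alpha /= c
        nxt = np.empty(K)
        for t in range(1, n):
            Pt = P[didx[s + t]]
            col = colors[s + t]
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[i] * Pt[i, j]
                nxt[j] = acc * B[j, col]
            c = nxt.sum()
            if c <= 0.0:
                c = _TINY
            ll += np.log(c)
            for j in range(K):
                alpha[j] = nxt[j] / c
    return ll


@njit(cache=True)
def em_pass(colors, didx, deltas, ptr, P, B, pi, H):
    """One exact E-step; returns (ll, B_num, pi_num, tick_transition_counts)."""
    K = B.shape[0]
    C = B.shape[1]
    nb = ptr.size - 1
    Bsum = np.zeros((K, C))
    pisum = np.zeros(K)
    trans = np.zeros((K, K))
    ll = 0.0
    for b in range(nb):
        s, e = ptr[b], ptr[b + 1]
        n = e - s
        alpha = np.empty((n, K))
        beta = np.empty((n, K))
        c = np.empty(n)
        # forward
        tot = 0.0
        for i in range(K):
            alpha[0, i] = pi[i] * B[i, colors[s]]
            tot += alpha[0, i]
        if tot <= 0.0:
            tot = _TINY
        c[0] = tot
        for i in range(K):
            alpha[0, i] /= tot
        for t in range(1, n):
            Pt = P[didx[s + t]]
            col = colors[s + t]
            tot = 0.0
            for j in range(K):
                acc = 0.0
                for i in range(K):
                    acc += alpha[t - 1, i] * Pt[i, j]
                alpha[t, j] = acc * B[j, col]
                tot += alpha[t, j]
            if tot <= 0.0:
                tot = _TINY
            c[t] = tot
            for j in range(K):
                alpha[t, j] /= tot
        for t in range(n):
            ll += np.log(c[t])
        # backward (scaled)
        for i in range(K):
            beta[n - 1, i] = 1.0
        for t in range(n - 2, -1, -1):
            Pt = P[didx[s + t + 1]]
            col = colors[s + t + 1]
            for i in range(K):
                acc = 0.0
                for j in range(K):
                    acc += Pt[i, j] * B[j, col] * beta[t + 1, j]
                beta[t, i] = acc / c[t + 1]
        # state posteriors -> emission / initial-state accumulators
        g = np.empty(K)
        for t in range(n):
            gs = 0.0
            for i in range(K):
                g[i] = alpha[t, i] * beta[t, i]
                gs += g[i]
            if gs <= 0.0:
                gs = _TINY
            col = colors[s + t]
            for i in range(K):
                g[i] /= gs
                Bsum[i, col] += g[i]
            if t == 0:
                for i in range(K):
                    pisum[i] += g[i]
        # expected tick-level transition counts per interval
        v = np.empty(K)
        Cij = np.empty((K, K))
        for t in range(1, n):
            Ht = H[didx[s + t]]
            col = colors[s + t]
            for j in range(K):
                v[j] = B[j, col] * beta[t, j]
            tot = 0.0
            for i in range(K):
                for j in range(K):
                    acc = 0.0
                    for p in range(K):
                        up = alpha[t - 1, p]
                        if up == 0.0:
                            continue
                        for q in range(K):
                            acc += up * v[q] * Ht[p, i, j, q]
                    if acc < 0.0:
                        acc = 0.0
                    Cij[i, j] = acc
                    tot += acc
            if tot > 0.0:
                scale = deltas[s + t] / tot
                for i in range(K):
                    for j in range(K):
                        trans[i, j] += Cij[i, j] * scale
    return ll, Bsum, pisum, trans


@njit(cache=True)
def viterbi_path(colors, didx, ptr, logP, logB, logpi):
    """Most probable state sequence per burst (flat output array)."""
    K = logB.shape[0]
    nb = ptr.size - 1
    states = np.empty(colors.size, dtype=np.int64)
    for b in range(nb):
        s, e = ptr[b], ptr[b + 1]
        n = e - s
        dp = np.empty((n, K))
        psi = np.empty((n, K), dtype=np.int64)
        for i in range(K):
            dp[0, i] = logpi[i] + logB[i, colors[s]]
            psi[0, i] = 0
        for t in range(1, n):
            Pt = logP[didx[s + t]]
            col = colors[s + t]
            for j in range(K):
                best = -1e308
                arg = 0
                for i in range(K):
                    v = dp[t - 1, i] + Pt[i, j]
                    if v > best:
                        best = v
                        arg = i
                dp[t, j] = best + logB[j, col]
                psi[t, j] = arg
        best = -1e308
        arg = 0
        for i in range(K):
            if dp[n - 1, i] > best:
                best = dp[n - 1, i]
                arg = i
        states[e - 1] = arg
        for t in range(n - 2, -1, -1):
            arg = psi[t + 1, arg]
            states[s + t] = arg
    return states
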