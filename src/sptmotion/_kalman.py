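"""Numba kernels: exact per-axis forward recursions for the motion models.

Each motion model is a linear-Gaussian state-space model per coordinate
axis, so the marginal likelihood of the observed positions (conditional on
the first observation) is computed exactly in O(n) by a Kalman-style
forward pass. All factors are accumulated in log space; there is nothing
to renormalize because the recursion carries (mean, variance) rather than
unnormalized densities.

Kernels operate on flat arrays of concatenated tracks (``offsets`` gives
track boundaries) so that population-level objectives cost a single call.
A non-finite return value signals a degenerate model (zero predictive
variance) for that track.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG2PI = 1.8378770664093453

__all__ = [
    "brownian_loglik_flat",
    "confined_loglik_flat",
    "directed_loglik_flat",
    "directed_smooth_velocity",
]


@njit(cache=True)
def _brownian_axis(x, d2, s2):
    n = x.shape[0] - 1
    m = x[0]
    P = d2 + s2
    ll = 0.0
    for i in range(1, n + 1):
        S = P + s2
        if S <= 0.0:
            return np.nan
        r = x[i] - m
        ll += -0.5 * (LOG2PI + np.log(S) + r * r / S)
        K = P / S
        m += K * r
        P -= K * P
        if i < n:
            P += d2
    return ll


@njit(cache=True)
def _confined_axis(x, d2, s2, l, q2, q02):
    # latent state (z_i, h_i); obs c_{i+1} = (1-l) z_i + l h_i + N(0, s2)
    # transition z' = (1-l) z + l h + N(0, d2); h' = h + N(0, q2)
    n = x.shape[0] - 1
    h1 = 1.0 - l
    h2 = l
    m1 = x[0]
    m2 = x[0]
    P11 = d2 + s2
    P12 = 0.0
    P22 = q02
    ll = 0.0
    for i in range(1, n + 1):
        yhat = h1 * m1 + h2 * m2
        PH1 = P11 * h1 + P12 * h2
        PH2 = P12 * h1 + P22 * h2
        S = h1 * PH1 + h2 * PH2 + s2
        if S <= 0.0:
            return np.nan
        r = x[i] - yhat
        ll += -0.5 * (LOG2PI + np.log(S) + r * r / S)
        k1 = PH1 / S
        k2 = PH2 / S
        m1 += k1 * r
        m2 += k2 * r
        P11 -= k1 * PH1
        P12 -= k1 * PH2
        P22 -= k2 * PH2
        if i < n:
            nm1 = h1 * m1 + h2 * m2
            A11 = h1 * h1 * P11 + 2.0 * h1 * h2 * P12 + h2 * h2 * P22 + d2
            A12 = h1 * P12 + h2 * P22
            A22 = P22 + q2
            m1 = nm1
            P11 = A11
            P12 = A12
            P22 = A22
    return ll


@njit(cache=True)
def _directed_axis(x, d2, s2, v2, q2):
    # latent state (r_i, w_i); prior r_0 ~ N(c_0, s2), w_0 ~ N(0, v2)
    # transition r' = r + w + N(0, d2); w' = w + N(0, q2)
    # obs c_i = r_i + N(0, s2) for i >= 1
    n = x.shape[0] - 1
    m1 = x[0]
    m2 = 0.0
    P11 = s2
    P12 = 0.0
    P22 = v2
    ll = 0.0
    for i in range(1, n + 1):
        # predict
        nm1 = m1 + m2
        A11 = P11 + 2.0 * P12 + P22 + d2
        A12 = P12 + P22
        A22 = P22 + q2
        # update
        S = A11 + s2
        if S <= 0.0:
            return np.nan
        r = x[i] - nm1
        ll += -0.5 * (LOG2PI + np.log(S) + r * r / S)
        k1 = A11 / S
        k2 = A12 / S
        m1 = nm1 + k1 * r
        m2 = m2 + k2 * r
        P11 = A11 - k1 * A11
        P12 = A12 - k1 * A12
        P22 = A22 - k2 * A12
    return ll


@njit(cache=True)
def brownian_loglik_flat(pos, offsets, d, sigma):
    d2 = d * d
    s2 = sigma * sigma
    nt = offsets.shape[0] - 1
    out = np.empty(nt)
    for t in range(nt):
        ll = 0.0
        for a in range(pos.shape[1]):
            ll += _brownian_axis(pos[offsets[t] : offsets[t + 1], a], d2, s2)
        out[t] = ll
    return out


@njit(cache=True)
def confined_loglik_flat(pos, offsets, d, sigma, l, q):
    d2 = d * d
    s2 = sigma * sigma
    q2 = q * q
    nt = offsets.shape[0] - 1
    out = np.empty(nt)
    if l < 1e-6:
        # rho = d / sqrt(2 l) diverges; the h-chain decouples (obs weight l -> 0)
        for t in range(nt):
            ll = 0.0
            for a in range(pos.shape[1]):
                ll += _brownian_axis(pos[offsets[t] : offsets[t + 1], a], d2, s2)
            out[t] = ll
        return out
    q02 = d2 / (2.0 * l) + s2
    for t in range(nt):
        ll = 0.0
        for a in range(pos.shape[1]):
            ll += _confined_axis(pos[offsets[t] : offsets[t + 1], a], d2, s2, l, q2, q02)
        out[t] = ll
    return out


@njit(cache=True)
def directed_loglik_flat(pos, offsets, d, sigma, v, q):
    d2 = d * d
    s2 = sigma * sigma
    v2 = v * v
    q2 = q * q
    nt = offsets.shape[0] - 1
    out = np.empty(nt)
    for t in range(nt):
        ll = 0.0
        for a in range(pos.shape[1]):
            ll += _directed_axis(pos[offsets[t] : offsets[t + 1], a], d2, s2, v2, q2)
        out[t] = ll
    return out


@njit(cache=True)
def directed_smooth_velocity(pos, d, sigma, v, q):
    """RTS-smoothed posterior mean velocities w_0..w_{n-1} per axis.

    Returns an (n, dim) array of posterior mean velocity components under
    the directed model with the given parameters.
    """
    n = pos.shape[0] - 1
    dim = pos.shape[1]
    d2 = d * d
    s2 = sigma * sigma
    v2 = v * v
    q2 = q * q
    out = np.empty((n, dim))
    eps = 1e-300
    for a in range(dim):
        x = pos[:, a]
        # filtered and predicted moments for states 0..n
        mf = np.empty((n + 1, 2))
        Pf = np.empty((n + 1, 3))  # (P11, P12, P22)
        mp = np.empty((n + 1, 2))
        Pp = np.empty((n + 1, 3))
        mf[0, 0] = x[0]
        mf[0, 1] = 0.0
        Pf[0, 0] = s2
        Pf[0, 1] = 0.0
        Pf[0, 2] = v2
        for i in range(1, n + 1):
            P11, P12, P22 = Pf[i - 1, 0], Pf[i - 1, 1], Pf[i - 1, 2]
            nm1 = mf[i - 1, 0] + mf[i - 1, 1]
            nm2 = mf[i - 1, 1]
            A11 = P11 + 2.0 * P12 + P22 + d2
            A12 = P12 + P22
            A22 = P22 + q2
            mp[i, 0] = nm1
            mp[i, 1] = nm2
            Pp[i, 0] = A11
            Pp[i, 1] = A12
            Pp[i, 2] = A22
            S = A11 + s2
            if S <= 0.0:
                S = eps
            r = x[i] - nm1
            k1 = A11 / S
            k2 = A12 / S
            mf[i, 0] = nm1 + k1 * r
            mf[i, 1] = nm2 + k2 * r
            Pf[i, 0] = A11 - k1 * A11
            Pf[i, 1] = A12 - k1 * A12
            Pf[i, 2] = A22 - k2 * A12
        # backward pass
        ms1 = mf[n, 0]
        ms2 = mf[n, 1]
        for i in range(n - 1, -1, -1):
            P11, P12, P22 = Pf[i, 0], Pf[i, 1], Pf[i, 2]
            # C = Pf[i] @ F.T with F = [[1,1],[0,1]]
            C11 = P11 + P12
            C12 = P12
            C21 = P12 + P22
            C22 = P22
            A11, A12, A22 = Pp[i + 1, 0], Pp[i + 1, 1], Pp[i + 1, 2]
            det = A11 * A22 - A12 * A12
            if det < eps:
                det = eps
            i11 = A22 / det
            i12 = -A12 / det
            i22 = A11 / det
            G11 = C11 * i11 + C12 * i12
            G12 = C11 * i12 + C12 * i22
            G21 = C21 * i11 + C22 * i12
            G22 = C21 * i12 + C22 * i22
            r1 = ms1 - mp[i + 1, 0]
            r2 = ms2 - mp[i + 1, 1]
            ms1 = mf[i, 0] + G11 * r1 + G12 * r2
            ms2 = mf[i, 1] + G21 * r1 + G22 * r2
            out[i, a] = ms2
    return out
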