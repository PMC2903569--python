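"""Jit-compiled multi-start least squares for the decreasing logistic curve.

The model is E_fit(M) = a / (1 + exp(b * (M - c))) with box constraints
a in [0, 200], b in [0, 50], c in [-50, 150]; b >= 0 enforces the
decreasing direction (high methylation -> low expression).

Each fit runs a projected Levenberg-Marquardt from eleven deterministic
starts: nine canonical ones (c at the 25/50/75th percentiles of M crossed
with b in {0.05, 0.2, 1}, a at max(E)) plus the two best points of a coarse
(b, c) grid scan in which a is profiled out analytically (for fixed b, c
the model is linear in a).  The grid seeds rescue fits whose optimum lies
far from the canonical starts, which matters for the many near-null
refits of the permutation test.  The kernel is compiled once per process
(cached on disk) so that tens of thousands of permutation refits stay
cheap.
"""

from __future__ import annotations

import numpy as np
from numba import njit

A_MAX = 200.0
B_MIN = 1e-8  # strictly positive floor: keeps the permutation statistic
              # tie-free (an exact b=0 collapse maps many null fits onto the
              # identical constant curve and R value, which would pile
              # permutation p-values onto exactly 1)
B_MAX = 50.0
C_LO = -50.0
C_HI = 150.0

# grid of decay rates and curve midpoints for the seeding scan
B_GRID = np.geomspace(0.002, 20.0, 13)
C_GRID = np.linspace(C_LO, C_HI, 13)

N_ITER = 100
TOL = 1e-14


@njit(cache=True)
def _sig(z):
    if z >= 0.0:
        e = np.exp(-z)
        return e / (1.0 + e)
    e = np.exp(z)
    return 1.0 / (1.0 + e)


@njit(cache=True)
def _sse_at(M, E, a, b, c):
    s = 0.0
    for j in range(M.size):
        r = a * _sig(b * (M[j] - c)) - E[j]
        s += r * r
    return s


@njit(cache=True)
def _lm_one(M, E, a, b, c, n_iter, tol):
    """Projected Levenberg-Marquardt from one start; returns (a, b, c, sse)."""
    n = M.size
    lam = 1e-3
    sse = _sse_at(M, E, a, b, c)
    stall = 0
    for _ in range(n_iter):
        h00 = h01 = h02 = h11 = h12 = h22 = 0.0
        g0 = g1 = g2 = 0.0
        for j in range(n):
            s = _sig(b * (M[j] - c))
            w = s * (1.0 - s)
            f = a * s - E[j]
            J0 = s
            J1 = -a * (M[j] - c) * w
            J2 = a * b * w
            g0 += J0 * f
            g1 += J1 * f
            g2 += J2 * f
            h00 += J0 * J0
            h01 += J0 * J1
            h02 += J0 * J2
            h11 += J1 * J1
            h12 += J1 * J2
            h22 += J2 * J2
        d0 = h00 + lam + 1e-12
        d1 = h11 + lam + 1e-12
        d2 = h22 + lam + 1e-12
        det = (d0 * (d1 * d2 - h12 * h12)
               - h01 * (h01 * d2 - h12 * h02)
               + h02 * (h01 * h12 - d1 * h02))
        if det == 0.0 or not np.isfinite(det):
            lam = min(lam * 6.0, 1e10)
            stall += 1
            if stall >= 8:
                break
            continue
        x0 = (g0 * (d1 * d2 - h12 * h12)
              - h01 * (g1 * d2 - h12 * g2)
              + h02 * (g1 * h12 - d1 * g2)) / det
        x1 = (d0 * (g1 * d2 - g2 * h12)
              - g0 * (h01 * d2 - h12 * h02)
              + h02 * (h01 * g2 - g1 * h02)) / det
        x2 = (d0 * (d1 * g2 - h12 * g1)
              - h01 * (h01 * g2 - g1 * h02)
              + g0 * (h01 * h12 - d1 * h02)) / det
        an = min(max(a - x0, 0.0), A_MAX)
        bn = min(max(b - x1, B_MIN), B_MAX)
        cn = min(max(c - x2, C_LO), C_HI)
        ssen = _sse_at(M, E, an, bn, cn)
        if ssen <= sse:
            if sse - ssen <= tol * (sse + 1e-30):
                stall += 1
            else:
                stall = 0
            a = an
            b = bn
            c = cn
            sse = ssen
            lam = max(lam * 0.25, 1e-10)
        else:
            lam = min(lam * 6.0, 1e10)
            stall += 1
        if stall >= 8:
            break
    return a, b, c, sse


@njit(cache=True)
def _fit_one(M, E, bgrid, cgrid, n_iter, tol):
    n = M.size
    Ms = np.sort(M)
    q1 = Ms[int(0.25 * (n - 1))]
    q2 = Ms[int(0.50 * (n - 1))]
    q3 = Ms[int(0.75 * (n - 1))]
    amax = 0.0
    for j in range(n):
        if E[j] > amax:
            amax = E[j]
    if amax > A_MAX:
        amax = A_MAX
    best_sse = 1e300
    ba = bb = bc = 0.0
    for b0 in (0.05, 0.2, 1.0):
        for c0 in (q1, q2, q3):
            a, b, c, sse = _lm_one(M, E, amax, b0, c0, n_iter, tol)
            if sse < best_sse:
                best_sse = sse
                ba, bb, bc = a, b, c
    # coarse (b, c) scan with analytically optimal a; refine the two best
    g1_sse = 1e300
    g1a = g1b = g1c = 0.0
    g2_sse = 1e300
    g2a = g2b = g2c = 0.0
    for bi in range(bgrid.size):
        for ci in range(cgrid.size):
            b0 = bgrid[bi]
            c0 = cgrid[ci]
            num = 0.0
            den = 1e-30
            for j in range(n):
                s = _sig(b0 * (M[j] - c0))
                num += E[j] * s
                den += s * s
            a0 = min(max(num / den, 0.0), A_MAX)
            sse = _sse_at(M, E, a0, b0, c0)
            if sse < g1_sse:
                g2_sse, g2a, g2b, g2c = g1_sse, g1a, g1b, g1c
                g1_sse, g1a, g1b, g1c = sse, a0, b0, c0
            elif sse < g2_sse:
                g2_sse, g2a, g2b, g2c = sse, a0, b0, c0
    for (a0, b0, c0) in ((g1a, g1b, g1c), (g2a, g2b, g2c)):
        a, b, c, sse = _lm_one(M, E, a0, b0, c0, n_iter, tol)
        if sse < best_sse:
            best_sse = sse
            ba, bb, bc = a, b, c
    return ba, bb, bc, best_sse


@njit(cache=True)
def fit_batch(Ms, Es, bgrid, cgrid, n_iter, tol):
    """Fit every row pair (Ms[i], Es[i]); returns (B, 4) of a, b, c, sse."""
    B = Ms.shape[0]
    out = np.empty((B, 4))
    for i in range(B):
        a, b, c, sse = _fit_one(Ms[i], Es[i], bgrid, cgrid, n_iter, tol)
        out[i, 0] = a
        out[i, 1] = b
        out[i, 2] = c
        out[i, 3] = sse
    return out


def fit_pairs(Ms: np.ndarray, Es: np.ndarray) -> np.ndarray:
    """Batched sigmoid fits on aligned (B, n) arrays without NaNs."""
    Ms = np.ascontiguousarray(Ms, dtype=np.float64)
    Es = np.ascontiguousarray(Es, dtype=np.float64)
    return fit_batch(Ms, Es, B_GRID, C_GRID, N_ITER, TOL)


def sigmoid(M: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """The fitted curve, evaluated stably in plain numpy."""
    z = np.clip(b * (np.asarray(M, dtype=float) - c), -500.0, 500.0)
    return a / (1.0 + np.exp(z))
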