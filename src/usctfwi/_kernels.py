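"""Numba kernels for the 2D constant-density acoustic solver.

All wavefields live on grids padded by two cells of permanent zeros so
the 4th-order Laplacian can read neighbours without branching; the zero
frame makes the discrete Laplacian exactly symmetric (zero-Dirichlet
extension), which the adjoint-state machinery relies on.

Scheme (interior cells only):

    p[n+1] = sigma * (2 p[n] - sigma p[n-1] + b (A p[n] + s[n]))

with b = dt^2 / m, m = slowness^2, A the 4th-order Laplacian and sigma
the multiplicative sponge profile. The receiver operator samples the
wavefield bilinearly in space and linearly in time onto the output grid;
``run_adjoint`` implements the exact transpose of the whole forward map
and accumulates the slowness-squared gradient using the identity

    sigma (A p[n] + s[n]) = (p[n+1] - 2 sigma p[n] + sigma^2 p[n-1]) / b

so no extra stencil pass is needed. Kernels are dtype-generic; the
inversion path runs float32, verification tests run float64.
"""

import numpy as np
from numba import njit

_C0 = -30.0 / 12.0
_C1 = 16.0 / 12.0
_C2 = -1.0 / 12.0


@njit(cache=True, fastmath=True)
def step_forward(p, pm, out, sigma, b, inv_h2):
    """One explicit step: out = sigma*(2p - sigma*pm + b*lap(p))."""
    ny, nx = p.shape
    for i in range(2, ny - 2):
        for j in range(2, nx - 2):
            lap = inv_h2 * (
                2.0 * _C0 * p[i, j]
                + _C1 * (p[i - 1, j] + p[i + 1, j] + p[i, j - 1] + p[i, j + 1])
                + _C2 * (p[i - 2, j] + p[i + 2, j] + p[i, j - 2] + p[i, j + 2])
            )
            s = sigma[i, j]
            out[i, j] = s * (2.0 * p[i, j] - s * pm[i, j] + b[i, j] * lap)


@njit(cache=True, fastmath=True)
def laplacian(p, out, inv_h2):
    """out = A p on the interior (frame untouched)."""
    ny, nx = p.shape
    for i in range(2, ny - 2):
        for j in range(2, nx - 2):
            out[i, j] = inv_h2 * (
                2.0 * _C0 * p[i, j]
                + _C1 * (p[i - 1, j] + p[i + 1, j] + p[i, j - 1] + p[i, j + 1])
                + _C2 * (p[i - 2, j] + p[i + 2, j] + p[i, j - 2] + p[i, j + 2])
            )


@njit(cache=True, fastmath=True)
def run_forward(
    sigma, b, inv_h2, wsamp,
    siy, six, swt,           # source cells (4,) and weights (4,)
    riy, rix, rwt,           # receiver cells (4, nrec) and weights
    ostart, alpha,           # output bookkeeping (see WaveSolver)
    n_steps, out, W, illum, store,
):
    """Full forward time loop with on-the-fly receiver sampling.

    ``ostart`` has length n_steps + 2: outputs with frame0 == n occupy
    ``range(ostart[n], ostart[n+1])``. With ``store`` true, frame n of
    ``W`` receives sigma * (A p[n-1] + s[n-1]) — the source-side field
    the adjoint gradient and Born modelling correlate against — and
    ``illum`` accumulates sum_n p^2.
    """
    ny, nx = sigma.shape
    nrec = riy.shape[1]
    p = np.zeros((ny, nx), dtype=sigma.dtype)
    pm = np.zeros((ny, nx), dtype=sigma.dtype)
    nxt = np.zeros((ny, nx), dtype=sigma.dtype)
    vals = np.empty(nrec, dtype=sigma.dtype)
    for n in range(n_steps + 1):
        if n > 0:
            if store:
                for i in range(2, ny - 2):
                    for j in range(2, nx - 2):
                        lap = inv_h2 * (
                            2.0 * _C0 * p[i, j]
                            + _C1 * (p[i - 1, j] + p[i + 1, j]
                                     + p[i, j - 1] + p[i, j + 1])
                            + _C2 * (p[i - 2, j] + p[i + 2, j]
                                     + p[i, j - 2] + p[i, j + 2])
                        )
                        s = sigma[i, j]
                        w_sl = s * lap
                        W[n, i, j] = w_sl
                        nxt[i, j] = s * (2.0 * p[i, j] - s * pm[i, j]) + b[i, j] * w_sl
            else:
                step_forward(p, pm, nxt, sigma, b, inv_h2)
            for k in range(4):
                i, j = siy[k], six[k]
                src = sigma[i, j] * wsamp[n - 1] * swt[k]
                nxt[i, j] += b[i, j] * src
                if store:
                    W[n, i, j] += src
            tmp = pm
            pm = p
            p = nxt
            nxt = tmp
        if store:
            for i in range(2, ny - 2):
                for j in range(2, nx - 2):
                    illum[i, j] += p[i, j] * p[i, j]
        lo1, hi1 = ostart[n], ostart[n + 1]
        lo2, hi2 = (ostart[n - 1], ostart[n]) if n >= 1 else (0, 0)
        if hi1 > lo1 or hi2 > lo2:
            for r in range(nrec):
                v = 0.0
                for k in range(4):
                    v += rwt[k, r] * p[riy[k, r], rix[k, r]]
                vals[r] = v
            for jo in range(lo1, hi1):
                w = 1.0 - alpha[jo]
                for r in range(nrec):
                    out[jo, r] += w * vals[r]
            for jo in range(lo2, hi2):
                w = alpha[jo]
                for r in range(nrec):
                    out[jo, r] += w * vals[r]


@njit(cache=True, fastmath=True)
def run_adjoint(
    sigma, b, inv_h2, wsamp,
    siy, six, swt,
    riy, rix, rwt,
    ostart, alpha,
    n_steps, residual, W, acc,
):
    """Reverse-time transpose of ``run_forward`` with gradient
    accumulation: acc = sum_n zeta[n] * W[n], where W[n] is the stored
    source-side field sigma * (A p[n-1] + s[n-1])."""
    ny, nx = sigma.shape
    nrec = riy.shape[1]
    z1 = np.zeros((ny, nx), dtype=sigma.dtype)  # zeta[n+1]
    z2 = np.zeros((ny, nx), dtype=sigma.dtype)  # zeta[n+2]
    zn = np.zeros((ny, nx), dtype=sigma.dtype)
    u = np.zeros((ny, nx), dtype=sigma.dtype)
    vals = np.empty(nrec, dtype=sigma.dtype)
    for n in range(n_steps, -1, -1):
        # transpose step: zn = 2*sigma*z1 + lap(sigma*b*z1) - sigma^2*z2
        for i in range(2, ny - 2):
            for j in range(2, nx - 2):
                u[i, j] = sigma[i, j] * b[i, j] * z1[i, j]
        for i in range(2, ny - 2):
            for j in range(2, nx - 2):
                lap = inv_h2 * (
                    2.0 * _C0 * u[i, j]
                    + _C1 * (u[i - 1, j] + u[i + 1, j] + u[i, j - 1] + u[i, j + 1])
                    + _C2 * (u[i - 2, j] + u[i + 2, j] + u[i, j - 2] + u[i, j + 2])
                )
                s = sigma[i, j]
                zn[i, j] = 2.0 * s * z1[i, j] + lap - s * s * z2[i, j]
        # R^T residual at frame n
        lo1, hi1 = ostart[n], ostart[n + 1]
        lo2, hi2 = (ostart[n - 1], ostart[n]) if n >= 1 else (0, 0)
        if hi1 > lo1 or hi2 > lo2:
            for r in range(nrec):
                vals[r] = 0.0
            for jo in range(lo1, hi1):
                w = 1.0 - alpha[jo]
                for r in range(nrec):
                    vals[r] += w * residual[jo, r]
            for jo in range(lo2, hi2):
                w = alpha[jo]
                for r in range(nrec):
                    vals[r] += w * residual[jo, r]
            for r in range(nrec):
                for k in range(4):
                    zn[riy[k, r], rix[k, r]] += rwt[k, r] * vals[r]
        if n >= 1:
            for i in range(2, ny - 2):
                for j in range(2, nx - 2):
                    acc[i, j] += zn[i, j] * W[n, i, j]
        tmp = z2
        z2 = z1
        z1 = zn
        zn = tmp
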