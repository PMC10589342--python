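"""Compiled inner loops for the noisy density-matrix simulator.

The pure-numpy implementation in :mod:`quanvnet.noise` is the reference;
these numba kernels compute the identical update (gate conjugation followed
by the single-qubit channel on every acted qubit) with explicit bit-indexed
loops over the density matrix stored as separate real and imaginary parts
(plain float arrays vectorize far better than complex ones), which is what
makes a 9-qubit, 300-gate noisy run cheap enough to repeat hundreds of
times in the mitigation studies.

All three channels act identically on the 2x2 block structure of the acted
qubit (a = (0,0) block, d = (1,1), o = off-diagonal blocks):

    a' = caa * a + cad * d,   d' = cda * a + cdd * d,   o' = co * o,

with real coefficients supplied by the caller, so one kernel serves every
channel.  Index pairs differing in one qubit's bit (mask ``m``) are
enumerated branch-free as ``r in [base, base+m)`` with partner ``r + m``
for ``base`` stepping by ``2m``.

Gate encoding: kind 0 = H, 1 = T, 2 = CNOT.
Qubit masks follow the package convention (qubit 0 = most significant bit).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_COS45 = float(np.cos(np.pi / 4.0))  # = sin(pi/4)


@njit(cache=True, fastmath=True)
def _h_rows(rr, ri, m, inv):
    dim = rr.shape[0]
    for base in range(0, dim, 2 * m):
        for r in range(base, base + m):
            r1 = r + m
            for c in range(dim):
                ar, ai = rr[r, c], ri[r, c]
                br, bi = rr[r1, c], ri[r1, c]
                rr[r, c] = (ar + br) * inv
                ri[r, c] = (ai + bi) * inv
                rr[r1, c] = (ar - br) * inv
                ri[r1, c] = (ai - bi) * inv


@njit(cache=True, fastmath=True)
def _h_cols(rr, ri, m, inv):
    dim = rr.shape[0]
    for r in range(dim):
        for base in range(0, dim, 2 * m):
            for c in range(base, base + m):
                c1 = c + m
                ar, ai = rr[r, c], ri[r, c]
                br, bi = rr[r, c1], ri[r, c1]
                rr[r, c] = (ar + br) * inv
                ri[r, c] = (ai + bi) * inv
                rr[r, c1] = (ar - br) * inv
                ri[r, c1] = (ai - bi) * inv


@njit(cache=True, fastmath=True)
def _t_rows(rr, ri, m, cos45):
    # row bit 1 picks up e^{+i pi/4}: (x + iy) -> (x - y, x + y) / sqrt(2)
    dim = rr.shape[0]
    for base in range(0, dim, 2 * m):
        for r in range(base, base + m):
            r1 = r + m
            for c in range(dim):
                x, y = rr[r1, c], ri[r1, c]
                rr[r1, c] = (x - y) * cos45
                ri[r1, c] = (x + y) * cos45


@njit(cache=True, fastmath=True)
def _t_cols(rr, ri, m, cos45):
    # col bit 1 picks up e^{-i pi/4}: (x + iy) -> (x + y, y - x) / sqrt(2)
    dim = rr.shape[0]
    for r in range(dim):
        for base in range(0, dim, 2 * m):
            for c in range(base, base + m):
                c1 = c + m
                x, y = rr[r, c1], ri[r, c1]
                rr[r, c1] = (x + y) * cos45
                ri[r, c1] = (y - x) * cos45


@njit(cache=True, fastmath=True)
def _cnot_rows(rr, ri, cm, tm):
    dim = rr.shape[0]
    for r in range(dim):
        if (r & cm) != 0 and (r & tm) == 0:
            r1 = r | tm
            for c in range(dim):
                tr, ti = rr[r, c], ri[r, c]
                rr[r, c], ri[r, c] = rr[r1, c], ri[r1, c]
                rr[r1, c], ri[r1, c] = tr, ti


@njit(cache=True, fastmath=True)
def _cnot_cols(rr, ri, cm, tm):
    dim = rr.shape[0]
    for r in range(dim):
        for c in range(dim):
            if (c & cm) != 0 and (c & tm) == 0:
                c1 = c | tm
                tr, ti = rr[r, c], ri[r, c]
                rr[r, c], ri[r, c] = rr[r, c1], ri[r, c1]
                rr[r, c1], ri[r, c1] = tr, ti


@njit(cache=True, fastmath=True)
def _channel_blocks(rr, ri, m, caa, cad, cda, cdd, co):
    dim = rr.shape[0]
    for rb in range(0, dim, 2 * m):
        for r in range(rb, rb + m):
            r1 = r + m
            for cb in range(0, dim, 2 * m):
                for c in range(cb, cb + m):
                    c1 = c + m
                    axr, axi = rr[r, c], ri[r, c]
                    dxr, dxi = rr[r1, c1], ri[r1, c1]
                    rr[r, c] = caa * axr + cad * dxr
                    ri[r, c] = caa * axi + cad * dxi
                    rr[r1, c1] = cda * axr + cdd * dxr
                    ri[r1, c1] = cda * axi + cdd * dxi
                    rr[r, c1] *= co
                    ri[r, c1] *= co
                    rr[r1, c] *= co
                    ri[r1, c] *= co


@njit(cache=True, fastmath=True)
def _diag_fix(rr, ri, m, u, v, w, x):
    """Diagonal-block mix a' = u*a + v*d, d' = w*a + x*d (off blocks untouched)."""
    dim = rr.shape[0]
    for rb in range(0, dim, 2 * m):
        for r in range(rb, rb + m):
            r1 = r + m
            for cb in range(0, dim, 2 * m):
                for c in range(cb, cb + m):
                    c1 = c + m
                    axr, axi = rr[r, c], ri[r, c]
                    dxr, dxi = rr[r1, c1], ri[r1, c1]
                    rr[r, c] = u * axr + v * dxr
                    ri[r, c] = u * axi + v * dxi
                    rr[r1, c1] = w * axr + x * dxr
                    ri[r1, c1] = w * axi + x * dxi


@njit(cache=True, fastmath=True)
def noisy_run_kernel(rr, ri, kinds, qa, qb, q, caa, cad, cda, cdd, co, fast):
    """Evolve rho = rr + i*ri in place through the encoded gate list.

    In the ``fast`` regime (co bounded away from zero) each channel is
    applied up to the global scalar ``co``: a scalar commutes with every
    later gate and channel, so the caller folds the accumulated co^K into
    the final trace normalization instead of sweeping the matrix once more
    per channel application.
    """
    inv = rr.dtype.type(_INV_SQRT2)
    cos45 = rr.dtype.type(_COS45)
    if fast:
        u = caa / co
        v = cad / co
        w = cda / co
        x = cdd / co
    else:
        u = v = w = x = rr.dtype.type(0.0)
    for g in range(kinds.shape[0]):
        k = kinds[g]
        ma = 1 << (q - 1 - qa[g])
        if k == 0:
            _h_rows(rr, ri, ma, inv)
            _h_cols(rr, ri, ma, inv)
        elif k == 1:
            _t_rows(rr, ri, ma, cos45)
            _t_cols(rr, ri, ma, cos45)
        else:
            mb = 1 << (q - 1 - qb[g])
            _cnot_rows(rr, ri, ma, mb)
            _cnot_cols(rr, ri, ma, mb)
            if fast:
                _diag_fix(rr, ri, mb, u, v, w, x)
            else:
                _channel_blocks(rr, ri, mb, caa, cad, cda, cdd, co)
        if fast:
            _diag_fix(rr, ri, ma, u, v, w, x)
        else:
            _channel_blocks(rr, ri, ma, caa, cad, cda, cdd, co)
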