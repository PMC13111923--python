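"""Numba kernels for the hot path: the temporal convolution and batch norm.

The temporal convolution of the first block touches a [batch, F1, C, T]
tensor; everything downstream of the spatial convolution is small, so only
these kernels need to be fast.  All kernels are dtype-generic: they run in
float32 for training and float64 for relevance propagation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["tconv_fwd", "tconv_gradw", "tconv_gradx", "bn_stats", "bn_apply",
           "bn_bwd_sums", "bn_bwd_dx"]


@njit(cache=True, fastmath=True)
def tconv_fwd(xpad, w, T):
    """Cross-correlate xpad [B,C,L] with kernels w [F,K] -> [B,F,C,T]."""
    B, C, L = xpad.shape
    F, K = w.shape
    y = np.zeros((B, F, C, T), xpad.dtype)
    for b in range(B):
        for c in range(C):
            xr = xpad[b, c]
            for f in range(F):
                wf = w[f]
                yr = y[b, f, c]
                for k in range(K):
                    wk = wf[k]
                    for t in range(T):
                        yr[t] += wk * xr[t + k]
    return y


@njit(cache=True, fastmath=True)
def tconv_gradw(xpad, gy):
    """d loss / d w for tconv_fwd: [F, K]."""
    B, F, C, T = gy.shape
    K = xpad.shape[2] - T + 1
    gw = np.zeros((F, K), xpad.dtype)
    for b in range(B):
        for c in range(C):
            xr = xpad[b, c]
            for f in range(F):
                gr = gy[b, f, c]
                for k in range(K):
                    acc = 0.0
                    for t in range(T):
                        acc += gr[t] * xr[t + k]
                    gw[f, k] += acc
    return gw


@njit(cache=True, fastmath=True)
def tconv_gradx(w, gy, L):
    """d loss / d xpad for tconv_fwd: [B, C, L]."""
    B, F, C, T = gy.shape
    K = w.shape[1]
    gx = np.zeros((B, C, L), gy.dtype)
    for b in range(B):
        for c in range(C):
            gxr = gx[b, c]
            for f in range(F):
                wf = w[f]
                gr = gy[b, f, c]
                for k in range(K):
                    wk = wf[k]
                    for t in range(T):
                        gxr[t + k] += wk * gr[t]
    return gx


@njit(cache=True, fastmath=True)
def bn_stats(x):
    """Per-map sum and sum of squares over [B, F, M] -> (s1[F], s2[F])."""
    B, F, M = x.shape
    s1 = np.zeros(F, np.float64)
    s2 = np.zeros(F, np.float64)
    for b in range(B):
        for f in range(F):
            xr = x[b, f]
            a1 = 0.0
            a2 = 0.0
            for m in range(M):
                v = xr[m]
                a1 += v
                a2 += v * v
            s1[f] += a1
            s2[f] += a2
    return s1, s2


@njit(cache=True, fastmath=True)
def bn_apply(x, scale, shift):
    """y = x * scale[f] + shift[f] on [B, F, M]."""
    B, F, M = x.shape
    y = np.empty_like(x)
    for b in range(B):
        for f in range(F):
            a = scale[f]
            s = shift[f]
            xr = x[b, f]
            yr = y[b, f]
            for m in range(M):
                yr[m] = a * xr[m] + s
    return y


@njit(cache=True, fastmath=True)
def bn_bwd_sums(g, x, mu, inv_sd):
    """Sums needed by batch-norm backward: (sum_g[F], sum_g_xhat[F])."""
    B, F, M = g.shape
    sg = np.zeros(F, np.float64)
    sgx = np.zeros(F, np.float64)
    for b in range(B):
        for f in range(F):
            gr = g[b, f]
            xr = x[b, f]
            m0 = mu[f]
            isd = inv_sd[f]
            a1 = 0.0
            a2 = 0.0
            for m in range(M):
                gv = gr[m]
                a1 += gv
                a2 += gv * (xr[m] - m0) * isd
            sg[f] += a1
            sgx[f] += a2
    return sg, sgx


@njit(cache=True, fastmath=True)
def bn_bwd_dx(g, x, mu, inv_sd, gamma, mean_g, mean_gx):
    """dx = gamma*inv_sd * (g - mean_g - xhat*mean_gx) on [B, F, M]."""
    B, F, M = g.shape
    dx = np.empty_like(g)
    for b in range(B):
        for f in range(F):
            gr = g[b, f]
            xr = x[b, f]
            m0 = mu[f]
            isd = inv_sd[f]
            a = gamma[f] * isd
            mg = mean_g[f]
            mgx = mean_gx[f]
            dxr = dx[b, f]
            for m in range(M):
                xhat = (xr[m] - m0) * isd
                dxr[m] = a * (gr[m] - mg - xhat * mgx)
    return dx


@njit(cache=True, fastmath=True)
def spatial_fwd(x, w):
    """Depthwise spatial conv: x [B,F,C,T], w [F,D,C] -> y [B,F*D,T]."""
    B, F, C, T = x.shape
    D = w.shape[1]
    y = np.zeros((B, F * D, T), x.dtype)
    for b in range(B):
        for f in range(F):
            for d in range(D):
                yr = y[b, f * D + d]
                for c in range(C):
                    wv = w[f, d, c]
                    xr = x[b, f, c]
                    for t in range(T):
                        yr[t] += wv * xr[t]
    return y


@njit(cache=True, fastmath=True)
def spatial_bwd_gx(w, g):
    """Input grad / adjoint: g [B,F,D,T], w [F,D,C] -> gx [B,F,C,T]."""
    B, F, D, T = g.shape
    C = w.shape[2]
    gx = np.zeros((B, F, C, T), g.dtype)
    for b in range(B):
        for f in range(F):
            for d in range(D):
                gr = g[b, f, d]
                for c in range(C):
                    wv = w[f, d, c]
                    xr = gx[b, f, c]
                    for t in range(T):
                        xr[t] += wv * gr[t]
    return gx


@njit(cache=True, fastmath=True)
def spatial_bwd_gw(x, g):
    """Weight grad: x [B,F,C,T], g [B,F,D,T] -> gw [F,D,C]."""
    B, F, C, T = x.shape
    D = g.shape[2]
    gw = np.zeros((F, D, C), x.dtype)
    for b in range(B):
        for f in range(F):
            for d in range(D):
                gr = g[b, f, d]
                for c in range(C):
                    acc = 0.0
                    xr = x[b, f, c]
                    for t in range(T):
                        acc += gr[t] * xr[t]
                    gw[f, d, c] += acc
    return gw
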