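"""Numerical kernels for delay-and-sum beamforming.

Compiled with numba when available; a pure-numpy fallback keeps the
package importable (slowly) without it.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def das_time_max(sig, d_samp, start, length, subsample):
    """Time-domain delay-and-sum: per focus point, align every channel by
    its propagation delay, average over channels and take the peak |.|.

    sig     : (M, S) float64 channel signals
    d_samp  : (P, M) float64 delays in samples
    start   : first aligned sample index of the frame
    length  : frame length in samples
    returns : (P,) float64 map values
    """
    P, M = d_samp.shape
    out = np.empty(P)
    acc = np.empty(length)
    for p in range(P):
        for k in range(length):
            acc[k] = 0.0
        for m in range(M):
            d = d_samp[p, m]
            if subsample:
                i0 = int(np.floor(d))
                f = d - i0
                off = start + i0
                for k in range(length):
                    acc[k] += (1.0 - f) * sig[m, off + k] + f * sig[m, off + k + 1]
            else:
                off = start + int(np.rint(d))
                for k in range(length):
                    acc[k] += sig[m, off + k]
        mx = 0.0
        for k in range(length):
            a = abs(acc[k])
            if a > mx:
                mx = a
        out[p] = mx / M
    return out


@njit(cache=True)
def das_baseband_max(bb, d_idx, steer_re, steer_im, start, length):
    """Complex-baseband delay-and-sum: channels demodulated at the band
    centre are aligned to the nearest decimated sample and phase-steered
    exactly; the map value is the peak envelope of the channel average.

    bb       : (M, S) complex128 baseband channel signals
    d_idx    : (P, M) int64 delays in decimated samples
    steer_re/im : (P, M) float64 carrier-phase steering terms
    """
    P, M = d_idx.shape
    out = np.empty(P)
    acc_re = np.empty(length)
    acc_im = np.empty(length)
    for p in range(P):
        for k in range(length):
            acc_re[k] = 0.0
            acc_im[k] = 0.0
        for m in range(M):
            off = start + d_idx[p, m]
            sr = steer_re[p, m]
            si = steer_im[p, m]
            for k in range(length):
                xr = bb[m, off + k].real
                xi = bb[m, off + k].imag
                acc_re[k] += xr * sr - xi * si
                acc_im[k] += xr * si + xi * sr
        mx = 0.0
        for k in range(length):
            a = acc_re[k] * acc_re[k] + acc_im[k] * acc_im[k]
            if a > mx:
                mx = a
        out[p] = np.sqrt(mx) / M
    return out


@njit(cache=True)
def frame_rms(sig, hop, length, n_frames):
    """(n_frames,) RMS over all channels per frame of ``length`` samples."""
    M = sig.shape[0]
    out = np.empty(n_frames)
    for f in range(n_frames):
        s0 = f * hop
        acc = 0.0
        for m in range(M):
            for k in range(length):
                v = sig[m, s0 + k]
                acc += v * v
        out[f] = np.sqrt(acc / (M * length))
    return out
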