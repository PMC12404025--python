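"""Boys function F_n(T) = int_0^1 t^{2n} exp(-T t^2) dt.

The radial kernel of all Gaussian Coulomb integrals.  Evaluation strategy:

* T <= 35: top order by the exp(-T)-scaled ascending series
  F_m(T) = e^{-T} sum_i (2T)^i / ((2m+1)(2m+3)...(2m+2i+1)),
  then stable downward recursion F_{n-1} = (2T F_n + e^{-T}) / (2n-1).
* T > 35: F_0 = sqrt(pi/T)/2 (the erfc remainder is < 1e-15 there) and
  upward recursion F_{n+1} = ((2n+1) F_n - e^{-T}) / (2T), which is stable
  because 2T > 2n+1 for all supported orders.

Absolute accuracy is ~1e-14 for n <= 32.
"""

from __future__ import annotations

import math

import numpy as np

MAX_ORDER = 64
_T_SWITCH = 35.0


def boys_array(nmax: int, T) -> np.ndarray:
    """Return F_n(T) for n = 0..nmax; T may be scalar or array (last axis kept)."""
    if nmax < 0:
        raise ValueError("negative Boys order")
    if nmax > MAX_ORDER:
        raise ValueError(f"Boys order {nmax} beyond supported maximum {MAX_ORDER}")
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("negative Boys argument")
    scalar = T.ndim == 0
    T = np.atleast_1d(T)
    out = np.empty((nmax + 1,) + T.shape)

    small = T <= _T_SWITCH
    if np.any(small):
        Ts = T[small]
        expT = np.exp(-Ts)
        # ascending series for the top order
        term = np.full_like(Ts, 1.0 / (2 * nmax + 1))
        acc = term.copy()
        i = 0
        while True:
            i += 1
            term = term * (2.0 * Ts) / (2 * nmax + 2 * i + 1)
            acc += term
            if np.all(term <= 1e-17 * acc) or i > 300:
                break
        fs = np.empty((nmax + 1,) + Ts.shape)
        fs[nmax] = acc * expT
        for n in range(nmax, 0, -1):
            fs[n - 1] = (2.0 * Ts * fs[n] + expT) / (2 * n - 1)
        out[:, small] = fs

    large = ~small
    if np.any(large):
        Tl = T[large]
        expT = np.exp(-Tl)
        fl = np.empty((nmax + 1,) + Tl.shape)
        fl[0] = 0.5 * np.sqrt(np.pi / Tl)
        for n in range(nmax):
            fl[n + 1] = ((2 * n + 1) * fl[n] - expT) / (2.0 * Tl)
        out[:, large] = fl

    if scalar:
        return out[:, 0]
    return out


def boys(n: int, T: float) -> float:
    """Single Boys function value F_n(T)."""
    if n < 0:
        raise ValueError("negative Boys order")
    if T < 0:
        raise ValueError("negative Boys argument")
    return float(boys_array(n, float(T))[n])
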