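"""Vectorized standard bivariate normal CDF via Owen's T function."""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = ["bvn_cdf"]


def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: np.ndarray | float) -> np.ndarray:
    """P(X <= h, Y <= k) for standard bivariate normal (X, Y) with corr rho.

    Uses Owen's (1956) identity
    ``Phi2(h,k,rho) = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - adj`` with
    ``a_h = (k - rho h)/(h sqrt(1-rho^2))`` and ``adj = 1/2`` when the
    arguments lie in opposite quadrants.  Fully vectorized; exact limits are
    substituted at ``rho = +/-1``.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, np.asarray(rho, dtype=float))

    out = np.empty(h.shape, dtype=float)

    hi = rho >= 1.0 - 1e-14
    lo = rho <= -1.0 + 1e-14
    mid = ~(hi | lo)
    if hi.any():
        out[hi] = ndtr(np.minimum(h[hi], k[hi]))
    if lo.any():
        out[lo] = np.clip(ndtr(h[lo]) + ndtr(k[lo]) - 1.0, 0.0, None)
    if mid.any():
        hm, km, rm = h[mid], k[mid], rho[mid]
        # Nudge exact zeros: the Owen formula has a removable singularity there.
        eps = 1e-14
        hm = np.where(hm == 0.0, eps, hm)
        km = np.where(km == 0.0, eps, km)
        root = np.sqrt(1.0 - rm * rm)
        a_h = (km - rm * hm) / (hm * root)
        a_k = (hm - rm * km) / (km * root)
        adj = np.where((hm * km > 0) | ((hm * km == 0) & (hm + km >= 0)), 0.0, 0.5)
        val = 0.5 * (ndtr(hm) + ndtr(km)) - owens_t(hm, a_h) - owens_t(km, a_k) - adj
        out[mid] = np.clip(val, 0.0, 1.0)
    return out
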