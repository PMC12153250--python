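"""Numerical-quadrature evaluation of the rejection-region probability.

Independent cross-check for the Monte-Carlo level estimates; production
calibration stays Monte Carlo.  The region is awkward but its conditional
structure is not: given the pooled-SD factor ``w = sigma_hat/sigma``, the
statistics ``(T_s, T_c) = (Z_s, Z_c)/w`` are independent scaled normals, and
for fixed ``T_s`` the admissible ``T_c`` set of the union region is a union
of at most two intervals whose normal measure is closed form.  The two
remaining integrals (over ``z_s`` and over ``w``) are Gauss-Legendre
quadratures, split at the only discontinuity of the inner integrand (the
subgroup path switching on at ``T_s = t_alpha_s``).
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .design import DesignSpec

__all__ = ["region_probability"]

_Z_LIM = 9.0


def _tc_union_mass(ts: np.ndarray, w: np.ndarray, design: DesignSpec) -> np.ndarray:
    """Normal measure (in z_c = w * T_c) of the admissible T_c set given T_s.

    ``ts`` and ``w`` broadcast; ``w`` must be strictly positive.
    """
    p = design.p
    k = design.require_k()
    root = np.sqrt(p * (1.0 - p))
    c_s = (1.0 - k * p) / root
    c_c = (1.0 - k * (1.0 - p)) / root

    # subgroup path: the ray (b-slope * T_s, inf) once T_s clears its critical value
    a_lo = np.where(ts > design.t_alpha_s, design.consistency_slope * ts, np.inf)

    # overall path: intersection of up to three half-lines in T_c
    lo = (design.t_alpha_o - np.sqrt(p) * ts) / np.sqrt(1.0 - p)
    lo = np.maximum(lo, k * ts / c_c)
    if k > 0:
        hi = c_s * ts / k
    elif k < 0:
        lo = np.maximum(lo, c_s * ts / k)
        hi = np.full_like(lo, np.inf)
    else:  # k == 0: the retention pair degenerates to requiring T_s > 0
        lo = np.where(ts > 0, lo, np.inf)
        hi = np.full_like(lo, np.inf)

    ndtr = special.ndtr

    def _cdf(x):
        # w * inf is inf (w > 0); ndtr handles +-inf
        return ndtr(np.multiply(w, x))

    p_a = np.where(np.isfinite(a_lo), 1.0 - _cdf(a_lo), 0.0)
    b_nonempty = lo < hi
    p_b = np.where(b_nonempty, _cdf(hi) - _cdf(lo), 0.0)
    olo = np.maximum(a_lo, lo)
    p_ab = np.where(b_nonempty & (hi > olo), np.clip(_cdf(hi) - _cdf(olo), 0.0, None), 0.0)
    return p_a + p_b - p_ab


from functools import lru_cache


@lru_cache(maxsize=16)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def _gauss_nodes(a, b, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Affine-mapped Gauss-Legendre nodes; a, b may be arrays (broadcast)."""
    x, wts = _leggauss(n)
    a = np.asarray(a, dtype=float)[..., None]
    b = np.asarray(b, dtype=float)[..., None]
    return 0.5 * (b - a) * x + 0.5 * (a + b), 0.5 * (b - a) * wts


def region_probability(design: DesignSpec, n_z: int = 240, n_w: int = 80) -> float:
    """P(intersection test rejects) under the global null, by nested quadrature."""
    chi = stats.chi(design.df, scale=1.0 / np.sqrt(design.df))
    w, ww = _gauss_nodes(chi.ppf(1e-10), chi.ppf(1.0 - 1e-10), n_w)
    # inner z_s-integral split at the subgroup path's switch-on point per w
    brk = np.clip(w * design.t_alpha_s, -_Z_LIM, _Z_LIM)
    inner = np.zeros_like(w)
    for lo, hi in ((np.full_like(brk, -_Z_LIM), brk), (brk, np.full_like(brk, _Z_LIM))):
        z, zw = _gauss_nodes(lo, hi, n_z)  # shape (n_w, n_z)
        vals = stats.norm.pdf(z) * _tc_union_mass(z / w[:, None], w[:, None], design)
        inner += np.sum(zw * vals, axis=-1)
    return float(np.sum(ww * chi.pdf(w) * inner))
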