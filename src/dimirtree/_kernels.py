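"""Compiled response log-likelihood kernels.

The samplers evaluate the tree likelihood thousands of times per fit, so
the per-observation node computations are JIT-compiled with numba.  Both
kernels implement exactly the two-exponential divide-by-total form of the
co-occurring-process nodes; correctness is checked in the test suite
against the generic (pure-python) tree evaluation.

Entries of the pseudo-response matrices that are negative encode missing
cells (by design or respondent-level); they contribute 0 to the
log-likelihood.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["agreement_intensity_ll", "midscale_ll"]


@njit(cache=True, fastmath=True, inline="always")
def _lae(a, b):
    # logaddexp via max + log1p(exp(-|a-b|)): cheaper than the ufunc
    if a > b:
        return a + np.log1p(np.exp(b - a))
    return b + np.log1p(np.exp(a - b))


@njit(cache=True, fastmath=True)
def agreement_intensity_ll(theta, eta, lam1, alpha, lam2, delta,
                           tau1, tau2, tau3, x1, x2, x3, out):
    """Agreement + two intensity nodes (4- or 6-point family).

    ``alpha`` (ERS dominance) or ``lam2`` (trait ideal point) may be all
    zeros, which reduces the intensity nodes to the single remaining
    process: a zero ideal-point discrimination makes the from-below and
    from-above terms coincide, doubling every component harmlessly.
    """
    n, i_n = out.shape
    c = tau2.shape[1] + 1
    m = 2 * (c - 1) + 1
    w = np.empty(c)
    for v in range(n):
        for i in range(i_n):
            xa = x1[v, i]
            if xa < 0:
                out[v, i] = 0.0
                continue
            d = theta[v] - delta[i]
            t1 = lam1[i] * d
            l0 = _lae(0.0, 3.0 * t1)
            l1 = _lae(t1, 2.0 * t1) - tau1[i, 0]
            hi = l0 if l0 > l1 else l1
            ll = (l1 if xa == 1 else l0) - (hi + np.log(np.exp(l0 - hi) + np.exp(l1 - hi)))

            xb = x2[v, i]
            xc = x3[v, i]
            if xb >= 0 or xc >= 0:
                ae = alpha[i] * eta[v]
                bi = lam2[i] * d
                rev = xb < 0
                x = xc if rev else xb
                t_cum = 0.0
                mx = -1.0e300
                for y in range(c):
                    if y > 0:
                        t_cum += tau3[i, y - 1] if rev else tau2[i, y - 1]
                    si = (c - 1 - y) if rev else y
                    below = y * ae + si * bi - t_cum
                    above = y * ae + (m - si) * bi - t_cum
                    w[y] = _lae(below, above)
                    if w[y] > mx:
                        mx = w[y]
                tot = 0.0
                for y in range(c):
                    tot += np.exp(w[y] - mx)
                ll += w[x] - (mx + np.log(tot))
            out[v, i] = ll


@njit(cache=True, fastmath=True)
def midscale_ll(theta, eta1, eta2, a1, lam, a2, a3, a4,
                tau1, tau2, tau3, tau4, ideal_mid,
                x1, x2, x3, x4, out):
    """Midscale / agreement / extreme-agree / extreme-disagree binary nodes.

    The midscale trait process is an ideal point with location tied to
    the agreement threshold ``beta2 = tau2 / a2`` when ``ideal_mid`` is
    true, or a plain dominance process otherwise.  The disagree-side
    extreme node carries reversed trait weights (1, 0).
    """
    n, i_n = out.shape
    for v in range(n):
        for i in range(i_n):
            xa = x1[v, i]
            if xa < 0:
                out[v, i] = 0.0
                continue
            am = a1[i] * eta1[v]
            if ideal_mid:
                bm = lam[i] * (theta[v] - tau2[i, 0] / a2[i])
                l0 = _lae(0.0, 3.0 * bm)
                l1 = _lae(am + bm, am + 2.0 * bm) - tau1[i, 0]
            else:
                l0 = np.log(2.0)
                l1 = np.log(2.0) + am + lam[i] * theta[v] - tau1[i, 0]
            hi = l0 if l0 > l1 else l1
            ll = (l1 if xa == 1 else l0) - (hi + np.log(np.exp(l0 - hi) + np.exp(l1 - hi)))

            xb = x2[v, i]
            if xb >= 0:
                lin = a2[i] * theta[v] - tau2[i, 0]
                ll += (lin if xb == 1 else 0.0) - _lae(0.0, lin)
            xc = x3[v, i]
            if xc >= 0:
                lin = a3[i] * eta2[v] + a4[i] * theta[v] - tau3[i, 0]
                ll += (lin if xc == 1 else 0.0) - _lae(0.0, lin)
            xd = x4[v, i]
            if xd >= 0:
                l0 = a4[i] * theta[v]
                l1 = a3[i] * eta2[v] - tau4[i, 0]
                ll += (l1 if xd == 1 else l0) - _lae(l0, l1)
            out[v, i] = ll
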