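"""Numba hot loops: Li-Stephens forward-backward and the BayesR Gibbs sweep.

Kept free of any package imports so the jitted signatures stay simple; the
public modules validate inputs before calling in here.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def ls_forward_backward_dosages(ref, obs, stay, eps, dosages):
    """Haplotype-copying posteriors, reduced on the fly to alt-allele dosages.

    ref : (H, M) uint8 reference alleles
    obs : (T, M) int8 observed target alleles, -1 at untyped sites
    stay : (M-1,) float64 probability of not switching between adjacent sites
           (0.0 across chromosome boundaries)
    eps : emission mismatch probability
    dosages : (T, M) float64 output buffer
    """
    H, M = ref.shape
    T = obs.shape[0]
    alpha = np.empty((M, H))
    beta = np.empty(H)
    btmp = np.empty(H)
    for t in range(T):
        # forward, normalised at every site
        s = 0.0
        for h in range(H):
            e = 1.0
            o = obs[t, 0]
            if o >= 0:
                e = (1.0 - eps) if ref[h, 0] == o else eps
            alpha[0, h] = e / H
            s += alpha[0, h]
        for h in range(H):
            alpha[0, h] /= s
        for j in range(1, M):
            st = stay[j - 1]
            sw = (1.0 - st) / H
            o = obs[t, j]
            s = 0.0
            for h in range(H):
                pred = st * alpha[j - 1, h] + sw
                e = 1.0
                if o >= 0:
                    e = (1.0 - eps) if ref[h, j] == o else eps
                alpha[j, h] = pred * e
                s += alpha[j, h]
            for h in range(H):
                alpha[j, h] /= s
        # backward, combining into posteriors as we go
        for h in range(H):
            beta[h] = 1.0
        s = 0.0
        d = 0.0
        for h in range(H):
            p = alpha[M - 1, h]
            s += p
            d += p * ref[h, M - 1]
        dosages[t, M - 1] = d / s
        for j in range(M - 2, -1, -1):
            st = stay[j]
            sw = (1.0 - st) / H
            o = obs[t, j + 1]
            msum = 0.0
            for h in range(H):
                e = 1.0
                if o >= 0:
                    e = (1.0 - eps) if ref[h, j + 1] == o else eps
                btmp[h] = beta[h] * e
                msum += btmp[h]
            msum /= H
            bmax = 0.0
            for h in range(H):
                beta[h] = st * btmp[h] + (1.0 - st) * msum
                if beta[h] > bmax:
                    bmax = beta[h]
            for h in range(H):
                beta[h] /= bmax
            s = 0.0
            d = 0.0
            for h in range(H):
                p = alpha[j, h] * beta[h]
                s += p
                d += p * ref[h, j]
            dosages[t, j] = d / s
    return dosages


@njit(cache=True)
def bayesr_sweep(X, xtx, e, beta, comp, gamma, pi, sigma_e, sigma_g, u):
    """One single-site Gibbs sweep over all variants.

    X : (n, m) centered dosage matrix (float64, C order by column access)
    xtx : (m,) column sums of squares
    e : (n,) current residual  y - X beta  (updated in place)
    beta : (m,) current effects (updated in place)
    comp : (m,) current component index 0..3 (updated in place)
    gamma : (4,) component variances as fractions of sigma_g (gamma[0] == 0)
    pi : (4,) mixing proportions
    u : (m, 2) uniform random numbers for this sweep (class draw, effect draw
        uses the normal draw in u[:, 1] already transformed by caller)

    Returns (ssq_by_comp, n_by_comp_0..3 packed) via output arrays is awkward
    in numba; instead the caller recomputes class counts from ``comp``.
    """
    n, m = X.shape
    logpi = np.empty(4)
    for k in range(4):
        logpi[k] = np.log(pi[k]) if pi[k] > 0 else -1e300
    logl = np.empty(4)
    for j in range(m):
        bj = beta[j]
        # rhs = X_j' e + xtx_j * beta_j  (add the variant's own contribution back)
        rhs = 0.0
        for i in range(n):
            rhs += X[i, j] * e[i]
        rhs += xtx[j] * bj
        # class-conditional log posteriors
        best = logpi[0]
        logl[0] = logpi[0]
        for k in range(1, 4):
            v = gamma[k] * sigma_g
            if v <= 0.0:
                logl[k] = -1e300
            else:
                c = xtx[j] + sigma_e / v
                logl[k] = (
                    logpi[k]
                    - 0.5 * np.log(v * xtx[j] / sigma_e + 1.0)
                    + 0.5 * rhs * rhs / (sigma_e * c)
                )
            if logl[k] > best:
                best = logl[k]
        tot = 0.0
        for k in range(4):
            logl[k] = np.exp(logl[k] - best)
            tot += logl[k]
        r = u[j, 0] * tot
        k = 0
        acc = logl[0]
        while acc < r and k < 3:
            k += 1
            acc += logl[k]
        comp[j] = k
        if k == 0:
            bnew = 0.0
        else:
            v = gamma[k] * sigma_g
            c = xtx[j] + sigma_e / v
            mean = rhs / c
            sd = np.sqrt(sigma_e / c)
            bnew = mean + sd * u[j, 1]
        if bnew != bj:
            diff = bnew - bj
            for i in range(n):
                e[i] -= X[i, j] * diff
            beta[j] = bnew
    return 0
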