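"""Low-level Cox partial-likelihood kernels (Efron tie handling).

Subjects must be pre-sorted by ascending survival time; tied times form
one risk-set group and tied events receive the Efron correction.  The
O(n p^2) accumulation loops are numba-compiled because the genome-wide
scan evaluates them tens of thousands of times.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def efron_loglik(t, d, Z, beta):
    """Efron partial log-likelihood at coefficient vector `beta`."""
    n, p = Z.shape
    eta = Z @ beta
    w = np.exp(eta)
    ll = 0.0
    S0 = 0.0
    i = n - 1
    while i >= 0:
        ti = t[i]
        j = i
        while j >= 0 and t[j] == ti:
            S0 += w[j]
            j -= 1
        s0t = 0.0
        dcount = 0
        for m in range(j + 1, i + 1):
            if d[m] == 1:
                s0t += w[m]
                dcount += 1
                ll += eta[m]
        for l in range(dcount):
            f = l / dcount
            ll -= np.log(S0 - f * s0t)
        i = j
    return ll


@njit(cache=True)
def efron_grad_hess(t, d, Z, beta):
    """Efron partial log-likelihood with gradient and Hessian.

    Returns (loglik, gradient, negative-definite Hessian).
    """
    n, p = Z.shape
    eta = Z @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    s1t = np.zeros(p)
    s2t = np.zeros((p, p))
    i = n - 1
    while i >= 0:
        ti = t[i]
        j = i
        while j >= 0 and t[j] == ti:
            wj = w[j]
            S0 += wj
            for a in range(p):
                za = Z[j, a]
                S1[a] += wj * za
                for b in range(a + 1):
                    S2[a, b] += wj * za * Z[j, b]
            j -= 1
        # events inside this tied-time group
        s0t = 0.0
        dcount = 0
        for a in range(p):
            s1t[a] = 0.0
            for b in range(a + 1):
                s2t[a, b] = 0.0
        for m in range(j + 1, i + 1):
            if d[m] == 1:
                wm = w[m]
                s0t += wm
                dcount += 1
                ll += eta[m]
                for a in range(p):
                    za = Z[m, a]
                    grad[a] += za
                    s1t[a] += wm * za
                    for b in range(a + 1):
                        s2t[a, b] += wm * za * Z[m, b]
        for l in range(dcount):
            f = l / dcount
            denom = S0 - f * s0t
            ll -= np.log(denom)
            for a in range(p):
                e1a = (S1[a] - f * s1t[a]) / denom
                grad[a] -= e1a
                for b in range(a + 1):
                    e1b = (S1[b] - f * s1t[b]) / denom
                    hess[a, b] -= (S2[a, b] - f * s2t[a, b]) / denom \
                        - e1a * e1b
        i = j
    for a in range(p):
        for b in range(a):
            hess[b, a] = hess[a, b]
            S2[b, a] = S2[a, b]
    return ll, grad, hess


def breslow_cumhaz(t, d, eta):
    """Breslow baseline cumulative hazard evaluated at each subject's
    observed time (subjects sorted ascending by `t`)."""
    w = np.exp(eta)
    n = len(t)
    # suffix sums of risk weights, group-aligned on tied times
    rev = np.cumsum(w[::-1])[::-1]
    uniq, first = np.unique(t, return_index=True)
    S0_group = rev[first]
    dsum = np.zeros(len(uniq))
    gidx = np.searchsorted(uniq, t)
    np.add.at(dsum, gidx, d)
    increments = dsum / S0_group
    cum = np.cumsum(increments)
    return cum[gidx]
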