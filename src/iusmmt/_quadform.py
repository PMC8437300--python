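"""Tail probabilities of positive mixtures of chi-square(1) variables.

Every variance-component score statistic in this package has a null
distribution of the form ``Q = sum_j lambda_j * chi2_1``, with the
``lambda_j`` the nonzero eigenvalues of a projected kernel matrix.  The
upper-tail probability ``P(Q > q)`` is computed by exact numerical
inversion of the characteristic function (Imhof's integral) with a
moment-matching (Liu-type) approximation as fallback when the quadrature
fails to converge or returns a value outside the representable range.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, stats

__all__ = ["mixture_chisq_tail", "liu_tail"]

#: relative eigenvalue threshold below which a weight is discarded
EIGEN_RTOL = 1e-10

#: requested absolute accuracy for the Imhof quadrature
IMHOF_ACC = 1e-9


def _imhof_integrand(u: np.ndarray, q: float, lam: np.ndarray) -> np.ndarray:
    lu = lam[:, None] * u[None, :]
    theta = 0.5 * np.sum(np.arctan(lu), axis=0) - 0.5 * q * u
    rho = np.exp(0.25 * np.sum(np.log1p(lu * lu), axis=0))
    return np.sin(theta) / (u * rho)


def _imhof_tail(q: float, lam: np.ndarray) -> float:
    """P(sum lam_j chi2_1 > q) by Imhof's inversion formula."""
    fun = lambda u: _imhof_integrand(np.atleast_1d(u), q, lam)[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(fun, 0.0, np.inf, epsabs=IMHOF_ACC,
                                  epsrel=1e-8, limit=200)
    p = 0.5 + val / np.pi
    if err > 1e-5 or not np.isfinite(p):
        raise FloatingPointError("Imhof quadrature did not converge")
    return p


def liu_tail(q: float, lam: np.ndarray) -> float:
    """Moment-matching approximation to P(sum lam_j chi2_1 > q).

    Matches the first three cumulants plus (modified) kurtosis to a
    shifted-and-scaled noncentral chi-square, following the standard
    four-moment construction.
    """
    c1 = lam.sum()
    c2 = (lam ** 2).sum()
    c3 = (lam ** 3).sum()
    c4 = (lam ** 4).sum()
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    t_star = (q - mu_q) / sigma_q
    if s1 * s1 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 * s1 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a * a - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2 if s2 > 0 else 1.0
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2.0 * delta))
    x = t_star * sigma_x + mu_x
    return float(stats.ncx2.sf(x, df, delta)) if delta > 0 else float(
        stats.chi2.sf(x, df))


def mixture_chisq_tail(q: float, weights) -> float:
    """Upper-tail probability ``P(sum_j w_j chi2_1 > q)``.

    Parameters
    ----------
    q : float
        Observed quadratic-form statistic, ``q >= 0``.
    weights : array-like
        Nonnegative mixture weights; weights below ``1e-10`` times the
        largest are dropped.  At least one must be positive.

    Returns
    -------
    float in [0, 1].
    """
    lam = np.asarray(weights, dtype=float).ravel()
    if lam.size == 0 or not np.any(lam > 0):
        raise ValueError("mixture_chisq_tail requires at least one "
                         "positive weight")
    if np.any(lam < 0):
        raise ValueError("mixture weights must be nonnegative")
    lam = lam[lam > EIGEN_RTOL * lam.max()]
    if q <= 0:
        return 1.0
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1))
    try:
        p = _imhof_tail(q, lam)
    except FloatingPointError:
        p = liu_tail(q, lam)
    if not (1e-14 <= p <= 1.0):
        p = liu_tail(q, lam)
    return float(min(max(p, 0.0), 1.0))
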