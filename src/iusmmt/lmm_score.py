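"""Methylation -> expression stage: variance-component score test.

The exposure-mediator model is a linear mixed model
``G = M a + X w2 + eps`` with ``a_k ~ N(0, tau2)`` and
``eps ~ N(0, sigma_eps^2)``.  The null of no methylation effect,
``H0: a = 0`` (equivalently ``tau2 = 0``), is tested with the
linear-kernel variance-component score statistic

    Q = r' M M' r / sigma_eps^2,

where ``r`` are the null OLS residuals of G on the covariates (with
intercept).  Under H0, Q follows a mixture of chi-square(1) variables
weighted by the nonzero eigenvalues of ``M' P0 M`` (P0 the residual-maker
of the covariate design); the pairing of the 1/sigma^2 scaling with those
eigenvalues makes the p-value exactly invariant to rescaling G.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from ._quadform import EIGEN_RTOL, mixture_chisq_tail
from .core_data import CovariateTable, GeneDataset, MethylationBlock

__all__ = ["NullLinearFit", "ScoreTestResult", "fit_null_linear",
           "score_statistic_q", "mixture_chisq_tail",
           "test_methylation_expression", "reml_tau2"]


@dataclass
class NullLinearFit:
    """OLS fit of the mediator on covariates-with-intercept."""

    coef: np.ndarray
    residuals: np.ndarray
    sigma2: float
    design: np.ndarray  # n x (L+1) design, kept for downstream projections


@dataclass
class ScoreTestResult:
    q: float
    weights: np.ndarray
    p_value: float
    tau2_hat: float | None = None


def fit_null_linear(G: np.ndarray, X: CovariateTable) -> NullLinearFit:
    """Least-squares fit of G on [1, X]; sigma2 = RSS / (n - rank)."""
    G = np.asarray(G, dtype=float).ravel()
    D = X.with_intercept()
    n, p = D.shape
    if n <= p:
        raise ValueError("need n > L + 1 samples for the null fit")
    rank = np.linalg.matrix_rank(D)
    if rank < p:
        # identify collinear columns by rank-revealing QR pivoting
        _, _, piv = sla.qr(D, pivoting=True, mode="economic")
        names = ["intercept"] + list(X.names)
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"covariate design is rank deficient; collinear "
                         f"columns: {', '.join(bad)}")
    coef, _, _, _ = np.linalg.lstsq(D, G, rcond=None)
    resid = G - D @ coef
    sigma2 = float(resid @ resid) / (n - rank)
    return NullLinearFit(coef=coef, residuals=resid, sigma2=sigma2, design=D)


def score_statistic_q(M: MethylationBlock | np.ndarray,
                      residuals: np.ndarray) -> float:
    """Linear-kernel score ``Q = sum_k (sum_i M_ik r_i)^2 = r' M M' r``."""
    vals = M.values if isinstance(M, MethylationBlock) else np.asarray(M)
    r = np.asarray(residuals, dtype=float).ravel()
    if vals.shape[0] != r.shape[0]:
        raise ValueError("methylation block and residuals disagree on n")
    s = vals.T @ r
    return float(s @ s)


def _kernel_eigenvalues(M: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Nonzero eigenvalues of M' P0 M, P0 the residual-maker of `design`."""
    Q, _ = np.linalg.qr(design)
    Mres = M - Q @ (Q.T @ M)
    # P0 idempotent, so M' P0 M = (P0 M)' (P0 M)
    lam = np.linalg.eigvalsh(Mres.T @ Mres)
    return lam[lam > EIGEN_RTOL * max(lam.max(), 1e-300)]


def test_methylation_expression(gd: GeneDataset,
                                estimate_tau2: bool = False
                                ) -> ScoreTestResult:
    """Variance-component score test of H0: tau2 = 0 for one gene."""
    fit = fit_null_linear(gd.expression, gd.covariates)
    if fit.sigma2 <= 0:
        raise ValueError("residual variance is zero; score test undefined")
    M = gd.methylation.values
    q = score_statistic_q(M, fit.residuals) / fit.sigma2
    lam = _kernel_eigenvalues(M, fit.design)
    if lam.size == 0:
        return ScoreTestResult(q=0.0, weights=lam, p_value=1.0)
    p = mixture_chisq_tail(q, lam)
    tau2 = reml_tau2(gd) if estimate_tau2 else None
    return ScoreTestResult(q=q, weights=lam, p_value=p, tau2_hat=tau2)


# ---------------------------------------------------------------------------
# REML magnitude estimate of tau2

def _reml_loglik(log_tau2: float, lam_k: np.ndarray, u2: np.ndarray,
                 n: int, p: int) -> float:
    """Restricted log-likelihood of the one-variance-component model,
    profiled over sigma_eps^2, in the eigenbasis of P0 M M' P0.

    lam_k : eigenvalues of M' P0 M;  u2 : squared residual projections on
    the corresponding eigenvectors (plus the null-space mass appended as
    u2[-1] with lam 0 implicitly handled by the remaining df).
    """
    tau2 = np.exp(log_tau2)
    d = 1.0 + tau2 * lam_k
    # residual degrees of freedom after the fixed effects
    df = n - p
    rss_white = np.sum(u2[: lam_k.size] / d) + u2[lam_k.size]
    sigma2 = rss_white / df
    return -0.5 * (np.sum(np.log(d)) + df * np.log(sigma2) + df)


def reml_tau2(gd: GeneDataset) -> float:
    """REML estimate of the methylation variance component tau2 >= 0,
    by a log-grid search on [1e-6, 10] with golden-section refinement."""
    from scipy.optimize import minimize_scalar

    fit = fit_null_linear(gd.expression, gd.covariates)
    M = gd.methylation.values
    Qd, _ = np.linalg.qr(fit.design)
    Mres = M - Qd @ (Qd.T @ M)
    lam, V = np.linalg.eigh(Mres.T @ Mres)
    keep = lam > EIGEN_RTOL * max(lam.max(), 1e-300)
    lam_k = lam[keep]
    # project residuals onto the kernel eigenvectors (in sample space)
    U = Mres @ (V[:, keep] / np.sqrt(lam_k))
    proj = U.T @ fit.residuals
    u2 = np.append(proj ** 2,
                   fit.residuals @ fit.residuals - np.sum(proj ** 2))
    n, p = fit.design.shape

    grid = np.log(np.logspace(-6, 1, 22))
    vals = [_reml_loglik(g, lam_k, u2, n, p) for g in grid]
    at_null = _reml_loglik(-np.inf, lam_k, u2, n, p)
    j = int(np.argmax(vals))
    if vals[j] <= at_null:
        return 0.0
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = minimize_scalar(lambda g: -_reml_loglik(g, lam_k, u2, n, p),
                          bounds=(lo, hi), method="bounded")
    best = float(np.exp(res.x))
    return best if -res.fun > at_null else 0.0
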