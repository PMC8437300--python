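"""Survival-side models.

Three pieces share one Efron partial-likelihood engine:

* ``fit_cox_ph`` — plain Cox proportional-hazards fit by Newton-Raphson,
  returning martingale residuals and the observed information;
* ``total_effect_test`` — kernel-machine score test of the total effect
  of the methylation block on survival (H0: tau1 = 0), built on the
  null-model martingale residuals;
* ``fit_coxlmm`` / ``wald_test_beta`` — the Cox mixed-effects model
  ``log h(t)/h0(t) = M gamma_DE + G beta + X w3`` with
  ``gamma_DE_k ~ N(0, tau3)``, fitted by ridge-penalized partial
  likelihood with the variance tau3 chosen by a Laplace-approximate
  integrated likelihood; the mediator effect beta is tested by Wald.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from ._cox_engine import breslow_cumhaz, efron_grad_hess
from ._quadform import mixture_chisq_tail
from .core_data import CovariateTable, GeneDataset, SurvivalOutcome

__all__ = ["CoxNullFit", "CoxlmmFit", "fit_cox_ph", "total_effect_test",
           "fit_coxlmm", "wald_test_beta"]

MAX_NEWTON_ITER = 50
MAX_STEP_HALVINGS = 30
LOGLIK_RTOL = 1e-9

#: default outer search grid for tau3 (log-spaced, then refined)
TAU3_GRID_DEFAULT = np.logspace(-6, 1, 21)
#: coarse grid for large simulation scans (no refinement)
TAU3_GRID_FAST = np.logspace(-4, 0, 5)


@dataclass
class CoxNullFit:
    coef: np.ndarray
    martingale_residuals: np.ndarray
    information: np.ndarray
    loglik: float
    _order: np.ndarray = field(repr=False, default=None)


@dataclass
class CoxlmmFit:
    beta_hat: float
    se_beta: float
    gamma_hat: np.ndarray
    tau3_hat: float
    w3_hat: np.ndarray
    converged: bool
    loglik: float = np.nan
    tau3_at_boundary: bool = False
    n_iter: int = 0


def _sorted_survival(outcome: SurvivalOutcome):
    """Deterministic ordering: stable sort on (time, status)."""
    order = np.lexsort((outcome.status, outcome.time))
    return outcome.time[order], outcome.status[order].astype(np.int64), order


def _newton(t, d, Z, penalty_diag, beta0=None):
    """Maximize the (ridge-penalized) Efron partial log-likelihood.

    penalty_diag : per-coefficient ridge precision (0 = unpenalized).
    Returns (beta, penalized loglik, unpenalized loglik, grad, neg_hess,
    converged, n_iter).  Step-halving keeps the penalized objective
    non-decreasing across accepted steps.
    """
    n, p = Z.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    ll, grad, hess = efron_grad_hess(t, d, Z, beta)
    pen_ll = ll - 0.5 * np.sum(penalty_diag * beta ** 2)
    converged = False
    it = 0
    for it in range(1, MAX_NEWTON_ITER + 1):
        pen_grad = grad - penalty_diag * beta
        neg_hess = -hess + np.diag(penalty_diag)
        try:
            step = np.linalg.solve(neg_hess, pen_grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(neg_hess, pen_grad, rcond=None)[0]
        accepted = False
        frac = 1.0
        for _ in range(MAX_STEP_HALVINGS + 1):
            cand = beta + frac * step
            ll_c, grad_c, hess_c = efron_grad_hess(t, d, Z, cand)
            pen_c = ll_c - 0.5 * np.sum(penalty_diag * cand ** 2)
            if np.isfinite(pen_c) and pen_c >= pen_ll - 1e-12:
                accepted = True
                break
            frac *= 0.5
        if not accepted:
            break
        rel = abs(pen_c - pen_ll) / (abs(pen_ll) + 1.0)
        beta, ll, grad, hess, pen_ll = cand, ll_c, grad_c, hess_c, pen_c
        if rel < LOGLIK_RTOL:
            converged = True
            break
    neg_hess = -hess + np.diag(penalty_diag)
    return beta, pen_ll, ll, grad, neg_hess, converged, it


def fit_cox_ph(outcome: SurvivalOutcome, X: CovariateTable) -> CoxNullFit:
    """Newton-Raphson Cox fit (Efron ties) with martingale residuals
    ``d_i - Lambda0(t_i) exp(x_i' coef)``."""
    if outcome.n_events < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    t, d, order = _sorted_survival(outcome)
    Z = X.values[order]
    n, p = Z.shape
    if p:
        if np.linalg.matrix_rank(Z) < p:
            raise ValueError("covariate matrix is rank deficient")
        beta, _, ll, grad, neg_hess, converged, _ = _newton(
            t, d, Z, np.zeros(p))
        if not converged and np.linalg.norm(grad) > 1e-4:
            raise RuntimeError("Cox fit did not converge (possible "
                               "monotone likelihood / separation)")
        eta = Z @ beta
    else:
        beta = np.zeros(0)
        eta = np.zeros(n)
        ll = float(efron_grad_hess(t, d, np.zeros((n, 1)), np.zeros(1))[0])
        neg_hess = np.zeros((0, 0))
    cumhaz = breslow_cumhaz(t, d, eta)
    resid_sorted = d - cumhaz * np.exp(eta)
    resid = np.empty(n)
    resid[order] = resid_sorted
    return CoxNullFit(coef=beta, martingale_residuals=resid,
                      information=neg_hess, loglik=float(ll), _order=order)


def total_effect_test(gd: GeneDataset, return_fit: bool = False):
    """Kernel-machine Cox score test of the methylation total effect.

    Q_T = r' M M' r with r the null-model martingale residuals, which is
    the squared norm of the partial-likelihood score for gamma at 0.  The
    reference mixture weights are the eigenvalues of the efficient score
    covariance I_MM - I_MX I_XX^-1 I_XM: the methylation block of the
    null-model partial-likelihood information with the covariate block
    projected out in the information metric (baseline-hazard profiling is
    inherent in the partial likelihood).
    """
    fit = fit_cox_ph(gd.outcome, gd.covariates)
    r = fit.martingale_residuals
    M = gd.methylation.values
    s = M.T @ r
    q = float(s @ s)
    K = gd.methylation.k
    t, d, order = _sorted_survival(gd.outcome)
    Z = np.column_stack([M, gd.covariates.values])[order]
    theta0 = np.concatenate([np.zeros(K), fit.coef])
    _, _, hess = efron_grad_hess(t, d, Z, theta0)
    info = -hess
    if gd.covariates.L:
        I_MX = info[:K, K:]
        V_eff = info[:K, :K] - I_MX @ np.linalg.solve(info[K:, K:],
                                                      I_MX.T)
    else:
        V_eff = info[:K, :K]
    lam = np.linalg.eigvalsh(V_eff)
    lam = lam[lam > 1e-10 * max(lam.max(), 1e-300)]
    p = 1.0 if lam.size == 0 or q <= 0 else mixture_chisq_tail(q, lam)
    return (p, fit) if return_fit else p


def _laplace_criterion(tau3, ll, gamma, neg_hess, K):
    """Laplace-approximate integrated partial log-likelihood in tau3."""
    Hgg = neg_hess[:K, :K] - np.diag(np.full(K, 1.0 / tau3))
    sign, logdet = np.linalg.slogdet(np.eye(K) + tau3 * Hgg)
    if sign <= 0:
        return -np.inf
    return ll - float(gamma @ gamma) / (2.0 * tau3) - 0.5 * logdet


def fit_coxlmm(gd: GeneDataset, tau3: float | None = None,
               tau3_grid="default", refine: bool = True) -> CoxlmmFit:
    """Fit the Cox mixed-effects model for one gene.

    For fixed tau3 the joint vector (gamma, beta, w3) maximizes the
    ridge-penalized partial likelihood (penalty gamma'gamma / (2 tau3));
    tau3 itself maximizes the Laplace-approximate integrated likelihood
    over a 1-D log-grid (``"default"``: 21 points in [1e-6, 10] plus
    golden-section refinement; ``"fast"``: 5 points, no refinement),
    unless fixed by the `tau3` argument.
    """
    if gd.outcome.n_events < 2:
        raise ValueError("need at least 2 events")
    K = gd.methylation.k
    L = gd.covariates.L
    if gd.n <= L + 2:
        raise ValueError("need n > L + 2 samples")
    t, d, order = _sorted_survival(gd.outcome)
    Z = np.column_stack([gd.methylation.values, gd.expression,
                         gd.covariates.values])[order]
    p = Z.shape[1]

    def solve(tau, beta0=None):
        pen = np.zeros(p)
        pen[:K] = 1.0 / tau
        return _newton(t, d, Z, pen, beta0=beta0)

    if tau3 is not None:
        chosen = float(tau3)
        grid = None
    else:
        if isinstance(tau3_grid, str):
            grid = (TAU3_GRID_FAST if tau3_grid == "fast"
                    else TAU3_GRID_DEFAULT)
            if tau3_grid == "fast":
                refine = False
        else:
            grid = np.asarray(tau3_grid, dtype=float)
        crits = np.full(len(grid), -np.inf)
        warm = None
        fits = [None] * len(grid)
        for j, tau in enumerate(grid):
            res = solve(tau, beta0=warm)
            theta, _, ll_j, _, neg_hess_j, conv_j, _ = res
            warm = theta
            fits[j] = res
            crits[j] = _laplace_criterion(tau, ll_j, theta[:K],
                                          neg_hess_j, K)
        j_best = int(np.nanargmax(crits))
        chosen = float(grid[j_best])
        if refine and 0 < j_best < len(grid) - 1:
            lo, hi = np.log(grid[j_best - 1]), np.log(grid[j_best + 1])

            def neg_crit(log_tau):
                tau = float(np.exp(log_tau))
                th, _, ll_t, _, nh, _, _ = solve(tau, beta0=fits[j_best][0])
                return -_laplace_criterion(tau, ll_t, th[:K], nh, K)

            res = minimize_scalar(neg_crit, bounds=(lo, hi),
                                  method="bounded",
                                  options={"xatol": 1e-3})
            if -res.fun > crits[j_best]:
                chosen = float(np.exp(res.x))

    theta, _, ll, grad, neg_hess, converged, it = solve(
        chosen, beta0=None if grid is None else fits[j_best][0])
    try:
        cov = np.linalg.inv(neg_hess)
        se_beta = float(np.sqrt(cov[K, K]))
    except np.linalg.LinAlgError:
        se_beta = np.nan
        converged = False
    boundary = (grid is not None
                and (chosen <= grid[0] * 1.0001
                     or chosen >= grid[-1] * 0.9999))
    return CoxlmmFit(beta_hat=float(theta[K]), se_beta=se_beta,
                     gamma_hat=theta[:K], tau3_hat=chosen,
                     w3_hat=theta[K + 1:], converged=converged,
                     loglik=float(ll), tau3_at_boundary=boundary,
                     n_iter=it)


def wald_test_beta(fit: CoxlmmFit) -> float:
    """Two-sided Wald p-value for the mediator effect beta."""
    if not fit.converged:
        raise ValueError("coxlmm fit did not converge")
    if not np.isfinite(fit.se_beta) or fit.se_beta <= 0:
        raise ValueError("standard error of beta is not finite")
    z = fit.beta_hat / fit.se_beta
    return float(2.0 * stats.norm.sf(abs(z)))
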