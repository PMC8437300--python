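"""Passenger-methylation screen: reverse multivariate score test.

For genes flagged as mediators, the causal arrow may in fact run from
expression to methylation (a "passenger" methylation event).  The screen
regresses the CpG block on expression in a multivariate model
``M = G btilde + X W + E`` with ``btilde_k ~ N(0, tau)`` and tests
``H0: btilde = 0`` (tau = 0) by the variance-component score

    Q_M = || G' (M - mu_hat) V_hat^-1 ||^2,

where mu_hat are the per-CpG covariate fits and V_hat the residual
covariance across CpGs.  The null reference is a mixture of chi-squares
with weights (G_res' G_res) * eigenvalues(V_hat^-1), G_res the
covariate-residualized expression.  Significance over the mediating-gene
set is controlled by Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._quadform import mixture_chisq_tail
from .core_data import GeneDataset

__all__ = ["ReverseTestResult", "reverse_score_test", "flag_passengers"]

#: ridge inflation applied to V_hat when its condition number exceeds 1e8
RIDGE_DELTA = 1e-4
COND_MAX = 1e8


@dataclass
class ReverseTestResult:
    q_m: float
    p_value: float
    passenger_flag: bool = False


def reverse_score_test(gd: GeneDataset) -> ReverseTestResult:
    """Multivariate variance-component score test of expression on the
    CpG block of one gene."""
    M = gd.methylation.values
    n, K = M.shape
    D = gd.covariates.with_intercept()
    p = D.shape[1]
    if K >= n - p:
        # V_hat would be singular without shrinkage; regularization below
        # still requires some residual degrees of freedom
        if K >= n - 1:
            raise ValueError("more CpGs than residual degrees of freedom")
    Q, _ = np.linalg.qr(D)
    R = M - Q @ (Q.T @ (M))          # M - mu_hat
    g = gd.expression - Q @ (Q.T @ gd.expression)
    V = (R.T @ R) / max(n - p, 1)
    w, U = np.linalg.eigh(V)
    if w[0] <= 0 or w[-1] / max(w[0], 1e-300) > COND_MAX:
        V = V + RIDGE_DELTA * np.mean(np.diag(V)) * np.eye(K)
        w, U = np.linalg.eigh(V)
        if w[0] <= 0:
            raise ValueError("residual covariance singular even after "
                             "ridge regularization")
    Vinv = (U / w) @ U.T
    score = g @ R @ Vinv
    q_m = float(score @ score)
    gg = float(g @ g)
    lam = gg / w                      # eigenvalues of gg * V^-1
    p_val = 1.0 if q_m <= 0 else mixture_chisq_tail(q_m, lam)
    return ReverseTestResult(q_m=q_m, p_value=p_val)


def flag_passengers(results: list[ReverseTestResult],
                    alpha: float = 0.05) -> np.ndarray:
    """Bonferroni flags over the mediating genes actually tested:
    flag gene i iff p_i < alpha / len(results)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    m = len(results)
    if m == 0:
        return np.zeros(0, dtype=bool)
    flags = np.array([r.p_value < alpha / m for r in results])
    for r, f in zip(results, flags):
        r.passenger_flag = bool(f)
    return flags
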