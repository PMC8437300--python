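"""Mixture-null calibration of the max-P mediation statistic.

The composite null of no mediation is a union of three states: exposures
affect the mediator but not vice versa (H10), the mediator affects the
outcome only (H01), or neither path exists (H00).  Under the composite
null the max-P statistic ``Pmax = max(P_alpha, P_beta)`` has CDF

    Pr(Pmax <= u | H0) = k10 * p10(u) * u + k01 * p01(u) * u + k00 * u^2

where (k10, k01, k00) are the null-component proportions and p10 / p01
the power curves of the stage tests under their respective alternatives.
This module estimates the proportions (Storey-type pi0 estimators under
a working independence assumption), estimates the power curves by
Grenander (least-concave-majorant) deconvolution of the pooled p-value
CDFs, evaluates the mixture-null CDF, and converts each gene's Pmax into
an adjusted significance value on which FWER or FDR control is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["NullProportions", "AltPowerCurve", "estimate_pi0",
           "estimate_null_proportions", "grenander_alt_cdf",
           "pmax_null_cdf", "iusmmt_pvalues", "significance_control",
           "MixtureCalibration"]

_DEGENERATE_PI0 = 1.0 - 1e-6


@dataclass
class NullProportions:
    """Weights of the three null components plus the alternative mass."""

    k00: float
    k01: float
    k10: float
    k11: float

    def __post_init__(self) -> None:
        for name in ("k00", "k01", "k10", "k11"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.k00 + self.k01 + self.k10 + self.k11
        if abs(total - 1.0) > 1e-8:
            raise ValueError("proportions must sum to 1")

    @property
    def null_mass(self) -> float:
        return self.k00 + self.k01 + self.k10

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.k00, self.k01, self.k10, self.k11)


class AltPowerCurve:
    """Monotone estimated CDF of a stage p-value under its alternative.

    Piecewise-linear, with F1(0) = 0 and F1(1) = 1; evaluates like a
    function on [0, 1].
    """

    def __init__(self, knots_x: np.ndarray, knots_y: np.ndarray):
        x = np.asarray(knots_x, dtype=float)
        y = np.asarray(knots_y, dtype=float)
        y = np.clip(np.maximum.accumulate(y), 0.0, 1.0)
        if x[0] > 0:
            x = np.insert(x, 0, 0.0)
            y = np.insert(y, 0, 0.0)
        if x[-1] < 1:
            x = np.append(x, 1.0)
            y = np.append(y, 1.0)
        y[0], y[-1] = 0.0, 1.0
        self._x, self._y = x, y

    @classmethod
    def identity(cls) -> "AltPowerCurve":
        return cls(np.array([0.0, 1.0]), np.array([0.0, 1.0]))

    def __call__(self, u):
        return np.interp(u, self._x, self._y)


def estimate_pi0(pvalues, lam: float = 0.5) -> float:
    """Storey estimator of the null proportion:
    ``#{p > lam} / ((1 - lam) * S)``, truncated to [0, 1]."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("cannot estimate pi0 from an empty p-value set")
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie in (0, 1)")
    if p.size < 100:
        warnings.warn("fewer than 100 p-values; pi0 estimate is unstable",
                      stacklevel=2)
    pi0 = np.sum(p > lam) / ((1.0 - lam) * p.size)
    return float(min(max(pi0, 0.0), 1.0))


def estimate_null_proportions(p_alpha, p_beta,
                              lam: float = 0.5) -> NullProportions:
    """Estimate (k00, k01, k10, k11) from the two stage p-value series
    under the working independence assumption
    ``k00 = pi0a * pi0b, k10 = (1 - pi0a) * pi0b, ...`` with negatives
    clipped to zero and the 4-vector renormalized."""
    pa = np.asarray(p_alpha, dtype=float).ravel()
    pb = np.asarray(p_beta, dtype=float).ravel()
    if pa.size != pb.size:
        raise ValueError("p_alpha and p_beta must have equal length")
    pi0a = estimate_pi0(pa, lam)
    pi0b = estimate_pi0(pb, lam)
    raw = np.array([pi0a * pi0b,            # k00
                    pi0a * (1.0 - pi0b),    # k01
                    (1.0 - pi0a) * pi0b,    # k10
                    1.0 - pi0a * pi0b - pi0a * (1 - pi0b)
                    - (1 - pi0a) * pi0b])   # k11 remainder
    raw = np.clip(raw, 0.0, 1.0)
    raw /= raw.sum()
    return NullProportions(k00=raw[0], k01=raw[1], k10=raw[2], k11=raw[3])


def _lcm_cdf_knots(pvalues: np.ndarray):
    """Least concave majorant of the empirical CDF on [0, 1]
    (the Grenander distribution estimator), as upper-hull knots."""
    p = np.sort(np.asarray(pvalues, dtype=float).ravel())
    n = p.size
    xs = np.concatenate([[0.0], p, [1.0]])
    ys = np.concatenate([[0.0], np.arange(1, n + 1) / n, [1.0]])
    # Andrew's monotone-chain upper hull (kept points = LCM vertices)
    hull: list[int] = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            cross = ((xs[k] - xs[j]) * (ys[i] - ys[j])
                     - (ys[k] - ys[j]) * (xs[i] - xs[j]))
            if cross >= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return xs[hull], ys[hull]


def grenander_alt_cdf(pvalues, pi0: float) -> AltPowerCurve:
    """Deconvolve the alternative p-value CDF from the pooled series.

    F1(u) = clip_monotone((F_hat(u) - pi0 * u) / (1 - pi0)) with F_hat
    the Grenander (LCM) estimate of the pooled CDF; degenerates to the
    identity (uniform) when pi0 ~ 1.
    """
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError("pi0 must lie in [0, 1]")
    if pi0 >= _DEGENERATE_PI0:
        return AltPowerCurve.identity()
    hx, hy = _lcm_cdf_knots(np.asarray(pvalues, dtype=float).ravel())
    f1 = (hy - pi0 * hx) / (1.0 - pi0)
    return AltPowerCurve(hx, f1)


def pmax_null_cdf(u, props: NullProportions, p10: AltPowerCurve,
                  p01: AltPowerCurve, normalize: bool = True):
    """Mixture-null CDF of Pmax at threshold(s) u.

    With ``normalize=True`` (default) the three-component mass is
    renormalized by the total null mass so that the conditional CDF is a
    proper distribution when k11 > 0.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr < 0) | (u_arr > 1)):
        raise ValueError("u must lie in [0, 1]")
    if props.null_mass <= 0:
        raise ValueError("no null mass (k11 = 1); mixture CDF undefined")
    val = (props.k10 * p10(u_arr) * u_arr
           + props.k01 * p01(u_arr) * u_arr
           + props.k00 * u_arr ** 2)
    if normalize:
        val = val / props.null_mass
    out = np.clip(val, 0.0, 1.0)
    return float(out) if np.isscalar(u) else out


@dataclass
class MixtureCalibration:
    """Per-gene adjusted mediation significance plus the fitted null."""

    table: pd.DataFrame
    proportions: NullProportions
    p10: AltPowerCurve
    p01: AltPowerCurve


def iusmmt_pvalues(p_alpha, p_beta, lam: float = 0.5,
                   normalize: bool = True) -> MixtureCalibration:
    """Mixture-adjusted mediation significance for every gene.

    Returns a table with per-gene ``p_max`` (the naive max-P statistic,
    itself a valid intersection-union p-value) and ``p_iusmmt`` (the
    estimated mixture-null CDF evaluated at Pmax), which dominates
    ``p_max`` elementwise.
    """
    pa = np.asarray(p_alpha, dtype=float).ravel()
    pb = np.asarray(p_beta, dtype=float).ravel()
    if pa.size != pb.size:
        raise ValueError("p_alpha and p_beta must have equal length")
    props = estimate_null_proportions(pa, pb, lam)
    pi0a = props.k00 + props.k01  # P(alpha null)
    pi0b = props.k00 + props.k10  # P(beta null)
    p10 = grenander_alt_cdf(pa, pi0a)
    p01 = grenander_alt_cdf(pb, pi0b)
    pmax = np.maximum(pa, pb)
    adjusted = pmax_null_cdf(pmax, props, p10, p01, normalize=normalize)
    table = pd.DataFrame({"p_alpha": pa, "p_beta": pb, "p_max": pmax,
                          "p_iusmmt": adjusted})
    return MixtureCalibration(table=table, proportions=props,
                              p10=p10, p01=p01)


def significance_control(adjusted, method: str = "fdr",
                         level: float = 0.05) -> np.ndarray:
    """Boolean rejection flags under family-wise (Bonferroni) or false
    discovery rate (Benjamini-Hochberg) control of the adjusted values."""
    adj = np.asarray(adjusted, dtype=float).ravel()
    if np.any((adj < 0) | (adj > 1)):
        raise ValueError("adjusted values must lie in [0, 1]")
    if not 0.0 < level < 1.0:
        raise ValueError("control level must lie in (0, 1)")
    key = {"fwer": "bonferroni", "bonferroni": "bonferroni",
           "fdr": "fdr_bh", "bh": "fdr_bh"}.get(str(method).lower())
    if key is None:
        raise ValueError(f"unknown control method: {method}")
    reject, *_ = multipletests(adj, alpha=level, method=key)
    return reject
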