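"""Goodness-of-fit battery: RMSEA with noncentral 90% CI, CFI, NNFI, AIC.

The incremental indices (CFI, NNFI) are computed against the independence
baseline — free item variances and means, zero covariances, no cross-group
constraints — which has a closed-form ML solution.  The multi-group RMSEA
uses the sqrt(G) multiplier convention; since decisions rest on
between-model deltas rather than absolute values, the convention cancels
out of every comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import ncx2

from .data_io import GroupSummary

__all__ = ["FitIndexSet", "baseline_stat", "rmsea", "cfi_nnfi", "aic", "compute_indices"]


@dataclass
class FitIndexSet:
    T: float
    df: int
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    nnfi: float
    aic: float
    T_baseline: float
    df_baseline: int
    N: int
    G: int

    def to_dict(self) -> dict:
        return {
            "chisq": self.T, "df": self.df,
            "rmsea": self.rmsea, "rmsea_ci90": list(self.rmsea_ci),
            "cfi": self.cfi, "nnfi": self.nnfi, "aic": self.aic,
            "baseline_chisq": self.T_baseline, "baseline_df": self.df_baseline,
        }


def baseline_stat(groups: list[GroupSummary]) -> tuple[float, int]:
    """Chi-square and df of the independence-with-free-means baseline.

    Per group the ML solution is exact (variances = sample variances, means =
    sample means), so F_g = sum_i ln s_ii - ln|S|; df is G * p(p-1)/2.
    """
    N = sum(g.n for g in groups)
    G = len(groups)
    F = 0.0
    for g in groups:
        w = (g.n - 1.0) / (N - G)
        sign, logdet = np.linalg.slogdet(g.S)
        if sign <= 0:
            raise np.linalg.LinAlgError("sample covariance not positive definite")
        F += w * (float(np.sum(np.log(np.diag(g.S)))) - logdet)
    p = groups[0].p
    df_b = G * p * (p - 1) // 2
    return (N - G) * F, df_b


def rmsea(T: float, df: int, N: int, G: int = 1) -> tuple[float, tuple[float, float]]:
    """RMSEA point estimate and 90% noncentral-chi-square CI.

    point = sqrt(G) * sqrt(max(T - df, 0) / (df * (N - G))); the CI maps the
    noncentrality bounds solving P(X2_{df,lam_L} >= T) = 0.95 and
    P(X2_{df,lam_U} >= T) = 0.05 through the same transformation.
    """
    if df <= 0:
        raise ValueError("RMSEA requires df > 0")
    if N <= G:
        raise ValueError("RMSEA requires N > G")

    def lam_to_rmsea(lam: float) -> float:
        return float(np.sqrt(G) * np.sqrt(max(lam, 0.0) / (df * (N - G))))

    point = lam_to_rmsea(T - df)

    def tail(lam: float) -> float:
        # P(X2_{df, lam} >= T); increasing in lam
        return float(ncx2.sf(T, df, lam)) if lam > 0 else float(ncx2.sf(T, df, 1e-12))

    def solve(prob: float) -> float:
        """Noncentrality with tail probability `prob` at T (0 if none)."""
        if tail(0.0) >= prob:
            return 0.0
        hi = max(T * 2, df * 2.0, 10.0)
        while tail(hi) < prob and hi < 1e9:
            hi *= 2
        return brentq(lambda l: tail(l) - prob, 0.0, hi, xtol=1e-10)

    lam_l = solve(0.05)   # lower bound: T at the 95th percentile
    lam_u = solve(0.95)   # upper bound: T at the 5th percentile
    return point, (lam_to_rmsea(lam_l), lam_to_rmsea(lam_u))


def cfi_nnfi(T: float, df: int, T_b: float, df_b: int) -> tuple[float, float]:
    """Comparative fit index and non-normed fit index (Tucker-Lewis).

    CFI = 1 - max(T - df, 0)/max(T_b - df_b, T - df, 0) with 0/0 -> 1.
    NNFI = ((T_b/df_b) - (T/df)) / ((T_b/df_b) - 1); may exceed 1 and is
    reported unclipped; undefined (NaN) when the baseline ratio is <= 1.
    """
    if df <= 0 or df_b <= 0:
        raise ValueError("df and df_b must be positive")
    num = max(T - df, 0.0)
    den = max(T_b - df_b, T - df, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    rb = T_b / df_b
    nnfi = float("nan") if rb <= 1.0 else (rb - T / df) / (rb - 1.0)
    return cfi, nnfi


def aic(T: float, q: int) -> float:
    """AIC on the chi-square scale: T + 2q (lower is better)."""
    if q < 0:
        raise ValueError("q must be nonnegative")
    return T + 2.0 * q


def compute_indices(fitted, groups: list[GroupSummary] | None = None) -> FitIndexSet:
    """Full index battery for a FittedModel."""
    if groups is None:
        groups = fitted._groups
    T_b, df_b = baseline_stat(groups)
    N = sum(g.n for g in groups)
    G = len(groups)
    point, ci = rmsea(fitted.T, fitted.df, N, G)
    cfi, nnfi = cfi_nnfi(fitted.T, fitted.df, T_b, df_b)
    return FitIndexSet(
        T=fitted.T, df=fitted.df, rmsea=point, rmsea_ci=ci,
        cfi=cfi, nnfi=nnfi, aic=aic(fitted.T, fitted.q),
        T_baseline=T_b, df_baseline=df_b, N=N, G=G,
    )
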