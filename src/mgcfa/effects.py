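"""Latent mean comparison (Hancock's d) and McDonald's omega reliability.

Once (at least partial) scalar invariance holds, the factor means of the
non-reference group — estimated relative to the reference group's means
fixed at zero — are interpretable as latent mean differences.  Hancock's d
standardizes such a difference by the pooled latent standard deviation, the
latent analogue of Cohen's d.  McDonald's omega summarizes how much of a
unit-weighted composite's variance a factor accounts for:
omega = (sum lambda)^2 phi / ((sum lambda)^2 phi + sum Theta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .estimation import FittedModel

__all__ = [
    "hancock_d",
    "FactorMeanDifference",
    "LatentMeanComparison",
    "latent_mean_comparison",
    "omega",
    "OmegaResult",
    "omega_table",
]


def hancock_d(m1: float, sd1: float, n1: int,
              m2: float, sd2: float, n2: int) -> float:
    """Standardized latent mean difference with (n-1)-weighted pooled SD.

    d = (m2 - m1) / sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2)).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("latent SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("pooled latent SD is zero")
    return float((m2 - m1) / pooled)


@dataclass
class FactorMeanDifference:
    factor: str
    mean_ref: float              # fixed at 0 by identification
    sd_ref: float
    mean_other: float
    se_other: float
    sd_other: float
    z: float
    p_value: float
    d: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class LatentMeanComparison:
    reference_group: str
    other_group: str
    n_ref: int
    n_other: int
    factors: list[FactorMeanDifference]

    def to_dict(self) -> dict:
        return {
            "reference_group": self.reference_group,
            "other_group": self.other_group,
            "n": [self.n_ref, self.n_other],
            "factors": [f.to_dict() for f in self.factors],
        }


def latent_mean_comparison(fitted: FittedModel) -> LatentMeanComparison:
    """Factor-mean estimates, z tests and Hancock's d from a fitted model.

    Requires a model fitted at scalar level or stricter (free non-reference
    factor means).  Latent SDs are the square roots of the model-implied
    factor variances per group; the large-sample z statistic is kappa / SE
    with SE from the fitted information matrix.
    """
    if not (fitted.spec.mean_structure
            and fitted.profile.free_factor_means_nonreference):
        raise ValueError(
            "latent mean comparison needs a model with free non-reference "
            "factor means (scalar level or stricter)"
        )
    if fitted.n_groups != 2:
        raise ValueError("latent mean comparison is defined for two groups")
    labels = fitted.group_labels
    ref = fitted.profile.reference_group or labels[0]
    ref_idx = labels.index(ref)
    oth_idx = 1 - ref_idx
    se = fitted.standard_errors()
    groups_n = [g.n for g in fitted._groups]
    rows = []
    for j, f in enumerate(fitted.spec.factors):
        kap = float(fitted.params[oth_idx].kappa[j])
        s = se.get(f"kappa[{f}]@{labels[oth_idx]}", float("nan"))
        sd_r = float(np.sqrt(fitted.params[ref_idx].Phi[j, j]))
        sd_o = float(np.sqrt(fitted.params[oth_idx].Phi[j, j]))
        z = kap / s if s and np.isfinite(s) and s > 0 else float("nan")
        p = 2 * norm.sf(abs(z)) if np.isfinite(z) else float("nan")
        d = hancock_d(0.0, sd_r, groups_n[ref_idx], kap, sd_o, groups_n[oth_idx])
        rows.append(FactorMeanDifference(
            factor=f, mean_ref=0.0, sd_ref=sd_r, mean_other=kap,
            se_other=float(s), sd_other=sd_o, z=float(z), p_value=float(p), d=d,
        ))
    return LatentMeanComparison(
        reference_group=ref, other_group=labels[oth_idx],
        n_ref=groups_n[ref_idx], n_other=groups_n[oth_idx], factors=rows,
    )


def omega(loadings, uniquenesses, factor_variance: float = 1.0) -> float:
    """McDonald's omega for one factor's items.

    omega = (sum lambda)^2 phi / ((sum lambda)^2 phi + sum Theta); with
    standardized inputs use phi = 1.
    """
    lam = np.asarray(loadings, dtype=float)
    th = np.asarray(uniquenesses, dtype=float)
    if lam.size < 2:
        raise ValueError("omega needs at least 2 items")
    if np.any(th <= 0):
        raise ValueError("uniquenesses must be positive")
    true_var = lam.sum() ** 2 * factor_variance
    den = true_var + th.sum()
    if den <= 0:
        raise ValueError("non-positive composite variance")
    return float(true_var / den)


@dataclass
class OmegaResult:
    factor: str
    group: str
    omega: float
    loadings: list[float]
    uniquenesses: list[float]
    factor_variance: float


def omega_table(fitted: FittedModel) -> list[OmegaResult]:
    """Omega per factor per group from a fitted model's parameters."""
    out = []
    items = list(fitted.spec.battery.item_names)
    for g, lab in enumerate(fitted.group_labels):
        ps = fitted.params[g]
        for j, f in enumerate(fitted.spec.factors):
            rows = [items.index(it) for it in fitted.spec.items_of(f)]
            lam = ps.Lambda[rows, j]
            th = ps.Theta[rows]
            out.append(OmegaResult(
                factor=f, group=lab,
                omega=omega(lam, th, float(ps.Phi[j, j])),
                loadings=lam.tolist(), uniquenesses=th.tolist(),
                factor_variance=float(ps.Phi[j, j]),
            ))
    return out
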