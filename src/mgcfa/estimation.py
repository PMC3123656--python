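"""Maximum-likelihood estimation of mean-and-covariance-structure CFA models.

The model for group g is

    Sigma_g = Lambda_g Phi_g Lambda_g' + diag(Theta_g)
    mu_g    = nu_g + Lambda_g kappa_g

with the normal-theory ML discrepancy

    F_g = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p + (xbar - mu)' Sigma^-1 (xbar - mu)

minimized jointly over groups as F = sum_g w_g F_g, w_g = (n_g - 1)/(N - G),
giving the test statistic T = (N - G) * F.  Cross-group equality constraints
(metric/scalar/uniqueness invariance, minus any partial-invariance
exemptions) are realized by mapping several parameter-matrix slots onto a
single underlying free parameter.

Variances are optimized on the log scale and factor covariance matrices
through their Cholesky factor, so implied covariance matrices stay positive
definite throughout.  Gradients are analytic; standard errors come from the
inverse of a numerically differentiated Hessian of (N - G)/2 * F at the
optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.optimize

from .data_io import GroupSummary
from .model_spec import ConstraintProfile, ModelSpec, degrees_of_freedom, free_parameter_count

__all__ = [
    "ParameterSet",
    "FittedModel",
    "implied_moments",
    "discrepancy",
    "fit",
    "standardize",
]

_THETA_FLOOR = 1e-6          # variance floor for Heywood cases
_CHOL_DIAG_FLOOR = 1e-4


@dataclass
class ParameterSet:
    """All parameters of one group's measurement model.

    ``Lambda`` is p x m with the marker entries fixed at 1, ``nu`` the item
    intercepts, ``Theta`` the residual (uniqueness) variances, ``Phi`` the
    factor covariance matrix and ``kappa`` the factor means.  Under a
    second-order layer, ``Phi`` is structured as
    ``Gamma phi2 Gamma' + diag(D)`` (phi2 fixed to 1 for identification).
    """

    Lambda: np.ndarray
    nu: np.ndarray
    Theta: np.ndarray
    Phi: np.ndarray
    kappa: np.ndarray
    Gamma: np.ndarray | None = None
    phi2: float = 1.0
    D: np.ndarray | None = None

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            Lambda=self.Lambda.copy(), nu=self.nu.copy(), Theta=self.Theta.copy(),
            Phi=self.Phi.copy(), kappa=self.kappa.copy(),
            Gamma=None if self.Gamma is None else self.Gamma.copy(),
            phi2=self.phi2,
            D=None if self.D is None else self.D.copy(),
        )

    def to_dict(self) -> dict:
        d = {
            "Lambda": self.Lambda.tolist(),
            "nu": self.nu.tolist(),
            "Theta": self.Theta.tolist(),
            "Phi": self.Phi.tolist(),
            "kappa": self.kappa.tolist(),
        }
        if self.Gamma is not None:
            d.update(Gamma=self.Gamma.tolist(), phi2=self.phi2, D=self.D.tolist())
        return d


def implied_moments(params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied covariance matrix and mean vector."""
    Lam = np.asarray(params.Lambda, dtype=float)
    p, m = Lam.shape
    Phi = np.asarray(params.Phi, dtype=float)
    if Phi.shape != (m, m):
        raise ValueError(f"Phi must be {m}x{m}, got {Phi.shape}")
    if len(params.nu) != p or len(params.Theta) != p or len(params.kappa) != m:
        raise ValueError("parameter dimensions inconsistent")
    Sigma = Lam @ Phi @ Lam.T + np.diag(params.Theta)
    mu = params.nu + Lam @ params.kappa
    return Sigma, mu


def discrepancy(summary: GroupSummary, Sigma: np.ndarray, mu: np.ndarray) -> float:
    """Normal-theory ML fit function for one group (zero iff perfect fit)."""
    p = summary.p
    sign_s, logdet_s = np.linalg.slogdet(summary.S)
    if sign_s <= 0:
        raise np.linalg.LinAlgError("sample covariance S is not positive definite")
    c, low = sla.cho_factor(Sigma, lower=True)
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
    Sinv_S = sla.cho_solve((c, low), summary.S)
    d = summary.xbar - mu
    quad = d @ sla.cho_solve((c, low), d)
    return float(logdet_sigma + np.trace(Sinv_S) - logdet_s - p + quad)


# ---------------------------------------------------------------------------
# Free-parameter layout
# ---------------------------------------------------------------------------

@dataclass
class _FreeParam:
    name: str
    transform: str                      # "id" | "log"
    slots: list[tuple[int, str, int, int]]   # (group, matrix, i, j)
    lower: float = -np.inf


class _Layout:
    """Maps the flat optimizer vector onto per-group parameter matrices."""

    def __init__(self, spec: ModelSpec, labels: list[str], profile: ConstraintProfile):
        self.spec = spec
        self.labels = labels
        self.profile = profile
        self.items = list(spec.battery.item_names)
        self.factors = list(spec.factors)
        self.p, self.m = spec.n_items, spec.n_factors
        G = len(labels)
        ref = profile.reference_group
        if ref is None:
            ref = labels[0]
        if ref not in labels:
            raise ValueError(f"reference group {ref!r} not among groups {labels}")
        self.ref_idx = labels.index(ref)

        self.params: list[_FreeParam] = []
        item_idx = {it: i for i, it in enumerate(self.items)}
        fac_idx = {f: j for j, f in enumerate(self.factors)}

        def add(name, transform, slots, lower=-np.inf):
            self.params.append(_FreeParam(name, transform, slots, lower))

        def cross_group(cls_: str, item: str) -> bool:
            return G > 1 and profile.is_equated(cls_, item)

        # loadings (non-marker)
        for it in self.items:
            if spec.is_marker(it):
                continue
            i, j = item_idx[it], fac_idx[spec.loading_pattern[it]]
            if cross_group("loading", it):
                add(f"loading[{it}]", "id", [(g, "lambda", i, j) for g in range(G)])
            else:
                for g in range(G):
                    add(f"loading[{it}]@{labels[g]}", "id", [(g, "lambda", i, j)])
        # intercepts
        if spec.mean_structure:
            for it in self.items:
                i = item_idx[it]
                if cross_group("intercept", it):
                    add(f"intercept[{it}]", "id", [(g, "nu", i, 0) for g in range(G)])
                else:
                    for g in range(G):
                        add(f"intercept[{it}]@{labels[g]}", "id", [(g, "nu", i, 0)])
        # uniquenesses (log scale, floored)
        lo = float(np.log(_THETA_FLOOR))
        for it in self.items:
            i = item_idx[it]
            if cross_group("uniqueness", it):
                add(f"uniqueness[{it}]", "log",
                    [(g, "theta", i, 0) for g in range(G)], lower=lo)
            else:
                for g in range(G):
                    add(f"uniqueness[{it}]@{labels[g]}", "log",
                        [(g, "theta", i, 0)], lower=lo)
        # factor covariance structure, always group-specific
        dlo = float(np.log(_CHOL_DIAG_FLOOR))
        for g in range(G):
            if spec.second_order:
                for f in self.factors:
                    add(f"gamma[{f}]@{labels[g]}", "id", [(g, "gamma", fac_idx[f], 0)])
                for f in self.factors:
                    add(f"disturbance[{f}]@{labels[g]}", "log",
                        [(g, "d", fac_idx[f], 0)], lower=lo)
            else:
                for j in range(self.m):
                    for k in range(j + 1):
                        tr = "log" if j == k else "id"
                        add(f"phi_chol[{j},{k}]@{labels[g]}", tr,
                            [(g, "phi_chol", j, k)],
                            lower=dlo if j == k else -np.inf)
        # factor means: fixed at 0 in reference group and below scalar level
        if spec.mean_structure and profile.free_factor_means_nonreference:
            for g in range(G):
                if g == self.ref_idx:
                    continue
                for f in self.factors:
                    add(f"kappa[{f}]@{labels[g]}", "id", [(g, "kappa", fac_idx[f], 0)])

        self.q = len(self.params)
        expected = free_parameter_count(spec, G, profile)
        assert self.q == expected, f"layout has {self.q} params, expected {expected}"

    # -- conversions ---------------------------------------------------
    def raw(self, x: np.ndarray) -> np.ndarray:
        out = x.copy()
        for k, fp in enumerate(self.params):
            if fp.transform == "log":
                out[k] = np.exp(x[k])
        return out

    def bounds(self) -> list[tuple[float, float]]:
        return [(fp.lower, np.inf) for fp in self.params]

    def build(self, x: np.ndarray) -> list[ParameterSet]:
        """Per-group ParameterSets from the flat vector."""
        G = len(self.labels)
        spec = self.spec
        mats = []
        for g in range(G):
            mats.append({
                "lambda": np.zeros((self.p, self.m)),
                "nu": np.zeros(self.p),
                "theta": np.full(self.p, np.nan),
                "phi_chol": np.zeros((self.m, self.m)),
                "gamma": np.zeros(self.m),
                "d": np.full(self.m, np.nan),
                "kappa": np.zeros(self.m),
            })
            for f, it in spec.markers.items():
                i = self.items.index(it)
                j = self.factors.index(f)
                mats[g]["lambda"][i, j] = 1.0
        raw = self.raw(np.asarray(x, dtype=float))
        for k, fp in enumerate(self.params):
            for (g, mat, i, j) in fp.slots:
                if mat in ("lambda", "phi_chol"):
                    mats[g][mat][i, j] = raw[k]
                else:
                    mats[g][mat][i] = raw[k]
        out = []
        for g in range(G):
            if spec.second_order:
                Gam = mats[g]["gamma"]
                D = mats[g]["d"]
                Phi = np.outer(Gam, Gam) + np.diag(D)
                ps = ParameterSet(
                    Lambda=mats[g]["lambda"], nu=mats[g]["nu"], Theta=mats[g]["theta"],
                    Phi=Phi, kappa=mats[g]["kappa"], Gamma=Gam, phi2=1.0, D=D,
                )
            else:
                L = mats[g]["phi_chol"]
                ps = ParameterSet(
                    Lambda=mats[g]["lambda"], nu=mats[g]["nu"], Theta=mats[g]["theta"],
                    Phi=L @ L.T, kappa=mats[g]["kappa"],
                )
            out.append(ps)
        return out

    def vector_from_paramsets(self, psets: list[ParameterSet]) -> np.ndarray:
        """Inverse of :meth:`build`; shared slots are averaged across groups."""
        G = len(self.labels)
        mats = []
        for g in range(G):
            ps = psets[g]
            slot = {
                "lambda": ps.Lambda, "nu": ps.nu, "theta": ps.Theta,
                "kappa": ps.kappa,
            }
            if self.spec.second_order:
                if ps.Gamma is not None:
                    slot["gamma"], slot["d"] = ps.Gamma, ps.D
                else:
                    # decompose Phi: equal-loading heuristic
                    m = self.m
                    off = ps.Phi[~np.eye(m, dtype=bool)]
                    c = float(np.mean(off)) if m > 1 else 0.0
                    c = max(c, 1e-4)
                    gam = np.full(m, np.sqrt(c))
                    slot["gamma"] = gam
                    slot["d"] = np.maximum(np.diag(ps.Phi) - c, 1e-4)
            else:
                Phi = ps.Phi.copy()
                jitter = 0.0
                for _ in range(8):
                    try:
                        L = np.linalg.cholesky(Phi + jitter * np.eye(self.m))
                        break
                    except np.linalg.LinAlgError:
                        jitter = max(2 * jitter, 1e-8)
                else:  # pragma: no cover
                    L = np.linalg.cholesky(np.diag(np.maximum(np.diag(Phi), 1e-4)))
                slot["phi_chol"] = L
            mats.append(slot)
        x = np.zeros(self.q)
        for k, fp in enumerate(self.params):
            vals = []
            for (g, mat, i, j) in fp.slots:
                arr = mats[g][mat]
                vals.append(arr[i, j] if arr.ndim == 2 else arr[i])
            v = float(np.mean(vals))
            if fp.transform == "log":
                x[k] = np.log(max(v, _THETA_FLOOR))
                x[k] = max(x[k], fp.lower)
            else:
                x[k] = v
        return x


# ---------------------------------------------------------------------------
# Objective and gradient
# ---------------------------------------------------------------------------

def _group_value_grad(summary: GroupSummary, ps: ParameterSet):
    """F_g and its gradients w.r.t. the raw parameter matrices."""
    Sigma, mu = implied_moments(ps)
    p = summary.p
    c, low = sla.cho_factor(Sigma, lower=True)
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
    A = sla.cho_solve((c, low), np.eye(p))          # Sigma^-1
    d = summary.xbar - mu
    Ad = A @ d
    AS = A @ summary.S
    sign_s, logdet_s = np.linalg.slogdet(summary.S)
    if sign_s <= 0:
        raise np.linalg.LinAlgError("sample covariance S is not positive definite")
    F = logdet_sigma + np.trace(AS) - logdet_s - p + d @ Ad

    Gm = A - AS @ A - np.outer(Ad, Ad)              # dF/dSigma (symmetric)
    h = -2.0 * Ad                                   # dF/dmu
    dLam = 2.0 * Gm @ ps.Lambda @ ps.Phi + np.outer(h, ps.kappa)
    dnu = h
    dTheta = np.diag(Gm).copy()
    M = ps.Lambda.T @ Gm @ ps.Lambda                # dF/dPhi (full)
    dkappa = ps.Lambda.T @ h
    return float(F), {"lambda": dLam, "nu": dnu, "theta": dTheta,
                      "phi_full": M, "kappa": dkappa}


def _objective(x, layout: _Layout, groups: list[GroupSummary], weights: np.ndarray):
    psets = layout.build(x)
    F = 0.0
    grads = []
    for g, (summ, ps) in enumerate(zip(groups, psets)):
        Fg, gr = _group_value_grad(summ, ps)
        F += weights[g] * Fg
        grads.append(gr)
    # chain into the flat vector
    raw = layout.raw(x)
    gx = np.zeros(layout.q)
    chol_grads = []
    dLs = []
    if layout.spec.second_order:
        # Phi = Gamma phi2 Gamma' + diag(D)
        for g, ps in enumerate(psets):
            M = grads[g]["phi_full"]
            chol_grads.append({"gamma": 2.0 * M @ ps.Gamma * ps.phi2,
                               "d": np.diag(M).copy()})
    else:
        # Phi = L L'  =>  dF/dL = 2 (dF/dPhi) L
        Ls = [np.zeros((layout.m, layout.m)) for _ in layout.labels]
        for k, fp in enumerate(layout.params):
            for (g, mat, i, j) in fp.slots:
                if mat == "phi_chol":
                    Ls[g][i, j] = raw[k]
        dLs = [2.0 * grads[g]["phi_full"] @ Ls[g] for g in range(len(layout.labels))]
    for k, fp in enumerate(layout.params):
        acc = 0.0
        for (g, mat, i, j) in fp.slots:
            w = weights[g]
            if mat == "lambda":
                acc += w * grads[g]["lambda"][i, j]
            elif mat == "nu":
                acc += w * grads[g]["nu"][i]
            elif mat == "theta":
                acc += w * grads[g]["theta"][i]
            elif mat == "kappa":
                acc += w * grads[g]["kappa"][i]
            elif mat == "phi_chol":
                acc += w * dLs[g][i, j]
            elif mat == "gamma":
                acc += w * chol_grads[g]["gamma"][i]
            elif mat == "d":
                acc += w * chol_grads[g]["d"][i]
        if fp.transform == "log":
            acc *= raw[k]
        gx[k] = acc
    return F, gx


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A converged (or best-effort) multi-group CFA solution."""

    spec: ModelSpec
    profile: ConstraintProfile
    group_labels: list[str]
    params: list[ParameterSet]
    F: float
    T: float
    df: int
    q: int
    n_total: int
    converged: bool
    n_iter: int
    grad_norm: float
    status: str
    heywood_items: list[tuple[str, str]] = field(default_factory=list)
    _layout: "_Layout" = None
    _x: np.ndarray = None
    _groups: list[GroupSummary] = None
    _se: dict[str, float] | None = None

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def implied(self, g: int) -> tuple[np.ndarray, np.ndarray]:
        return implied_moments(self.params[g])

    # -- standard errors ----------------------------------------------
    def standard_errors(self) -> dict[str, float]:
        """Per-free-parameter SEs from the inverse numeric Hessian.

        The Hessian of (N - G)/2 * F is differentiated numerically from the
        analytic gradient; SEs for log-scale parameters (variances) are
        mapped back to the raw scale by the delta method.
        """
        if self._se is not None:
            return self._se
        layout, x, groups = self._layout, self._x, self._groups
        weights = _weights(groups)
        scale = 0.5 * (self.n_total - self.n_groups)
        q = layout.q
        H = np.zeros((q, q))
        eps = 1e-5
        for k in range(q):
            xp = x.copy(); xp[k] += eps
            xm = x.copy(); xm[k] -= eps
            _, gp = _objective(xp, layout, groups, weights)
            _, gm = _objective(xm, layout, groups, weights)
            H[k] = scale * (gp - gm) / (2 * eps)
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        se_x = np.sqrt(np.maximum(np.diag(cov), 0.0))
        raw = layout.raw(x)
        se = {}
        for k, fp in enumerate(layout.params):
            jac = raw[k] if fp.transform == "log" else 1.0
            se[fp.name] = float(se_x[k] * abs(jac))
        self._se = se
        return se

    def free_parameter_values(self) -> dict[str, float]:
        raw = self._layout.raw(self._x)
        return {fp.name: float(raw[k]) for k, fp in enumerate(self._layout.params)}

    def to_dict(self) -> dict:
        return {
            "groups": self.group_labels,
            "T": self.T, "F": self.F, "df": self.df, "q": self.q,
            "converged": self.converged, "n_iter": self.n_iter,
            "grad_norm": self.grad_norm, "status": self.status,
            "heywood": [list(t) for t in self.heywood_items],
            "parameters": {
                lab: ps.to_dict() for lab, ps in zip(self.group_labels, self.params)
            },
        }


def _weights(groups: list[GroupSummary]) -> np.ndarray:
    n = np.array([g.n for g in groups], dtype=float)
    return (n - 1.0) / (n.sum() - len(groups))


def default_start(
    spec: ModelSpec, groups: list[GroupSummary]
) -> list[ParameterSet]:
    """Marker-covariance start values: markers 1, loadings s_im/s_mm,
    intercepts at observed means, uniquenesses at half the observed
    variances, Phi from the marker-item covariance block."""
    items = list(spec.battery.item_names)
    factors = list(spec.factors)
    p, m = spec.n_items, spec.n_factors
    midx = [items.index(spec.markers[f]) for f in factors]
    out = []
    for summ in groups:
        S, xbar = summ.S, summ.xbar
        Lam = np.zeros((p, m))
        for it, f in spec.loading_pattern.items():
            i, j = items.index(it), factors.index(f)
            if spec.is_marker(it):
                Lam[i, j] = 1.0
            else:
                smm = S[midx[j], midx[j]]
                Lam[i, j] = S[i, midx[j]] / smm if smm > 0 else 0.5
        Phi = 0.5 * S[np.ix_(midx, midx)].copy()
        # keep start PD
        try:
            np.linalg.cholesky(Phi)
        except np.linalg.LinAlgError:
            Phi = np.diag(np.maximum(np.diag(Phi), 1e-2))
        Theta = np.maximum(0.5 * np.diag(S), 1e-3)
        ps = ParameterSet(Lambda=Lam, nu=xbar.copy(), Theta=Theta,
                          Phi=Phi, kappa=np.zeros(m))
        if spec.second_order:
            diag = np.diag(Phi)
            off = Phi[~np.eye(m, dtype=bool)]
            c = float(np.clip(np.mean(off), 1e-3, 0.9 * diag.min())) if m > 1 else 0.1
            ps.Gamma = np.full(m, np.sqrt(c))
            ps.D = np.maximum(diag - c, 1e-3)
            ps.Phi = np.outer(ps.Gamma, ps.Gamma) + np.diag(ps.D)
        out.append(ps)
    return out


def fit(
    spec: ModelSpec,
    groups: list[GroupSummary],
    profile: ConstraintProfile | None = None,
    start: list[ParameterSet] | None = None,
    maxiter: int = 4000,
    gtol: float = 1e-7,
) -> FittedModel:
    """Fit the model by minimizing the group-weighted ML discrepancy."""
    if len(groups) == 0:
        raise ValueError("at least one group required")
    if profile is None:
        profile = ConstraintProfile(level="configural",
                                    reference_group=groups[0].label or None)
    labels = [g.label or f"group{i}" for i, g in enumerate(groups)]
    layout = _Layout(spec, labels, profile)
    df = degrees_of_freedom(spec, len(groups), profile)
    weights = _weights(groups)
    if start is None:
        start = default_start(spec, groups)
    x0 = layout.vector_from_paramsets(start)
    lo = np.array([b[0] for b in layout.bounds()])
    x0 = np.maximum(x0, lo + 1e-8)

    res = scipy.optimize.minimize(
        _objective, x0, args=(layout, groups, weights),
        jac=True, method="L-BFGS-B", bounds=layout.bounds(),
        options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                 "ftol": 1e-13, "gtol": gtol},
    )
    psets = layout.build(res.x)
    N = sum(g.n for g in groups)
    G = len(groups)
    F = float(res.fun)
    heywood = []
    for g, ps in enumerate(psets):
        for i, it in enumerate(layout.items):
            if ps.Theta[i] <= _THETA_FLOOR * 1.01:
                heywood.append((labels[g], it))
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm < 1e-3
    return FittedModel(
        spec=spec, profile=profile, group_labels=labels, params=psets,
        F=F, T=max((N - G) * F, 0.0), df=df, q=layout.q, n_total=N,
        converged=converged, n_iter=int(res.nit), grad_norm=grad_norm,
        status=str(res.message), heywood_items=heywood,
        _layout=layout, _x=res.x.copy(), _groups=list(groups),
    )


def standardize(params: ParameterSet, Sigma: np.ndarray | None = None) -> ParameterSet:
    """Rescale parameters to the standardized metric.

    Loadings become ``lambda * sqrt(Phi_jj) / sqrt(Sigma_ii)``, uniquenesses
    ``Theta_i / Sigma_ii``, intercepts ``nu_i / sqrt(Sigma_ii)``; Phi becomes
    the factor correlation matrix and kappa is expressed in latent-SD units.
    """
    if Sigma is None:
        Sigma, _ = implied_moments(params)
    sd_items = np.sqrt(np.diag(Sigma))
    if np.any(sd_items <= 0):
        raise ValueError("implied item variance must be positive")
    sd_fac = np.sqrt(np.diag(params.Phi))
    Lam = params.Lambda * sd_fac[None, :] / sd_items[:, None]
    Theta = params.Theta / np.diag(Sigma)
    nu = params.nu / sd_items
    Phi = params.Phi / np.outer(sd_fac, sd_fac)
    kappa = params.kappa / sd_fac
    return ParameterSet(Lambda=Lam, nu=nu, Theta=Theta, Phi=Phi, kappa=kappa)
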