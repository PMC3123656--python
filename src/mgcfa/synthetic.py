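"""Two-group synthetic CES-D-like data with a known factor structure.

The default generating parameters are the published unstandardized loadings,
intercepts and uniquenesses of the four-factor CES-D model for the Chinese
(n = 4903) and Dutch (n = 1903) elderly samples, together with the latent
means and SDs of the latent-mean comparison: the two groups share all
loadings, differ in the intercepts of Failure and Good, differ in the
uniquenesses of Depressed, Failure, Fearful, Good and Dislike, and the
second group's factor means sit below the first group's.  Factor
correlations are not published; the default is a uniform latent correlation
of 0.5 (all factors positively oriented after reverse coding), which is an
implementation assumption, not a published value.

Respondents are drawn as eta ~ N(kappa, Phi), e ~ N(0, diag(Theta)),
y = nu + Lambda eta + e.  Continuous responses are the default (the
analysis treats Likert items as continuous); optionally responses are
discretized to 1..4 through thresholds at the quartiles of each item's
reference-group marginal, and an MCAR mask (default <1% missing) is
applied.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_io import GROUP_COLUMN, ItemDataTable
from .estimation import ParameterSet, implied_moments
from .model_spec import ModelSpec, builtin_spec

__all__ = [
    "GeneratorConfig",
    "default_cesd_params",
    "default_config",
    "generate",
    "planted_noninvariance",
]

DEFAULT_SIZES = (4903, 1903)

# Latent correlations are not published.  The default is moderately
# heterogeneous — somatic complaints and depressive affect correlate more
# strongly with each other than either does with positive affect or
# interpersonal problems — which keeps the four-factor structure
# distinguishable from a second-order (single general factor) structure; a
# constant correlation matrix would be exactly second-order representable.
# Order: SOM, DEP, POS, INT (positive orientation after reverse coding).
DEFAULT_LATENT_CORR = np.array([
    [1.00, 0.65, 0.45, 0.40],
    [0.65, 1.00, 0.50, 0.55],
    [0.45, 0.50, 1.00, 0.35],
    [0.40, 0.55, 0.35, 1.00],
])

# Published four-factor solution (unstandardized; groups equal unless a pair
# is given).  Order matches the battery's analysis order.
_LOADINGS = {
    "Bothered": 1.00, "Appetite": 1.03, "Mind": 1.18, "Effort": 1.29,
    "Sleep": 1.07, "Talk": 1.02, "GetGoing": 1.26,
    "Blues": 1.00, "Depressed": 1.13, "Failure": 0.82, "Fearful": 0.91,
    "Lonely": 1.11, "Crying": 0.92, "Sad": 1.06,
    "Good": 1.00, "Hopeful": 1.66, "Happy": 2.30, "Enjoyed": 2.29,
    "Unfriendly": 1.00, "Dislike": 0.94,
}
_INTERCEPTS = {
    "Bothered": 0.69, "Appetite": 0.56, "Mind": 0.78, "Effort": 0.81,
    "Sleep": 0.88, "Talk": 0.74, "GetGoing": 0.70,
    "Blues": 0.52, "Depressed": 0.55, "Failure": (0.57, 0.30),
    "Fearful": 0.42, "Lonely": 0.57, "Crying": 0.50, "Sad": 0.56,
    "Good": (1.54, 0.68), "Hopeful": 1.36, "Happy": 1.16, "Enjoyed": 1.08,
    "Unfriendly": 0.44, "Dislike": 0.41,
}
_UNIQUENESSES = {
    "Bothered": 0.45, "Appetite": 0.37, "Mind": 0.39, "Effort": 0.40,
    "Sleep": 0.57, "Talk": 0.51, "GetGoing": 0.37,
    "Blues": 0.29, "Depressed": (0.30, 0.13), "Failure": (0.41, 0.09),
    "Fearful": (0.31, 0.14), "Lonely": 0.29, "Crying": 0.27, "Sad": 0.24,
    "Good": (1.20, 0.72), "Hopeful": 0.81, "Happy": 0.32, "Enjoyed": 0.32,
    "Unfriendly": 0.19, "Dislike": (0.23, 0.08),
}
_LATENT_MEANS = ((0.0, 0.0, 0.0, 0.0), (-0.261, -0.259, -0.125, -0.323))
_LATENT_SDS = ((0.482, 0.570, 0.354, 0.574), (0.324, 0.318, 0.329, 0.184))


def _pair(v) -> tuple[float, float]:
    return tuple(v) if isinstance(v, tuple) else (float(v), float(v))


def default_cesd_params(
    latent_corr: float | np.ndarray | None = None,
) -> tuple[ParameterSet, ParameterSet, tuple[int, int]]:
    """The published two-group four-factor parameter sets and sample sizes.

    ``latent_corr`` may be a scalar (uniform correlation) or a 4x4
    correlation matrix; the default is :data:`DEFAULT_LATENT_CORR`, an
    implementation assumption since the correlations are not published.
    """
    spec = builtin_spec("four_factor")
    items = list(spec.battery.item_names)
    factors = list(spec.factors)
    p, m = spec.n_items, spec.n_factors
    if latent_corr is None:
        R_base = DEFAULT_LATENT_CORR
    elif np.isscalar(latent_corr):
        R_base = np.full((m, m), float(latent_corr))
        np.fill_diagonal(R_base, 1.0)
    else:
        R_base = np.asarray(latent_corr, dtype=float)
    out = []
    for g in range(2):
        Lam = np.zeros((p, m))
        nu = np.zeros(p)
        Theta = np.zeros(p)
        for i, it in enumerate(items):
            j = factors.index(spec.loading_pattern[it])
            Lam[i, j] = _pair(_LOADINGS[it])[g]
            nu[i] = _pair(_INTERCEPTS[it])[g]
            Theta[i] = _pair(_UNIQUENESSES[it])[g]
        sds = np.asarray(_LATENT_SDS[g])
        Phi = R_base * np.outer(sds, sds)
        kappa = np.asarray(_LATENT_MEANS[g], dtype=float)
        out.append(ParameterSet(Lambda=Lam, nu=nu, Theta=Theta, Phi=Phi, kappa=kappa))
    return out[0], out[1], DEFAULT_SIZES


@dataclass
class GeneratorConfig:
    """Everything :func:`generate` needs, including the truth for tests."""

    spec: ModelSpec
    group_labels: tuple[str, str]
    params: tuple[ParameterSet, ParameterSet]
    sizes: tuple[int, int]
    seed: int = 0
    likert: bool = False
    missing_rate: float = 0.01
    edit_log: list[tuple[str, str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate <= 0.05):
            raise ValueError("missing_rate must be within [0, 0.05]")
        p = self.spec.n_items
        for n in self.sizes:
            if n < p + 1:
                raise ValueError(f"group size {n} < p + 1 = {p + 1}")
        for ps in self.params:
            np.linalg.cholesky(ps.Phi)  # raises on non-PD

    def to_dict(self) -> dict:
        return {
            "model": self.spec.to_dict(),
            "group_labels": list(self.group_labels),
            "sizes": list(self.sizes),
            "seed": self.seed,
            "likert": self.likert,
            "missing_rate": self.missing_rate,
            "params": [ps.to_dict() for ps in self.params],
            "edit_log": [list(e) for e in self.edit_log],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        spec = ModelSpec.from_dict(d["model"])
        params = tuple(
            ParameterSet(
                Lambda=np.asarray(p["Lambda"], dtype=float),
                nu=np.asarray(p["nu"], dtype=float),
                Theta=np.asarray(p["Theta"], dtype=float),
                Phi=np.asarray(p["Phi"], dtype=float),
                kappa=np.asarray(p["kappa"], dtype=float),
            )
            for p in d["params"]
        )
        return cls(
            spec=spec,
            group_labels=tuple(d["group_labels"]),
            params=params,
            sizes=tuple(int(n) for n in d["sizes"]),
            seed=int(d.get("seed", 0)),
            likert=bool(d.get("likert", False)),
            missing_rate=float(d.get("missing_rate", 0.01)),
            edit_log=[tuple(e) for e in d.get("edit_log", [])],
        )


def default_config(
    seed: int = 0,
    sizes: tuple[int, int] | None = None,
    likert: bool = False,
    missing_rate: float = 0.01,
    latent_corr: float | np.ndarray | None = None,
) -> GeneratorConfig:
    """The study conditions: published parameters, n = (4903, 1903)."""
    ps1, ps2, default_sizes = default_cesd_params(latent_corr)
    return GeneratorConfig(
        spec=builtin_spec("four_factor"),
        group_labels=("chinese", "dutch"),
        params=(ps1, ps2),
        sizes=tuple(sizes) if sizes is not None else default_sizes,
        seed=seed,
        likert=likert,
        missing_rate=missing_rate,
    )


def invariant_config(seed: int = 0, sizes: tuple[int, int] = (1000, 1000),
                     **kw) -> GeneratorConfig:
    """A fully invariant variant: both groups use group 1's measurement
    parameters (loadings, intercepts, uniquenesses); latent means and
    covariances keep their group-specific defaults."""
    cfg = default_config(seed=seed, sizes=sizes, **kw)
    ps1, ps2 = cfg.params[0], cfg.params[1].copy()
    ps2.Lambda = ps1.Lambda.copy()
    ps2.nu = ps1.nu.copy()
    ps2.Theta = ps1.Theta.copy()
    return GeneratorConfig(
        spec=cfg.spec, group_labels=cfg.group_labels, params=(ps1, ps2),
        sizes=cfg.sizes, seed=seed, likert=cfg.likert,
        missing_rate=cfg.missing_rate,
    )


def generate(config: GeneratorConfig) -> ItemDataTable:
    """Draw a two-group item table; fully reproducible from config.seed."""
    rng = np.random.default_rng(config.seed)
    spec = config.spec
    items = list(spec.battery.item_names)
    frames = []
    # Likert thresholds from the reference (first) group's implied marginals
    thresholds = None
    if config.likert:
        Sigma0, mu0 = implied_moments(config.params[0])
        sd0 = np.sqrt(np.diag(Sigma0))
        qs = norm.ppf([0.25, 0.5, 0.75])
        thresholds = mu0[:, None] + sd0[:, None] * qs[None, :]
    for g, (label, ps, n) in enumerate(
        zip(config.group_labels, config.params, config.sizes)
    ):
        eta = rng.multivariate_normal(ps.kappa, ps.Phi, size=n,
                                      method="cholesky")
        e = rng.standard_normal((n, spec.n_items)) * np.sqrt(ps.Theta)[None, :]
        y = ps.nu[None, :] + eta @ ps.Lambda.T + e
        if config.likert:
            y = 1.0 + (y[:, :, None] > thresholds[None, :, :]).sum(axis=2)
        if config.missing_rate > 0:
            mask = rng.random(y.shape) < config.missing_rate
            y = np.where(mask, np.nan, y.astype(float))
        df = pd.DataFrame(y, columns=items)
        df.insert(0, GROUP_COLUMN, label)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    return ItemDataTable(battery=spec.battery, data=data,
                         continuous=not config.likert)


_EDIT_CLASSES = ("loading", "intercept", "uniqueness")


def planted_noninvariance(
    base: GeneratorConfig,
    edits: list[tuple[str, str, str, float]],
) -> GeneratorConfig:
    """Additively perturb named parameters of one group.

    Each edit is (parameter-class, item, group-label, delta); the edit log is
    stored on the returned config so tests can track the planted truth.
    """
    cfg = copy.deepcopy(base)
    params = [ps.copy() for ps in cfg.params]
    items = list(cfg.spec.battery.item_names)
    factors = list(cfg.spec.factors)
    for cls_, item, group, delta in edits:
        if cls_ not in _EDIT_CLASSES:
            raise ValueError(f"unknown parameter class {cls_!r}")
        if item not in items:
            raise ValueError(f"unknown item {item!r}")
        if group not in cfg.group_labels:
            raise ValueError(f"unknown group {group!r}")
        g = cfg.group_labels.index(group)
        i = items.index(item)
        if cls_ == "loading":
            j = factors.index(cfg.spec.loading_pattern[item])
            params[g].Lambda[i, j] += delta
        elif cls_ == "intercept":
            params[g].nu[i] += delta
        else:
            params[g].Theta[i] += delta
            if params[g].Theta[i] <= 0:
                raise ValueError(f"edit makes uniqueness of {item!r} non-positive")
    return GeneratorConfig(
        spec=cfg.spec, group_labels=cfg.group_labels, params=tuple(params),
        sizes=cfg.sizes, seed=cfg.seed, likert=cfg.likert,
        missing_rate=cfg.missing_rate,
        edit_log=cfg.edit_log + [tuple(e) for e in edits],
    )
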