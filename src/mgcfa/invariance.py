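"""The measurement-invariance ladder and the partial-invariance search.

Four nested multi-group models are fitted in order — configural (same factor
pattern, all parameters group-specific, factor means fixed to 0), metric
(loadings equated), scalar (loadings + intercepts equated, factor means free
in non-reference groups), uniqueness (residual variances additionally
equated) — and each step is judged against the previous *accepted* step by
the change-in-fit rules dCFI < 0.01 and dRMSEA < 0.015 (both must hold by
default).  A rejected step may be retried as a partial-invariance model:
constraints of that step's class are released one at a time, largest
chi-square gain first, until the deltas satisfy the cutoffs or the
candidates are exhausted.  Marker loadings are never released (the latent
scale must stay anchored) and every factor keeps at least one equated
intercept (so the latent mean difference stays identified); items released
at the scalar level stay released at the uniqueness level.

Chi-square differences are computed and reported but never drive decisions;
with the sample sizes this method is aimed at they are essentially always
significant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from scipy.stats import chi2 as chi2_dist

from .data_io import GroupSummary
from .estimation import FittedModel, fit
from .fit_indices import FitIndexSet, compute_indices
from .model_spec import ConstraintProfile, ModelSpec

__all__ = [
    "CutoffConfig",
    "DeltaRecord",
    "InvarianceStep",
    "InvarianceReport",
    "compare_nested",
    "run_sequence",
    "partial_search",
]

LADDER = ("configural", "metric", "scalar", "uniqueness")
#: Parameter class newly constrained at each non-configural level.
NEW_CLASS = {"metric": "loading", "scalar": "intercept", "uniqueness": "uniqueness"}


@dataclass(frozen=True)
class CutoffConfig:
    """Decision rules for nested invariance comparisons."""

    delta_cfi_max: float = 0.01
    delta_rmsea_max: float = 0.015
    require_both: bool = True

    def __post_init__(self) -> None:
        if self.delta_cfi_max <= 0 or self.delta_rmsea_max <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class DeltaRecord:
    delta_chisq: float
    delta_df: int
    delta_cfi: float
    delta_rmsea: float
    p_value: float
    accepted: bool
    chisq_floored: bool = False

    def to_dict(self) -> dict:
        return {
            "delta_chisq": self.delta_chisq, "delta_df": self.delta_df,
            "delta_cfi": self.delta_cfi, "delta_rmsea": self.delta_rmsea,
            "p_value": self.p_value, "accepted": self.accepted,
        }


def compare_nested(
    free: tuple[FittedModel, FitIndexSet],
    restricted: tuple[FittedModel, FitIndexSet],
    cutoffs: CutoffConfig = CutoffConfig(),
) -> DeltaRecord:
    """Delta record for a restricted model against the freer model it nests in.

    dCFI = CFI_free - CFI_restricted and dRMSEA = RMSEA_restricted -
    RMSEA_free, so positive deltas mean deterioration.  The decision accepts
    when dCFI < delta_cfi_max and dRMSEA < delta_rmsea_max (both, by
    default; either one suffices when require_both is off).
    """
    mf, xf = free
    mr, xr = restricted
    ddf = mr.df - mf.df
    if ddf < 0:
        raise ValueError("restricted model must not have fewer df than the free model")
    dchi = mr.T - mf.T
    floored = dchi < 0
    dchi = max(dchi, 0.0)
    dcfi = xf.cfi - xr.cfi
    drmsea = xr.rmsea - xf.rmsea
    p = float(chi2_dist.sf(dchi, ddf)) if ddf > 0 else 1.0
    ok_cfi = dcfi < cutoffs.delta_cfi_max
    ok_rmsea = drmsea < cutoffs.delta_rmsea_max
    accepted = (ok_cfi and ok_rmsea) if cutoffs.require_both else (ok_cfi or ok_rmsea)
    return DeltaRecord(
        delta_chisq=float(dchi), delta_df=int(ddf), delta_cfi=float(dcfi),
        delta_rmsea=float(drmsea), p_value=float(p), accepted=bool(accepted),
        chisq_floored=bool(floored),
    )


@dataclass
class InvarianceStep:
    level: str
    label: str                      # e.g. "metric", "partial scalar"
    model: FittedModel
    indices: FitIndexSet
    deltas: DeltaRecord | None      # vs previous accepted step (None for first)
    decision: str                   # accepted | rejected | partial-accepted
    released: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "level": self.level, "label": self.label,
            "decision": self.decision,
            "released": [list(t) for t in self.released],
            "indices": self.indices.to_dict(),
            "deltas": None if self.deltas is None else self.deltas.to_dict(),
            "df": self.model.df,
            "converged": self.model.converged,
        }


@dataclass
class InvarianceReport:
    steps: list[InvarianceStep]
    final_accepted: InvarianceStep | None

    def step(self, label: str) -> InvarianceStep:
        for s in self.steps:
            if s.label == label:
                return s
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {
            "steps": [s.to_dict() for s in self.steps],
            "final_accepted": None if self.final_accepted is None
            else self.final_accepted.label,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=1, **kw)


def _profile_for_level(
    level: str,
    reference_group: str,
    inherited: frozenset[tuple[str, str]],
) -> ConstraintProfile:
    keep = {
        "configural": (),
        "metric": ("loading",),
        "scalar": ("loading", "intercept"),
        "uniqueness": ("loading", "intercept", "uniqueness"),
    }[level]
    ex = frozenset((c, i) for (c, i) in inherited if c in keep)
    if level == "uniqueness":
        # items with released intercepts also keep their uniquenesses free
        ex = ex | frozenset(
            ("uniqueness", i) for (c, i) in inherited if c == "intercept"
        )
    return ConstraintProfile(level=level, exemptions=ex,
                             reference_group=reference_group)


def _fit_step(spec, groups, profile, warm: FittedModel | None) -> tuple[FittedModel, FitIndexSet]:
    start = warm.params if warm is not None else None
    m = fit(spec, groups, profile, start=start)
    return m, compute_indices(m, groups)


def partial_search(
    spec: ModelSpec,
    groups: list[GroupSummary],
    failed_profile: ConstraintProfile,
    failed_fit: tuple[FittedModel, FitIndexSet],
    previous_accepted: tuple[FittedModel, FitIndexSet],
    cutoffs: CutoffConfig = CutoffConfig(),
) -> tuple[list[tuple[str, str]], tuple[FittedModel, FitIndexSet], DeltaRecord]:
    """Release equality constraints of the failed step's class one at a time.

    Every currently-equated parameter of the class newly constrained at this
    level (marker anchors excluded for loadings and intercepts) is tried in a
    separate refit; the candidate with the largest chi-square improvement is
    released.  This repeats until the deltas against the previous accepted
    model satisfy the cutoffs or no candidates remain.  Exact refits are used
    rather than modification-index approximations; ties are broken by item
    order.
    """
    cls_ = NEW_CLASS[failed_profile.level]
    profile = failed_profile
    current = failed_fit
    released: list[tuple[str, str]] = []
    deltas = compare_nested(previous_accepted, current, cutoffs)

    def _releasable(prof: ConstraintProfile, it: str) -> bool:
        if not prof.is_equated(cls_, it):
            return False
        if cls_ == "loading":
            # marker loadings are fixed anchors, never free to release
            return not spec.is_marker(it)
        if cls_ == "intercept":
            # keep >=1 equated intercept per factor so the factor mean
            # difference stays identified
            fac = spec.loading_pattern[it]
            return any(
                prof.is_equated("intercept", other)
                for other in spec.items_of(fac) if other != it
            )
        return True

    while not deltas.accepted:
        candidates = [
            it for it in spec.battery.item_names if _releasable(profile, it)
        ]
        if not candidates:
            break
        best = None
        for it in candidates:
            trial_profile = profile.with_exemption(cls_, it)
            trial = _fit_step(spec, groups, trial_profile, warm=current[0])
            gain = current[0].T - trial[0].T
            if best is None or gain > best[0] + 1e-9:
                best = (gain, it, trial_profile, trial)
        _, it, profile, current = best
        released.append((cls_, it))
        deltas = compare_nested(previous_accepted, current, cutoffs)
    return released, current, deltas


def run_sequence(
    spec: ModelSpec,
    groups: list[GroupSummary],
    cutoffs: CutoffConfig = CutoffConfig(),
    allow_partial: bool = True,
    reference_group: str | None = None,
) -> InvarianceReport:
    """Run the configural -> metric -> scalar -> uniqueness ladder.

    Each step is compared with the previous accepted (possibly partial)
    model; on rejection, if ``allow_partial``, the partial-invariance search
    is invoked and its result recorded as a separate step.  Scalar-level
    releases are inherited by the uniqueness level.
    """
    if len(groups) < 2:
        raise ValueError("invariance testing requires at least two groups")
    ref = reference_group or (groups[0].label or "group0")
    steps: list[InvarianceStep] = []
    inherited: frozenset[tuple[str, str]] = frozenset()
    prev_accepted: tuple[FittedModel, FitIndexSet] | None = None
    prev_step: InvarianceStep | None = None
    warm: FittedModel | None = None

    for level in LADDER:
        profile = _profile_for_level(level, ref, inherited)
        current = _fit_step(spec, groups, profile, warm=warm)
        warm = current[0]
        if prev_accepted is None:
            step = InvarianceStep(level=level, label=level, model=current[0],
                                  indices=current[1], deltas=None,
                                  decision="accepted")
            steps.append(step)
            prev_accepted, prev_step = current, step
            continue
        deltas = compare_nested(prev_accepted, current, cutoffs)
        if deltas.accepted:
            step = InvarianceStep(level=level, label=level, model=current[0],
                                  indices=current[1], deltas=deltas,
                                  decision="accepted")
            steps.append(step)
            prev_accepted, prev_step = current, step
            continue
        # full-constraint step rejected
        steps.append(InvarianceStep(level=level, label=level, model=current[0],
                                    indices=current[1], deltas=deltas,
                                    decision="rejected"))
        if not allow_partial:
            break
        released, partial, pdeltas = partial_search(
            spec, groups, profile, current, prev_accepted, cutoffs,
        )
        label = f"partial {level}"
        decision = "partial-accepted" if pdeltas.accepted else "rejected"
        step = InvarianceStep(level=level, label=label, model=partial[0],
                              indices=partial[1], deltas=pdeltas,
                              decision=decision, released=released)
        steps.append(step)
        if not pdeltas.accepted:
            break
        inherited = inherited | frozenset(released) | partial[0].profile.exemptions
        prev_accepted, prev_step = partial, step
        warm = partial[0]

    final = None
    for s in steps:
        if s.decision in ("accepted", "partial-accepted"):
            final = s
    return InvarianceReport(steps=steps, final_accepted=final)
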