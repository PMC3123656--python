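"""Factor-model specifications, constraint profiles, and parameter bookkeeping.

A :class:`ModelSpec` describes a congeneric confirmatory factor model over an
:class:`ItemBattery`: each item loads on exactly one factor, one marker item
per factor has its loading fixed to 1 to set the latent scale, and an optional
second-order layer places a single general factor above the first-order
factors.  A :class:`ConstraintProfile` describes which parameter classes are
equated across groups in a multi-group analysis (the configural / metric /
scalar / uniqueness ladder) and which individual items are exempted from those
equalities (partial invariance).

Free-parameter and degrees-of-freedom counting lives here so that every fitted
model's df can be derived analytically, independent of the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "ItemBattery",
    "ModelSpec",
    "ConstraintProfile",
    "CESD_ITEMS",
    "CESD_REVERSED",
    "builtin_spec",
    "free_parameter_count",
    "degrees_of_freedom",
    "validate_spec",
]

# Parameter classes that a ConstraintProfile can equate across groups.
PARAM_CLASSES = ("loading", "intercept", "uniqueness")

#: Classes equated across groups at each invariance level.
LEVEL_CLASSES: dict[str, tuple[str, ...]] = {
    "configural": (),
    "metric": ("loading",),
    "scalar": ("loading", "intercept"),
    "uniqueness": ("loading", "intercept", "uniqueness"),
}

#: The 20 CES-D items in analysis order (grouped by factor: somatic
#: complaints, depressive affect, positive affect, interpersonal problems).
CESD_ITEMS = (
    "Bothered", "Appetite", "Mind", "Effort", "Sleep", "Talk", "GetGoing",
    "Blues", "Depressed", "Failure", "Fearful", "Lonely", "Crying", "Sad",
    "Good", "Hopeful", "Happy", "Enjoyed",
    "Unfriendly", "Dislike",
)

#: The four positive-affect items, answered in the opposite direction and
#: reverse-coded before analysis.
CESD_REVERSED = frozenset({"Good", "Hopeful", "Happy", "Enjoyed"})


@dataclass(frozen=True)
class ItemBattery:
    """An ordered set of Likert items with a common response scale."""

    item_names: tuple[str, ...]
    reverse_coded: frozenset[str] = frozenset()
    scale_min: int = 1
    scale_max: int = 4

    def __post_init__(self) -> None:
        if len(set(self.item_names)) != len(self.item_names):
            raise ValueError("item names must be unique")
        unknown = set(self.reverse_coded) - set(self.item_names)
        if unknown:
            raise ValueError(f"reverse_coded items not in battery: {sorted(unknown)}")
        if not self.scale_min < self.scale_max:
            raise ValueError("scale_min must be < scale_max")

    @property
    def n_items(self) -> int:
        return len(self.item_names)


def cesd_battery() -> ItemBattery:
    """The 20-item CES-D battery on its 1-4 frequency scale."""
    return ItemBattery(item_names=CESD_ITEMS, reverse_coded=CESD_REVERSED)


@dataclass(frozen=True)
class ModelSpec:
    """A single-loading ("congeneric") factor model over an item battery.

    Parameters
    ----------
    battery:
        The item battery the model is defined over.
    factors:
        Ordered factor labels.
    loading_pattern:
        Mapping item -> factor; every item belongs to exactly one factor.
    markers:
        Mapping factor -> marker item whose loading is fixed to 1.
    second_order:
        If true, a single second-order factor sits above the first-order
        factors: Phi = Gamma * phi2 * Gamma' + diag(D) with phi2 fixed to 1.
    mean_structure:
        If true the model includes item intercepts and factor means.
    """

    battery: ItemBattery
    factors: tuple[str, ...]
    loading_pattern: dict[str, str]
    markers: dict[str, str]
    second_order: bool = False
    second_order_label: str = "GEN"
    mean_structure: bool = True

    @property
    def n_items(self) -> int:
        return self.battery.n_items

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def items_of(self, factor: str) -> list[str]:
        return [i for i in self.battery.item_names if self.loading_pattern.get(i) == factor]

    def is_marker(self, item: str) -> bool:
        return item in self.markers.values()

    def n_phi_params(self) -> int:
        """Free parameters in the factor-covariance structure of one group."""
        m = self.n_factors
        if self.second_order:
            # second-order variance fixed to 1; m loadings + m disturbances
            return 2 * m
        return m * (m + 1) // 2

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "items": list(self.battery.item_names),
            "reverse_coded": sorted(self.battery.reverse_coded),
            "scale": [self.battery.scale_min, self.battery.scale_max],
            "factors": {f: self.items_of(f) for f in self.factors},
            "markers": dict(self.markers),
            "second_order": self.second_order,
            "mean_structure": self.mean_structure,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        battery = ItemBattery(
            item_names=tuple(d["items"]),
            reverse_coded=frozenset(d.get("reverse_coded", ())),
            scale_min=d.get("scale", [1, 4])[0],
            scale_max=d.get("scale", [1, 4])[1],
        )
        pattern = {item: f for f, items in d["factors"].items() for item in items}
        markers = d.get("markers") or {
            f: items[0] for f, items in d["factors"].items()
        }
        return cls(
            battery=battery,
            factors=tuple(d["factors"]),
            loading_pattern=pattern,
            markers=markers,
            second_order=bool(d.get("second_order", False)),
            mean_structure=bool(d.get("mean_structure", True)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class ConstraintProfile:
    """Cross-group equality constraints for a multi-group fit.

    ``level`` names the rung of the invariance ladder; ``exemptions`` lists
    (parameter-class, item) pairs released from the equality their class would
    otherwise impose (partial invariance).  Factor means are fixed to zero in
    the reference group; at scalar level and above they are freely estimated
    in every non-reference group, which is what makes latent mean comparison
    possible.
    """

    level: str = "configural"
    exemptions: frozenset[tuple[str, str]] = frozenset()
    reference_group: str | None = None
    free_factor_means_nonreference: bool | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVEL_CLASSES:
            raise ValueError(f"unknown invariance level: {self.level!r}")
        allowed = set(LEVEL_CLASSES[self.level])
        for cls_, item in self.exemptions:
            if cls_ not in PARAM_CLASSES:
                raise ValueError(f"unknown parameter class: {cls_!r}")
            if cls_ not in allowed:
                raise ValueError(
                    f"exemption ({cls_!r}, {item!r}) references a class not "
                    f"constrained at level {self.level!r}"
                )
        if self.free_factor_means_nonreference is None:
            object.__setattr__(
                self,
                "free_factor_means_nonreference",
                self.level in ("scalar", "uniqueness"),
            )

    @property
    def equated_classes(self) -> tuple[str, ...]:
        return LEVEL_CLASSES[self.level]

    def is_equated(self, param_class: str, item: str) -> bool:
        """Whether this item's parameter of the given class is equated across groups."""
        return (
            param_class in self.equated_classes
            and (param_class, item) not in self.exemptions
        )

    def with_exemption(self, param_class: str, item: str) -> "ConstraintProfile":
        return replace(self, exemptions=self.exemptions | {(param_class, item)})


# ---------------------------------------------------------------------------
# Built-in CES-D structures
# ---------------------------------------------------------------------------

_CESD_FOUR = {
    "SOM": ["Bothered", "Appetite", "Mind", "Effort", "Sleep", "Talk", "GetGoing"],
    "DEP": ["Blues", "Depressed", "Failure", "Fearful", "Lonely", "Crying", "Sad"],
    "POS": ["Good", "Hopeful", "Happy", "Enjoyed"],
    "INT": ["Unfriendly", "Dislike"],
}

BUILTIN_NAMES = ("one_factor", "three_factor", "four_factor", "second_order")


def builtin_spec(name: str) -> ModelSpec:
    """Return one of the competing CES-D factor structures.

    ``four_factor`` is Radloff's structure (somatic complaints, depressive
    affect, positive affect, interpersonal problems with 7/7/4/2 items);
    ``three_factor`` merges the somatic and depressive-affect items into one
    14-item affect/somatic factor; ``one_factor`` loads all 20 items on a
    single factor; ``second_order`` places a single general depression factor
    above the four first-order factors.
    """
    battery = cesd_battery()
    if name == "four_factor" or name == "second_order":
        factors = _CESD_FOUR
    elif name == "three_factor":
        factors = {
            "AFFSOM": _CESD_FOUR["SOM"] + _CESD_FOUR["DEP"],
            "POS": _CESD_FOUR["POS"],
            "INT": _CESD_FOUR["INT"],
        }
    elif name == "one_factor":
        factors = {"DEPR": list(CESD_ITEMS)}
    else:
        raise ValueError(f"unknown builtin model: {name!r}; choose from {BUILTIN_NAMES}")
    pattern = {item: f for f, items in factors.items() for item in items}
    markers = {f: items[0] for f, items in factors.items()}
    return ModelSpec(
        battery=battery,
        factors=tuple(factors),
        loading_pattern=pattern,
        markers=markers,
        second_order=(name == "second_order"),
    )


# ---------------------------------------------------------------------------
# Parameter / df bookkeeping
# ---------------------------------------------------------------------------

def _per_group_count(spec: ModelSpec, free_means: bool) -> int:
    """Free parameters of one unconstrained group."""
    p, m = spec.n_items, spec.n_factors
    count = (p - m)            # non-marker loadings
    count += spec.n_phi_params()
    count += p                 # uniquenesses
    if spec.mean_structure:
        count += p             # intercepts
        if free_means:
            count += m         # factor means
    return count


def free_parameter_count(
    spec: ModelSpec, n_groups: int, profile: ConstraintProfile
) -> int:
    """Count free parameters of the multi-group model under a profile.

    Equality constraints collapse each cross-group-equal parameter to a single
    count; each exemption restores ``n_groups - 1`` per-group copies.  Factor
    means are fixed to 0 everywhere at configural/metric level and in the
    reference group otherwise.
    """
    p, m = spec.n_items, spec.n_factors
    free_means = bool(spec.mean_structure and profile.free_factor_means_nonreference)
    # reference group never has free means
    total = _per_group_count(spec, free_means=False)
    total += (n_groups - 1) * _per_group_count(spec, free_means=free_means)

    if n_groups > 1:
        for cls_ in profile.equated_classes:
            if cls_ == "loading":
                candidates = [i for i in spec.battery.item_names if not spec.is_marker(i)]
            else:
                candidates = list(spec.battery.item_names)
            n_equated = sum(1 for i in candidates if profile.is_equated(cls_, i))
            total -= (n_groups - 1) * n_equated
    return total


def degrees_of_freedom(
    spec: ModelSpec, n_groups: int, profile: ConstraintProfile
) -> int:
    """Model degrees of freedom: sample moments minus free parameters."""
    p = spec.n_items
    moments_per_group = p * (p + 1) // 2 + (p if spec.mean_structure else 0)
    df = n_groups * moments_per_group - free_parameter_count(spec, n_groups, profile)
    if df < 0:
        raise ValueError(f"negative degrees of freedom ({df}): model under-identified")
    return df


def validate_spec(spec: ModelSpec) -> list[str]:
    """Return diagnostics for an ill-formed spec (empty list when clean)."""
    diags: list[str] = []
    assigned = set(spec.loading_pattern)
    for item in spec.battery.item_names:
        if item not in assigned:
            diags.append(f"item {item!r} is not assigned to any factor")
    for item, f in spec.loading_pattern.items():
        if item not in spec.battery.item_names:
            diags.append(f"loading pattern references unknown item {item!r}")
        if f not in spec.factors:
            diags.append(f"item {item!r} assigned to unknown factor {f!r}")
    for f in spec.factors:
        items = spec.items_of(f)
        if len(items) < 2:
            diags.append(f"factor {f!r} has {len(items)} item(s); at least 2 required")
        marker = spec.markers.get(f)
        if marker is None:
            diags.append(f"factor {f!r} has no marker item")
        elif marker not in items:
            diags.append(f"marker {marker!r} does not belong to factor {f!r}")
    if spec.second_order and spec.n_factors < 3:
        diags.append(
            "second-order layer over fewer than 3 first-order factors is "
            "under-identified"
        )
    return diags
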