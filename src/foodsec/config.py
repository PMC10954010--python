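"""Indicator configuration: food groups, cutoffs, coping items, 4-point maps.

The defaults implement the standard WFP instrument: eight food groups with
the usual nutritional weights, the 28/42 Food Consumption Score cutoffs, the
50/65/75% food-expenditure-share bands, and the three-tier livelihood-coping
item set (stress / crisis / emergency).  Everything is overridable through a
YAML config file so an adapted questionnaire can be scored without touching
code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import IO, Mapping, Sequence

import yaml

from .errors import ConfigError

# Category vocabularies, in severity order where one exists.
FCS_CATEGORIES = ("poor", "borderline", "acceptable")
PWFE_CATEGORIES = ("lt50", "p50_65", "p65_75", "gt75")
CSI_CATEGORIES = ("none", "stress", "crisis", "emergency")
COPING_TIERS = ("stress", "crisis", "emergency")
FSI_LABELS = ("FS", "MFS", "MFI", "SFI")  # score 1..4

AREAS = ("urban", "non_urban")
SEXES = ("female", "male")
CIVIL_STATUSES = ("married_or_couple", "divorced_or_widowed", "single")


@dataclass(frozen=True)
class FoodGroup:
    """A food group with its FCS nutritional weight."""

    name: str
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ConfigError(f"food group {self.name!r}: weight must be positive")


@dataclass(frozen=True)
class CopingItem:
    """A livelihood coping strategy and its severity tier."""

    name: str
    tier: str

    def __post_init__(self) -> None:
        if self.tier not in COPING_TIERS:
            raise ConfigError(
                f"coping item {self.name!r}: tier {self.tier!r} not in {COPING_TIERS}"
            )


#: Standard WFP food groups and weights (staples 2, pulses 3, vegetables 1,
#: fruits 1, meat/fish/eggs 4, dairy 4, sugar 0.5, oil/fat 0.5).
DEFAULT_FOOD_GROUPS = (
    FoodGroup("staples", 2.0),
    FoodGroup("pulses", 3.0),
    FoodGroup("vegetables", 1.0),
    FoodGroup("fruits", 1.0),
    FoodGroup("meat_fish_eggs", 4.0),
    FoodGroup("dairy", 4.0),
    FoodGroup("sugar", 0.5),
    FoodGroup("oil_fat", 0.5),
)

#: Standard WFP livelihood-coping item set by tier.
DEFAULT_COPING_ITEMS = (
    CopingItem("spent_savings", "stress"),
    CopingItem("borrowed_money", "stress"),
    CopingItem("sold_household_goods", "stress"),
    CopingItem("bought_on_credit", "stress"),
    CopingItem("sold_productive_assets", "crisis"),
    CopingItem("reduced_health_education_spending", "crisis"),
    CopingItem("withdrew_children_school", "crisis"),
    CopingItem("sold_house_or_land", "emergency"),
    CopingItem("begged", "emergency"),
    CopingItem("illegal_degrading_activities", "emergency"),
)


@dataclass(frozen=True)
class FourPointMap:
    """Per-indicator category -> 1..4 console score (CARI convention).

    Food consumption has no level 2: an acceptable score is fully food
    secure (1), a borderline one already signals moderate insecurity (3).
    """

    fcs_map: Mapping[str, int] = field(
        default_factory=lambda: {"acceptable": 1, "borderline": 3, "poor": 4}
    )
    pwfe_map: Mapping[str, int] = field(
        default_factory=lambda: {"lt50": 1, "p50_65": 2, "p65_75": 3, "gt75": 4}
    )
    csi_map: Mapping[str, int] = field(
        default_factory=lambda: {"none": 1, "stress": 2, "crisis": 3, "emergency": 4}
    )

    def __post_init__(self) -> None:
        for name, m, cats in (
            ("fcs_map", self.fcs_map, FCS_CATEGORIES),
            ("pwfe_map", self.pwfe_map, PWFE_CATEGORIES),
            ("csi_map", self.csi_map, CSI_CATEGORIES),
        ):
            if set(m) != set(cats):
                raise ConfigError(f"{name} must map exactly the categories {cats}")
            bad = [v for v in m.values() if v not in (1, 2, 3, 4)]
            if bad:
                raise ConfigError(f"{name}: scores must be in 1..4, got {bad}")


@dataclass(frozen=True)
class IndicatorConfig:
    """Everything needed to score the three indicators and combine them."""

    food_groups: Sequence[FoodGroup] = DEFAULT_FOOD_GROUPS
    fcs_cutoffs: tuple[float, float] = (28.0, 42.0)  # poor_max, borderline_max
    pwfe_cutoffs: tuple[float, float, float] = (0.50, 0.65, 0.75)
    coping_items: Sequence[CopingItem] = DEFAULT_COPING_ITEMS
    four_point_map: FourPointMap = field(default_factory=FourPointMap)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        names = [g.name for g in self.food_groups]
        if len(set(names)) != len(names):
            raise ConfigError("food group names must be unique")
        item_names = [i.name for i in self.coping_items]
        if len(set(item_names)) != len(item_names):
            raise ConfigError("coping item names must be unique")
        if not self.fcs_cutoffs[0] < self.fcs_cutoffs[1]:
            raise ConfigError("fcs_cutoffs must be strictly increasing")
        if not (self.pwfe_cutoffs[0] < self.pwfe_cutoffs[1] < self.pwfe_cutoffs[2]):
            raise ConfigError("pwfe_cutoffs must be strictly increasing")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.food_groups)

    @property
    def weights(self) -> dict[str, float]:
        return {g.name: g.weight for g in self.food_groups}

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(i.name for i in self.coping_items)

    @property
    def item_tiers(self) -> dict[str, str]:
        return {i.name: i.tier for i in self.coping_items}

    @property
    def max_fcs(self) -> float:
        return 7.0 * sum(g.weight for g in self.food_groups)


@dataclass(frozen=True)
class ChaidParams:
    """Stopping and adjustment settings for CHAID segmentation."""

    alpha_split: float = 0.05
    alpha_merge: float = 0.05
    max_depth: int = 3
    min_parent: int = 100
    min_child: int = 50
    bonferroni: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_split", "alpha_merge"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1")
        if self.min_parent <= 0 or self.min_child <= 0:
            raise ConfigError("node-size minima must be positive")


def default_config() -> IndicatorConfig:
    """The WFP-standard configuration used throughout unless overridden."""
    return IndicatorConfig()


# ---------------------------------------------------------------------------
# YAML (de)serialization

def config_to_dict(config: IndicatorConfig) -> dict:
    return {
        "food_groups": [asdict(g) for g in config.food_groups],
        "fcs_cutoffs": list(config.fcs_cutoffs),
        "pwfe_cutoffs": list(config.pwfe_cutoffs),
        "coping_items": [asdict(i) for i in config.coping_items],
        "four_point_map": {
            "fcs_map": dict(config.four_point_map.fcs_map),
            "pwfe_map": dict(config.four_point_map.pwfe_map),
            "csi_map": dict(config.four_point_map.csi_map),
        },
        "alpha": config.alpha,
    }


def config_from_dict(data: Mapping) -> IndicatorConfig:
    try:
        kwargs: dict = {}
        if "food_groups" in data:
            kwargs["food_groups"] = tuple(FoodGroup(**g) for g in data["food_groups"])
        if "fcs_cutoffs" in data:
            kwargs["fcs_cutoffs"] = tuple(float(x) for x in data["fcs_cutoffs"])
        if "pwfe_cutoffs" in data:
            kwargs["pwfe_cutoffs"] = tuple(float(x) for x in data["pwfe_cutoffs"])
        if "coping_items" in data:
            kwargs["coping_items"] = tuple(CopingItem(**i) for i in data["coping_items"])
        if "four_point_map" in data:
            kwargs["four_point_map"] = FourPointMap(**data["four_point_map"])
        if "alpha" in data:
            kwargs["alpha"] = float(data["alpha"])
        return IndicatorConfig(**kwargs)
    except TypeError as exc:  # unexpected keys
        raise ConfigError(f"malformed config: {exc}") from exc


def save_config(config: IndicatorConfig, stream: IO[str]) -> None:
    yaml.safe_dump(config_to_dict(config), stream, sort_keys=False)


def load_config(stream: IO[str]) -> IndicatorConfig:
    data = yaml.safe_load(stream)
    if not isinstance(data, Mapping):
        raise ConfigError("config file must contain a mapping at top level")
    return config_from_dict(data)
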