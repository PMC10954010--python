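"""Synthetic household surveys with the dependence structure the analysis assumes.

Generation is *category-first*: each household draws a latent severity level
(the four food-security strata), then its three indicator categories from
severity-conditional distributions, and only then raw survey responses —
food-group day counts, a spending pair, coping answers — constructed so that
re-scoring them reproduces the drawn categories exactly.  Demographics are
drawn independently of severity.

The default parameters are calibrated to a national Venezuelan household
survey run during the 2020-21 complex humanitarian emergency: 2,041
households (1,023 urban), a (9, 69, 18, 4)% severity mix, indicator
conditionals equal to the published column percentages of each indicator
given the food security index, and published demographics (56.9% female
household heads, head age 48.7 +/- 21.5, etc.).  Because the three
conditionals are applied independently given severity, the generator matches
each indicator's FSI-conditional margins but not the unpublished three-way
joint distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Mapping

import numpy as np
import pandas as pd
import yaml

from .config import (
    CIVIL_STATUSES,
    CSI_CATEGORIES,
    FCS_CATEGORIES,
    FSI_LABELS,
    PWFE_CATEGORIES,
    IndicatorConfig,
    default_config,
)
from .console import ContingencyTable, contingency_from_counts
from .errors import ConfigError, GenerationError
from .survey import SurveyDataset, coping_column, day_column, required_columns

# Published column conditionals: P(category | severity level), in percent.
_COND_FCS = {
    "FS": {"acceptable": 100.0, "borderline": 0.0, "poor": 0.0},
    "MFS": {"acceptable": 99.5, "borderline": 0.5, "poor": 0.0},
    "MFI": {"acceptable": 40.1, "borderline": 52.8, "poor": 7.1},
    "SFI": {"acceptable": 0.0, "borderline": 46.4, "poor": 53.6},
}
_COND_PWFE = {
    "FS": {"lt50": 82.5, "p50_65": 17.5, "p65_75": 0.0, "gt75": 0.0},
    "MFS": {"lt50": 26.9, "p50_65": 20.5, "p65_75": 16.5, "gt75": 36.1},
    "MFI": {"lt50": 14.7, "p50_65": 9.4, "p65_75": 11.8, "gt75": 64.0},
    "SFI": {"lt50": 0.0, "p50_65": 1.2, "p65_75": 8.3, "gt75": 90.5},
}
_COND_CSI = {
    "FS": {"none": 65.6, "stress": 34.4, "crisis": 0.0, "emergency": 0.0},
    "MFS": {"none": 5.3, "stress": 10.1, "crisis": 71.7, "emergency": 12.9},
    "MFI": {"none": 4.7, "stress": 4.1, "crisis": 42.2, "emergency": 49.0},
    "SFI": {"none": 0.0, "stress": 6.0, "crisis": 38.1, "emergency": 56.0},
}

#: Published 4x4 coping-tier x expenditure-band counts within the
#: marginally-food-secure stratum (n=1352); used as a desk-check fixture.
TABLE4_COUNTS = (
    (4, 0, 17, 51),
    (3, 47, 22, 64),
    (276, 176, 145, 373),
    (81, 54, 39, 0),
)


@dataclass
class GeneratorParams:
    """Latent-severity mixture and conditional response distributions."""

    n: int = 2041
    urban_share: float = 1023 / 2041
    severity_mix: tuple[float, float, float, float] = (0.09, 0.69, 0.18, 0.04)
    cond_fcs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _COND_FCS.items()}
    )
    cond_pwfe: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _COND_PWFE.items()}
    )
    cond_csi: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _COND_CSI.items()}
    )
    female_share: float = 0.569
    head_age_mean: float = 48.7
    head_age_sd: float = 21.5
    head_age_range: tuple[float, float] = (18.0, 100.0)
    civil_mix: tuple[float, float, float] = (0.508, 0.234, 0.258)
    size_band_mix: tuple[float, float, float] = (0.361, 0.594, 0.045)
    total_spend_range: tuple[float, float] = (120.0, 1200.0)
    incomplete_rate: float = 83 / 2041
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if not 0 <= self.incomplete_rate < 1:
            raise ConfigError("incomplete_rate must lie in [0, 1)")
        if abs(sum(self.severity_mix) - 1) > 1e-9:
            raise ConfigError("severity_mix must sum to 1")
        for name, cond, cats in (
            ("cond_fcs", self.cond_fcs, FCS_CATEGORIES),
            ("cond_pwfe", self.cond_pwfe, PWFE_CATEGORIES),
            ("cond_csi", self.cond_csi, CSI_CATEGORIES),
        ):
            for level in FSI_LABELS:
                if level not in cond:
                    raise ConfigError(f"{name} lacks severity level {level!r}")
                if set(cond[level]) != set(cats):
                    raise ConfigError(f"{name}[{level!r}] must cover {cats}")

    def conditional(self, which: str, level: str) -> np.ndarray:
        cond, cats = {
            "fcs": (self.cond_fcs, FCS_CATEGORIES),
            "pwfe": (self.cond_pwfe, PWFE_CATEGORIES),
            "csi": (self.cond_csi, CSI_CATEGORIES),
        }[which]
        vec = np.array([cond[level][c] for c in cats], dtype=float)
        total = vec.sum()
        if total <= 0:
            raise ConfigError(f"cond_{which}[{level!r}] sums to zero")
        return vec / total


def default_params() -> GeneratorParams:
    """Parameters calibrated to the published survey (n=2041, 83 incomplete)."""
    return GeneratorParams()


# ---------------------------------------------------------------------------
# raw-response synthesis

def _fcs_band(cat: str, config: IndicatorConfig) -> tuple[float, float]:
    """(exclusive lower, inclusive upper) FCS bound for a category."""
    poor_max, borderline_max = config.fcs_cutoffs
    if cat == "poor":
        return (-1.0, poor_max)
    if cat == "borderline":
        return (poor_max, borderline_max)
    return (borderline_max, config.max_fcs)


def _draw_food_days(
    rng: np.random.Generator, cat: str, config: IndicatorConfig
) -> np.ndarray:
    """Random day counts whose FCS lands in the category's band.

    Start from a uniform day pattern and nudge single groups up or down
    until the weighted score enters the band.
    """
    lo, hi = _fcs_band(cat, config)
    if lo >= config.max_fcs:
        raise GenerationError(
            f"FCS band {cat!r} unreachable with configured weights "
            f"(max score {config.max_fcs})"
        )
    weights = np.array([g.weight for g in config.food_groups])
    days = rng.integers(0, 8, size=len(weights)).astype(float)
    fcs = float(days @ weights)
    for _ in range(10_000):
        if lo < fcs <= hi:
            return days
        if fcs > hi:
            candidates = np.flatnonzero(days > 0)
        else:
            candidates = np.flatnonzero(days < 7)
        g = rng.choice(candidates)
        days[g] += 1 if fcs <= lo else -1
        fcs = float(days @ weights)
    raise GenerationError(f"could not reach FCS band {cat!r}")  # pragma: no cover


def _draw_spending(
    rng: np.random.Generator, cat: str, params: GeneratorParams,
    config: IndicatorConfig,
) -> tuple[float, float]:
    """A (food, total) spending pair whose ratio lands in the target band."""
    from .indicators import categorize_pwfe

    lo, hi = _PWFE_BANDS_FROM_CUTOFFS(config)[cat]
    for _ in range(100):
        total = round(rng.uniform(*params.total_spend_range), 2)
        ratio = rng.uniform(lo, hi)
        food = round(total * ratio, 2)
        if categorize_pwfe(food / total, config.pwfe_cutoffs) == cat:
            return food, total
    raise GenerationError(f"could not reach PWFE band {cat!r}")  # pragma: no cover


def _PWFE_BANDS_FROM_CUTOFFS(config: IndicatorConfig) -> dict[str, tuple[float, float]]:
    c1, c2, c3 = config.pwfe_cutoffs
    eps = 0.003
    return {
        "lt50": (0.02, c1 - eps),
        "p50_65": (c1 + eps, c2 - eps),
        "p65_75": (c2 + eps, c3 - eps),
        "gt75": (c3 + eps, 0.995),
    }


def _draw_coping(
    rng: np.random.Generator, cat: str, config: IndicatorConfig
) -> dict[str, int]:
    """Yes/no answers whose most severe yes-tier equals the target category."""
    tiers = config.item_tiers
    answers = {name: 0 for name in config.item_names}
    if cat == "none":
        return answers
    target_rank = CSI_CATEGORIES.index(cat)  # 1..3 for stress/crisis/emergency
    for name in config.item_names:
        rank = CSI_CATEGORIES.index(tiers[name])
        if rank == target_rank:
            answers[name] = int(rng.random() < 0.4)
        elif rank < target_rank:
            answers[name] = int(rng.random() < 0.3)
    target_items = [n for n in config.item_names if tiers[n] == cat]
    if not target_items:
        raise GenerationError(f"no coping items configured for tier {cat!r}")
    if not any(answers[n] for n in target_items):
        answers[rng.choice(target_items)] = 1
    return answers


def generate(
    params: GeneratorParams | None = None,
    seed: int | None = None,
    config: IndicatorConfig | None = None,
) -> SurveyDataset:
    """Generate a raw survey (no derived columns), reproducible from the seed.

    The intended indicator categories of each household are stored in
    ``meta["intended"]`` so tests can verify the category-first contract;
    intended categories of records later blanked to emulate item
    non-response are kept as drawn.
    """
    params = params or default_params()
    config = config or default_config()
    rng = np.random.default_rng(params.seed if seed is None else seed)

    n = params.n
    severity = rng.choice(4, size=n, p=np.asarray(params.severity_mix))
    cond = {
        which: {lev: params.conditional(which, lev) for lev in FSI_LABELS}
        for which in ("fcs", "pwfe", "csi")
    }

    rows: list[dict] = []
    intended = {"fcs_cat": [], "pwfe_cat": [], "csi_cat": [], "severity": []}
    width = len(str(n))
    for i in range(n):
        level = FSI_LABELS[severity[i]]
        fcs_cat = FCS_CATEGORIES[rng.choice(3, p=cond["fcs"][level])]
        pwfe_cat = PWFE_CATEGORIES[rng.choice(4, p=cond["pwfe"][level])]
        csi_cat = CSI_CATEGORIES[rng.choice(4, p=cond["csi"][level])]
        intended["severity"].append(level)
        intended["fcs_cat"].append(fcs_cat)
        intended["pwfe_cat"].append(pwfe_cat)
        intended["csi_cat"].append(csi_cat)

        days = _draw_food_days(rng, fcs_cat, config)
        food, total = _draw_spending(rng, pwfe_cat, params, config)
        coping = _draw_coping(rng, csi_cat, config)

        size_band = rng.choice(3, p=np.asarray(params.size_band_mix))
        hh_size = int(
            rng.integers(*((1, 3), (3, 7), (7, 13))[size_band])
        )
        age = rng.normal(params.head_age_mean, params.head_age_sd)
        while not params.head_age_range[0] <= age <= params.head_age_range[1]:
            age = rng.normal(params.head_age_mean, params.head_age_sd)

        row = {
            "id": f"h{i:0{width}d}",
            "area": "urban" if rng.random() < params.urban_share else "non_urban",
            "head_sex": "female" if rng.random() < params.female_share else "male",
            "head_age": round(float(age), 1),
            "civil_status": CIVIL_STATUSES[rng.choice(3, p=np.asarray(params.civil_mix))],
            "hh_size": hh_size,
            **{day_column(g): int(d) for g, d in zip(config.group_names, days)},
            "food_spend": food,
            "total_spend": total,
            **{coping_column(k): v for k, v in coping.items()},
        }
        rows.append(row)

    df = pd.DataFrame(rows, columns=list(required_columns(config)))

    # blank one indicator field in a fixed number of randomly chosen records
    n_incomplete = int(round(params.incomplete_rate * n))
    if n_incomplete:
        victims = rng.choice(n, size=n_incomplete, replace=False)
        blankable = (
            [day_column(g) for g in config.group_names]
            + ["food_spend", "total_spend"]
            + [coping_column(i) for i in config.item_names]
        )
        for v in victims:
            df.loc[v, blankable[rng.integers(len(blankable))]] = np.nan

    ds = SurveyDataset(
        df=df,
        config=config,
        provenance=f"synthetic survey, n={n}, seed={params.seed if seed is None else seed}",
    )
    ds.meta["intended"] = pd.DataFrame(intended, index=df.index)
    ds.meta["n_incomplete_planned"] = n_incomplete
    return ds


def table4_fixture() -> ContingencyTable:
    """The published MFS-stratum coping x expenditure contingency (n=1352)."""
    return contingency_from_counts(
        np.array(TABLE4_COUNTS),
        row_labels=list(CSI_CATEGORIES),
        col_labels=list(PWFE_CATEGORIES),
    )


# ---------------------------------------------------------------------------
# (de)serialization

def params_to_dict(params: GeneratorParams) -> dict:
    return {
        "n": params.n,
        "urban_share": params.urban_share,
        "severity_mix": list(params.severity_mix),
        "cond_fcs": {k: dict(v) for k, v in params.cond_fcs.items()},
        "cond_pwfe": {k: dict(v) for k, v in params.cond_pwfe.items()},
        "cond_csi": {k: dict(v) for k, v in params.cond_csi.items()},
        "female_share": params.female_share,
        "head_age_mean": params.head_age_mean,
        "head_age_sd": params.head_age_sd,
        "head_age_range": list(params.head_age_range),
        "civil_mix": list(params.civil_mix),
        "size_band_mix": list(params.size_band_mix),
        "total_spend_range": list(params.total_spend_range),
        "incomplete_rate": params.incomplete_rate,
        "seed": params.seed,
    }


def params_from_dict(data: Mapping) -> GeneratorParams:
    kwargs = dict(data)
    for key in ("severity_mix", "civil_mix", "size_band_mix", "head_age_range",
                "total_spend_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    try:
        return GeneratorParams(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"malformed generator params: {exc}") from exc


def save_params(params: GeneratorParams, stream: IO[str]) -> None:
    yaml.safe_dump(params_to_dict(params), stream, sort_keys=False)


def load_params(stream: IO[str]) -> GeneratorParams:
    data = yaml.safe_load(stream)
    if not isinstance(data, Mapping):
        raise ConfigError("params file must contain a mapping at top level")
    return params_from_dict(data)
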