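"""The three CARI component indicators.

* FCS — Food Consumption Score: weighted sum over food groups of the number
  of days (0..7) each group was eaten in the past week; banded into
  poor / borderline / acceptable at 28 and 42 points.
* PWFE — proportion of total household spending that goes to food; banded at
  50 / 65 / 75%.
* CSI (livelihood variant) — the most severe coping tier among the
  strategies a household reported using (none / stress / crisis / emergency).

Scalar operations work on one household; :func:`compute_indicators` applies
them across a :class:`~foodsec.survey.SurveyDataset`, filling the derived
columns for every household whose raw fields allow it.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import COPING_TIERS, CopingItem, FoodGroup
from .errors import ConfigError, MissingDataError, ValidationError
from .survey import SurveyDataset, coping_column, day_column


def compute_fcs(
    food_days: Mapping[str, float], groups: Sequence[FoodGroup]
) -> float:
    """Weighted day-count sum; with default weights the range is [0, 112]."""
    total = 0.0
    for g in groups:
        if g.name not in food_days:
            raise ConfigError(f"no day count for configured food group {g.name!r}")
        days = food_days[g.name]
        if not 0 <= days <= 7:
            raise ValidationError(f"days for {g.name!r} outside 0..7: {days}")
        total += g.weight * days
    unknown = set(food_days) - {g.name for g in groups}
    if unknown:
        raise ConfigError(f"unconfigured food group(s): {sorted(unknown)}")
    return total


def categorize_fcs(fcs: float, cutoffs: tuple[float, float] = (28.0, 42.0)) -> str:
    """poor if fcs <= 28, borderline if 28 < fcs <= 42, else acceptable."""
    if fcs < 0:
        raise ValidationError(f"negative FCS: {fcs}")
    poor_max, borderline_max = cutoffs
    if fcs <= poor_max:
        return "poor"
    if fcs <= borderline_max:
        return "borderline"
    return "acceptable"


def compute_pwfe(food_spend: float, total_spend: float) -> float:
    """Food share of total spending, in [0, 1]."""
    if total_spend == 0:
        raise MissingDataError("PWFE undefined: total_spend is zero")
    if food_spend < 0 or total_spend < 0:
        raise ValidationError("spending must be nonnegative")
    if food_spend > total_spend:
        raise ValidationError(
            f"food_spend {food_spend} exceeds total_spend {total_spend}"
        )
    return food_spend / total_spend


def categorize_pwfe(
    pwfe: float, cutoffs: tuple[float, float, float] = (0.50, 0.65, 0.75)
) -> str:
    """Band the food-spending share.

    The top band is strict ("more than 75%"), so the boundary value 0.75
    still falls in the 65-75% band; the lower boundaries are closed on the
    left.
    """
    if not 0 <= pwfe <= 1:
        raise ValidationError(f"PWFE outside [0, 1]: {pwfe}")
    c1, c2, c3 = cutoffs
    if pwfe < c1:
        return "lt50"
    if pwfe < c2:
        return "p50_65"
    if pwfe <= c3:
        return "p65_75"
    return "gt75"


_TIER_RANK = {tier: i + 1 for i, tier in enumerate(COPING_TIERS)}


def classify_coping(
    coping_answers: Mapping[str, object], items: Sequence[CopingItem]
) -> str:
    """Most severe coping tier reported, or ``"none"``.

    Households using no strategy at all are food secure on this indicator;
    otherwise the classification follows the worst tier among the strategies
    answered yes, under the order stress < crisis < emergency.
    """
    worst = 0
    for item in items:
        if item.name not in coping_answers or coping_answers[item.name] is None:
            raise MissingDataError(f"coping item {item.name!r} unanswered")
        ans = coping_answers[item.name]
        yes = ans in (1, 1.0, True, "yes")
        if yes:
            worst = max(worst, _TIER_RANK[item.tier])
    return "none" if worst == 0 else COPING_TIERS[worst - 1]


def compute_indicators(dataset: SurveyDataset) -> SurveyDataset:
    """Fill fcs/fcs_cat, pwfe/pwfe_cat and csi_cat columns row-wise.

    Each indicator is computed for every household whose raw fields for that
    indicator are present (so the CARI console can report per-indicator n);
    households missing a field keep a missing derived value.  Deterministic
    and row-order independent.
    """
    cfg = dataset.config
    df = dataset.df.copy()
    day_cols = [day_column(g) for g in cfg.group_names]
    weights = np.array([g.weight for g in cfg.food_groups])

    days = df[day_cols].to_numpy(dtype=float)
    bad = (days < 0) | (days > 7)
    if np.any(bad & ~np.isnan(days)):
        rows = np.unique(np.where(bad & ~np.isnan(days))[0])
        ids = df["id"].iloc[rows].tolist()
        raise ValidationError(f"food days outside 0..7 for id(s) {ids[:5]}")
    fcs = days @ weights  # NaN-propagating: any missing group leaves fcs NaN
    df["fcs"] = fcs
    df["fcs_cat"] = [
        categorize_fcs(v, cfg.fcs_cutoffs) if not np.isnan(v) else None for v in fcs
    ]

    food = df["food_spend"].to_numpy(dtype=float)
    total = df["total_spend"].to_numpy(dtype=float)
    over = ~np.isnan(food) & ~np.isnan(total) & (food > total)
    if over.any():
        ids = df["id"].to_numpy()[over].tolist()
        raise ValidationError(f"food_spend > total_spend for id(s) {ids[:5]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        pwfe = np.where(total > 0, food / total, np.nan)
    df["pwfe"] = pwfe
    df["pwfe_cat"] = [
        categorize_pwfe(v, cfg.pwfe_cutoffs) if not np.isnan(v) else None
        for v in pwfe
    ]

    cs_cols = [coping_column(i) for i in cfg.item_names]
    answers = df[cs_cols].to_numpy(dtype=float)
    tier_ranks = np.array([_TIER_RANK[i.tier] for i in cfg.coping_items])
    csi_cat: list[str | None] = []
    for row in answers:
        if np.isnan(row).any():
            csi_cat.append(None)
            continue
        worst = int((row * tier_ranks).max())
        csi_cat.append("none" if worst == 0 else COPING_TIERS[worst - 1])
    df["csi_cat"] = csi_cat

    out = SurveyDataset(
        df=df, config=cfg, provenance=dataset.provenance, meta=dict(dataset.meta)
    )
    out.meta["indicator_n"] = {
        "fcs": int(pd.notna(df["fcs_cat"]).sum()),
        "pwfe": int(pd.notna(df["pwfe_cat"]).sum()),
        "csi": int(pd.notna(df["csi_cat"]).sum()),
    }
    return out
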