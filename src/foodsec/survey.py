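"""Household survey container and CSV schema.

A survey is held as a :class:`pandas.DataFrame` wrapped in
:class:`SurveyDataset`, one row per household.  The on-disk format is a
single-dialect UTF-8 CSV with the columns::

    id, area, head_sex, head_age, civil_status, hh_size,
    days_<group> ...            (7-day consumption frequency, 0..7)
    food_spend, total_spend,    (same currency)
    cs_<item> ...               (coping strategy applied, 0/1)

plus, when already computed, the derived columns
``fcs, fcs_cat, pwfe, pwfe_cat, csi_cat, fsi``.

Missing responses are empty cells; malformed numeric cells are read back as
missing rather than coerced to a value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .config import (
    AREAS,
    CIVIL_STATUSES,
    IndicatorConfig,
    SEXES,
    default_config,
)
from .errors import SchemaError, ValidationError

DAYS_PREFIX = "days_"
CS_PREFIX = "cs_"

DEMOG_COLUMNS = ("id", "area", "head_sex", "head_age", "civil_status", "hh_size")
SPEND_COLUMNS = ("food_spend", "total_spend")
DERIVED_COLUMNS = ("fcs", "fcs_cat", "pwfe", "pwfe_cat", "csi_cat", "fsi")

#: Household-size bands used in demographic summaries.
SIZE_BANDS = ("<3", "3-6", ">6")


def day_column(group: str) -> str:
    return DAYS_PREFIX + group


def coping_column(item: str) -> str:
    return CS_PREFIX + item


def required_columns(config: IndicatorConfig) -> tuple[str, ...]:
    """Schema columns every survey file must carry, in canonical order."""
    return (
        DEMOG_COLUMNS
        + tuple(day_column(g) for g in config.group_names)
        + SPEND_COLUMNS
        + tuple(coping_column(i) for i in config.item_names)
    )


@dataclass
class SurveyDataset:
    """An ordered collection of household records plus its scoring config."""

    df: pd.DataFrame
    config: IndicatorConfig = field(default_factory=default_config)
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.df["id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise SchemaError(f"duplicate household ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def indicator_columns(self) -> list[str]:
        """Raw columns required by the three indicators."""
        cfg = self.config
        return (
            [day_column(g) for g in cfg.group_names]
            + list(SPEND_COLUMNS)
            + [coping_column(i) for i in cfg.item_names]
        )

    def is_complete(self) -> pd.Series:
        """Boolean mask of households usable for all three indicators.

        Complete means: every food-group day count, both spending fields and
        every coping answer present, and ``total_spend > 0`` so the food
        expenditure share is defined.
        """
        cols = self.indicator_columns()
        mask = self.df[cols].notna().all(axis=1)
        return mask & (self.df["total_spend"] > 0)


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str]) -> None:
    for col in columns:
        df[col] = pd.to_numeric(df[col], errors="coerce")


def _coerce_categorical(df: pd.DataFrame, col: str, allowed: tuple[str, ...]) -> None:
    # unknown labels become missing; demographics never feed the indicators
    df[col] = df[col].where(df[col].isin(allowed))


def read_survey(
    source: IO[str] | str,
    config: IndicatorConfig | None = None,
) -> SurveyDataset:
    """Read a survey CSV into a :class:`SurveyDataset`.

    Raises
    ------
    SchemaError
        If a required column is absent or household ids repeat.
    ValidationError
        If a food-group day count lies outside 0..7 or spending is negative.
    """
    config = config or default_config()
    df = pd.read_csv(source, dtype={"id": str})
    missing = [c for c in required_columns(config) if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    day_cols = [day_column(g) for g in config.group_names]
    cs_cols = [coping_column(i) for i in config.item_names]
    _coerce_numeric(df, day_cols + list(SPEND_COLUMNS) + cs_cols + ["head_age", "hh_size"])
    _coerce_categorical(df, "area", AREAS)
    _coerce_categorical(df, "head_sex", SEXES)
    _coerce_categorical(df, "civil_status", CIVIL_STATUSES)

    for col in day_cols:
        bad = df.index[df[col].notna() & ~df[col].isin(range(8))]
        if len(bad):
            rid = df.loc[bad[0], "id"]
            raise ValidationError(
                f"{col}: value outside 0..7 for household id={rid!r}"
            )
    for col in SPEND_COLUMNS:
        bad = df.index[df[col].notna() & (df[col] < 0)]
        if len(bad):
            rid = df.loc[bad[0], "id"]
            raise ValidationError(f"{col}: negative value for household id={rid!r}")
    for col in cs_cols:
        bad = df.index[df[col].notna() & ~df[col].isin((0, 1))]
        if len(bad):
            rid = df.loc[bad[0], "id"]
            raise ValidationError(f"{col}: coping answer must be 0/1, id={rid!r}")

    ds = SurveyDataset(df=df, config=config)
    ds.meta["n_read"] = len(df)
    ds.meta["n_incomplete"] = int((~ds.is_complete()).sum())
    return ds


def write_survey(dataset: SurveyDataset, sink: IO[str] | str) -> None:
    """Write the survey back to CSV, canonical columns first, derived last."""
    cols = [c for c in required_columns(dataset.config) if c in dataset.df.columns]
    cols += [c for c in DERIVED_COLUMNS if c in dataset.df.columns]
    out = dataset.df[cols]
    out.to_csv(sink, index=False)


def complete_cases(dataset: SurveyDataset) -> SurveyDataset:
    """Keep only households with every field the three indicators need.

    The returned dataset's ``meta`` records ``n_retained`` and ``n_dropped``.
    Idempotent: applying it twice changes nothing.
    """
    mask = dataset.is_complete()
    kept = dataset.df[mask].copy()
    out = SurveyDataset(df=kept, config=dataset.config, provenance=dataset.provenance)
    out.meta["n_retained"] = int(mask.sum())
    out.meta["n_dropped"] = int((~mask).sum())
    return out


@dataclass
class DemographicSummary:
    """Table-style frequencies/percentages of the household descriptives."""

    n: int
    head_sex: pd.DataFrame
    civil_status: pd.DataFrame
    size_bands: pd.DataFrame
    head_age_mean: float
    head_age_sd: float

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"Households: {self.n}\n")
        buf.write(
            f"Head age: {self.head_age_mean:.1f} ± {self.head_age_sd:.1f}\n"
        )
        for title, tbl in (
            ("Head sex", self.head_sex),
            ("Civil status", self.civil_status),
            ("Household size", self.size_bands),
        ):
            buf.write(f"\n{title}\n")
            buf.write(tbl.to_string())
            buf.write("\n")
        return buf.getvalue()


def _freq_table(values: pd.Series, categories: tuple[str, ...]) -> pd.DataFrame:
    values = values.dropna()
    counts = values.value_counts().reindex(categories, fill_value=0)
    denom = counts.sum()
    pct = 100.0 * counts / denom if denom else counts * np.nan
    return pd.DataFrame({"n": counts.astype(int), "pct": pct.round(1)})


def size_band(size: float) -> str:
    if size < 3:
        return SIZE_BANDS[0]
    if size <= 6:
        return SIZE_BANDS[1]
    return SIZE_BANDS[2]


def describe(dataset: SurveyDataset) -> DemographicSummary:
    """Demographic summary: sex, civil status, size bands, head age.

    Percentages use non-missing denominators per variable; each frequency
    column therefore sums to 100 up to rounding.
    """
    df = dataset.df
    bands = df["hh_size"].dropna().map(size_band)
    age = df["head_age"].dropna()
    return DemographicSummary(
        n=len(df),
        head_sex=_freq_table(df["head_sex"], SEXES),
        civil_status=_freq_table(df["civil_status"], CIVIL_STATUSES),
        size_bands=_freq_table(bands, SIZE_BANDS),
        head_age_mean=float(age.mean()) if len(age) else float("nan"),
        head_age_sd=float(age.std(ddof=1)) if len(age) > 1 else float("nan"),
    )
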