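"""Food Security Index and the CARI reporting console.

The CARI framework summarizes a household in two domains:

* current status — the food consumption score category;
* coping capacity — economic vulnerability (food spending share) and
  livelihood coping, averaged.

Each indicator category maps to a 1..4 console score; the index is

    FSI = round_half_up( (fcs_pt + (pwfe_pt + csi_pt) / 2) / 2 )

with 1=food secure (FS), 2=marginally food secure (MFS), 3=moderately food
insecure (MFI), 4=severely food insecure (SFI).  Rounding is half-up, not
banker's: a household with acceptable consumption but emergency coping and
>75% food spending scores (1 + 4)/2 = 2.5 and must land in MFI, not MFS.

This module also builds the console report (per-indicator distributions over
the four levels) and the indicator-by-FSI association cross-tabs with
Pearson chi-square tests.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    CSI_CATEGORIES,
    FCS_CATEGORIES,
    FSI_LABELS,
    FourPointMap,
    PWFE_CATEGORIES,
)
from .errors import ConfigError, DegenerateTableError
from .survey import SurveyDataset


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (for positive input)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class FsiResult:
    """Console scores, coping-capacity average and the combined index."""

    fcs_pt: int
    pwfe_pt: int
    csi_pt: int
    coping_capacity: float
    fsi: int

    @property
    def label(self) -> str:
        return FSI_LABELS[self.fsi - 1]


def compute_fsi(
    fcs_cat: str,
    pwfe_cat: str,
    csi_cat: str,
    four_point: FourPointMap | None = None,
) -> FsiResult:
    """Combine the three indicator categories into the 4-level index.

    Monotone: worsening any single category never lowers the index.
    """
    four_point = four_point or FourPointMap()
    try:
        fcs_pt = four_point.fcs_map[fcs_cat]
        pwfe_pt = four_point.pwfe_map[pwfe_cat]
        csi_pt = four_point.csi_map[csi_cat]
    except KeyError as exc:
        raise ConfigError(f"category {exc.args[0]!r} has no 4-point score") from exc
    coping = (pwfe_pt + csi_pt) / 2
    fsi = round_half_up((fcs_pt + coping) / 2)
    return FsiResult(fcs_pt, pwfe_pt, csi_pt, coping, fsi)


def classify_dataset(dataset: SurveyDataset) -> SurveyDataset:
    """Fill the ``fsi`` column for every household with all three categories.

    ``meta["fsi_counts"]`` records the number of households per level.
    """
    df = dataset.df.copy()
    for col in ("fcs_cat", "pwfe_cat", "csi_cat"):
        if col not in df.columns:
            raise ConfigError(f"{col} not computed; run compute_indicators first")
    fp = dataset.config.four_point_map
    fsi: list[float] = []
    for f, p, c in zip(df["fcs_cat"], df["pwfe_cat"], df["csi_cat"]):
        if f is None or p is None or c is None or pd.isna(f) or pd.isna(p) or pd.isna(c):
            fsi.append(np.nan)
        else:
            fsi.append(compute_fsi(f, p, c, fp).fsi)
    df["fsi"] = fsi
    out = SurveyDataset(
        df=df, config=dataset.config, provenance=dataset.provenance,
        meta=dict(dataset.meta),
    )
    counts = df["fsi"].value_counts()
    out.meta["fsi_counts"] = {
        label: int(counts.get(i + 1, 0)) for i, label in enumerate(FSI_LABELS)
    }
    return out


# ---------------------------------------------------------------------------
# Console report

@dataclass
class ConsoleReport:
    """Row-percentage distribution of each indicator over the four levels.

    ``rows`` maps a row title to ``(n, percentages over FS/MFS/MFI/SFI)``
    with integer-rounded percentages, the convention of published CARI
    consoles.
    """

    rows: dict[str, tuple[int, np.ndarray]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = {
            title: {"n": n, **{lab: p for lab, p in zip(FSI_LABELS, pct)}}
            for title, (n, pct) in self.rows.items()
        }
        return pd.DataFrame(data).T[["n", *FSI_LABELS]]

    def to_text(self) -> str:
        return self.to_frame().to_string()

    def to_csv(self, sink) -> None:
        self.to_frame().to_csv(sink, index_label="indicator")


def _row_percent(scores: pd.Series) -> tuple[int, np.ndarray]:
    scores = scores.dropna().astype(int)
    n = len(scores)
    counts = np.array([(scores == i).sum() for i in (1, 2, 3, 4)])
    pct = np.round(100.0 * counts / n).astype(int) if n else np.zeros(4, int)
    return n, pct


def build_console(dataset: SurveyDataset) -> ConsoleReport:
    """CARI console: four-level distribution of each indicator and the FSI.

    Each indicator row uses all households with that indicator computed, so
    row n's can differ (they equal the per-indicator non-missing counts).
    """
    df = dataset.df
    fp = dataset.config.four_point_map
    report = ConsoleReport()
    for title, col, mapping in (
        ("Food consumption score (FCS)", "fcs_cat", fp.fcs_map),
        ("Food expenditure share (PWFE)", "pwfe_cat", fp.pwfe_map),
        ("Coping strategy index (CSI)", "csi_cat", fp.csi_map),
    ):
        pts = df[col].map(mapping)
        report.rows[title] = _row_percent(pts)
    report.rows["Food security index"] = _row_percent(df["fsi"])
    return report


# ---------------------------------------------------------------------------
# Cross-tabs

@dataclass
class ContingencyTable:
    """Labeled counts with a Pearson chi-square test of independence."""

    counts: pd.DataFrame  # rows x cols, integer counts
    chi2: float
    df: int
    p_value: float

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_percent(self) -> pd.DataFrame:
        return (100.0 * self.counts.div(self.row_totals, axis=0)).round(1)

    def col_percent(self) -> pd.DataFrame:
        return (100.0 * self.counts.div(self.col_totals, axis=1)).round(1)

    def total_percent(self) -> pd.DataFrame:
        return (100.0 * self.counts / self.grand_total).round(1)

    def to_text(self, percent: str | None = None) -> str:
        buf = io.StringIO()
        buf.write(self.counts.to_string())
        if percent == "row":
            buf.write("\n\nrow %\n" + self.row_percent().to_string())
        elif percent == "col":
            buf.write("\n\ncolumn %\n" + self.col_percent().to_string())
        elif percent == "total":
            buf.write("\n\ntotal %\n" + self.total_percent().to_string())
        buf.write(
            f"\n\nchi2 = {self.chi2:.3f}, df = {self.df}, p = {self.p_value:.3g}\n"
        )
        return buf.getvalue()


def pearson_chi2(observed: np.ndarray) -> tuple[float, int, float]:
    """Pearson X^2 without continuity correction on an r x c count table."""
    observed = np.asarray(observed, dtype=float)
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise DegenerateTableError("table needs at least 2 rows and 2 columns")
    chi2, p, dof, expected = stats.chi2_contingency(observed, correction=False)
    if (expected < 5).any():
        warnings.warn(
            "some expected counts are below 5; the chi-square approximation "
            "may be poor",
            stacklevel=2,
        )
    return float(chi2), int(dof), float(p)


def contingency_from_counts(
    counts: pd.DataFrame | np.ndarray,
    row_labels=None,
    col_labels=None,
) -> ContingencyTable:
    """Wrap a count matrix (dropping empty rows/columns) and test it."""
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame(counts, index=row_labels, columns=col_labels)
    counts = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DegenerateTableError(
            f"degenerate table after dropping empty margins: shape {counts.shape}"
        )
    chi2, dof, p = pearson_chi2(counts.to_numpy())
    return ContingencyTable(counts=counts.astype(int), chi2=chi2, df=dof, p_value=p)


_VAR_CATEGORIES = {
    "fcs_cat": FCS_CATEGORIES,
    "pwfe_cat": PWFE_CATEGORIES,
    "csi_cat": CSI_CATEGORIES,
    "fsi": (1, 2, 3, 4),
}


def _labelled(series: pd.Series, var: str) -> pd.Series:
    if var == "fsi":
        return series.dropna().astype(int).map(dict(enumerate(FSI_LABELS, start=1)))
    return series.dropna()


def crosstab(dataset: SurveyDataset, row_var: str, col_var: str) -> ContingencyTable:
    """Cross-tabulate two computed categorical variables with a chi-square test.

    Raises :class:`DegenerateTableError` when either variable shows a single
    observed category (df would be 0).
    """
    df = dataset.df
    for var in (row_var, col_var):
        if var not in df.columns:
            raise ConfigError(f"variable {var!r} not computed on this dataset")
    rows = _labelled(df[row_var], row_var)
    cols = _labelled(df[col_var], col_var)
    tab = pd.crosstab(rows, cols)
    order_r = [c for c in _category_order(row_var) if c in tab.index]
    order_c = [c for c in _category_order(col_var) if c in tab.columns]
    tab = tab.loc[order_r, order_c]
    return contingency_from_counts(tab)


def _category_order(var: str):
    cats = _VAR_CATEGORIES.get(var)
    if cats is None:
        return []
    if var == "fsi":
        return list(FSI_LABELS)
    return list(cats)


def association_report(dataset: SurveyDataset) -> dict[str, ContingencyTable]:
    """The three indicator-by-FSI cross-tabs (column-percent view on demand)."""
    return {
        var: crosstab(dataset, var, "fsi")
        for var in ("fcs_cat", "pwfe_cat", "csi_cat")
    }
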