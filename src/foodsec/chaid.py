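"""CHAID recursive partitioning (Kass-style, merge-only).

The tree segments households on a categorical target (here the 4-level food
security index) using categorical predictors.  At each node, every
predictor's categories are first reduced by the classic merge step:
repeatedly merge the pair of (adjacent, for ordinal predictors) category
groups that are *most alike* with respect to the target — the pair whose
2 x J chi-square test has the largest p-value — as long as that p exceeds
``alpha_merge``.  The merged table's Pearson chi-square p-value is then
Bonferroni-adjusted by the number of ways the original categories can be
reduced to that many groups, and the predictor with the smallest adjusted
p-value wins the split, provided it clears ``alpha_split`` and every
prospective child is large enough.

This is the merge-only variant (no re-splitting of merged groups, no
floating missing category), which is complete for the 3- and 4-category
severity-ordered predictors this package uses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    CSI_CATEGORIES,
    FCS_CATEGORIES,
    FSI_LABELS,
    PWFE_CATEGORIES,
    ChaidParams,
)
from .errors import ValidationError
from .survey import SurveyDataset


@dataclass(frozen=True)
class Predictor:
    """A categorical predictor; ordinal predictors merge adjacent categories only."""

    name: str
    categories: tuple
    scale: str = "ordinal"  # or "nominal"

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValidationError(f"predictor {self.name!r} needs >= 2 categories")
        if self.scale not in ("ordinal", "nominal"):
            raise ValidationError(f"unknown scale {self.scale!r}")


def default_predictors() -> tuple[Predictor, ...]:
    """FCS, CSI, PWFE categories in severity order (the fixed tie-break order)."""
    return (
        Predictor("fcs_cat", FCS_CATEGORIES),
        Predictor("csi_cat", CSI_CATEGORIES),
        Predictor("pwfe_cat", PWFE_CATEGORIES),
    )


# ---------------------------------------------------------------------------
# chi-square machinery

def _chi2_p(table: np.ndarray) -> float:
    """Pearson chi-square p for a count table, 1.0 when degenerate.

    Zero rows/columns are dropped; a table left with fewer than two rows or
    columns carries no evidence against homogeneity, hence p = 1.
    """
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def _group_target_counts(
    groups: Sequence[tuple], pred: np.ndarray, target_codes: np.ndarray, n_t: int
) -> np.ndarray:
    """r x J table of target counts per category group."""
    out = np.zeros((len(groups), n_t))
    for i, grp in enumerate(groups):
        mask = np.isin(pred, np.asarray(list(grp), dtype=pred.dtype))
        out[i] = np.bincount(target_codes[mask], minlength=n_t)
    return out


def merge_categories(
    pred_values: Sequence,
    target_values: Sequence,
    categories: Sequence,
    scale: str = "ordinal",
    alpha_merge: float = 0.05,
) -> tuple[tuple, ...]:
    """Kass merge step: collapse the predictor's categories into groups.

    Returns the final partition as a tuple of category tuples, in category
    order for ordinal predictors.  Categories with no observations are
    dropped before merging.
    """
    pred = np.asarray(pred_values)
    target, _ = pd.factorize(np.asarray(target_values), use_na_sentinel=False)
    n_t = int(target.max()) + 1 if len(target) else 0
    observed = [c for c in categories if (pred == c).any()]
    groups: list[tuple] = [(c,) for c in observed]

    while len(groups) > 1:
        if scale == "ordinal":
            pairs = [(i, i + 1) for i in range(len(groups) - 1)]
        else:
            pairs = [
                (i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))
            ]
        best_pair, best_p = None, -1.0
        for i, j in pairs:
            tab = _group_target_counts(
                [groups[i], groups[j]], pred, target, n_t
            )
            p = _chi2_p(tab)
            if p > best_p:
                best_pair, best_p = (i, j), p
        if best_p <= alpha_merge:
            break
        i, j = best_pair
        groups[i] = groups[i] + groups[j]
        del groups[j]
    return tuple(groups)


def bonferroni_multiplier(c: int, r: int, scale: str = "ordinal") -> int:
    """Number of ways to reduce c ordered/unordered categories to r groups.

    Ordinal: contiguous partitions, C(c-1, r-1).  Nominal: Stirling-type sum
    sum_{i=0}^{r-1} (-1)^i (r-i)^c / (i! (r-i)!).
    """
    if not 1 <= r <= c:
        raise ValidationError(f"need 1 <= r <= c, got r={r}, c={c}")
    if scale == "ordinal":
        return math.comb(c - 1, r - 1)
    total = 0.0
    for i in range(r):
        total += (-1) ** i * (r - i) ** c / (math.factorial(i) * math.factorial(r - i))
    return int(round(total))


def _enforce_min_child(
    groups: tuple[tuple, ...],
    pred: np.ndarray,
    target_codes: np.ndarray,
    n_t: int,
    min_child: int,
    scale: str,
) -> tuple[tuple, ...]:
    """Merge undersized category groups into their most similar neighbor.

    Standard CHAID behavior: a prospective child below the minimum size is
    absorbed by the (adjacent, for ordinal) group whose target distribution
    it resembles most — the largest 2 x J chi-square p-value — rather than
    disqualifying the predictor.
    """
    groups = list(groups)
    while len(groups) > 1:
        sizes = [
            int(np.isin(pred, np.asarray(list(g), dtype=pred.dtype)).sum())
            for g in groups
        ]
        small = [i for i, s in enumerate(sizes) if s < min_child]
        if not small:
            break
        i = min(small, key=lambda k: sizes[k])
        if scale == "ordinal":
            neighbors = [j for j in (i - 1, i + 1) if 0 <= j < len(groups)]
        else:
            neighbors = [j for j in range(len(groups)) if j != i]
        j = max(
            neighbors,
            key=lambda k: _chi2_p(
                _group_target_counts([groups[i], groups[k]], pred, target_codes, n_t)
            ),
        )
        lo, hi = sorted((i, j))
        groups[lo] = groups[lo] + groups[hi]
        del groups[hi]
    return tuple(groups)


@dataclass(frozen=True)
class SplitCandidate:
    predictor: Predictor
    partition: tuple[tuple, ...]
    adjusted_p: float


def best_split(
    node_df: pd.DataFrame,
    target: str,
    predictors: Sequence[Predictor],
    params: ChaidParams | None = None,
) -> SplitCandidate | None:
    """Pick the predictor whose merged table is most significantly associated.

    Prospective children smaller than ``min_child`` are first absorbed into
    their most similar neighboring group.  Returns ``None`` when no
    predictor achieves a Bonferroni-adjusted p <= ``alpha_split``.  Ties are
    broken by predictor order, then by fewer merged groups.
    """
    params = params or ChaidParams()
    tvals = node_df[target].to_numpy()
    target_codes, _ = pd.factorize(tvals, use_na_sentinel=False)
    n_t = int(target_codes.max()) + 1 if len(target_codes) else 0
    if n_t < 2:
        return None

    best: tuple | None = None  # (adj_p, predictor_index, r) -> candidate
    for idx, predictor in enumerate(predictors):
        pred = node_df[predictor.name].to_numpy()
        observed = [c for c in predictor.categories if (pred == c).any()]
        c = len(observed)
        if c < 2:
            continue
        partition = merge_categories(
            pred, tvals, predictor.categories, predictor.scale, params.alpha_merge
        )
        partition = _enforce_min_child(
            partition, pred, target_codes, n_t, params.min_child, predictor.scale
        )
        r = len(partition)
        if r < 2:
            continue
        tab = _group_target_counts(partition, pred, target_codes, n_t)
        p = _chi2_p(tab)
        adj = min(1.0, p * bonferroni_multiplier(c, r, predictor.scale)) \
            if params.bonferroni else p
        if adj > params.alpha_split:
            continue
        key = (adj, idx, r)
        if best is None or key < best[0]:
            best = (key, SplitCandidate(predictor, partition, adj))
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# tree

@dataclass
class ChaidNode:
    """One node of the segmentation tree."""

    id: int
    depth: int
    index: pd.Index  # row labels of member households
    predicate: tuple[str, tuple] | None  # (predictor, category group) from parent
    counts: dict[str, int]
    split_predictor: str | None = None
    groups: tuple[tuple, ...] | None = None
    adjusted_p: float | None = None
    children: list["ChaidNode"] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.index)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def modal_label(self) -> str:
        return max(self.counts, key=lambda k: (self.counts[k], -FSI_LABELS.index(k)))

    @property
    def label_share(self) -> float:
        return self.counts[self.modal_label] / self.n if self.n else float("nan")

    def to_dict(self) -> dict:
        d = {
            "id": self.id,
            "n": self.n,
            "label": self.modal_label,
            "label_share": round(self.label_share, 4),
            "counts": self.counts,
        }
        if self.predicate is not None:
            d["predicate"] = {
                "predictor": self.predicate[0],
                "categories": list(self.predicate[1]),
            }
        if not self.is_leaf:
            d["split"] = {
                "predictor": self.split_predictor,
                "adjusted_p": self.adjusted_p,
                "groups": [list(g) for g in self.groups],
            }
            d["children"] = [ch.to_dict() for ch in self.children]
        return d


@dataclass
class ChaidTree:
    """A grown segmentation tree plus the data it was grown on."""

    root: ChaidNode
    target: str
    predictors: tuple[Predictor, ...]
    params: ChaidParams
    data: pd.DataFrame

    def leaves(self) -> list[ChaidNode]:
        out: list[ChaidNode] = []

        def walk(node: ChaidNode) -> None:
            if node.is_leaf:
                out.append(node)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "params": {
                "alpha_split": self.params.alpha_split,
                "alpha_merge": self.params.alpha_merge,
                "max_depth": self.params.max_depth,
                "min_parent": self.params.min_parent,
                "min_child": self.params.min_child,
                "bonferroni": self.params.bonferroni,
            },
            "root": self.root.to_dict(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: ChaidNode) -> None:
            pad = "  " * node.depth
            if node.predicate is None:
                head = "root"
            else:
                var, cats = node.predicate
                head = f"{var} in {{{', '.join(map(str, cats))}}}"
            line = (
                f"{pad}{head}: n={node.n}, label={node.modal_label} "
                f"({100 * node.label_share:.1f}%)"
            )
            if not node.is_leaf:
                line += (
                    f" | split on {node.split_predictor}"
                    f" (adj p={node.adjusted_p:.3g})"
                )
            lines.append(line)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return "\n".join(lines) + "\n"


def _label_counts(values: pd.Series) -> dict[str, int]:
    vals = values.dropna().astype(int)
    return {lab: int((vals == i + 1).sum()) for i, lab in enumerate(FSI_LABELS)}


def grow_tree(
    dataset: SurveyDataset | pd.DataFrame,
    predictors: Sequence[Predictor] | None = None,
    params: ChaidParams | None = None,
    target: str = "fsi",
) -> ChaidTree:
    """Grow the CHAID tree from the root by recursive best_split.

    Deterministic for given data and parameters, independent of row order.
    """
    df = dataset.df if isinstance(dataset, SurveyDataset) else dataset
    predictors = tuple(predictors or default_predictors())
    params = params or ChaidParams()
    needed = [target] + [p.name for p in predictors]
    df = df.dropna(subset=needed)
    if df.empty:
        raise ValidationError("cannot grow a tree on an empty dataset")

    counter = {"next_id": 0}

    def build(index: pd.Index, depth: int, predicate) -> ChaidNode:
        node_df = df.loc[index]
        node = ChaidNode(
            id=counter["next_id"],
            depth=depth,
            index=index,
            predicate=predicate,
            counts=_label_counts(node_df[target]),
        )
        counter["next_id"] += 1
        if (
            depth >= params.max_depth
            or len(index) < params.min_parent
            or node_df[target].nunique() < 2
        ):
            return node
        cand = best_split(node_df, target, predictors, params)
        if cand is None:
            return node
        node.split_predictor = cand.predictor.name
        node.groups = cand.partition
        node.adjusted_p = cand.adjusted_p
        for grp in cand.partition:
            mask = node_df[cand.predictor.name].isin(grp)
            child = build(
                node_df.index[mask], depth + 1, (cand.predictor.name, grp)
            )
            node.children.append(child)
        return node

    root = build(df.index, 0, None)
    return ChaidTree(root=root, target=target, predictors=predictors,
                     params=params, data=df)


@dataclass
class TerminalGroup:
    """A leaf of the tree described by its path predicates and composition."""

    name: str
    path: list[tuple[str, tuple]]
    n: int
    modal_label: str
    label_share: float
    fsi_counts: dict[str, int]
    pwfe_pct: dict[str, float]

    def describe(self) -> str:
        preds = (
            " & ".join(f"{v} in {{{', '.join(map(str, g))}}}" for v, g in self.path)
            or "(all households)"
        )
        return (
            f"{self.name}: {preds} -> n={self.n}, {self.modal_label} "
            f"({100 * self.label_share:.1f}%)"
        )


def terminal_groups(tree: ChaidTree) -> list[TerminalGroup]:
    """Leaf summaries in left-to-right order, named G1, G2, ...

    Each record carries the defining path, the FSI composition, and the
    within-leaf distribution of the food-expenditure-share category (the
    style in which marginally-food-secure subgroups are usually profiled).
    """
    groups: list[TerminalGroup] = []

    def walk(node: ChaidNode, path: list) -> None:
        new_path = path + ([node.predicate] if node.predicate else [])
        if node.is_leaf:
            leaf_df = tree.data.loc[node.index]
            if "pwfe_cat" in leaf_df.columns:
                pw = leaf_df["pwfe_cat"].dropna()
                pwfe_pct = {
                    c: round(100.0 * (pw == c).sum() / len(pw), 1) if len(pw) else 0.0
                    for c in PWFE_CATEGORIES
                }
            else:
                pwfe_pct = {}
            groups.append(
                TerminalGroup(
                    name=f"G{len(groups) + 1}",
                    path=new_path,
                    n=node.n,
                    modal_label=node.modal_label,
                    label_share=node.label_share,
                    fsi_counts=node.counts,
                    pwfe_pct=pwfe_pct,
                )
            )
        for ch in node.children:
            walk(ch, new_path)

    walk(tree.root, [])
    return groups
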