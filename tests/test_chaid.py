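"""CHAID: category merging, Bonferroni adjustment, split selection, trees."""

import itertools

import numpy as np
import pandas as pd
import pytest

from foodsec import (
    best_split,
    bonferroni_multiplier,
    grow_tree,
    merge_categories,
    terminal_groups,
)
from foodsec.chaid import Predictor
from foodsec.config import ChaidParams
from foodsec.errors import ValidationError

SMALL = ChaidParams(min_parent=2, min_child=1)


def contiguous_partitions(cats):
    """All ways to cut an ordered category list into contiguous groups."""
    n = len(cats)
    for cuts in range(0, n):
        for pos in itertools.combinations(range(1, n), cuts):
            bounds = (0,) + pos + (n,)
            yield tuple(
                tuple(cats[bounds[i]: bounds[i + 1]]) for i in range(len(bounds) - 1)
            )


def set_partitions(items):
    """All set partitions (for the nominal Bonferroni oracle)."""
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + ((first,) + part[i],) + part[i + 1:]
        yield ((first,),) + part


class TestBonferroni:
    def test_ordinal_counts_contiguous_partitions(self):
        # enumerate contiguous partitions as the independent oracle
        for c in range(2, 6):
            cats = tuple(range(c))
            for r in range(1, c + 1):
                expected = sum(
                    1 for p in contiguous_partitions(cats) if len(p) == r
                )
                assert bonferroni_multiplier(c, r, "ordinal") == expected

    def test_nominal_counts_set_partitions(self):
        for c in range(2, 6):
            cats = tuple(range(c))
            for r in range(1, c + 1):
                expected = sum(1 for p in set_partitions(cats) if len(p) == r)
                assert bonferroni_multiplier(c, r, "nominal") == expected

    def test_r_equals_one_is_one(self):
        assert bonferroni_multiplier(5, 1, "ordinal") == 1
        assert bonferroni_multiplier(5, 1, "nominal") == 1

    def test_pinned_values(self):
        assert bonferroni_multiplier(4, 2, "ordinal") == 3
        assert bonferroni_multiplier(3, 2, "nominal") == 3

    def test_invalid_r_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_multiplier(3, 4, "ordinal")


class TestMerge:
    def test_two_categories_keep_or_collapse(self):
        rng = np.random.default_rng(0)
        pred = np.repeat(["a", "b"], 50)
        target = rng.integers(0, 2, size=100)
        part = merge_categories(pred, target, ("a", "b"))
        assert part in ((("a",), ("b",)), (("a", "b"),))

    def test_perfect_association_never_merges(self):
        # predictor identical to a 4-class target, n large
        pred = np.repeat(["a", "b", "c", "d"], 100)
        target = np.repeat([1, 2, 3, 4], 100)
        part = merge_categories(pred, target, ("a", "b", "c", "d"))
        assert part == (("a",), ("b",), ("c",), ("d",))

    def test_independent_predictor_usually_collapses(self):
        collapsed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pred = rng.choice(["a", "b", "c"], size=400)
            target = rng.integers(0, 3, size=400)
            part = merge_categories(pred, target, ("a", "b", "c"))
            collapsed += len(part) == 1
        assert collapsed > 10

    def test_empty_categories_dropped(self):
        pred = np.repeat(["a", "c"], 30)
        target = np.array([0] * 30 + [1] * 30)
        part = merge_categories(pred, target, ("a", "b", "c"))
        assert all("b" not in grp for grp in part)

    def test_ordinal_groups_are_contiguous(self):
        rng = np.random.default_rng(3)
        cats = ("a", "b", "c", "d")
        pred = rng.choice(cats, size=200)
        target = rng.integers(0, 2, size=200)
        part = merge_categories(pred, target, cats)
        flat = [c for grp in part for c in grp]
        assert flat == [c for c in cats if c in flat]


def _frame(pred_cols: dict, target) -> pd.DataFrame:
    return pd.DataFrame({**pred_cols, "y": target})


class TestBestSplit:
    def test_informative_predictor_wins(self):
        rng = np.random.default_rng(5)
        n = 300
        y = rng.integers(0, 3, size=n)
        informative = np.array(["a", "b", "c"])[y]
        noise = rng.choice(["a", "b", "c"], size=n)
        df = _frame({"x1": noise, "x2": informative}, y)
        preds = (Predictor("x1", ("a", "b", "c")), Predictor("x2", ("a", "b", "c")))
        cand = best_split(df, "y", preds, SMALL)
        assert cand is not None
        assert cand.predictor.name == "x2"
        assert cand.adjusted_p < 1e-6

    def test_node_below_min_parent_returns_none(self):
        df = _frame({"x1": ["a", "b"] * 5}, [0, 1] * 5)
        preds = (Predictor("x1", ("a", "b")),)
        assert best_split(df, "y", preds, ChaidParams(min_parent=100)) is None

    def test_independent_predictor_rarely_splits(self):
        """Bonferroni-adjusted selection holds the per-predictor false-split
        rate near alpha (no cross-predictor correction is applied, so the
        family-wise rate grows with the number of predictors, as in classic
        CHAID)."""
        splits = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 300
            y = rng.integers(0, 3, size=n)
            df = _frame({"x1": rng.choice(["a", "b", "c"], size=n)}, y)
            preds = (Predictor("x1", ("a", "b", "c")),)
            splits += best_split(df, "y", preds, SMALL) is not None
        assert splits / reps <= 0.10

    def test_constant_target_returns_none(self):
        df = _frame({"x1": ["a", "b"] * 10}, [1] * 20)
        assert best_split(df, "y", (Predictor("x1", ("a", "b")),), SMALL) is None

    def test_min_child_enforced_by_neighbor_merge(self):
        # category "a" has only 3 members: it must be absorbed, not split off
        y = np.array([0] * 3 + [0] * 40 + [1] * 40)
        x = np.array(["a"] * 3 + ["b"] * 40 + ["c"] * 40)
        df = _frame({"x1": x}, y)
        cand = best_split(
            df, "y", (Predictor("x1", ("a", "b", "c")),),
            ChaidParams(min_parent=2, min_child=10),
        )
        assert cand is not None
        sizes = [df["x1"].isin(g).sum() for g in cand.partition]
        assert min(sizes) >= 10


class TestGrowTree:
    def test_constant_target_single_node(self, config, row_factory,
                                         dataset_factory):
        df = pd.DataFrame(
            {
                "fsi": [2] * 50,
                "fcs_cat": ["acceptable"] * 50,
                "csi_cat": ["crisis"] * 50,
                "pwfe_cat": ["gt75"] * 50,
            }
        )
        tree = grow_tree(df, params=ChaidParams())
        assert tree.root.is_leaf
        assert tree.root.modal_label == "MFS"

    def test_empty_dataset_rejected(self):
        df = pd.DataFrame(columns=["fsi", "fcs_cat", "csi_cat", "pwfe_cat"])
        with pytest.raises(ValidationError):
            grow_tree(df)

    def test_calibrated_split_order(self, calibrated_scored):
        tree = grow_tree(calibrated_scored)
        assert tree.root.split_predictor == "fcs_cat"
        second = {
            ch.predicate[1]: ch.split_predictor for ch in tree.root.children
        }
        assert second[("acceptable",)] == "csi_cat"
        assert second[("borderline",)] == "csi_cat"

    def test_no_split_under_poor_fcs_at_study_n(self):
        # at the study's sample size the poor-FCS branch is below min_parent
        from foodsec import (
            classify_dataset, complete_cases, compute_indicators, generate,
        )
        ds = generate(seed=5)
        scored = complete_cases(classify_dataset(compute_indicators(ds)))
        tree = grow_tree(scored)
        poor = [
            ch for ch in tree.root.children if ch.predicate[1] == ("poor",)
        ]
        assert len(poor) == 1
        assert poor[0].is_leaf
        assert poor[0].n < tree.params.min_parent

    def test_leaves_partition_membership(self, calibrated_scored):
        tree = grow_tree(calibrated_scored)
        leaves = tree.leaves()
        all_idx = np.concatenate([leaf.index.to_numpy() for leaf in leaves])
        assert len(all_idx) == len(set(all_idx)) == tree.root.n

    def test_constraints_respected(self, calibrated_scored):
        tree = grow_tree(calibrated_scored)

        def walk(node):
            assert node.depth <= tree.params.max_depth
            if node.predicate is not None and not node.is_leaf:
                pass
            if node.children:
                for ch in node.children:
                    assert ch.n >= tree.params.min_child
                    walk(ch)

        walk(tree.root)

    def test_row_order_invariance(self, calibrated_scored):
        tree_a = grow_tree(calibrated_scored)
        shuffled = calibrated_scored.df.sample(
            frac=1.0, random_state=9
        )
        ds = type(calibrated_scored)(
            df=shuffled, config=calibrated_scored.config
        )
        tree_b = grow_tree(ds)
        da, db = tree_a.to_dict(), tree_b.to_dict()
        assert da == db

    def test_tree_exports(self, calibrated_scored):
        tree = grow_tree(calibrated_scored)
        text = tree.to_text()
        assert text.startswith("root:")
        assert "split on fcs_cat" in text
        d = tree.to_dict()
        assert d["root"]["split"]["predictor"] == "fcs_cat"


class TestTerminalGroups:
    def test_single_node_tree_one_group(self):
        df = pd.DataFrame(
            {
                "fsi": [1] * 30,
                "fcs_cat": ["acceptable"] * 30,
                "csi_cat": ["none"] * 30,
                "pwfe_cat": ["lt50"] * 30,
            }
        )
        groups = terminal_groups(grow_tree(df))
        assert len(groups) == 1
        assert groups[0].n == 30
        assert groups[0].path == []

    def test_leaf_sizes_sum_to_n(self, calibrated_scored):
        tree = grow_tree(calibrated_scored)
        groups = terminal_groups(tree)
        assert sum(g.n for g in groups) == tree.root.n

    def test_fs_leaf_on_calibrated_data(self, calibrated_scored):
        """A leaf with acceptable FCS, no coping and low PWFE, labeled FS."""
        tree = grow_tree(calibrated_scored)
        found = False
        for g in terminal_groups(tree):
            preds = dict(g.path)
            if (
                preds.get("fcs_cat") == ("acceptable",)
                and preds.get("csi_cat") == ("none",)
                and g.modal_label == "FS"
                and "gt75" not in preds.get("pwfe_cat", ("gt75",))
            ):
                found = True
        assert found
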