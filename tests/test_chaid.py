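"""CHAID merging, split selection, tree growth, and node statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nachr_pharm import ChaidConfig, grow_tree, node_mean
from nachr_pharm import chaid


def exhaustive_best_split(df, outcome, predictors):
    """Oracle: rank all single-(binary)-predictor splits by plain ANOVA p."""
    best = None
    for pred in predictors:
        cats = pd.unique(df[pred])
        if len(cats) < 2:
            continue
        groups = [df.loc[df[pred] == c, outcome].to_numpy() for c in cats]
        if min(len(g) for g in groups) < 2:
            continue
        f, p = stats.f_oneway(*groups)
        if not np.isfinite(p):
            continue
        if best is None or p < best[1]:
            best = (pred, p)
    return best


class TestMergeCategories:
    def test_binary_predictor_unchanged(self, rng):
        groups = chaid.merge_categories(
            {"with": rng.normal(0, 1, 10), "without": rng.normal(5, 1, 10)})
        assert sorted(map(sorted, groups)) == [["with"], ["without"]]

    def test_identical_distributions_fully_merge(self):
        vals = np.arange(10.0)
        groups = chaid.merge_categories({"a": vals, "b": vals, "c": vals})
        assert len(groups) == 1 and groups[0] == frozenset("abc")

    def test_fixture_compound_merge_separates_ach(self, core):
        df = chaid.chaid_frame(core)
        by = {c: df.loc[df["compound"] == c, "pec50"].to_numpy()
              for c in df["compound"].unique()}
        groups = chaid.merge_categories(by, 0.05)
        # the reference agonist is ~1.4-2.2 pEC50 units below the
        # neonicotinoids and must end up alone in its own group
        assert frozenset(["ACh"]) in groups

    def test_empty_category_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            chaid.merge_categories({"a": [1.0, 2.0], "b": []})


class TestBonferroni:
    @pytest.mark.parametrize("c,r,expected", [
        (2, 2, 1.0),    # binary: no multiplicity
        (3, 3, 1.0),
        (4, 2, 7.0),    # 2^4/2 - 1 ways to bipartition 4 nominal categories
        (3, 2, 3.0),
        (4, 3, 6.0),
    ])
    def test_collapse_counts(self, c, r, expected):
        assert chaid.bonferroni_multiplier(c, r) == expected


class TestBestSplit:
    def test_fixture_first_split_is_da2(self, core):
        df = chaid.chaid_frame(core)
        pred, groups, p = chaid.best_split(df, "pec50", ChaidConfig())
        assert pred == "Da2"
        assert p < 0.05

    def test_perfect_separator_chosen(self):
        df = pd.DataFrame({
            "good": [0] * 6 + [1] * 6,
            "bad": [0, 1] * 6,
            "y": [1.0] * 6 + [2.0] * 6,
        })
        cfg = ChaidConfig(predictors=("bad", "good"))
        pred, _, p = chaid.best_split(df, "y", cfg)
        assert pred == "good"
        assert p < 1e-10

    def test_alpha_gate_blocks_weak_split(self, rng):
        df = pd.DataFrame({"x": [0, 1] * 10, "y": rng.normal(0, 1, 20)})
        cfg = ChaidConfig(predictors=("x",), alpha_split=1e-6)
        assert chaid.best_split(df, "y", cfg) is None

    def test_false_split_rate_near_nominal(self):
        # pure-noise outcome, one binary predictor, alpha 0.05, 200 seeds:
        # the gated split frequency should track the nominal type-I rate
        cfg = ChaidConfig(predictors=("x",), alpha_split=0.05)
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            df = pd.DataFrame({"x": [0, 1] * 24, "y": rng.normal(0, 1, 48)})
            if chaid.best_split(df, "y", cfg) is not None:
                hits += 1
        assert hits / 200 <= 0.08

    def test_matches_exhaustive_oracle_on_random_panels(self):
        rng = np.random.default_rng(11)
        preds = ("p1", "p2", "p3", "p4")
        cfg = ChaidConfig(predictors=preds, min_node=2)
        for _ in range(25):
            n = int(rng.integers(12, 64))
            df = pd.DataFrame({p: rng.integers(0, 2, n) for p in preds})
            df["y"] = rng.normal(0, 1, n) + df["p1"] * rng.normal(0, 1)
            ours = chaid.best_split(df, "y", cfg)
            oracle = exhaustive_best_split(df, "y", preds)
            if oracle is None:
                continue
            assert ours is not None
            assert ours[0] == oracle[0]
            assert ours[2] == pytest.approx(oracle[1], rel=1e-9)


class TestGrowTree:
    def test_fixture_tree_contains_published_leaf(self, core):
        tree = grow_tree(core, ChaidConfig(max_depth=4))
        assert tree.split_var == "Da2"
        leaves = {(round(l.mean, 3), l.n) for l in tree.leaves()}
        assert (7.506, 8) in leaves

    def test_depth_one_is_root_with_grand_mean(self, core):
        tree = grow_tree(core, ChaidConfig(max_depth=1))
        assert tree.is_leaf
        assert tree.n == 48
        assert tree.mean == pytest.approx(6.775, abs=1e-3)

    def test_constant_outcome_no_split(self):
        df = pd.DataFrame({"x": [0, 1] * 10, "y": [3.0] * 20})
        tree = grow_tree(df, ChaidConfig(predictors=("x",)), outcome="y")
        assert tree.is_leaf

    def test_parent_child_bookkeeping(self, core):
        tree = grow_tree(core, ChaidConfig(max_depth=4))

        def walk(node):
            if node.children:
                assert node.n == sum(c.n for c in node.children)
                weighted = sum(c.n * c.mean for c in node.children) / node.n
                assert node.mean == pytest.approx(weighted, rel=1e-12)
                assert all(c.depth == node.depth + 1 for c in node.children)
                for c in node.children:
                    walk(c)
            assert node.depth <= 4

        walk(tree)

    def test_leaf_conservation(self, core):
        tree = grow_tree(core, ChaidConfig(max_depth=4))
        total = sum(l.n * l.mean for l in tree.leaves())
        df = chaid.chaid_frame(core)
        assert total == pytest.approx(df["pec50"].sum(), rel=1e-12)

    def test_tightening_alpha_never_grows_tree(self, core):
        sizes = []
        for alpha in (0.5, 0.2, 0.05, 0.01, 0.001):
            tree = grow_tree(core, ChaidConfig(alpha_split=alpha))
            sizes.append(tree.size())
        assert sizes == sorted(sizes, reverse=True)

    def test_missing_predictor_rejected(self, core):
        with pytest.raises(KeyError, match="nope"):
            grow_tree(core, ChaidConfig(predictors=("nope",)))

    def test_compound_predictor_dominates_root_when_included(self, core):
        cfg = ChaidConfig(predictors=("Da1", "Da2", "Da3", "Db2", "compound"))
        tree = grow_tree(core, cfg)
        assert tree.split_var == "compound"


class TestNodeMean:
    def test_published_node(self, core):
        n, mean = node_mean(core, {"Da1": 0, "Da2": 0, "Da3": 1})
        assert n == 8
        assert mean == pytest.approx(7.506, abs=1e-3)

    def test_da2_present_count(self, core):
        n, _ = node_mean(core, {"Da2": 1})
        assert n == 24

    def test_single_row_predicate(self, core):
        df = chaid.chaid_frame(core)
        n, mean = node_mean(
            df, {"Da1": 1, "Da2": 0, "Da3": 0, "Db2": 0, "compound": "ACh"})
        assert n == 1
        assert mean == pytest.approx(5.24)

    def test_empty_predicate_match_rejected(self, core):
        with pytest.raises(ValueError, match="matches no rows"):
            node_mean(core, {"Da1": 7})
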