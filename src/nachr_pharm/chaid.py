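"""CHAID-style regression tree for a continuous outcome over categorical predictors.

Kass-procedure CHAID adapted to a continuous outcome: category pairs of each
predictor are merged while the pairwise one-way F-test cannot tell them apart
(p > alpha_merge); the split variable is the predictor whose merged grouping
has the smallest Bonferroni-adjusted ANOVA p-value.  For a two-group
comparison the F statistic is the square of the pooled-variance t statistic,
so the merge and split tests are mutually consistent.

Growth stops at the depth limit or the minimum node size.  By default the
best admissible split is taken regardless of its p-value — the behaviour of
the widely used Python CHAID implementation, and the configuration that
reproduces the published subunit tree, where ligand-to-ligand variation
inflates within-node variance far above the subunit signal.  Setting
``alpha_split`` additionally requires the adjusted p to clear that threshold
(the classic Kass stopping rule), which controls the false-split rate on
noise at roughly the nominal level.

The Bonferroni multiplier for a nominal predictor with c observed categories
collapsed into r groups counts the distinct ways that collapse can happen:

    B(c, r) = Σ_{i=0}^{r−1} (−1)^i (r − i)^c / (i! (r − i)!)

(the Stirling-number-of-the-second-kind formula; B = 1 when r = c, so binary
predictors are never penalized).

Everything is deterministic: ties in adjusted p are broken by predictor order
in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .receptor_data import PotencyEfficacyTable

__all__ = [
    "ChaidConfig",
    "ChaidNode",
    "chaid_frame",
    "merge_categories",
    "best_split",
    "grow_tree",
    "node_mean",
]

SUBUNIT_PREDICTORS = ("Da1", "Da2", "Da3", "Db2")


@dataclass(frozen=True)
class ChaidConfig:
    """Growth and significance controls.

    max_depth counts node levels including the root, so max_depth = 1 yields
    the root alone and the published setting of 4 allows three nested splits.
    alpha_split = None (default) grows to the depth/size limits taking the
    best split at each node; a float enables the significance stopping rule.
    """

    max_depth: int = 4
    alpha_split: Optional[float] = None
    alpha_merge: float = 0.05
    min_node: int = 2
    bonferroni: bool = True
    predictors: tuple = SUBUNIT_PREDICTORS

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        for a in (self.alpha_split, self.alpha_merge):
            if a is not None and not 0.0 < a < 1.0:
                raise ValueError("alpha thresholds must lie in (0, 1)")


@dataclass
class ChaidNode:
    """One node of the grown tree.

    conditions is the conjunction of (predictor, allowed-category-set) pairs
    on the path from the root; leaves have split_var None.
    """

    conditions: tuple
    n: int
    mean: float
    depth: int
    split_var: Optional[str] = None
    p_adj: Optional[float] = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def size(self) -> int:
        return 1 + sum(ch.size() for ch in self.children)

    def to_dict(self) -> dict:
        return {
            "conditions": [[p, sorted(map(str, g))] for p, g in self.conditions],
            "n": self.n,
            "mean": self.mean,
            "split_var": self.split_var,
            "p_adj": self.p_adj,
            "children": [ch.to_dict() for ch in self.children],
        }

    def format(self, indent: int = 0) -> str:
        cond = " & ".join(
            f"{p}∈{{{','.join(map(str, sorted(map(str, g))))}}}" for p, g in self.conditions
        ) or "(root)"
        line = f"{'  ' * indent}{cond}  [mean={self.mean:.3f}, n={self.n}]"
        if self.split_var is not None:
            line += f"  split={self.split_var} (p_adj={self.p_adj:.3g})"
        return "\n".join([line] + [ch.format(indent + 1) for ch in self.children])


def chaid_frame(table: PotencyEfficacyTable, outcome: str = "pec50") -> pd.DataFrame:
    """Long analysis frame: binary subunit columns, a compound column, outcome.

    One row per (receptor, ligand) of the panel; subunit predictors are 0/1
    presence indicators, ``compound`` is the ligand name.
    """
    col = "pec50_mean" if outcome == "pec50" else "imax_mean"
    rows = []
    for _, rec in table.frame.iterrows():
        row = {s: int(s in rec["receptor"]) for s in SUBUNIT_PREDICTORS}
        row["compound"] = rec["ligand"]
        row[outcome] = float(rec[col])
        rows.append(row)
    return pd.DataFrame(rows)


def _anova_p(groups: Sequence[np.ndarray]) -> float:
    """One-way F-test p across groups; degenerate cases resolved explicitly."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        return 1.0
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0.0:
        return 1.0  # identical values everywhere: nothing to distinguish
    means = [g.mean() for g in groups]
    sse = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    if sse == 0.0:
        return 0.0  # groups internally constant but different: perfect separation
    n = len(allv)
    k = len(groups)
    if n - k <= 0:
        return 1.0
    ssb = sum(len(g) * (m - allv.mean()) ** 2 for g, m in zip(groups, means))
    f = (ssb / (k - 1)) / (sse / (n - k))
    return float(stats.f.sf(f, k - 1, n - k))


def bonferroni_multiplier(c: int, r: int) -> float:
    """Number of ways c nominal categories can collapse into r groups."""
    if r >= c:
        return 1.0
    return float(sum(
        (-1) ** i * (r - i) ** c / (factorial(i) * factorial(r - i))
        for i in range(r)
    ))


def merge_categories(values_by_category: dict, alpha_merge: float = 0.05) -> list:
    """Kass merging: fuse the least-distinguishable pair until all differ.

    *values_by_category* maps category → outcome array.  Returns a list of
    frozensets of original categories.  A binary predictor is returned
    unchanged (its only merge would erase the predictor).
    """
    cats = list(values_by_category)
    if any(len(np.atleast_1d(values_by_category[c])) == 0 for c in cats):
        empty = [c for c in cats if len(np.atleast_1d(values_by_category[c])) == 0]
        raise ValueError(f"empty categories: {empty}")
    groups = [(frozenset([c]), np.atleast_1d(np.asarray(values_by_category[c], dtype=float)))
              for c in cats]
    if len(groups) <= 2:
        return [g for g, _ in groups]
    while len(groups) > 1:
        best_pair, best_p = None, -1.0
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                p = _anova_p([groups[i][1], groups[j][1]])
                if p > best_p:
                    best_pair, best_p = (i, j), p
        if best_p <= alpha_merge:
            break
        i, j = best_pair
        merged = (groups[i][0] | groups[j][0],
                  np.concatenate([groups[i][1], groups[j][1]]))
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]
    return [g for g, _ in groups]


def best_split(df: pd.DataFrame, outcome: str, config: ChaidConfig):
    """Most significant admissible split of *df*, or None.

    Returns ``(predictor, groups, p_adj)`` where groups is the merged
    categorization; None when every candidate would create a child smaller
    than min_node, or (with alpha_split set) when no adjusted p clears it.
    """
    y = df[outcome].to_numpy(dtype=float)
    best = None
    for pred in config.predictors:
        if pred not in df.columns:
            raise KeyError(f"predictor {pred!r} not in data")
        cats = pd.unique(df[pred])
        if len(cats) < 2:
            continue
        by_cat = {c: y[df[pred].to_numpy() == c] for c in cats}
        groups = merge_categories(by_cat, config.alpha_merge)
        if len(groups) < 2:
            continue
        sizes = [sum(len(by_cat[c]) for c in g) for g in groups]
        if min(sizes) < config.min_node:
            continue
        arrays = [np.concatenate([by_cat[c] for c in g]) for g in groups]
        p = _anova_p(arrays)
        if config.bonferroni:
            p = min(1.0, p * bonferroni_multiplier(len(cats), len(groups)))
        if config.alpha_split is not None and p > config.alpha_split:
            continue
        if best is None or p < best[2]:
            best = (pred, groups, p)
    return best


def grow_tree(
    data, config: Optional[ChaidConfig] = None, outcome: str = "pec50"
) -> ChaidNode:
    """Grow the CHAID tree; *data* is a PotencyEfficacyTable or analysis frame."""
    config = config or ChaidConfig()
    df = chaid_frame(data, outcome) if isinstance(data, PotencyEfficacyTable) else data
    for pred in config.predictors:
        if pred not in df.columns:
            raise KeyError(f"predictor {pred!r} not in data")
    if outcome not in df.columns:
        raise KeyError(f"outcome column {outcome!r} not in data")

    def build(sub: pd.DataFrame, conditions: tuple, depth: int) -> ChaidNode:
        node = ChaidNode(
            conditions=conditions, n=len(sub),
            mean=float(sub[outcome].mean()), depth=depth,
        )
        if depth >= config.max_depth or len(sub) < 2 * config.min_node:
            return node
        if sub[outcome].nunique() <= 1:
            return node  # nothing to explain in a constant node
        split = best_split(sub, outcome, config)
        if split is None:
            return node
        pred, groups, p = split
        node.split_var, node.p_adj = pred, p
        for g in groups:
            mask = sub[pred].isin(g)
            node.children.append(
                build(sub[mask], conditions + ((pred, g),), depth + 1)
            )
        return node

    return build(df, (), 1)


def node_mean(data, predicate: dict, outcome: str = "pec50"):
    """Count and mean outcome of rows matching a {predictor: value(s)} predicate."""
    df = chaid_frame(data, outcome) if isinstance(data, PotencyEfficacyTable) else data
    mask = pd.Series(True, index=df.index)
    for col, val in predicate.items():
        if col not in df.columns:
            raise KeyError(f"predicate column {col!r} not in data")
        allowed = val if isinstance(val, (set, frozenset, list, tuple)) else [val]
        mask &= df[col].isin(list(allowed))
    sub = df[mask]
    if len(sub) == 0:
        raise ValueError(f"predicate {predicate!r} matches no rows")
    return int(len(sub)), float(sub[outcome].mean())
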