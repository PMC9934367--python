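"""Hasse-diagram ΔpEC50 analysis of subunit contributions.

The receptors form a subset of the powerset lattice of subunits ordered by
inclusion.  Covering edges connect sets differing by exactly one subunit; each
edge is labelled "+<subunit>" with the added subunit and weighted, per ligand,
by ΔpEC50 = pEC50(larger set) − pEC50(smaller set).  Grouping the edges by
added subunit and putting a t-based 95% confidence interval on the mean delta
gives a model-free estimate of each subunit's potency contribution that can be
set against the linear factor model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .receptor_data import SUBUNIT_ORDER, PotencyEfficacyTable, SubunitSet

__all__ = [
    "LatticeEdge",
    "SubunitDeltaSummary",
    "build_hasse",
    "edge_deltas",
    "summarize_by_subunit",
    "edges_to_frame",
    "to_dot",
]


@dataclass(frozen=True)
class LatticeEdge:
    """One covering edge of the inclusion order, evaluated for one ligand."""

    smaller: SubunitSet
    larger: SubunitSet
    added_subunit: str
    ligand: Optional[str] = None
    delta: Optional[float] = None

    def __post_init__(self):
        if self.larger.members != self.smaller.members | {self.added_subunit}:
            raise ValueError("larger must equal smaller ∪ {added_subunit}")


@dataclass(frozen=True)
class SubunitDeltaSummary:
    """Mean ΔpEC50 of all "+subunit" edges with a 95% CI.

    significant is True when the CI excludes zero; with fewer than 2 edges the
    CI is undefined (NaN bounds) and ci_defined is False.
    """

    subunit: str
    n_edges: int
    mean_delta: float
    ci_low: float
    ci_high: float
    significant: bool
    ci_defined: bool = True


def build_hasse(receptors: Iterable[SubunitSet]) -> list:
    """Ligand-free edge skeleton: all pairs differing by exactly one subunit."""
    sets = sorted(set(receptors))
    if len(sets) < 2:
        raise ValueError("need at least 2 distinct subunit sets")
    edges = []
    for a, b in combinations(sets, 2):
        small, large = (a, b) if len(a) < len(b) else (b, a)
        if len(large) == len(small) + 1 and small.members < large.members:
            (added,) = large.members - small.members
            edges.append(LatticeEdge(small, large, added))
    return edges


def edge_deltas(
    skeleton: Sequence[LatticeEdge],
    table: PotencyEfficacyTable,
    ligands: Optional[Sequence[str]] = None,
) -> list:
    """Evaluate ΔpEC50 on every edge for every selected ligand."""
    ligands = list(ligands) if ligands is not None else table.ligands
    out = []
    for edge in skeleton:
        for lig in ligands:
            try:
                hi = table.pec50(edge.larger, lig)
                lo = table.pec50(edge.smaller, lig)
            except KeyError as exc:
                raise KeyError(
                    f"panel lacks a pEC50 needed for edge "
                    f"{edge.smaller.canonical} → {edge.larger.canonical}: {exc}"
                ) from exc
            out.append(LatticeEdge(edge.smaller, edge.larger, edge.added_subunit,
                                   ligand=lig, delta=hi - lo))
    return out


def summarize_by_subunit(
    edges: Sequence[LatticeEdge],
    per_ligand: bool = False,
    alpha: float = 0.05,
) -> list:
    """Group evaluated edges by added subunit (optionally × ligand) and
    summarize the deltas with a mean and a t-based CI.

    CI: mean ± t(1−alpha/2, n−1) · s/√n, treating edge deltas as independent
    observations; with n = 1 the CI is reported undefined rather than guessed.
    """
    if any(e.delta is None for e in edges):
        raise ValueError("edges must carry deltas; run edge_deltas first")
    keys = sorted(
        {(e.added_subunit, e.ligand if per_ligand else None) for e in edges},
        key=lambda k: (SUBUNIT_ORDER.index(k[0]), str(k[1])),
    )
    out = []
    for subunit, lig in keys:
        vals = np.array([
            e.delta for e in edges
            if e.added_subunit == subunit and (not per_ligand or e.ligand == lig)
        ])
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2:
            sd = float(vals.std(ddof=1))
            half = stats.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
            lo, hi = mean - half, mean + half
            summary = SubunitDeltaSummary(
                subunit=subunit, n_edges=n, mean_delta=mean,
                ci_low=float(lo), ci_high=float(hi),
                significant=not (lo <= 0.0 <= hi), ci_defined=True,
            )
        else:
            summary = SubunitDeltaSummary(
                subunit=subunit, n_edges=n, mean_delta=mean,
                ci_low=float("nan"), ci_high=float("nan"),
                significant=False, ci_defined=False,
            )
        if per_ligand:
            summary = (lig, summary)
        out.append(summary)
    return out


def edges_to_frame(edges: Sequence[LatticeEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "smaller": [e.smaller.canonical for e in edges],
            "larger": [e.larger.canonical for e in edges],
            "added_subunit": [e.added_subunit for e in edges],
            "ligand": [e.ligand for e in edges],
            "delta": [e.delta for e in edges],
        }
    )


def to_dot(edges: Sequence[LatticeEdge]) -> str:
    """GraphViz DOT rendering of the (evaluated or skeleton) lattice."""
    lines = ["digraph hasse {", "  rankdir=BT;"]
    nodes = {e.smaller for e in edges} | {e.larger for e in edges}
    for node in sorted(nodes):
        lines.append(f'  "{node.canonical}" [label="{node.display}"];')
    for e in edges:
        label = f"+{e.added_subunit}"
        if e.delta is not None:
            label += f" ({e.ligand}: {e.delta:+.2f})"
        lines.append(f'  "{e.smaller.canonical}" -> "{e.larger.canonical}" [label="{label}"];')
    lines.append("}")
    return "\n".join(lines)
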