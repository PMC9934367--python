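"""Domain types and CSV I/O for receptor subunit combinations and potency panels.

A *Drosophila melanogaster* nicotinic acetylcholine receptor (nAChR) is a
pentamer assembled from a combination of alpha (Dα1–Dα4) and beta (Dβ1–Dβ3)
subunits.  Here a receptor is identified purely by the *set* of distinct
subunits it contains (presence/absence, not stoichiometry).  Subunit names are
stored ASCII-normalized ("Da1", "Db1", ...) to keep CSV round-trips
encoding-safe; Greek rendering ("Dα1") is a display concern only.

The module also ships a machine-readable copy of the published potency/efficacy
panel: mean ± SE of pEC50 and Imax for 18 subunit combinations × 4 agonists
(ACh and the neonicotinoids imidacloprid, thiacloprid, clothianidin), n = 5
oocytes per value.  The 12-receptor "core panel" (combinations of Dα1, Dα2,
Dα3, Dβ2 with the obligatory Dβ1) feeds the factor-model, CHAID and lattice
analyses; the remaining 6 rows carry Dα4/Dβ3 substitutions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "SUBUNIT_ORDER",
    "LIGANDS",
    "REFERENCE_LIGAND",
    "SubunitSet",
    "PotencyEfficacyTable",
    "ParseError",
    "ValidationError",
    "parse_subunit_set",
    "parse_ligand",
    "load_potency_table",
    "write_potency_table",
    "load_table1_fixture",
]

#: Canonical subunit ordering used for the "/"-joined string form.
SUBUNIT_ORDER = ("Da1", "Da2", "Da3", "Da4", "Db1", "Db2", "Db3")

#: Greek display names, index-aligned with SUBUNIT_ORDER.
_GREEK = ("Dα1", "Dα2", "Dα3", "Dα4", "Dβ1", "Dβ2", "Dβ3")

_ASCII_BY_ALIAS = {}
for _a, _g in zip(SUBUNIT_ORDER, _GREEK):
    _ASCII_BY_ALIAS[_a.lower()] = _a
    _ASCII_BY_ALIAS[_g.lower()] = _a

#: Recognized agonists; ACh is the normalization reference (Imax ≡ 1).
LIGANDS = ("ACh", "imidacloprid", "thiacloprid", "clothianidin")
REFERENCE_LIGAND = "ACh"

_LIGAND_BY_ALIAS = {name.lower(): name for name in LIGANDS}
_LIGAND_BY_ALIAS["acetylcholine"] = "ACh"


class ParseError(ValueError):
    """Unrecognized token while parsing a subunit set or ligand name."""


class ValidationError(ValueError):
    """A domain invariant is violated."""


@dataclass(frozen=True)
class SubunitSet:
    """An unordered, duplicate-free set of nAChR subunit identifiers.

    Immutable and hashable so it can key potency tables and lattice nodes.
    The Dβ1 subunit is essential for functional expression of every receptor
    in this panel; :meth:`is_functional` checks for it.
    """

    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValidationError("a subunit set must be non-empty")
        unknown = set(self.members) - set(SUBUNIT_ORDER)
        if unknown:
            raise ValidationError(f"unknown subunit identifiers: {sorted(unknown)}")

    @property
    def canonical(self) -> str:
        """Stable "/"-joined ASCII form in fixed subunit order."""
        return "/".join(s for s in SUBUNIT_ORDER if s in self.members)

    @property
    def display(self) -> str:
        """Greek-lettered rendering for human-facing output."""
        return "/".join(g for a, g in zip(SUBUNIT_ORDER, _GREEK) if a in self.members)

    @property
    def is_functional(self) -> bool:
        return "Db1" in self.members

    def presence_vector(self, covariates: Iterable[str]) -> tuple:
        """Binary presence indicators in the order given by *covariates*."""
        return tuple(int(c in self.members) for c in covariates)

    def __contains__(self, subunit: str) -> bool:
        return subunit in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __or__(self, other: "SubunitSet") -> "SubunitSet":
        return SubunitSet(self.members | other.members)

    def union(self, *subunits: str) -> "SubunitSet":
        return SubunitSet(self.members | frozenset(subunits))

    def __str__(self) -> str:
        return self.canonical

    def __repr__(self) -> str:
        return f"SubunitSet({self.canonical!r})"

    def __lt__(self, other: "SubunitSet") -> bool:
        # sort by size then canonical form; gives a stable panel ordering
        return (len(self.members), self.canonical) < (len(other.members), other.canonical)


def parse_subunit_set(text: str) -> SubunitSet:
    """Parse a "/"-separated subunit list ("Dα1/Dβ1" or "Da1/Db1") into a set.

    Raises :class:`ParseError` on an unrecognized token and
    :class:`ValidationError` on a duplicated subunit.  Parsing the canonical
    form of the result reproduces the same set (round-trip).
    """
    if not isinstance(text, str) or not text.strip():
        raise ParseError("empty subunit set string")
    seen = []
    for token in text.split("/"):
        token = token.strip()
        ascii_name = _ASCII_BY_ALIAS.get(token.lower())
        if ascii_name is None:
            raise ParseError(f"unknown subunit name: {token!r}")
        if ascii_name in seen:
            raise ValidationError(f"duplicate subunit: {token!r}")
        seen.append(ascii_name)
    return SubunitSet(frozenset(seen))


def parse_ligand(name: str) -> str:
    """Normalize a ligand name to its canonical form."""
    canonical = _LIGAND_BY_ALIAS.get(str(name).strip().lower())
    if canonical is None:
        raise ParseError(f"unknown ligand: {name!r}")
    return canonical


_TABLE_COLUMNS = [
    "receptor", "ligand", "pec50_mean", "pec50_se",
    "imax_mean", "imax_se", "n", "core_panel",
]


class PotencyEfficacyTable:
    """Panel of (receptor, ligand) → pEC50/Imax summaries.

    Thin validated wrapper around a pandas DataFrame with columns
    ``receptor`` (SubunitSet), ``ligand``, ``pec50_mean``, ``pec50_se``,
    ``imax_mean``, ``imax_se``, ``n``, ``core_panel``.  Extra columns (e.g. a
    true Hill slope carried by synthetic truth tables) are preserved.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _TABLE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        frame = frame.copy()
        frame["receptor"] = [
            r if isinstance(r, SubunitSet) else parse_subunit_set(r)
            for r in frame["receptor"]
        ]
        frame["ligand"] = [parse_ligand(l) for l in frame["ligand"]]
        self._validate(frame)
        self.frame = frame.reset_index(drop=True)

    @staticmethod
    def _validate(frame: pd.DataFrame) -> None:
        dup = frame.duplicated(subset=["receptor", "ligand"])
        if dup.any():
            raise ValidationError(
                f"duplicate (receptor, ligand) rows at index {list(frame.index[dup])}"
            )
        pec = pd.to_numeric(frame["pec50_mean"], errors="coerce")
        if pec.isna().any():
            raise ValidationError(
                f"non-numeric pec50_mean at index {list(frame.index[pec.isna()])}"
            )
        bad = ~pec.between(2.0, 12.0)
        if bad.any():
            raise ValidationError(
                f"pec50_mean outside [2, 12] at index {list(frame.index[bad])}"
            )
        imax = pd.to_numeric(frame["imax_mean"], errors="coerce")
        if imax.isna().any() or (imax < 0).any():
            raise ValidationError("imax_mean must be numeric and non-negative")
        ref = frame["ligand"] == REFERENCE_LIGAND
        if ref.any() and not (imax[ref] == 1.0).all():
            raise ValidationError(
                f"{REFERENCE_LIGAND} rows must have imax_mean = 1 (normalization reference)"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def receptors(self) -> list:
        """Distinct receptors in stable (size, canonical) order."""
        return sorted(set(self.frame["receptor"]))

    @property
    def ligands(self) -> list:
        return [l for l in LIGANDS if l in set(self.frame["ligand"])]

    def core_panel(self) -> "PotencyEfficacyTable":
        """Restrict to the 12-receptor core panel used for the factor analyses."""
        return PotencyEfficacyTable(self.frame[self.frame["core_panel"]].copy())

    def lookup(self, receptor, ligand: str) -> pd.Series:
        """The single row for (receptor, ligand); KeyError if absent."""
        if not isinstance(receptor, SubunitSet):
            receptor = parse_subunit_set(receptor)
        ligand = parse_ligand(ligand)
        mask = (self.frame["receptor"] == receptor) & (self.frame["ligand"] == ligand)
        sub = self.frame[mask]
        if len(sub) == 0:
            raise KeyError(f"no row for ({receptor.canonical}, {ligand})")
        return sub.iloc[0]

    def pec50(self, receptor, ligand: str) -> float:
        return float(self.lookup(receptor, ligand)["pec50_mean"])

    def imax(self, receptor, ligand: str) -> float:
        return float(self.lookup(receptor, ligand)["imax_mean"])

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["receptor"] = [r.canonical for r in out["receptor"]]
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, PotencyEfficacyTable):
            return NotImplemented
        a = self.to_frame().sort_values(["receptor", "ligand"]).reset_index(drop=True)
        b = other.to_frame().sort_values(["receptor", "ligand"]).reset_index(drop=True)
        return a.equals(b)


def load_potency_table(path: Union[str, Path, io.IOBase]) -> PotencyEfficacyTable:
    """Read and validate a potency/efficacy panel CSV.

    Expected header: ``receptor,ligand,pec50_mean,pec50_se,imax_mean,imax_se,
    n,core_panel``; receptor in canonical "/" form (Greek or ASCII accepted).
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty or unreadable potency table: {exc}") from exc
    if frame.empty:
        raise ValidationError("potency table has no data rows")
    if "core_panel" in frame.columns and frame["core_panel"].dtype == object:
        frame["core_panel"] = frame["core_panel"].astype(str).str.lower() == "true"
    return PotencyEfficacyTable(frame)


def write_potency_table(table: PotencyEfficacyTable, path: Union[str, Path, io.IOBase]) -> None:
    """Write a panel to CSV so that :func:`load_potency_table` round-trips it."""
    table.to_frame().to_csv(path, index=False)


def load_table1_fixture() -> PotencyEfficacyTable:
    """The bundled published panel: 18 receptors × 4 ligands.

    Reference-agonist (ACh) efficacy rows are materialized as Imax = 1.0 with
    SE 0, which the normalization rule implies; pEC50 rows carry the printed
    mean ± SE (n = 5 oocytes throughout).
    """
    with resources.files("nachr_pharm.data").joinpath("table1.csv").open("r") as fh:
        return load_potency_table(fh)
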