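"""Hexamer active-site occupancy analysis and filling order.

Hexameric purine nucleoside phosphorylases are trimers of dimers: each
monomer's active site is completed by residues donated by its dimer
partner, and every site adopts either an open or a closed conformation.
Crystallographic occupancy factors of a nucleoside-site ligand (formycin A)
refined for a series of complexes at increasing ligand:hexamer molar ratios
reveal which *class* of site fills first.  Sites fall into three classes
determined by the conformation of a site and of its dimer partner:

* ``closed`` — the site itself is closed;
* ``open_in_closed_open_dimer`` — open site paired with a closed one;
* ``open_in_open_open_dimer`` — open site whose partner is also open.

In hexagonal crystal forms only half the hexamer is crystallographically
independent; the other half is generated here by symmetry expansion
(primed chain ids) so both space groups share one data model.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SiteClass",
    "ChainRecord",
    "OccupancyTable",
    "classify_sites",
    "class_mean_occupancy",
    "filling_order",
    "FillingStep",
    "read_occupancy_csv",
    "load_reference_occupancy_series",
]


class SiteClass(enum.Enum):
    CLOSED = "closed"
    OPEN_IN_CLOSED_OPEN_DIMER = "open_in_closed_open_dimer"
    OPEN_IN_OPEN_OPEN_DIMER = "open_in_open_open_dimer"


@dataclass(frozen=True)
class ChainRecord:
    """One monomer: active-site conformation and ligand occupancy.

    ``fa_occupancy`` is None when no ligand was modelled in the site
    ("no FA"), which is distinct from a refined low occupancy.
    """

    chain_id: str
    conformation: str  # "open" | "closed"
    fa_occupancy: float | None

    def __post_init__(self) -> None:
        if self.conformation not in ("open", "closed"):
            raise ValueError(f"conformation must be open/closed, got {self.conformation!r}")
        if self.fa_occupancy is not None and not 0.0 <= self.fa_occupancy <= 1.0:
            raise ValueError(f"occupancy must lie in [0, 1], got {self.fa_occupancy}")


@dataclass(frozen=True)
class OccupancyTable:
    """Per-chain conformations and occupancies of one complex.

    ``dimer_map`` lists the chain-id pairs forming dimers; every chain must
    belong to exactly one pair.
    """

    structure_id: str
    molar_ratio: float
    chains: tuple[ChainRecord, ...]
    dimer_map: tuple[tuple[str, str], ...]
    space_group: str = ""

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chain ids")
        seen: list[str] = []
        for x, y in self.dimer_map:
            seen.extend((x, y))
        if sorted(seen) != sorted(ids) or len(set(seen)) != len(seen):
            raise ValueError(
                f"{self.structure_id}: every chain must belong to exactly one dimer"
            )
        if self.molar_ratio < 0:
            raise ValueError("molar_ratio must be non-negative")

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def partner_of(self, chain_id: str) -> str:
        for x, y in self.dimer_map:
            if x == chain_id:
                return y
            if y == chain_id:
                return x
        raise KeyError(f"chain {chain_id!r} has no dimer partner")


def symmetry_expand(
    chains: Sequence[ChainRecord], dimer_map: Sequence[tuple[str, str]]
) -> tuple[tuple[ChainRecord, ...], tuple[tuple[str, str], ...]]:
    """Generate the symmetry-related half of a hexagonal half-hexamer.

    Every stored chain X gets a primed copy X' inheriting its conformation
    and occupancy.  A dimer pair within the stored half (A-D) is duplicated
    as (A'-D'); a pair that already crosses the symmetry axis (B-B') is
    kept as is.
    """
    out_chains = list(chains)
    for c in chains:
        out_chains.append(
            ChainRecord(c.chain_id + "'", c.conformation, c.fa_occupancy)
        )
    out_pairs: list[tuple[str, str]] = []
    for x, y in dimer_map:
        if y == x + "'" or x == y + "'":
            out_pairs.append((x, y))
        else:
            out_pairs.append((x, y))
            out_pairs.append((x + "'", y + "'"))
    return tuple(out_chains), tuple(out_pairs)


def classify_sites(table: OccupancyTable) -> dict[str, SiteClass]:
    """Site class of every chain from (own, partner) conformations."""
    out: dict[str, SiteClass] = {}
    for c in table.chains:
        partner = table.chain(table.partner_of(c.chain_id))
        if c.conformation == "closed":
            out[c.chain_id] = SiteClass.CLOSED
        elif partner.conformation == "closed":
            out[c.chain_id] = SiteClass.OPEN_IN_CLOSED_OPEN_DIMER
        else:
            out[c.chain_id] = SiteClass.OPEN_IN_OPEN_OPEN_DIMER
    return out


def class_mean_occupancy(table: OccupancyTable, site_class: SiteClass) -> float:
    """Mean occupancy over the member sites of one class.

    Unmodelled ligands ("no FA") count as occupancy 0.  Returns NaN when
    the class has no member sites in this hexamer.
    """
    classes = classify_sites(table)
    vals = [
        (c.fa_occupancy or 0.0)
        for c in table.chains
        if classes[c.chain_id] is site_class
    ]
    if not vals:
        return math.nan
    return sum(vals) / len(vals)


@dataclass(frozen=True)
class FillingStep:
    site_class: SiteClass
    first_occupied_ratio: float | None  # None == never reaches the threshold


def filling_order(
    series: Iterable[OccupancyTable], occ_threshold: float = 0.4
) -> list[FillingStep]:
    """Order in which site classes fill along a molar-ratio series.

    For each site class, the smallest molar ratio at which its mean
    occupancy reaches ``occ_threshold`` (default 0.4, the smallest refined
    occupancy treated as a present ligand).  Classes are returned sorted by
    that ratio; classes that never reach it come last.
    """
    tables = sorted(series, key=lambda t: t.molar_ratio)
    if not tables:
        raise ValueError("empty occupancy series")
    if not 0 < occ_threshold < 1:
        raise ValueError("occ_threshold must lie in (0, 1)")
    first: dict[SiteClass, float | None] = {}
    for sc in SiteClass:
        first[sc] = None
        for tab in tables:
            occ = class_mean_occupancy(tab, sc)
            if not math.isnan(occ) and occ >= occ_threshold:
                first[sc] = tab.molar_ratio
                break
    steps = [FillingStep(sc, r) for sc, r in first.items()]
    steps.sort(
        key=lambda s: (s.first_occupied_ratio is None,
                       s.first_occupied_ratio if s.first_occupied_ratio is not None else 0.0)
    )
    return steps


# ---------------------------------------------------------------------------
# CSV schema: structure_id, enzyme_form, space_group, molar_ratio, chain,
# partner, conformation, occupancy (empty cell == no ligand modelled)
# ---------------------------------------------------------------------------

_HEXAGONAL = {"P6122", "P 61 2 2"}


def _tables_from_frame(df: pd.DataFrame) -> list[OccupancyTable]:
    tables = []
    for sid, grp in df.groupby("structure_id", sort=False):
        chains = []
        pairs: list[tuple[str, str]] = []
        for _, row in grp.iterrows():
            occ = row["occupancy"]
            occ = None if pd.isna(occ) else float(occ)
            chains.append(ChainRecord(str(row["chain"]), str(row["conformation"]), occ))
            pair = tuple(sorted((str(row["chain"]), str(row["partner"]))))
            if pair not in pairs:
                pairs.append(pair)
        sg = str(grp["space_group"].iloc[0]).replace(" ", "")
        if sg in _HEXAGONAL:
            chains, pairs = symmetry_expand(chains, pairs)
        tables.append(
            OccupancyTable(
                structure_id=str(sid),
                molar_ratio=float(grp["molar_ratio"].iloc[0]),
                chains=tuple(chains),
                dimer_map=tuple(pairs),
                space_group=sg,
            )
        )
    return tables


def read_occupancy_csv(path) -> list[OccupancyTable]:
    """Read an occupancy-series CSV (see module docstring for the schema)."""
    df = pd.read_csv(path)
    required = {
        "structure_id", "space_group", "molar_ratio",
        "chain", "partner", "conformation", "occupancy",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s) in {path}: {sorted(missing)}")
    return _tables_from_frame(df)


def load_reference_occupancy_series(enzyme_form: str = "WT") -> list[OccupancyTable]:
    """Packaged co-crystallisation series for the wild-type or the
    Asp204Ala/Arg217Ala double mutant, sorted by molar ratio."""
    with resources.files("allokin.data").joinpath("occupancy_series.csv").open() as fh:
        df = pd.read_csv(fh)
    df = df[df["enzyme_form"] == enzyme_form]
    if df.empty:
        raise ValueError(f"unknown enzyme_form {enzyme_form!r} (use 'WT' or 'DM')")
    return sorted(_tables_from_frame(df), key=lambda t: t.molar_ratio)
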