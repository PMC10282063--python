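"""Data model for the combinatorial salen/salan ligand space.

A symmetric tetradentate ligand for an Al polymerization catalyst is built
from two kinds of building block: an arene ring (fragment ``A_m``, carrying
the phenolate substituents) and an amine linker (fragment ``B_nC_p``,
carrying the N-substituent and the backbone that makes the ligand salen- or
salan-type). Because the ligand is symmetric, one arene id plus one linker
id identifies the whole molecule, and the accessible design space is the
Cartesian product of the two fragment sets.

This module holds the fragment/ligand/record containers, library
enumeration, the synthetic-scale cost metric (summed expected synthesis
steps of the two fragments), delimited-text dataset I/O, and small
stoichiometric utilities such as the theoretical molecular weight implied by
feed ratio and conversion.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FamilyMismatchError,
    SchemaError,
    UnknownSyntheticCostError,
    ValidationError,
)

ARENE = "arene-A"
LINKER = "linker-BC"
FAMILIES = (ARENE, LINKER)

#: Molar mass of lactide (C6H8O4), g/mol. One ring adds two lactate units.
LACTIDE_MW = 144.13

#: Molar mass of the benzyl-alcohol chain end, g/mol (optional end group).
BENZYL_ALCOHOL_MW = 108.14

DATASET_COLUMNS = [
    "a_id",
    "bc_id",
    "temp_C",
    "conc_M",
    "ratio",
    "p_m",
    "conversion",
    "m_n_kDa",
    "dispersity",
    "source",
]

_RELATIONS = {
    ">": operator.gt,
    "<": operator.lt,
    ">=": operator.ge,
    "<=": operator.le,
    "≥": operator.ge,
    "≤": operator.le,
}


@dataclass(frozen=True)
class Atom:
    """One heavy (or hydrogen) atom of a molecular graph."""

    element: str
    atomic_number: int
    valence_electrons: int
    principal_quantum_number: int


@dataclass(frozen=True)
class MolecularGraph:
    """Minimal molecular graph: atoms plus undirected bonds (index pairs)."""

    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int], ...]
    coords: np.ndarray | None = None  # (n_atoms, 3) in Angstrom

    def degree(self, i: int) -> int:
        return sum(1 for a, b in self.bonds if i in (a, b))


@dataclass(frozen=True)
class Fragment:
    """A ligand building block: an arene ring or an amine linker.

    ``synthetic_steps`` is the expected number of synthesis steps to prepare
    the fragment; ``None`` means unknown cost (never silently zero).
    """

    id: str
    family: str
    structure: MolecularGraph | None = None
    smiles: str | None = None
    synthetic_steps: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise FamilyMismatchError(
                f"fragment {self.id!r}: family must be one of {FAMILIES}, "
                f"got {self.family!r}"
            )
        if self.synthetic_steps is not None and self.synthetic_steps < 0:
            raise ValidationError(
                f"fragment {self.id!r}: synthetic_steps must be >= 0"
            )


@dataclass(frozen=True)
class Ligand:
    """A symmetric A-BC-A ligand, identified by its two fragment ids."""

    a_id: str
    bc_id: str

    @property
    def id(self) -> str:
        return f"{self.a_id}{self.bc_id}"


@dataclass
class CatalystRecord:
    """One polymerization experiment with a given ligand and conditions.

    ``p_m`` is the probability of meso dyad linkages in the product PLA
    (``p_r = 1 - p_m`` is the probability of racemic linkages); conversion
    is a fraction in [0, 1]; ``m_n`` in kDa and dispersity are optional.
    """

    ligand: Ligand
    p_m: float
    temperature: float | None = None
    monomer_conc: float | None = None
    feed_ratio: float | None = None
    conversion: float | None = None
    m_n: float | None = None
    dispersity: float | None = None
    source: str = "literature"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_m <= 1.0):
            raise ValidationError(f"p_m must lie in [0, 1], got {self.p_m}")
        if self.conversion is not None and not (0.0 <= self.conversion <= 1.0):
            raise ValidationError(
                f"conversion must lie in [0, 1], got {self.conversion}"
            )
        if self.dispersity is not None and self.dispersity < 1.0:
            raise ValidationError(f"dispersity must be >= 1, got {self.dispersity}")

    @property
    def p_r(self) -> float:
        return 1.0 - self.p_m


@dataclass
class Dataset:
    """An ordered collection of catalyst records plus a fragment registry."""

    records: list[CatalystRecord] = field(default_factory=list)
    fragment_registry: dict[str, Fragment] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ligand_ids(self) -> list[str]:
        return [r.ligand.id for r in self.records]

    def outcome(self, field_name: str) -> np.ndarray:
        """Vector of one outcome over records (``p_r`` is derived)."""
        known = {
            "p_m", "p_r", "conversion", "m_n", "dispersity",
            "temperature", "monomer_conc", "feed_ratio",
        }
        if field_name not in known:
            raise SchemaError(f"unknown outcome field {field_name!r}")
        if field_name == "p_r":
            return np.array([r.p_r for r in self.records])
        return np.array(
            [getattr(r, field_name) for r in self.records], dtype=float
        )

    def validate(self) -> None:
        """Check ligand references resolve against the registry."""
        if not self.fragment_registry:
            return
        for rec in self.records:
            for fid, fam in (
                (rec.ligand.a_id, ARENE),
                (rec.ligand.bc_id, LINKER),
            ):
                frag = self.fragment_registry.get(fid)
                if frag is None:
                    raise SchemaError(f"ligand references unknown fragment {fid!r}")
                if frag.family != fam:
                    raise FamilyMismatchError(
                        f"fragment {fid!r} has family {frag.family!r}, "
                        f"expected {fam!r}"
                    )


def enumerate_library(
    arene_set: Sequence[Fragment], linker_set: Sequence[Fragment]
) -> list[Ligand]:
    """Enumerate every symmetric ligand from the two fragment sets.

    Returns the full Cartesian product in lexicographic (a_id, bc_id)
    order. The combinatorial explosion this enables — e.g. 16 arenes x 36
    linkers = 576 ligands — is exactly why fragment-level descriptors are
    computed once per fragment and concatenated per ligand.
    """
    for frag in arene_set:
        if frag.family != ARENE:
            raise FamilyMismatchError(
                f"fragment {frag.id!r} in arene set has family {frag.family!r}"
            )
    for frag in linker_set:
        if frag.family != LINKER:
            raise FamilyMismatchError(
                f"fragment {frag.id!r} in linker set has family {frag.family!r}"
            )
    a_ids = [f.id for f in arene_set]
    bc_ids = [f.id for f in linker_set]
    if len(set(a_ids)) != len(a_ids) or len(set(bc_ids)) != len(bc_ids):
        raise ValidationError("fragment ids must be unique within each set")
    return [
        Ligand(a_id=a, bc_id=bc) for a in sorted(a_ids) for bc in sorted(bc_ids)
    ]


def synthetic_scale(ligand: Ligand, registry: Mapping[str, Fragment]) -> int:
    """Synthetic-scale cost of a ligand: steps(A_m) + steps(B_nC_p).

    This is the cost metric used to keep proposed catalysts practical to
    make; campaign proposal filters ligands whose total exceeds a step
    budget (3 by default).
    """
    total = 0
    for fid in (ligand.a_id, ligand.bc_id):
        frag = registry.get(fid)
        if frag is None:
            raise SchemaError(f"fragment {fid!r} not in registry")
        if frag.synthetic_steps is None:
            raise UnknownSyntheticCostError(
                f"fragment {fid!r} has no synthetic step count"
            )
        total += frag.synthetic_steps
    return total


def filter_by_scale(
    ligands: Iterable[Ligand],
    registry: Mapping[str, Fragment],
    max_steps: int,
) -> list[Ligand]:
    """Keep only ligands whose synthetic scale is at most ``max_steps``."""
    return [lg for lg in ligands if synthetic_scale(lg, registry) <= max_steps]


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def load_dataset(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    fragment_registry: Mapping[str, Fragment] | None = None,
) -> Dataset:
    """Load a catalyst dataset from delimited text.

    The default schema expects columns ``a_id, bc_id, temp_C, conc_M,
    ratio, p_m, conversion, m_n_kDa, dispersity, source`` (optional fields
    may be empty). ``schema`` maps canonical names to file column names.
    If only one of p_m / p_r is present, the other is filled as its
    complement.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty dataset file") from exc
    if schema:
        frame = frame.rename(columns={v: k for k, v in schema.items()})

    for col in ("a_id", "bc_id"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if "p_m" not in frame.columns and "p_r" not in frame.columns:
        raise SchemaError(f"{path}: missing required column 'p_m' (or 'p_r')")
    if "p_m" not in frame.columns:
        frame["p_m"] = 1.0 - frame["p_r"].astype(float)

    records = []
    for idx, row in frame.iterrows():
        p_m = float(row["p_m"])
        if not (0.0 <= p_m <= 1.0):
            raise ValidationError(f"{path}: row {idx}: p_m={p_m} outside [0, 1]")
        records.append(
            CatalystRecord(
                ligand=Ligand(a_id=str(row["a_id"]), bc_id=str(row["bc_id"])),
                p_m=p_m,
                temperature=_opt(row.get("temp_C")),
                monomer_conc=_opt(row.get("conc_M")),
                feed_ratio=_opt(row.get("ratio")),
                conversion=_opt(row.get("conversion")),
                m_n=_opt(row.get("m_n_kDa")),
                dispersity=_opt(row.get("dispersity")),
                source=str(row["source"]) if "source" in frame.columns
                and not pd.isna(row.get("source")) else "literature",
            )
        )
    dataset = Dataset(
        records=records, fragment_registry=dict(fragment_registry or {})
    )
    dataset.validate()
    return dataset


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset back to the delimited-text schema (round-trippable)."""
    rows = [
        {
            "a_id": r.ligand.a_id,
            "bc_id": r.ligand.bc_id,
            "temp_C": r.temperature,
            "conc_M": r.monomer_conc,
            "ratio": r.feed_ratio,
            "p_m": r.p_m,
            "conversion": r.conversion,
            "m_n_kDa": r.m_n,
            "dispersity": r.dispersity,
            "source": r.source,
        }
        for r in dataset.records
    ]
    pd.DataFrame(rows, columns=DATASET_COLUMNS).to_csv(path, index=False)


def count_by_threshold(
    dataset: Dataset, field_name: str, relation: str, threshold: float
) -> int:
    """Count records whose outcome satisfies ``field relation threshold``."""
    if relation not in _RELATIONS:
        raise ValidationError(f"unknown relation {relation!r}")
    values = dataset.outcome(field_name)
    op = _RELATIONS[relation]
    return int(np.sum([op(v, threshold) for v in values]))


def theoretical_mn(
    conversion: float,
    feed_ratio: float,
    monomer_mw: float = LACTIDE_MW,
    end_group_mw: float = 0.0,
) -> float:
    """Theoretical number-average molecular weight, in kDa.

    MW_cal = (conversion x [monomer]/[initiator] x monomer MW + end group)
    / 1000: every initiator grows one chain, so the chain picks up
    ``conversion x feed_ratio`` monomer units.
    """
    if not (0.0 <= conversion <= 1.0):
        raise ValidationError(f"conversion must lie in [0, 1], got {conversion}")
    if feed_ratio <= 0:
        raise ValidationError(f"feed_ratio must be > 0, got {feed_ratio}")
    if monomer_mw < 0 or end_group_mw < 0:
        raise ValidationError("molar masses must be nonnegative")
    return (conversion * feed_ratio * monomer_mw + end_group_mw) / 1000.0


def load_fragment_registry(path: str | Path) -> dict[str, Fragment]:
    """Load a fragment registry from delimited text.

    Expected columns: ``id, family, smiles, steps`` (optionally
    ``xyz_path``); blank steps mean unknown cost.
    """
    frame = pd.read_csv(path)
    for col in ("id", "family"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    registry: dict[str, Fragment] = {}
    for _, row in frame.iterrows():
        steps = row.get("steps")
        registry[str(row["id"])] = Fragment(
            id=str(row["id"]),
            family=str(row["family"]),
            smiles=None if pd.isna(row.get("smiles")) else str(row["smiles"]),
            synthetic_steps=None if pd.isna(steps) else int(steps),
        )
    return registry


def with_source(record: CatalystRecord, source: str) -> CatalystRecord:
    """Copy of a record with a new provenance tag."""
    return replace(record, source=source)
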