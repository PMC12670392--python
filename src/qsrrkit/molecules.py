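"""Structure ingestion, standardization, and duplicate merging.

Calibration corpora for retention-index models arrive as SMILES strings with
experimental retention indices.  This module parses SMILES into lightweight
hydrogen-depleted molecular graphs, assigns a canonical key so that the same
structure drawn two ways is recognised as one compound, and merges duplicate
records by averaging their retention indices (duplicates are common when
several sources report the same flavour compound).

Duplicate identity is structural (canonical graph), deliberately stricter
than formula matching, which would merge constitutional isomers.
Stereochemistry is stripped before canonicalization because all descriptors
used downstream are 2D/topological.  Multi-component SMILES (salts, mixtures)
are rejected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "RIRecord",
    "SmilesParseError",
    "parse_smiles",
    "merge_duplicates",
    "read_smi",
    "read_records_csv",
    "write_records_csv",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a single molecule."""

    def __init__(self, smiles: str, reason: str, position: int | None = None):
        self.smiles = smiles
        self.reason = reason
        self.position = position
        loc = f" near position {position}" if position is not None else ""
        super().__init__(f"cannot parse SMILES {smiles!r}{loc}: {reason}")


@dataclass(frozen=True)
class Molecule:
    """Hydrogen-depleted molecular graph with a canonical identity key.

    ``atoms`` holds ``(element, formal_charge, aromatic)`` triples and
    ``bonds`` holds ``(i, j, order)`` with ``order`` in ``{1, 2, 3}`` or
    ``"ar"`` for aromatic bonds.  ``canonical_key`` is identical for any two
    SMILES encodings of the same (stereo-stripped) structure.
    """

    atoms: tuple[tuple[str, int, bool], ...]
    bonds: tuple[tuple[int, int, object], ...]
    smiles_source: str
    canonical_key: str

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def neighbors(self) -> list[list[int]]:
        """Adjacency lists over heavy atoms."""
        adj: list[list[int]] = [[] for _ in self.atoms]
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def to_rdkit(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.canonical_key)


@dataclass
class RIRecord:
    """A molecule together with its experimental retention index."""

    molecule: Molecule
    ri_experimental: float | None
    identifier: str

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("identifier must be nonempty")
        if self.ri_experimental is not None and self.ri_experimental <= 0:
            raise ValueError(
                f"retention index must be positive, got {self.ri_experimental}"
            )


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "ar",
}


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a hydrogen-depleted :class:`Molecule`.

    Stereochemistry is discarded.  Raises :class:`SmilesParseError` for
    malformed input and for multi-component SMILES (salts/mixtures).
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty SMILES")
    smiles = smiles.strip()
    if "." in smiles:
        raise SmilesParseError(
            smiles, "multi-component SMILES (salt/mixture) not supported",
            position=smiles.index("."),
        )
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        # locate the offending token for the error message
        pos = _first_bad_position(smiles)
        raise SmilesParseError(smiles, "invalid SMILES syntax or valence", pos)
    Chem.RemoveStereochemistry(mol)
    canonical = Chem.MolToSmiles(mol)
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic())
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER[b.GetBondType()])
        for b in mol.GetBonds()
    )
    return Molecule(atoms=atoms, bonds=bonds, smiles_source=smiles,
                    canonical_key=canonical)


def _first_bad_position(smiles: str) -> int | None:
    """Best-effort localisation of the first unparseable prefix."""
    for end in range(1, len(smiles) + 1):
        if Chem.MolFromSmiles(smiles[:end]) is None:
            # a dangling ring-closure/branch can recover later; only report
            # positions where no longer prefix parses either
            if all(Chem.MolFromSmiles(smiles[:e]) is None
                   for e in range(end, len(smiles) + 1)):
                return end - 1
    return None


def merge_duplicates(records: Iterable[RIRecord]) -> list[RIRecord]:
    """Merge records sharing a canonical structure; average their RIs.

    One record per canonical key is returned, sorted by key.  The merged
    retention index is the arithmetic mean of the members' indices (records
    with no RI are ignored in the mean); the identifier of the first member
    in input order is kept.
    """
    groups: dict[str, list[RIRecord]] = {}
    for rec in records:
        groups.setdefault(rec.molecule.canonical_key, []).append(rec)
    merged: list[RIRecord] = []
    for key in sorted(groups):
        members = groups[key]
        ris = [r.ri_experimental for r in members if r.ri_experimental is not None]
        mean_ri = sum(ris) / len(ris) if ris else None
        merged.append(
            RIRecord(molecule=members[0].molecule, ri_experimental=mean_ri,
                     identifier=members[0].identifier)
        )
    return merged


# ---------------------------------------------------------------------------
# readers / writers


def read_smi(path: str | Path) -> list[RIRecord]:
    """Read a ``.smi`` file: one ``SMILES<whitespace>identifier`` per line."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        ident = parts[1].strip() if len(parts) > 1 else smiles
        try:
            mol = parse_smiles(smiles)
        except SmilesParseError as exc:
            raise SmilesParseError(smiles, f"line {lineno}: {exc.reason}",
                                   exc.position) from exc
        records.append(RIRecord(molecule=mol, ri_experimental=None,
                                identifier=ident))
    return records


def read_records_csv(path: str | Path) -> list[RIRecord]:
    """Read a CSV with header ``smiles,identifier,ri`` (ri may be empty)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"smiles", "identifier", "ri"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"CSV must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            ri = row["ri"].strip()
            records.append(
                RIRecord(
                    molecule=parse_smiles(row["smiles"]),
                    ri_experimental=float(ri) if ri else None,
                    identifier=row["identifier"],
                )
            )
    return records


def write_records_csv(records: Sequence[RIRecord], path: str | Path) -> None:
    """Write curated records with the canonical key as an extra column."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", "identifier", "ri", "canonical_key"])
        for rec in records:
            writer.writerow([
                rec.molecule.smiles_source,
                rec.identifier,
                "" if rec.ri_experimental is None else rec.ri_experimental,
                rec.molecule.canonical_key,
            ])
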