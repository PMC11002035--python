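"""SMILES parsing and labeled-dataset I/O.

Molecules are heavy-atom graphs: hydrogens stay implicit (recorded per atom,
never graph nodes), stereo descriptors are accepted but do not affect
topology, and multi-component SMILES (``.``) yield a single molecule whose
graph is disconnected.  Parsing is delegated to RDKit; the rest of the
package only ever sees the light-weight :class:`Molecule` container defined
here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from rdkit import Chem, RDLogger
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: bond-order vocabulary used throughout the package
BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RDKIT_BOND_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; names the input."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class DatasetFormatError(ValueError):
    """Raised on malformed dataset rows; carries the 1-based line number."""


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    formal_charge: int = 0
    aromatic: bool = False
    implicit_h: int = 0


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: str  # one of BOND_ORDERS

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError("self-bonds are not allowed")
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order {self.order!r}")


@dataclass(frozen=True)
class Molecule:
    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    source_smiles: str

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


@dataclass(frozen=True)
class LabeledRecord:
    smiles: str
    label: int
    id: str | None = None

    def __post_init__(self):
        if not self.smiles:
            raise ValueError("empty SMILES")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a heavy-atom :class:`Molecule`.

    Hydrogen counts are recorded on each atom (``implicit_h``) but hydrogens
    never become graph nodes.  Raises :class:`SmilesParseError` on invalid
    input.
    """
    if not smiles:
        raise SmilesParseError(smiles)
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise SmilesParseError(smiles)
    atoms = tuple(
        Atom(
            index=a.GetIdx(),
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            implicit_h=a.GetTotalNumHs(),
        )
        for a in rdmol.GetAtoms()
    )
    if not atoms:
        raise SmilesParseError(smiles)
    bonds = tuple(
        Bond(
            a=b.GetBeginAtomIdx(),
            b=b.GetEndAtomIdx(),
            order=_RDKIT_BOND_ORDER[b.GetBondType()],
        )
        for b in rdmol.GetBonds()
    )
    return Molecule(atoms=atoms, bonds=bonds, source_smiles=smiles)


def molecular_formula(mol: Molecule) -> str:
    """Hill-order molecular formula, counting implicit hydrogens."""
    rdmol = Chem.MolFromSmiles(mol.source_smiles)
    if rdmol is None:  # pragma: no cover - Molecule always built from valid SMILES
        raise SmilesParseError(mol.source_smiles)
    return CalcMolFormula(rdmol)


def _parse_label(raw: str, lineno: int) -> int:
    raw = raw.strip()
    if raw not in ("0", "1"):
        raise DatasetFormatError(f"line {lineno}: label must be 0 or 1, got {raw!r}")
    return int(raw)


def read_dataset(path: str | Path) -> list[LabeledRecord]:
    """Read labeled molecules from delimited text.

    Two layouts are accepted: comma-separated with a ``smiles,label[,id]``
    header, and whitespace-separated ``.smi``-style ``SMILES label`` lines
    (no header).  Duplicate SMILES are allowed but logged.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise DatasetFormatError("empty dataset file")
    records: list[LabeledRecord] = []
    first = lines[0].strip().lower()
    if first.startswith("smiles") and ("," in lines[0] or "\t" in lines[0]):
        reader = csv.reader(lines)
        header = [h.strip().lower() for h in next(reader)]
        if header[:2] != ["smiles", "label"]:
            raise DatasetFormatError(f"line 1: bad header {lines[0]!r}")
        has_id = len(header) > 2 and header[2] == "id"
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise DatasetFormatError(f"line {lineno}: expected smiles,label")
            rid = row[2].strip() if has_id and len(row) > 2 and row[2].strip() else None
            records.append(
                LabeledRecord(row[0].strip(), _parse_label(row[1], lineno), rid)
            )
    else:
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise DatasetFormatError(f"line {lineno}: expected 'SMILES label'")
            records.append(LabeledRecord(parts[0], _parse_label(parts[1], lineno)))
    seen: set[str] = set()
    for r in records:
        if r.smiles in seen:
            logger.warning("duplicate SMILES in dataset: %s", r.smiles)
        seen.add(r.smiles)
    return records


def write_dataset(records: Iterable[LabeledRecord], path: str | Path) -> None:
    """Write records as ``smiles,label[,id]`` CSV; inverse of :func:`read_dataset`."""
    records = list(records)
    path = Path(path)
    has_id = any(r.id is not None for r in records)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", "label", "id"] if has_id else ["smiles", "label"])
        for r in records:
            row = [r.smiles, str(r.label)]
            if has_id:
                row.append(r.id or "")
            writer.writerow(row)
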