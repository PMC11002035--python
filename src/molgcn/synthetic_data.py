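"""Synthetic structure-activity datasets with a planted substructure signal.

Real fruit-quality bioactivity labels are not redistributable, so tests and
demonstrations run on generated molecules: random skeletons assembled from a
small fragment grammar (alkyl chains, branches, ethers, amines, alcohols,
carbocycles, benzene rings), balanced 174 positive / 174 negative by default.
The planted rule is a carbonyl group: positives receive a ketone or aldehyde
fragment, negatives are built from carbonyl-free fragments only.  Labels can
be flipped with probability ``label_noise`` to study graceful degradation.
Every emitted SMILES is checked to re-parse and to respect the heavy-atom cap;
the class rule is verifiable independently with a SMARTS substructure match.

A tiny fixture of real, well-known molecules (pigments, flavor compounds,
sugars, simple acids) is packaged for smoke tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem_io import LabeledRecord, parse_smiles

#: SMARTS for the planted motif: a carbonyl carbon double-bonded to oxygen.
MOTIF_SMARTS = "[#6]=[#8]"

# carbonyl-free building blocks (chains, branch points, heteroatoms, rings)
_NEUTRAL_FRAGMENTS = [
    "C", "CC", "CCC", "CCCC", "C(C)C", "C(C)(C)C",
    "CO", "OC", "CN", "NC", "COC", "CNC",
    "C1CCCCC1", "C1CCCC1", "c1ccccc1", "C=C", "C#C", "CCl", "CF",
]
# carbonyl-bearing blocks planted into positives (ketone / aldehyde / ester)
_MOTIF_FRAGMENTS = ["C(=O)C", "CC(=O)C", "C=O", "C(=O)OC"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_pos: int = 174
    n_neg: int = 174
    motif: str = MOTIF_SMARTS
    label_noise: float = 0.0
    max_heavy_atoms: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class counts must be positive")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.max_heavy_atoms < 5:
            raise ValueError("max_heavy_atoms too small for the grammar")


def _heavy_atoms(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    return 0 if mol is None else mol.GetNumHeavyAtoms()


def has_motif(smiles: str, motif: str = MOTIF_SMARTS) -> bool:
    """Independent substructure check used to audit generated labels."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return mol.HasSubstructMatch(Chem.MolFromSmarts(motif))


def _random_molecule(rng: np.random.Generator, positive: bool,
                     max_heavy_atoms: int) -> str:
    """Concatenate grammar fragments into one linear-assembly SMILES."""
    while True:
        n_frag = int(rng.integers(2, 6))
        parts = list(rng.choice(_NEUTRAL_FRAGMENTS, size=n_frag))
        if positive:
            pos = int(rng.integers(0, len(parts) + 1))
            parts.insert(pos, str(rng.choice(_MOTIF_FRAGMENTS)))
        smiles = "".join(parts)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        if mol.GetNumHeavyAtoms() > max_heavy_atoms:
            continue
        # audit: the assembly must not create (or lose) the motif by accident
        if has_motif(smiles) != positive:
            continue
        return Chem.MolToSmiles(mol)


def generate_dataset(config: GeneratorConfig = GeneratorConfig()) -> list[LabeledRecord]:
    """Generate a balanced labeled dataset with the planted motif rule.

    At ``label_noise`` 0 the label equals motif presence for every record.
    The output is fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    records: list[LabeledRecord] = []
    for cls, count in ((1, config.n_pos), (0, config.n_neg)):
        for k in range(count):
            smiles = _random_molecule(rng, positive=cls == 1, max_heavy_atoms=config.max_heavy_atoms)
            parse_smiles(smiles)  # every emitted record must round-trip
            label = cls
            if config.label_noise > 0 and rng.random() < config.label_noise:
                label = 1 - label
            records.append(LabeledRecord(smiles=smiles, label=label,
                                         id=f"{'pos' if cls else 'neg'}{k:04d}"))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


#: Real, well-known small molecules for smoke tests. Labels are illustrative
#: (1 = pigments/flavor compounds of the kind associated with fruit quality),
#: not measured bioactivity.
_FIXTURES: list[tuple[str, int, str]] = [
    ("C[C@H](CCC=C(C)C)CC=O", 1, "citronellal"),
    ("CC1=CC(=O)CC(C)(C)C1", 1, "isophorone"),
    ("OC1=CC2=C(C=C1O)[O+]=C(C=C2O)C1=CC=C(O)C(O)=C1", 1, "cyanidin_cation"),
    ("CC(C)=CCCC(C)=CC=O", 1, "citral"),
    ("CC(=O)OCC", 1, "ethyl_acetate"),
    ("OC(=O)CC(O)(CC(O)=O)C(O)=O", 1, "citric_acid"),
    ("OC(=O)C=CC1=CC=C(O)C=C1", 1, "p_coumaric_acid"),
    ("CC1=CC=C(C=C1)C(C)C", 1, "p_cymene"),
    ("OCC1OC(O)C(O)C(O)C1O", 1, "glucose"),
    ("CC(=O)C1=CC=CC=C1", 1, "acetophenone"),
    ("c1ccccc1", 0, "benzene"),
    ("ClC(Cl)Cl", 0, "chloroform"),
    ("CCO", 0, "ethanol"),
    ("CCCCCC", 0, "hexane"),
    ("C1CCOC1", 0, "tetrahydrofuran"),
    ("CN(C)C", 0, "trimethylamine"),
    ("CC(C)O", 0, "isopropanol"),
    ("C1CCCCC1", 0, "cyclohexane"),
    ("CCOCC", 0, "diethyl_ether"),
    ("CS(=O)C", 0, "dmso"),
]


def fixture_dataset() -> list[LabeledRecord]:
    """A small packaged list of real molecules for smoke tests."""
    return [LabeledRecord(smiles=s, label=lab, id=name) for s, lab, name in _FIXTURES]
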