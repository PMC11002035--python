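"""Numeric graph objects consumed by the GCN.

A molecule becomes a :class:`MolGraph`: binary adjacency ``A`` (bond order is
deliberately ignored here), the self-loop-augmented ``A_tilde = A + I``, its
diagonal degree matrix ``D_tilde``, and the symmetric normalization
``A_hat = D_tilde^{-1/2} A_tilde D_tilde^{-1/2}`` whose eigenvalues lie in
[-1, 1].  Node identity is categorical: each atom is assigned the integer id
of its radius-r atom environment (the atom itself plus the sorted multiset of
bond-order/neighbor-signature pairs out to r bonds), looked up in an
:class:`AtomVocabulary`.  Id 0 is reserved for environments never seen while
the vocabulary was growing, so a frozen vocabulary can encode test molecules
without leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import Molecule

Signature = tuple

UNK_ID = 0


class AtomVocabulary:
    """Dense, stable signature -> integer-id map with a reserved unknown id."""

    def __init__(self):
        self._ids: dict[Signature, int] = {}
        self.frozen: bool = False

    unk_id = UNK_ID

    def __len__(self) -> int:
        # +1 for the reserved unknown id
        return len(self._ids) + 1

    def __contains__(self, signature: Signature) -> bool:
        return signature in self._ids

    def lookup(self, signature: Signature) -> int:
        """Return the id for a signature, growing the map unless frozen."""
        got = self._ids.get(signature)
        if got is not None:
            return got
        if self.frozen:
            return UNK_ID
        new_id = len(self._ids) + 1
        self._ids[signature] = new_id
        return new_id

    def freeze(self) -> "AtomVocabulary":
        self.frozen = True
        return self


@dataclass(frozen=True)
class MolGraph:
    n: int
    A: np.ndarray
    A_tilde: np.ndarray
    D_tilde: np.ndarray
    A_hat: np.ndarray
    node_ids: np.ndarray  # int array of length n


def build_adjacency(mol: Molecule) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary adjacency A, augmented A_tilde = A + I, and its degree matrix.

    ``A[i, j] = 1`` iff a bond joins atoms i and j, regardless of bond order.
    ``D_tilde`` is diagonal with the row sums of ``A_tilde``; its diagonal is
    at least 1 (the self-loop), so the inverse square root always exists.
    """
    n = mol.n_atoms
    A = np.zeros((n, n), dtype=float)
    for bond in mol.bonds:
        A[bond.a, bond.b] = 1.0
        A[bond.b, bond.a] = 1.0
    A_tilde = A + np.eye(n)
    D_tilde = np.diag(A_tilde.sum(axis=1))
    return A, A_tilde, D_tilde


def normalize_adjacency(A_tilde: np.ndarray, D_tilde: np.ndarray) -> np.ndarray:
    """Symmetric normalization D_tilde^(-1/2) A_tilde D_tilde^(-1/2)."""
    A_tilde = np.asarray(A_tilde, dtype=float)
    D_tilde = np.asarray(D_tilde, dtype=float)
    if A_tilde.ndim != 2 or A_tilde.shape[0] != A_tilde.shape[1]:
        raise ValueError("A_tilde must be square")
    if D_tilde.shape != A_tilde.shape:
        raise ValueError("D_tilde and A_tilde shapes differ")
    d = np.diag(D_tilde)
    if np.any(d <= 0):
        raise ValueError("D_tilde diagonal must be strictly positive")
    inv_sqrt = 1.0 / np.sqrt(d)
    return inv_sqrt[:, None] * A_tilde * inv_sqrt[None, :]


def atom_environment_signature(mol: Molecule, atom_index: int, radius: int) -> Signature:
    """Canonical signature of the radius-r environment of one atom.

    Radius 0 is ``('atom', element, formal_charge, aromatic)``.  Radius r
    prepends the atom's own radius-0 signature to the sorted multiset of
    ``(bond_order, neighbor radius-(r-1) signature)`` pairs, so the result is
    independent of atom input ordering.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if not 0 <= atom_index < mol.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range")
    neighbors: dict[int, list[tuple[int, str]]] = {a.index: [] for a in mol.atoms}
    for bond in mol.bonds:
        neighbors[bond.a].append((bond.b, bond.order))
        neighbors[bond.b].append((bond.a, bond.order))

    def sig(i: int, r: int) -> Signature:
        atom = mol.atoms[i]
        base = ("atom", atom.element, atom.formal_charge, atom.aromatic)
        if r == 0:
            return base
        shell = sorted((order, sig(j, r - 1)) for j, order in neighbors[i])
        return (base, tuple(shell))

    return sig(atom_index, radius)


def encode_graph(mol: Molecule, vocab: AtomVocabulary, radius: int = 1) -> MolGraph:
    """Build the full MolGraph for a molecule against a vocabulary.

    Growing vocabularies assign fresh ids to new environments; frozen ones map
    unseen environments to the reserved unknown id.
    """
    A, A_tilde, D_tilde = build_adjacency(mol)
    A_hat = normalize_adjacency(A_tilde, D_tilde)
    node_ids = np.array(
        [vocab.lookup(atom_environment_signature(mol, i, radius)) for i in range(mol.n_atoms)],
        dtype=np.int64,
    )
    return MolGraph(n=mol.n_atoms, A=A, A_tilde=A_tilde, D_tilde=D_tilde,
                    A_hat=A_hat, node_ids=node_ids)


def dump_matrix(matrix: np.ndarray) -> str:
    """Whitespace-delimited text rendering of a matrix, for debugging."""
    return "\n".join(" ".join(f"{v:.6g}" for v in row) for row in np.atleast_2d(matrix))
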