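"""Parse a SMILES string and inspect the heavy-atom graph.

Citronellal (C10H18O) is the running example: 10 carbons and one oxygen,
hydrogens implicit. The adjacency matrix is binary and symmetric; adding
self-loops and normalizing by joint degree gives the propagation matrix the
classifier uses.
"""

from molgcn import build_adjacency, molecular_formula, normalize_adjacency, parse_smiles
from molgcn.graph_build import dump_matrix

mol = parse_smiles("C[C@H](CCC=C(C)C)CC=O")
print(f"SMILES:       {mol.source_smiles}")
print(f"formula:      {molecular_formula(mol)}")
print(f"heavy atoms:  {mol.n_atoms}")
print(f"bonds:        {mol.n_bonds}")

A, A_tilde, D_tilde = build_adjacency(mol)
A_hat = normalize_adjacency(A_tilde, D_tilde)
print("\nadjacency A (1 = bonded pair, any bond order):")
print(dump_matrix(A))
print("\nsymmetric-normalized adjacency A_hat (row i mixes atom i with its")
print("neighbors, weighted by 1/sqrt((deg_i+1)(deg_j+1))):")
print(dump_matrix(A_hat.round(3)))
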