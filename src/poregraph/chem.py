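"""Kmer chemical structures: SMILES assembly, molecular graphs, graph tensors.

A kmer's structure is written as one SMILES string by concatenating
per-nucleotide SMILES building blocks in sequence order and appending a final
``O`` for the residual unbonded backbone hydroxyl.  The building blocks are
chosen so that plain string concatenation produces the correct phosphodiester
backbone: each block starts at the 5' phosphate and ends at the 3' carbon, so
the first atom of the next block bonds to it directly.

The molecular graph uses atoms as nodes (indexed 0-based in order of
appearance in the SMILES string) and covalent bonds as edges.  Eight features
per atom: one-hot element (C/N/O/P), degree (number of bonded heavy-atom
neighbors), implicit valence (standard valence minus valence accounted for by
explicit bonds), total hydrogen count, and an aromaticity flag.

For batching, adjacency and feature matrices are zero-padded to the size of
the largest kmer in the configured alphabets: 133 heavy atoms for DNA 6mers
and 116 for RNA 5mers over the canonical-plus-6mA alphabet.

RDKit performs SMILES parsing and aromaticity perception; atom indices in
RDKit follow SMILES appearance order, which the rest of the package relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger

from .alphabet import Alphabet, Kmer

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "NUCLEOTIDE_SMILES",
    "Atom",
    "MolGraph",
    "PaddedGraphTensor",
    "SmilesError",
    "PaddingOverflowError",
    "assemble_smiles",
    "parse_smiles",
    "kmer_graph",
    "atom_features",
    "heavy_atom_count",
    "nucleotide_atom_count",
    "padding_size",
    "to_padded_tensors",
    "encode_kmer",
    "encode_kmers",
    "N_FEATURES",
]

N_FEATURES = 8

#: Per-nucleotide SMILES building blocks, keyed by (base symbol, nucleic type).
#: Each string runs 5'-phosphate -> sugar -> base -> 3' carbon so that plain
#: concatenation forms the phosphodiester backbone.
NUCLEOTIDE_SMILES: dict[tuple[str, str], str] = {
    ("A", "DNA"): "OP(=O)(O)OCC1OC(N3C=NC2=C(N)N=CN=C23)CC1",
    ("T", "DNA"): "OP(=O)(O)OCC1OC(N2C(=O)NC(=O)C(C)=C2)CC1",
    ("C", "DNA"): "OP(=O)(O)OCC1OC(N2C(=O)N=C(N)C=C2)CC1",
    ("G", "DNA"): "OP(=O)(O)OCC1OC(N2C=NC3=C2N=C(N)NC3=O)CC1",
    ("5mC", "DNA"): "OP(=O)(O)OCC1OC(N2C(=O)N=C(N)C(C)=C2)CC1",
    ("6mA", "DNA"): "OP(=O)(O)OCC1OC(N3C=NC2=C(NC)N=CN=C23)CC1",
    ("A", "RNA"): "OP(=O)(O)OCC1OC(N3C=NC2=C(N)N=CN=C23)C(O)C1",
    ("U", "RNA"): "OP(=O)(O)OCC1OC(N2C(=O)NC(=O)C=C2)C(O)C1",
    ("C", "RNA"): "OP(=O)(O)OCC1OC(N2C(=O)N=C(N)C=C2)C(O)C1",
    ("G", "RNA"): "OP(=O)(O)OCC1OC(N2C=NC3=C2N=C(N)NC3=O)C(O)C1",
    ("6mA", "RNA"): "OP(=O)(O)OCC1OC(N3C=NC2=C(NC)N=CN=C23)C(O)C1",
    ("2mG", "RNA"): "OP(=O)(O)OCC1OC(N2C=NC3=C2N=C(NC)NC3=O)C(O)C1",
}

_SUPPORTED_ELEMENTS = ("C", "N", "O", "P")


class SmilesError(ValueError):
    """Unparseable SMILES or unsupported base/element."""


class PaddingOverflowError(ValueError):
    """Graph has more atoms than the declared padding size."""


@dataclass(frozen=True)
class Atom:
    element: str
    degree: int
    implicit_valence: int
    n_hydrogens: int
    aromatic: bool


@dataclass(frozen=True)
class MolGraph:
    """Heavy-atom molecular graph in SMILES appearance order."""

    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int, int], ...]  # (i, j, order), i < j
    smiles: str
    source_kmer: Kmer | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> np.ndarray:
        """Binary adjacency (1 for any covalent bond, regardless of order)."""
        A = np.zeros((self.n_atoms, self.n_atoms), dtype=np.float32)
        for i, j, _ in self.bonds:
            A[i, j] = A[j, i] = 1.0
        return A


@dataclass(frozen=True)
class PaddedGraphTensor:
    """Fixed-size adjacency ``A`` (P, P) and feature matrix ``X`` (P, 8)."""

    A: np.ndarray
    X: np.ndarray
    n_real: int


def assemble_smiles(kmer: Kmer) -> str:
    """Concatenate per-nucleotide SMILES in kmer order, plus a terminal ``O``."""
    if kmer.k == 0:
        raise SmilesError("cannot assemble SMILES for an empty kmer")
    nt = kmer.alphabet.nucleic_type
    parts = []
    for sym in kmer.symbols:
        try:
            parts.append(NUCLEOTIDE_SMILES[(sym, nt)])
        except KeyError:
            raise SmilesError(f"no SMILES building block for base {sym!r} ({nt})") from None
    return "".join(parts) + "O"


def parse_smiles(smiles: str) -> MolGraph:
    """Parse a SMILES string into a :class:`MolGraph`.

    Atom order equals appearance order in the string.  Bond orders are taken
    from the kekulized form; aromaticity flags come from RDKit's perception
    on the sanitized molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    aromatic = [a.GetIsAromatic() for a in mol.GetAtoms()]
    # kekulize a copy so bond orders are 1/2 rather than "aromatic"
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    atoms = []
    for a, arom in zip(mol.GetAtoms(), aromatic):
        if a.GetSymbol() not in _SUPPORTED_ELEMENTS:
            raise SmilesError(
                f"unsupported element {a.GetSymbol()!r} at atom {a.GetIdx()}"
            )
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                degree=a.GetDegree(),
                implicit_valence=a.GetImplicitValence(),
                n_hydrogens=a.GetTotalNumHs(),
                aromatic=bool(arom),
            )
        )
    bonds = []
    for b in kek.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        order = int(b.GetBondTypeAsDouble())
        bonds.append((min(i, j), max(i, j), order))
    bonds.sort()
    return MolGraph(atoms=tuple(atoms), bonds=tuple(bonds), smiles=smiles)


def kmer_graph(kmer: Kmer) -> MolGraph:
    """Assemble and parse a kmer's molecular graph."""
    g = parse_smiles(assemble_smiles(kmer))
    return MolGraph(atoms=g.atoms, bonds=g.bonds, smiles=g.smiles, source_kmer=kmer)


def atom_features(graph: MolGraph) -> np.ndarray:
    """Per-atom 8-vector: one-hot C/N/O/P, degree, implicit valence, H count, aromatic."""
    X = np.zeros((graph.n_atoms, N_FEATURES), dtype=np.float32)
    for i, a in enumerate(graph.atoms):
        X[i, _SUPPORTED_ELEMENTS.index(a.element)] = 1.0
        X[i, 4] = a.degree
        X[i, 5] = a.implicit_valence
        X[i, 6] = a.n_hydrogens
        X[i, 7] = 1.0 if a.aromatic else 0.0
    return X


def heavy_atom_count(kmer: Kmer) -> int:
    """Heavy atoms in the assembled kmer: sum of per-base counts plus 1."""
    nt = kmer.alphabet.nucleic_type
    return sum(nucleotide_atom_count(s, nt) for s in kmer.symbols) + 1


def nucleotide_atom_count(base: str, nucleic_type: str) -> int:
    """Heavy atoms in one nucleotide building block (parsed, cached)."""
    key = (base, nucleic_type)
    if key not in _ATOM_COUNT_CACHE:
        try:
            smiles = NUCLEOTIDE_SMILES[key]
        except KeyError:
            raise SmilesError(f"no SMILES building block for {key}") from None
        _ATOM_COUNT_CACHE[key] = parse_smiles(smiles).n_atoms
    return _ATOM_COUNT_CACHE[key]


_ATOM_COUNT_CACHE: dict[tuple[str, str], int] = {}


def padding_size(alphabets: Iterable[Alphabet], k: int) -> int:
    """Maximum heavy-atom count over all length-*k* kmers of the alphabets.

    Because atom counts are additive over positions this equals
    ``k * max_per_base_count + 1``.  For DNA 6mers over the canonical, 5mC
    and 6mA alphabets this is 133; for RNA 5mers over canonical plus 6mA,
    116.  Alphabets containing 2mG (one atom heavier than G) push RNA
    padding to 121.
    """
    alphabets = list(alphabets)
    if not alphabets:
        raise ValueError("need at least one alphabet")
    types = {a.nucleic_type for a in alphabets}
    if len(types) > 1:
        raise ValueError(f"mixed nucleic types: {sorted(types)}")
    nt = types.pop()
    bases = {b for a in alphabets for b in a.bases}
    max_base = max(nucleotide_atom_count(b, nt) for b in bases)
    return k * max_base + 1


def to_padded_tensors(graph: MolGraph, P: int) -> PaddedGraphTensor:
    """Zero-pad adjacency and features to side length / row count *P*.

    Padding occupies the trailing rows (and columns of ``A``) and is exactly
    zero; the real graph sits in the top-left block.
    """
    n = graph.n_atoms
    if P < n:
        raise PaddingOverflowError(f"padding size {P} < atom count {n}")
    A = np.zeros((P, P), dtype=np.float32)
    A[:n, :n] = graph.adjacency()
    X = np.zeros((P, N_FEATURES), dtype=np.float32)
    X[:n] = atom_features(graph)
    return PaddedGraphTensor(A=A, X=X, n_real=n)


def encode_kmer(kmer: Kmer, P: int) -> PaddedGraphTensor:
    """Kmer -> padded (A, X) tensors in one step."""
    return to_padded_tensors(kmer_graph(kmer), P)


def encode_kmers(
    kmers: Sequence[Kmer], P: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode a batch of kmers into stacked arrays ``(A, X, n_real)``.

    Returns ``A`` of shape (n, P, P), ``X`` of shape (n, P, 8) and the
    per-kmer real-atom counts.  Duplicate kmers are encoded once.
    """
    cache: dict[str, PaddedGraphTensor] = {}
    A = np.zeros((len(kmers), P, P), dtype=np.float32)
    X = np.zeros((len(kmers), P, N_FEATURES), dtype=np.float32)
    n_real = np.zeros(len(kmers), dtype=np.int64)
    for i, kmer in enumerate(kmers):
        key = str(kmer)
        if key not in cache:
            cache[key] = encode_kmer(kmer, P)
        t = cache[key]
        A[i], X[i], n_real[i] = t.A, t.X, t.n_real
    return A, X, n_real
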