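"""SMILES assembly, molecular graphs, atom features and padded tensors."""

import re

import numpy as np
import pytest

import poregraph as pg
from poregraph.chem import (
    NUCLEOTIDE_SMILES,
    PaddingOverflowError,
    SmilesError,
    assemble_smiles,
    atom_features,
    heavy_atom_count,
    kmer_graph,
    nucleotide_atom_count,
    padding_size,
    parse_smiles,
    to_padded_tensors,
)


def oracle_parse(smiles):
    """Independent hand-rolled topology parser for the restricted grammar.

    Supports atoms C/N/O/P, double-bond '=', branches and ring-closure
    digits.  Returns (elements, set of undirected bonds) and exists purely
    to cross-check the production parser.
    """
    elements, bonds = [], set()
    prev = None
    stack = []
    ring_open = {}
    pending_double = False
    i = 0
    while i < len(smiles):
        ch = smiles[i]
        if ch in "CNOP":
            idx = len(elements)
            elements.append(ch)
            if prev is not None:
                bonds.add((min(prev, idx), max(prev, idx)))
            prev = idx
            pending_double = False
        elif ch == "=":
            pending_double = True
        elif ch == "(":
            stack.append(prev)
        elif ch == ")":
            prev = stack.pop()
        elif ch.isdigit():
            if ch in ring_open:
                j = ring_open.pop(ch)
                bonds.add((min(prev, j), max(prev, j)))
            else:
                ring_open[ch] = prev
        else:
            raise ValueError(f"oracle cannot parse {ch!r}")
        i += 1
    assert not ring_open, "unmatched ring closures"
    return elements, bonds


def _kmer(text, alphabet=pg.DNA_5MC_6MA):
    return pg.parse_kmer(text, alphabet)


class TestAssembly:
    def test_dna_c_monomer_exact_string(self):
        kmer = pg.Kmer(("C",), pg.DNA)
        assert assemble_smiles(kmer) == "OP(=O)(O)OCC1OC(N2C(=O)N=C(N)C=C2)CC1O"

    def test_empty_kmer_rejected(self):
        with pytest.raises(SmilesError):
            assemble_smiles(pg.Kmer((), pg.DNA))

    def test_cgacgt_heavy_atom_count(self):
        graph = kmer_graph(_kmer("CGACGT"))
        assert graph.n_atoms == 124

    def test_atom_count_additivity_all_nucleotides(self):
        # parsed atom count == regex heavy-atom count for all 12 blocks
        for (base, nt), smiles in NUCLEOTIDE_SMILES.items():
            regex_count = len(re.findall(r"[CNOP]", smiles))
            assert nucleotide_atom_count(base, nt) == regex_count

    @pytest.mark.parametrize(
        "text,alphabet",
        [("ACGT", pg.DNA), ("AC[6mA]U", pg.RNA_6MA), ("[2mG]GAC", pg.RNA_6MA_2MG)],
    )
    def test_kmer_additivity(self, text, alphabet):
        kmer = pg.parse_kmer(text, alphabet)
        graph = kmer_graph(kmer)
        assert graph.n_atoms == heavy_atom_count(kmer)


class TestParsing:
    def test_phosphate_prefix(self):
        g = parse_smiles("OP(=O)(O)O")
        assert g.n_atoms == 5
        assert len(g.bonds) == 4
        assert sum(1 for *_, order in g.bonds if order == 2) == 1

    def test_unparseable_rejected(self):
        with pytest.raises(SmilesError):
            parse_smiles("C1CC")  # unmatched ring closure

    def test_unsupported_element_rejected(self):
        with pytest.raises(SmilesError):
            parse_smiles("CS")

    @pytest.mark.parametrize("base,nt", list(NUCLEOTIDE_SMILES))
    def test_topology_matches_independent_oracle(self, base, nt):
        smiles = NUCLEOTIDE_SMILES[(base, nt)]
        g = parse_smiles(smiles)
        elements, bonds = oracle_parse(smiles)
        assert [a.element for a in g.atoms] == elements
        assert {(i, j) for i, j, _ in g.bonds} == bonds


class TestFigureAnchors:
    def test_cgacgt_phosphorus_and_ring_oxygens(self):
        g = kmer_graph(_kmer("CGACGT"))
        p_idx = [i for i, a in enumerate(g.atoms) if a.element == "P"]
        assert p_idx == [1, 20, 42, 63, 82, 104]
        ring_o = [
            i
            for i, a in enumerate(g.atoms)
            if a.element == "O" and _in_ring(g, i)
        ]
        assert ring_o == [7, 26, 48, 69, 88, 110]

    def test_gt5mcaga_methyl_carbons_and_phosphorus(self):
        g = kmer_graph(_kmer("GT[5mC]AGA"))
        p_idx = [i for i, a in enumerate(g.atoms) if a.element == "P"]
        assert p_idx == [1, 23, 43, 63, 84, 106]
        # methyl carbons: degree-1 carbons with 3 hydrogens
        methyls = [
            i
            for i, a in enumerate(g.atoms)
            if a.element == "C" and a.degree == 1 and a.n_hydrogens == 3
        ]
        assert 38 in methyls and 58 in methyls


def _in_ring(graph, idx):
    # cycle membership via networkx-free union of ring bonds: an atom is in a
    # ring iff removing it leaves its neighbors connected; cheap check via
    # rdkit is avoided here to stay independent -- use cycle basis on edges.
    import networkx as nx

    G = nx.Graph((i, j) for i, j, _ in graph.bonds)
    return any(idx in cycle for cycle in nx.cycle_basis(G))


class TestAtomFeatures:
    def test_phosphate_phosphorus_row(self):
        g = kmer_graph(_kmer("A", pg.DNA))
        X = atom_features(g)
        p = next(i for i, a in enumerate(g.atoms) if a.element == "P")
        assert list(X[p, :4]) == [0, 0, 0, 1]
        assert X[p, 4] == 4  # bonded to four oxygens

    def test_terminal_hydroxyl(self):
        g = kmer_graph(_kmer("A", pg.DNA))
        X = atom_features(g)
        last = g.n_atoms - 1
        assert g.atoms[last].element == "O"
        assert X[last, 4] == 1  # degree
        assert X[last, 6] == 1  # one implicit hydrogen

    def test_adenine_ring_is_aromatic(self):
        g = kmer_graph(_kmer("A", pg.DNA))
        aromatic_n = sum(1 for a in g.atoms if a.aromatic)
        assert aromatic_n == 9  # fused purine: 9 ring atoms

    def test_adjacency_row_sums_equal_degree(self):
        for (base, nt) in NUCLEOTIDE_SMILES:
            g = parse_smiles(NUCLEOTIDE_SMILES[(base, nt)])
            X = atom_features(g)
            assert np.array_equal(g.adjacency().sum(axis=1), X[:, 4])

    def test_no_negative_features(self):
        g = kmer_graph(_kmer("CGACGT"))
        assert (atom_features(g) >= 0).all()


class TestPadding:
    @pytest.mark.parametrize(
        "alphabets,k,expected",
        [
            ([pg.DNA, pg.DNA_5MC, pg.DNA_6MA], 6, 133),
            ([pg.RNA, pg.RNA_6MA], 5, 116),
            ([pg.RNA_6MA_2MG], 5, 121),  # 2mG is one atom heavier than G
        ],
    )
    def test_padding_size(self, alphabets, k, expected):
        assert padding_size(alphabets, k) == expected

    def test_mixed_nucleic_types_rejected(self):
        with pytest.raises(ValueError):
            padding_size([pg.DNA, pg.RNA], 5)

    def test_padded_tensor_contract(self):
        g = kmer_graph(_kmer("CGACGT"))
        t = to_padded_tensors(g, 133)
        assert t.A.shape == (133, 133)
        assert t.X.shape == (133, 8)
        assert t.n_real == 124
        assert np.array_equal(t.A, t.A.T)
        assert np.diagonal(t.A).sum() == 0
        assert not t.A[124:].any() and not t.A[:, 124:].any()
        assert not t.X[124:].any()

    def test_padding_overflow(self):
        g = kmer_graph(_kmer("CGACGT"))
        with pytest.raises(PaddingOverflowError):
            to_padded_tensors(g, 100)
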