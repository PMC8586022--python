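"""From kmer sequence to padded graph tensors.

Assembles the SMILES string of a 5mC-containing DNA 6mer, parses it into a
molecular graph, and shows the padded adjacency/feature matrices the
network consumes.
"""

import poregraph as pg

kmer = pg.parse_kmer("GT[5mC]AGA", pg.DNA_5MC)
smiles = pg.assemble_smiles(kmer)
graph = pg.kmer_graph(kmer)
P = pg.padding_size([pg.DNA, pg.DNA_5MC, pg.DNA_6MA], 6)
tensor = pg.encode_kmer(kmer, P)

print(f"kmer            : {kmer}")
print(f"SMILES length   : {len(smiles)} characters")
print(f"heavy atoms     : {graph.n_atoms}")
print(f"covalent bonds  : {len(graph.bonds)}")
p_atoms = [i for i, a in enumerate(graph.atoms) if a.element == "P"]
print(f"phosphorus atoms: {p_atoms}")
print(f"padded A        : {tensor.A.shape}, X: {tensor.X.shape}, real atoms: {tensor.n_real}")

# The six phosphorus indices mark each nucleotide's phosphate group in
# SMILES appearance order; rows past n_real are zero padding so that every
# DNA 6mer (even all-6mA) fits the same {133, 133} / {133, 8} tensors.
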