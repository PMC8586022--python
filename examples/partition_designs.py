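"""The train/test partition designs behind each generalization experiment.

Prints the exact train/test cardinalities each design produces on the
canonical DNA 6mer and RNA 5mer universes.
"""

import poregraph as pg
from poregraph.splits import (
    base_dropout_split,
    combination_split,
    count_containing,
    position_dropout_split,
    random_split,
)

dna = pg.enumerate_kmers(pg.DNA, 6)
rna = pg.enumerate_kmers(pg.RNA, 5)
print(f"universes: {len(dna)} DNA 6mers, {len(rna)} RNA 5mers")

ds = random_split(rna, 0.95, seed=0)
print(f"downsample RNA 0.95      : {ds.n_train} train / {ds.n_test} test")
bd = base_dropout_split(pg.DNA, 6, "A")
print(f"base dropout DNA (A)     : {bd.n_train} train / {bd.n_test} test")
pd_ = position_dropout_split(pg.DNA, 6, "A", 3)
print(f"position dropout DNA (A@3): {pd_.n_train} train / {pd_.n_test} test")
cb = combination_split(pg.DNA, 6, "G", "C")
print(f"combination DNA (G-C)    : {cb.n_train} train / {cb.n_test} test")

print(f"C-containing DNA 6mers   : {count_containing(pg.DNA, 6, 'C')}")
print(f"single-5mC DNA 6mers     : {count_containing(pg.DNA_5MC, 6, '5mC', exactly=1)}")
print(f"{{A,T,C,G,5mC}} 6mers      : {len(pg.enumerate_kmers(pg.DNA_5MC, 6))}")

# A base "dropped" from training is retained in testing, so every design
# partitions the universe exactly; the counts follow closed forms such as
# (b-1)^k for base dropout and 2(b-1)^k - (b-2)^k for the combination.
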