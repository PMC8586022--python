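"""Alphabets, kmer enumeration and the train/test partition designs."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import poregraph as pg
from poregraph.alphabet import Alphabet, AlphabetError
from poregraph.splits import (
    base_dropout_split,
    combination_split,
    count_containing,
    imputation_split,
    position_dropout_split,
    random_split,
)


class TestEnumeration:
    @pytest.mark.parametrize(
        "alphabet,k,expected",
        [
            (pg.DNA, 6, 4096),
            (pg.DNA_5MC, 6, 15625),
            (pg.RNA_6MA_2MG, 5, 7776),
            (Alphabet("a-only", "DNA", ("A",)), 1, 1),
        ],
    )
    def test_counts(self, alphabet, k, expected):
        assert len(pg.enumerate_kmers(alphabet, k)) == expected

    def test_order_is_lexicographic_and_stable(self):
        first = pg.enumerate_kmers(pg.DNA, 3)
        second = pg.enumerate_kmers(pg.DNA, 3)
        assert [str(k) for k in first] == [str(k) for k in second]
        order = {b: i for i, b in enumerate(pg.DNA.bases)}
        ranks = [tuple(order[s] for s in km.symbols) for km in first]
        assert ranks == sorted(ranks)
        assert len(set(map(str, first))) == len(first)

    def test_unknown_base_rejected(self):
        with pytest.raises(AlphabetError):
            Alphabet("bad", "DNA", ("A", "Z"))
        with pytest.raises(AlphabetError):
            Alphabet("bad", "RNA", ("A", "T"))  # T is DNA-only

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            pg.enumerate_kmers(pg.DNA, 0)


class TestKmerText:
    def test_bracket_round_trip(self):
        kmer = pg.parse_kmer("GT[5mC]AGA", pg.DNA_5MC)
        assert kmer.symbols == ("G", "T", "5mC", "A", "G", "A")
        assert str(kmer) == "GT[5mC]AGA"

    def test_nanopolish_m_dialect(self):
        kmer = pg.parse_kmer("GTMAGA", pg.DNA_5MC, dialect="nanopolish")
        assert kmer.symbols == ("G", "T", "5mC", "A", "G", "A")


class TestRandomSplit:
    @pytest.mark.parametrize(
        "alphabet,k,fraction,n_train",
        [(pg.RNA, 5, 0.95, 972), (pg.DNA, 6, 0.25, 1024)],
    )
    def test_floor_cardinality(self, alphabet, k, fraction, n_train):
        kmers = pg.enumerate_kmers(alphabet, k)
        split = random_split(kmers, fraction, seed=0)
        assert split.n_train == n_train
        assert split.n_train + split.n_test == len(kmers)

    def test_deterministic_for_seed(self):
        kmers = pg.enumerate_kmers(pg.DNA, 3)
        a = random_split(kmers, 0.4, seed=9)
        b = random_split(kmers, 0.4, seed=9)
        assert [str(k) for k in a.train] == [str(k) for k in b.train]
        c = random_split(kmers, 0.4, seed=10)
        assert [str(k) for k in a.train] != [str(k) for k in c.train]

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1, 1.5])
    def test_fraction_bounds(self, fraction):
        kmers = pg.enumerate_kmers(pg.DNA, 2)
        with pytest.raises(ValueError):
            random_split(kmers, fraction, seed=0)


class TestDropoutDesigns:
    def test_base_dropout_dna(self):
        split = base_dropout_split(pg.DNA, 6, "A")
        assert (split.n_train, split.n_test) == (729, 3367)
        assert all("A" not in km.symbols for km in split.train)
        assert all("A" in km.symbols for km in split.test)

    def test_base_dropout_rna(self):
        split = base_dropout_split(pg.RNA, 5, "G")
        assert (split.n_train, split.n_test) == (243, 781)

    def test_base_dropout_k1(self):
        split = base_dropout_split(pg.DNA, 1, "A")
        assert sorted(map(str, split.train)) == ["C", "G", "T"]
        assert [str(k) for k in split.test] == ["A"]

    def test_position_dropout_dna(self):
        split = position_dropout_split(pg.DNA, 6, "A", 3)
        assert (split.n_train, split.n_test) == (3072, 1024)
        assert all(km.symbols[2] == "A" for km in split.test)

    def test_position_dropout_rna(self):
        split = position_dropout_split(pg.RNA, 5, "C", 1)
        assert (split.n_train, split.n_test) == (768, 256)

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            position_dropout_split(pg.DNA, 6, "A", 7)

    def test_combination_dna(self):
        split = combination_split(pg.DNA, 6, "G", "C")
        assert (split.n_train, split.n_test) == (1394, 2702)

    def test_combination_rna(self):
        split = combination_split(pg.RNA, 5, "A", "U")
        assert (split.n_train, split.n_test) == (454, 570)

    def test_combination_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            combination_split(pg.DNA, 6, "A", "A")

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_combination_inclusion_exclusion(self, k):
        # |train| = 2*(b-1)^k - (b-2)^k, checked against brute force
        split = combination_split(pg.DNA, k, "A", "T")
        brute = [
            s
            for s in itertools.product(pg.DNA.bases, repeat=k)
            if not ("A" in s and "T" in s)
        ]
        assert split.n_train == len(brute) == 2 * 3**k - 2**k


@pytest.fixture(scope="module")
def universe():
    canonical = pg.enumerate_kmers(pg.DNA, 3)
    canon_keys = {str(k) for k in canonical}
    modified = [
        k for k in pg.enumerate_kmers(pg.DNA_5MC, 3) if str(k) not in canon_keys
    ]
    return canonical, modified


class TestImputation:

    def test_modified_count_identity(self):
        canonical = pg.enumerate_kmers(pg.DNA, 6)
        modified = 5**6 - len(canonical)
        assert modified == 11529

    def test_fraction_zero_is_denovo(self, universe):
        canonical, modified = universe
        split = imputation_split(canonical, modified, 0.0, seed=1)
        assert split.n_train == len(canonical)
        assert split.n_test == len(modified)

    def test_fraction_one_empty_test(self, universe):
        canonical, modified = universe
        split = imputation_split(canonical, modified, 1.0, seed=1)
        assert split.n_test == 0

    def test_overlap_rejected(self, universe):
        canonical, _ = universe
        with pytest.raises(ValueError):
            imputation_split(canonical, canonical[:2], 0.5, seed=1)


class TestCountContaining:
    def test_c_containing_dna(self):
        assert count_containing(pg.DNA, 6, "C") == 3367

    def test_single_5mc(self):
        assert count_containing(pg.DNA_5MC, 6, "5mC", exactly=1) == 6144

    @pytest.mark.parametrize("alphabet,k", [(pg.DNA, 3), (pg.RNA_6MA, 2)])
    def test_exactly_zero_closed_form(self, alphabet, k):
        assert count_containing(alphabet, k, alphabet.bases[0], exactly=0) == (
            len(alphabet) - 1
        ) ** k

    def test_matches_enumeration(self):
        n = sum(
            1 for km in pg.enumerate_kmers(pg.DNA, 4) if km.count("G") == 2
        )
        assert count_containing(pg.DNA, 4, "G", exactly=2) == n


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    k=st.integers(min_value=1, max_value=4),
    base_i=st.integers(min_value=0, max_value=3),
    pos_offset=st.integers(min_value=0, max_value=3),
)
def test_split_invariants_brute_force(k, base_i, pos_offset):
    """Every design partitions the universe disjointly with the closed-form counts."""
    alphabet = pg.DNA
    b = len(alphabet)
    base = alphabet.bases[base_i]
    universe = {str(km) for km in pg.enumerate_kmers(alphabet, k)}

    bd = base_dropout_split(alphabet, k, base)
    pd_ = position_dropout_split(alphabet, k, base, 1 + pos_offset % k)
    for split, train_count in [
        (bd, (b - 1) ** k),
        (pd_, b**k - b ** (k - 1)),
    ]:
        train, test = set(map(str, split.train)), set(map(str, split.test))
        assert train.isdisjoint(test)
        assert train | test == universe
        assert len(train) == train_count
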