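"""Nucleotide alphabets and kmers.

Kmers are sequences of base *symbols*, not raw strings: modified bases are
multi-character tokens (``5mC``, ``6mA``, ``2mG``) and treating kmers as plain
strings would make tokenization ambiguous.  The text form brackets modified
bases, e.g. ``GT[5mC]AGA``; the nanopolish convention of writing ``M`` for
5-methylcytosine is supported as a reader dialect.

DNA kmers are 6 bases long and RNA kmers 5 bases long by default, matching the
sensing-region length of the respective nanopore chemistries.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "Alphabet",
    "Kmer",
    "AlphabetError",
    "PARENT_BASE",
    "DNA",
    "RNA",
    "DNA_5MC",
    "DNA_6MA",
    "DNA_5MC_6MA",
    "RNA_6MA",
    "RNA_6MA_2MG",
    "get_alphabet",
    "default_k",
    "enumerate_kmers",
    "format_kmer",
    "parse_kmer",
]

#: Canonical parent of each modified base.
PARENT_BASE = {"5mC": "C", "6mA": "A", "2mG": "G"}

_CANONICAL = {"A", "T", "U", "C", "G"}
_ALL_BASES = _CANONICAL | set(PARENT_BASE)


class AlphabetError(ValueError):
    """Unknown base symbol or inconsistent alphabet definition."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of base symbols with a nucleic-acid type.

    Parameters
    ----------
    name
        Identifier used in registries and CLI flags.
    nucleic_type
        ``"DNA"`` or ``"RNA"``.
    bases
        Ordered, unique base symbols drawn from
        ``{A, T, U, C, G, 5mC, 6mA, 2mG}``.  ``T`` is DNA-only and ``U``
        RNA-only.
    """

    name: str
    nucleic_type: str
    bases: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.nucleic_type not in ("DNA", "RNA"):
            raise AlphabetError(f"nucleic_type must be DNA or RNA, got {self.nucleic_type!r}")
        if len(set(self.bases)) != len(self.bases):
            raise AlphabetError(f"duplicate bases in alphabet {self.name!r}: {self.bases}")
        for b in self.bases:
            if b not in _ALL_BASES:
                raise AlphabetError(f"unknown base symbol {b!r} in alphabet {self.name!r}")
            if b == "T" and self.nucleic_type != "DNA":
                raise AlphabetError("T is only valid in DNA alphabets")
            if b == "U" and self.nucleic_type != "RNA":
                raise AlphabetError("U is only valid in RNA alphabets")

    def __contains__(self, base: str) -> bool:
        return base in self.bases

    def __len__(self) -> int:
        return len(self.bases)

    def index(self, base: str) -> int:
        try:
            return self.bases.index(base)
        except ValueError:
            raise AlphabetError(f"base {base!r} not in alphabet {self.name!r}") from None


@dataclass(frozen=True)
class Kmer:
    """A fixed-length sequence of base symbols over an alphabet."""

    symbols: tuple[str, ...]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        for s in self.symbols:
            if s not in self.alphabet:
                raise AlphabetError(
                    f"symbol {s!r} not in alphabet {self.alphabet.name!r}"
                )

    @property
    def k(self) -> int:
        return len(self.symbols)

    def count(self, base: str) -> int:
        return self.symbols.count(base)

    def __str__(self) -> str:
        return format_kmer(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)


# ---------------------------------------------------------------------------
# Registry.  Base order is the declared (hence enumeration) order.
# ---------------------------------------------------------------------------

DNA = Alphabet("dna", "DNA", ("A", "C", "G", "T"))
RNA = Alphabet("rna", "RNA", ("A", "C", "G", "U"))
DNA_5MC = Alphabet("dna+5mC", "DNA", ("A", "C", "G", "T", "5mC"))
DNA_6MA = Alphabet("dna+6mA", "DNA", ("A", "C", "G", "T", "6mA"))
DNA_5MC_6MA = Alphabet("dna+5mC+6mA", "DNA", ("A", "C", "G", "T", "5mC", "6mA"))
RNA_6MA = Alphabet("rna+6mA", "RNA", ("A", "C", "G", "U", "6mA"))
RNA_6MA_2MG = Alphabet("rna+6mA+2mG", "RNA", ("A", "C", "G", "U", "6mA", "2mG"))

_REGISTRY = {
    a.name: a
    for a in (DNA, RNA, DNA_5MC, DNA_6MA, DNA_5MC_6MA, RNA_6MA, RNA_6MA_2MG)
}


def get_alphabet(name: str) -> Alphabet:
    """Look up a registered alphabet by name (e.g. ``"dna"``, ``"dna+5mC"``)."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise AlphabetError(
            f"unknown alphabet {name!r}; known: {sorted(_REGISTRY)}"
        ) from None


def default_k(nucleic_type: str) -> int:
    """Default kmer length: 6 for DNA, 5 for RNA."""
    return {"DNA": 6, "RNA": 5}[nucleic_type]


def enumerate_kmers(alphabet: Alphabet, k: int) -> list[Kmer]:
    """Enumerate all ``len(alphabet)**k`` kmers in lexicographic order.

    Order is lexicographic over the alphabet's declared base order, so output
    is deterministic and stable across calls.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return [
        Kmer(symbols, alphabet)
        for symbols in itertools.product(alphabet.bases, repeat=k)
    ]


# ---------------------------------------------------------------------------
# Text serialization
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\[([^\]]+)\]|(.)")


def format_kmer(symbols: Sequence[str]) -> str:
    """Join symbols; multi-character (modified) bases are bracketed."""
    return "".join(s if len(s) == 1 else f"[{s}]" for s in symbols)


def parse_kmer(
    text: str, alphabet: Alphabet, dialect: str = "bracket"
) -> Kmer:
    """Parse a kmer string into symbols over *alphabet*.

    ``dialect="bracket"`` reads the native form (``GT[5mC]AGA``);
    ``dialect="nanopolish"`` additionally maps ``M`` to ``5mC``.
    """
    symbols: list[str] = []
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(1) or m.group(2)
        if dialect == "nanopolish" and tok == "M":
            tok = "5mC"
        symbols.append(tok)
    return Kmer(tuple(symbols), alphabet)
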