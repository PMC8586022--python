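"""Train/test partition designs for kmer-model learning experiments.

Each design answers a different generalization question:

* ``downsample`` — random train/test split; how many kmers carry enough
  information to recapitulate the full model?
* ``base_dropout`` — train only on kmers that never contain a given base;
  can the base's effect be inferred from shared substructure?
* ``position_dropout`` — hold out all kmers with a given base at a given
  position.
* ``combination`` — train on the union of two base-dropout training sets,
  test on kmers containing both bases (two modifications known separately,
  their combination unseen).
* ``imputation`` — train on all canonical kmers plus a fraction of
  modification-containing kmers; at fraction 0 this is the de novo design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alphabet import Alphabet, AlphabetError, Kmer, enumerate_kmers

__all__ = [
    "SplitSpec",
    "random_split",
    "base_dropout_split",
    "position_dropout_split",
    "combination_split",
    "imputation_split",
    "count_containing",
]


@dataclass(frozen=True)
class SplitSpec:
    """A disjoint train/test partition produced by one experiment design."""

    design: str
    train: tuple[Kmer, ...]
    test: tuple[Kmer, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(map(str, self.train)) & set(map(str, self.test))
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]} ...")

    @property
    def n_train(self) -> int:
        return len(self.train)

    @property
    def n_test(self) -> int:
        return len(self.test)


def random_split(
    kmers: Sequence[Kmer], train_fraction: float, seed: int
) -> SplitSpec:
    """Random train/test split with ``|train| = floor(fraction * n)``.

    Reproducible for a fixed seed; e.g. 1024 RNA 5mers at fraction 0.95
    give 972 training kmers and 4096 DNA 6mers at 0.25 give 1024.
    """
    if not kmers:
        raise ValueError("empty kmer set")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = len(kmers)
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return SplitSpec(
        design="downsample",
        train=tuple(kmers[i] for i in train_idx),
        test=tuple(kmers[i] for i in test_idx),
        params={"fraction": train_fraction, "seed": seed},
    )


def base_dropout_split(alphabet: Alphabet, k: int, base: str) -> SplitSpec:
    """Train on kmers never containing *base*; test on all the rest.

    For canonical DNA 6mers this yields 729 training / 3367 test kmers.
    """
    if base not in alphabet:
        raise AlphabetError(f"base {base!r} not in alphabet {alphabet.name!r}")
    train, test = [], []
    for kmer in enumerate_kmers(alphabet, k):
        (test if base in kmer.symbols else train).append(kmer)
    return SplitSpec(
        design="base_dropout",
        train=tuple(train),
        test=tuple(test),
        params={"base": base},
    )


def position_dropout_split(
    alphabet: Alphabet, k: int, base: str, position: int
) -> SplitSpec:
    """Test on kmers whose 1-based *position* holds *base*; train on the rest."""
    if base not in alphabet:
        raise AlphabetError(f"base {base!r} not in alphabet {alphabet.name!r}")
    if not 1 <= position <= k:
        raise ValueError(f"position must be in [1, {k}], got {position}")
    train, test = [], []
    for kmer in enumerate_kmers(alphabet, k):
        (test if kmer.symbols[position - 1] == base else train).append(kmer)
    return SplitSpec(
        design="position_dropout",
        train=tuple(train),
        test=tuple(test),
        params={"base": base, "position": position},
    )


def combination_split(
    alphabet: Alphabet, k: int, base1: str, base2: str
) -> SplitSpec:
    """Union of two base-dropout training sets; test on kmers with both bases.

    ``|train| = 2(b-1)^k - (b-2)^k`` by inclusion–exclusion; for DNA 6mers
    this is 1394 training / 2702 test kmers.
    """
    if base1 == base2:
        raise ValueError("combination requires two distinct bases")
    for b in (base1, base2):
        if b not in alphabet:
            raise AlphabetError(f"base {b!r} not in alphabet {alphabet.name!r}")
    train, test = [], []
    for kmer in enumerate_kmers(alphabet, k):
        if base1 in kmer.symbols and base2 in kmer.symbols:
            test.append(kmer)
        else:
            train.append(kmer)
    return SplitSpec(
        design="combination",
        train=tuple(train),
        test=tuple(test),
        params={"base1": base1, "base2": base2},
    )


def imputation_split(
    canonical: Sequence[Kmer],
    modified: Sequence[Kmer],
    fraction: float,
    seed: int,
) -> SplitSpec:
    """All canonical kmers plus a random *fraction* of modified kmers in train.

    At ``fraction=0`` no modified kmer is seen during training (the de novo
    design); at ``fraction=1`` the test set is empty.
    """
    canon_keys = set(map(str, canonical))
    overlap = canon_keys & set(map(str, modified))
    if overlap:
        raise ValueError(
            f"canonical and modified sets overlap: {sorted(overlap)[:5]} ..."
        )
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    n_mod = len(modified)
    n_sample = int(round(fraction * n_mod))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_mod)
    chosen = set(np.sort(perm[:n_sample]).tolist())
    sampled = [modified[i] for i in sorted(chosen)]
    held_out = [modified[i] for i in range(n_mod) if i not in chosen]
    return SplitSpec(
        design="imputation",
        train=tuple(canonical) + tuple(sampled),
        test=tuple(held_out),
        params={"fraction": fraction, "seed": seed},
    )


def count_containing(
    alphabet: Alphabet, k: int, base: str, exactly: Optional[int] = None
) -> int:
    """Count kmers containing *base* at least once, or exactly *n* times.

    Closed forms: at-least-once is ``b^k - (b-1)^k``; exactly ``m`` is
    ``C(k, m) (b-1)^(k-m)``.  Computed here by the closed form after
    validating the base.
    """
    if base not in alphabet:
        raise AlphabetError(f"base {base!r} not in alphabet {alphabet.name!r}")
    b = len(alphabet)
    if exactly is None:
        return b**k - (b - 1) ** k
    if exactly < 0 or exactly > k:
        return 0
    from math import comb

    return comb(k, exactly) * (b - 1) ** (k - exactly)
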