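"""Kmer-model tables and nanopolish eventalign event tables.

A kmer model is a lookup table mapping each kmer to its characteristic
ionic-current level (mean, in pA, optionally with a standard deviation).
Two TSV dialects are read: the native/ONT layout (columns ``kmer``,
``level_mean``[, ``level_stdv``], header and ``#`` comments tolerated) and
the nanopolish layout, which writes 5-methylcytosine as the letter ``M``.

Empirical models are built from nanopolish ``eventalign`` tables by
averaging the measured event levels of every instance of each kmer; rows
whose ``model_kmer`` is the all-``N`` placeholder (unalignable events) are
skipped and counted.  Event-table coordinates are 0-based half-open, per
the upstream tool convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .alphabet import Alphabet, Kmer, format_kmer, parse_kmer

__all__ = [
    "KmerModel",
    "EventRecord",
    "KmerModelFormatError",
    "read_kmer_model",
    "write_kmer_model",
    "read_eventalign",
    "EventalignStats",
    "empirical_model_from_events",
]


class KmerModelFormatError(ValueError):
    """Malformed kmer-model or event table."""


@dataclass
class KmerModel:
    """kmer -> characteristic ionic current (pA).

    Keys are kmer text in bracket form (e.g. ``GT[5mC]AGA``); values are
    level means, with optional per-kmer standard deviations.
    """

    nucleic_type: str
    k: int
    levels: dict[str, float]
    stdvs: dict[str, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for key, v in self.levels.items():
            if not np.isfinite(v):
                raise KmerModelFormatError(f"non-finite level for kmer {key}")

    def __len__(self) -> int:
        return len(self.levels)

    def __contains__(self, kmer) -> bool:
        return _key(kmer) in self.levels

    def __getitem__(self, kmer) -> float:
        return self.levels[_key(kmer)]

    def values_for(self, kmers: Sequence) -> np.ndarray:
        """Level means for *kmers*, in order; KeyError listing any missing."""
        keys = [_key(k) for k in kmers]
        missing = [key for key in keys if key not in self.levels]
        if missing:
            raise KeyError(f"{len(missing)} kmers missing from model, e.g. {missing[:5]}")
        return np.array([self.levels[key] for key in keys], dtype=float)

    @classmethod
    def from_pairs(
        cls,
        kmers: Sequence[Kmer],
        values: Iterable[float],
        nucleic_type: Optional[str] = None,
        provenance: str = "",
    ) -> "KmerModel":
        kmers = list(kmers)
        nt = nucleic_type or kmers[0].alphabet.nucleic_type
        return cls(
            nucleic_type=nt,
            k=kmers[0].k,
            levels={str(km): float(v) for km, v in zip(kmers, values)},
            provenance=provenance,
        )


def _key(kmer) -> str:
    return str(kmer) if isinstance(kmer, Kmer) else kmer


def read_kmer_model(
    path, alphabet: Alphabet, dialect: str = "ont"
) -> KmerModel:
    """Read a kmer-model TSV; ``dialect`` is ``"ont"`` or ``"nanopolish"``."""
    if dialect not in ("ont", "nanopolish"):
        raise ValueError(f"unknown dialect {dialect!r}")
    token_dialect = "nanopolish" if dialect == "nanopolish" else "bracket"
    levels: dict[str, float] = {}
    stdvs: dict[str, float] = {}
    k_seen: Optional[int] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() == "kmer":
                continue  # header
            if len(fields) < 2:
                raise KmerModelFormatError(f"line {lineno}: expected >= 2 columns")
            try:
                kmer = parse_kmer(fields[0], alphabet, dialect=token_dialect)
            except ValueError as e:
                raise KmerModelFormatError(f"line {lineno}: {e}") from None
            try:
                mean = float(fields[1])
            except ValueError:
                raise KmerModelFormatError(
                    f"line {lineno}: non-numeric level_mean {fields[1]!r}"
                ) from None
            key = str(kmer)
            if key in levels:
                raise KmerModelFormatError(f"line {lineno}: duplicate kmer {key}")
            if k_seen is None:
                k_seen = kmer.k
            elif kmer.k != k_seen:
                raise KmerModelFormatError(
                    f"line {lineno}: mixed kmer lengths ({kmer.k} vs {k_seen})"
                )
            levels[key] = mean
            if len(fields) >= 3 and fields[2] != "":
                try:
                    stdvs[key] = float(fields[2])
                except ValueError:
                    raise KmerModelFormatError(
                        f"line {lineno}: non-numeric level_stdv {fields[2]!r}"
                    ) from None
    if k_seen is None:
        raise KmerModelFormatError(f"no kmer rows found in {path}")
    return KmerModel(
        nucleic_type=alphabet.nucleic_type,
        k=k_seen,
        levels=levels,
        stdvs=stdvs,
        provenance=str(path),
    )


def write_kmer_model(model: KmerModel, path) -> None:
    """Write a model as TSV with deterministic (sorted) kmer order."""
    with open(path, "w") as fh:
        cols = ["kmer", "level_mean"] + (["level_stdv"] if model.stdvs else [])
        fh.write("\t".join(cols) + "\n")
        for key in sorted(model.levels):
            row = [key, f"{model.levels[key]:.5f}"]
            if model.stdvs:
                row.append(f"{model.stdvs.get(key, float('nan')):.5f}")
            fh.write("\t".join(row) + "\n")


@dataclass(frozen=True)
class EventRecord:
    """One row of a nanopolish eventalign table."""

    contig: str
    position: int
    reference_kmer: str
    read_index: int
    strand: str
    event_index: int
    event_level_mean: float
    event_stdv: float
    event_length: float
    model_kmer: str
    model_mean: float
    model_stdv: float


_EVENT_COLUMNS = {
    "contig",
    "position",
    "reference_kmer",
    "read_index",
    "strand",
    "event_index",
    "event_level_mean",
    "event_stdv",
    "event_length",
    "model_kmer",
    "model_mean",
    "model_stdv",
}


@dataclass
class EventalignStats:
    """Row accounting for one eventalign pass."""

    n_records: int = 0
    n_skipped_placeholder: int = 0


def read_eventalign(
    path, stats: Optional[EventalignStats] = None
) -> Iterator[EventRecord]:
    """Stream EventRecords from an eventalign TSV.

    Column order is free (name-based lookup).  Rows whose ``model_kmer`` is
    the all-``N`` placeholder are skipped; pass an :class:`EventalignStats`
    to collect counts.
    """
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise KmerModelFormatError(f"empty eventalign file {path}")
        missing = _EVENT_COLUMNS - set(reader.fieldnames)
        if missing:
            raise KmerModelFormatError(
                f"eventalign file missing columns: {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            model_kmer = row["model_kmer"]
            if set(model_kmer) == {"N"}:
                if stats is not None:
                    stats.n_skipped_placeholder += 1
                continue
            try:
                rec = EventRecord(
                    contig=row["contig"],
                    position=int(row["position"]),
                    reference_kmer=row["reference_kmer"],
                    read_index=int(row["read_index"]),
                    strand=row["strand"],
                    event_index=int(row["event_index"]),
                    event_level_mean=float(row["event_level_mean"]),
                    event_stdv=float(row["event_stdv"]),
                    event_length=float(row["event_length"]),
                    model_kmer=model_kmer,
                    model_mean=float(row["model_mean"]),
                    model_stdv=float(row["model_stdv"]),
                )
            except ValueError as e:
                raise KmerModelFormatError(f"line {lineno}: {e}") from None
            if stats is not None:
                stats.n_records += 1
            yield rec


def empirical_model_from_events(
    events: Iterable[EventRecord],
    nucleic_type: str = "RNA",
    min_count: int = 1,
) -> tuple[KmerModel, dict[str, int]]:
    """Average measured event levels per ``model_kmer``.

    The model kmer (strand/orientation-corrected) keys the model.  Kmers
    observed fewer than *min_count* times are excluded; the returned dict
    reports per-kmer instance counts for all kmers seen, including excluded
    ones.  Averaging is streaming (count/sum), so it is order-independent
    up to floating-point roundoff.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    k: Optional[int] = None
    for rec in events:
        key = rec.model_kmer
        if k is None:
            k = len(key)
        sums[key] = sums.get(key, 0.0) + rec.event_level_mean
        counts[key] = counts.get(key, 0) + 1
    levels = {
        key: sums[key] / counts[key]
        for key in sums
        if counts[key] >= min_count
    }
    if not levels:
        import warnings

        warnings.warn("no kmers passed min_count filtering; model is empty")
    model = KmerModel(
        nucleic_type=nucleic_type,
        k=k or 0,
        levels=levels,
        provenance="empirical:eventalign",
    )
    return model, counts
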