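"""Atom embeddings from the final graph-convolution layer.

After training, the final GCN layer's activation matrix holds one feature
vector per atom; Pearson correlation between these vectors measures
atom-level chemical similarity (phosphate groups, sugar backbones and
nucleobase modules each cluster with high internal correlation), and a
seeded tSNE projection gives a global 2-D view of atom space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import Kmer
from .chem import encode_kmer, kmer_graph, nucleotide_atom_count
from .model import TrainedModel
from .nn import normalize_adjacency

__all__ = [
    "AtomEmbedding",
    "SimilarityMatrix",
    "atom_embeddings",
    "atom_similarity",
    "project_2d",
    "similarity_to_frame",
]


@dataclass(frozen=True)
class AtomEmbedding:
    """Final-GCN feature vectors for the real (non-padded) atoms of one kmer."""

    kmer: Kmer
    matrix: np.ndarray  # (n_real, final_gcn_width)
    labels: tuple[str, ...]  # "idx:element:pos<i>" per atom

    @property
    def n_atoms(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise Pearson r between atom feature vectors.

    Square and symmetric with unit diagonal for self-similarity; rectangular
    (n1, n2) for cross-kmer similarity.  Zero-variance rows yield NaN
    entries rather than raising.
    """

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]


def _atom_labels(kmer: Kmer) -> tuple[str, ...]:
    graph = kmer_graph(kmer)
    nt = kmer.alphabet.nucleic_type
    # atom index ranges per nucleotide position: block sizes are additive
    bounds = []
    start = 0
    for sym in kmer.symbols:
        n = nucleotide_atom_count(sym, nt)
        bounds.append((start, start + n))
        start += n
    labels = []
    for i, atom in enumerate(graph.atoms):
        pos = next(
            (p for p, (a, b) in enumerate(bounds) if a <= i < b), len(bounds)
        )
        tag = kmer.symbols[pos] if pos < len(bounds) else "3'OH"
        labels.append(f"{i}:{atom.element}:{tag}{pos if pos < len(bounds) else ''}")
    return tuple(labels)


def atom_embeddings(model: TrainedModel, kmer: Kmer) -> AtomEmbedding:
    """Final-GCN activations (post-ELU, dropout off) for one kmer's atoms."""
    tensor = encode_kmer(kmer, model.padding)
    A_hat = normalize_adjacency(tensor.A[None])
    H = model.network.gcn_activations(A_hat, tensor.X[None])[0]
    return AtomEmbedding(
        kmer=kmer,
        matrix=np.asarray(H[: tensor.n_real]),
        labels=_atom_labels(kmer),
    )


def _row_corr(M1: np.ndarray, M2: np.ndarray) -> np.ndarray:
    c1 = M1 - M1.mean(axis=1, keepdims=True)
    c2 = M2 - M2.mean(axis=1, keepdims=True)
    s1 = np.sqrt((c1**2).sum(axis=1))
    s2 = np.sqrt((c2**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (c1 @ c2.T) / np.outer(s1, s2)
    corr[~np.isfinite(corr)] = np.nan
    return corr


def atom_similarity(
    e1: AtomEmbedding, e2: Optional[AtomEmbedding] = None
) -> SimilarityMatrix:
    """Pairwise Pearson r between atom rows; cross-kmer when *e2* is given."""
    if e2 is None:
        corr = _row_corr(e1.matrix, e1.matrix)
        has_variance = np.isfinite(np.diagonal(corr))
        np.fill_diagonal(corr, np.where(has_variance, 1.0, np.nan))
        return SimilarityMatrix(corr, e1.labels, e1.labels)
    corr = _row_corr(e1.matrix, e2.matrix)
    return SimilarityMatrix(corr, e1.labels, e2.labels)


def project_2d(
    embeddings: Sequence[AtomEmbedding],
    seed: int = 0,
    perplexity: float = 30.0,
) -> pd.DataFrame:
    """Seeded tSNE projection of pooled atom vectors to 2-D.

    Perplexity is capped below the number of atoms (tSNE requirement); the
    default of 30 follows the standard implementation and is configurable.
    Returns a DataFrame with columns kmer, label, x, y.
    """
    if not embeddings:
        raise ValueError("need at least one embedding")
    M = np.vstack([e.matrix for e in embeddings])
    if M.shape[0] < 2:
        raise ValueError("need at least 2 atoms to project")
    from sklearn.manifold import TSNE

    eff_perplexity = min(perplexity, (M.shape[0] - 1) / 3)
    coords = TSNE(
        n_components=2,
        random_state=seed,
        perplexity=eff_perplexity,
        init="pca",
    ).fit_transform(M)
    rows = []
    i = 0
    for e in embeddings:
        for label in e.labels:
            rows.append(
                {"kmer": str(e.kmer), "label": label,
                 "x": float(coords[i, 0]), "y": float(coords[i, 1])}
            )
            i += 1
    return pd.DataFrame(rows)


def similarity_to_frame(sim: SimilarityMatrix) -> pd.DataFrame:
    """Similarity matrix as a labelled DataFrame for TSV export."""
    return pd.DataFrame(sim.values, index=list(sim.row_labels),
                        columns=list(sim.col_labels))
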