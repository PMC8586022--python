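"""Experiment battery: goodness of fit over the train/test designs.

For each design a reference kmer model supplies the targets, a network is
trained on the design's training kmers, and goodness of fit — RMSE in pA
and Pearson's r — is recorded separately on the train and test subsets.
Repeats quantify training stochasticity: the downsample design redraws the
random split every repeat (cross-validation style), whereas the dropout,
combination and imputation designs keep the split fixed and vary only the
training randomness.  Repeat seeds derive deterministically from a base
seed plus the repeat index.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import Alphabet, Kmer, enumerate_kmers
from .io import KmerModel
from .model import (
    ArchitectureConfig,
    TrainConfig,
    TrainedModel,
    predict_kmers,
    train_on_kmers,
)
from .splits import SplitSpec, imputation_split, random_split

__all__ = [
    "Metrics",
    "ExperimentResult",
    "evaluate",
    "run_experiment",
    "denovo_prediction",
    "results_table",
    "DOWNSAMPLE_FRACTIONS",
    "IMPUTATION_FRACTIONS",
]

#: Downsample ladder: train fractions at 5% intervals, 0.05 .. 0.95.
DOWNSAMPLE_FRACTIONS = tuple(round(0.05 * i, 2) for i in range(1, 20))
#: Imputation ladder for modification-containing kmers.
IMPUTATION_FRACTIONS = (0.01, 0.05, 0.10, 0.30, 0.50, 0.70, 0.90)


@dataclass(frozen=True)
class Metrics:
    """RMSE (pA) and Pearson's r over *n* evaluated kmers.

    ``pearson_r`` is NaN (flagged, not raised) when either side has zero
    variance.
    """

    rmse: float
    pearson_r: float
    n: int

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


@dataclass(frozen=True)
class ExperimentResult:
    design: str
    params: dict
    repeat: int
    seed: int
    train_metrics: Metrics
    test_metrics: Optional[Metrics]


def evaluate(
    predicted: KmerModel, reference: KmerModel, subset: Sequence[Kmer]
) -> Metrics:
    """Goodness of fit of *predicted* against *reference* on *subset*."""
    if len(subset) < 1:
        raise ValueError("empty evaluation subset")
    p = predicted.values_for(subset)
    r = reference.values_for(subset)
    rmse = float(np.sqrt(np.mean((p - r) ** 2)))
    if len(subset) < 2 or p.std() == 0 or r.std() == 0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(p, r)[0, 1])
    return Metrics(rmse=rmse, pearson_r=pearson, n=len(subset))


def _one_repeat(
    split: SplitSpec,
    reference: KmerModel,
    config: ArchitectureConfig,
    tc: TrainConfig,
    P: int,
    repeat: int,
) -> ExperimentResult:
    fitted = train_on_kmers(list(split.train), reference, config, tc, P)
    all_kmers = list(split.train) + list(split.test)
    predicted = predict_kmers(fitted, all_kmers)
    train_m = evaluate(predicted, reference, list(split.train))
    test_m = (
        evaluate(predicted, reference, list(split.test)) if split.test else None
    )
    return ExperimentResult(
        design=split.design,
        params=dict(split.params),
        repeat=repeat,
        seed=tc.seed,
        train_metrics=train_m,
        test_metrics=test_m,
    )


def run_experiment(
    split_factory: Callable[[int], SplitSpec] | SplitSpec,
    reference: KmerModel,
    config: ArchitectureConfig,
    train_config: TrainConfig,
    P: int,
    n_repeats: int = 1,
    base_seed: int = 0,
) -> list[ExperimentResult]:
    """Run *n_repeats* independently trained networks over a split design.

    Pass a fixed :class:`SplitSpec` for the dropout/combination/imputation
    designs (only training stochasticity varies between repeats), or a
    callable ``seed -> SplitSpec`` for the downsample design, which draws a
    fresh random split per repeat.  Repeat ``i`` uses seed
    ``base_seed + i``.
    """
    results = []
    for i in range(n_repeats):
        seed = base_seed + i
        split = split_factory(seed) if callable(split_factory) else split_factory
        missing = [
            str(km)
            for km in list(split.train) + list(split.test)
            if km not in reference
        ]
        if missing:
            raise KeyError(
                f"reference model missing {len(missing)} kmers of the design "
                f"universe, e.g. {missing[:5]}"
            )
        tc = replace(train_config, seed=seed)
        results.append(_one_repeat(split, reference, config, tc, P, repeat=i))
    return results


def denovo_prediction(
    reference_canonical: KmerModel,
    canonical_alphabet: Alphabet,
    target_alphabet: Alphabet,
    k: int,
    config: ArchitectureConfig,
    train_config: TrainConfig,
    P: int,
    n_repeats: int = 1,
    base_seed: int = 0,
) -> tuple[KmerModel, list[KmerModel]]:
    """Train on canonical kmers only; predict the full extended alphabet.

    Returns the per-kmer mean over repeats plus each repeat's full
    prediction.  The padding size *P* must accommodate the extended
    alphabet.
    """
    if not set(canonical_alphabet.bases) <= set(target_alphabet.bases):
        raise ValueError("target alphabet must extend the canonical one")
    train_kmers = enumerate_kmers(canonical_alphabet, k)
    target_kmers = enumerate_kmers(target_alphabet, k)
    per_repeat: list[KmerModel] = []
    for i in range(n_repeats):
        tc = replace(train_config, seed=base_seed + i)
        fitted = train_on_kmers(train_kmers, reference_canonical, config, tc, P)
        per_repeat.append(predict_kmers(fitted, target_kmers))
    mean_values = np.mean(
        [m.values_for(target_kmers) for m in per_repeat], axis=0
    )
    summary = KmerModel.from_pairs(
        target_kmers, mean_values, provenance="denovo:mean-over-repeats"
    )
    return summary, per_repeat


def results_table(results: Sequence[ExperimentResult]) -> pd.DataFrame:
    """Long-format table: one row per (design, params, repeat, subset)."""
    rows = []
    for res in results:
        for subset, m in (("train", res.train_metrics), ("test", res.test_metrics)):
            if m is None:
                continue
            rows.append(
                {
                    "design": res.design,
                    **{f"param_{k}": v for k, v in res.params.items()},
                    "repeat": res.repeat,
                    "seed": res.seed,
                    "subset": subset,
                    "n": m.n,
                    "rmse": m.rmse,
                    "pearson_r": m.pearson_r,
                }
            )
    return pd.DataFrame(rows)
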