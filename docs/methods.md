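# Methods

## The problem

During nanopore sequencing the k nucleotides occupying the pore's sensing
region (a *kmer*: 6 bases for DNA, 5 for RNA) determine the measured ionic
current. Kmer models — lookup tables mapping each kmer to its characteristic
current level in picoamperes — underpin both basecalling-adjacent analyses
and the detection of chemically modified bases. Character-based kmer models
treat every base (including each modification) as an unrelated symbol, so
they need exhaustive control data and cannot predict the current signature
of a modification they have never seen. poregraph instead regresses the
current level directly on the kmer's *chemical structure*, so that chemical
groups shared between bases (e.g. the 5-methyl group common to thymine and
5-methylcytosine) carry information across the alphabet.

## Chemical representation

Each kmer is written as a single SMILES string by concatenating
per-nucleotide building blocks in sequence order and appending a terminal
`O` for the residual backbone hydroxyl. The blocks (one per base × nucleic
type; see `poregraph.chem.NUCLEOTIDE_SMILES`) are chosen so that plain
string concatenation forms the phosphodiester backbone: each runs
5'-phosphate → sugar → base → 3' carbon, and the leading `O` of the next
block bonds to the preceding 3' carbon.

The string is parsed (via RDKit, which preserves SMILES atom-appearance
order) into a heavy-atom graph: atoms as nodes, covalent bonds as edges, and
eight features per atom —

| feature | definition |
|---|---|
| C, N, O, P | one-hot element indicators |
| degree | number of bonded heavy-atom neighbors (a double bond counts once, so adjacency row sums equal the degree feature exactly) |
| implicit valence | standard valence minus valence accounted for by explicit bonds |
| hydrogens | total (implicit) hydrogen count |
| aromaticity | 1 if the atom is in an aromatic ring |

Hydrogens are implicit throughout; formal charges and stereochemistry are
absent from the building blocks and are ignored. Aromaticity comes from
standard perception on the kekulized strings: the conjugated purine and
pyrimidine rings perceive as aromatic (9 atoms for purines, 6 for
pyrimidines).

For batching, adjacency `A` and feature matrix `X` are zero-padded (trailing
rows/columns) to the largest kmer in the configured alphabets. Atom counts
are additive over positions, so the padding size is `k × max-per-base-atoms
+ 1`: 133 for DNA 6mers over the canonical + 5mC + 6mA alphabets and 116 for
RNA 5mers over canonical + 6mA. An alphabet containing 2mG (one atom heavier
than G) pushes RNA padding to 121 — a 5mer of five 2mG residues has
5 × 24 + 1 atoms — so padding is always computed from the configured
alphabets at run time rather than hard-coded; published RNA dimension
constants that assume at most the canonical + 6mA alphabet cannot
accommodate arbitrary 2mG kmers, and the package documents this by simply
computing the honest maximum.

## Network

The regressor stacks three layer groups:

1. **Graph convolutions** with the symmetric renormalization
   `H^(l+1) = ELU( D̃^(-1/2) (A + I) D̃^(-1/2) H^(l) W^(l) )`, `H^(0) = X`.
   The *inverse* square root of the self-loop-augmented degree matrix is
   used; this is the convention that keeps feature scales stable as layers
   stack (a positive-exponent scaling would blow them up). Padded atoms have
   only their identity self-loop, so their activations stay exactly zero.
   Each layer widens an atom's receptive field by one bond.
2. **1-D convolutions** (valid, ReLU) over the atom axis summarize
   longer-range structure, each followed by 2×2 stride-1 *average pooling*
   over the (length × channels) matrix, shrinking both dimensions by one.
   The first convolution output is {P − K + 1, N′} (K the kernel size, N′
   the final GCN width) and each subsequent stage follows
   {m − K + 1 − 2 + 1, n − 2 + 1}. Because pooling spans the channel axis,
   the next convolution's input channel count is the pooled one.
3. A row-wise **flatten**, one **dense** layer, and a scalar linear output
   (the predicted pA value). The dense layer is linear — the output is an
   explicit linear combination of dense-layer activations; adding a ReLU
   there is a documented sensitivity, not the default.

Layer widths follow `n = 16 × 2^(l−1)` counted from the output end of each
group (a depth-4 GCN group is 128/64/32/16 wide); CNN channel counts mirror
the same wide→narrow ordering. Grid-searched hyperparameters: GCN depth
{2..6}, CNN depth {2..6}, kernel size {2, 4, 10, 20}, dense width {32, 128,
512, 2048, 8192} — 500 combinations, selected by 10-fold cross-validated
mean RMSE (`poregraph.model.grid_search`). The best architectures found at
full scale are exposed as `DNA_OPTIMAL` (4 GCN / 3 CNN / K=10 / 8192),
`RNA_OPTIMAL` (4/5/10/8192) and `RNA_MODIFIED_OPTIMAL` (6/6/10/8192).

### Implementation

The network, including backpropagation and the Adam optimizer, is
implemented directly in numpy (`poregraph.nn`). All layer gradients are
hand-derived and validated against central finite differences (relative
error < 1e-5 in the test suite), and the graph convolution is checked
elementwise (1e-6) against a brute-force per-atom neighbor-accumulation
oracle. Training is deterministic for a fixed seed on a single thread.

### Training procedure

Mean-squared error, Adam with canonical defaults (learning rate 1e-3,
β₁ 0.9, β₂ 0.999, ε 1e-8), minibatches of 32, at most 500 epochs, 10%
inverted dropout after every GCN/CNN/dense layer during training only. A
10% seeded random held-out fraction of the training kmers monitors
validation loss; training stops after 10 epochs without improvement and the
best-validation weights are restored. Targets are z-scored with
training-set statistics before optimization and un-scaled at prediction;
reported losses are on the pA scale. These are numerical conveniences: the
network itself sees raw chemistry.

## Experiment designs

All designs live in `poregraph.splits` and are driven by
`poregraph.experiments.run_experiment`:

- **downsample** — random split at 5% intervals (0.05…0.95); each repeat
  redraws the split (cross-validation style).
- **base dropout** — train on kmers never containing a base: 729/3367
  train/test for DNA, 243/781 for RNA.
- **position dropout** — hold out all kmers with a base at one position:
  3072/1024 (DNA), 768/256 (RNA).
- **combination** — union of two base-dropout training sets, testing on
  kmers containing both bases: 1394/2702 (DNA), 454/570 (RNA).
- **imputation** — all canonical kmers plus {1, 5, 10, 30, 50, 70, 90}% of
  modification-containing kmers in training.
- **de novo** — train on canonical kmers only, predict the full extended
  alphabet (15,625 {A,T,C,G,5mC} DNA 6mers; 7,776 {A,6mA,U,G,2mG,C} RNA
  5mers).

For the fixed-split designs, repeat-to-repeat variability comes only from
training stochasticity; repeat seeds derive deterministically as
`base_seed + repeat_index` so every run is reproducible. Goodness of fit is
RMSE (pA) and Pearson's r, computed separately on the train and test
subsets; zero-variance cases yield a flagged NaN r rather than an
exception.

## Atom embeddings

`poregraph.embeddings` extracts the final GCN layer's activation rows
(post-ELU, dropout off) for the real atoms of a kmer. Pearson correlation
between atom rows quantifies atom-level chemical similarity — phosphate
groups, sugar backbones and nucleobase modules each form high-correlation
blocks in a trained model — and a seeded tSNE (scikit-learn; perplexity
configurable, default 30 capped below the atom count) provides a global
2-D view. Whether to correlate pre- or post-activation values is a genuine
choice; post-activation values are used because they are what downstream
layers consume.

## Synthetic reference models

Real reference kmer models (ONT DNA 6mer and RNA 5mer tables, the
nanopolish 5mC table, empirical models built from eventalign output)
require downloads, so the package ships a generator
(`poregraph.synthetic`) whose defaults define the desk-scale study
conditions:

    level(kmer) = intercept + Σ_p effect(p, base_p) + N(0, noise_sd)

with intercept 100 pA, per-(position, base) effects drawn N(0, 4 pA) and
noise_sd 0.5 pA — giving ~70–130 pA ranges comparable to real models; the
scale is otherwise arbitrary. Modified bases inherit their parent's effects
plus a per-position offset. The model is linear in one-hot position-base
indicators, so ordinary least squares (`fit_additive_ols`) recovers the
generating effects exactly at zero noise and serves as the independent
oracle for parameter-recovery testing of the network.

What the generator does *not* emulate: position × base interactions (real
kmer currents are not strictly additive), heteroscedastic per-kmer noise,
and any relationship between chemistry and effect size. Passing the
recovery test therefore shows the network can learn a position-additive
map from raw chemical graphs through the full pipeline — not that it
reaches the published accuracy on real current tables, which requires the
external reference models and full-scale training (see below).

## Problem sizes and verification scale

Desk-scale checks use the reduced architecture `REDUCED`
(2 GCN / 2 CNN / K=4 / dense 128) and at most 50 epochs. The recovery
experiment in the test suite trains on a 50% random split of all 4096
canonical DNA 6mers against a synthetic reference (noise 0.5 pA) and
requires held-out Pearson r ≥ 0.9 and RMSE within 3× the OLS oracle's
held-out RMSE; a representative run reaches r ≈ 0.996 and RMSE ≈ 0.64 pA
against an OLS RMSE of ≈ 0.49 pA. Published full-scale numbers (test RMSE
≈ 1 pA / r ≈ 0.995 at ≥ 40% downsample; RMSE 1.2 / r 0.995 at 5% 5mC
imputation; RMSE 1.8 / r 0.993 for de novo 5mC) are reproduction
experiments that need the external ONT/nanopolish tables, the full
architectures and 50 repeats of up-to-500-epoch training; the CLI supports
them (`poregraph experiment … --repeats 50`) but they are not part of the
test suite.

## Numerical and design choices

- Kmers are symbol sequences with multi-character modified-base tokens
  (`5mC`, `6mA`, `2mG`), bracketed in text form (`GT[5mC]AGA`); the
  nanopolish `M` convention is a reader dialect.
- Kmer enumeration order is lexicographic in declared base order —
  reproducible fixtures and stable file output.
- `random_split` takes the floor of fraction × n (972 = ⌊0.95 × 1024⌋).
- Early stopping uses no-improvement patience with best-weight restoration
  (the behavior of the standard Keras-style callback), which subsumes the
  stricter "strictly increasing for ten epochs" reading.
- Empirical model building keys on `model_kmer` (strand/orientation
  corrected), skips all-`N` placeholder rows with a counter, applies no
  deduplication of consecutive events, and defaults to `min_count = 1`
  (average *all* instances); the threshold is exposed because sparse
  coverage is common.
- Degenerate inputs are flagged, not silently propagated: zero-variance
  Pearson r is NaN, empty post-filter empirical models warn, dimension
  collapse in an architecture raises with the offending layer index.

## Known limitations

- The SMILES subset is exactly what the nucleotide blocks need (C/N/O/P,
  double bonds, branches, ring closures); charges, isotopes and chirality
  are out of scope.
- Chemical-context stacking limits de novo generalization: a group whose
  local context differs between donor and target base (e.g. the
  methylamine of 6mA vs. a plain methyl plus amine) is not correctly
  composable, so de novo predictions are only trustworthy where the shared
  group sits in the same context.
- The numpy engine is single-threaded CPU code; full-scale 500-epoch ×
  50-repeat experiment batteries are long-running (flagged as such in the
  CLI help), though entirely feasible.
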