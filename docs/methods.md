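# Methods

## Problem setting

Given a dataset D = {(eᵢ, tᵢ, aᵢ)} of epitope sequences e, TCRβ sequences t
(CDR3 loop or full variable region) and binary binding labels a, the task
is to learn Φ : E × T → [0, 1]. Two properties of public binding data shape
everything here: labels exist only for *positives* (negatives must be
synthesized), and the epitope space is sampled extremely sparsely relative
to the receptor space (tens of thousands of receptors vs. a few hundred
epitopes). The package therefore treats the splitting protocol as part of
the model contract: a receptor-disjoint split measures generalization to
unseen receptors, an additionally epitope-disjoint ("strict") split
measures generalization to unseen epitopes, and the two give very
different answers.

## Dataset pipeline

**Curation.** Positives are deduplicated per epitope by receptor identity
(receptor identity is the exact sequence string, so splitting leaks are
judged at sequence level — duplicated sequences with different metadata
collapse). Epitopes with fewer than `min_tcrs_per_epitope` (default 15)
receptors are removed; epitopes above `max_tcrs_per_epitope` (default 400)
are downsampled uniformly at random under the configured seed. Both bounds
follow common practice for repertoire binding data; downsampling is random
because no quality ranking is assumed. Curation is idempotent and
bit-reproducible under a fixed seed.

**Negative sampling.** Each receptor is paired with epitopes drawn
uniformly from the in-scope epitope set, excluding epitopes it is recorded
to bind, until it has exactly as many negatives as positives; the result
is an exact 50/50 balance, with no negative duplicating a positive pair.
Draws retry up to 100 times on collision before falling back to exhaustive
enumeration of valid epitopes; receptors with no valid negative (e.g. a
single-epitope scope) are logged and contribute none. When a fold
assignment is supplied, sampling is confined within folds so disjointness
survives.

**Splitting.** `tcr_split` shuffles receptors into folds; all records of a
receptor follow it. `strict_split` assigns epitopes greedily — largest
epitope first into the currently smallest fold — which keeps fold sizes
balanced without any tuning; receptors that then span folds are kept only
in the fold holding most of their records (ties to the lowest fold index)
and dropped elsewhere, with counts logged. The greedy rule and the
majority-fold tie-break are this package's choices; only the end condition
(pairwise-disjoint receptor and epitope sets) is fundamental.

**Compound–protein pretraining tables.** `preprocess_cpi` binarizes a
ligand–protein affinity table (all listed entries labeled binding),
balances it with random ligand-to-protein reassignments that avoid listed
pairs, discards ligands over 250 SMILES tokens and proteins over 1028
residues, and splits 90/10 into train/validation. The enlarged network
configuration for this regime (`ModelConfig.pretrain()`) pads receptors to
1028 tokens, uses attention space A = 256, four convolution channels of
kernel sizes 3/7/9/13 (epitope) and 3/7/13/19 (receptor) without a
residual channel, and a 2048/1024/512 dense stack.

## Sequence encodings

Both streams are flanked by a shared start/stop token (index 1), padded
with index 0 to a fixed length, and embedded per token. Flank and pad
tokens participate in attention by default (a masking flag exists but
defaults off); the pad embedding row is zero in every scheme.

* **BLOSUM62** (default for the full-size configuration): each residue is
  its 26-dimensional substitution-score row over the extended alphabet of
  20 standard residues plus B, Z, X, U, O, `*`. U and O do not appear in
  the published matrix and embed as zero rows. Loaded from Biopython's
  matrix data.
* **Biophysical**: molecular weight, residue weight, pKa, pKb, pKx, pI and
  hydrophobicity at pH 2, from standard reference tables stored as a
  versioned constant in the source; side chains without an ionizable group
  get pKx 7.0 (neutral). Values are min–max scaled to [0, 1] by default so
  molecular weight does not dominate the geometry.
* **Learned**: a trainable 32-dimensional table, seeded standard-normal
  initialization scaled by 0.1.

**SMILES epitopes.** Peptides are condensed residue-by-residue into the
linear molecule (free termini, L-stereocenters; a flag strips
stereochemistry) via RDKit and serialized canonically. Augmentation
renumbers atoms by a seeded permutation and re-serializes
non-canonically — the output always canonicalizes back to the same
molecule, which is the entire point: fresh token sequences, identical
chemistry. Tokenization is atom-level (bracket atoms, two-letter halogens
and two-digit ring closures as single tokens); the vocabulary is built
from the training epitopes' canonical forms plus a few augmented variants
so augmented strings tokenize without unknowns, and persists as JSON.

## The K-NN baseline

The inter-pair distance D(eᵢ,tᵢ,eⱼ,tⱼ) = Lev(eᵢ,eⱼ)/|eⱼ| + Lev(tᵢ,tⱼ)/|tⱼ|
normalizes by the *query* pair's lengths, exactly as the formula is
written, and is therefore mildly asymmetric; a symmetric variant
(normalizing by mean lengths) is available behind a flag for study. Edit
distances come from edlib; distance ties at the k-th rank break by stable
training order. The score is the mean neighbor label, so with odd k the
0.5 threshold never ties; k is swept over odd 1…25 and selected by
cross-validated ROC-AUC on training folds (selection on test metrics is
also possible but not the default). Training sets here are small enough
that exact search with memoized distances beats any index structure.

## Network architecture and training

Channel counts match across streams because attention pairs them
channel-wise. Convolutions are same-padded so sequence lengths are
preserved — required for the T×U coupling matrix W₃ to be well-defined.
Each channel of each stream has its own attention parameter set (sharing
across channels is conceivable but not assumed), and the attention readout
is the α-weighted sum over positions — the standard attention pooling —
giving one feature vector per channel per stream, concatenated into the
dense stack. Filter counts per channel (H = K) default to 32 and are
configurable; they are an open knob rather than a reproduced constant.
Dropout (p = 0.5 by default) applies after every convolution and dense
ReLU during training only. The output unit is logistic, trained with
binary cross-entropy (computed on logits for numerical stability) under
Adam (lr 1e-4, β = 0.9/0.999, ε = 1e-8, batch 512 by default).

`semifrozen` scope freezes everything under the epitope stream prefix —
embedding, convolutions and attention — leaving the receptor stream and
dense stack adaptable; the optimizer simply skips frozen tensors, so their
values stay bit-identical. Fixed-epoch training records a per-epoch loss
trace; when a validation set is supplied, validation ROC-AUC is tracked
per epoch and the best-epoch parameters are restored at the end (no early
stopping or learning-rate schedule is used).

The network runs on a package-local reverse-mode autodiff core
(`tcrbind.autograd`): a tensor type over float64 numpy arrays with the
dozen primitives the architecture needs (broadcast-aware arithmetic,
batched matmul, unfold-based convolution, softmax, embedding gather,
dropout, stable BCE-on-logits) and an Adam implementation. Every
primitive's gradient is tested against central finite differences.

### Desk-scale profile

`ModelConfig.reduced()` (receptor length 24, epitope length 16, 16 filters,
A = 16, dense 368/184) and `TrainConfig.desk_scale()` (batch 64, 30
epochs, lr 1e-3, dropout 0.2) together define the CPU-scale study
configuration used by the benchmarks and the acceptance script. The
learning rate and dropout were calibrated on validation folds of the
synthetic benchmark: at the full-scale defaults (lr 1e-4, dropout 0.5) the
training loss is still near its starting value after 30 epochs, whereas
the desk-scale pair converges comfortably within the epoch budget. The
reduced profile also defaults both streams to learned embeddings: with
only 16 filters per channel, exact short motifs separate better in a
learned embedding space than on substitution-matrix rows (≈0.92 vs ≈0.87
held-out ROC-AUC on the planted benchmark); at full scale the choice of
embedding is known to matter little.

## Attention analysis

Per (receptor, epitope) pair the four channels' attention maps are
averaged into one per-token row per stream (the aggregation into a single
heatmap is this package's choice). Variance statistics use the population
estimator by default (ddof configurable): *inter*-group variance is the
per-token variance of group-mean attention across groups, averaged over
tokens; *intra*-group variance is the per-token variance across contexts
within a group, averaged over tokens and then groups. Epitope compression
keeps residues whose attention strictly exceeds a threshold (0.1 by
default) in order, excluding flank/pad columns; when an epitope occurs
with several receptor contexts its context-averaged row is used (justified
whenever intra-epitope variance is negligible). If the compressed strings
remain unique across the epitope set, the attended positions suffice to
identify the epitope — the signature of a model acting as an implicit
epitope classifier rather than reading epitope chemistry.

## Synthetic benchmark design

The generator emulates the *shape* of curated repertoire data — tens of
epitopes (8–11 residues), 15–400 CDR3-like receptors (10–18 residues) per
epitope, balanced labels, 5% label noise by default — with uniform amino
acid composition and no V/J-gene or codon realism: enough for the test
surface, not a biological simulator. Motifs are contiguous 3-mers drawn
without replacement (contiguity mirrors the roughly contiguous contact
loop and keeps the edit-distance property provable); positive receptors
carry their epitope's motif at a random internal position and no other
epitope's motif, negative receptors carry no motif at all. The planted
rule ships with the dataset as a JSON manifest, and a motif-presence
oracle bounds what any classifier can achieve (≈0.95 ROC-AUC at 5% label
noise). The `epitope_class_only` rule instead draws each label from a
per-epitope Bernoulli rate (uniform on [0.1, 0.9]) with receptor sequences
carrying no signal: learnable when test epitopes were seen (memorize base
rates), chance when they were not.

What passing these benchmarks does *not* show: performance on real
repertoires, where motifs are degenerate, receptors are clonally related,
epitope similarity structure exists, and labels are assay-dependent. The
benchmarks validate machinery and qualitative regimes (unseen-receptor
learnability, unseen-epitope collapse), not headline numbers.

## Benchmark protocols and problem sizes

`tcrbind.benchmarks` fixes two protocols, chosen to run in minutes on one
CPU. *Planted rule*: 30 epitopes × 100 positive receptors (6000 records),
ten receptor-disjoint folds, one fold held out; the reduced network trains
on the rest (desk-scale profile), K-NN selects k by an inner 3-fold sweep
on the training data; three consecutive seeds are averaged. *Unseen
epitopes*: same size under the epitope-identity-only rule with ten strict
folds; K-NN (k fixed at 25, the top of the sweep range) runs all ten
folds, the network the first two. Expected outcomes: network ≈ 0.92 and
K-NN ≈ 0.87 held-out ROC-AUC on the planted rule; both ≈ 0.5 on unseen
epitopes.

## Numerical choices and degenerate inputs

* Attention rows are validated to sum to 1 within 1e-6; zero feature
  inputs yield exactly uniform attention (softmax of a constant).
* Balanced accuracy thresholds scores at exactly 0.5 (predictions ≥ 0.5
  count positive); no calibration is attempted.
* The "±" across folds is the population standard deviation of fold
  scores.
* Fold-AUC is undefined on single-class folds; the harness raises rather
  than imputing.
* Empty sequences are rejected at tokenization; empty query sequences are
  rejected by the pair distance (they normalize the metric).
* All stochastic steps — curation downsampling, negative draws, fold
  shuffles, parameter initialization, batch order, dropout, SMILES
  augmentation — derive from explicit integer seeds, and runs are
  bit-reproducible given them.

## Known limitations

* Full-scale training (500-token padding, 512 batches, hundreds of
  epochs, CPI pretraining corpora) is architecturally supported but far
  beyond the desk-scale profile this package is tuned and tested at.
* MHC context, TCRα chains, paired-chain data and V/J-gene-to-sequence
  reconstruction are out of scope; full variable-region sequences are
  accepted as given input.
* The biophysical table is one standard reference among several; swapping
  sources changes embedding values (not structure).
* The float64 numpy core favors reproducibility and auditability over
  speed; it is single-threaded and has no GPU path.
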