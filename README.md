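# tcrbind

Sequence-based prediction of T-cell receptor (TCR) — epitope binding
specificity.

T cells recognize short antigenic peptides (epitopes, 5–15 residues)
presented on MHC through the hypervariable CDR3 loop of the TCRβ chain.
Public binding databases list tens of thousands of receptor sequences but
only a few hundred distinct epitopes, which makes *unseen-receptor*
generalization measurable while *unseen-epitope* generalization remains the
open problem. `tcrbind` is a toolkit for studying exactly this regime: it
implements a bimodal neural predictor with context attention, a deliberately
simple edit-distance baseline, the data curation / negative sampling /
leakage-free splitting pipeline the problem demands, attention-based
interpretability statistics, and a synthetic repertoire generator with a
planted, auditable binding rule so that every claim is testable on a laptop.

## The models

**Bimodal context-attention network.** A receptor stream and an epitope
stream are embedded per token (BLOSUM62 rows, seven biophysical descriptors,
or a learned table; epitopes may alternatively be rendered as SMILES and
embedded at atom level), passed through parallel same-padded 1-D
convolution channels of kernel sizes 3/5/11 plus a residual channel, and
coupled channel-wise by context attention. With reference features
X₁ ∈ ℝ^{T×H} and context features X₂ ∈ ℝ^{U×K},

```
u = tanh(X1 W1 + W3 (X2 W2)) v,      α = softmax(u),
```

with W₁ ∈ ℝ^{H×A}, W₂ ∈ ℝ^{K×A}, W₃ ∈ ℝ^{T×U}, v ∈ ℝ^{A} learned and A the
common attention space (16 by default). The attention weights α filter the
reference stream (weighted-sum pooling); pooled features of all channels
and both streams feed a dense stack (368/184 units) ending in a logistic
binding probability. Training minimizes binary cross-entropy with Adam.
Because SMILES strings are not unique per molecule, the epitope stream
supports on-the-fly augmentation, and a *semifrozen* mode freezes the whole
epitope stream during fine-tuning.

**Levenshtein K-NN baseline.** The distance between pairs is

```
D(eᵢ, tᵢ, eⱼ, tⱼ) = Lev(eᵢ, eⱼ)/|eⱼ| + Lev(tᵢ, tⱼ)/|tⱼ|,
```

normalized by the query pair's lengths; the score of a query is the mean
label of its k nearest training records, with k swept over odd 1…25 and
chosen by cross-validated ROC-AUC.

**Evaluation protocol.** `tcr_split` cross-validation confines every
receptor to one fold (epitopes shared); `strict_split` additionally
confines every epitope to one fold, with negatives generated by shuffling
*within* folds so no pairing leaks across them.

## Worked example

```python
import numpy as np
from tcrbind import (SyntheticConfig, TCRBindingModel, TrainConfig,
                     ModelConfig, generate_benchmark, make_folds)

records, rule = generate_benchmark(SyntheticConfig(rng_seed=1))
folds = make_folds(records, 10, mode="tcr_split", rng_seed=1)
train = [records[i] for i, f in folds.fold_of.items() if f != 0]
test  = [records[i] for i, f in folds.fold_of.items() if f == 0]

model = TCRBindingModel(train, config=ModelConfig.reduced(), rng_seed=1)
results = model.fit(TrainConfig.desk_scale(rng_seed=1))
print(results.summary())
print("held-out ROC-AUC:", round(results.evaluate(test).roc_auc, 4))
```

prints

```
Bimodal context-attention binding model
==============================================
training records                5400  (positives 2716)
epitopes                          30
parameters                    156993
epitope encoding             learned
receptor encoding            learned
attention space A                 16
conv channels                      4
trainable scope                  all
epochs trained                    30
final training loss           0.1082
held-out ROC-AUC: 0.9155
```

The benchmark plants a 3-residue motif per epitope inside positive
receptors (5% label noise, so the attainable ceiling is ≈0.95); a held-out
ROC-AUC of ≈0.92 on receptor-disjoint folds means the network recovered
the rule for receptors it never saw. The same data give the K-NN baseline
≈0.87–0.89 — edit-distance proximity picks up shared motifs — while on the
epitope-identity-only benchmark under the strict split both models fall to
chance (≈0.5), reproducing the unseen-epitope failure mode that attention
analysis (`tcrbind.attention`) traces to epitopes being treated as class
labels.

A command-line interface mirrors the library:

```
tcrbind synth --epitopes 30 --tcrs 100 --out bench/
tcrbind curate --in positives.csv --min 15 --max 400 --seed 1 --out curated.csv
tcrbind split --in curated.csv --mode strict_split --folds 10 --out folds.csv
tcrbind knn --train train.csv --test test.csv --k 13 --out scores.csv
tcrbind train --data bench/records.csv --split tcr_split --folds 10 --out cv.json
tcrbind pep2smi GILGFVFTL
```

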