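# ncrna-funclass

Predict the functional class of a non-coding RNA (tRNA, miRNA, 5S rRNA,
snoRNA subclasses, ribozymes, …) from its primary sequence alone — no
secondary-structure prediction, no external database searches.

Structure-based classifiers are accurate but pay a steep computational
price for secondary-structure inference; plain sequence CNNs are fast but
see only short local windows. This package implements a hybrid: a small
convolutional network over one-hot sequence matrices, augmented — by
concatenation just before the softmax output layer — with three
whole-sequence "global information" vectors:

* **KM** — the normalized overlapping k-mer spectrum
  (4^k components, default k = 6 → 4096 features; the chance a given k-mer
  occurs in a random length-n sequence is `1 − (1 − 4⁻ᵏ)ⁿ⁻ᵏ⁺¹`);
* **SP** — sequence-pattern class propensities: for each length-L pattern
  `p` (default L = 11) seen in the training set,
  `P(class = c | p ∈ s) = N(c,p)/N(p)`; a query is encoded as the
  occurrence-weighted mean of the rows of the patterns it contains;
* **IB** — instance-based propensities: the query's top global-alignment
  hits (Needleman–Wunsch, match 1 / mismatch 0 / gap −1) among the
  training instances vote, score-weighted, for their classes.

Training uses Adam (learning rate 0.5 × 10⁻³, batch 32) on categorical
cross-entropy, with an internal stratified 80/20 train/validation split and
best-validation-epoch weight selection. Alongside accuracy and macro-F1,
the package reports **step75** — the optimizer step at which smoothed
training accuracy first reaches 75% — to quantify how much the global
channels accelerate training.

The whole network (conv/pool/dense layers, backprop, Adam) is implemented
in NumPy; there is no deep-learning framework dependency.

## Worked example

Everything runs on synthetic data generated by the package itself
(13 ncRNA-like classes with realistic length distributions, class-specific
base compositions and planted sequence motifs):

```bash
ncrna-funclass simulate --out-dir data/train --n-per-class 100 --seed 1
ncrna-funclass simulate --out-dir data/test  --n-per-class 50  --seed 2
ncrna-funclass train --fasta data/train/sequences.fasta \
    --labels data/train/labels.tsv --out-dir run1 \
    --global-channels KM,SP,IB --max-epochs 20 --max-len 600 \
    --conv-filters 64 --seed 0
ncrna-funclass evaluate --model run1/model.pkl \
    --fasta data/test/sequences.fasta --labels data/test/labels.tsv \
    --out-dir run1/eval
```

which prints

```
wrote 1300 sequences (13 classes) to data/train/sequences.fasta
wrote 650 sequences (13 classes) to data/test/sequences.fasta
model -> run1/model.pkl
accuracy 0.8092, macro-F1 0.8091
```

i.e. the full KM + SP + IB configuration classifies 80.9% of the 650
held-out synthetic sequences correctly after 20 epochs. The same run as a
local-only baseline (`--global-channels none`) reaches 60.9% — the gap is
the contribution of the global information. `run1/eval/confusion.tsv`
holds the 13×13 confusion matrix and `run1/report.json` the per-class
precision/recall/F1.

The same pipeline is available as a scikit-learn-style estimator:

```python
from ncrna_funclass import HybridConvNetClassifier, generate_dataset, default_13class_specs

ds = generate_dataset(default_13class_specs(), n_per_class=100, seed=1)
clf = HybridConvNetClassifier(global_channels=("KM", "SP", "IB"),
                              max_epochs=20, random_state=0)
clf.fit(ds.sequences(), ds.labels())
probs = clf.predict_proba(["ACGUACGU..."])   # rows sum to 1
print(clf.step75())                           # training-speed metric
```

`ncrna-funclass ablation` runs the full 8-configuration grid (every subset
of {KM, SP, IB}) over repeated seeds and writes a TSV with one row per
configuration: step75, macro-F1 (%), accuracy (%).

See `docs/methods.md` for the model, its assumptions and all parameter
defaults.

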