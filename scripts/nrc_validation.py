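#!/usr/bin/env python
"""Extended validation on the public nRC benchmark (13 ncRNA classes,
6320 training / 2600 test sequences).

This script is NOT part of the automated test suite: it requires the nRC
dataset files, which are distributed separately and must be downloaded by
the user.  Point it at the training and test FASTA/label files and it trains
the full KM + SP + IB configuration with default hyperparameters, then
reports test accuracy and macro-F1 for comparison with published results on
the same split.

Usage:
  python scripts/nrc_validation.py \
      --train-fasta nrc_train.fasta --train-labels nrc_train.tsv \
      --test-fasta nrc_test.fasta --test-labels nrc_test.tsv \
      --out-dir results/nrc
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from ncrna_funclass.evaluation import evaluate_classifier
from ncrna_funclass.io import read_fasta, read_labels
from ncrna_funclass.network import HybridConvNetClassifier


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--train-fasta", required=True)
    parser.add_argument("--train-labels", required=True)
    parser.add_argument("--test-fasta", required=True)
    parser.add_argument("--test-labels", required=True)
    parser.add_argument("--out-dir", type=Path, default=Path("results/nrc"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--max-epochs", type=int, default=100)
    args = parser.parse_args()

    train_ds = read_labels(args.train_labels, read_fasta(args.train_fasta))
    test_ds = read_labels(args.test_labels, read_fasta(args.test_fasta))
    print(f"train: {len(train_ds)} sequences, {len(train_ds.classes)} classes")
    print(f"test:  {len(test_ds)} sequences")

    clf = HybridConvNetClassifier(
        global_channels=("KM", "SP", "IB"),
        max_epochs=args.max_epochs,
        random_state=args.seed,
    )
    clf.fit(train_ds.sequences(), np.array(train_ds.labels(), dtype=object))

    report = evaluate_classifier(clf, test_ds.sequences(), test_ds.labels())
    args.out_dir.mkdir(parents=True, exist_ok=True)
    report.to_json(args.out_dir / "report.json")
    report.confusion_to_tsv(args.out_dir / "confusion.tsv")
    clf.save(args.out_dir / "model.pkl")
    print(f"accuracy {report.accuracy * 100:.2f}%  macro-F1 {report.macro_f1 * 100:.2f}%")
    print(f"step75 {report.step75}  best epoch {clf.best_epoch_}")


if __name__ == "__main__":
    main()
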