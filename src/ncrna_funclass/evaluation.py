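"""Evaluation metrics and the global-information ablation study.

Accuracy is overall multi-class accuracy (confusion-matrix trace over
total); precision, recall and F1 are computed one-vs-rest per class and F1
is aggregated unweighted (macro), the usual convention for imbalanced
multi-class ncRNA benchmarks.  ``run_ablation`` reproduces the
configuration-grid experiment: the 8 subsets of the {KM, SP, IB} global
channels, each scored by test accuracy, macro-F1 and step75 (the optimizer
step at which smoothed training accuracy first reaches 75%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .io import LabeledDataset, stratified_split_indices
from .network import (
    GLOBAL_CHANNELS,
    HybridConvNetClassifier,
    assemble_inputs,
    build_model,
    compute_step75,
    predict,
    train,
)

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "metrics_from_confusion",
    "evaluate_classifier",
    "ablation_grid",
    "config_label",
    "run_ablation",
]


@dataclass
class EvalReport:
    """Test-set summary: accuracy, macro-F1, per-class metrics, confusion."""

    accuracy: float
    macro_f1: float
    per_class: dict[str, dict[str, float]]
    confusion: np.ndarray
    classes: list[str]
    step75: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "step75": self.step75,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def confusion_to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.confusion, index=self.classes, columns=self.classes).to_csv(
            path, sep="\t", index_label="true\\pred"
        )


def confusion_matrix(
    true_labels: Sequence[str], predicted_labels: Sequence[str], classes: Sequence[str]
) -> np.ndarray:
    """Counts of class-i sequences predicted as class j (rows = true class)."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    known = set(classes)
    unknown = {lab for lab in (*true_labels, *predicted_labels) if lab not in known}
    if unknown:
        raise ValueError(f"labels outside the class vocabulary: {sorted(unknown)[:5]}")
    return _sk_confusion(true_labels, predicted_labels, labels=list(classes)).astype(np.int64)


def metrics_from_confusion(
    confusion: np.ndarray, classes: Sequence[str] | None = None
) -> EvalReport:
    """Per-class precision/recall/F1 (one-vs-rest) and overall accuracy.

    A class with zero predicted positives gets precision 0 (and hence F1 0
    unless its recall is also undefined).
    """
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total == 0:
        raise ValueError("confusion matrix is all-zero")
    n = confusion.shape[0]
    names = list(classes) if classes is not None else [str(i) for i in range(n)]
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    per_class = {
        name: {"precision": float(p), "recall": float(r), "f1": float(f)}
        for name, p, r, f in zip(names, precision, recall, f1)
    }
    return EvalReport(
        accuracy=float(tp.sum() / total),
        macro_f1=float(f1.mean()),
        per_class=per_class,
        confusion=confusion.astype(np.int64),
        classes=names,
    )


def evaluate_classifier(
    clf: HybridConvNetClassifier, sequences: Sequence[str], labels: Sequence[str]
) -> EvalReport:
    """Score a fitted classifier on a labeled test set."""
    predicted = clf.predict(sequences)
    cm = confusion_matrix(list(labels), list(predicted), [str(c) for c in clf.classes_])
    report = metrics_from_confusion(cm, [str(c) for c in clf.classes_])
    report.step75 = clf.step75()
    return report


def ablation_grid() -> list[tuple[str, ...]]:
    """All 8 subsets of the global channels, local-only first."""
    grid: list[tuple[str, ...]] = []
    for r in range(len(GLOBAL_CHANNELS) + 1):
        grid.extend(combinations(GLOBAL_CHANNELS, r))
    return grid


def config_label(channels: Sequence[str]) -> str:
    return " + ".join(channels) if channels else "Local-only"


def run_ablation(
    train_ds: LabeledDataset,
    test_ds: LabeledDataset,
    base: HybridConvNetClassifier | None = None,
    channel_grid: Sequence[tuple[str, ...]] | None = None,
    seeds: Sequence[int] = (0, 1, 2),
) -> pd.DataFrame:
    """Channel-ablation study over repeated seeded runs.

    For every seed the train set is split 80/20 (stratified), the global
    encoders are fitted once on the 80% part, and every configuration in the
    grid is trained on identical inputs (shared encodings, shared network
    init seed) and scored on the held-out test set.  Rows report, per
    configuration, the mean over seeds of test accuracy (%), macro-F1 (%)
    and step75; runs that never reach the 75% threshold enter the step75
    mean as (total steps + 1).

    ``base`` carries every hyperparameter (its ``global_channels`` is
    ignored, the grid decides that).
    """
    base = base or HybridConvNetClassifier()
    grid = list(channel_grid) if channel_grid is not None else ablation_grid()
    needed = sorted({c for cfg in grid for c in cfg}, key=GLOBAL_CHANNELS.index)
    classes = list(train_ds.classes)
    class_idx = {c: i for i, c in enumerate(classes)}
    test_seqs = test_ds.sequences()
    test_y = np.array([class_idx[lab] for lab in test_ds.labels()])

    rows: dict[tuple[str, ...], list[dict[str, float]]] = {tuple(c): [] for c in grid}
    for seed in seeds:
        root = np.random.default_rng(seed)
        split_seed, net_seed = (int(s) for s in root.integers(2**31, size=2))
        tr_idx, val_idx = stratified_split_indices(
            train_ds.labels(), 1.0 - base.validation_fraction, split_seed
        )
        tr, val = train_ds.subset(tr_idx), train_ds.subset(val_idx)
        proto = HybridConvNetClassifier(**base.get_params()).set_params(
            global_channels=tuple(needed)
        )
        proto.classes_ = np.array(classes, dtype=object)
        proto._fit_encoders(tr.sequences(), np.array(tr.labels(), dtype=object))

        onehot = proto.onehot_encoder_
        enc_sets = {
            "train": (tr.sequences(), True),
            "val": (val.sequences(), False),
            "test": (test_seqs, False),
        }
        g_all = {name: proto._encode(s, loo_ib=loo) for name, (s, loo) in enc_sets.items()}
        x_all = {name: onehot.transform(s) for name, (s, _) in enc_sets.items()}
        y_tr = np.array([class_idx[lab] for lab in tr.labels()])
        y_val = np.array([class_idx[lab] for lab in val.labels()])

        for cfg_channels in grid:
            cfg = base._model_config(net_seed)
            cfg.global_channels = tuple(
                c for c in GLOBAL_CHANNELS if c in cfg_channels
            )
            xl_tr, xg_tr = assemble_inputs(x_all["train"], g_all["train"], cfg)
            xl_val, xg_val = assemble_inputs(x_all["val"], g_all["val"], cfg)
            xl_te, xg_te = assemble_inputs(x_all["test"], g_all["test"], cfg)
            global_dims = {c: g_all["train"][c].shape[1] for c in cfg.global_channels}
            net = build_model(cfg, base.max_len, len(classes), global_dims)
            trace = train(net, (xl_tr, xg_tr, y_tr), (xl_val, xg_val, y_val), cfg)
            probs = predict(net, xl_te, xg_te)
            cm = _sk_confusion(test_y, probs.argmax(axis=1), labels=range(len(classes)))
            report = metrics_from_confusion(cm, classes)
            s75 = compute_step75(trace)
            rows[tuple(cfg_channels)].append(
                {
                    "accuracy": report.accuracy * 100.0,
                    "f1": report.macro_f1 * 100.0,
                    "step75": float(s75) if s75 is not None else len(trace.step_accuracy) + 1.0,
                }
            )

    out = []
    for cfg_channels in grid:
        runs = rows[tuple(cfg_channels)]
        out.append(
            {
                "configuration": config_label(cfg_channels),
                "step75": float(np.mean([r["step75"] for r in runs])),
                "f1": float(np.mean([r["f1"] for r in runs])),
                "accuracy": float(np.mean([r["accuracy"] for r in runs])),
            }
        )
    return pd.DataFrame(out, columns=["configuration", "step75", "f1", "accuracy"])
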