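"""The hybrid local/global convolutional classifier.

The architecture has three parts: a convolutional branch reading the one-hot
sequence matrix (a strided convolution spanning all four base channels,
cascaded into further 1-D convolutions, each followed by average pooling and
ReLU); a dense branch reading the concatenated global-information vectors
(KM / SP / IB); and an output head that concatenates both branch outputs
immediately before a softmax dense layer — one neuron per functional class.
Training minimizes categorical cross-entropy with Adam.

``HybridConvNetClassifier`` packages the whole procedure — stratified
train/validation split, leakage-free global-feature construction on the
training part only, best-validation-epoch weight selection — behind the
scikit-learn estimator API, taking raw sequence strings as ``X``.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .encoding import OneHotSequenceEncoder
from .features import (
    InstancePropensityEncoder,
    KmerFrequencyEncoder,
    PatternPropensityEncoder,
)
from .io import stratified_split_indices

__all__ = [
    "GLOBAL_CHANNELS",
    "ModelConfig",
    "TrainingTrace",
    "HybridNet",
    "build_model",
    "train",
    "predict",
    "compute_step75",
    "exponential_smoothing",
    "HybridConvNetClassifier",
]

GLOBAL_CHANNELS = ("KM", "SP", "IB")


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults follow the reference configuration: 128 convolution filters,
    kernel 5 along the sequence, stride 2, average pooling, Adam at learning
    rate 0.5e-3 with batches of 32, global information concatenated just
    before the output layer.
    """

    conv2d_filters: int = 128
    conv1d_filters: int = 128
    kernel_size: int = 5
    stride: int = 2
    n_conv1d_layers: int = 2
    pool_size: int = 2
    mlp_sizes: tuple[int, ...] = (64, 32)
    dropout_rate: float = 0.3
    global_channels: tuple[str, ...] = ()
    injection: str = "output"
    learning_rate: float = 0.5e-3
    batch_size: int = 32
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.stride < 1:
            raise ValueError("kernel_size and stride must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        unknown = set(self.global_channels) - set(GLOBAL_CHANNELS)
        if unknown:
            raise ValueError(f"unknown global channels: {sorted(unknown)}")
        if self.injection not in ("input", "output"):
            raise ValueError("injection must be 'input' or 'output'")
        if self.injection == "input" and not self.global_channels:
            raise ValueError("injection='input' requires at least one global channel")
        self.global_channels = tuple(
            c for c in GLOBAL_CHANNELS if c in self.global_channels
        )


@dataclass
class TrainingTrace:
    """Per-step training-batch accuracy and per-epoch validation accuracy."""

    step_accuracy: np.ndarray
    step_loss: np.ndarray
    epoch_val_accuracy: np.ndarray
    best_epoch: int  # 1-based epoch whose weights were kept
    steps_per_epoch: int

    def to_csv(self, path: str | Path, smoothing: float = 0.1) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "step": np.arange(1, len(self.step_accuracy) + 1),
                "batch_accuracy": self.step_accuracy,
                "smoothed_accuracy": exponential_smoothing(self.step_accuracy, smoothing),
                "loss": self.step_loss,
            }
        ).to_csv(path, index=False)


def exponential_smoothing(values: np.ndarray, factor: float) -> np.ndarray:
    """EMA with s_1 = a_1 and s_t = factor*a_t + (1-factor)*s_{t-1}."""
    values = np.asarray(values, dtype=np.float64)
    out = np.empty_like(values)
    if len(values) == 0:
        return out
    out[0] = values[0]
    for i in range(1, len(values)):
        out[i] = factor * values[i] + (1.0 - factor) * out[i - 1]
    return out


def compute_step75(
    trace: TrainingTrace, threshold: float = 0.75, smoothing: float = 0.1
) -> int | None:
    """First (1-based) optimizer step whose smoothed batch accuracy >= threshold.

    Returns None when the threshold is never attained within the trace — the
    training-speed analogue of "not reached".  Smoothing stabilizes the
    crossing point, which raw batch-of-32 accuracies (granularity 1/32) would
    otherwise make noisy.
    """
    if len(trace.step_accuracy) == 0:
        raise ValueError("trace is empty")
    smoothed = exponential_smoothing(trace.step_accuracy, smoothing)
    hits = np.nonzero(smoothed >= threshold)[0]
    return int(hits[0]) + 1 if len(hits) else None


class HybridNet:
    """Assembled network: conv branch + optional dense global branch + head."""

    def __init__(
        self,
        config: ModelConfig,
        max_len: int,
        n_classes: int,
        global_dims: dict[str, int],
        rng_init: np.random.Generator,
        rng_dropout: np.random.Generator,
    ):
        missing = set(config.global_channels) - set(global_dims)
        if missing:
            raise ValueError(f"global_dims missing configured channels: {sorted(missing)}")
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.config = config
        self.n_classes = n_classes
        self.channels = tuple(config.global_channels)
        in_ch = 4 + (len(self.channels) if config.injection == "input" else 0)

        layers: list[_nn.Layer] = []
        length = max_len
        filters_in = in_ch
        widths = [config.conv2d_filters] + [config.conv1d_filters] * config.n_conv1d_layers
        for f_out in widths:
            conv = _nn.Conv1D(filters_in, f_out, config.kernel_size, config.stride, rng_init)
            length = conv.out_length(length)
            layers += [conv, _nn.AvgPool1D(config.pool_size), _nn.ReLU()]
            length //= config.pool_size
            if length < 1:
                raise ValueError(f"max_len={max_len} too short for this conv stack")
            filters_in = f_out
        layers.append(_nn.Flatten())
        self.local_layers = layers
        self.local_dim = length * filters_in

        self.global_layers: list[_nn.Layer] | None = None
        self.global_dim = 0
        if config.injection == "output" and self.channels:
            d = sum(global_dims[c] for c in self.channels)
            glayers: list[_nn.Layer] = []
            for m in config.mlp_sizes:
                glayers += [
                    _nn.Dense(d, m, rng_init),
                    _nn.ReLU(),
                    _nn.Dropout(config.dropout_rate, rng_dropout),
                ]
                d = m
            self.global_layers = glayers
            self.global_dim = d
        self.head = _nn.Dense(self.local_dim + self.global_dim, n_classes, rng_init)

    def _all_layers(self) -> list[_nn.Layer]:
        layers = list(self.local_layers)
        if self.global_layers is not None:
            layers += self.global_layers
        layers.append(self.head)
        return layers

    def params(self) -> list[np.ndarray]:
        return [p for layer in self._all_layers() for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._all_layers() for g in layer.grads()]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    def forward(
        self, x_local: np.ndarray, x_global: np.ndarray | None, training: bool
    ) -> np.ndarray:
        h = x_local
        for layer in self.local_layers:
            h = layer.forward(h, training)
        if self.global_layers is not None:
            if x_global is None:
                raise ValueError("model expects a global-feature input")
            g = x_global.astype(np.float32, copy=False)
            for layer in self.global_layers:
                g = layer.forward(g, training)
            h = np.concatenate([h, g], axis=1)
        return self.head.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.head.backward(dlogits)
        dh, dg = dz[:, : self.local_dim], dz[:, self.local_dim :]
        if self.global_layers is not None:
            g = dg
            for layer in reversed(self.global_layers):
                g = layer.backward(g)
        h = dh
        for layer in reversed(self.local_layers):
            h = layer.backward(h)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w


def build_model(
    config: ModelConfig, max_len: int, n_classes: int, global_dims: dict[str, int]
) -> HybridNet:
    """Instantiate the network with seed-deterministic initialization."""
    ss = np.random.SeedSequence(config.seed)
    init_ss, drop_ss, shuffle_ss = ss.spawn(3)
    net = HybridNet(
        config,
        max_len,
        n_classes,
        global_dims,
        np.random.default_rng(init_ss),
        np.random.default_rng(drop_ss),
    )
    net._shuffle_rng = np.random.default_rng(shuffle_ss)
    return net


def _assemble_input_injection(
    onehot: np.ndarray, globals_by_channel: dict[str, np.ndarray], channels: Sequence[str]
) -> np.ndarray:
    """Stack each global vector, resampled to max_len, as an extra channel."""
    n, max_len, _ = onehot.shape
    extra = []
    grid = np.linspace(0.0, 1.0, max_len)
    for c in channels:
        g = globals_by_channel[c]
        src = np.linspace(0.0, 1.0, g.shape[1])
        resampled = np.stack([np.interp(grid, src, row) for row in g]).astype(np.float32)
        extra.append(resampled[:, :, None])
    return np.concatenate([onehot] + extra, axis=2)


def assemble_inputs(
    onehot: np.ndarray,
    globals_by_channel: dict[str, np.ndarray],
    config: ModelConfig,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Produce (x_local, x_global) as the configured injection mode expects."""
    channels = config.global_channels
    if not channels:
        return onehot, None
    if config.injection == "input":
        return _assemble_input_injection(onehot, globals_by_channel, channels), None
    x_global = np.concatenate(
        [globals_by_channel[c] for c in channels], axis=1
    ).astype(np.float32)
    return onehot, x_global


def _batched_probs(net: HybridNet, x_local, x_global, batch: int = 256) -> np.ndarray:
    out = []
    for i in range(0, len(x_local), batch):
        xg = None if x_global is None else x_global[i : i + batch]
        logits = net.forward(x_local[i : i + batch], xg, training=False)
        out.append(_nn.softmax(logits))
    return np.concatenate(out, axis=0)


def train(
    model: HybridNet,
    train_data: tuple[np.ndarray, np.ndarray | None, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray | None, np.ndarray] | None,
    config: ModelConfig,
) -> TrainingTrace:
    """Mini-batch Adam training with best-validation-epoch weight selection.

    ``train_data``/``val_data`` are (x_local, x_global_or_None, y_index)
    triples.  Per-step batch accuracy is recorded before each update; the
    weight snapshot of the epoch with the highest validation accuracy (ties
    broken by earliest epoch) is restored at the end.
    """
    x_local, x_global, y = train_data
    n = len(y)
    present = np.unique(y)
    if len(present) < model.n_classes:
        raise ValueError(
            f"only {len(present)} of {model.n_classes} classes present in training data"
        )
    eye = np.eye(model.n_classes, dtype=np.float32)
    optimizer = _nn.Adam(model.params(), lr=config.learning_rate)
    shuffle_rng: np.random.Generator = getattr(model, "_shuffle_rng", None) or (
        np.random.default_rng(config.seed)
    )

    step_acc: list[float] = []
    step_loss: list[float] = []
    val_acc_per_epoch: list[float] = []
    best_val, best_epoch, best_weights = -np.inf, 1, model.get_weights()
    steps_per_epoch = ceil(n / config.batch_size)

    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(n)
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            xg = None if x_global is None else x_global[idx]
            logits = model.forward(x_local[idx], xg, training=True)
            loss, probs, dlogits = _nn.softmax_cce(logits, eye[y[idx]])
            step_acc.append(float(np.mean(probs.argmax(axis=1) == y[idx])))
            step_loss.append(loss)
            model.backward(dlogits)
            optimizer.step(model.grads())
        if val_data is not None:
            vx, vg, vy = val_data
            vprobs = _batched_probs(model, vx, vg)
            v_acc = float(np.mean(vprobs.argmax(axis=1) == vy))
        else:
            v_acc = float(np.mean(step_acc[-steps_per_epoch:]))
        val_acc_per_epoch.append(v_acc)
        if v_acc > best_val:
            best_val, best_epoch, best_weights = v_acc, epoch, model.get_weights()

    model.set_weights(best_weights)
    return TrainingTrace(
        step_accuracy=np.array(step_acc),
        step_loss=np.array(step_loss),
        epoch_val_accuracy=np.array(val_acc_per_epoch),
        best_epoch=best_epoch,
        steps_per_epoch=steps_per_epoch,
    )


def predict(
    model: HybridNet, x_local: np.ndarray, x_global: np.ndarray | None = None
) -> np.ndarray:
    """Per-sequence class-probability vectors (softmax outputs, rows sum to 1)."""
    return _batched_probs(model, x_local, x_global)


class HybridConvNetClassifier(ClassifierMixin, BaseEstimator):
    """ncRNA functional-class classifier from raw sequences.

    ``X`` is a sequence of residue strings (DNA or RNA spelling), ``y`` the
    class labels.  ``fit`` performs a stratified train/validation split,
    builds the configured global-information encoders on the training part
    only (the IB channel additionally excludes each sequence's self-hit),
    trains the hybrid network and keeps the weights of the epoch with the
    best validation accuracy.

    Parameters mirror :class:`ModelConfig` plus the global-feature settings
    (``k`` for the KM spectrum, ``L``/``min_support`` for the SP pattern
    table, alignment and pre-filter settings for the IB channel).

    Attributes
    ----------
    classes_ : ndarray of class labels
    net_ : the trained :class:`HybridNet`
    training_trace_ : :class:`TrainingTrace`
    best_epoch_ : int
    """

    def __init__(
        self,
        max_len: int = 800,
        conv2d_filters: int = 128,
        conv1d_filters: int = 128,
        kernel_size: int = 5,
        stride: int = 2,
        n_conv1d_layers: int = 2,
        pool_size: int = 2,
        mlp_sizes: tuple[int, ...] = (64, 32),
        dropout_rate: float = 0.3,
        global_channels: tuple[str, ...] = ("KM", "SP", "IB"),
        injection: str = "output",
        k: int = 6,
        L: int = 11,
        min_support: int = 2,
        top_n: int = 5,
        seed_k: int = 11,
        candidate_pool: int = 50,
        use_prefilter: bool = True,
        match_score: float = 1.0,
        mismatch_score: float = 0.0,
        gap_penalty: float = -1.0,
        learning_rate: float = 0.5e-3,
        batch_size: int = 32,
        max_epochs: int = 100,
        validation_fraction: float = 0.2,
        random_state: int | None = None,
    ):
        self.max_len = max_len
        self.conv2d_filters = conv2d_filters
        self.conv1d_filters = conv1d_filters
        self.kernel_size = kernel_size
        self.stride = stride
        self.n_conv1d_layers = n_conv1d_layers
        self.pool_size = pool_size
        self.mlp_sizes = mlp_sizes
        self.dropout_rate = dropout_rate
        self.global_channels = global_channels
        self.injection = injection
        self.k = k
        self.L = L
        self.min_support = min_support
        self.top_n = top_n
        self.seed_k = seed_k
        self.candidate_pool = candidate_pool
        self.use_prefilter = use_prefilter
        self.match_score = match_score
        self.mismatch_score = mismatch_score
        self.gap_penalty = gap_penalty
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _model_config(self, seed: int) -> ModelConfig:
        return ModelConfig(
            conv2d_filters=self.conv2d_filters,
            conv1d_filters=self.conv1d_filters,
            kernel_size=self.kernel_size,
            stride=self.stride,
            n_conv1d_layers=self.n_conv1d_layers,
            pool_size=self.pool_size,
            mlp_sizes=tuple(self.mlp_sizes),
            dropout_rate=self.dropout_rate,
            global_channels=tuple(self.global_channels),
            injection=self.injection,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            seed=seed,
        )

    def _fit_encoders(self, seqs: list[str], labels: np.ndarray) -> None:
        self.onehot_encoder_ = OneHotSequenceEncoder(max_len=self.max_len).fit(seqs)
        self.channel_encoders_ = {}
        for c in self._model_config(0).global_channels:
            if c == "KM":
                enc = KmerFrequencyEncoder(k=self.k).fit(seqs)
            elif c == "SP":
                enc = PatternPropensityEncoder(L=self.L, min_support=self.min_support).fit(
                    seqs, labels
                )
            else:
                enc = InstancePropensityEncoder(
                    top_n=self.top_n,
                    seed_k=self.seed_k,
                    candidate_pool=self.candidate_pool,
                    use_prefilter=self.use_prefilter,
                    match_score=self.match_score,
                    mismatch_score=self.mismatch_score,
                    gap_penalty=self.gap_penalty,
                ).fit(seqs, labels)
            self.channel_encoders_[c] = enc

    def _encode(self, seqs: Sequence[str], loo_ib: bool = False) -> dict[str, np.ndarray]:
        out = {}
        for c, enc in self.channel_encoders_.items():
            if c == "IB" and loo_ib:
                out[c] = enc.transform_loo()
            else:
                out[c] = enc.transform(seqs)
        return out

    def fit(self, X: Sequence[str], y: Sequence[str]) -> "HybridConvNetClassifier":
        seqs = [str(s) for s in X]
        y_arr = np.asarray(y, dtype=object)
        if len(seqs) != len(y_arr):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y_arr)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        class_idx = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_idx[lab] for lab in y_arr], dtype=np.int64)

        root = np.random.default_rng(
            self.random_state if self.random_state is not None else 0
        )
        split_seed, net_seed = (int(s) for s in root.integers(2**31, size=2))

        tr, val = stratified_split_indices(
            list(y_arr), 1.0 - self.validation_fraction, split_seed
        )
        tr_seqs = [seqs[i] for i in tr]
        if len(np.unique(y_idx[tr])) < len(self.classes_):
            raise ValueError("a class is absent from the training split")

        self._fit_encoders(tr_seqs, y_arr[tr])
        config = self._model_config(net_seed)

        g_train = self._encode(tr_seqs, loo_ib=True)
        x_tr = self.onehot_encoder_.transform(tr_seqs)
        xl_tr, xg_tr = assemble_inputs(x_tr, g_train, config)

        val_seqs = [seqs[i] for i in val]
        g_val = self._encode(val_seqs)
        x_val = self.onehot_encoder_.transform(val_seqs)
        xl_val, xg_val = assemble_inputs(x_val, g_val, config)

        global_dims = {c: g.shape[1] for c, g in g_train.items()}
        self.net_ = build_model(config, self.max_len, len(self.classes_), global_dims)
        self.training_trace_ = train(
            self.net_, (xl_tr, xg_tr, y_idx[tr]), (xl_val, xg_val, y_idx[val]), config
        )
        self.best_epoch_ = self.training_trace_.best_epoch
        self.config_ = config
        return self

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        check_is_fitted(self, "net_")
        seqs = [str(s) for s in X]
        if not seqs:
            return np.empty((0, len(self.classes_)))
        g = self._encode(seqs)
        xl, xg = assemble_inputs(self.onehot_encoder_.transform(seqs), g, self.config_)
        return predict(self.net_, xl, xg)

    def predict(self, X: Sequence[str]) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def step75(self, threshold: float = 0.75, smoothing: float = 0.1) -> int | None:
        check_is_fitted(self, "training_trace_")
        return compute_step75(self.training_trace_, threshold, smoothing)

    def save(self, path: str | Path) -> None:
        """Serialize the fitted classifier (weights, encoders, config)."""
        check_is_fitted(self, "net_")
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "HybridConvNetClassifier":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, HybridConvNetClassifier):
            raise TypeError(f"{path} does not contain a HybridConvNetClassifier")
        return obj
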