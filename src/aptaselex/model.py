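"""Two-branch convolutional binding-prediction model.

The model ingests an (aptamer, target) pair as two tensors — a padded
one-hot sequence matrix (default 100 x 4) and a 166-bit MACCS fingerprint —
and outputs a single binding probability.  Each input is processed by its own
stack of three same-padded 1-D convolution layers (32, 64 and 96 filters by
default), each followed by ReLU and max-pooling; the per-filter features of
the two branches are aggregated (global max over positions by default — the
position-invariant convention of sequence-motif CNNs; plain flattening is
available via ``aggregate="flatten"``), concatenated, and passed through
three fully connected layers (1050, 1050, 512 by default, dropout 0.1 after
each of the first two) into a single sigmoid output unit.

Training minimises binary cross-entropy with Adam; the label is the reported
binder / non-binder state and a probability >= the decision threshold
(default 0.5, ties to positive) is called a binder.  The layer stack is
implemented directly on NumPy (see :mod:`aptaselex._nn`) and every source of
randomness — weight init, batch shuffling, dropout masks — derives from the
config seed, so a run is exactly reproducible.

Hyperparameters without an externally fixed value (kernel sizes, pooling
window, optimiser, batch size) default to kernel 5, pool 2, Adam, batch 32
and are all exposed in :class:`ModelConfig` for the grid search.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from aptaselex import _nn
from aptaselex.encoding import DEFAULT_PAD_LENGTH, MACCS_BITS, EncodedPair, stack_pairs


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters of the binding model."""

    conv_filters: tuple[int, int, int] = (32, 64, 96)
    kernel_sizes: tuple[int, int, int] = (5, 5, 5)
    pool_size: int = 2
    fc_sizes: tuple[int, int, int] = (1050, 1050, 512)
    dropout_rate: float = 0.1
    learning_rate: float = 1e-3
    epochs: int = 25
    batch_size: int = 32
    decision_threshold: float = 0.5
    pad_length: int = DEFAULT_PAD_LENGTH
    aggregate: str = "global_max"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aggregate not in ("global_max", "flatten"):
            raise ValueError("aggregate must be 'global_max' or 'flatten'")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")
        for name in ("conv_filters", "kernel_sizes", "fc_sizes"):
            vals = getattr(self, name)
            if len(vals) != 3 or any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be three positive integers, got {vals}")
        if self.pool_size <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("pool_size, epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the derived classification ratios.

    ``pre`` (precision) is None — flagged undefined — when no positive calls
    were made (tp + fp == 0), rather than silently reported as 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float
    spe: float
    pre: Optional[float]


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> MetricsReport:
    """Accuracy, sensitivity, specificity and precision from confusion counts.

    acc = (TP+TN)/(TP+TN+FP+FN), sen = TP/(TP+FN), spe = TN/(TN+FP),
    pre = TP/(TP+FP).  A ratio with a zero denominator is reported as NaN
    (sen/spe) or None (pre), never as 0.
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError(f"confusion counts must be non-negative, got {counts}")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion counts sum to zero")
    acc = (tp + tn) / total
    sen = tp / (tp + fn) if tp + fn > 0 else float("nan")
    spe = tn / (tn + fp) if tn + fp > 0 else float("nan")
    pre = tp / (tp + fp) if tp + fp > 0 else None
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn, acc=acc, sen=sen, spe=spe, pre=pre)


def classify(prob: float, threshold: float = 0.5) -> int:
    """Binder call from a probability; ties at the threshold go positive."""
    return 1 if prob >= threshold else 0


class TwoBranchCNN:
    """The two-branch convolutional binding model (see module docstring)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f1, f2, f3 = config.conv_filters
        k1, k2, k3 = config.kernel_sizes
        p = config.pool_size

        def branch(c_in: int) -> list:
            return [
                _nn.Conv1D(c_in, f1, k1, rng), _nn.ReLU(), _nn.MaxPool1D(p),
                _nn.Conv1D(f1, f2, k2, rng), _nn.ReLU(), _nn.MaxPool1D(p),
                _nn.Conv1D(f2, f3, k3, rng), _nn.ReLU(), _nn.MaxPool1D(p),
            ]

        self.seq_branch = branch(4)
        self.fp_branch = branch(1)

        len_seq = config.pad_length
        len_fp = MACCS_BITS
        for _ in range(3):
            len_seq //= p
            len_fp //= p
        if len_seq <= 0 or len_fp <= 0:
            raise ValueError("pooling collapses the inputs to zero length")
        if config.aggregate == "global_max":
            self._n_concat = 2 * f3
        else:
            self._n_concat = len_seq * f3 + len_fp * f3

        d1, d2, d3 = config.fc_sizes
        self.fc1 = _nn.Dense(self._n_concat, d1, rng)
        self.drop1 = _nn.Dropout(config.dropout_rate)
        self.fc2 = _nn.Dense(d1, d2, rng)
        self.drop2 = _nn.Dropout(config.dropout_rate)
        self.fc3 = _nn.Dense(d2, d3, rng)
        self.relu1, self.relu2, self.relu3 = _nn.ReLU(), _nn.ReLU(), _nn.ReLU()
        # zero-init output layer: an untrained model answers exactly 0.5
        self.out = _nn.Dense(d3, 1, rng=None, zero_init=True)
        self._dropout_rng = np.random.default_rng(config.seed + 1)

    # -- forward/backward ---------------------------------------------------

    def _forward_branch(self, layers: list, x: np.ndarray) -> np.ndarray:
        for layer in layers:
            x = layer.forward(x)
        return x

    def _backward_branch(self, layers: list, d: np.ndarray) -> np.ndarray:
        for layer in reversed(layers):
            d = layer.backward(d)
        return d

    def forward_logits(
        self, xseq: np.ndarray, xfp: np.ndarray, training: bool = False
    ) -> np.ndarray:
        if xfp.ndim == 2:
            xfp = xfp[:, :, None]
        a = self._forward_branch(self.seq_branch, xseq)
        b = self._forward_branch(self.fp_branch, xfp)
        B = a.shape[0]
        self._a_shape, self._b_shape = a.shape, b.shape
        if self.config.aggregate == "global_max":
            # position-invariant aggregation: max over the length axis
            self._a_arg, self._b_arg = a.argmax(axis=1), b.argmax(axis=1)
            h = np.concatenate([a.max(axis=1), b.max(axis=1)], axis=1)
        else:
            h = np.concatenate([a.reshape(B, -1), b.reshape(B, -1)], axis=1)
        rng = self._dropout_rng
        h = self.drop1.forward(self.relu1.forward(self.fc1.forward(h)), training, rng)
        h = self.drop2.forward(self.relu2.forward(self.fc2.forward(h)), training, rng)
        h = self.relu3.forward(self.fc3.forward(h))
        return self.out.forward(h)

    def backward(self, dz: np.ndarray) -> None:
        d = self.out.backward(dz)
        d = self.fc3.backward(self.relu3.backward(d))
        d = self.fc2.backward(self.relu2.backward(self.drop2.backward(d)))
        d = self.fc1.backward(self.relu1.backward(self.drop1.backward(d)))
        if self.config.aggregate == "global_max":
            B, _, ca = self._a_shape
            cb = self._b_shape[2]
            da = np.zeros(self._a_shape)
            db = np.zeros(self._b_shape)
            bi, ci = np.ogrid[:B, :ca]
            da[bi, self._a_arg, ci] = d[:, :ca]
            bi, ci = np.ogrid[:B, :cb]
            db[bi, self._b_arg, ci] = d[:, ca:]
        else:
            na = int(np.prod(self._a_shape[1:]))
            da = d[:, :na].reshape(self._a_shape)
            db = d[:, na:].reshape(self._b_shape)
        self._backward_branch(self.seq_branch, da)
        self._backward_branch(self.fp_branch, db)

    # -- parameter plumbing -------------------------------------------------

    @property
    def _layers(self) -> list:
        return (
            self.seq_branch
            + self.fp_branch
            + [self.fc1, self.fc2, self.fc3, self.out]
        )

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers for _, p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self._layers for g in layer.grads]

    # -- inference ----------------------------------------------------------

    def predict_proba(
        self, xseq: np.ndarray, xfp: np.ndarray, batch_size: int = 256
    ) -> np.ndarray:
        out = []
        for i in range(0, xseq.shape[0], batch_size):
            z = self.forward_logits(xseq[i : i + batch_size], xfp[i : i + batch_size])
            out.append(_nn.sigmoid(z).ravel())
        return np.concatenate(out)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Weights as .npz plus a JSON sidecar with the config."""
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = dataclasses.asdict(self.config)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TwoBranchCNN":
        path = Path(path)
        cfg_dict = json.loads(path.with_suffix(".json").read_text())
        for key in ("conv_filters", "kernel_sizes", "fc_sizes"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = cls(ModelConfig(**cfg_dict))
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        return model


def build_model(config: ModelConfig | None = None) -> TwoBranchCNN:
    """Construct a (seeded, untrained) two-branch binding model."""
    return TwoBranchCNN(config or ModelConfig())


def train(
    model: TwoBranchCNN,
    train_set: Sequence[EncodedPair],
    config: ModelConfig | None = None,
) -> tuple[TwoBranchCNN, list[float]]:
    """Fit the model on labelled pairs; returns (model, per-epoch mean loss).

    Minimises binary cross-entropy with Adam over shuffled mini-batches.
    A single-class training set is accepted with a warning (threshold
    metrics on such data are degenerate).
    """
    config = config or model.config
    xseq, xfp, y = stack_pairs(train_set)
    if y is None:
        raise ValueError("training requires labelled pairs")
    if len(np.unique(y)) < 2:
        warnings.warn(
            "training set contains a single class; the fitted model will be "
            "degenerate under threshold metrics",
            stacklevel=2,
        )
    xfp = xfp[:, :, None]
    rng = np.random.default_rng(config.seed + 2)
    opt = _nn.Adam(model.parameters(), lr=config.learning_rate)
    n = xseq.shape[0]
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            z = model.forward_logits(xseq[idx], xfp[idx], training=True)
            loss, dz = _nn.bce_loss_and_grad(z, y[idx])
            model.backward(dz)
            opt.step(model.gradients())
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def predict_binding(model: TwoBranchCNN, pair: EncodedPair) -> float:
    """Binding probability for one encoded (aptamer, target) pair."""
    xseq, xfp, _ = stack_pairs([pair])
    return float(model.predict_proba(xseq, xfp)[0])


def evaluate(
    model: TwoBranchCNN,
    pairs: Sequence[EncodedPair],
    threshold: float | None = None,
) -> MetricsReport:
    """Confusion-count metrics of the model on labelled pairs."""
    threshold = model.config.decision_threshold if threshold is None else threshold
    xseq, xfp, y = stack_pairs(pairs)
    if y is None:
        raise ValueError("evaluation requires labelled pairs")
    probs = model.predict_proba(xseq, xfp)
    calls = (probs >= threshold).astype(int)
    y = y.astype(int)
    tp = int(((calls == 1) & (y == 1)).sum())
    tn = int(((calls == 0) & (y == 0)).sum())
    fp = int(((calls == 1) & (y == 0)).sum())
    fn = int(((calls == 0) & (y == 1)).sum())
    return compute_metrics(tp, tn, fp, fn)


def grid_search_cv(
    grid: dict[str, list],
    data: Sequence[EncodedPair],
    k: int = 5,
    seed: int = 0,
    base_config: ModelConfig | None = None,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Exhaustive grid search with stratified k-fold cross-validation.

    Every grid cell (a dict of ModelConfig field overrides) is evaluated on
    the same seeded folds; the returned config is the cell with the highest
    mean validation accuracy (first cell wins ties, iteration order is the
    sorted key product).  The full per-cell results table is also returned.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if k < 2:
        raise ValueError("k-fold cross-validation requires k >= 2")
    base = base_config or ModelConfig()
    _, _, y = stack_pairs(data)
    if y is None:
        raise ValueError("grid search requires labelled pairs")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))

    keys = sorted(grid)
    rows = []
    best_cfg, best_acc = None, -1.0
    for values in itertools.product(*(grid[key] for key in keys)):
        cell = dict(zip(keys, values))
        cfg = dataclasses.replace(base, **cell, seed=seed)
        accs = []
        for train_idx, val_idx in folds:
            m = build_model(cfg)
            m, _ = train(m, [data[i] for i in train_idx], cfg)
            rep = evaluate(m, [data[i] for i in val_idx])
            accs.append(rep.acc)
        mean_acc = float(np.mean(accs))
        rows.append({**{key: str(cell[key]) for key in keys},
                     "mean_val_acc": mean_acc,
                     "std_val_acc": float(np.std(accs))})
        if mean_acc > best_acc:
            best_acc, best_cfg = mean_acc, cfg
    assert best_cfg is not None
    return best_cfg, pd.DataFrame(rows)
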