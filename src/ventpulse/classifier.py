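"""Weak-effort classification from flow and airway-pressure waveforms.

A 1D convolutional network maps one segmented breath (two channels: flow
and Paw, resampled to a fixed grid) to the probability that the
inspiratory effort is weak. Architecture: five convolutional blocks of two
identical ReLU convolutions each followed by max pooling, with
filters/kernels (64,3), (64,9), (128,9), (256,9), (32,7); then two dense
ReLU layers of 128 units with dropout 0.5, and a single sigmoid output.
Training minimizes class-weighted binary cross-entropy (with label
smoothing) and early stopping on validation loss; the decision threshold
is chosen on the validation set from Youden's J (sensitivity +
specificity - 1), taking the smallest threshold within one standard error
of the maximum — the sensitivity-favoring choice appropriate for a
screening alarm.

Esophageal pressure is never an input: the prediction path consumes
preprocessed flow/Paw arrays only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .dataio import BreathSegment, Recording

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "ClassifierOutput",
    "WeakEffortCNN",
    "preprocess_breath",
    "build_model",
    "train",
    "predict",
]

_DEFAULT_BLOCKS = ((64, 3), (64, 9), (128, 9), (256, 9), (32, 7))


@dataclass(frozen=True)
class ModelSpec:
    """Network architecture description."""

    conv_blocks: Tuple[Tuple[int, int], ...] = _DEFAULT_BLOCKS
    convs_per_block: int = 2
    pool_size: int = 2
    dense_widths: Tuple[int, ...] = (128, 128)
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if len(self.conv_blocks) == 0:
            raise ValueError("at least one convolutional block required")


@dataclass
class TrainConfig:
    """Training-time configuration for the classifier."""

    segment_len: int = 300
    fs_model: float = 50.0
    flow_scale: float = 2.0  # L/s, fixed population normalization
    paw_scale: float = 20.0  # cmH2O above PEEP
    class_weight: str = "balanced"
    label_smoothing: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 4
    seed: int = 0
    decision_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.segment_len < 2 ** len(_DEFAULT_BLOCKS):
            raise ValueError("segment_len must allow five halvings (>= 32)")
        if self.decision_threshold is not None and not (
            0 < self.decision_threshold < 1
        ):
            raise ValueError("decision_threshold must be in (0, 1)")


@dataclass(frozen=True)
class ClassifierOutput:
    """Per-breath probability and thresholded prediction."""

    prob_weak: float
    pred_weak: bool
    key: Optional[tuple] = None


def preprocess_breath(
    rec: Recording, seg: BreathSegment, cfg: TrainConfig = TrainConfig()
) -> np.ndarray:
    """Fixed-length 2-channel input array for one breath.

    Flow and Paw over [onset, breath_end) are linearly resampled to
    ``fs_model`` and right-zero-padded (or truncated) to ``segment_len``.
    Channels are normalized by fixed population scales: flow / flow_scale,
    (Paw - PEEP) / paw_scale. Deterministic.
    """
    if not seg.valid:
        raise ValueError("invalid_segment")
    s, e = seg.onset_idx, seg.breath_end_idx
    t_src = np.arange(e - s) / rec.fs
    n_out = int(np.floor(t_src[-1] * cfg.fs_model)) + 1 if e - s > 1 else 1
    t_dst = np.arange(n_out) / cfg.fs_model
    flow = np.interp(t_dst, t_src, rec.flow[s:e]) / cfg.flow_scale
    paw = (np.interp(t_dst, t_src, rec.paw[s:e]) - rec.peep) / cfg.paw_scale
    out = np.zeros((2, cfg.segment_len), dtype=np.float32)
    m = min(n_out, cfg.segment_len)
    out[0, :m] = flow[:m]
    out[1, :m] = paw[:m]
    return out


def build_model(
    spec: ModelSpec,
    segment_len: int,
    rng: Optional[np.random.Generator] = None,
    in_channels: int = 2,
    dtype=np.float32,
) -> nn.Sequential:
    """Instantiate the network for a given input length.

    Raises a configuration error when ``segment_len`` cannot survive one
    max-pool halving per convolutional block.
    """
    if segment_len < spec.pool_size ** len(spec.conv_blocks):
        raise ValueError(
            f"segment_len {segment_len} too small for "
            f"{len(spec.conv_blocks)} poolings of size {spec.pool_size}"
        )
    rng = rng or np.random.default_rng(0)
    layers: List[nn.Layer] = []
    ch = in_channels
    length = segment_len
    for filters, kernel in spec.conv_blocks:
        for _ in range(spec.convs_per_block):
            layers.append(nn.Conv1d(ch, filters, kernel, rng, dtype=dtype))
            layers.append(nn.ReLU())
            ch = filters
        layers.append(nn.MaxPool1d(spec.pool_size))
        length //= spec.pool_size
    layers.append(nn.Flatten())
    dim = ch * length
    for width in spec.dense_widths:
        layers.append(nn.Dense(dim, width, rng, dtype=dtype))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(spec.dropout, rng))
        dim = width
    layers.append(nn.Dense(dim, 1, rng, dtype=dtype))
    return nn.Sequential(layers)


def _class_weights(y: np.ndarray) -> Tuple[float, float]:
    """Inverse-frequency weights (w_neg, w_pos), mean weight 1."""
    n = y.size
    n_pos = int(y.sum())
    n_neg = n - n_pos
    return n / (2.0 * n_neg), n / (2.0 * n_pos)


def _youden_threshold(probs: np.ndarray, y: np.ndarray, one_se: bool = True) -> float:
    """Youden's J (sensitivity + specificity - 1) maximized on a 0.01 grid.

    With ``one_se`` (default) the smallest threshold whose J lies within one
    binomial standard error of the maximum is returned: among statistically
    indistinguishable operating points the sensitivity-favoring one is the
    right choice for a screening alarm, and it is far more stable on small
    validation sets than the raw argmax.
    """
    grid = np.round(np.arange(0.01, 0.991, 0.01), 2)
    pos = y == 1
    n_pos = max(int(pos.sum()), 1)
    n_neg = max(int((~pos).sum()), 1)
    sens = np.array([(probs[pos] >= t).mean() if pos.any() else 0.0 for t in grid])
    spec = np.array([(probs[~pos] < t).mean() if (~pos).any() else 0.0 for t in grid])
    j = sens + spec - 1.0
    k = int(np.argmax(j))
    if not one_se:
        return float(grid[k])
    se = np.sqrt(
        sens[k] * (1 - sens[k]) / n_pos + spec[k] * (1 - spec[k]) / n_neg
    )
    ok = np.nonzero(j >= j[k] - se)[0]
    return float(grid[ok[0]])


class WeakEffortCNN(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style estimator wrapping the 1D-CNN.

    ``fit`` expects X of shape (n_breaths, 2, segment_len) as produced by
    :func:`preprocess_breath` and binary labels y (1 = weak). An optional
    validation set drives early stopping and Youden threshold selection.

    Fitted attributes: ``model_`` (the network), ``threshold_`` (decision
    threshold), ``history_`` (per-epoch losses), ``n_params_``.
    """

    def __init__(
        self,
        spec: ModelSpec = ModelSpec(),
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 30,
        patience: int = 4,
        class_weight: str = "balanced",
        label_smoothing: float = 0.1,
        decision_threshold: Optional[float] = None,
        seed: int = 0,
    ):
        self.spec = spec
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.class_weight = class_weight
        self.label_smoothing = label_smoothing
        self.decision_threshold = decision_threshold
        self.seed = seed

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y).astype(np.float64).ravel()
        if X.ndim != 3:
            raise ValueError("X must be (n_breaths, channels, segment_len)")
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise ValueError("training labels must contain both classes")
        self.classes_ = np.array([0, 1])
        rng = np.random.default_rng(self.seed)
        self.model_ = build_model(self.spec, X.shape[2], rng, in_channels=X.shape[1])
        self.n_params_ = self.model_.n_params

        if self.class_weight == "balanced":
            w_neg, w_pos = _class_weights(y)
        else:
            w_neg = w_pos = 1.0
        sample_w = np.where(y == 1, w_pos, w_neg)
        # label smoothing de-saturates the output probabilities, which keeps
        # the validation threshold search well conditioned
        eps = self.label_smoothing
        y_soft = y * (1 - eps) + eps / 2
        val_w = y_val_soft = None
        if X_val is not None:
            X_val = np.asarray(X_val, dtype=np.float32)
            y_val = np.asarray(y_val).astype(np.float64).ravel()
            val_w = np.where(y_val == 1, w_pos, w_neg)
            y_val_soft = y_val * (1 - eps) + eps / 2

        opt = nn.Adam(self.model_.params, lr=self.learning_rate)
        history: Dict[str, List[float]] = {"train_loss": [], "val_loss": []}
        best_loss, best_weights, bad_epochs = np.inf, None, 0
        n = X.shape[0]
        for _epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = self.model_.forward(X[idx], train=True)[:, 0]
                loss, dlogit = nn.weighted_bce_with_logits(
                    logits, y_soft[idx], sample_w[idx]
                )
                self.model_.backward(dlogit[:, None])
                opt.step(self.model_.grads)
                epoch_loss += loss * idx.size
            history["train_loss"].append(epoch_loss / n)

            if X_val is not None:
                logits = self._forward_eval(X_val)
                monitor, _ = nn.weighted_bce_with_logits(logits, y_val_soft, val_w)
                history["val_loss"].append(monitor)
            else:
                monitor = history["train_loss"][-1]
            if monitor < best_loss - 1e-6:
                best_loss = monitor
                best_weights = self.model_.get_weights()
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= self.patience:
                    break
        if best_weights is not None:
            self.model_.set_weights(best_weights)
        self.history_ = history

        if self.decision_threshold is not None:
            self.threshold_ = float(self.decision_threshold)
        elif X_val is not None:
            probs = nn.sigmoid(self._forward_eval(X_val))
            self.threshold_ = _youden_threshold(probs, y_val)
        else:
            self.threshold_ = 0.5
        return self

    def _forward_eval(self, X: np.ndarray, chunk: int = 512) -> np.ndarray:
        out = np.empty(X.shape[0], dtype=np.float64)
        for start in range(0, X.shape[0], chunk):
            out[start : start + chunk] = self.model_.forward(
                X[start : start + chunk], train=False
            )[:, 0]
        return out

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        p = nn.sigmoid(self._forward_eval(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return (p >= self.threshold_).astype(int)

    def architecture_audit(self) -> List[Dict]:
        """Layer-by-layer description of the built network."""
        return self.model_.describe()


def train(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
    spec: ModelSpec = ModelSpec(),
) -> Tuple[WeakEffortCNN, float, Dict[str, List[float]]]:
    """Train the classifier; returns (estimator, decision threshold, history)."""
    clf = WeakEffortCNN(
        spec=spec,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        class_weight=cfg.class_weight,
        label_smoothing=cfg.label_smoothing,
        decision_threshold=cfg.decision_threshold,
        seed=cfg.seed,
    )
    clf.fit(X_train, y_train, X_val, y_val)
    return clf, clf.threshold_, clf.history_


def predict(
    clf: WeakEffortCNN,
    X: np.ndarray,
    decision_threshold: Optional[float] = None,
    keys: Optional[Sequence[tuple]] = None,
) -> List[ClassifierOutput]:
    """Order-preserving per-breath outputs from flow/Paw arrays only."""
    thr = clf.threshold_ if decision_threshold is None else decision_threshold
    probs = clf.predict_proba(X)[:, 1]
    keys = keys if keys is not None else [None] * len(probs)
    return [
        ClassifierOutput(prob_weak=float(p), pred_weak=bool(p >= thr), key=k)
        for p, k in zip(probs, keys)
    ]
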