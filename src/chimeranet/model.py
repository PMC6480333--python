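"""The convolutional oncogenicity classifier and its decision rule.

The network maps a one-hot encoded fusion protein (N positions x 22 channels)
to a score in (0, 1), interpreted as the probability that the fusion takes
part in an oncogenic process.  Architecture: two blocks of
[convolution -> batch-norm -> ReLU -> max-pool -> dropout] along the sequence
axis, then a flatten, a 128-unit ReLU dense layer, and a single sigmoid unit.
Training is stochastic gradient descent on binary cross-entropy with early
stopping on a held-out validation split.

The probability is thresholded at 0.5 (scores >= 0.5 are called Onco) and
zoned by confidence: below 0.2 the NotOnco call is high-confidence, above 0.8
the Onco call is high-confidence, anything between is uncertain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedShuffleSplit

from .encoding import EncodingSpec
from .exceptions import EmptyClassError, ShapeInfeasibleError
from .nn import (
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    ReLU,
    SGD,
    Sequential,
)

ONCO = "Onco"
NOTONCO = "NotOnco"

ZONE_NOTONCO = "high_conf_notonco"
ZONE_UNCERTAIN = "uncertain"
ZONE_ONCO = "high_conf_onco"

DECISION_THRESHOLD = 0.5
ZONE_LOW = 0.2
ZONE_HIGH = 0.8


@dataclass(frozen=True)
class ModelConfig:
    """Architectural hyper-parameters: Conv and Pool kernel sizes and the dropout rate."""

    conv_kernel: int = 10
    pool_kernel: int = 5
    dropout: float = 0.1
    n_filters: tuple[int, int] = (32, 64)
    dense_units: int = 128
    input_spec: EncodingSpec = field(default_factory=EncodingSpec)
    name: str = ""

    def __post_init__(self) -> None:
        if self.conv_kernel < 1 or self.pool_kernel < 1:
            raise ValueError("kernel sizes must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    def feature_lengths(self) -> list[int]:
        """Length of the feature map after each conv and pool stage.

        Each valid convolution maps L -> L - k + 1 and each non-overlapping
        pool maps L -> floor(L / p).  Raises if any stage collapses to zero.
        """
        lengths = []
        length = self.input_spec.n
        for _ in range(2):
            length = length - self.conv_kernel + 1
            if length < 1:
                raise ShapeInfeasibleError(
                    f"conv kernel {self.conv_kernel} exceeds feature length"
                )
            lengths.append(length)
            length = length // self.pool_kernel
            if length < 1:
                raise ShapeInfeasibleError(
                    f"pool kernel {self.pool_kernel} collapses the feature map"
                )
            lengths.append(length)
        return lengths


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings: SGD with early stopping on validation loss."""

    learning_rate: float = 0.005
    batch_size: int = 128
    max_epochs: int = 50
    patience: int = 30
    momentum: float = 0.0
    validation_fraction: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs, patience must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")


def build_network(cfg: ModelConfig, rng: np.random.Generator, dtype=np.float32) -> Sequential:
    """Assemble the layer stack for a configuration, validating feature-map shapes."""
    lengths = cfg.feature_lengths()
    c_in = cfg.input_spec.c
    layers = []
    channels = c_in
    for i, filters in enumerate(cfg.n_filters):
        layers += [
            Conv1D(cfg.conv_kernel, channels, filters, rng, dtype, input_layer=(i == 0)),
            BatchNorm(filters, dtype),
            ReLU(),
            MaxPool1D(cfg.pool_kernel),
            Dropout(cfg.dropout, rng),
        ]
        channels = filters
    flat = lengths[-1] * cfg.n_filters[-1]
    layers += [
        Flatten(),
        Dense(flat, cfg.dense_units, rng, dtype),
        ReLU(),
        Dense(cfg.dense_units, 1, rng, dtype),
    ]
    return Sequential(layers)


class FusionCNNClassifier(ClassifierMixin, BaseEstimator):
    """Convolutional classifier over one-hot encoded fusion proteins.

    Parameters
    ----------
    conv_kernel, pool_kernel, dropout : architecture grid parameters
        (defaults are the Conf_10 setting: 10 / 5 / 0.1).
    n_filters : pair of int
        Filters of the two convolutional layers.
    dense_units : int
        Width of the penultimate dense layer.
    learning_rate, batch_size, max_epochs, patience, momentum :
        SGD training schedule; training stops early when the validation loss
        has not improved for ``patience`` epochs, restoring the best weights.
    validation_fraction : float
        Share of the training data held out for early stopping.  When
        ``groups`` (gene-pair labels) are passed to :meth:`fit`, the holdout
        is gene-disjoint from the retained training portion.
    random_state : int or None
        Seeds weight initialisation, shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; the second entry is treated as the positive
        (oncogenic) class, which for string labels is ``"Onco"``.
    network_ : Sequential
        The fitted layer stack.
    history_ : dict of lists
        Per-epoch training/validation loss and accuracy.
    """

    def __init__(
        self,
        conv_kernel: int = 10,
        pool_kernel: int = 5,
        dropout: float = 0.1,
        n_filters: tuple[int, int] = (32, 64),
        dense_units: int = 128,
        learning_rate: float = 0.005,
        batch_size: int = 128,
        max_epochs: int = 50,
        patience: int = 30,
        momentum: float = 0.0,
        validation_fraction: float = 0.1,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.conv_kernel = conv_kernel
        self.pool_kernel = pool_kernel
        self.dropout = dropout
        self.n_filters = n_filters
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.momentum = momentum
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers ---------------------------------------------------------------
    @staticmethod
    def _as_3d(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 4:
            if X.shape[2] != 1:
                raise ValueError(f"expected width-1 tensors, got width {X.shape[2]}")
            X = X[:, :, 0, :]
        if X.ndim != 3:
            raise ValueError(f"expected (n, N, 1, C) or (n, N, C) input, got shape {X.shape}")
        return X

    def _model_config(self, n: int, c: int) -> ModelConfig:
        return ModelConfig(
            conv_kernel=self.conv_kernel,
            pool_kernel=self.pool_kernel,
            dropout=self.dropout,
            n_filters=tuple(self.n_filters),
            dense_units=self.dense_units,
            input_spec=EncodingSpec(n=n, c=c),
        )

    def _encode_labels(self, y) -> np.ndarray:
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise EmptyClassError("training data must contain both classes")
        if len(self.classes_) > 2:
            raise ValueError("binary classification only")
        # np.unique sorts, so string labels come out as [NotOnco, Onco]
        return (y == self.classes_[1]).astype(np.float64)

    # -- estimator API ---------------------------------------------------------
    def fit(self, X, y, groups=None):
        """Train by SGD on binary cross-entropy with early stopping.

        ``groups``, when given, is an (n, 2) array of (gene5, gene3) names per
        fusion used to make the early-stopping holdout gene-disjoint.
        """
        X = self._as_3d(X)
        y01 = self._encode_labels(y)
        n, seq_len, c = X.shape
        self.config_ = self._model_config(seq_len, c)
        self.config_.feature_lengths()  # raises ShapeInfeasibleError early
        rng = np.random.default_rng(self.random_state)
        self.network_ = build_network(self.config_, rng)

        idx = np.arange(n)
        if self.validation_fraction > 0.0 and n >= 10:
            tr_idx, va_idx = self._holdout(idx, y01, groups, rng)
        else:
            tr_idx, va_idx = idx, np.array([], dtype=int)
        if len(np.unique(y01[tr_idx])) < 2:
            raise EmptyClassError("training portion lost one class in the holdout")

        opt = SGD(self.network_, self.learning_rate, self.momentum)
        history = {"epoch": [], "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
        best_state, best_val, best_epoch = None, np.inf, -1
        monitor_val = len(va_idx) > 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(tr_idx)
            losses, hits, seen = [], 0, 0
            for start in range(0, len(order), self.batch_size):
                batch = order[start : start + self.batch_size]
                xb = X[batch].astype(np.float32)
                yb = y01[batch]
                loss, probs = self.network_.train_batch_gradients(xb, yb)
                if not np.isfinite(loss):
                    warnings.warn(f"training diverged (non-finite loss) at epoch {epoch}")
                    break
                opt.step()
                losses.append(loss * len(batch))
                hits += int(((probs >= DECISION_THRESHOLD) == (yb == 1)).sum())
                seen += len(batch)
            train_loss = float(np.sum(losses) / max(seen, 1))
            train_acc = hits / max(seen, 1)
            if monitor_val:
                pv = self._forward_proba(X[va_idx])
                val_loss = self.network_.bce_loss(pv, y01[va_idx])
                val_acc = float(((pv >= DECISION_THRESHOLD) == (y01[va_idx] == 1)).mean())
            else:
                val_loss, val_acc = np.nan, np.nan
            history["epoch"].append(epoch)
            history["train_loss"].append(train_loss)
            history["train_acc"].append(train_acc)
            history["val_loss"].append(val_loss)
            history["val_acc"].append(val_acc)
            if self.verbose:
                print(
                    f"epoch {epoch:3d}  train_loss {train_loss:.4f}  train_acc {train_acc:.3f}"
                    + (f"  val_loss {val_loss:.4f}  val_acc {val_acc:.3f}" if monitor_val else "")
                )
            monitored = val_loss if monitor_val else train_loss
            if monitored < best_val - 1e-6:
                best_val, best_epoch = monitored, epoch
                best_state = self.network_.state_dict()
            elif epoch - best_epoch >= self.patience:
                break
        if best_state is not None:
            self.network_.load_state_dict(best_state)
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_features_in_ = seq_len * c
        return self

    def _holdout(self, idx, y01, groups, rng):
        from .datasets import GeneDisjointSplit
        from .exceptions import SplitInfeasibleError

        if groups is not None:
            splitter = GeneDisjointSplit(
                test_fraction=self.validation_fraction,
                random_state=int(rng.integers(2**31 - 1)),
            )
            try:
                tr, va = next(splitter.split(idx, y01, groups))
                if len(np.unique(y01[idx[tr]])) == 2:
                    return idx[tr], idx[va]
            except SplitInfeasibleError:
                pass  # tiny or lopsided data: fall back to a random holdout
        sss = StratifiedShuffleSplit(
            n_splits=1,
            test_size=self.validation_fraction,
            random_state=int(rng.integers(2**31 - 1)),
        )
        try:
            tr, va = next(sss.split(idx[:, None], y01))
        except ValueError:
            return idx, np.array([], dtype=int)
        return idx[tr], idx[va]

    def _forward_proba(self, X3: np.ndarray) -> np.ndarray:
        out = np.empty(len(X3), dtype=np.float64)
        step = max(1, int(self.batch_size))
        for start in range(0, len(X3), step):
            xb = X3[start : start + step].astype(np.float32)
            out[start : start + step] = self.network_.predict_proba(xb)
        return out

    def oncogenic_probability(self, X) -> np.ndarray:
        """Score in (0, 1) per fusion: the probability of the positive (Onco) class."""
        self._check_fitted()
        X = self._as_3d(X)
        expected = (self.config_.input_spec.n, self.config_.input_spec.c)
        if X.shape[1:] != expected:
            raise ValueError(f"input shape {X.shape[1:]} does not match fitted spec {expected}")
        return self._forward_proba(X)

    def predict_proba(self, X) -> np.ndarray:
        p = self.oncogenic_probability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.oncogenic_probability(X)
        return np.where(p >= DECISION_THRESHOLD, self.classes_[1], self.classes_[0])

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted; call fit() first")

    # -- persistence -----------------------------------------------------------
    def save(self, path) -> None:
        """Serialise weights, running statistics and configuration to one ``.npz``."""
        self._check_fitted()
        state = self.network_.state_dict()
        meta = {
            "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.get_params().items()},
            "classes": [str(c) for c in self.classes_],
            "input_n": self.config_.input_spec.n,
            "input_c": self.config_.input_spec.c,
            "best_epoch": int(self.best_epoch_),
        }
        np.savez_compressed(path, __meta__=np.array(json.dumps(meta)), **state)

    @classmethod
    def load(cls, path) -> "FusionCNNClassifier":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            state = {k: data[k] for k in data.files if k != "__meta__"}
        params = meta["params"]
        params["n_filters"] = tuple(params["n_filters"])
        est = cls(**params)
        est.classes_ = np.array(meta["classes"])
        est.config_ = est._model_config(meta["input_n"], meta["input_c"])
        rng = np.random.default_rng(0)
        est.network_ = build_network(est.config_, rng)
        est.network_.load_state_dict(state)
        est.best_epoch_ = meta["best_epoch"]
        est.history_ = {}
        est.n_features_in_ = meta["input_n"] * meta["input_c"]
        return est


# -- decision rule -------------------------------------------------------------
def _check_prob(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def label_from_prob(p):
    """Binary call from the oncogenic probability: Onco iff p >= 0.5."""
    arr = _check_prob(p)
    out = np.where(arr >= DECISION_THRESHOLD, ONCO, NOTONCO)
    return out.item() if np.isscalar(p) or np.ndim(p) == 0 else out


def confidence_zone(p):
    """Confidence zoning: < 0.2 high-confidence NotOnco, > 0.8 high-confidence Onco."""
    arr = _check_prob(p)
    out = np.full(arr.shape, ZONE_UNCERTAIN, dtype=object)
    out[arr < ZONE_LOW] = ZONE_NOTONCO
    out[arr > ZONE_HIGH] = ZONE_ONCO
    return out.item() if np.isscalar(p) or np.ndim(p) == 0 else out.astype(str)


@dataclass(frozen=True)
class Prediction:
    """One scored fusion: probability, thresholded label and confidence zone."""

    fusion_id: str
    prob: float
    label: str
    zone: str

    @classmethod
    def from_prob(cls, fusion_id: str, prob: float) -> "Prediction":
        return cls(fusion_id=fusion_id, prob=float(prob), label=label_from_prob(prob), zone=confidence_zone(prob))


def predictions_table(fusion_ids, probs):
    """Predictions as a DataFrame: id, prob (6 decimals), label, zone."""
    import pandas as pd

    probs = _check_prob(np.asarray(probs))
    return pd.DataFrame(
        {
            "fusion_id": list(fusion_ids),
            "prob": np.round(probs, 6),
            "label": label_from_prob(probs),
            "zone": confidence_zone(probs),
        }
    )
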