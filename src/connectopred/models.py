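"""Outcome-prediction models: the TL-CNN and its comparison baselines.

The TL-CNN couples a frozen very-deep convolutional backbone (see
:mod:`connectopred.backbone`) with a trainable "shallow" head: two 3x3
convolutional layers of 256 filters on the 2x2x512 backbone feature map
(same-padding, so the 3x3 kernels remain applicable at that size),
followed by two fully connected layers of 256 and 64 units, each with
batch normalization and dropout, and a task output — a two-way softmax for
high-/low-risk classification or a single linear unit for score
regression.  Only the head receives gradient updates; training uses Adam
(learning rate 0.001) for 50 epochs with cross-entropy or MAE loss, and
the epoch with the lowest validation loss is kept when a validation split
is available.

Baselines: logistic/linear (ridge) regression and SVMs on the 4005-edge
vectors (scikit-learn, grids as published), a DNN on edge vectors, a
"shallow" CNN trained from scratch on the matrix, and a TL-DNN whose
fully connected layers are initialized by tied-weight autoencoder
pretraining on a source-domain pool of connectomes.

Regression targets are standardized internally (fit-set mean/SD) before
training and predictions mapped back to the 40-160 score scale; recorded
MAE history is rescaled to score units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .backbone import BackboneSpec, FrozenBackbone, build_backbone
from .connectome import Cohort, N_EDGES
from .nn.layers import (
    BatchNorm1D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    MaxPool2D,
    Param,
    ReLU,
)
from .nn.losses import (
    mae_with_grad,
    softmax,
    softmax_cross_entropy_with_grad,
)
from .nn.network import Adam, Sequential, checksum_params

__all__ = [
    "Task",
    "HeadSpec",
    "TrainConfig",
    "TrainingError",
    "Prediction",
    "build_baseline",
    "build_model",
    "pretrain_unsupervised",
    "TLCNNSpec",
    "SklearnSpec",
    "DNNSpec",
    "CNNSpec",
    "TLDNNSpec",
    "MODEL_KINDS",
    "OutcomeModel",
    "OutcomeResults",
]

Task = Literal["classification", "regression"]
MODEL_KINDS = ("lr", "svm-linear", "svm-poly", "svm-rbf", "dnn", "cnn",
               "tl-dnn", "tl-cnn")

LR_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
SVM_C_GRID = tuple(2.0 ** k for k in range(-3, 4))


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class Prediction:
    """Per-subject model output: probability of high risk, or a score."""

    subject_id: str
    p: float | None = None
    y_hat: float | None = None

    def __post_init__(self) -> None:
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"probability {self.p} outside [0, 1]")


@dataclass(frozen=True)
class HeadSpec:
    conv_filters: tuple[int, int] = (256, 256)
    fc_units: tuple[int, int] = (256, 64)
    dropout_rate: float = 0.5


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# generic network training loop
# ---------------------------------------------------------------------------

def _loss_and_grad(task: Task, out: np.ndarray, y: np.ndarray):
    if task == "classification":
        return softmax_cross_entropy_with_grad(out, y)
    return mae_with_grad(out, y)


def _eval_loss(net: Sequential, X: np.ndarray, y: np.ndarray, task: Task,
               batch: int) -> float:
    total, n = 0.0, len(y)
    for i0 in range(0, n, batch):
        out = net.forward(X[i0 : i0 + batch], train=False)
        loss, _ = _loss_and_grad(task, out, y[i0 : i0 + batch])
        total += loss * len(y[i0 : i0 + batch])
    return total / n


def _train_network(
    net: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray | None,
    y_val: np.ndarray | None,
    task: Task,
    config: TrainConfig,
) -> dict:
    """Mini-batch Adam training with best-validation-epoch selection."""
    rng = np.random.default_rng(config.seed)
    net.set_rng(rng)
    opt = Adam(net.params, lr=config.learning_rate)
    n = len(y)
    history = {"train_loss": [], "val_loss": []}
    best = {"loss": np.inf, "state": None, "epoch": -1}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i0 in range(0, n, config.batch_size):
            idx = order[i0 : i0 + config.batch_size]
            out = net.forward(X[idx], train=True)
            loss, grad = _loss_and_grad(task, out, y[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch + 1}")
            net.zero_grad()
            net.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / n)
        if X_val is not None and len(y_val):
            vloss = _eval_loss(net, X_val, y_val, task, config.batch_size)
            history["val_loss"].append(vloss)
            if vloss < best["loss"]:
                best = {"loss": vloss, "state": net.state_dict(), "epoch": epoch}
    if best["state"] is not None:
        net.load_state_dict(best["state"])
        history["selected_epoch"] = best["epoch"]
    else:
        history["selected_epoch"] = config.epochs - 1
    return history


def _predict_network(net: Sequential, X: np.ndarray, task: Task,
                     batch: int = 64) -> np.ndarray:
    outs = []
    for i0 in range(0, len(X), batch):
        outs.append(net.forward(X[i0 : i0 + batch], train=False))
    out = np.concatenate(outs)
    if task == "classification":
        return softmax(out.astype(np.float64))[:, 1]
    return out[:, 0].astype(np.float64)


class _ScoreScaler:
    """Standardize regression targets; predictions map back to score units."""

    def __init__(self, scores: np.ndarray):
        self.mean = float(np.mean(scores))
        self.sd = float(np.std(scores)) or 1.0

    def transform(self, scores: np.ndarray) -> np.ndarray:
        return ((scores - self.mean) / self.sd).astype(np.float32)

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.sd + self.mean


# ---------------------------------------------------------------------------
# model specs (statsmodels-style: spec.fit(...) returns a fitted object)
# ---------------------------------------------------------------------------

def _targets(cohort: Cohort, task: Task) -> np.ndarray:
    return cohort.labels if task == "classification" else cohort.scores


def _check_atlas(fit_atlas, cohort: Cohort) -> None:
    if fit_atlas.abbreviations != cohort.atlas.abbreviations:
        raise ValueError("cohort atlas does not match the atlas used for fitting")


class FittedModel:
    """Common surface of all fitted models."""

    kind: str
    task: Task

    def predict(self, cohort: Cohort) -> list[Prediction]:
        values = self.predict_values(cohort)
        if self.task == "classification":
            return [Prediction(s.id, p=float(v)) for s, v in zip(cohort, values)]
        return [Prediction(s.id, y_hat=float(v)) for s, v in zip(cohort, values)]

    def predict_values(self, cohort: Cohort) -> np.ndarray:
        """Array of probabilities (classification) or scores (regression)."""
        raise NotImplementedError


@dataclass(frozen=True)
class TLCNNSpec:
    """Frozen backbone + trainable shallow head."""

    task: Task = "classification"
    head: HeadSpec = HeadSpec()
    train_config: TrainConfig = TrainConfig()
    backbone: FrozenBackbone | None = None
    backbone_spec: BackboneSpec = BackboneSpec()

    kind = "tl-cnn"

    def build_head(self, rng: np.random.Generator) -> Sequential:
        c1, c2 = self.head.conv_filters
        f1, f2 = self.head.fc_units
        out_dim = 2 if self.task == "classification" else 1
        flat = c2 * 2 * 2  # head convs preserve the 2x2 backbone grid
        return Sequential([
            Conv2D(512, c1, rng, name="head_conv1"),
            ReLU(),
            Conv2D(c1, c2, rng, name="head_conv2"),
            ReLU(),
            Flatten(),
            Dense(flat, f1, rng, name="fc1"),
            ReLU(),
            BatchNorm1D(f1, name="bn1"),
            Dropout(self.head.dropout_rate),
            Dense(f1, f2, rng, name="fc2"),
            ReLU(),
            BatchNorm1D(f2, name="bn2"),
            Dropout(self.head.dropout_rate),
            Dense(f2, out_dim, rng, name="out"),
        ])

    def fit(self, train: Cohort, val: Cohort | None = None) -> "FittedTLCNN":
        if len(train) == 0:
            raise ValueError("training cohort is empty")
        backbone = self.backbone or build_backbone(self.backbone_spec)
        checksum_before = backbone.checksum()
        X = backbone.features(train.matrices())
        X_val = backbone.features(val.matrices()) if val is not None else None
        y = _targets(train, self.task)
        y_val = _targets(val, self.task) if val is not None else None
        scaler = None
        if self.task == "regression":
            scaler = _ScoreScaler(y)
            y = scaler.transform(y)
            y_val = scaler.transform(y_val) if y_val is not None else None
        rng = np.random.default_rng(self.train_config.seed)
        head = self.build_head(rng)
        history = _train_network(head, X, y, X_val, y_val, self.task,
                                 self.train_config)
        if self.task == "regression":
            history["train_loss"] = [l * scaler.sd for l in history["train_loss"]]
            history["val_loss"] = [l * scaler.sd for l in history["val_loss"]]
        if backbone.checksum() != checksum_before:
            raise TrainingError("frozen-backbone contract violated during training")
        return FittedTLCNN(self, backbone, head, history, scaler, train.atlas,
                           checksum_before)


class FittedTLCNN(FittedModel):
    kind = "tl-cnn"

    def __init__(self, spec, backbone, head, history, scaler, atlas, checksum):
        self.spec = spec
        self.task = spec.task
        self.backbone = backbone
        self.head = head
        self.history = history
        self.scaler = scaler
        self.atlas = atlas
        self.backbone_checksum = checksum

    @property
    def n_backbone_conv_layers(self) -> int:
        return self.backbone.n_conv_layers

    @property
    def head_conv_layers(self) -> list[Conv2D]:
        return [l for l in self.head.layers if isinstance(l, Conv2D)]

    def predict_values(self, cohort: Cohort) -> np.ndarray:
        _check_atlas(self.atlas, cohort)
        X = self.backbone.features(cohort.matrices())
        out = _predict_network(self.head, X, self.task)
        if self.task == "regression":
            out = self.scaler.inverse(out)
        return out

    def head_forward_with_grad(self, features: np.ndarray, target_class: int = 1):
        """Forward one feature map and backprop the target unit's gradient.

        Returns (activations, gradient) at the output of the last head
        convolution's ReLU — the ingredients of Grad-CAM.  The gradient is
        of the target logit (classification) or of the linear output
        (regression) w.r.t. those activations; head parameters are left
        untouched (gradients are discarded).
        """
        out = self.head.forward(features, train=False, cache=True)
        grad = np.zeros_like(out)
        if self.task == "classification":
            grad[:, target_class] = 1.0
        else:
            grad[:, 0] = 1.0
        self.head.zero_grad()
        self.head.backward(grad)
        relu_idx = max(
            i for i, l in enumerate(self.head.layers)
            if isinstance(self.head.layers[i], ReLU)
            and i > 0 and isinstance(self.head.layers[i - 1], Conv2D)
        )
        relu = self.head.layers[relu_idx]
        self.head.zero_grad()
        return relu.last_output, relu.grad_wrt_output


# -- scikit-learn baselines -------------------------------------------------


@dataclass(frozen=True)
class SklearnSpec:
    """Edge-vector baselines: logistic/ridge regression and SVMs.

    Hyperparameters are grid-searched on the supplied validation split
    (balanced accuracy for classification, MAE for regression); with no
    validation split the middle grid value is used.
    """

    kind: str = "lr"
    task: Task = "classification"
    seed: int = 0

    @property
    def grid(self) -> tuple[float, ...]:
        return LR_GRID if self.kind == "lr" else SVM_C_GRID

    def _make(self, value: float):
        from sklearn.linear_model import LogisticRegression, Ridge
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC, SVR

        if self.kind == "lr":
            est = (LogisticRegression(C=value, max_iter=5000)
                   if self.task == "classification" else Ridge(alpha=value))
        else:
            kernel = {"svm-linear": "linear", "svm-poly": "poly",
                      "svm-rbf": "rbf"}[self.kind]
            if self.task == "classification":
                est = SVC(kernel=kernel, C=value, gamma="scale")
            else:
                est = SVR(kernel=kernel, C=value, gamma="scale")
        return make_pipeline(StandardScaler(), est)

    def fit(self, train: Cohort, val: Cohort | None = None) -> "FittedSklearn":
        X, y = train.edge_matrix(), _targets(train, self.task)
        candidates = []
        for value in self.grid:
            est = self._make(value)
            est.fit(X, y)
            candidates.append((value, est))
        if val is not None and len(val) > 0:
            Xv, yv = val.edge_matrix(), _targets(val, self.task)
            scores = []
            for value, est in candidates:
                if self.task == "classification":
                    from sklearn.metrics import balanced_accuracy_score

                    scores.append(balanced_accuracy_score(yv, est.predict(Xv)))
                else:
                    scores.append(-np.mean(np.abs(est.predict(Xv) - yv)))
            best = int(np.argmax(scores))
        else:
            best = len(candidates) // 2
        value, est = candidates[best]
        return FittedSklearn(self, est, value, train.atlas)


class FittedSklearn(FittedModel):
    def __init__(self, spec: SklearnSpec, estimator, chosen_value: float, atlas):
        self.spec = spec
        self.kind = spec.kind
        self.task = spec.task
        self.estimator = estimator
        self.chosen_value = chosen_value
        self.atlas = atlas

    def predict_values(self, cohort: Cohort) -> np.ndarray:
        _check_atlas(self.atlas, cohort)
        X = cohort.edge_matrix()
        if self.task == "regression":
            return np.asarray(self.estimator.predict(X), dtype=float)
        if hasattr(self.estimator[-1], "predict_proba"):
            return self.estimator.predict_proba(X)[:, 1]
        d = self.estimator.decision_function(X)
        return 1.0 / (1.0 + np.exp(-d))  # logistic squash of the SVM margin


# -- edge-vector neural baselines ------------------------------------------


class _EdgeScaler:
    """Per-edge standardization fitted on the training cohort."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd = sd

    def transform(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.mean) / self.sd).astype(np.float32)


def _fc_stack(rng, in_dim: int, units: tuple[int, int], out_dim: int,
              dropout: float) -> list:
    f1, f2 = units
    return [
        Dense(in_dim, f1, rng, name="fc1"),
        ReLU(),
        BatchNorm1D(f1, name="bn1"),
        Dropout(dropout),
        Dense(f1, f2, rng, name="fc2"),
        ReLU(),
        BatchNorm1D(f2, name="bn2"),
        Dropout(dropout),
        Dense(f2, out_dim, rng, name="out"),
    ]


@dataclass(frozen=True)
class DNNSpec:
    """Fully connected net (256, 64) on the flattened 4005-edge vector."""

    task: Task = "classification"
    units: tuple[int, int] = (256, 64)
    dropout_rate: float = 0.5
    train_config: TrainConfig = TrainConfig()
    init_params: tuple | None = None  # (W1, b1, W2, b2) from pretraining

    kind = "dnn"

    def fit(self, train: Cohort, val: Cohort | None = None) -> "FittedVectorNet":
        scaler = _EdgeScaler(train.edge_matrix())
        X = scaler.transform(train.edge_matrix())
        X_val = scaler.transform(val.edge_matrix()) if val is not None else None
        y = _targets(train, self.task)
        y_val = _targets(val, self.task) if val is not None else None
        sscaler = None
        if self.task == "regression":
            sscaler = _ScoreScaler(y)
            y = sscaler.transform(y)
            y_val = sscaler.transform(y_val) if y_val is not None else None
        rng = np.random.default_rng(self.train_config.seed)
        out_dim = 2 if self.task == "classification" else 1
        net = Sequential(_fc_stack(rng, N_EDGES, self.units, out_dim,
                                   self.dropout_rate))
        if self.init_params is not None:
            w1, b1, w2, b2 = self.init_params
            net.layers[0].weight.value[...] = w1
            net.layers[0].bias.value[...] = b1
            net.layers[4].weight.value[...] = w2
            net.layers[4].bias.value[...] = b2
        history = _train_network(net, X, y, X_val, y_val, self.task,
                                 self.train_config)
        return FittedVectorNet(self, net, scaler, sscaler, history, train.atlas)


@dataclass(frozen=True)
class TLDNNSpec:
    """DNN initialized by unsupervised reconstruction pretraining."""

    task: Task = "classification"
    source: Cohort | None = None
    pretrain_epochs: int = 30
    train_config: TrainConfig = TrainConfig()

    kind = "tl-dnn"

    def fit(self, train: Cohort, val: Cohort | None = None) -> "FittedVectorNet":
        if self.source is None:
            raise ValueError("tl-dnn requires a source cohort for pretraining")
        init = pretrain_unsupervised(
            self.source, epochs=self.pretrain_epochs,
            seed=self.train_config.seed,
        )
        dnn = DNNSpec(task=self.task, train_config=self.train_config,
                      init_params=init["params"])
        fitted = dnn.fit(train, val)
        fitted.kind = "tl-dnn"
        fitted.pretrain_history = init["history"]
        return fitted


class FittedVectorNet(FittedModel):
    def __init__(self, spec, net, scaler, score_scaler, history, atlas):
        self.spec = spec
        self.kind = spec.kind
        self.task = spec.task
        self.net = net
        self.scaler = scaler
        self.score_scaler = score_scaler
        self.history = history
        self.atlas = atlas

    def predict_values(self, cohort: Cohort) -> np.ndarray:
        _check_atlas(self.atlas, cohort)
        X = self.scaler.transform(cohort.edge_matrix())
        out = _predict_network(self.net, X, self.task)
        if self.task == "regression":
            out = self.score_scaler.inverse(out)
        return out


@dataclass(frozen=True)
class CNNSpec:
    """Shallow CNN trained from scratch on the 90x90 matrix (no transfer).

    Two 3x3 convolutional layers of 256 filters; a 4x4 max-pool follows
    each convolution (90 -> 22 -> 5) to keep the fully connected stage
    tractable.
    """

    task: Task = "classification"
    dropout_rate: float = 0.5
    train_config: TrainConfig = TrainConfig()

    kind = "cnn"

    def _build(self, rng) -> Sequential:
        out_dim = 2 if self.task == "classification" else 1
        return Sequential([
            Conv2D(1, 256, rng, name="conv1"),
            ReLU(),
            MaxPool2D(4),
            Conv2D(256, 256, rng, name="conv2"),
            ReLU(),
            MaxPool2D(4),
            Flatten(),
            *_fc_stack(rng, 256 * 5 * 5, (256, 64), out_dim, self.dropout_rate),
        ])

    @staticmethod
    def _inputs(cohort: Cohort) -> np.ndarray:
        m = cohort.matrices(dtype=np.float32)
        mu = m.mean(axis=(1, 2), keepdims=True)
        sd = m.std(axis=(1, 2), keepdims=True)
        sd[sd == 0] = 1.0
        return ((m - mu) / sd)[:, None]  # (n, 1, 90, 90)

    def fit(self, train: Cohort, val: Cohort | None = None) -> "FittedCNN":
        X = self._inputs(train)
        X_val = self._inputs(val) if val is not None else None
        y = _targets(train, self.task)
        y_val = _targets(val, self.task) if val is not None else None
        sscaler = None
        if self.task == "regression":
            sscaler = _ScoreScaler(y)
            y = sscaler.transform(y)
            y_val = sscaler.transform(y_val) if y_val is not None else None
        rng = np.random.default_rng(self.train_config.seed)
        net = self._build(rng)
        history = _train_network(net, X, y, X_val, y_val, self.task,
                                 self.train_config)
        return FittedCNN(self, net, sscaler, history, train.atlas)


class FittedCNN(FittedModel):
    kind = "cnn"

    def __init__(self, spec, net, score_scaler, history, atlas):
        self.spec = spec
        self.task = spec.task
        self.net = net
        self.score_scaler = score_scaler
        self.history = history
        self.atlas = atlas

    def predict_values(self, cohort: Cohort) -> np.ndarray:
        _check_atlas(self.atlas, cohort)
        X = CNNSpec._inputs(cohort)
        out = _predict_network(self.net, X, self.task, batch=16)
        if self.task == "regression":
            out = self.score_scaler.inverse(out)
        return out


# ---------------------------------------------------------------------------
# unsupervised pretraining (tied-weight autoencoder on edge vectors)
# ---------------------------------------------------------------------------

class _TiedDense:
    """Decoder layer sharing (transposed) weights with an encoder Dense."""

    def __init__(self, tied: Dense, out_features: int):
        self.tied = tied
        self.bias = Param(np.zeros(out_features), "tied.bias")
        self.params = (self.bias,)
        self._x = None

    def forward(self, x, train=False, cache=None):
        self._x = x
        return x @ self.tied.weight.value.T + self.bias.value

    def backward(self, grad):
        self.tied.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.tied.weight.value


def pretrain_unsupervised(
    source: Cohort,
    epochs: int = 30,
    learning_rate: float = 0.001,
    batch_size: int = 16,
    seed: int = 0,
) -> dict:
    """Tied-weight autoencoder pretraining of the DNN's encoder layers.

    Minimizes mean squared reconstruction error of standardized edge
    vectors through a 4005 -> 256 -> 64 -> 256 -> 4005 bottleneck whose
    decoder shares the encoder weights transposed.  Returns the encoder
    parameters (used to initialize a TL-DNN) and the per-epoch
    reconstruction loss.
    """
    if len(source) == 0:
        raise ValueError("source cohort is empty")
    scaler = _EdgeScaler(source.edge_matrix())
    X = scaler.transform(source.edge_matrix())
    rng = np.random.default_rng(seed)
    enc1 = Dense(N_EDGES, 256, rng, name="enc1")
    enc2 = Dense(256, 64, rng, name="enc2")
    layers = [enc1, ReLU(), enc2, ReLU(),
              _TiedDense(enc2, 256), ReLU(), _TiedDense(enc1, N_EDGES)]
    params = tuple(p for l in layers for p in l.params)
    opt = Adam(params, lr=learning_rate)
    n = len(X)
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i0 in range(0, n, batch_size):
            idx = order[i0 : i0 + batch_size]
            x = X[idx]
            h = x
            for l in layers:
                h = l.forward(h, train=True)
            resid = h - x
            loss = float(np.mean(resid ** 2))
            grad = (2.0 * resid / resid.size).astype(np.float32)
            for p in params:
                p.grad[...] = 0.0
            for l in reversed(layers):
                grad = l.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    return {
        "params": (enc1.weight.value.copy(), enc1.bias.value.copy(),
                   enc2.weight.value.copy(), enc2.bias.value.copy()),
        "history": history,
    }


# ---------------------------------------------------------------------------
# factory + statsmodels-style wrapper
# ---------------------------------------------------------------------------

def build_model(
    kind: str,
    task: Task = "classification",
    train_config: TrainConfig | None = None,
    backbone: FrozenBackbone | None = None,
    source_cohort: Cohort | None = None,
):
    """Model spec for any supported kind, with published hyperparameters."""
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
    tc = train_config or TrainConfig()
    if kind == "tl-cnn":
        return TLCNNSpec(task=task, train_config=tc, backbone=backbone)
    if kind in ("lr", "svm-linear", "svm-poly", "svm-rbf"):
        return SklearnSpec(kind=kind, task=task, seed=tc.seed)
    if kind == "dnn":
        return DNNSpec(task=task, train_config=tc)
    if kind == "cnn":
        return CNNSpec(task=task, train_config=tc)
    if kind == "tl-dnn":
        return TLDNNSpec(task=task, source=source_cohort, train_config=tc)
    raise AssertionError


def build_baseline(kind: str, task: Task = "classification", **kwargs):
    """Alias of :func:`build_model` for the comparison models."""
    if kind == "tl-cnn":
        raise ValueError("tl-cnn is the primary model, not a baseline")
    return build_model(kind, task, **kwargs)


class OutcomeModel:
    """Cognitive-outcome model bound to a cohort (statsmodels-style).

    Parameters
    ----------
    cohort : Cohort
        Labelled training cohort.
    kind : str
        One of ``lr, svm-linear, svm-poly, svm-rbf, dnn, cnn, tl-dnn,
        tl-cnn`` (default ``tl-cnn``).
    task : {"classification", "regression"}
        Predict the high-risk class or the continuous score.

    Examples
    --------
    >>> model = OutcomeModel(cohort, kind="tl-cnn", task="classification")
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        cohort: Cohort,
        kind: str = "tl-cnn",
        task: Task = "classification",
        train_config: TrainConfig | None = None,
        backbone: FrozenBackbone | None = None,
        source_cohort: Cohort | None = None,
        val_fraction: float = 0.3,
    ):
        self.cohort = cohort
        self.kind = kind
        self.task = task
        self.train_config = train_config or TrainConfig()
        self.backbone = backbone
        self.source_cohort = source_cohort
        self.val_fraction = val_fraction

    def fit(self, seed: int | None = None) -> "OutcomeResults":
        from .evaluation import train_val_split

        tc = (replace(self.train_config, seed=seed)
              if seed is not None else self.train_config)
        if self.val_fraction > 0 and len(self.cohort) >= 10:
            fit_c, val_c = train_val_split(
                self.cohort, 1.0 - self.val_fraction, seed=tc.seed,
                stratified=self.task == "classification",
            )
        else:
            fit_c, val_c = self.cohort, None
        spec = build_model(self.kind, self.task, train_config=tc,
                           backbone=self.backbone,
                           source_cohort=self.source_cohort)
        fitted = spec.fit(fit_c, val_c)
        return OutcomeResults(self, fitted, fit_c, val_c)


class OutcomeResults:
    """Fit results: trained parameters, history, predictions, summary."""

    def __init__(self, model: OutcomeModel, fitted: FittedModel,
                 fit_cohort: Cohort, val_cohort: Cohort | None):
        self.model = model
        self.fitted = fitted
        self.fit_cohort = fit_cohort
        self.val_cohort = val_cohort

    @property
    def history(self) -> dict | None:
        return getattr(self.fitted, "history", None)

    def predict(self, cohort: Cohort | None = None) -> list[Prediction]:
        return self.fitted.predict(cohort if cohort is not None else self.model.cohort)

    def predict_values(self, cohort: Cohort | None = None) -> np.ndarray:
        return self.fitted.predict_values(
            cohort if cohort is not None else self.model.cohort
        )

    def summary(self) -> str:
        lines = [
            "Connectome outcome model",
            "=" * 38,
            f"model kind:        {self.fitted.kind}",
            f"task:              {self.fitted.task}",
            f"n fit subjects:    {len(self.fit_cohort)}",
            f"n val subjects:    {len(self.val_cohort) if self.val_cohort else 0}",
        ]
        if isinstance(self.fitted, FittedTLCNN):
            n_head = sum(p.value.size for p in self.fitted.head.params)
            lines += [
                f"backbone conv layers: {self.fitted.n_backbone_conv_layers} (frozen)",
                f"head parameters:      {n_head}",
                f"backbone checksum:    {self.fitted.backbone_checksum[:16]}...",
            ]
        h = self.history
        if h and h.get("train_loss"):
            lines.append(f"final train loss:  {h['train_loss'][-1]:.4f}")
            if h.get("val_loss"):
                lines.append(
                    f"best val loss:     {min(h['val_loss']):.4f} "
                    f"(epoch {h['selected_epoch'] + 1})"
                )
        if isinstance(self.fitted, FittedSklearn):
            lines.append(f"selected grid value: {self.fitted.chosen_value}")
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training/validation loss curves (matplotlib Axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history or {}
        ax.plot(h.get("train_loss", []), label="train")
        if h.get("val_loss"):
            ax.plot(h["val_loss"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        return ax
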