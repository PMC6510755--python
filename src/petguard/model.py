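"""The small demographic-prediction CNN: build, train, apply.

Architecture contract: exactly four 3 x 3 convolutional blocks (ReLU) and
three 2 x 2 max-pooling stages, so a 64 x 64 input reaches 8 x 8 feature
maps; local response normalization after the first block by default; a dense
layer with dropout; then a 2-class softmax head (sex) or a single linear
output (age or weight — unbounded, no squashing).

Training uses Adam on cross-entropy (classification) or mean-squared error
(regression), with patient-level validation monitoring, early stopping on
validation loss and best-epoch weight restoration.  Regression targets are
standardized internally and predictions returned in natural units (years,
kg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .augmentation import AugmentConfig, augment_set
from .errors import ConfigurationError, EmptyInputError, PredictionError
from .nn import softmax  # re-exported: the probability head of the classifier
from .projection import MIPImage

__all__ = [
    "SEX_CLASSES",
    "NetworkSpec",
    "TrainingConfig",
    "EarlyStopping",
    "CNNModel",
    "build_model",
    "split_patients",
    "train",
    "predict_image",
    "predict_batch",
    "softmax",
    "save_model",
    "load_model",
]

#: Class order of the softmax head everywhere in the package.
SEX_CLASSES = ("male", "female")

TASKS = ("sex", "age", "weight")


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters of the 4-conv / 3-pool network.

    Filter counts are deliberately small (the prediction task is coarse and
    the images are 64 x 64); all counts are configurable.  ``pool_after``
    and ``lrn_after`` index the convolution blocks (0-based).
    """

    input_size: int = 64
    filters: tuple[int, int, int, int] = (4, 8, 8, 16)
    kernel: int = 3
    dense_units: int = 32
    dropout_rate: float = 0.5
    lrn_radius: int = 2
    lrn_alpha: float = 1e-4
    lrn_beta: float = 0.75
    lrn_bias: float = 1.0
    lrn_after: tuple[int, ...] = (0,)
    pool_after: tuple[int, int, int] = (0, 1, 3)
    head: str = "softmax"
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.filters) != 4:
            raise ConfigurationError("exactly 4 convolutional blocks required")
        if len(self.pool_after) != 3:
            raise ConfigurationError("exactly 3 max-pooling stages required")
        if self.kernel != 3:
            raise ConfigurationError("only 3x3 kernels are supported")
        if self.head not in ("softmax", "linear"):
            raise ConfigurationError("head must be 'softmax' or 'linear'")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if any(p not in range(4) for p in self.pool_after):
            raise ConfigurationError("pool_after indices must reference conv blocks 0-3")

    @property
    def n_outputs(self) -> int:
        return self.n_classes if self.head == "softmax" else 1


@dataclass(frozen=True)
class TrainingConfig:
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 128
    max_epochs: int = 50
    patience: int = 3
    restore_best: bool = True
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ConfigurationError("val_fraction must lie in (0, 1)")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")


class EarlyStopping:
    """Stop when the monitored loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = -1
        self._since = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record one epoch's loss; return True when training should stop."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = epoch
            self._since = 0
            return False
        self._since += 1
        return self._since >= self.patience


class CNNModel:
    """A (possibly trained) network plus its spec, task and training history."""

    def __init__(self, spec: NetworkSpec, net: nn.Sequential, task: str = "sex"):
        if task not in TASKS:
            raise ConfigurationError(f"task must be one of {TASKS}")
        if task == "sex" and spec.head != "softmax":
            raise ConfigurationError("sex task requires the softmax head")
        if task in ("age", "weight") and spec.head != "linear":
            raise ConfigurationError("regression tasks require the linear head")
        self.spec = spec
        self.net = net
        self.task = task
        self.trained = False
        self.history: pd.DataFrame | None = None
        self.target_mean = 0.0
        self.target_std = 1.0

    @property
    def weights(self) -> list[np.ndarray]:
        return self.net.get_weights()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x.astype(np.float32), train=train)

    def last_conv_index(self) -> int:
        """Index (in the Sequential) of the ReLU following the last conv block."""
        idx = [i for i, l in enumerate(self.net.layers) if isinstance(l, nn.ReLU)]
        conv_relus = [i for i in idx if i < self._flatten_index()]
        return conv_relus[-1]

    def _flatten_index(self) -> int:
        return next(i for i, l in enumerate(self.net.layers) if isinstance(l, nn.Flatten))


def build_model(
    spec: NetworkSpec, task: str = "sex", seed: int = 0, backbone=None
) -> CNNModel:
    """Assemble an untrained model.

    ``backbone`` is a hook for plugging in an alternative feature extractor:
    a callable ``(spec, rng) -> Sequential`` replacing the default 4-conv
    stack (e.g. a residual network); the default build is used when None.
    """
    rng = np.random.default_rng(seed)
    if backbone is not None:
        net = backbone(spec, rng)
    else:
        layers: list[nn.Layer] = []
        cin = 1
        for i, cout in enumerate(spec.filters):
            layers.append(nn.Conv3x3(cin, cout, rng))
            layers.append(nn.ReLU())
            if i in spec.lrn_after:
                layers.append(
                    nn.LRN(spec.lrn_radius, spec.lrn_alpha, spec.lrn_beta, spec.lrn_bias)
                )
            if i in spec.pool_after:
                layers.append(nn.MaxPool2())
            cin = cout
        side = spec.input_size // 2 ** len(spec.pool_after)
        layers.append(nn.Flatten())
        layers.append(nn.Dense(side * side * spec.filters[-1], spec.dense_units, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(spec.dropout_rate, rng))
        layers.append(nn.Dense(spec.dense_units, spec.n_outputs, rng))
        net = nn.Sequential(layers)
    return CNNModel(spec, net, task=task)


def split_patients(cohort, train_fraction: float = 0.7, seed: int = 0):
    """Patient-level split: (train_ids, test_ids), sizes floor(f*n) / remainder."""
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must lie in (0, 1)")
    ids = [getattr(r, "patient_id", r) for r in cohort]
    if len(ids) == 0:
        raise EmptyInputError("cannot split an empty cohort")
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate patient ids in cohort")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.floor(train_fraction * len(ids)))
    train = [ids[i] for i in order[:n_train]]
    test = [ids[i] for i in order[n_train:]]
    return train, test


def _stack(images: list[MIPImage]) -> np.ndarray:
    return np.stack([im.pixels for im in images]).astype(np.float32)[..., None]


def _encode_labels(model: CNNModel, labels) -> np.ndarray:
    if model.task == "sex":
        idx = np.array([SEX_CLASSES.index(l) for l in labels])
        onehot = np.zeros((len(idx), model.spec.n_classes), dtype=np.float32)
        onehot[np.arange(len(idx)), idx] = 1.0
        return onehot
    return np.asarray(labels, dtype=np.float32)


def train(
    model: CNNModel,
    images: list[MIPImage],
    labels,
    cfg: TrainingConfig,
    augment: AugmentConfig | None = None,
) -> CNNModel:
    """Train in place and return the model.

    A patient-level validation fold (``cfg.val_fraction`` of the training
    patients) is carved out *before* any augmentation; only the remaining
    training images are augmented.  Stops at ``cfg.max_epochs`` or when the
    validation loss has not improved for ``cfg.patience`` epochs; with
    ``restore_best`` the returned weights are those of the best validation
    epoch.
    """
    if len(images) == 0:
        raise EmptyInputError("empty training set")
    if len(images) != len(labels):
        raise ConfigurationError("images and labels must align")
    rng = np.random.default_rng(cfg.seed)
    for layer in model.net.layers:
        if isinstance(layer, nn.Dropout):
            layer.rng = rng

    pids = np.array([im.patient_id for im in images])
    unique = np.array(sorted(set(pids)))
    perm = rng.permutation(len(unique))
    n_val = max(1, int(round(cfg.val_fraction * len(unique)))) if len(unique) > 1 else 0
    val_ids = set(unique[perm[:n_val]])
    val_sel = np.array([p in val_ids for p in pids])

    tr_images = [im for im, v in zip(images, val_sel) if not v]
    tr_labels = [l for l, v in zip(labels, val_sel) if not v]
    va_images = [im for im, v in zip(images, val_sel) if v]
    va_labels = [l for l, v in zip(labels, val_sel) if v]
    if augment is not None and augment.factor > 1:
        tr_images = augment_set(tr_images, augment)
        tr_labels = list(np.repeat(tr_labels, augment.factor))

    X = _stack(tr_images)
    Y = _encode_labels(model, tr_labels)
    Xv = _stack(va_images) if va_images else None
    Yv = _encode_labels(model, va_labels) if va_images else None

    if model.task in ("age", "weight"):
        model.target_mean = float(np.mean(Y))
        model.target_std = float(np.std(Y)) or 1.0
        Y = (Y - model.target_mean) / model.target_std
        if Yv is not None:
            Yv = (Yv - model.target_mean) / model.target_std

    opt = nn.Adam(lr=cfg.lr, betas=cfg.betas)
    stopper = EarlyStopping(cfg.patience)
    best_weights = model.net.get_weights()
    rows = []
    n = X.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        tot_loss = 0.0
        tot_correct = 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = X[sel], Y[sel]
            out = model.forward(xb, train=True)
            if model.task == "sex":
                loss, dout = nn.softmax_cross_entropy(out, yb)
                tot_correct += int((out.argmax(axis=1) == yb.argmax(axis=1)).sum())
            else:
                loss, dout = nn.mse_loss(out, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check the input images"
                )
            tot_loss += loss * len(sel)
            model.net.backward(dout)
            opt.step(model.net.params())
        train_loss = tot_loss / n
        val_loss, val_acc = _evaluate_fold(model, Xv, Yv) if Xv is not None else (train_loss, None)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "train_acc": tot_correct / n if model.task == "sex" else np.nan,
                "val_acc": val_acc if val_acc is not None else np.nan,
            }
        )
        stop = stopper.update(val_loss, epoch)
        if stopper.best_epoch == epoch:
            best_weights = model.net.get_weights()
        if stop:
            break
    if cfg.restore_best:
        model.net.set_weights(best_weights)
    model.history = pd.DataFrame(rows)
    model.trained = True
    return model


def _evaluate_fold(model: CNNModel, X: np.ndarray, Y: np.ndarray):
    out = model.forward(X, train=False)
    if model.task == "sex":
        loss, _ = nn.softmax_cross_entropy(out, Y)
        acc = float((out.argmax(axis=1) == Y.argmax(axis=1)).mean())
        return loss, acc
    loss, _ = nn.mse_loss(out, Y)
    return loss, None


def predict_batch(model: CNNModel, images: list[MIPImage]) -> np.ndarray:
    """Class probabilities (N, 2) for sex, natural-unit scalars (N,) otherwise."""
    if not model.trained:
        raise PredictionError("model has not been trained")
    if len(images) == 0:
        raise EmptyInputError("no images to predict")
    out = model.forward(_stack(images), train=False)
    if model.task == "sex":
        return softmax(out)
    return out.reshape(-1) * model.target_std + model.target_mean


def predict_image(model: CNNModel, image: MIPImage):
    """Probability pair for the sex task, a single real (years / kg) otherwise."""
    res = predict_batch(model, [image])
    return res[0] if model.task == "sex" else float(res[0])


def save_model(model: CNNModel, path_prefix) -> None:
    np.savez(
        f"{path_prefix}.weights.npz", **{f"w{i}": w for i, w in enumerate(model.net.get_weights())}
    )
    meta = {
        "spec": vars(model.spec) | {"filters": list(model.spec.filters)},
        "task": model.task,
        "target_mean": model.target_mean,
        "target_std": model.target_std,
        "trained": model.trained,
    }
    meta["spec"] = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(model.spec).items()
    }
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    if model.history is not None:
        model.history.to_csv(f"{path_prefix}.history.csv", index=False)


def load_model(path_prefix) -> CNNModel:
    with open(f"{path_prefix}.json") as fh:
        meta = json.load(fh)
    spec_d = meta["spec"]
    for key in ("filters", "lrn_after", "pool_after", "betas"):
        if key in spec_d and isinstance(spec_d[key], list):
            spec_d[key] = tuple(spec_d[key])
    spec = NetworkSpec(**spec_d)
    model = build_model(spec, task=meta["task"])
    with np.load(f"{path_prefix}.weights.npz") as z:
        model.net.set_weights([z[f"w{i}"] for i in range(len(z.files))])
    model.target_mean = meta["target_mean"]
    model.target_std = meta["target_std"]
    model.trained = meta["trained"]
    return model
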