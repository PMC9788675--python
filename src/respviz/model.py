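"""Image classifiers for the rendered visualizations.

The training protocol mirrors the transfer-learning recipe the pipeline was
designed around: stochastic gradient descent with momentum, mini-batches of
15, at most 10 epochs, base learning rate 1e-4, data reshuffled every
epoch, a softmax output trained with cross-entropy, and a freshly appended
fully connected head whose learning rate is multiplied by 20 relative to
the carried-over feature layers (which in turn get a multiplier below 1 to
preserve transferred features).

Two backbones are available:

- ``tiny`` (default): a small from-scratch CNN (two conv blocks plus a
  dense head) implemented in numpy. It is fully self-contained — no
  pretrained weights, no deep-learning framework — and is the backbone the
  test-suite experiments use. Since nothing is transferred, its feature
  layers train at the full base rate by default.
- ``alexnet``: the AlexNet-compatible pretrained path. It requires the
  optional torch/torchvision dependency at runtime and is feature-flagged;
  constructing it without those packages raises ImportError.

:class:`ImageClassifier` follows scikit-learn estimator conventions
(``fit``/``predict``/``predict_proba``, ``get_params``, fitted attributes
with trailing underscores) so it composes with sklearn model selection.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn
from .errors import ValidationError
from .types import IMAGE_SIDE

INPUT_SHAPE = (IMAGE_SIDE, IMAGE_SIDE, 3)


@dataclass(frozen=True)
class TrainingConfig:
    """The training hyperparameters, defaults fixed to the study protocol."""

    batch_size: int = 15
    max_epochs: int = 10
    base_learning_rate: float = 1.0e-4
    head_lr_factor: float = 20.0
    backbone_lr_multiplier: float = 1.0
    momentum: float = 0.9
    shuffle_each_epoch: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValidationError("batch_size: must be >= 1")
        if self.max_epochs < 0:
            raise ValidationError("max_epochs: must be >= 0")
        for name in ("base_learning_rate", "momentum"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: must be >= 0")
        if self.head_lr_factor < 1:
            raise ValidationError("head_lr_factor: must be >= 1")
        if self.backbone_lr_multiplier <= 0:
            raise ValidationError("backbone_lr_multiplier: must be > 0")


@dataclass(frozen=True)
class ClassifierSpec:
    """Backbone choice and output width."""

    backbone: str = "tiny"
    n_classes: int = 2
    input_shape: tuple = INPUT_SHAPE

    def validate(self) -> None:
        if self.backbone not in ("tiny", "alexnet"):
            raise ValidationError(f"backbone: unsupported {self.backbone!r}")
        if self.n_classes < 2:
            raise ValidationError("n_classes: must be >= 2")


def _tiny_network(n_classes: int, backbone_lr_multiplier: float,
                  head_lr_factor: float) -> _nn.Network:
    # 227 -> conv7/s4 -> 56 -> pool -> 28 -> conv3 -> 26 -> pool -> 13
    return _nn.Network([
        _nn.Conv2D(3, 8, k=7, stride=4, lr_mult=backbone_lr_multiplier),
        _nn.ReLU(),
        _nn.MaxPool2(),
        _nn.Conv2D(8, 16, k=3, stride=1, lr_mult=backbone_lr_multiplier),
        _nn.ReLU(),
        _nn.MaxPool2(),
        _nn.Flatten(),
        _nn.Dense(16 * 13 * 13, n_classes, lr_mult=head_lr_factor),
    ])


class ImageClassifier(BaseEstimator, ClassifierMixin):
    """CNN classifier over 227x227x3 8-bit visualization images.

    Parameters default to the study protocol (see module docstring).
    ``backbone_lr_multiplier`` only makes sense below 1 for the pretrained
    backbone; for the from-scratch ``tiny`` backbone the default of 1.0
    trains all layers at the base rate while the head still runs
    ``head_lr_factor`` times faster.

    Attributes (after ``fit``)
    --------------------------
    classes_ : ndarray
        Sorted unique training labels.
    history_ : list of dict
        Per-epoch ``{"epoch", "train_loss", "val_accuracy"}`` records
        (``val_accuracy`` is None when no validation set was given).
    """

    def __init__(
        self,
        backbone: str = "tiny",
        batch_size: int = 15,
        max_epochs: int = 10,
        base_learning_rate: float = 1.0e-4,
        head_lr_factor: float = 20.0,
        backbone_lr_multiplier: float = 1.0,
        momentum: float = 0.9,
        shuffle_each_epoch: bool = True,
        random_state: int = 0,
    ):
        self.backbone = backbone
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.base_learning_rate = base_learning_rate
        self.head_lr_factor = head_lr_factor
        self.backbone_lr_multiplier = backbone_lr_multiplier
        self.momentum = momentum
        self.shuffle_each_epoch = shuffle_each_epoch
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _check_images(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[1:] != INPUT_SHAPE:
            raise ValidationError(
                "X: expected images of shape (n, %d, %d, 3), got %r"
                % (IMAGE_SIDE, IMAGE_SIDE, X.shape)
            )
        # uint8 pixels -> centred floats in [-0.5, 0.5], NCHW
        return (X.astype(np.float32) / 255.0 - 0.5).transpose(0, 3, 1, 2)

    def _build(self, n_classes: int) -> _nn.Network:
        spec = ClassifierSpec(backbone=self.backbone, n_classes=n_classes)
        spec.validate()
        if self.backbone == "alexnet":
            raise ImportError(
                "backbone='alexnet' requires the optional torch/torchvision "
                "dependency with pretrained weights; install them or use "
                "backbone='tiny'"
            )
        return _tiny_network(n_classes, self.backbone_lr_multiplier,
                             self.head_lr_factor)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on images ``X`` with labels ``y``.

        An optional validation set provides the per-epoch accuracy in
        ``history_``; it must not contain labels unseen in training.
        """
        cfg = TrainingConfig(
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            base_learning_rate=self.base_learning_rate,
            head_lr_factor=self.head_lr_factor,
            backbone_lr_multiplier=self.backbone_lr_multiplier,
            momentum=self.momentum, shuffle_each_epoch=self.shuffle_each_epoch,
            seed=self.random_state,
        )
        cfg.validate()
        Xn = self._check_images(X)
        y = np.asarray(y)
        if y.shape[0] != Xn.shape[0]:
            raise ValidationError("y: length does not match X")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValidationError(
                "y: training labels must cover at least 2 classes; "
                f"got only {self.classes_.tolist()!r}"
            )
        if y_val is not None:
            missing = set(np.unique(y_val)) - set(self.classes_)
            if missing:
                raise ValidationError(
                    f"y_val: labels {sorted(missing)!r} absent from training labels"
                )

        rng = np.random.default_rng(self.random_state)
        net = self._build(self.classes_.size)
        net.init(rng)
        opt = _nn.SGDMomentum(lr=self.base_learning_rate, momentum=self.momentum)
        history = []
        n = Xn.shape[0]
        for epoch in range(self.max_epochs):
            order = rng.permutation(n) if self.shuffle_each_epoch else np.arange(n)
            losses = []
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                losses.append(net.train_step(Xn[batch], y_idx[batch], opt))
            record = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                      "val_accuracy": None}
            if X_val is not None and y_val is not None:
                self._net = net  # predict() needs the live network
                record["val_accuracy"] = float(
                    np.mean(self.predict(X_val) == np.asarray(y_val))
                )
            history.append(record)
        self._net = net
        self.history_ = history
        self.n_features_in_ = int(np.prod(INPUT_SHAPE))
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Class-probability vectors, one row per image (rows sum to 1)."""
        if not hasattr(self, "_net"):
            raise ValidationError("model: not fitted; call fit first")
        Xn = self._check_images(X)
        out = []
        for start in range(0, Xn.shape[0], 64):
            out.append(self._net.predict_proba(Xn[start : start + 64]))
        return np.concatenate(out, axis=0) if out else np.empty((0, self.classes_.size))

    def predict(self, X) -> np.ndarray:
        """Argmax labels; ties break to the lowest class index."""
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Serialize parameters and config to an ``.npz`` checkpoint."""
        if not hasattr(self, "_net"):
            raise ValidationError("model: not fitted; call fit first")
        meta = json.dumps({"params": self.get_params(),
                           "classes": self.classes_.tolist(),
                           "history": self.history_})
        np.savez(path, __meta__=np.array(meta), **self._net.state_dict())

    @classmethod
    def load(cls, path: str) -> "ImageClassifier":
        archive = np.load(path, allow_pickle=False)
        meta = json.loads(str(archive["__meta__"]))
        est = cls(**meta["params"])
        est.classes_ = np.asarray(meta["classes"])
        est.history_ = meta["history"]
        est._net = est._build(est.classes_.size)
        est._net.load_state_dict({k: archive[k] for k in archive.files
                                  if k != "__meta__"})
        return est


# ---------------------------------------------------------------------------
# function-style wrappers


def build_model(spec: ClassifierSpec, cfg: TrainingConfig | None = None) -> ImageClassifier:
    """Untrained classifier from a spec (thin wrapper over ImageClassifier)."""
    spec.validate()
    cfg = cfg or TrainingConfig()
    cfg.validate()
    return ImageClassifier(
        backbone=spec.backbone, batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs, base_learning_rate=cfg.base_learning_rate,
        head_lr_factor=cfg.head_lr_factor,
        backbone_lr_multiplier=cfg.backbone_lr_multiplier,
        momentum=cfg.momentum, shuffle_each_epoch=cfg.shuffle_each_epoch,
        random_state=cfg.seed,
    )


def train(model: ImageClassifier, X_train, y_train, X_val=None, y_val=None) -> ImageClassifier:
    """Fit ``model``; returns it with ``history_`` populated."""
    return model.fit(X_train, y_train, X_val=X_val, y_val=y_val)


def predict(model: ImageClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Per-image probability vectors and argmax labels."""
    probs = model.predict_proba(X)
    return probs, model.classes_[np.argmax(probs, axis=1)]
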