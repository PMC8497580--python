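"""The incrementally finetuned patch classifier.

Architecture: a frozen feature backbone followed by a small trainable head of
two fully connected layers with 32 rectified units each and a 2-unit softmax
output. Finetuning follows the live-annotation protocol exactly:

* stratified 75/25 train/validation split of the labeled cells,
* minority-class oversampling with replacement so every epoch presents a
  balanced stream,
* stochastic gradient descent, learning rate 1e-5, momentum 0.9,
* at most 100 epochs, early stopping when validation accuracy has not
  improved for 10 epochs, keeping the best-epoch head,
* a fresh finetune every five newly labeled cells during a session.

Only the head's parameters ever change; the backbone is bitwise frozen. The
32-dimensional activation of the second head layer (the layer feeding the
output) is the embedding handed to the active learner.

The head is trained at the protocol's very small learning rate, so its hidden
layers stay close to their initialization; initialization therefore matters.
Hidden weights use He scaling with a positive bias (units start active, the
layers start near-linear), and the output layer starts at zero so the learned
read-out direction is driven entirely by the labeled data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import patchio

HEAD_WIDTH = 32
_HIDDEN_BIAS_INIT = 1.0


class NotInitializedError(RuntimeError):
    """predict() was called before the model was ever finetuned."""


class InsufficientLabelsError(ValueError):
    """A class has too few labeled examples for the stratified split."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    momentum: float = 0.9
    max_epochs: int = 100
    patience: int = 10
    train_fraction: float = 0.75
    retrain_interval: int = 5
    batch_size: int = 4
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.retrain_interval < 1:
            raise ValueError("retrain_interval must be >= 1")


@dataclass
class LabelPool:
    """Bookkeeping of the labeled set L and unlabeled set U."""

    labeled: dict[int, int] = field(default_factory=dict)  # cell_id -> label
    unlabeled: set[int] = field(default_factory=set)

    def add_label(self, cell_id: int, label: int) -> None:
        if cell_id in self.labeled:
            raise ValueError(f"cell {cell_id} already labeled")
        self.labeled[cell_id] = label
        self.unlabeled.discard(cell_id)

    def counts(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for lab in self.labeled.values():
            out[lab] = out.get(lab, 0) + 1
        return out


@dataclass
class FeatureMatrix:
    """Per-cell embeddings with a row <-> cell_id index."""

    rows: np.ndarray  # (n, d)
    ids: list[int]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("id_index length must equal row count")
        if not np.isfinite(self.rows).all():
            raise ValueError("feature matrix contains non-finite values")
        self._index = {cid: i for i, cid in enumerate(self.ids)}

    def row_of(self, cell_id: int) -> np.ndarray:
        return self.rows[self._index[cell_id]]


@dataclass
class FinetuneResult:
    val_accuracy: float
    best_epoch: int
    epochs_run: int
    epoch_class_counts: list[dict[int, int]]


class ClassifierModel:
    """Frozen backbone + trainable 2x32 head with softmax output."""

    def __init__(self, backbone, n_classes: int = 2, seed: int = 0):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.backbone = backbone
        self.n_classes = n_classes
        self.seed = seed
        self.is_finetuned = False
        self._velocity = None
        self._init_head(seed)

    def _init_head(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        d = self.backbone.dim
        self.head = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / d), (d, HEAD_WIDTH)),
            "b1": np.full(HEAD_WIDTH, _HIDDEN_BIAS_INIT),
            "W2": rng.normal(0.0, np.sqrt(2.0 / HEAD_WIDTH), (HEAD_WIDTH, HEAD_WIDTH)),
            "b2": np.full(HEAD_WIDTH, _HIDDEN_BIAS_INIT),
            "W3": np.zeros((HEAD_WIDTH, self.n_classes)),
            "b3": np.zeros(self.n_classes),
        }

    # forward pieces -------------------------------------------------------
    def _hidden(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h1 = np.maximum(X @ self.head["W1"] + self.head["b1"], 0.0)
        h2 = np.maximum(h1 @ self.head["W2"] + self.head["b2"], 0.0)
        return h1, h2

    def _forward(self, X: np.ndarray) -> np.ndarray:
        _, h2 = self._hidden(X)
        return _softmax(h2 @ self.head["W3"] + self.head["b3"])

    def features(self, patches: np.ndarray) -> np.ndarray:
        return self.backbone.transform(patches)

    def backbone_fingerprint(self) -> str:
        return self.backbone.fingerprint()


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_classifier(backbone, n_classes: int = 2, seed: int = 0) -> ClassifierModel:
    """Fresh model: seeded head initialization, backbone flagged frozen."""
    return ClassifierModel(backbone, n_classes=n_classes, seed=seed)


def _stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise InsufficientLabelsError(
                f"class {cls} has {len(idx)} labeled example(s); need >= 2"
            )
        idx = rng.permutation(idx)
        n_train = int(np.clip(round(len(idx) * train_fraction), 1, len(idx) - 1))
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def _oversampled_stream(
    train_labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices into the training set with per-class counts made equal."""
    classes, counts = np.unique(train_labels, return_counts=True)
    target = counts.max()
    stream: list[np.ndarray] = []
    for cls, count in zip(classes, counts):
        idx = np.flatnonzero(train_labels == cls)
        stream.append(idx)
        if count < target:
            stream.append(rng.choice(idx, size=target - count, replace=True))
    out = np.concatenate(stream)
    return out[rng.permutation(len(out))]


def finetune(
    model: ClassifierModel,
    patches: np.ndarray,
    labels,
    cfg: TrainConfig | None = None,
    features: np.ndarray | None = None,
) -> FinetuneResult:
    """Finetune the head on all labeled data; returns best validation accuracy.

    ``features`` may carry precomputed backbone embeddings of ``patches`` to
    avoid re-embedding inside a session loop. Training continues from the
    model's current head (incremental, warm-start finetuning); the best-epoch
    head by validation accuracy (ties to the earliest epoch) is kept.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    labels = np.asarray(labels, dtype=int)
    X = model.features(patches) if features is None else np.asarray(features)
    if len(X) != len(labels):
        raise ValueError("patches and labels disagree in length")

    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = _stratified_split(labels, cfg.train_fraction, rng)
    X_train, y_train = X[train_idx], labels[train_idx]
    X_val, y_val = X[val_idx], labels[val_idx]

    head = model.head
    velocity = {k: np.zeros_like(v) for k, v in head.items()}
    best_acc = -1.0
    best_epoch = -1
    best_head = None
    epoch_counts: list[dict[int, int]] = []

    epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        stream = _oversampled_stream(y_train, rng)
        classes, counts = np.unique(y_train[stream], return_counts=True)
        epoch_counts.append({int(c): int(n) for c, n in zip(classes, counts)})
        for start in range(0, len(stream), cfg.batch_size):
            batch = stream[start : start + cfg.batch_size]
            _sgd_step(head, velocity, X_train[batch], y_train[batch], cfg)
        probs = _softmax(
            np.maximum(
                np.maximum(X_val @ head["W1"] + head["b1"], 0.0) @ head["W2"]
                + head["b2"],
                0.0,
            )
            @ head["W3"]
            + head["b3"]
        )
        acc = float((probs.argmax(axis=1) == y_val).mean())
        if acc > best_acc:  # strict: ties keep the earliest epoch
            best_acc = acc
            best_epoch = epoch
            best_head = {k: v.copy() for k, v in head.items()}
        elif epoch - best_epoch >= cfg.patience:
            break

    model.head = best_head
    model.is_finetuned = True
    return FinetuneResult(
        val_accuracy=best_acc,
        best_epoch=best_epoch,
        epochs_run=epoch,
        epoch_class_counts=epoch_counts,
    )


def _sgd_step(head, velocity, x, t, cfg: TrainConfig) -> None:
    """One minibatch step of mean-reduced cross-entropy SGD with momentum."""
    h1 = np.maximum(x @ head["W1"] + head["b1"], 0.0)
    h2 = np.maximum(h1 @ head["W2"] + head["b2"], 0.0)
    p = _softmax(h2 @ head["W3"] + head["b3"])
    delta = p.copy()
    delta[np.arange(len(t)), t] -= 1.0
    delta /= len(t)
    grads = {}
    grads["W3"] = h2.T @ delta
    grads["b3"] = delta.sum(axis=0)
    dh2 = delta @ head["W3"].T
    dh2[h2 <= 0.0] = 0.0
    grads["W2"] = h1.T @ dh2
    grads["b2"] = dh2.sum(axis=0)
    dh1 = dh2 @ head["W2"].T
    dh1[h1 <= 0.0] = 0.0
    grads["W1"] = x.T @ dh1
    grads["b1"] = dh1.sum(axis=0)
    for key, grad in grads.items():
        velocity[key] = cfg.momentum * velocity[key] - cfg.learning_rate * grad
        head[key] = head[key] + velocity[key]


def predict_proba(
    model: ClassifierModel, patches: np.ndarray, features: np.ndarray | None = None
) -> np.ndarray:
    if not model.is_finetuned:
        raise NotInitializedError("model not initialized: finetune it first")
    X = model.features(patches) if features is None else np.asarray(features)
    return model._forward(X)


def predict(
    model: ClassifierModel, patches: np.ndarray, features: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, probabilities); label = argmax, deterministic for fixed head."""
    probs = predict_proba(model, patches, features=features)
    return probs.argmax(axis=1), probs


def embed(
    model: ClassifierModel,
    patches: np.ndarray,
    ids=None,
    features: np.ndarray | None = None,
    layer: str = "head",
) -> FeatureMatrix:
    """Second-to-last-layer embedding for labeled and unlabeled cells.

    ``layer="head"`` (default) reads the second 32-unit head layer;
    ``layer="backbone"`` returns the frozen backbone features instead.
    """
    X = model.features(patches) if features is None else np.asarray(features)
    if layer == "head":
        _, rows = model._hidden(X)
    elif layer == "backbone":
        rows = X
    else:
        raise ValueError(f"unknown embedding layer {layer!r}")
    if ids is None:
        ids = list(range(len(rows)))
    return FeatureMatrix(rows=rows, ids=list(ids))


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: ClassifierModel, path) -> None:
    """Single-file .npz archive: head parameters + config snapshot.

    The backbone is identified by fingerprint only; it is reconstructed (or
    re-supplied) by the caller at load time.
    """
    meta = {
        "n_classes": model.n_classes,
        "seed": model.seed,
        "is_finetuned": model.is_finetuned,
        "backbone_fingerprint": model.backbone_fingerprint(),
    }
    arrays = {f"head_{k}": v for k, v in model.head.items()}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path, backbone) -> ClassifierModel:
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["meta"]))
    if backbone.fingerprint() != meta["backbone_fingerprint"]:
        raise ValueError("backbone fingerprint mismatch for checkpoint")
    model = ClassifierModel(backbone, n_classes=int(meta["n_classes"]), seed=int(meta["seed"]))
    model.head = {k[len("head_"):]: archive[k] for k in archive.files if k.startswith("head_")}
    model.is_finetuned = bool(meta["is_finetuned"])
    return model
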