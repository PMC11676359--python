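"""Training and evaluation for both classifier geometries.

Cross-entropy training with SGD + momentum and a cosine learning-rate
decay.  Parameters attached to a Lorentz manifold are updated with
Riemannian SGD semantics (Euclidean gradient -> metric correction ->
exp-map retraction); in the default models every parameter — including
the curvature, stored as ``log k`` — is an unconstrained Euclidean
reparameterisation, so the Riemannian branch exists for point-valued
parameters and is exercised directly in the tests.

Augmentation follows the usual image-classification recipe: per-channel
normalisation (statistics computed from the training split), random
rotation within a configured angle, and horizontal flips.  Everything is
driven by explicit numpy Generators, so a fixed seed reproduces the loss
curve bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .autodiff import Parameter, Tensor, as_tensor
from .lorentz import LorentzManifold, egrad_to_rgrad, expmap
from .models import ClassifierModel

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "augment",
    "train",
    "evaluate",
    "topk_accuracy",
    "cross_entropy_loss",
    "stratified_split",
    "RiemannianSGD",
]


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 0.01
    momentum: float = 0.9
    seed: int = 0
    rotation_degrees: float = 10.0
    flip_prob: float = 0.5
    normalize_mean: float | None = None  # None -> computed from the training split
    normalize_sd: float | None = None
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    cosine_decay: bool = True

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class MetricsReport:
    cross_entropy: float
    top1: float                      # percent
    top5: float                      # percent
    per_class_accuracy: np.ndarray = field(repr=False)
    n_eval: int = 0

    def as_dict(self) -> dict:
        return {
            "cross_entropy": self.cross_entropy,
            "top1": self.top1,
            "top5": self.top5,
            "per_class_accuracy": [float(a) for a in self.per_class_accuracy],
            "n_eval": self.n_eval,
        }


# ---------------------------------------------------------------------------
# Data utilities
# ---------------------------------------------------------------------------

def stratified_split(labels: np.ndarray, fractions=(0.8, 0.1, 0.1), seed: int = 0
                     ) -> np.ndarray:
    """Per-class random assignment to {train, val, test} in given fractions."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    out = np.empty(len(labels), dtype=object)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        out[idx[:n_train]] = "train"
        out[idx[n_train:n_train + n_val]] = "val"
        out[idx[n_train + n_val:]] = "test"
    return out.astype(str)


def augment(images: np.ndarray, cfg: TrainConfig, rng: np.random.Generator,
            mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
    """Normalise, randomly rotate and randomly flip a batch of images.

    ``images`` is (B, C, H, W) (a single (C, H, W) image is also accepted).
    Rotation is bilinear with nearest-edge padding; a rotation of 0 degrees
    and flip probability 0 reduce to pure normalisation.
    """
    images = np.asarray(images, dtype=np.float64)
    single = images.ndim == 3
    if single:
        images = images[None]
    out = (images - mean) / sd
    if cfg.rotation_degrees > 0:
        angles = rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees, size=len(out))
        out = np.stack([
            ndimage.rotate(img, ang, axes=(-2, -1), reshape=False,
                           order=1, mode="nearest")
            for img, ang in zip(out, angles)
        ])
    if cfg.flip_prob > 0:
        flips = rng.random(len(out)) < cfg.flip_prob
        out[flips] = out[flips][..., ::-1]
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Loss / metrics
# ---------------------------------------------------------------------------

def cross_entropy_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean multinomial cross-entropy from raw logits."""
    labels = np.asarray(labels, dtype=int)
    n_classes = logits.shape[-1]
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label out of range for the logit matrix")
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    lse = logits.logsumexp(axis=-1)
    true_logit = (logits * onehot).sum(axis=-1)
    return (lse - true_logit).mean()


def topk_accuracy(logits: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Percent of rows whose true label is among the k largest logits.

    Ties are broken in favour of the lowest class index (stable sort on
    the negated logits), so the result is deterministic.
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if k > logits.shape[1]:
        raise ValueError(f"k={k} exceeds n_classes={logits.shape[1]}")
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise ValueError("label out of range")
    order = np.argsort(-logits, axis=1, kind="stable")[:, :k]
    hit = (order == labels[:, None]).any(axis=1)
    return 100.0 * float(hit.mean())


def evaluate(model: ClassifierModel, split, batch_size: int = 256) -> MetricsReport:
    """Loss / Top-1 / Top-5 / per-class accuracy over a (images, labels) split."""
    X, y = split
    if len(X) == 0:
        raise ValueError("cannot evaluate on an empty split")
    y = np.asarray(y, dtype=int)
    mean = getattr(model, "norm_mean", 0.0)
    sd = getattr(model, "norm_sd", 1.0)
    logits = _forward_in_batches(model, (np.asarray(X, dtype=np.float64) - mean) / sd,
                                 batch_size)
    n_classes = logits.shape[1]
    ce = float(cross_entropy_loss(as_tensor(logits), y).data)
    top1 = topk_accuracy(logits, y, 1)
    top5 = topk_accuracy(logits, y, min(5, n_classes))
    preds = np.argmax(logits, axis=1)
    per_class = np.array([
        float((preds[y == c] == c).mean()) if np.any(y == c) else np.nan
        for c in range(n_classes)
    ])
    return MetricsReport(ce, top1, top5, per_class, n_eval=len(y))


def _forward_in_batches(model, X, batch_size):
    outs = []
    for lo in range(0, len(X), batch_size):
        outs.append(model.forward(X[lo:lo + batch_size]).data)
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class RiemannianSGD:
    """SGD with momentum; manifold-attached parameters take Riemannian steps.

    A parameter whose ``manifold`` attribute is a :class:`LorentzManifold`
    is treated as a point (or row-wise batch of points) on the hyperboloid:
    its Euclidean gradient is converted to the Riemannian gradient and the
    update is the exp-map retraction ``x <- exp_x(-lr * rgrad)``.  Momentum
    is intentionally not applied on the manifold branch (transporting the
    buffer is out of scope); Euclidean parameters use classical momentum.
    """

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, vel in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            lr = self.lr * getattr(p, "lr_scale", 1.0)
            if isinstance(getattr(p, "manifold", None), LorentzManifold):
                rgrad = egrad_to_rgrad(p.data, p.grad, p.manifold)
                p.data = expmap(p.data, -lr * rgrad, p.manifold)
            else:
                vel *= self.momentum
                vel += p.grad
                p.data = p.data - lr * vel


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(model: ClassifierModel, data, cfg: TrainConfig):
    """Train ``model`` on ``data`` = {"train": (X, y), "val": (X, y)?}.

    Returns ``(model, log)`` where ``log`` is a list of per-epoch dicts
    (epoch, lr, train loss/top1, validation metrics when a validation
    split is present).  Raises ``RuntimeError`` on divergence, naming the
    epoch and batch.
    """
    if isinstance(data, tuple):
        data = {"train": data}
    X, y = data["train"]
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("training needs >= 2 classes with >= 2 images each")

    mean = cfg.normalize_mean if cfg.normalize_mean is not None else float(X.mean())
    sd = cfg.normalize_sd if cfg.normalize_sd is not None else float(X.std()) or 1.0
    model.norm_mean, model.norm_sd = mean, sd

    rng = np.random.default_rng(cfg.seed)
    opt = RiemannianSGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    log: list[dict] = []
    n = len(X)
    for epoch in range(1, cfg.epochs + 1):
        if cfg.cosine_decay:
            opt.lr = cfg.learning_rate * 0.5 * (1 + math.cos(math.pi * (epoch - 1) / cfg.epochs))
        order = rng.permutation(n)
        epoch_loss, epoch_hits, seen = 0.0, 0, 0
        for bi, lo in enumerate(range(0, n, cfg.batch_size)):
            idx = order[lo:lo + cfg.batch_size]
            xb = augment(X[idx], cfg, rng, mean=mean, sd=sd)
            logits = model.forward(as_tensor(xb), train=True)
            loss = cross_entropy_loss(logits, y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, batch {bi}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            epoch_hits += int((np.argmax(logits.data, axis=1) == y[idx]).sum())
            seen += len(idx)
        model.sync_manifold()
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": epoch_loss / seen,
            "train_top1": 100.0 * epoch_hits / seen,
        }
        if "val" in data and len(data["val"][0]):
            rep = evaluate(model, data["val"])
            entry.update(val_loss=rep.cross_entropy, val_top1=rep.top1, val_top5=rep.top5)
        log.append(entry)
    return model, log
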