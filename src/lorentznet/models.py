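"""Hybrid image classifiers: one convolutional encoder, two geometries.

Both variants share an identical residual convolutional encoder producing a
``embedding_dim``-dimensional penultimate feature vector (by default one
dimension per class).  They differ only in the classification head:

* ``euclidean`` — an affine map ``W z + b`` (the baseline CNN);
* ``lorentz``  — feature clipping to radius ``clip_radius`` (default 1.0),
  exponential map onto the hyperboloid of learnable curvature ``k``, then a
  Lorentz multinomial-logistic decoder whose class score is the
  curvature-scaled signed hyperbolic distance to a learnable hyperplane
  (offset scalar + direction vector per class).

With equal ``embedding_dim`` and ``n_classes`` the two heads hold exactly
the same number of trainable parameters, so the Lorentz variant exceeds its
Euclidean twin by exactly one parameter: the curvature scalar (stored as
``log k`` so it can be optimised without a positivity constraint).

Two encoder scales are available: ``resnet18`` (the standard 4-stage
basic-block residual network) and ``tiny`` (3x3 stem, two residual stages
of width 16/32, global average pooling) for desk-scale experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Parameter, Tensor, as_tensor
from .lorentz import LorentzManifold

__all__ = [
    "ModelConfig",
    "ClassifierModel",
    "build_model",
    "euclidean_logits",
    "lorentz_logits",
    "save_checkpoint",
    "load_checkpoint",
]

_GEOMETRIES = ("euclidean", "lorentz")
_ENCODERS = ("resnet18", "tiny")
_CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters shared by both geometries."""

    geometry: str = "euclidean"
    n_classes: int = 2
    embedding_dim: int | None = None  # default: one dimension per class
    encoder_scale: str = "tiny"
    clip_radius: float = 1.0
    k_init: float = 1.0
    image_size: int = 64
    in_channels: int = 1

    def __post_init__(self):
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"geometry must be one of {_GEOMETRIES}, got {self.geometry!r}")
        if self.encoder_scale not in _ENCODERS:
            raise ValueError(f"encoder_scale must be one of {_ENCODERS}, got {self.encoder_scale!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if self.embedding_dim is None:
            self.embedding_dim = self.n_classes
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be at least 2")
        if self.clip_radius <= 0 or self.k_init <= 0:
            raise ValueError("clip_radius and k_init must be positive")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Conv2d:
    def __init__(self, cin, cout, k, rng, stride=1, padding=0, bias=False):
        fan_in = cin * k * k
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.weight = Parameter(w, name=f"conv{cout}x{cin}")
        self.bias = Parameter(np.zeros(cout), name="conv_bias") if bias else None
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Parameter(np.ones(c), name="bn_gamma")
        self.beta = Parameter(np.zeros(c), name="bn_beta")
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
        else:
            mu = as_tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = as_tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        c = self.gamma.data.size
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)

    def parameters(self):
        return [self.gamma, self.beta]


class Linear:
    def __init__(self, din, dout, rng):
        w = rng.normal(0.0, math.sqrt(2.0 / din), size=(dout, din))
        self.weight = Parameter(w, name=f"linear{dout}x{din}")
        self.bias = Parameter(np.zeros(dout), name="linear_bias")

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        return x @ self.weight.T + self.bias

    def parameters(self):
        return [self.weight, self.bias]


class BasicBlock:
    """Standard two-convolution residual block (optionally downsampling)."""

    def __init__(self, cin, cout, rng, stride=1):
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=stride, padding=1)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng, padding=1)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(cin, cout, 1, rng, stride=stride)
            self.down_bn = BatchNorm2d(cout)
        else:
            self.down_conv = None

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        out = self.bn1(self.conv1(x, train), train).relu()
        out = self.bn2(self.conv2(out, train), train)
        if self.down_conv is not None:
            x = self.down_bn(self.down_conv(x, train), train)
        return (out + x).relu()

    def parameters(self):
        ps = self.conv1.parameters() + self.bn1.parameters()
        ps += self.conv2.parameters() + self.bn2.parameters()
        if self.down_conv is not None:
            ps += self.down_conv.parameters() + self.down_bn.parameters()
        return ps


class TinyEncoder:
    """Reduced-width residual encoder: 3x3 stem, stages of width 16/32, GAP."""

    widths = (16, 32)

    def __init__(self, cfg: ModelConfig, rng):
        w1, w2 = self.widths
        self.stem = Conv2d(cfg.in_channels, w1, 3, rng, padding=1)
        self.bn = BatchNorm2d(w1)
        self.stage1 = BasicBlock(w1, w1, rng)
        self.stage2 = BasicBlock(w1, w2, rng, stride=2)
        self.fc = Linear(w2, cfg.embedding_dim, rng)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        h = self.bn(self.stem(x, train), train).relu()
        h = self.stage1(h, train)
        h = self.stage2(h, train)
        h = h.mean(axis=(2, 3))  # global average pool -> (B, width)
        return self.fc(h)

    def parameters(self):
        ps = self.stem.parameters() + self.bn.parameters()
        ps += self.stage1.parameters() + self.stage2.parameters()
        ps += self.fc.parameters()
        return ps


class ResNet18Encoder:
    """4-stage basic-block residual network (widths 64..512, two blocks each)."""

    def __init__(self, cfg: ModelConfig, rng):
        self.stem = Conv2d(cfg.in_channels, 64, 7, rng, stride=2, padding=3)
        self.bn = BatchNorm2d(64)
        self.blocks = []
        cin = 64
        for width, stride in ((64, 1), (128, 2), (256, 2), (512, 2)):
            self.blocks.append(BasicBlock(cin, width, rng, stride=stride))
            self.blocks.append(BasicBlock(width, width, rng))
            cin = width
        self.fc = Linear(512, cfg.embedding_dim, rng)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        h = self.bn(self.stem(x, train), train).relu()
        h = h.maxpool2d(2, 2)
        for blk in self.blocks:
            h = blk(h, train)
        h = h.mean(axis=(2, 3))
        return self.fc(h)

    def parameters(self):
        ps = self.stem.parameters() + self.bn.parameters()
        for blk in self.blocks:
            ps += blk.parameters()
        return ps + self.fc.parameters()


# ---------------------------------------------------------------------------
# Heads
# ---------------------------------------------------------------------------

class EuclideanHead:
    def __init__(self, cfg: ModelConfig, rng):
        self.linear = Linear(cfg.embedding_dim, cfg.n_classes, rng)

    def __call__(self, z: Tensor) -> Tensor:
        return self.linear(z)

    def parameters(self):
        return self.linear.parameters()


class LorentzHead:
    """Clip -> exp-map -> Lorentz multinomial-logistic decoder.

    Each class owns a direction vector ``z_c`` and an offset scalar ``r_c``
    defining a hyperbolic hyperplane through the Minkowski normal
    ``w_c = (||z_c|| tanh r_c, z_c)`` — the tanh reparameterisation keeps
    ``w_c`` spacelike (``<w_c,w_c>_L > 0``) for every real offset, so all
    head parameters are unconstrained Euclidean.  The logit is the signed
    hyperbolic distance to the hyperplane:

        logit_c(x) = (1/sqrt(k)) asinh( sqrt(k) <w_c, x>_L / ||w_c||_L ).
    """

    def __init__(self, cfg: ModelConfig, rng, log_k: Parameter):
        d, n = cfg.embedding_dim, cfg.n_classes
        self.directions = Parameter(
            rng.normal(0.0, 1.0 / math.sqrt(d), size=(n, d)), name="mlr_directions"
        )
        self.offsets = Parameter(np.zeros(n), name="mlr_offsets")
        self.log_k = log_k
        self.clip_radius = cfg.clip_radius

    def __call__(self, z: Tensor) -> Tensor:
        k = self.log_k.exp()
        sk = k**0.5
        # feature clipping: v = z * r / max(||z||, r)
        zn = ((z**2).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
        v = z * (self.clip_radius / zn.maximum(self.clip_radius))
        # exp-map at the origin
        vn = ((v**2).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
        t = vn * sk
        x0 = t.cosh() / sk                    # (B, 1)
        xs = v * (t.sinh() / t)               # (B, d); vn >= 1e-6 keeps t safe
        # hyperplane normals w_c = (a_c, z_c), a_c = ||z_c|| tanh r_c
        dn = ((self.directions**2).sum(axis=-1) + 1e-12) ** 0.5      # (n,)
        a = dn * self.offsets.tanh()                                  # (n,)
        w_lnorm = dn / self.offsets.cosh()                            # ||w||_L
        inner = xs @ self.directions.T - x0 * a.reshape(1, -1)        # <w, x>_L
        return (inner * (sk / w_lnorm.reshape(1, -1))).arcsinh() / sk

    def parameters(self):
        return [self.directions, self.offsets, self.log_k]


def euclidean_logits(z, head: EuclideanHead) -> np.ndarray:
    """Affine class scores ``W z + b`` for a batch of embeddings."""
    return head(as_tensor(z)).data


def lorentz_logits(z, head: LorentzHead, m: LorentzManifold) -> np.ndarray:
    """Lorentz MLR class scores for a batch of (pre-clip) embeddings."""
    head.log_k.data = np.asarray(math.log(m.k), dtype=np.float64)
    out = head(as_tensor(z)).data
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("lorentz_logits produced non-finite values")
    return out


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class ClassifierModel:
    """Encoder + geometry-specific head, with the Lorentz manifold attached."""

    def __init__(self, config: ModelConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        enc_rng = np.random.default_rng([seed, 0])
        head_rng = np.random.default_rng([seed, 1])
        enc_cls = TinyEncoder if config.encoder_scale == "tiny" else ResNet18Encoder
        self.encoder = enc_cls(config, enc_rng)
        if config.geometry == "lorentz":
            self.manifold = LorentzManifold(
                k=config.k_init, clip_radius=config.clip_radius, learnable_k=True
            )
            # curvature trains with a damped step: large k excursions are the
            # dominant instability of the hyperbolic head
            self.log_k = Parameter(np.asarray(math.log(config.k_init)), name="log_k",
                                   lr_scale=0.1)
            self.head = LorentzHead(config, head_rng, self.log_k)
        else:
            self.manifold = None
            self.log_k = None
            self.head = EuclideanHead(config, head_rng)

    @property
    def geometry(self) -> str:
        return self.config.geometry

    def parameters(self) -> list[Parameter]:
        return self.encoder.parameters() + self.head.parameters()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _check_images(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[:, None]
        c, s = self.config.in_channels, self.config.image_size
        if images.shape[1:] != (c, s, s):
            raise ValueError(
                f"expected images of shape (B, {c}, {s}, {s}), got {images.shape}"
            )
        return images

    def forward(self, images, train: bool = False) -> Tensor:
        """Full forward pass to class logits.  Accepts arrays or Tensors."""
        if isinstance(images, Tensor):
            x = images
        else:
            x = as_tensor(self._check_images(images))
        z = self.encoder(x, train)
        logits = self.head(z)
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError(
                f"{self.geometry} forward pass produced non-finite logits"
            )
        return logits

    def forward_embeddings(self, images) -> np.ndarray:
        """Penultimate features (pre-clip encoder output), eval mode."""
        x = as_tensor(self._check_images(images))
        return self.encoder(x, train=False).data

    def predict(self, images, batch_size: int = 256) -> np.ndarray:
        """Argmax class prediction in eval mode (lowest index wins ties)."""
        images = self._check_images(images)
        preds = []
        for lo in range(0, len(images), batch_size):
            logits = self.forward(images[lo:lo + batch_size]).data
            preds.append(np.argmax(logits, axis=1))
        return np.concatenate(preds) if preds else np.empty(0, dtype=int)

    def sync_manifold(self) -> None:
        """Copy the trained log-k scalar back into the manifold object."""
        if self.manifold is not None:
            self.manifold.log_k = float(self.log_k.data)


def build_model(config: ModelConfig, seed: int) -> ClassifierModel:
    """Build a classifier; encoders of both geometries built from the same
    seed are identical array-for-array (heads draw from a separate stream)."""
    return ClassifierModel(config, seed)


# ---------------------------------------------------------------------------
# Checkpoints: single .npz archive embedding weights + config + seed.
# ---------------------------------------------------------------------------

def save_checkpoint(model: ClassifierModel, path) -> None:
    meta = {
        "format_version": _CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "seed": model.seed,
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    bn_state = _batchnorm_states(model)
    arrays.update({f"bn_{i}_{k}": v for i, st in enumerate(bn_state) for k, v in st.items()})
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> ClassifierModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"].tolist()).decode())
        if meta["format_version"] != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        model = build_model(ModelConfig(**meta["config"]), meta["seed"])
        for i, p in enumerate(model.parameters()):
            p.data = z[f"param_{i}"]
        for i, bn in enumerate(_batchnorms(model)):
            bn.running_mean = z[f"bn_{i}_mean"]
            bn.running_var = z[f"bn_{i}_var"]
    model.sync_manifold()
    return model


def _batchnorms(model: ClassifierModel) -> list[BatchNorm2d]:
    found = []

    def scan(obj):
        if isinstance(obj, BatchNorm2d):
            found.append(obj)
            return
        for attr in ("stem", "bn", "bn1", "bn2", "conv1", "conv2", "down_bn",
                     "stage1", "stage2", "fc"):
            if hasattr(obj, attr) and getattr(obj, attr) is not None:
                scan(getattr(obj, attr))
        if hasattr(obj, "blocks"):
            for b in obj.blocks:
                scan(b)

    scan(model.encoder)
    return found


def _batchnorm_states(model: ClassifierModel):
    return [{"mean": bn.running_mean, "var": bn.running_var} for bn in _batchnorms(model)]
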