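"""Projected Gradient Descent (PGD) adversarial evaluation.

The attack maximises the classification cross-entropy by iterated
sign-gradient ascent, projecting after every step onto the sup-norm ball
of radius ``epsilon`` around the original images and clipping to the valid
pixel range.  ``epsilon = 0`` is the identity attack, giving the clean
accuracy row of a sweep.

Budget convention: :func:`robust_accuracy` takes epsilons on the **raw
[0, 1] pixel scale** (the convention of the adversarial literature, e.g.
8/255) and converts them to the model's normalised input scale internally;
:func:`pgd_attack` itself is agnostic — it perturbs whatever scale it is
handed.  Both published epsilon presets are provided — ``EPSILONS_COARSE``
(0.03, 0.06, 0.12) and ``EPSILONS_FINE`` (0.003, 0.006, 0.012) — and the
sweep is config-driven, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .models import ClassifierModel
from .training import cross_entropy_loss, topk_accuracy

__all__ = [
    "AttackConfig",
    "pgd_attack",
    "robust_accuracy",
    "EPSILONS_COARSE",
    "EPSILONS_FINE",
]

EPSILONS_COARSE = (0.03, 0.06, 0.12)
EPSILONS_FINE = (0.003, 0.006, 0.012)


@dataclass
class AttackConfig:
    """PGD hyperparameters.

    ``epsilon`` is the sup-norm budget; ``step_size`` defaults to
    ``epsilon / 4`` with 20 iterations and a random start inside the ball.
    ``pixel_range`` bounds the attacked inputs (set it to the normalised
    image of the raw pixel range; ``None`` disables range clipping).
    """

    epsilon: float
    step_size: float | None = None
    n_iter: int = 20
    random_start: bool = True
    pixel_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be nonnegative, got {self.epsilon}")
        if self.step_size is None:
            self.step_size = self.epsilon / 4.0
        if self.step_size > self.epsilon + 1e-12:
            raise ValueError("step_size must not exceed epsilon")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def _input_gradient(model: ClassifierModel, x: np.ndarray, labels: np.ndarray
                    ) -> np.ndarray:
    xt = Tensor(x, requires_grad=True)
    loss = cross_entropy_loss(model.forward(xt), labels)
    loss.backward()
    return xt.grad


def pgd_attack(model: ClassifierModel, images: np.ndarray, labels: np.ndarray,
               cfg: AttackConfig) -> np.ndarray:
    """Adversarial images within ``||x_adv - x||_inf <= epsilon``.

    ``images`` must already be on the model's input (normalised) scale.
    The model is used in eval mode; no parameters are modified.
    """
    x0 = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if cfg.epsilon == 0.0:
        return x0.copy()
    rng = np.random.default_rng(cfg.seed)
    if cfg.random_start:
        x = x0 + rng.uniform(-cfg.epsilon, cfg.epsilon, size=x0.shape)
    else:
        x = x0.copy()
    if cfg.pixel_range is not None:
        x = np.clip(x, *cfg.pixel_range)
    for _ in range(cfg.n_iter):
        g = _input_gradient(model, x, labels)
        x = x + cfg.step_size * np.sign(g)
        x = np.clip(x, x0 - cfg.epsilon, x0 + cfg.epsilon)
        if cfg.pixel_range is not None:
            x = np.clip(x, *cfg.pixel_range)
    assert np.max(np.abs(x - x0)) <= cfg.epsilon + 1e-6
    return x


def fgsm_reference(model: ClassifierModel, images: np.ndarray,
                   labels: np.ndarray, epsilon: float) -> np.ndarray:
    """Single-step sign-gradient attack (the n_iter=1, no-random-start PGD
    limit with step_size = epsilon); kept as an independent cross-check."""
    x0 = np.asarray(images, dtype=np.float64)
    g = _input_gradient(model, x0, labels)
    return x0 + epsilon * np.sign(g)


def robust_accuracy(model: ClassifierModel, dataset, sweep: list[AttackConfig],
                    batch_size: int = 64) -> pd.DataFrame:
    """Top-1/Top-5 accuracy under each attack of the sweep.

    ``dataset`` is ``(images, labels)`` on the raw [0, 1] pixel scale, and
    so are the sweep's epsilons/step sizes: images are normalised with the
    model's training statistics, budgets are divided by the normalisation
    sd, and each attack's ``pixel_range`` (if unset) becomes the image of
    [0, 1] under normalisation.  Rows are ordered by epsilon, reported on
    the raw scale.
    """
    if not sweep:
        raise ValueError("sweep must contain at least one AttackConfig")
    X, y = dataset
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    mean = getattr(model, "norm_mean", 0.0)
    sd = getattr(model, "norm_sd", 1.0)
    Xn = (X - mean) / sd
    default_range = ((0.0 - mean) / sd, (1.0 - mean) / sd)
    rows = []
    for cfg in sorted(sweep, key=lambda c: c.epsilon):
        scaled = AttackConfig(
            cfg.epsilon / sd, cfg.step_size / sd if cfg.step_size else None,
            cfg.n_iter, cfg.random_start,
            cfg.pixel_range if cfg.pixel_range is not None else default_range,
            cfg.seed,
        )
        logits = []
        for lo in range(0, len(Xn), batch_size):
            xa = pgd_attack(model, Xn[lo:lo + batch_size], y[lo:lo + batch_size],
                            scaled)
            logits.append(model.forward(xa).data)
        logits = np.concatenate(logits, axis=0)
        n_classes = logits.shape[1]
        rows.append({
            "epsilon": cfg.epsilon,
            "top1": topk_accuracy(logits, y, 1),
            "top5": topk_accuracy(logits, y, min(5, n_classes)),
        })
    return pd.DataFrame(rows)
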