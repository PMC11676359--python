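"""Lorentz (hyperboloid) model of hyperbolic space.

Points live on the upper sheet of the hyperboloid

    H^d_k = { x in R^{d+1} : <x, x>_L = -1/k,  x_0 > 0 },

where ``<x, y>_L = -x_0 y_0 + sum_{i>=1} x_i y_i`` is the Lorentz
(Minkowski) bilinear form and ``k > 0`` is the curvature magnitude.  The
coordinate convention is time-coordinate-first throughout the package.

All functions accept single vectors or batches (last axis is the
coordinate axis) and are plain float64 numpy; autodiff-traced versions of
the operations needed inside the classifier head live in
:mod:`lorentznet.models`.

Numerical safety choices (these matter — training instability is the
known failure mode of hyperbolic classifiers):

* the arccosh argument in the geodesic distance is floored at 1.0;
* ``sinh(t)/t`` uses a Taylor branch below ``t = 1e-6``;
* a learnable curvature is stored as ``log k`` so no gradient step can
  push ``k`` out of the positive domain.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "LorentzManifold",
    "lorentz_inner",
    "clip_features",
    "expmap0",
    "logmap0",
    "geodesic_distance",
    "project_to_hyperboloid",
]

_ON_MANIFOLD_TOL = 1e-4


def lorentz_inner(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lorentz bilinear form ``-x_0 y_0 + sum_{i>=1} x_i y_i``.

    Broadcasts over leading axes; the last axis is the coordinate axis.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError(
            f"dimension mismatch: {x.shape[-1]} vs {y.shape[-1]} coordinates"
        )
    if x.shape[-1] < 2:
        raise ValueError("Lorentz vectors need at least 2 coordinates")
    return -x[..., 0] * y[..., 0] + np.sum(x[..., 1:] * y[..., 1:], axis=-1)


def clip_features(v: np.ndarray, r: float) -> np.ndarray:
    """Rescale tangent features to Euclidean norm at most ``r``.

    ``v * min(1, r / ||v||)``: direction is preserved, zero maps to zero.
    This is the stabilising feature-clipping constraint applied before the
    exp-map (default radius 1.0 in the classifier).
    """
    if r <= 0:
        raise ValueError(f"clip radius must be positive, got {r}")
    v = np.asarray(v, dtype=np.float64)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    scale = np.where(norm > r, r / np.where(norm == 0, 1.0, norm), 1.0)
    return v * scale


def _sinhc(t: np.ndarray) -> np.ndarray:
    """sinh(t)/t with a Taylor branch for small t."""
    t = np.asarray(t, dtype=np.float64)
    small = np.abs(t) < 1e-6
    safe = np.where(small, 1.0, t)
    return np.where(small, 1.0 + t**2 / 6.0, np.sinh(safe) / safe)


class LorentzManifold:
    """Curvature-parameterised hyperboloid.

    Parameters
    ----------
    k:
        Positive curvature magnitude; the manifold satisfies
        ``<x, x>_L = -1/k``.
    clip_radius:
        Maximum tangent-feature norm admitted before the exp-map.
    learnable_k:
        Marks the curvature as trainable.  The trainable state is kept as
        ``log k`` (see :attr:`log_k`), so optimisation is unconstrained
        and ``k`` stays positive by construction.
    """

    def __init__(self, k: float = 1.0, clip_radius: float = 1.0,
                 learnable_k: bool = False):
        if k <= 0:
            raise ValueError(f"curvature magnitude k must be positive, got {k}")
        if clip_radius <= 0:
            raise ValueError(f"clip_radius must be positive, got {clip_radius}")
        self.log_k = math.log(k)
        self.clip_radius = float(clip_radius)
        self.learnable_k = bool(learnable_k)

    @property
    def k(self) -> float:
        return math.exp(self.log_k)

    @k.setter
    def k(self, value: float) -> None:
        if value <= 0:
            raise ValueError(f"curvature magnitude k must be positive, got {value}")
        self.log_k = math.log(value)

    def origin(self, d: int) -> np.ndarray:
        """The hyperboloid apex ``(1/sqrt(k), 0, ..., 0)`` with d space dims."""
        o = np.zeros(d + 1)
        o[0] = 1.0 / math.sqrt(self.k)
        return o

    def check_point(self, x: np.ndarray, tol: float = _ON_MANIFOLD_TOL) -> None:
        """Verify ``k <x,x>_L = -1`` up to float cancellation.

        The residual of the constraint is measured relative to ``k x_0^2``:
        far from the origin ``cosh^2 - sinh^2`` cancels catastrophically in
        float64, so an absolute tolerance would spuriously reject exact
        points.
        """
        x = np.asarray(x, dtype=np.float64)
        scale = np.maximum(1.0, self.k * x[..., 0] ** 2)
        err = np.abs(self.k * lorentz_inner(x, x) + 1.0) / scale
        if np.any(err > tol) or np.any(x[..., 0] <= 0):
            raise ValueError(
                "point is not on the hyperboloid "
                f"(max relative constraint violation {float(np.max(err)):.3e})"
            )

    def __repr__(self):  # pragma: no cover
        return f"LorentzManifold(k={self.k:.6g}, clip_radius={self.clip_radius})"


def expmap0(v: np.ndarray, m: LorentzManifold) -> np.ndarray:
    """Exponential map at the origin: tangent vector(s) -> hyperboloid point(s).

    For a tangent vector ``v`` (space components only; time component is
    implicitly zero at the origin) with ``t = sqrt(k) ||v||``:

        x_0 = cosh(t) / sqrt(k),   x_space = sinh(t) v / (sqrt(k) ||v||)

    so the geodesic distance from the origin to ``expmap0(v)`` equals
    ``||v||`` (radial isometry).
    """
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("expmap0 received non-finite tangent vector")
    sk = math.sqrt(m.k)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    t = sk * norm
    x0 = np.cosh(t) / sk
    xs = _sinhc(t) * v  # = sinh(t) v/(sk*norm), since sinh(t)/t * sk cancels
    return np.concatenate([x0, xs], axis=-1)


def logmap0(x: np.ndarray, m: LorentzManifold) -> np.ndarray:
    """Logarithm map at the origin (left inverse of :func:`expmap0`)."""
    x = np.asarray(x, dtype=np.float64)
    m.check_point(x)
    sk = math.sqrt(m.k)
    xs = x[..., 1:]
    norm = np.linalg.norm(xs, axis=-1, keepdims=True)
    t = np.arccosh(np.maximum(sk * x[..., :1], 1.0))  # sk*x0 = cosh(t)
    # v = (t / sk) * xs / ||xs||; guard the radial factor at the origin
    return np.where(norm > 0, t / (sk * np.where(norm == 0, 1.0, norm)), 1.0) * xs


def geodesic_distance(x: np.ndarray, y: np.ndarray, m: LorentzManifold,
                      check: bool = True) -> np.ndarray:
    """Geodesic distance on the hyperboloid.

    Mathematically ``(1/sqrt(k)) arccosh(-k <x,y>_L)`` with the arccosh
    argument floored at 1; computed here through the equivalent stable form

        d = (2/sqrt(k)) asinh( sqrt(k * <x-y, x-y>_L) / 2 ),

    which avoids the cancellation of the direct arccosh for nearby points
    (``<x-y, x-y>_L >= 0`` is the floored quantity) and returns exactly 0
    for identical points.
    """
    if check:
        m.check_point(x)
        m.check_point(y)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    s = np.maximum(lorentz_inner(x - y, x - y), 0.0)
    sk = math.sqrt(m.k)
    return 2.0 * np.arcsinh(0.5 * sk * np.sqrt(s)) / sk


def project_to_hyperboloid(u: np.ndarray, m: LorentzManifold) -> np.ndarray:
    """Restore the hyperboloid constraint by recomputing the time coordinate.

    Keeps the space components of ``u`` and sets
    ``x_0 = sqrt(1/k + ||space||^2)``; used after tangent averaging or to
    undo numerical drift.
    """
    u = np.asarray(u, dtype=np.float64)
    space = u[..., 1:]
    if not np.all(np.isfinite(space)):
        raise FloatingPointError("project_to_hyperboloid: non-finite space components")
    x0 = np.sqrt(1.0 / m.k + np.sum(space**2, axis=-1, keepdims=True))
    return np.concatenate([x0, space], axis=-1)


# ---------------------------------------------------------------------------
# Riemannian helpers used by the optimizer for manifold-attached parameters.
# ---------------------------------------------------------------------------

def egrad_to_rgrad(x: np.ndarray, egrad: np.ndarray, m: LorentzManifold) -> np.ndarray:
    """Euclidean gradient -> Riemannian gradient on the hyperboloid at x.

    Flip the time component (inverse metric) then project onto the tangent
    space: ``proj_x(u) = u + k <x, u>_L x``.
    """
    u = np.array(egrad, dtype=np.float64, copy=True)
    u[..., 0] *= -1.0
    return u + m.k * lorentz_inner(x, u)[..., None] * x


def expmap(x: np.ndarray, v: np.ndarray, m: LorentzManifold) -> np.ndarray:
    """Exponential map at an arbitrary point x (retraction for RSGD steps)."""
    sk = math.sqrt(m.k)
    vn = np.sqrt(np.maximum(lorentz_inner(v, v), 0.0))[..., None]
    t = sk * vn
    out = np.cosh(t) * x + _sinhc(t) * v
    return project_to_hyperboloid(out, m)
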