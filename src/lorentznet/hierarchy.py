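"""Embedding-organisation analysis: does a trained classifier arrange its
class centroids the way the known class taxonomy does?

Pipeline: per-class centroids of the penultimate embeddings -> pairwise
geodesic distance matrix in the model's own geometry -> comparison against
a ground-truth distance matrix built from the categorical class
descriptors.  Both matrices are normalised by their maximum off-diagonal
entry; agreement is summarised by the mean absolute pairwise difference
(with a bootstrap confidence interval over class-pair entries) and by
Spearman's rank correlation over the upper-triangle distances.  Two models
are compared by a Welch two-sample t-test on their per-pair absolute
difference vectors.  A dendrogram over the model distance matrix
(average-linkage agglomerative clustering) exposes the learned class tree.

Geometry conventions: Euclidean embeddings are averaged and compared with
L2 distances.  For the Lorentz model the stored embeddings are the
post-clip tangent features; centroids are taken as the tangent-space mean
and exp-mapped onto the hyperboloid, where geodesic distances are
measured.  (A Karcher/Frechet mean is available as an option but the
tangent mean is the deterministic default.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .lorentz import LorentzManifold, clip_features, expmap0, geodesic_distance, logmap0

__all__ = [
    "EmbeddingSet",
    "DistanceMatrix",
    "HierarchyAlignmentResult",
    "BootstrapConfig",
    "class_centroids",
    "model_distance_matrix",
    "ground_truth_matrix",
    "normalize_matrix",
    "mean_absolute_difference",
    "spearman_alignment",
    "compare_models_ttest",
    "dendrogram",
    "hierarchy_alignment",
]


@dataclass
class BootstrapConfig:
    n_resamples: int = 1000
    seed: int = 0
    level: float = 0.95

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must be in (0, 1)")


@dataclass
class EmbeddingSet:
    """Per-sample penultimate embeddings with labels and a geometry tag.

    For ``geometry='lorentz'`` the rows must be post-clip tangent features,
    so hyperbolic centroids and geodesic distances are recomputable.
    """

    matrix: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    geometry: str = "euclidean"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.matrix) != len(self.labels):
            raise ValueError("embedding row count must equal label count")

    @classmethod
    def from_model(cls, model, images, batch_size: int = 256) -> "EmbeddingSet":
        """Extract the canonical evaluation embeddings from a trained model.

        Images are normalised with the model's training statistics; for the
        Lorentz geometry the encoder output is clipped to the configured
        radius (the decoder's own input representation).
        """
        mean = getattr(model, "norm_mean", 0.0)
        sd = getattr(model, "norm_sd", 1.0)
        X = (np.asarray(images, dtype=np.float64) - mean) / sd
        chunks = [model.forward_embeddings(X[lo:lo + batch_size])
                  for lo in range(0, len(X), batch_size)]
        Z = np.concatenate(chunks, axis=0)
        if model.geometry == "lorentz":
            Z = clip_features(Z, model.config.clip_radius)
        return cls(Z, labels=np.zeros(len(Z), dtype=int), geometry=model.geometry)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative class-distance matrix with a provenance tag."""

    values: np.ndarray = field(repr=False)
    provenance: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric (tol 1e-9)")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < -1e-12):
            raise ValueError("distance matrix must be nonnegative")
        self.values = np.clip(v, 0.0, None)

    @property
    def n_classes(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_classes, k=1)
        return self.values[iu]


@dataclass
class HierarchyAlignmentResult:
    mad: float
    mad_ci: tuple[float, float]
    spearman_rho: float
    spearman_p: float

    def as_dict(self) -> dict:
        return {
            "mad": self.mad,
            "mad_ci": list(self.mad_ci),
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
        }


# ---------------------------------------------------------------------------
# Centroids and distance matrices
# ---------------------------------------------------------------------------

def class_centroids(emb: EmbeddingSet) -> np.ndarray:
    """Arithmetic per-class mean of the stored rows, ordered by class id.

    For Lorentz embeddings this is the tangent-space mean; distances are
    obtained by exp-mapping it in :func:`model_distance_matrix`.
    """
    classes = np.arange(emb.labels.max() + 1)
    missing = [int(c) for c in classes if not np.any(emb.labels == c)]
    if missing:
        raise ValueError(f"no samples for class ids {missing}")
    return np.stack([emb.matrix[emb.labels == c].mean(axis=0) for c in classes])


def frechet_centroids(emb: EmbeddingSet, m: LorentzManifold, n_iter: int = 20
                      ) -> np.ndarray:
    """Karcher-mean alternative for Lorentz embeddings (tangent rows).

    Iterates gradient steps of the squared-distance functional on the
    hyperboloid; returns tangent-space coordinates (log-map at the origin)
    so the result is interchangeable with :func:`class_centroids`.
    """
    tangent = class_centroids(emb)
    classes = np.arange(emb.labels.max() + 1)
    out = np.empty_like(tangent)
    for c in classes:
        pts = expmap0(emb.matrix[emb.labels == c], m)
        mu = expmap0(tangent[c], m)
        for _ in range(n_iter):
            vs = _log_at(mu, pts, m)
            step = vs.mean(axis=0)
            mu = _exp_at(mu, 0.5 * step, m)
        out[c] = logmap0(mu, m)
    return out


def _log_at(x, ys, m):
    # log map at x: v = d(x,y) * (y - alpha x) / ||y - alpha x||_L,
    # alpha = -k<x,y>_L, ||y - alpha x||_L = sqrt((alpha^2-1)/k).
    from .lorentz import lorentz_inner
    alpha = np.maximum(-m.k * lorentz_inner(x, ys), 1.0)[..., None]
    d = np.arccosh(alpha) / np.sqrt(m.k)
    u = ys - alpha * x
    un = np.sqrt(np.maximum((alpha**2 - 1.0) / m.k, 1e-30))
    return d * u / un


def _exp_at(x, v, m):
    from .lorentz import expmap
    return expmap(x, v, m)


def model_distance_matrix(centroids: np.ndarray, geometry: str,
                          m: LorentzManifold | None = None) -> DistanceMatrix:
    """Pairwise class-centroid distances in the model's geometry."""
    centroids = np.asarray(centroids, dtype=np.float64)
    if not np.all(np.isfinite(centroids)):
        raise ValueError("centroids must be finite")
    if geometry == "euclidean":
        if m is not None:
            raise ValueError("euclidean geometry takes no manifold")
        diff = centroids[:, None, :] - centroids[None, :, :]
        d = np.sqrt(np.sum(diff**2, axis=-1))
    elif geometry == "lorentz":
        if m is None:
            raise ValueError("lorentz geometry requires a manifold")
        pts = expmap0(centroids, m)
        d = geodesic_distance(pts[:, None, :], pts[None, :, :], m, check=False)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, provenance=geometry)


def ground_truth_matrix(descriptors: pd.DataFrame,
                        level_weights=None) -> DistanceMatrix:
    """Hierarchy distance from categorical descriptors.

    ``entry(i, j) = sum_l w_l * [descriptor of i and j differs at level l]``.
    Levels are the descriptor columns (class_id/class_name excluded),
    ordered coarsest first; default weights descend ``L, L-1, ..., 1`` so a
    modality mismatch costs more than a subtype mismatch.
    """
    cols = [c for c in descriptors.columns if c not in ("class_id", "class_name")]
    if not cols:
        raise ValueError("descriptor table has no level columns")
    if descriptors[cols].duplicated().any():
        dup = descriptors[descriptors[cols].duplicated(keep=False)]
        raise ValueError(f"duplicate descriptor rows for classes {list(dup.get('class_id', dup.index))}")
    if level_weights is None:
        level_weights = np.arange(len(cols), 0, -1, dtype=float)
    w = np.asarray(level_weights, dtype=np.float64)
    if len(w) != len(cols):
        raise ValueError(f"{len(w)} weights for {len(cols)} levels")
    if np.any(w < 0) or np.all(w == 0):
        raise ValueError("weights must be nonnegative and not all zero")
    if "class_id" in descriptors.columns:
        descriptors = descriptors.sort_values("class_id")
    vals = descriptors[cols].to_numpy()
    n = len(vals)
    d = np.zeros((n, n))
    for l, wl in enumerate(w):
        diff = vals[:, None, l] != vals[None, :, l]
        d += wl * diff
    return DistanceMatrix(d, provenance="ground_truth")


def normalize_matrix(D: DistanceMatrix) -> DistanceMatrix:
    """Divide by the maximum off-diagonal entry (idempotent)."""
    off_max = float(D.upper_triangle().max(initial=0.0))
    if off_max <= 0:
        raise ValueError("cannot normalize an all-zero distance matrix")
    return DistanceMatrix(D.values / off_max, provenance=D.provenance)


# ---------------------------------------------------------------------------
# Alignment statistics
# ---------------------------------------------------------------------------

def _pair_abs_diff(Dm: DistanceMatrix, Dg: DistanceMatrix) -> np.ndarray:
    if Dm.values.shape != Dg.values.shape:
        raise ValueError(
            f"shape mismatch {Dm.values.shape} vs {Dg.values.shape}"
        )
    return np.abs(Dm.upper_triangle() - Dg.upper_triangle())


def mean_absolute_difference(Dm: DistanceMatrix, Dg: DistanceMatrix,
                             boot: BootstrapConfig | None = None):
    """Mean |model - ground truth| over class pairs, with a bootstrap CI.

    Both matrices must already be normalised.  The bootstrap resamples the
    strict-upper-triangle class-pair entries with replacement
    (``n_resamples`` draws, percentile interval, seeded).
    """
    for D in (Dm, Dg):
        if abs(float(D.upper_triangle().max(initial=0.0)) - 1.0) > 1e-9:
            raise ValueError("matrices must be normalised (max off-diagonal = 1)")
    diffs = _pair_abs_diff(Dm, Dg)
    mad = float(diffs.mean())
    boot = boot or BootstrapConfig()
    rng = np.random.default_rng(boot.seed)
    idx = rng.integers(0, len(diffs), size=(boot.n_resamples, len(diffs)))
    means = diffs[idx].mean(axis=1)
    alpha = 100 * (1 - boot.level) / 2
    lo, hi = np.percentile(means, [alpha, 100 - alpha])
    return mad, (float(lo), float(hi))


def spearman_alignment(Dm: DistanceMatrix, Dg: DistanceMatrix):
    """Tie-corrected Spearman rank correlation over class-pair distances."""
    if Dm.n_classes < 3:
        raise ValueError("need at least 3 classes for a rank correlation")
    a, b = Dm.upper_triangle(), Dg.upper_triangle()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant distance vector")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def compare_models_ttest(diffs_a: np.ndarray, diffs_b: np.ndarray):
    """Welch two-sample t-test on per-pair absolute-difference vectors."""
    a = np.asarray(diffs_a, dtype=np.float64)
    b = np.asarray(diffs_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each vector needs at least 2 entries")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("degenerate t-test: both vectors have zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def dendrogram(centroids: np.ndarray, geometry: str,
               m: LorentzManifold | None = None) -> np.ndarray:
    """Average-linkage agglomerative merge table over the class distances.

    Returns the standard (n-1) x 4 linkage array (merged ids, height,
    cluster size).
    """
    D = model_distance_matrix(centroids, geometry, m)
    if D.n_classes < 2:
        raise ValueError("need at least 2 classes")
    return linkage(squareform(D.values, checks=False), method="average")


def hierarchy_alignment(emb: EmbeddingSet, descriptors: pd.DataFrame,
                        m: LorentzManifold | None = None,
                        level_weights=None,
                        boot: BootstrapConfig | None = None
                        ) -> HierarchyAlignmentResult:
    """End-to-end alignment of one model's embeddings with the taxonomy."""
    cents = class_centroids(emb)
    Dm = normalize_matrix(model_distance_matrix(cents, emb.geometry, m))
    Dg = normalize_matrix(ground_truth_matrix(descriptors, level_weights))
    mad, ci = mean_absolute_difference(Dm, Dg, boot)
    rho, p = spearman_alignment(Dm, Dg)
    return HierarchyAlignmentResult(mad, ci, rho, p)
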