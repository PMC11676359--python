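"""Synthetic hierarchical image data with a known class taxonomy.

Real multi-modality neuroimaging compilations organise their classes on an
implicit tree — modality first, then imaging sequence / disease category,
then disease and subtype.  This module generates image datasets with that
statistical structure made explicit and exactly known:

* a balanced :class:`ClassTaxonomy` over a configurable set of levels;
* per-class prototypes built additively from random spatial patterns shared
  by all classes under the same ancestor at each level (coarser levels get
  larger amplitudes, mirroring how modality separates images far more than
  disease subtype), plus a leaf-unique pattern;
* i.i.d. Gaussian pixel noise on top of the prototype;
* patient-series fixtures for the zero-shot setting: stacks of
  normal-class slices in which positive patients carry at least one slice
  from an *unseen* disease class (a localized perturbation of the normal
  prototype, emulating subtle ischemic findings on non-contrast CT);
* a single-slice binary cohort for the out-of-sample protocol.

Because the generating tree is known, downstream hierarchy-alignment
statistics have an exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .training import stratified_split

__all__ = [
    "ClassTaxonomy",
    "SyntheticSpec",
    "PatientSeries",
    "build_taxonomy",
    "generate_dataset",
    "generate_patient_cohort",
    "generate_binary_cohort",
    "taxonomy_ground_truth_labels",
    "write_dataset",
]

_DEFAULT_LEVELS = ("modality", "category", "disease", "subtype")

# Pixel model: gray = 0.5 + PIXEL_GAIN * (prototype + noise), clipped to [0, 1].
PIXEL_GAIN = 0.15


@dataclass
class ClassTaxonomy:
    """Tree of class descriptors; one leaf per class."""

    levels: list[str]
    leaves: list[dict]  # each: {"class_id", "name", "path", "descriptors"}

    @property
    def n_classes(self) -> int:
        return len(self.leaves)

    def descriptor_table(self) -> pd.DataFrame:
        rows = [{"class_id": lf["class_id"], "class_name": lf["name"],
                 **lf["descriptors"]} for lf in self.leaves]
        return pd.DataFrame(rows)


@dataclass
class SyntheticSpec:
    """Generator settings.

    ``level_amplitudes`` default to a geometric decay (coarsest level
    strongest), so the visual separation between branches shrinks with
    depth; ``leaf_amplitude`` continues the decay one step further.
    ``noise_sd`` is the per-pixel Gaussian noise standard deviation on the
    prototype scale.
    """

    image_size: int = 64
    n_per_class: int = 200
    level_amplitudes: list[float] | None = None
    leaf_amplitude: float | None = None
    noise_sd: float = 1.0
    seed: int = 0

    def resolve_amplitudes(self, n_levels: int) -> tuple[list[float], float]:
        amps = self.level_amplitudes
        if amps is None:
            amps = [1.0 * 0.5**l for l in range(n_levels)]
        if len(amps) != n_levels:
            raise ValueError(
                f"level_amplitudes has {len(amps)} entries for {n_levels} levels"
            )
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be >= 0")
        leaf = self.leaf_amplitude if self.leaf_amplitude is not None else 0.5 ** n_levels
        if leaf < 0:
            raise ValueError("leaf_amplitude must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        return list(amps), float(leaf)


@dataclass
class PatientSeries:
    """Ordered image stack for one synthetic patient."""

    patient_id: str
    images: np.ndarray = field(repr=False)      # (n_slices, 1, H, W)
    slice_positive: np.ndarray = field(repr=False)  # bool per slice

    @property
    def is_positive(self) -> bool:
        """Patient-level truth: any positive slice."""
        return bool(np.any(self.slice_positive))


def build_taxonomy(branching: list[int], seed: int = 0) -> ClassTaxonomy:
    """Balanced taxonomy with ``prod(branching)`` leaves.

    Level names come from (modality, category, disease, subtype) for up to
    four levels, then ``level5``, ``level6``...; descriptor values are
    stable strings derived from the path indices, so two leaves share a
    value at a level exactly when they share the ancestor at that level.
    """
    if len(branching) == 0:
        raise ValueError("branching must be non-empty")
    if any(b < 1 for b in branching):
        raise ValueError("branching factors must be >= 1")
    names = [_DEFAULT_LEVELS[i] if i < len(_DEFAULT_LEVELS) else f"level{i + 1}"
             for i in range(len(branching))]
    leaves = []
    paths = [()]
    for b in branching:
        paths = [p + (i,) for p in paths for i in range(b)]
    for cid, path in enumerate(paths):
        desc = {
            names[l]: f"{names[l]}_" + ".".join(str(i) for i in path[:l + 1])
            for l in range(len(branching))
        }
        leaves.append({
            "class_id": cid,
            "name": "class_" + "_".join(str(i) for i in path),
            "path": path,
            "descriptors": desc,
        })
    return ClassTaxonomy(levels=names, leaves=leaves)


def _random_field(H: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth, bilaterally symmetric random field with unit pixel variance.

    Gaussian-filtered white noise (correlation length H/8) mirrored about
    the vertical midline: anatomical patterns are spatially smooth and
    brains are roughly left-right symmetric, which also makes the class
    signal survive the rotation/flip augmentations applied in training.
    """
    from scipy.ndimage import gaussian_filter

    p = gaussian_filter(rng.standard_normal((H, H)), H / 8.0, mode="wrap")
    p = (p + p[:, ::-1]) / np.sqrt(2.0)
    return p / p.std()


def _prototypes(tax: ClassTaxonomy, spec: SyntheticSpec) -> np.ndarray:
    """(n_classes, H, W) additive level-pattern prototypes."""
    amps, leaf_amp = spec.resolve_amplitudes(len(tax.levels))
    H = spec.image_size
    rng = np.random.default_rng([spec.seed, 17])
    patterns: dict[tuple, np.ndarray] = {}
    protos = np.zeros((tax.n_classes, H, H))
    for lf in tax.leaves:
        path = lf["path"]
        for l in range(len(tax.levels)):
            key = ("lvl", l, path[:l + 1])
            if key not in patterns:
                patterns[key] = _random_field(H, rng)
            protos[lf["class_id"]] += amps[l] * patterns[key]
    # leaf-unique component, drawn after all level patterns for stability
    for lf in tax.leaves:
        protos[lf["class_id"]] += leaf_amp * _random_field(H, rng)
    return protos


def _to_pixels(raw: np.ndarray) -> np.ndarray:
    return np.clip(0.5 + PIXEL_GAIN * raw, 0.0, 1.0)


def generate_dataset(tax: ClassTaxonomy, spec: SyntheticSpec):
    """Generate ``(images, labels, manifest)`` for the taxonomy.

    ``images`` is (N, 1, H, W) float64 in [0, 1]; ``labels`` holds class
    ids; the manifest carries one row per image with its (synthetic) path,
    class id, per-level descriptors and a seeded stratified 80/10/10 split.
    """
    protos = _prototypes(tax, spec)
    rng = np.random.default_rng([spec.seed, 23])
    n, H = spec.n_per_class, spec.image_size
    images = np.empty((tax.n_classes * n, 1, H, H))
    labels = np.empty(tax.n_classes * n, dtype=int)
    rows = []
    for lf in tax.leaves:
        cid = lf["class_id"]
        noise = rng.normal(0.0, spec.noise_sd, size=(n, H, H))
        images[cid * n:(cid + 1) * n, 0] = _to_pixels(protos[cid] + noise)
        labels[cid * n:(cid + 1) * n] = cid
        for j in range(n):
            rows.append({
                "path": f"images/{lf['name']}/img_{cid:03d}_{j:05d}.png",
                "class_id": cid,
                **lf["descriptors"],
            })
    manifest = pd.DataFrame(rows)
    manifest["split"] = stratified_split(labels, seed=spec.seed)
    return images, labels, manifest


def _unseen_disease_slice(normal_proto: np.ndarray, spec: SyntheticSpec,
                          rng: np.random.Generator) -> np.ndarray:
    """A positive slice: normal prototype + localized blob + noise.

    The blob is a Gaussian bump at a random location — a disease signature
    never present in the training classes, emulating a subtle acute finding
    on an otherwise normal scan.
    """
    H = spec.image_size
    cy, cx = rng.uniform(0.25 * H, 0.75 * H, size=2)
    yy, xx = np.mgrid[0:H, 0:H]
    # sigma H/6, amplitude 2.5x noise sd: subtle enough that detection is
    # imperfect (the clinical reading of these scans is itself ~50% sensitive)
    sigma = H / 6.0
    blob = 2.5 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    raw = normal_proto + blob + rng.normal(0.0, spec.noise_sd, size=(H, H))
    return _to_pixels(raw)


def generate_patient_cohort(n_patients: int, slices_per_patient: int,
                            positive_fraction: float, tax: ClassTaxonomy,
                            spec: SyntheticSpec, normal_class: int = 0
                            ) -> list[PatientSeries]:
    """Synthetic patient series for the zero-shot protocol.

    Every slice of a negative patient comes from the trained normal class;
    a positive patient additionally carries at least one slice from the
    unseen disease (localized perturbation of the normal prototype).
    Reproducible from ``spec.seed``.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must be in [0, 1]")
    protos = _prototypes(tax, spec)
    normal_proto = protos[normal_class]
    rng = np.random.default_rng([spec.seed, 31])
    n_positive = int(round(positive_fraction * n_patients))
    H = spec.image_size
    cohort = []
    for p in range(n_patients):
        is_pos = p < n_positive
        flags = np.zeros(slices_per_patient, dtype=bool)
        if is_pos:
            n_pos_slices = 1 + rng.binomial(slices_per_patient - 1, 0.25)
            pos_idx = rng.choice(slices_per_patient, size=n_pos_slices, replace=False)
            flags[pos_idx] = True
        imgs = np.empty((slices_per_patient, 1, H, H))
        for s in range(slices_per_patient):
            if flags[s]:
                imgs[s, 0] = _unseen_disease_slice(normal_proto, spec, rng)
            else:
                raw = normal_proto + rng.normal(0.0, spec.noise_sd, size=(H, H))
                imgs[s, 0] = _to_pixels(raw)
        cohort.append(PatientSeries(f"patient_{p:04d}", imgs, flags))
    return cohort


def generate_binary_cohort(n_subjects: int, n_positive: int, tax: ClassTaxonomy,
                           spec: SyntheticSpec, positive_class: int,
                           negative_class: int = 0):
    """Single-slice out-of-sample cohort: (images, truth_flags).

    Each subject contributes one image; ``n_positive`` subjects draw it
    from ``positive_class`` (a trained disease class), the rest from the
    normal ``negative_class``.  Mirrors a cross-sectional single-slice
    screening cohort (e.g. 436 subjects, 40 positive / 396 negative).
    """
    if not 0 <= n_positive <= n_subjects:
        raise ValueError("n_positive must be between 0 and n_subjects")
    protos = _prototypes(tax, spec)
    rng = np.random.default_rng([spec.seed, 41])
    H = spec.image_size
    images = np.empty((n_subjects, 1, H, H))
    truth = np.zeros(n_subjects, dtype=bool)
    truth[:n_positive] = True
    for i in range(n_subjects):
        proto = protos[positive_class] if truth[i] else protos[negative_class]
        images[i, 0] = _to_pixels(proto + rng.normal(0.0, spec.noise_sd, size=(H, H)))
    return images, truth


def taxonomy_ground_truth_labels(tax: ClassTaxonomy) -> pd.DataFrame:
    """One row per class with its categorical descriptor per level."""
    return tax.descriptor_table()


def write_dataset(images: np.ndarray, manifest: pd.DataFrame, outdir) -> None:
    """Write images as 8-bit grayscale PNGs plus ``manifest.csv``."""
    from pathlib import Path

    from PIL import Image

    outdir = Path(outdir)
    for img, path in zip(images, manifest["path"]):
        target = outdir / path
        target.parent.mkdir(parents=True, exist_ok=True)
        arr = np.clip(img[0] * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(target)
    manifest.to_csv(outdir / "manifest.csv", index=False)
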