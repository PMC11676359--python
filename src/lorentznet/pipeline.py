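"""Manifest I/O, experiment orchestration and report generation.

A dataset is described by a manifest CSV with one row per image:
``path, class_id, <one column per taxonomy level>, [patient_id],
[slice_positive], split``.  Validation is total — a manifest that loads
never fails downstream on schema grounds — and reports *every* violation,
not just the first.

``run_experiment`` ties the stages together: synthetic data generation,
training of both geometries from a shared encoder seed, clean evaluation,
hierarchy alignment, the PGD sweep, and the zero-shot patient protocol.
Every report embeds the fully resolved configuration and all derived
seeds; the global seed fans out to per-stage seeds as ``seed + stage
index`` so each stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import hierarchy as H
from . import generalization as G
from .models import ModelConfig, build_model, save_checkpoint
from .robustness import AttackConfig, robust_accuracy
from .synthetic import (SyntheticSpec, build_taxonomy, generate_dataset,
                        generate_patient_cohort, taxonomy_ground_truth_labels)
from .training import TrainConfig, evaluate, train

__all__ = [
    "DatasetManifest",
    "ExperimentConfig",
    "load_manifest",
    "summarize_manifest",
    "reference_composition",
    "composition_to_manifest",
    "run_experiment",
    "directional_study",
]

_REQUIRED_COLUMNS = ("path", "class_id", "split")
_SPLITS = {"train", "val", "test"}

# Stage indices for the seed fan-out (global_seed + index).
STAGE_SEEDS = {
    "generate": 0,
    "train_euclidean": 1,
    "train_lorentz": 2,
    "hierarchy_bootstrap": 3,
    "attack": 4,
    "zeroshot": 5,
}


@dataclass
class DatasetManifest:
    """Validated per-image manifest plus descriptor bookkeeping."""

    table: pd.DataFrame = field(repr=False)
    level_columns: list[str] = field(default_factory=list)

    @property
    def n_images(self) -> int:
        return len(self.table)

    @property
    def n_classes(self) -> int:
        return int(self.table["class_id"].nunique())

    def per_class_counts(self) -> pd.Series:
        return self.table["class_id"].value_counts().sort_index()

    def split(self, name: str) -> pd.DataFrame:
        return self.table[self.table["split"] == name]


def _validate_manifest(df: pd.DataFrame) -> list[str]:
    errors = []
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            errors.append(f"missing required column '{col}'")
    if errors:
        return errors
    dups = df["path"][df["path"].duplicated()]
    for p in dups.unique():
        errors.append(f"duplicate path '{p}'")
    bad_splits = sorted(set(df["split"].unique()) - _SPLITS)
    for s in bad_splits:
        errors.append(f"unknown split value '{s}' (expected one of {sorted(_SPLITS)})")
    if df["class_id"].isna().any():
        errors.append("class_id contains missing values")
    if "slice_positive" in df.columns:
        vals = set(pd.unique(df["slice_positive"].dropna()))
        if not vals <= {0, 1, True, False}:
            errors.append(f"slice_positive must be boolean/0-1, found {sorted(map(str, vals))}")
    return errors


def load_manifest(path) -> DatasetManifest:
    """Read and fully validate a manifest CSV (all violations reported)."""
    df = pd.read_csv(path)
    errors = _validate_manifest(df)
    if errors:
        raise ValueError(
            f"invalid manifest {path}: " + "; ".join(errors)
        )
    reserved = set(_REQUIRED_COLUMNS) | {"patient_id", "slice_positive", "class_name"}
    levels = [c for c in df.columns if c not in reserved]
    return DatasetManifest(df, level_columns=levels)


def summarize_manifest(m: DatasetManifest) -> dict:
    """Totals and per-class counts (per-class counts always sum to total)."""
    counts = m.per_class_counts()
    return {
        "n_images": int(counts.sum()),
        "n_classes": int(len(counts)),
        "per_class_counts": {int(k): int(v) for k, v in counts.items()},
        "per_split_counts": {s: int((m.table["split"] == s).sum()) for s in sorted(_SPLITS)},
    }


def reference_composition(name: str = "mmn") -> pd.DataFrame:
    """Class composition table of a reference compilation (class, count)."""
    fname = f"{name}_composition.csv"
    with resources.files("lorentznet.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


def composition_to_manifest(composition: pd.DataFrame) -> DatasetManifest:
    """Expand a (class_name, images) composition into a per-image manifest.

    Paths are synthesised; all rows land in the train split.  This turns a
    published dataset-composition table into something the bookkeeping
    operations can audit (class counts, totals).
    """
    rows = []
    for cid, rec in enumerate(composition.itertuples(index=False)):
        for j in range(int(rec.images)):
            rows.append({
                "path": f"images/{cid:03d}/{j:06d}.png",
                "class_id": cid,
                "class_label": rec.class_name,
                "split": "train",
            })
    df = pd.DataFrame(rows)
    errors = _validate_manifest(df)
    if errors:  # pragma: no cover - construction guarantees validity
        raise ValueError("; ".join(errors))
    return DatasetManifest(df, level_columns=["class_label"])


# ---------------------------------------------------------------------------
# Experiment orchestration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Everything needed for a full two-geometry comparison run.

    ``lorentz_epoch_multiplier`` reflects the slower convergence of the
    hyperbolic head: the Lorentz model trains for ``epochs * multiplier``
    epochs under otherwise identical hyperparameters.
    """

    branching: list[int] = field(default_factory=lambda: [3, 2, 2])
    image_size: int = 16
    n_per_class: int = 60
    noise_sd: float = 1.0
    encoder_scale: str = "tiny"
    clip_radius: float = 1.0
    k_init: float = 1.0
    epochs: int = 15
    lorentz_epoch_multiplier: int = 2
    batch_size: int = 64
    learning_rate: float = 0.05
    momentum: float = 0.9
    rotation_degrees: float = 10.0
    flip_prob: float = 0.5
    attack_epsilons: list[float] = field(default_factory=lambda: [0.03, 0.06, 0.12])
    attack_iters: int = 20
    n_patients: int = 30
    slices_per_patient: int = 8
    positive_fraction: float = 0.5
    bootstrap_n: int = 1000
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _train_one(geometry, cfg: ExperimentConfig, data, n_classes):
    mcfg = ModelConfig(
        geometry=geometry, n_classes=n_classes, encoder_scale=cfg.encoder_scale,
        clip_radius=cfg.clip_radius, k_init=cfg.k_init, image_size=cfg.image_size,
    )
    model = build_model(mcfg, seed=cfg.seed)
    epochs = cfg.epochs * (cfg.lorentz_epoch_multiplier if geometry == "lorentz" else 1)
    tcfg = TrainConfig(
        epochs=epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, momentum=cfg.momentum,
        rotation_degrees=cfg.rotation_degrees, flip_prob=cfg.flip_prob,
        seed=cfg.seed + STAGE_SEEDS[f"train_{geometry}"],
    )
    return train(model, data, tcfg)


def directional_study(base_cfg: ExperimentConfig | None = None, n_seeds: int = 10,
                      base_seed: int = 0, attack_subset: int = 48) -> pd.DataFrame:
    """Multi-seed two-geometry comparison: the package's desk-scale analogue
    of the full-dataset study.

    For each seed: fresh synthetic dataset, both models trained from a
    shared encoder initialisation, then per-geometry validation Top-1,
    hierarchy alignment (MAD and Spearman rho against the taxonomy ground
    truth) and PGD robust Top-1 at the middle epsilon of the sweep on a
    fixed-size validation subset.  Returns one row per (seed, geometry).
    """
    from dataclasses import replace

    cfg0 = base_cfg or ExperimentConfig()
    rows = []
    for s in range(n_seeds):
        cfg = replace(cfg0, seed=base_seed + 1000 * s)
        tax = build_taxonomy(cfg.branching)
        spec = SyntheticSpec(image_size=cfg.image_size, n_per_class=cfg.n_per_class,
                             noise_sd=cfg.noise_sd,
                             seed=cfg.seed + STAGE_SEEDS["generate"])
        images, labels, manifest = generate_dataset(tax, spec)
        split = manifest["split"].to_numpy()
        data = {"train": (images[split == "train"], labels[split == "train"]),
                "val": (images[split == "val"], labels[split == "val"])}
        descriptors = taxonomy_ground_truth_labels(tax)
        Dg = H.normalize_matrix(H.ground_truth_matrix(descriptors))
        mid_eps = sorted(cfg.attack_epsilons)[len(cfg.attack_epsilons) // 2]
        rng = np.random.default_rng(cfg.seed + STAGE_SEEDS["attack"])
        vx, vy = data["val"]
        sub = rng.permutation(len(vx))[:attack_subset]
        for geometry in ("euclidean", "lorentz"):
            model, _ = _train_one(geometry, cfg, data, tax.n_classes)
            rep = evaluate(model, data["val"])
            emb = H.EmbeddingSet.from_model(model, images)
            emb.labels = labels
            Dm = H.normalize_matrix(H.model_distance_matrix(
                H.class_centroids(emb), geometry,
                model.manifold if geometry == "lorentz" else None))
            mad = float(np.abs(Dm.upper_triangle() - Dg.upper_triangle()).mean())
            rho, _ = H.spearman_alignment(Dm, Dg)
            atk = AttackConfig(mid_eps, n_iter=cfg.attack_iters,
                               seed=cfg.seed + STAGE_SEEDS["attack"])
            robust = robust_accuracy(model, (vx[sub], vy[sub]), [atk])
            rows.append({
                "seed": cfg.seed, "geometry": geometry,
                "val_top1": rep.top1, "val_top5": rep.top5,
                "mad": mad, "spearman_rho": rho,
                "robust_top1_mid_eps": float(robust["top1"].iloc[0]),
                "mid_epsilon": mid_eps,
            })
    return pd.DataFrame(rows)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Generate -> train both geometries -> evaluate -> hierarchy ->
    robustness -> zero-shot; returns (and optionally writes) the report."""
    report: dict = {"config": asdict(cfg), "seeds": {
        name: cfg.seed + off for name, off in STAGE_SEEDS.items()
    }}
    stage = "generate"
    try:
        # --- data ---------------------------------------------------------
        tax = build_taxonomy(cfg.branching)
        spec = SyntheticSpec(
            image_size=cfg.image_size, n_per_class=cfg.n_per_class,
            noise_sd=cfg.noise_sd, seed=cfg.seed + STAGE_SEEDS["generate"],
        )
        images, labels, manifest = generate_dataset(tax, spec)
        split = manifest["split"].to_numpy()
        data = {
            "train": (images[split == "train"], labels[split == "train"]),
            "val": (images[split == "val"], labels[split == "val"]),
        }
        test = (images[split == "test"], labels[split == "test"])
        descriptors = taxonomy_ground_truth_labels(tax)
        report["dataset"] = {
            "n_classes": tax.n_classes, "n_images": len(images),
            "levels": tax.levels,
        }

        # --- training + clean metrics --------------------------------------
        models, stage = {}, "train"
        for geometry in ("euclidean", "lorentz"):
            stage = f"train_{geometry}"
            model, log = _train_one(geometry, cfg, data, tax.n_classes)
            models[geometry] = model
            report[geometry] = {
                "train_log": log,
                "val": evaluate(model, data["val"]).as_dict(),
                "test": evaluate(model, test).as_dict(),
            }
            if geometry == "lorentz":
                report[geometry]["curvature_k"] = model.manifold.k

        # --- hierarchy alignment -------------------------------------------
        stage = "hierarchy"
        boot = H.BootstrapConfig(n_resamples=cfg.bootstrap_n,
                                 seed=cfg.seed + STAGE_SEEDS["hierarchy_bootstrap"])
        Dg = H.normalize_matrix(H.ground_truth_matrix(descriptors))
        pair_diffs = {}
        for geometry, model in models.items():
            # centroids over the full dataset: the embedding-space analysis
            # averages every image of a class, not a held-out subset
            emb = H.EmbeddingSet.from_model(model, images)
            emb.labels = labels
            cents = H.class_centroids(emb)
            Dm = H.normalize_matrix(H.model_distance_matrix(
                cents, geometry, models["lorentz"].manifold if geometry == "lorentz" else None))
            mad, ci = H.mean_absolute_difference(Dm, Dg, boot)
            rho, p = H.spearman_alignment(Dm, Dg)
            pair_diffs[geometry] = np.abs(Dm.upper_triangle() - Dg.upper_triangle())
            report[geometry]["hierarchy"] = H.HierarchyAlignmentResult(
                mad, ci, rho, p).as_dict()
            merges = H.dendrogram(
                cents, geometry,
                models["lorentz"].manifold if geometry == "lorentz" else None)
            report[geometry]["dendrogram"] = merges.tolist()
        t, p = H.compare_models_ttest(pair_diffs["euclidean"], pair_diffs["lorentz"])
        report["hierarchy_ttest"] = {"t": t, "p": p}

        # --- adversarial robustness ----------------------------------------
        stage = "attack"
        sweep = [AttackConfig(e, n_iter=cfg.attack_iters,
                              seed=cfg.seed + STAGE_SEEDS["attack"])
                 for e in cfg.attack_epsilons]
        for geometry, model in models.items():
            table = robust_accuracy(model, data["val"], sweep)
            report[geometry]["robustness"] = table.to_dict(orient="records")

        # --- zero-shot patient protocol ------------------------------------
        stage = "zeroshot"
        # the cohort shares the dataset spec: its normal class must be the
        # class the models were trained on (slice noise draws use their own
        # stream, so the cohort is still disjoint from the training images)
        cohort = generate_patient_cohort(
            cfg.n_patients, cfg.slices_per_patient, cfg.positive_fraction, tax, spec)
        # positive outcome := any non-normal class; negative := the normal class
        mapping = G.ClassMapping(
            positive_classes=frozenset(range(1, tax.n_classes)),
            negative_classes=frozenset({0}),
        )
        all_imgs = np.concatenate([s.images for s in cohort])
        truth = np.concatenate([s.slice_positive for s in cohort])
        for geometry, model in models.items():
            preds = _predict_normalized(model, all_imgs)
            n_id, rate = G.patient_identification_rate(cohort, preds, mapping)
            report[geometry]["zeroshot"] = {
                "patients_identified": n_id,
                "n_patients": len(cohort),
                "patient_rate": rate,
                "image_accuracy": G.zero_shot_image_accuracy(preds, truth, mapping),
            }
    except Exception as err:
        err.args = (f"experiment failed at stage '{stage}': {err}",)
        if cfg.output_dir:
            _write_report(report, cfg.output_dir, partial=True)
        raise

    if cfg.output_dir:
        _write_report(report, cfg.output_dir)
        for geometry, model in models.items():
            save_checkpoint(model, Path(cfg.output_dir) / f"model_{geometry}.npz")
    return report


def _predict_normalized(model, images, batch_size: int = 256):
    X = (np.asarray(images, dtype=np.float64) - model.norm_mean) / model.norm_sd
    preds = []
    for lo in range(0, len(X), batch_size):
        preds.append(np.argmax(model.forward(X[lo:lo + batch_size]).data, axis=1))
    return np.concatenate(preds)


def _write_report(report: dict, outdir, partial: bool = False) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = "report_partial.json" if partial else "report.json"
    with open(outdir / name, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    rows = []
    for geometry in ("euclidean", "lorentz"):
        section = report.get(geometry, {})
        for rec in section.get("robustness", []):
            rows.append({"model": geometry, **rec})
        if "train_log" in section:
            with open(outdir / f"train_log_{geometry}.jsonl", "w") as fh:
                for entry in section["train_log"]:
                    fh.write(json.dumps(entry) + "\n")
        if "dendrogram" in section:
            pd.DataFrame(
                section["dendrogram"],
                columns=["merge_a", "merge_b", "height", "cluster_size"],
            ).to_csv(outdir / f"dendrogram_{geometry}.csv", index=False)
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "robustness.csv", index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
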