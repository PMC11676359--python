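"""Out-of-sample and zero-shot evaluation rules.

A multi-class classifier is scored on a binary clinical question by
mapping its predicted classes to positive / negative outcomes:

* subject-level accuracy on a single-slice cohort (out-of-sample rule);
* image-level zero-shot accuracy: (TP + TN) / N, where a true positive is
  a truth-positive image predicted into a positive class and a true
  negative a truth-negative image predicted into a negative class;
* patient-level identification: a patient counts as identified when at
  least one of their truth-positive slices is predicted into a positive
  class (rates displayed to two decimals, e.g. 62/151 -> 0.41).

Uncertainty comes from a seeded percentile bootstrap (1000 resamples by
default); the resampling unit is subjects/patients for cohort metrics and
images for image metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import PatientSeries

__all__ = [
    "ClassMapping",
    "BootstrapConfig",
    "binary_outcome_accuracy",
    "zero_shot_image_accuracy",
    "patient_identification_rate",
    "bootstrap_ci",
]


@dataclass
class ClassMapping:
    """Class-id sets defining the binary outcome.

    Predictions landing in neither set follow ``unmapped``:
    ``count_as_error`` (default) or ``exclude``.
    """

    positive_classes: frozenset = field(default_factory=frozenset)
    negative_classes: frozenset = field(default_factory=frozenset)
    unmapped: str = "count_as_error"

    def __post_init__(self):
        self.positive_classes = frozenset(self.positive_classes)
        self.negative_classes = frozenset(self.negative_classes)
        if self.positive_classes & self.negative_classes:
            raise ValueError(
                "positive and negative class sets overlap: "
                f"{sorted(self.positive_classes & self.negative_classes)}"
            )
        if self.unmapped not in ("count_as_error", "exclude"):
            raise ValueError(f"unknown unmapped policy {self.unmapped!r}")

    def outcome(self, predicted_classes: np.ndarray) -> np.ndarray:
        """Map predictions to +1 (positive), 0 (negative), -1 (unmapped)."""
        preds = np.asarray(predicted_classes)
        out = np.full(len(preds), -1, dtype=int)
        out[np.isin(preds, list(self.positive_classes))] = 1
        out[np.isin(preds, list(self.negative_classes))] = 0
        return out

    @classmethod
    def from_yaml(cls, path) -> "ClassMapping":
        """Load a mapping from YAML: keys ``positive``, ``negative``,
        optional ``unmapped`` (class-id lists)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(frozenset(raw.get("positive", ())),
                   frozenset(raw.get("negative", ())),
                   raw.get("unmapped", "count_as_error"))


@dataclass
class BootstrapConfig:
    n_resamples: int = 1000
    seed: int = 0
    level: float = 0.95

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")


def bootstrap_ci(values: np.ndarray, statistic, cfg: BootstrapConfig | None = None):
    """Seeded percentile bootstrap interval of ``statistic`` over ``values``."""
    values = np.asarray(values)
    if len(values) == 0:
        raise ValueError("cannot bootstrap an empty vector")
    cfg = cfg or BootstrapConfig()
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, len(values), size=(cfg.n_resamples, len(values)))
    stats = np.array([statistic(values[row]) for row in idx])
    alpha = 100 * (1 - cfg.level) / 2
    lo, hi = np.percentile(stats, [alpha, 100 - alpha])
    return float(lo), float(hi)


def binary_outcome_accuracy(predicted_classes, true_flags, mapping: ClassMapping,
                            boot: BootstrapConfig | None = None):
    """Subject-level accuracy of mapped predictions against binary truth.

    Returns ``(accuracy, (ci_lo, ci_hi))``; the bootstrap resamples
    subjects.  Under ``count_as_error`` an unmapped prediction is wrong
    regardless of truth; under ``exclude`` such subjects are dropped from
    numerator and denominator (of every resample too).
    """
    preds = np.asarray(predicted_classes)
    truth = np.asarray(true_flags, dtype=bool)
    if len(preds) != len(truth):
        raise ValueError("predictions and truth flags differ in length")
    outcome = mapping.outcome(preds)
    correct = (outcome == truth.astype(int)).astype(float)
    if mapping.unmapped == "exclude":
        keep = outcome >= 0
        correct = correct[keep]
        if len(correct) == 0:
            raise ValueError("all predictions unmapped under 'exclude' policy")
    acc = float(correct.mean())
    ci = bootstrap_ci(correct, np.mean, boot)
    return acc, ci


def zero_shot_image_accuracy(per_image_preds, per_image_truth,
                             mapping: ClassMapping) -> float:
    """(TP + TN) / N over all images."""
    preds = np.asarray(per_image_preds)
    truth = np.asarray(per_image_truth, dtype=bool)
    if len(preds) != len(truth):
        raise ValueError("predictions and truth flags differ in length")
    outcome = mapping.outcome(preds)
    tp = int(np.sum(truth & (outcome == 1)))
    tn = int(np.sum(~truth & (outcome == 0)))
    return (tp + tn) / len(preds)


def patient_identification_rate(series: list[PatientSeries], per_image_preds,
                                mapping: ClassMapping):
    """Patients with >= 1 truth-positive slice predicted positive.

    ``per_image_preds`` maps each patient id to that patient's per-slice
    predicted classes (dict), or is a flat array covering all series in
    order.  Returns ``(identified_count, rate)`` with the rate rounded to
    two decimals (display convention of the zero-shot protocol).
    """
    if isinstance(per_image_preds, dict):
        missing = [s.patient_id for s in series if s.patient_id not in per_image_preds]
        if missing:
            raise ValueError(f"missing predictions for patients {missing}")
        per_patient = [np.asarray(per_image_preds[s.patient_id]) for s in series]
    else:
        flat = np.asarray(per_image_preds)
        total = sum(len(s.slice_positive) for s in series)
        if len(flat) != total:
            raise ValueError(
                f"flat prediction vector has {len(flat)} entries for {total} slices"
            )
        per_patient, lo = [], 0
        for s in series:
            per_patient.append(flat[lo:lo + len(s.slice_positive)])
            lo += len(s.slice_positive)
    identified = 0
    for s, preds in zip(series, per_patient):
        if len(preds) != len(s.slice_positive):
            raise ValueError(f"prediction count mismatch for {s.patient_id}")
        outcome = mapping.outcome(preds)
        if np.any(s.slice_positive & (outcome == 1)):
            identified += 1
    rate = round(identified / len(series), 2) if series else 0.0
    return identified, rate


def identification_overlap(identified_by: dict[str, set], all_patients) -> "object":
    """Overlap summary across evaluators (models, readers).

    ``identified_by`` maps an evaluator name to the set of patient ids it
    identified.  Returns a DataFrame with one row per evaluator (count
    identified) plus a ``none`` row: patients no evaluator identified.
    """
    import pandas as pd

    all_patients = set(all_patients)
    rows = [{"evaluator": name, "identified": len(set(ids) & all_patients)}
            for name, ids in identified_by.items()]
    caught = set().union(*identified_by.values()) if identified_by else set()
    rows.append({"evaluator": "none", "identified": len(all_patients - caught)})
    return pd.DataFrame(rows)
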