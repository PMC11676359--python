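"""Out-of-sample and zero-shot rules: mappings, rates, bootstrap."""

import numpy as np
import pytest

from lorentznet.generalization import (BootstrapConfig, ClassMapping,
                                       binary_outcome_accuracy, bootstrap_ci,
                                       patient_identification_rate,
                                       zero_shot_image_accuracy)
from lorentznet.synthetic import PatientSeries

POS = frozenset({1, 2})
NEG = frozenset({0})
MAPPING = ClassMapping(POS, NEG)


def make_series(pid, preds_flags):
    flags = np.array([f for _, f in preds_flags], dtype=bool)
    imgs = np.zeros((len(flags), 1, 2, 2))
    return PatientSeries(pid, imgs, flags), np.array([p for p, _ in preds_flags])


class TestClassMapping:
    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ClassMapping({1, 2}, {2, 3})

    def test_outcome_coding(self):
        out = MAPPING.outcome(np.array([0, 1, 2, 7]))
        np.testing.assert_array_equal(out, [0, 1, 1, -1])


class TestBinaryOutcomeAccuracy:
    def test_all_correct_gives_one_with_degenerate_ci(self):
        preds = np.array([1, 2, 0, 0])
        truth = np.array([True, True, False, False])
        acc, ci = binary_outcome_accuracy(preds, truth, MAPPING,
                                          BootstrapConfig(seed=0))
        assert acc == 1.0 and ci == (1.0, 1.0)

    def test_always_negative_predictor_on_40_of_436_positive_cohort(self):
        # 436 subjects, 40 positive: the constant-negative rule scores 396/436
        truth = np.zeros(436, dtype=bool)
        truth[:40] = True
        preds = np.zeros(436, dtype=int)  # always the normal class
        acc, _ = binary_outcome_accuracy(preds, truth, MAPPING,
                                         BootstrapConfig(seed=1))
        assert abs(acc - 396 / 436) < 1e-12
        assert round(acc, 3) == 0.908

    def test_hand_counted_toy(self):
        preds = np.array([1, 0, 2, 0, 7])
        truth = np.array([True, True, False, False, False])
        # correct: idx0 (pos->pos), idx3 (neg->neg); idx4 unmapped counts wrong
        acc, _ = binary_outcome_accuracy(preds, truth, MAPPING,
                                         BootstrapConfig(seed=2))
        assert abs(acc - 2 / 5) < 1e-12
        excl = ClassMapping(POS, NEG, unmapped="exclude")
        acc2, _ = binary_outcome_accuracy(preds, truth, excl, BootstrapConfig(seed=2))
        assert abs(acc2 - 2 / 4) < 1e-12


class TestZeroShotImageAccuracy:
    def test_perfect_predictor(self):
        preds = np.array([1, 2, 0, 0])
        truth = np.array([True, True, False, False])
        assert zero_shot_image_accuracy(preds, truth, MAPPING) == 1.0

    def test_half_right_two_pos_two_neg(self):
        preds = np.array([1, 0, 0, 1])  # TP, miss, TN, FP
        truth = np.array([True, True, False, False])
        assert zero_shot_image_accuracy(preds, truth, MAPPING) == 0.5

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(3)
        preds = rng.integers(0, 4, 200)
        truth = rng.random(200) < 0.4
        got = zero_shot_image_accuracy(preds, truth, MAPPING)
        is_pos = np.isin(preds, list(POS))
        is_neg = np.isin(preds, list(NEG))
        tp = np.sum(truth & is_pos)
        tn = np.sum(~truth & is_neg)
        assert got == (tp + tn) / 200


class TestPatientIdentificationRate:
    def test_62_of_151_displays_as_0_41(self):
        series, preds = [], []
        for i in range(151):
            hit = i < 62
            s, p = make_series(f"p{i}", [(1 if hit else 0, True), (0, False)])
            series.append(s)
            preds.append(p)
        n, rate = patient_identification_rate(series, np.concatenate(preds), MAPPING)
        assert (n, rate) == (62, 0.41)

    def test_94_of_151_displays_as_0_62(self):
        series, preds = [], []
        for i in range(151):
            hit = i < 94
            s, p = make_series(f"p{i}", [(2 if hit else 0, True)])
            series.append(s)
            preds.append(p)
        n, rate = patient_identification_rate(series, np.concatenate(preds), MAPPING)
        assert (n, rate) == (94, 0.62)

    def test_none_identified(self):
        series, preds = [], []
        for i in range(5):
            s, p = make_series(f"p{i}", [(0, True), (0, True)])
            series.append(s)
            preds.append(p)
        n, rate = patient_identification_rate(series, np.concatenate(preds), MAPPING)
        assert (n, rate) == (0, 0.0)

    def test_positive_prediction_on_negative_slice_does_not_count(self):
        s, p = make_series("p0", [(1, False), (0, True)])
        n, _ = patient_identification_rate([s], {"p0": p}, MAPPING)
        assert n == 0

    def test_invariant_to_slice_order(self):
        s1, p1 = make_series("p0", [(0, False), (1, True), (0, False)])
        s2, p2 = make_series("p0", [(1, True), (0, False), (0, False)])
        r1 = patient_identification_rate([s1], {"p0": p1}, MAPPING)
        r2 = patient_identification_rate([s2], {"p0": p2}, MAPPING)
        assert r1 == r2

    def test_missing_patient_predictions_named(self):
        s, p = make_series("p0", [(1, True)])
        with pytest.raises(ValueError, match="p0"):
            patient_identification_rate([s], {}, MAPPING)


class TestMappingIO:
    def test_from_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "mapping.yaml"
        path.write_text(yaml.safe_dump({"positive": [1, 2], "negative": [0],
                                        "unmapped": "exclude"}))
        m = ClassMapping.from_yaml(path)
        assert m.positive_classes == frozenset({1, 2})
        assert m.negative_classes == frozenset({0})
        assert m.unmapped == "exclude"


class TestIdentificationOverlap:
    def test_counts_per_evaluator_and_none(self):
        from lorentznet.generalization import identification_overlap

        table = identification_overlap(
            {"model_a": {"p1", "p2"}, "model_b": {"p2", "p3"},
             "reader": {"p1"}},
            all_patients=["p1", "p2", "p3", "p4", "p5"])
        by = table.set_index("evaluator")["identified"]
        assert by["model_a"] == 2 and by["model_b"] == 2 and by["reader"] == 1
        assert by["none"] == 2  # p4, p5 caught by nobody


class TestBootstrapCI:
    def test_constant_vector_gives_degenerate_interval(self):
        lo, hi = bootstrap_ci(np.full(30, 0.7), np.mean, BootstrapConfig(seed=0))
        assert lo == hi
        assert abs(lo - 0.7) < 1e-12

    def test_fixed_seed_reproduces_interval(self):
        v = np.random.default_rng(4).random(50)
        a = bootstrap_ci(v, np.mean, BootstrapConfig(seed=5))
        b = bootstrap_ci(v, np.mean, BootstrapConfig(seed=5))
        assert a == b

    def test_bernoulli_coverage_near_95_percent(self):
        # 200 replications of n=200 Bernoulli(0.5): CI should cover 0.5 ~95%
        rng = np.random.default_rng(6)
        covered = 0
        reps = 200
        for r in range(reps):
            v = (rng.random(200) < 0.5).astype(float)
            lo, hi = bootstrap_ci(v, np.mean,
                                  BootstrapConfig(n_resamples=500, seed=r))
            covered += lo <= 0.5 <= hi
        assert 0.91 <= covered / reps <= 0.99

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bootstrap_ci(np.array([]), np.mean)
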