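"""Kernel-Bayes classification, jackknife rates, LSD, confusion arithmetic."""

import dataclasses
from fractions import Fraction

import numpy as np
import pytest

from conftest import chance_records, records_from_truth
from pearbrowning.classify import (
    ConfusionMatrix,
    SliceRecord,
    bayes_fit,
    confusion_metrics,
    improvement_over_singles,
    jackknife_rate,
    lsd_compare,
    read_records,
    two_class_report,
    write_records,
)
from pearbrowning.synthetic import GeneratorConfig, generate_shape_trajectories


def _recs(values_a, values_b, feature2=1.0):
    recs = []
    for i, v in enumerate(values_a):
        recs.append(SliceRecord(f"a{i}", "A", 0.0, v, feature2))
    for i, v in enumerate(values_b):
        recs.append(SliceRecord(f"b{i}", "B", 0.0, v, feature2))
    return recs


def test_separated_classes_classify_by_proximity():
    recs = _recs([1.0, 1.1, 0.9], [11.0, 10.9, 11.1])
    model = bayes_fit(recs, ("beta_bi",), bandwidth=1.0)
    assert model.predict(np.array([[2.0]])) == ["A"]
    assert model.predict(np.array([[10.0]])) == ["B"]


def test_training_points_classified_to_own_class():
    recs = [SliceRecord(f"a{i}", "A", 0.0, v, v + 0.3) for i, v in enumerate([1.0, 1.2, 0.8])]
    recs += [SliceRecord(f"b{i}", "B", 0.0, v, v - 0.4) for i, v in enumerate([5.0, 5.2, 4.8])]
    model = bayes_fit(recs)
    X = np.array([[r.beta_bi, r.beta_yi] for r in recs])
    assert model.predict(X) == [r.group for r in recs]


def test_decision_boundary_at_midpoint_of_symmetric_classes():
    recs = _recs([4.0, 5.0, 6.0], [8.0, 9.0, 10.0])
    model = bayes_fit(recs, ("beta_bi",), bandwidth=1.0)
    grid = np.linspace(6.0, 8.0, 4001)
    scores = model.log_score(grid[:, None])
    boundary = grid[np.argmin(np.abs(scores[:, 0] - scores[:, 1]))]
    assert abs(boundary - 7.0) <= 1.0 / 10  # within bandwidth/10


def test_jackknife_perfect_separation():
    rng = np.random.default_rng(0)
    recs = _recs(rng.normal(1, 0.05, 20), rng.normal(10, 0.05, 20))
    assert jackknife_rate(recs, ("beta_bi",)) == {"A": 100.0, "B": 100.0}


def test_jackknife_chance_level_on_identical_distributions():
    """With no class signal the mean rate over seeds sits near 50%."""
    pooled = []
    for seed in range(10):
        rates = jackknife_rate(chance_records(seed), ("beta_bi",))
        pooled.append(np.mean(list(rates.values())))
    assert abs(np.mean(pooled) - 50.0) <= 15.0


def test_noise_feature_cannot_inflate_chance_rate():
    """Leakage guard: adding a pure-noise feature to the chance fixture must
    not raise the jackknife rate by more than 10 points."""
    diffs = []
    for seed in range(5):
        recs = chance_records(seed)
        r1 = jackknife_rate(recs, ("beta_bi",))
        r2 = jackknife_rate(recs, ("beta_bi", "beta_yi"))  # beta_yi is noise
        diffs.append(np.mean(list(r2.values())) - np.mean(list(r1.values())))
    assert max(diffs) <= 10.0


def test_jackknife_invariant_to_record_order():
    recs = records_from_truth(generate_shape_trajectories(
        GeneratorConfig(seed=5, n_per_group=30)))
    base = jackknife_rate(recs, ("beta_bi", "beta_yi"))
    rng = np.random.default_rng(1)
    for _ in range(5):
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert jackknife_rate(shuffled, ("beta_bi", "beta_yi")) == base


def test_combined_features_beat_singles_per_class_under_parametric_densities():
    """On the study-structured cohort the two-feature classifier should match
    or beat the best single feature for each class in ≥ 80% of seeds.  The
    Gaussian-mode classifier models the cohort's class densities correctly
    and expresses the complementary-information effect; the kernel mode is
    exercised on the pooled version of this property in the acceptance suite.
    """
    wins = 0
    for seed in range(25):
        recs = records_from_truth(generate_shape_trajectories(GeneratorConfig(seed=seed)))
        r_bi = jackknife_rate(recs, ("beta_bi",), mode="gaussian")
        r_yi = jackknife_rate(recs, ("beta_yi",), mode="gaussian")
        r_both = jackknife_rate(recs, ("beta_bi", "beta_yi"), mode="gaussian")
        wins += all(r_both[c] >= max(r_bi[c], r_yi[c]) for c in r_both)
    assert wins >= 20


def test_bayes_fit_refusals():
    with pytest.raises(ValueError, match="two classes"):
        bayes_fit([SliceRecord("a", "A", 0, 1, 1), SliceRecord("b", "A", 0, 2, 2)])
    constant = _recs([2.0, 2.0, 2.0], [3.0, 3.1, 2.9])
    with pytest.raises(ValueError, match="bandwidth"):
        bayes_fit(constant, ("beta_bi",))
    bayes_fit(constant, ("beta_bi",), bandwidth=0.5)  # override works
    with pytest.raises(ValueError):
        bayes_fit(_recs([1.0], [2.0, 2.1]), ("beta_bi",))


# ---------------------------------------------------------------------------
# confusion arithmetic


def test_confusion_metrics_exact_rational_identities():
    cm = ConfusionMatrix(TP=7, FP=3, FN=2, TN=8)
    m = confusion_metrics(cm)
    assert m.accuracy == Fraction(15, 20)
    assert m.precision == Fraction(7, 10)
    assert m.recall == Fraction(7, 9)
    assert m.f1 == 2 * m.precision * m.recall / (m.precision + m.recall)


def test_confusion_metrics_symmetric_and_balanced_cases():
    perfect = confusion_metrics(ConfusionMatrix(TP=5, FP=0, FN=0, TN=5))
    assert (perfect.accuracy, perfect.precision, perfect.recall, perfect.f1) == (1, 1, 1, 1)
    half = confusion_metrics(ConfusionMatrix(TP=1, FP=1, FN=1, TN=1))
    assert (half.accuracy, half.precision, half.recall, half.f1) == (
        Fraction(1, 2),) * 4


def test_zero_denominator_reported_as_undefined():
    m = confusion_metrics(ConfusionMatrix(TP=0, FP=0, FN=3, TN=5))
    assert m.precision is None
    assert m.recall == 0
    assert m.f1 is None


def test_swapped_labels_exchange_precision_and_recall():
    cm = ConfusionMatrix(TP=50, FP=5, FN=10, TN=40)
    rep = two_class_report(cm, "pos", "neg")
    rep_sw = two_class_report(cm.swapped(), "neg", "pos")
    assert rep["pos"] == rep_sw["pos"]
    assert rep["neg"] == rep_sw["neg"]
    assert rep["accuracy_percent"] == rep_sw["accuracy_percent"]


def test_improvement_arithmetic():
    assert improvement_over_singles([70.0, 80.0], 80.0) == pytest.approx(5.0)


def test_invalid_confusion():
    with pytest.raises(ValueError):
        ConfusionMatrix(TP=-1, FP=0, FN=0, TN=0)
    with pytest.raises(ValueError):
        ConfusionMatrix(TP=0, FP=0, FN=0, TN=0)


# ---------------------------------------------------------------------------
# Fisher's LSD


def test_lsd_type_one_error_near_nominal():
    """Two groups from one distribution: ≈5% of 100 seeds flag significance."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        recs = _recs(rng.normal(5, 1, 50).clip(0.05), rng.normal(5, 1, 50).clip(0.05))
        hits += bool(lsd_compare(recs, "beta_bi").significant.iloc[0])
    assert hits <= 12  # ≈95% non-significant, binomial slack


def test_lsd_detects_huge_effect():
    rng = np.random.default_rng(3)
    recs = _recs(rng.normal(1, 1, 20).clip(0.05), rng.normal(6, 1, 20).clip(0.05))
    table = lsd_compare(recs, "beta_bi")
    assert table.significant.all()
    assert table.mean_diff.iloc[0] == pytest.approx(-5.0, abs=1.0)


def test_lsd_identical_groups_never_flagged():
    vals = [1.0, 1.5, 2.0, 2.5]
    recs = []
    for g in ("A", "B", "C"):
        for i, v in enumerate(vals):
            recs.append(SliceRecord(f"{g}{i}", g, 0.0, v, 1.0))
    table = lsd_compare(recs, "beta_bi")
    assert len(table) == 3
    assert not table.significant.any()


def test_lsd_refuses_degenerate_groups():
    with pytest.raises(ValueError):
        lsd_compare(_recs([1.0], [2.0, 2.1]), "beta_bi")


def test_records_csv_round_trip(tmp_path):
    recs = _recs([1.0, 2.0], [3.0, 4.0])
    write_records(tmp_path / "r.csv", recs)
    assert read_records(tmp_path / "r.csv") == recs
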