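"""Loss/optimizer recipe, splitting, metric oracles and the RSBI baseline.

The ranking metrics are pinned against brute-force oracles: AUROC
against explicit concordant-pair counting, the Youden cutoff against
exhaustive threshold search, and the confusion-matrix metrics against
direct hand arithmetic over small count tables.
"""

import math

import numpy as np
import pytest

from weanwave.preprocess import PreprocessConfig
from weanwave.sbt_sim import SimConfig, default_priors, simulate_cohort
from weanwave.train_eval import (
    ConfusionCounts,
    TrainingConfig,
    bce_loss,
    bootstrap_ci,
    confusion_metrics,
    labels_to_binary,
    metrics_from_scores,
    pr_auc,
    roc_auc,
    rsbi_baseline,
    split_cohort,
    train_model,
    youden_cutoff,
)
from weanwave.vent_data import SBTRecord, ValidationError
from weanwave.wean_net import assemble_model


# --------------------------------------------------------------------------
# independent oracles


def auroc_pair_count(scores, labels):
    """Concordant-pair fraction with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels):
    best_j, best_t = -math.inf, None
    for t in sorted(set(scores)):
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / np.sum(labels == 1)
        spec = np.sum(~pred & (labels == 0)) / np.sum(labels == 0)
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t, best_j


# --------------------------------------------------------------------------
# loss


def test_bce_closed_forms():
    assert bce_loss(0.0, 1) == pytest.approx(math.log(2), abs=1e-12)
    assert bce_loss(20.0, 1) == pytest.approx(0.0, abs=1e-8)
    assert bce_loss(-3.0, 0) == pytest.approx(math.log1p(math.exp(-3)), abs=1e-12)
    assert bce_loss(-3.0, 0) == pytest.approx(0.048587, abs=1e-6)


def test_bce_extreme_logits_finite():
    assert np.isfinite(bce_loss(500.0, 0))
    assert np.isfinite(bce_loss(-500.0, 1))


# --------------------------------------------------------------------------
# splitting


def _label_cohort(n, prevalence, seed=0):
    return simulate_cohort(default_priors(), SimConfig(
        n_patients=n, failure_prevalence=prevalence, duration_s=20.0,
        cough_rate_per_min=0.0, seed=seed))


def test_split_sizes_8_2():
    cohort = _label_cohort(10, 0.4)
    train, test = split_cohort(cohort, 0.8, seed=0)
    assert (len(train), len(test)) == (8, 2)


def test_split_disjoint_exhaustive():
    cohort = _label_cohort(11, 0.3)
    train, test = split_cohort(cohort, 0.8, seed=1)
    ids = {r.patient_id for r in cohort}
    tr = {r.patient_id for r in train}
    te = {r.patient_id for r in test}
    assert tr | te == ids
    assert tr & te == set()


def test_split_stratified_counts():
    """n=20 at 25% prevalence: the 20% test split holds exactly 1 failure."""
    cohort = _label_cohort(20, 0.25)
    _, test = split_cohort(cohort, 0.8, seed=2, stratified=True)
    assert sum(lab == "failure" for lab in test.labels) == 1


def test_split_reproducible():
    cohort = _label_cohort(12, 0.5)
    a = split_cohort(cohort, 0.8, seed=3)
    b = split_cohort(cohort, 0.8, seed=3)
    assert [r.patient_id for r in a[1]] == [r.patient_id for r in b[1]]


# --------------------------------------------------------------------------
# confusion metrics


def test_confusion_hand_example():
    m = confusion_metrics(ConfusionCounts(tp=8, fp=2, tn=6, fn=4))
    assert m["sensitivity"] == pytest.approx(0.667, abs=5e-4)
    assert m["specificity"] == pytest.approx(0.750, abs=5e-4)
    assert m["ppv"] == pytest.approx(0.800, abs=5e-4)
    assert m["npv"] == pytest.approx(0.600, abs=5e-4)
    assert m["accuracy"] == pytest.approx(0.700, abs=5e-4)
    assert m["f1"] == pytest.approx(0.727, abs=5e-4)


def test_confusion_perfect_classifier():
    m = confusion_metrics(ConfusionCounts(tp=5, fp=0, tn=7, fn=0))
    assert all(m[k] == 1.0 for k in m)


def test_confusion_undefined_marker_not_zero():
    m = confusion_metrics(ConfusionCounts(tp=0, fp=3, tn=4, fn=0))
    assert m["sensitivity"] is None
    assert m["specificity"] == pytest.approx(4 / 7)


def test_confusion_all_zero_rejected():
    with pytest.raises(ValidationError):
        ConfusionCounts(tp=0, fp=0, tn=0, fn=0)


def test_confusion_exhaustive_small_counts():
    """Agreement with hand arithmetic on every count 4-tuple with entries
    <= 4 (skipping the empty table)."""
    for tp in range(5):
        for fp in range(5):
            for tn in range(5):
                for fn in range(5):
                    if tp + fp + tn + fn == 0:
                        continue
                    m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
                    assert m["sensitivity"] == (
                        None if tp + fn == 0 else pytest.approx(tp / (tp + fn)))
                    assert m["ppv"] == (
                        None if tp + fp == 0 else pytest.approx(tp / (tp + fp)))
                    assert m["f1"] == (
                        None if 2 * tp + fp + fn == 0
                        else pytest.approx(2 * tp / (2 * tp + fp + fn)))


# --------------------------------------------------------------------------
# ranking metrics vs oracles


def test_auroc_worked_example():
    assert roc_auc([.9, .8, .4, .3], [1, 0, 1, 0]) == pytest.approx(0.75)


def test_auroc_perfect_and_ties():
    assert roc_auc([.9, .8, .2, .1], [1, 1, 0, 0]) == 1.0
    assert pr_auc([.9, .8, .2, .1], [1, 1, 0, 0]) == 1.0
    assert roc_auc([.5, .5, .5, .5], [1, 0, 1, 0]) == pytest.approx(0.5)


def test_auroc_single_class_rejected():
    with pytest.raises(ValidationError):
        roc_auc([.1, .2], [1, 1])


def test_auroc_matches_pair_counting_oracle():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(4, 51))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.random(n), 2)  # rounding induces ties
        assert roc_auc(scores, labels) == pytest.approx(
            auroc_pair_count(scores, labels), abs=1e-12)


def test_youden_worked_example():
    scores = np.array([.1, .4, .6, .9])
    labels = np.array([0, 0, 1, 1])
    assert youden_cutoff(scores, labels) == pytest.approx(0.6)


def test_youden_matches_exhaustive_search():
    rng = np.random.default_rng(1)
    for _ in range(100):
        n = int(rng.integers(4, 40))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.random(n), 1)
        t = youden_cutoff(scores, labels)
        t_oracle, j_oracle = youden_exhaustive(scores, labels)
        assert t == pytest.approx(t_oracle)


def test_youden_tie_breaks_to_smallest_threshold():
    # both 0.2 and 0.8 reach J = 1 in the separated case; smallest wins
    scores = np.array([.1, .2, .8, .9])
    labels = np.array([0, 0, 1, 1])
    assert youden_cutoff(scores, labels) == pytest.approx(0.8)
    # duplicate scores: candidates collapse, smallest achieving max J
    scores = np.array([.3, .3, .7, .7])
    labels = np.array([0, 0, 1, 1])
    assert youden_cutoff(scores, labels) == pytest.approx(0.7)


def test_youden_label_inversion_symmetry():
    """Inverting labels and complementing predictions leaves |J| attainable:
    the maximum J on inverted labels equals the original maximum."""
    rng = np.random.default_rng(2)
    scores = np.round(rng.random(20), 1)
    labels = (rng.random(20) > 0.5).astype(int)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    _, j = youden_exhaustive(scores, labels)
    # J of "predict positive when score < t" on inverted labels
    best_inv = -math.inf
    for t in sorted(set(scores)):
        pred = ~(scores >= t)
        inv = 1 - labels
        sens = np.sum(pred & (inv == 1)) / np.sum(inv == 1)
        spec = np.sum(~pred & (inv == 0)) / np.sum(inv == 0)
        best_inv = max(best_inv, sens + spec - 1)
    assert best_inv == pytest.approx(j, abs=1e-12)


# --------------------------------------------------------------------------
# bootstrap


def test_bootstrap_degenerate_single_replicate():
    lo, hi = bootstrap_ci(roc_auc, [.9, .1, .8, .2], [1, 0, 1, 0],
                          n_boot=1, seed=0)
    assert lo == hi


def test_bootstrap_reproducible():
    args = (roc_auc, [.9, .1, .8, .2, .7, .3], [1, 0, 1, 0, 1, 0])
    assert bootstrap_ci(*args, n_boot=200, seed=5) == \
        bootstrap_ci(*args, n_boot=200, seed=5)


def test_bootstrap_concentrates_with_replication():
    rng = np.random.default_rng(3)
    scores = rng.random(12)
    labels = np.array([1, 0] * 6)
    lo1, hi1 = bootstrap_ci(roc_auc, scores, labels, n_boot=300, seed=1)
    big_scores = np.tile(scores, 100)
    big_labels = np.tile(labels, 100)
    lo2, hi2 = bootstrap_ci(roc_auc, big_scores, big_labels, n_boot=300, seed=1)
    assert (hi2 - lo2) < (hi1 - lo1)


# --------------------------------------------------------------------------
# RSBI baseline


def _record_with_summary(f, vt, tiny_record):
    from dataclasses import replace
    return replace(tiny_record, summary_frequency=f, summary_tidal_volume=vt)


def test_rsbi_formula_and_threshold(tiny_record):
    r = rsbi_baseline(_record_with_summary(30.0, 0.25, tiny_record))
    assert r.rsbi == pytest.approx(120.0)
    assert r.predicted_label == "failure"
    r = rsbi_baseline(_record_with_summary(20.0, 0.50, tiny_record))
    assert r.rsbi == pytest.approx(40.0)
    assert r.predicted_label == "success"


def test_rsbi_boundary_is_failure(tiny_record):
    r = rsbi_baseline(_record_with_summary(21.0, 0.20, tiny_record))
    assert r.rsbi == pytest.approx(105.0)
    assert r.predicted_label == "failure"


def test_rsbi_requires_positive_summaries(tiny_record):
    from dataclasses import replace
    bad = replace(tiny_record, summary_frequency=None, summary_tidal_volume=0.4)
    with pytest.raises(ValidationError):
        rsbi_baseline(bad)


# --------------------------------------------------------------------------
# metrics report


def test_report_perfect_predictions_all_ones():
    scores = np.array([.9, .95, .1, .2, .15, .05])
    labels = np.array([1, 1, 0, 0, 0, 0])
    rep = metrics_from_scores(scores, labels, n_boot=100, seed=0)
    for key in ("auroc", "auprc", "sensitivity", "specificity",
                "ppv", "npv", "accuracy", "f1"):
        assert getattr(rep, key).point == 1.0


def test_report_cis_bracket_points():
    rng = np.random.default_rng(4)
    scores = rng.random(30)
    labels = (rng.random(30) < 0.4).astype(int)
    rep = metrics_from_scores(scores, labels, n_boot=100, seed=0)
    for key in ("auroc", "auprc", "sensitivity", "specificity",
                "ppv", "npv", "accuracy", "f1"):
        mv = getattr(rep, key)
        if mv.point is not None and mv.ci is not None:
            assert mv.ci[0] <= mv.point <= mv.ci[1]


# --------------------------------------------------------------------------
# training loop (tiny scale: 60-s records, short crops, default architecture)


@pytest.fixture(scope="module")
def micro_setup():
    cohort = simulate_cohort(default_priors(), SimConfig(
        n_patients=4, failure_prevalence=0.5, duration_s=60.0,
        cough_rate_per_min=0.0, seed=21))
    pp = PreprocessConfig(crop_len_waveform=1300, crop_len_numeric=70)
    return cohort, pp


def test_zero_learning_rate_freezes_weights(micro_setup):
    cohort, _ = micro_setup
    # full-length "crops" make every epoch see identical data, so with
    # lr=0 the loss history must be exactly flat
    pp = PreprocessConfig(crop_len_waveform=len(cohort[0].waveform),
                          crop_len_numeric=len(cohort[0].numeric))
    am = assemble_model(seed=5)
    before = {n: p.data.copy() for n, p in am.model.named_parameters()}
    cfg = TrainingConfig(learning_rate=0.0, weight_decay=0.0, max_epochs=2,
                         val_fraction=0.0, crops_per_epoch=1, seed=5)
    res = train_model(am, cohort, cfg, pp)
    for n, p in am.model.named_parameters():
        assert np.array_equal(before[n], p.data), n
    assert res.loss_history[0] == pytest.approx(res.loss_history[1], abs=1e-9)


def test_training_is_reproducible_under_seed(micro_setup):
    cohort, pp = micro_setup
    hists = []
    for _ in range(2):
        am = assemble_model(seed=6)
        cfg = TrainingConfig(max_epochs=2, val_fraction=0.25,
                             crops_per_epoch=1, seed=6)
        res = train_model(am, cohort, cfg, pp)
        hists.append((res.loss_history, res.val_history))
    assert hists[0] == hists[1]


def test_training_rejects_records_shorter_than_crop(micro_setup):
    cohort, _ = micro_setup
    pp_long = PreprocessConfig(crop_len_waveform=10 ** 6, crop_len_numeric=70)
    am = assemble_model(seed=7)
    with pytest.raises(ValidationError, match="crop"):
        train_model(am, cohort, TrainingConfig(max_epochs=1, seed=0), pp_long)
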