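"""Training loop, cohort splitting, nine-metric evaluation and the RSBI
baseline.

Training follows the published recipe: per-recording min-max
normalization, random fixed-length crops each epoch, binary cross
entropy on the failure logit, AdamW (lr 1e-4, weight decay 5e-2,
batch size 4), with early stopping on an internal validation slice of
the training set.  Evaluation runs on full-length (uncropped) inputs and
reports AUROC, AUPRC, sensitivity, specificity, PPV, NPV, accuracy, F1
and the parameter count, each with a percentile-bootstrap confidence
interval, at the Youden-index operating cutoff.

The rapid-shallow-breathing-index baseline classifies a record as
failure when f/VT >= 105 breaths/min/L (the classical threshold; the
boundary itself counts as failure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .preprocess import PreprocessConfig, prepare_inputs
from .vent_data import Cohort, SBTRecord, ValidationError
from .wean_net import AssembledModel, count_parameters, predict_logit_batch
from . import nn

__all__ = [
    "TrainingConfig",
    "ConfusionCounts",
    "MetricsReport",
    "RSBIResult",
    "TrainResult",
    "split_cohort",
    "bce_loss",
    "train_model",
    "confusion_metrics",
    "roc_auc",
    "pr_auc",
    "bootstrap_ci",
    "youden_cutoff",
    "rsbi_baseline",
    "rsbi_scores",
    "evaluate",
    "grid_search",
    "labels_to_binary",
]

RSBI_THRESHOLD = 105.0  # breaths/min/L, classical cutoff


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 5e-2
    batch_size: int = 4
    max_epochs: int = 50
    early_stop_patience: int = 10
    val_fraction: float = 0.1
    crops_per_epoch: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValidationError("batch_size and max_epochs must be >= 1")
        if self.crops_per_epoch < 1:
            raise ValidationError("crops_per_epoch must be >= 1")
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValidationError("learning rate / weight decay must be >= 0")


def labels_to_binary(labels: Sequence[str]) -> np.ndarray:
    """failure -> 1 (positive class), success -> 0."""
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab == "failure":
            out[i] = 1
        elif lab == "success":
            out[i] = 0
        else:
            raise ValidationError(f"record {i} is unlabelled or mislabelled: {lab!r}")
    return out


def split_cohort(cohort: Cohort, train_fraction: float = 0.8,
                 seed: int = 0, stratified: bool = True) -> tuple[Cohort, Cohort]:
    """Random 8:2-style split into disjoint, exhaustive train/test cohorts.

    With ``stratified`` the test share is rounded per class, so e.g. a
    20-patient cohort at 25% prevalence puts exactly one failure in the
    20% test split.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = [r.patient_id for r in cohort]
    if stratified:
        y = labels_to_binary(cohort.labels)
        test_ids: list[str] = []
        for cls in (0, 1):
            cls_ids = [i for i, yy in zip(ids, y) if yy == cls]
            if len(cls_ids) < 1:
                raise ValidationError(
                    f"stratified split requires records of class {cls}")
            cls_ids = list(np.array(cls_ids)[rng.permutation(len(cls_ids))])
            n_test = int(round(len(cls_ids) * (1.0 - train_fraction)))
            test_ids.extend(cls_ids[:n_test])
    else:
        perm = rng.permutation(len(ids))
        n_test = int(round(len(ids) * (1.0 - train_fraction)))
        test_ids = [ids[i] for i in perm[:n_test]]
    test_set = set(test_ids)
    train = Cohort(tuple(r for r in cohort if r.patient_id not in test_set))
    test = Cohort(tuple(r for r in cohort if r.patient_id in test_set))
    return train, test


def bce_loss(logit, label) -> float:
    """Numerically safe binary cross entropy with a sigmoid on the logit:
    max(z,0) - z*y + log(1 + exp(-|z|)), averaged over the batch."""
    z = np.asarray(logit, dtype=np.float64)
    y = np.asarray(label, dtype=np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(np.mean(loss))


def _bce_grad(logit, label) -> np.ndarray:
    z = np.asarray(logit, dtype=np.float64)
    y = np.asarray(label, dtype=np.float64)
    return (nn.sigmoid(z) - y) / z.size


def recalibrate_batchnorm(model: nn.Module, batches) -> None:
    """Recompute every batch-norm layer's running statistics as the equal-
    weight average of batch statistics under the *final* weights.

    After a short training run the exponentially averaged statistics still
    remember early, stale activations; one stat-refresh pass over the
    training batches removes that mismatch between train- and eval-mode
    forward passes.
    """
    from .wean_net import _walk_modules

    bns = [m for _, m in _walk_modules(model) if hasattr(m, "running_mean")]
    saved = [m.momentum for m in bns]
    for m in bns:
        m.running_mean[...] = 0.0
        m.running_var[...] = 1.0
    for k, (xw, xn) in enumerate(batches):
        for m in bns:
            m.momentum = 1.0 / (k + 1)
        model.forward(xw, xn, training=True)
    for m, mom in zip(bns, saved):
        m.momentum = mom


@dataclass
class TrainResult:
    loss_history: list[float]
    val_history: list[float]
    best_epoch: int
    stopped_early: bool


def train_model(assembled: AssembledModel, train_cohort: Cohort,
                config: Optional[TrainingConfig] = None,
                pp_config: Optional[PreprocessConfig] = None) -> TrainResult:
    """Train in place; returns per-epoch loss histories.

    Every record must be at least as long as the configured crop lengths
    (checked up front).  Fully reproducible under ``config.seed``.
    """
    config = config or TrainingConfig()
    pp = pp_config or PreprocessConfig()
    for rec in train_cohort:
        if len(rec.waveform) < pp.crop_len_waveform:
            raise ValidationError(
                f"record {rec.patient_id}: waveform length {len(rec.waveform)} "
                f"< crop length {pp.crop_len_waveform}")
        if len(rec.numeric) < pp.crop_len_numeric:
            raise ValidationError(
                f"record {rec.patient_id}: numeric length {len(rec.numeric)} "
                f"< crop length {pp.crop_len_numeric}")
    y_all = labels_to_binary(train_cohort.labels)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = len(train_cohort)
    n_val = int(round(config.val_fraction * n))
    perm = rng.permutation(n)
    val_idx = set(perm[:n_val].tolist())
    fit_idx = [i for i in range(n) if i not in val_idx]

    model = assembled.model
    opt = nn.AdamW(model.parameters(), lr=config.learning_rate,
                   weight_decay=config.weight_decay)

    def batch_arrays(indices):
        xws, xns = [], []
        for i in indices:
            xw, xn = prepare_inputs(train_cohort[i], pp, rng=rng, crop=True)
            xws.append(xw)
            xns.append(xn)
        return np.stack(xws), np.stack(xns)

    best_val = math.inf
    best_epoch = 0
    since_best = 0
    loss_hist: list[float] = []
    val_hist: list[float] = []
    stopped = False
    # random cropping is the augmentation: each record contributes
    # crops_per_epoch independent crop draws per epoch
    fit_pool = fit_idx * config.crops_per_epoch
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(fit_pool))
        epoch_losses = []
        for start in range(0, len(fit_pool), config.batch_size):
            idx = [fit_pool[j] for j in order[start:start + config.batch_size]]
            xw, xn = batch_arrays(idx)
            y = y_all[idx]
            logit = model.forward(xw, xn, training=True)
            epoch_losses.append(bce_loss(logit, y))
            model.zero_grad()
            model.backward(_bce_grad(logit, y))
            opt.step()
        loss_hist.append(float(np.mean(epoch_losses)))

        if val_idx:
            vidx = sorted(val_idx)
            xw, xn = batch_arrays(vidx)
            vlogit = model.forward(xw, xn, training=False)
            vloss = bce_loss(vlogit, y_all[vidx])
        else:
            vloss = loss_hist[-1]
        val_hist.append(vloss)
        if vloss < best_val - 1e-12:
            best_val = vloss
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                stopped = True
                break

    # refresh batch-norm running statistics under the final weights
    recal_batches = []
    for start in range(0, len(fit_idx), config.batch_size):
        idx = fit_idx[start:start + config.batch_size]
        recal_batches.append(batch_arrays(idx))
    recalibrate_batchnorm(model, recal_batches)
    return TrainResult(loss_history=loss_hist, val_history=val_hist,
                       best_epoch=best_epoch, stopped_early=stopped)


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValidationError("confusion counts must total >= 1")


def _ratio(num: int, den: int) -> Optional[float]:
    """0/0 surfaces as None (an explicit undefined marker), never as 0."""
    return None if den == 0 else num / den


def confusion_metrics(c: ConfusionCounts) -> dict[str, Optional[float]]:
    """Sensitivity, specificity, PPV, NPV, accuracy, F1 from counts."""
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    acc = (c.tp + c.tn) / (c.tp + c.tn + c.fp + c.fn)
    f1 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv,
            "npv": npv, "accuracy": acc, "f1": f1}


def _check_two_classes(labels: np.ndarray):
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """AUROC = concordant-pair fraction with ties counted 1/2
    (Mann-Whitney form)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve by step integration
    (average precision)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def youden_cutoff(scores, labels) -> float:
    """Observed-score threshold maximizing J = sensitivity + specificity - 1;
    a record is called positive when score >= threshold.  Ties break toward
    the smallest threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    best_j, best_thr = -math.inf, None
    for thr in np.sort(np.unique(scores)):
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        fn = int(np.sum(~pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        fp = int(np.sum(pred & (labels == 0)))
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, float(thr)
    return best_thr


def bootstrap_ci(metric_fn: Callable, scores, labels, n_boot: int = 2000,
                 level: float = 0.95, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap over case resampling.

    Single-class resamples are redrawn; if the metric stays undefined on
    more than half the attempts, an error is raised.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if min(np.sum(labels == 1), np.sum(labels == 0)) < 1:
        raise ValidationError("bootstrap requires records of both classes")
    rng = np.random.default_rng(seed)
    n = len(scores)
    vals = []
    failures = 0
    attempts = 0
    while len(vals) < n_boot:
        attempts += 1
        if attempts > 20 * n_boot:
            raise ValidationError("bootstrap: metric undefined on most resamples")
        idx = rng.integers(0, n, n)
        ys = labels[idx]
        if len(np.unique(ys)) < 2:
            continue
        try:
            v = metric_fn(scores[idx], ys)
        except (ValidationError, ValueError):
            failures += 1
            if failures > 0.5 * (len(vals) + failures) and attempts > 50:
                raise ValidationError(
                    "bootstrap: metric undefined on >50% of resamples")
            continue
        if v is None:
            failures += 1
            continue
        vals.append(v)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(np.asarray(vals), [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class RSBIResult:
    rsbi: float
    predicted_label: str
    threshold: float = RSBI_THRESHOLD


def rsbi_baseline(record: SBTRecord) -> RSBIResult:
    """f/VT in breaths/min/L; failure is predicted when rsbi >= 105
    (the boundary counts as failure)."""
    f = record.summary_frequency
    vt = record.summary_tidal_volume
    if f is None or not (f > 0):
        raise ValidationError("summary_frequency must be > 0")
    if vt is None or not (vt > 0):
        raise ValidationError("summary_tidal_volume must be > 0")
    rsbi = f / vt
    label = "failure" if rsbi >= RSBI_THRESHOLD else "success"
    return RSBIResult(rsbi=rsbi, predicted_label=label)


def rsbi_scores(cohort: Cohort) -> np.ndarray:
    """Continuous RSBI values (higher = more failure-like), for ROC use."""
    return np.array([rsbi_baseline(r).rsbi for r in cohort])


@dataclass(frozen=True)
class MetricValue:
    point: Optional[float]
    ci: Optional[tuple[float, float]] = None


@dataclass(frozen=True)
class MetricsReport:
    """The nine evaluation metrics with bootstrap CIs."""

    auroc: MetricValue
    auprc: MetricValue
    sensitivity: MetricValue
    specificity: MetricValue
    ppv: MetricValue
    npv: MetricValue
    accuracy: MetricValue
    f1: MetricValue
    parameter_count: int
    cutoff: float

    def to_dict(self) -> dict:
        def mv(v: MetricValue):
            return {"point": v.point, "ci": list(v.ci) if v.ci else None}

        return {
            "auroc": mv(self.auroc), "auprc": mv(self.auprc),
            "sensitivity": mv(self.sensitivity),
            "specificity": mv(self.specificity),
            "ppv": mv(self.ppv), "npv": mv(self.npv),
            "accuracy": mv(self.accuracy), "f1": mv(self.f1),
            "parameter_count": self.parameter_count,
            "cutoff": self.cutoff,
        }


def _threshold_metric(key: str):
    def fn(scores, labels):
        thr = fn.cutoff
        pred = scores >= thr
        c = ConfusionCounts(
            tp=int(np.sum(pred & (labels == 1))),
            fp=int(np.sum(pred & (labels == 0))),
            tn=int(np.sum(~pred & (labels == 0))),
            fn=int(np.sum(~pred & (labels == 1))),
        )
        return confusion_metrics(c)[key]

    return fn


def metrics_from_scores(scores, labels, cutoff: Optional[float] = None,
                        parameter_count: int = 0, n_boot: int = 2000,
                        seed: int = 0) -> MetricsReport:
    """Nine-metric report from failure scores and binary labels."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    if cutoff is None:
        cutoff = youden_cutoff(scores, labels)
    out = {}
    out["auroc"] = MetricValue(
        roc_auc(scores, labels),
        bootstrap_ci(roc_auc, scores, labels, n_boot=n_boot, seed=seed))
    out["auprc"] = MetricValue(
        pr_auc(scores, labels),
        bootstrap_ci(pr_auc, scores, labels, n_boot=n_boot, seed=seed + 1))
    for k, key in enumerate(
            ("sensitivity", "specificity", "ppv", "npv", "accuracy", "f1")):
        fn = _threshold_metric(key)
        fn.cutoff = cutoff
        point = fn(scores, labels)
        ci = None
        if point is not None:
            ci = bootstrap_ci(fn, scores, labels, n_boot=n_boot, seed=seed + 2 + k)
        out[key] = MetricValue(point, ci)
    for key, v in out.items():
        if v.ci is not None and v.point is not None:
            lo, hi = v.ci
            lo, hi = min(lo, v.point), max(hi, v.point)
            out[key] = MetricValue(v.point, (lo, hi))
    return MetricsReport(parameter_count=parameter_count, cutoff=float(cutoff),
                         **out)


def evaluate(assembled: AssembledModel, test_cohort: Cohort,
             pp_config: Optional[PreprocessConfig] = None,
             cutoff: Optional[float] = None, n_boot: int = 2000,
             seed: int = 0) -> MetricsReport:
    """Score full-length test inputs and compile the nine-metric report.

    With ``cutoff=None`` the operating point is the Youden-index cutoff
    selected on the test scores themselves (as reported alongside the
    AUCs); pass a fixed probability cutoff to evaluate a pre-chosen
    operating point.  Records are ranked by logit internally (monotone in
    the probability but immune to sigmoid underflow); the reported cutoff
    is on the probability scale.
    """
    labels = labels_to_binary(test_cohort.labels)
    _check_two_classes(labels)
    logits = predict_logit_batch(assembled, test_cohort, pp_config)
    logit_cutoff = None
    if cutoff is not None:
        if not (0.0 < cutoff < 1.0):
            raise ValidationError("probability cutoff must be in (0, 1)")
        logit_cutoff = math.log(cutoff / (1.0 - cutoff))
    report = metrics_from_scores(
        logits, labels, cutoff=logit_cutoff,
        parameter_count=count_parameters(assembled),
        n_boot=n_boot, seed=seed)
    from dataclasses import replace as _replace
    prob_cutoff = 1.0 / (1.0 + math.exp(-report.cutoff))
    return _replace(report, cutoff=prob_cutoff)


def grid_search(build_fn: Callable[[dict], AssembledModel],
                param_grid: dict[str, Sequence],
                train_cohort: Cohort,
                config: Optional[TrainingConfig] = None,
                pp_config: Optional[PreprocessConfig] = None
                ) -> tuple[dict, list[tuple[dict, float]]]:
    """Small grid search over declared hyperparameter values.

    ``build_fn(params)`` assembles a fresh model for one combination;
    selection is by best (lowest) internal-validation loss.  Returns the
    winning combination and the full (params, val_loss) trace.
    """
    import itertools

    keys = list(param_grid)
    trace: list[tuple[dict, float]] = []
    best: tuple[Optional[dict], float] = (None, math.inf)
    for combo in itertools.product(*(param_grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        assembled = build_fn(params)
        result = train_model(assembled, train_cohort, config, pp_config)
        vloss = min(result.val_history)
        trace.append((params, vloss))
        if vloss < best[1]:
            best = (params, vloss)
    return best[0], trace
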