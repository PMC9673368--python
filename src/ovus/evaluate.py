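"""Evaluation metrics, repeated random subsampling, paired t-tests, and the
accuracy/time trade-off curve.

Malignant is the positive class. The summary statistics are

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SE  = TP / (TP + FP)        ("as_printed" mode)
    SP  = TN / (TN + FN)        ("as_printed" mode)
    SD  = sqrt( (1/N) sum (x_i - mu)^2 )   (population form)

all reported as percentages. Note the as_printed SE/SP are algebraically
the positive predictive value and the negative predictive value; the
textbook definitions SE = TP/(TP+FN), SP = TN/(TN+FP) are available as
mode="conventional", and every report records which mode produced it.

The repeated-holdout protocol re-splits, re-augments and re-trains the
whole backbone zoo per repetition (seed = base_seed + repetition) and
averages the per-repetition metrics; the mean of the repetitions is the
final assessment and the spread is the population SD above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import augment as _augment
from . import backbone as _backbone
from . import ensemble as _ensemble
from .synthgen import BENIGN, CLASSES, MALIGNANT, LabeledDataset, split_dataset


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    se: float | None
    sp: float | None
    mode: str = "as_printed"


def confusion_counts(truth, predicted) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with malignant as the positive class."""
    truth, predicted = list(truth), list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    if not truth:
        raise ValueError("empty inputs")
    tp = tn = fp = fn = 0
    for t, p in zip(truth, predicted):
        if t == MALIGNANT:
            tp, fn = (tp + 1, fn) if p == MALIGNANT else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if p == BENIGN else (tn, fp + 1)
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def accuracy(counts: ConfusionCounts) -> float:
    """Overall accuracy as a percentage."""
    if counts.total == 0:
        raise ValueError("total count is zero")
    return 100.0 * (counts.TP + counts.TN) / counts.total


def sensitivity(counts: ConfusionCounts, mode: str = "as_printed") -> float:
    """SE %, as_printed: TP/(TP+FP); conventional: TP/(TP+FN)."""
    denom = counts.TP + (counts.FP if mode == "as_printed" else counts.FN)
    if mode not in ("as_printed", "conventional"):
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0:
        raise ZeroDivisionError(f"sensitivity undefined: {mode} denominator is 0")
    return 100.0 * counts.TP / denom


def specificity(counts: ConfusionCounts, mode: str = "as_printed") -> float:
    """SP %, as_printed: TN/(TN+FN); conventional: TN/(TN+FP)."""
    denom = counts.TN + (counts.FN if mode == "as_printed" else counts.FP)
    if mode not in ("as_printed", "conventional"):
        raise ValueError(f"unknown mode {mode!r}")
    if denom == 0:
        raise ZeroDivisionError(f"specificity undefined: {mode} denominator is 0")
    return 100.0 * counts.TN / denom


def metrics_report(counts: ConfusionCounts, mode: str = "as_printed"
                   ) -> MetricsReport:
    def _safe(fn):
        try:
            return fn(counts, mode)
        except ZeroDivisionError:
            return None
    return MetricsReport(acc=accuracy(counts), se=_safe(sensitivity),
                         sp=_safe(specificity), mode=mode)


def std_dev(values) -> float:
    """Population standard deviation (divisor N, mean mu)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("empty list")
    mu = values.mean()
    return float(math.sqrt(np.mean((values - mu) ** 2)))


def paired_t_test(a, b) -> tuple[float, float]:
    """Classic paired t on the differences, df = n - 1, two-sided p.

    All-zero differences are degenerate: (t, p) = (0, 1). Zero-variance
    non-zero differences give an infinite t with p = 0.
    """
    a, b = np.asarray(list(a), float), np.asarray(list(b), float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


# --- repeated random subsampling --------------------------------------------

@dataclass
class RepetitionSummary:
    """Per-repetition metric reports plus mean +- population-SD summaries."""
    per_rep: dict[str, list[MetricsReport]]     # keyed by model/strategy name
    records: pd.DataFrame                        # per-image prediction records
    mode: str = "as_printed"

    def mean_sd(self, name: str, metric: str = "acc") -> tuple[float, float]:
        vals = [getattr(r, metric) for r in self.per_rep[name]]
        if any(v is None for v in vals):
            raise ValueError(f"{metric} undefined in some repetition for {name}")
        return float(np.mean(vals)), std_dev(vals)

    def metric_values(self, name: str, metric: str = "acc") -> list[float]:
        return [getattr(r, metric) for r in self.per_rep[name]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, reports in self.per_rep.items():
            for rep, r in enumerate(reports):
                rows.append({"repetition": rep, "model_or_strategy": name,
                             "acc": r.acc, "se": r.se, "sp": r.sp,
                             "mode": r.mode})
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.per_rep:
            row = {"model_or_strategy": name}
            for metric in ("acc", "se", "sp"):
                vals = self.metric_values(name, metric)
                if any(v is None for v in vals):
                    row[f"{metric}_mean"] = row[f"{metric}_sd"] = np.nan
                else:
                    row[f"{metric}_mean"] = float(np.mean(vals))
                    row[f"{metric}_sd"] = std_dev(vals)
            rows.append(row)
        return pd.DataFrame(rows)


def _per_class_accuracy(truth, predicted) -> dict[str, float]:
    out = {}
    for cls in CLASSES:
        idx = [i for i, t in enumerate(truth) if t == cls]
        out[cls] = (sum(predicted[i] == cls for i in idx) / len(idx)
                    if idx else 0.0)
    return out


def run_one_repetition(dataset: LabeledDataset, backbone_specs,
                       training_config: _backbone.TrainingConfig,
                       augmentation_config: _augment.AugmentationConfig,
                       train_fraction: float, seed: int,
                       weight_factor: float = 1.5, metric_mode="as_printed"):
    """Split -> augment -> train the zoo -> score singles and the three
    ensembles on the validation fold. Returns (reports, prediction rows)."""
    from dataclasses import replace

    plan = split_dataset(dataset, train_fraction, seed=seed, mode="pooled")
    train = dataset.subset(plan.train_indices)
    val = dataset.subset(plan.validation_indices)
    aug_cfg = replace(augmentation_config, seed=seed)
    train_aug, _tags = _augment.build_augmented_training_set(train, aug_cfg)

    models = []
    for spec in backbone_specs:
        model = _backbone.build_backbone(spec, seed=seed)
        cfg = replace(training_config, seed=seed)
        _backbone.train_model(model, train_aug, cfg)
        models.append(model)

    truth = [item.label for item in val.items]
    val_scores = {m.name: _backbone.predict_batch(m, val) for m in models}

    # Per-class best model, measured on the un-augmented training fold.
    train_truth = [item.label for item in train.items]
    best_per_class: dict[str, str] = {}
    class_acc = {}
    for m in models:
        preds = [v.argmax_label for v in _backbone.predict_batch(m, train)]
        class_acc[m.name] = _per_class_accuracy(train_truth, preds)
    for cls in CLASSES:
        best_per_class[cls] = max(class_acc, key=lambda n: class_acc[n][cls])

    weighted_cfg = _ensemble.EnsembleConfig(
        strategy="weighted_sum", weight_factor=weight_factor,
        best_model_per_class=best_per_class)

    reports: dict[str, MetricsReport] = {}
    rows = []
    preds_by_name: dict[str, list[str]] = {}

    for m in models:
        decisions = [(v.argmax_label, max(v.scores)) for v in val_scores[m.name]]
        preds_by_name[m.name] = [d[0] for d in decisions]
        for item, (label, conf) in zip(val.items, decisions):
            rows.append({"repetition_seed": seed, "image_id": item.subject_id,
                         "source": m.name, "truth": item.label,
                         "predicted": label, "confidence": conf})

    strategies = {"ensemble_vote": lambda vs: _ensemble.majority_vote(vs),
                  "ensemble_sum": lambda vs: _ensemble.confidence_sum(vs),
                  "ensemble_weighted": lambda vs:
                      _ensemble.weighted_confidence_sum(vs, weighted_cfg)}
    for sname, rule in strategies.items():
        preds, confs = [], []
        for i in range(len(val.items)):
            vectors = [val_scores[m.name][i] for m in models]
            decision = rule(vectors)
            preds.append(decision.label)
            confs.append(decision.confidence)
        preds_by_name[sname] = preds
        for item, label, conf in zip(val.items, preds, confs):
            rows.append({"repetition_seed": seed, "image_id": item.subject_id,
                         "source": sname, "truth": item.label,
                         "predicted": label, "confidence": conf})

    for name, preds in preds_by_name.items():
        reports[name] = metrics_report(confusion_counts(truth, preds),
                                       mode=metric_mode)
    return reports, rows


def repeated_holdout(dataset: LabeledDataset, backbone_specs,
                     training_config: _backbone.TrainingConfig | None = None,
                     augmentation_config: _augment.AugmentationConfig | None = None,
                     repetitions: int = 10, train_fraction: float = 0.7,
                     base_seed: int = 0, weight_factor: float = 1.5,
                     metric_mode: str = "as_printed") -> RepetitionSummary:
    """Monte-Carlo cross-validation: repetition r re-splits, re-augments and
    re-trains everything with seed base_seed + r, then evaluates singles and
    the three ensemble strategies on the held-out fold."""
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    training_config = training_config or _backbone.TrainingConfig()
    augmentation_config = augmentation_config or _augment.AugmentationConfig()
    per_rep: dict[str, list[MetricsReport]] = {}
    all_rows = []
    for r in range(repetitions):
        reports, rows = run_one_repetition(
            dataset, backbone_specs, training_config, augmentation_config,
            train_fraction, seed=base_seed + r, weight_factor=weight_factor,
            metric_mode=metric_mode)
        all_rows.extend(rows)
        for name, report in reports.items():
            per_rep.setdefault(name, []).append(report)
    return RepetitionSummary(per_rep=per_rep, records=pd.DataFrame(all_rows),
                             mode=metric_mode)


# --- accuracy/time trade-off -------------------------------------------------

@dataclass(frozen=True)
class TradeoffCurve:
    subset_sizes: tuple[int, ...]
    accuracies: tuple[float, ...]
    times: tuple[float, ...]
    accuracy_ratio: tuple[float, ...]    # min-max scaled across subsets
    time_ratio: tuple[float, ...]
    degenerate_axes: tuple[str, ...] = ()


def tradeoff_curve(singles: dict[str, tuple[float, float]],
                   subset_accuracy=None) -> TradeoffCurve:
    """Accuracy-improvement vs time-difference as models are appended.

    ``singles`` maps model_id -> (accuracy %, single-image seconds). Models
    are appended in ascending time order; the k-model subset's time is the
    sum of its members' times and its accuracy comes from
    ``subset_accuracy(model_ids)`` (default: the members' mean accuracy, a
    stand-in when no ensemble evaluation is supplied). Both axes are min-max
    scaled across subsets into [0, 1]; a flat axis is flagged degenerate and
    reported as zeros.
    """
    if len(singles) < 2:
        raise ValueError("need at least two models")
    order = sorted(singles, key=lambda m: singles[m][1])
    if subset_accuracy is None:
        def subset_accuracy(ids):
            return float(np.mean([singles[m][0] for m in ids]))
    sizes, accs, times = [], [], []
    for k in range(1, len(order) + 1):
        ids = order[:k]
        sizes.append(k)
        accs.append(float(subset_accuracy(ids)))
        times.append(float(sum(singles[m][1] for m in ids)))

    def _scale(vals):
        lo, hi = min(vals), max(vals)
        if hi == lo:
            return [0.0] * len(vals), True
        return [(v - lo) / (hi - lo) for v in vals], False

    acc_ratio, acc_flat = _scale(accs)
    time_ratio, time_flat = _scale(times)
    degenerate = tuple(n for n, f in
                       (("accuracy", acc_flat), ("time", time_flat)) if f)
    return TradeoffCurve(subset_sizes=tuple(sizes), accuracies=tuple(accs),
                         times=tuple(times), accuracy_ratio=tuple(acc_ratio),
                         time_ratio=tuple(time_ratio),
                         degenerate_axes=degenerate)


def t_test_frame(summary: RepetitionSummary, pairs, metric="acc") -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        t, p = paired_t_test(summary.metric_values(a, metric),
                             summary.metric_values(b, metric))
        rows.append({"pair": f"{a} vs {b}",
                     "t": t, "df": len(summary.per_rep[a]) - 1, "p": p})
    return pd.DataFrame(rows)
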