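"""Selective prediction over ensemble confidences.

A deployed classifier should defer low-confidence cases to a human reader.
Given per-image prediction records (truth, predicted label, confidence),
this module computes retained fractions at a threshold, the 0.80 -> 1.00
threshold sweep in 0.01 steps, and the operating-point report at a chosen
threshold (default 0.86): how many images are excluded for manual review,
and the accuracy on the retained set versus the no-triage baseline.

Retention uses confidence >= threshold throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import BENIGN, MALIGNANT


@dataclass(frozen=True)
class PredictionRecord:
    image_id: str
    truth: str
    predicted: str
    confidence: float

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def correct(self) -> bool:
        return self.truth == self.predicted


@dataclass(frozen=True)
class TriageCurve:
    thresholds: tuple[float, ...]
    benign_retained_frac: tuple[float, ...]      # among correct benign
    malignant_retained_frac: tuple[float, ...]   # among correct malignant
    retained_accuracy: tuple[float | None, ...]  # None when all excluded
    excluded_frac: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "benign_retained_frac": self.benign_retained_frac,
            "malignant_retained_frac": self.malignant_retained_frac,
            "retained_accuracy": [np.nan if v is None else v
                                  for v in self.retained_accuracy],
            "excluded_frac": self.excluded_frac,
        })


def _check_records(records) -> list[PredictionRecord]:
    records = list(records)
    if not records:
        raise ValueError("records are empty")
    return records


def retained_fraction(records, threshold: float,
                      restrict_to_correct: bool = True,
                      by_class: bool = True):
    """Fraction of records with confidence >= threshold.

    With restrict_to_correct, the population is the correctly classified
    records (per class when by_class); this is the quantity plotted on
    retained-fraction curves.
    """
    records = _check_records(records)
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")

    def _frac(pop):
        if not pop:
            return math.nan
        return sum(r.confidence >= threshold for r in pop) / len(pop)

    pool = [r for r in records if r.correct] if restrict_to_correct else records
    if not by_class:
        return _frac(pool)
    return {BENIGN: _frac([r for r in pool if r.truth == BENIGN]),
            MALIGNANT: _frac([r for r in pool if r.truth == MALIGNANT])}


def threshold_sweep(records, start: float = 0.80, stop: float = 1.00,
                    step: float = 0.01) -> TriageCurve:
    """One curve row per threshold in [start, stop] inclusive."""
    records = _check_records(records)
    if not (start < stop) or step <= 0:
        raise ValueError("need start < stop and step > 0")
    n_steps = int(round((stop - start) / step))
    thresholds = tuple(round(start + i * step, 10) for i in range(n_steps + 1))
    ben, mal, acc, exc = [], [], [], []
    for th in thresholds:
        fr = retained_fraction(records, th)
        ben.append(fr[BENIGN])
        mal.append(fr[MALIGNANT])
        retained = [r for r in records if r.confidence >= th]
        exc.append(1.0 - len(retained) / len(records))
        acc.append(sum(r.correct for r in retained) / len(retained)
                   if retained else None)
    return TriageCurve(thresholds=thresholds,
                       benign_retained_frac=tuple(ben),
                       malignant_retained_frac=tuple(mal),
                       retained_accuracy=tuple(acc),
                       excluded_frac=tuple(exc))


@dataclass(frozen=True)
class TriageReport:
    threshold: float
    n_total: int
    n_excluded: int
    n_retained_correct: int
    n_retained_incorrect: int
    retained_accuracy: float | None      # %, None when everything is excluded
    baseline_accuracy: float             # %

    def as_dict(self) -> dict:
        return {"threshold": self.threshold, "n_total": self.n_total,
                "n_excluded": self.n_excluded,
                "n_retained_correct": self.n_retained_correct,
                "n_retained_incorrect": self.n_retained_incorrect,
                "retained_accuracy": self.retained_accuracy,
                "baseline_accuracy": self.baseline_accuracy}


def triage_report(records, threshold: float = 0.86) -> TriageReport:
    """Operating-point summary at one confidence threshold."""
    records = _check_records(records)
    retained = [r for r in records if r.confidence >= threshold]
    n_total = len(records)
    n_correct = sum(r.correct for r in retained)
    n_incorrect = len(retained) - n_correct
    retained_acc = (100.0 * n_correct / len(retained)) if retained else None
    baseline = 100.0 * sum(r.correct for r in records) / n_total
    return TriageReport(threshold=threshold, n_total=n_total,
                        n_excluded=n_total - len(retained),
                        n_retained_correct=n_correct,
                        n_retained_incorrect=n_incorrect,
                        retained_accuracy=retained_acc,
                        baseline_accuracy=baseline)


def records_from_frame(df: pd.DataFrame) -> list[PredictionRecord]:
    """Build records from a frame with image_id/truth/predicted/confidence."""
    return [PredictionRecord(image_id=str(r.image_id), truth=r.truth,
                             predicted=r.predicted,
                             confidence=float(r.confidence))
            for r in df.itertuples(index=False)]
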