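"""Ensemble decision rules over per-model confidence vectors.

Three rules combine the softmax outputs of several classifiers:

* majority vote — each model votes its argmax; ties fall back to the
  confidence sum over the tied classes;
* confidence sum — soft voting: per-class scores are summed and the argmax
  wins;
* weighted confidence sum — as above, but the model with the highest
  per-class accuracy gets its score for that class multiplied by a weight
  factor (default 1.5) before summation.

Exact ties resolve to malignant: missing a malignancy is the costlier
error. Every decision carries a normalized confidence in [0, 1] (winning
combined score over the attainable maximum) so the triage analysis can
compare strategies on one scale.

Also hosts the accuracy/time backbone-selection rule used to pick which
trained models enter the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthgen import BENIGN, CLASSES, MALIGNANT

_N_CLASSES = len(CLASSES)
_MALIGNANT_IDX = CLASSES.index(MALIGNANT)


@dataclass(frozen=True)
class ConfidenceVector:
    scores: tuple[float, float]          # ordered (benign, malignant)
    model_id: str = ""

    def validate(self) -> None:
        if len(self.scores) != _N_CLASSES:
            raise ValueError("expected one score per class")
        if any(s < -1e-9 or s > 1 + 1e-9 for s in self.scores):
            raise ValueError(f"scores {self.scores} outside [0, 1]")
        if abs(sum(self.scores) - 1.0) > 1e-6:
            raise ValueError(f"scores {self.scores} do not sum to 1")

    @property
    def argmax_label(self) -> str:
        # exact tie resolves to malignant
        if self.scores[_MALIGNANT_IDX] >= self.scores[1 - _MALIGNANT_IDX]:
            return MALIGNANT
        return BENIGN


@dataclass(frozen=True)
class EnsembleConfig:
    strategy: str = "sum"                # vote | sum | weighted_sum
    weight_factor: float = 1.5
    best_model_per_class: dict[str, str] | None = None

    def validate(self) -> None:
        if self.strategy not in ("vote", "sum", "weighted_sum"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.weight_factor <= 0:
            raise ValueError("weight_factor must be positive")
        if self.strategy == "weighted_sum":
            if (self.best_model_per_class is None
                    or set(self.best_model_per_class) != set(CLASSES)):
                raise ValueError("weighted_sum requires best_model_per_class "
                                 "covering both classes")


@dataclass(frozen=True)
class EnsembleDecision:
    label: str
    confidence: float
    per_class_combined: tuple[float, float]


def _decide(per_class: np.ndarray, denom: float) -> EnsembleDecision:
    if per_class[_MALIGNANT_IDX] >= per_class[1 - _MALIGNANT_IDX]:
        winner = _MALIGNANT_IDX
    else:
        winner = 1 - _MALIGNANT_IDX
    return EnsembleDecision(label=CLASSES[winner],
                            confidence=float(per_class[winner] / denom),
                            per_class_combined=tuple(float(v) for v in per_class))


def _check(vectors) -> list[ConfidenceVector]:
    vectors = list(vectors)
    if not vectors:
        raise ValueError("at least one confidence vector is required")
    for v in vectors:
        v.validate()
    return vectors


def confidence_sum(vectors) -> EnsembleDecision:
    """Soft voting: per-class sum of scores, argmax wins (ties -> malignant).

    Confidence is the winning combined score divided by the model count.
    """
    vectors = _check(vectors)
    per_class = np.sum([v.scores for v in vectors], axis=0)
    return _decide(per_class, denom=len(vectors))


def majority_vote(vectors) -> EnsembleDecision:
    """Hard voting; a tied vote falls back to the confidence sum restricted
    to the tied classes. Confidence is the winning label's vote share."""
    vectors = _check(vectors)
    votes = np.zeros(_N_CLASSES)
    for v in vectors:
        votes[CLASSES.index(v.argmax_label)] += 1
    top = votes.max()
    tied = np.nonzero(votes == top)[0]
    if len(tied) == 1:
        winner = int(tied[0])
    else:
        sums = np.sum([v.scores for v in vectors], axis=0)
        masked = np.full(_N_CLASSES, -np.inf)
        masked[tied] = sums[tied]
        if masked[_MALIGNANT_IDX] >= masked[1 - _MALIGNANT_IDX]:
            winner = _MALIGNANT_IDX
        else:
            winner = 1 - _MALIGNANT_IDX
    return EnsembleDecision(label=CLASSES[winner],
                            confidence=float(votes[winner] / len(vectors)),
                            per_class_combined=tuple(float(v) for v in votes))


def weighted_confidence_sum(vectors, config: EnsembleConfig) -> EnsembleDecision:
    """Confidence sum with the per-class best model's score multiplied by
    config.weight_factor before summation.

    Confidence is normalized by (n_models - 1 + weight_factor), the maximum
    attainable combined score.
    """
    vectors = _check(vectors)
    cfg = EnsembleConfig(strategy="weighted_sum",
                         weight_factor=config.weight_factor,
                         best_model_per_class=config.best_model_per_class)
    cfg.validate()
    ids = [v.model_id for v in vectors]
    for cls, mid in cfg.best_model_per_class.items():
        if mid not in ids:
            raise ValueError(f"best model {mid!r} for class {cls!r} not among "
                             f"the supplied vectors {ids}")
    per_class = np.zeros(_N_CLASSES)
    for v in vectors:
        for ci, cls in enumerate(CLASSES):
            w = cfg.weight_factor if cfg.best_model_per_class[cls] == v.model_id else 1.0
            per_class[ci] += w * v.scores[ci]
    return _decide(per_class, denom=len(vectors) - 1 + cfg.weight_factor)


def ensemble_confidence(decision: EnsembleDecision) -> float:
    """The decision's normalized winning combined score, in [0, 1]."""
    return decision.confidence


def apply_strategy(vectors, config: EnsembleConfig) -> EnsembleDecision:
    config.validate()
    if config.strategy == "vote":
        return majority_vote(vectors)
    if config.strategy == "sum":
        return confidence_sum(vectors)
    return weighted_confidence_sum(vectors, config)


def select_backbones(accuracies: dict[str, float], times: dict[str, float],
                     k: int) -> list[str]:
    """Rank models by accuracy/time ratio (descending) and return the top k.

    Ties break toward the higher accuracy. Emulates picking the models with
    the best accuracy-per-second before forming the ensemble.
    """
    if set(accuracies) != set(times):
        raise ValueError("accuracies and times must cover the same models")
    if k > len(accuracies):
        raise ValueError("k exceeds the number of models")
    for mid, t in times.items():
        if t <= 0:
            raise ValueError(f"non-positive time for model {mid!r}")
    ranked = sorted(accuracies,
                    key=lambda m: (-accuracies[m] / times[m], -accuracies[m], m))
    return ranked[:k]


# --- CSV interchange --------------------------------------------------------

def scores_to_frame(image_ids, vectors_per_image) -> pd.DataFrame:
    rows = []
    for img_id, vectors in zip(image_ids, vectors_per_image):
        for v in vectors:
            rows.append({"image_id": img_id, "model_id": v.model_id,
                         "score_benign": v.scores[0],
                         "score_malignant": v.scores[1]})
    return pd.DataFrame(rows)


def frame_to_scores(df: pd.DataFrame):
    """Inverse of scores_to_frame: {image_id: [ConfidenceVector, ...]}."""
    out: dict[str, list[ConfidenceVector]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["image_id"], []).append(ConfidenceVector(
            scores=(float(row["score_benign"]), float(row["score_malignant"])),
            model_id=str(row["model_id"])))
    return out


def decisions_to_frame(image_ids, strategies, decisions) -> pd.DataFrame:
    return pd.DataFrame([
        {"image_id": i, "strategy": s, "label": d.label,
         "confidence": d.confidence}
        for i, s, d in zip(image_ids, strategies, decisions)])
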