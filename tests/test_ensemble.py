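import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ovus.ensemble import (ConfidenceVector, EnsembleConfig, confidence_sum,
                           ensemble_confidence, majority_vote,
                           select_backbones, weighted_confidence_sum)
from ovus.synthgen import BENIGN, MALIGNANT


def _cv(b, m=None, model_id=""):
    if m is None:
        m = 1.0 - b
    return ConfidenceVector(scores=(b, m), model_id=model_id)


# --- independent brute-force reference rules (used as the oracle) ----------

def _oracle_vote(vectors):
    votes = {BENIGN: 0, MALIGNANT: 0}
    for v in vectors:
        if v.scores[1] >= v.scores[0]:
            votes[MALIGNANT] += 1
        else:
            votes[BENIGN] += 1
    if votes[BENIGN] != votes[MALIGNANT]:
        return max(votes, key=votes.get)
    sums = [sum(v.scores[i] for v in vectors) for i in range(2)]
    return MALIGNANT if sums[1] >= sums[0] else BENIGN


def _oracle_sum(vectors):
    sums = [sum(v.scores[i] for v in vectors) for i in range(2)]
    return MALIGNANT if sums[1] >= sums[0] else BENIGN


def _oracle_weighted(vectors, best, factor):
    sums = [0.0, 0.0]
    for v in vectors:
        for i, cls in enumerate((BENIGN, MALIGNANT)):
            w = factor if best[cls] == v.model_id else 1.0
            sums[i] += w * v.scores[i]
    return MALIGNANT if sums[1] >= sums[0] else BENIGN


class TestMajorityVote:
    def test_vote_counting(self):
        d = majority_vote([_cv(0.8), _cv(0.7), _cv(0.2)])
        assert d.label == BENIGN
        assert d.confidence == pytest.approx(2 / 3)

    def test_unanimous(self):
        d = majority_vote([_cv(0.1), _cv(0.2), _cv(0.3)])
        assert d.label == MALIGNANT and d.confidence == 1.0

    def test_tie_falls_back_to_confidence_sum(self):
        # benign sum 1.1 vs malignant 0.9 -> the sum fallback elects benign
        d = majority_vote([_cv(0.9, 0.1), _cv(0.2, 0.8)])
        assert d.label == BENIGN

    def test_tie_with_equal_sums_resolves_malignant(self):
        d = majority_vote([_cv(0.7, 0.3), _cv(0.3, 0.7)])
        assert d.label == MALIGNANT

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestConfidenceSum:
    def test_arithmetic(self):
        d = confidence_sum([_cv(0.9), _cv(0.4), _cv(0.8)])
        assert d.label == BENIGN
        assert d.per_class_combined == pytest.approx((2.1, 0.9))
        assert d.confidence == pytest.approx(0.7)

    def test_single_model_identity(self):
        d = confidence_sum([_cv(0.3, 0.7)])
        assert d.label == MALIGNANT and d.confidence == pytest.approx(0.7)

    def test_exact_tie_resolves_malignant(self):
        d = confidence_sum([_cv(0.5), _cv(0.5)])
        assert d.label == MALIGNANT

    def test_invalid_vector_rejected(self):
        with pytest.raises(ValueError):
            confidence_sum([ConfidenceVector(scores=(0.9, 0.9))])


class TestWeightedConfidenceSum:
    def _cfg(self, factor=1.5):
        return EnsembleConfig(strategy="weighted_sum", weight_factor=factor,
                              best_model_per_class={BENIGN: "m0",
                                                    MALIGNANT: "m1"})

    def test_arithmetic(self):
        vectors = [_cv(0.9, model_id="m0"), _cv(0.4, model_id="m1"),
                   _cv(0.8, model_id="m2")]
        d = weighted_confidence_sum(vectors, self._cfg())
        assert d.per_class_combined == pytest.approx((2.55, 1.2))
        assert d.label == BENIGN
        assert d.confidence == pytest.approx(2.55 / 3.5)

    def test_factor_one_reduces_to_confidence_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            bs = rng.random(3)
            vectors = [_cv(b, model_id=f"m{i}") for i, b in enumerate(bs)]
            dw = weighted_confidence_sum(vectors, self._cfg(factor=1.0))
            ds = confidence_sum(vectors)
            assert dw.label == ds.label
            assert dw.per_class_combined == pytest.approx(ds.per_class_combined)

    def test_weight_can_flip_the_argmax(self):
        # found by exhaustive search over a coarse score grid: the x1.5
        # weight on m1's malignant score overturns the unweighted decision
        found = None
        grid = [round(0.1 * k, 1) for k in range(11)]
        for b0, b1, b2 in itertools.product(grid, repeat=3):
            vectors = [_cv(b0, model_id="m0"), _cv(b1, model_id="m1"),
                       _cv(b2, model_id="m2")]
            plain = _oracle_sum(vectors)
            weighted = _oracle_weighted(
                vectors, {BENIGN: "m0", MALIGNANT: "m1"}, 1.5)
            if plain != weighted:
                found = vectors
                break
        assert found is not None
        d = weighted_confidence_sum(found, self._cfg())
        assert d.label == weighted

    def test_rejects_missing_model_id(self):
        vectors = [_cv(0.9, model_id="mX"), _cv(0.4, model_id="m1")]
        with pytest.raises(ValueError):
            weighted_confidence_sum(vectors, self._cfg())


class TestEnsembleConfidence:
    def test_unanimous_perfect_scores(self):
        d = confidence_sum([_cv(1.0, 0.0)] * 3)
        assert ensemble_confidence(d) == pytest.approx(1.0)

    def test_maximal_disagreement(self):
        d = confidence_sum([_cv(0.5)] * 3)
        assert ensemble_confidence(d) == pytest.approx(0.5)

    def test_bounded_for_random_inputs(self):
        rng = np.random.default_rng(1)
        cfg = EnsembleConfig(strategy="weighted_sum", weight_factor=1.5,
                             best_model_per_class={BENIGN: "m0",
                                                   MALIGNANT: "m1"})
        for _ in range(200):
            vectors = [_cv(float(b), model_id=f"m{i}")
                       for i, b in enumerate(rng.random(3))]
            for d in (majority_vote(vectors), confidence_sum(vectors),
                      weighted_confidence_sum(vectors, cfg)):
                assert 0.0 <= ensemble_confidence(d) <= 1.0


@settings(deadline=None, max_examples=60)
@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=5))
def test_permutation_invariance(benign_scores):
    vectors = [_cv(round(b, 6), model_id=f"m{i}")
               for i, b in enumerate(benign_scores)]
    cfg = EnsembleConfig(strategy="weighted_sum", weight_factor=1.5,
                         best_model_per_class={BENIGN: "m0", MALIGNANT: "m1"})
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(len(vectors)))
    shuffled = [vectors[i] for i in perm]
    assert majority_vote(vectors).label == majority_vote(shuffled).label
    assert confidence_sum(vectors).label == confidence_sum(shuffled).label
    assert (weighted_confidence_sum(vectors, cfg).label
            == weighted_confidence_sum(shuffled, cfg).label)


def test_single_model_vote_is_argmax():
    for b in (0.2, 0.5, 0.8):
        assert majority_vote([_cv(b)]).label == _cv(b).argmax_label


class TestSelectBackbones:
    # accuracy/time values as published for the ten reference architectures
    TABLE_ACC = {"ResNet-50": 90.51, "ResNet-101": 90.15, "ResNet-18": 89.90,
                 "DenseNet-201": 89.79, "Inception-V3": 89.79,
                 "Darknet-53": 89.53, "ShuffleNet": 89.40, "Xception": 88.79,
                 "Darknet-19": 88.28, "MobileNet-v2": 87.41}
    TABLE_TIME = {"ResNet-18": 0.32, "Xception": 0.67, "ResNet-50": 0.81,
                  "ShuffleNet": 0.83, "Darknet-19": 0.97, "MobileNet-v2": 1.21,
                  "Darknet-53": 1.27, "ResNet-101": 1.58, "Inception-V3": 1.90,
                  "DenseNet-201": 1.96}

    def test_reference_tables_rank_resnet18_first(self):
        top3 = select_backbones(self.TABLE_ACC, self.TABLE_TIME, k=3)
        assert top3[0] == "ResNet-18"   # 89.90 / 0.32 = 280.9, the best ratio
        assert top3 == ["ResNet-18", "Xception", "ResNet-50"]

    def test_k_equals_all_returns_ordered_full_list(self):
        out = select_backbones(self.TABLE_ACC, self.TABLE_TIME, k=10)
        ratios = [self.TABLE_ACC[m] / self.TABLE_TIME[m] for m in out]
        assert ratios == sorted(ratios, reverse=True)

    def test_equal_accuracy_orders_by_ascending_time(self):
        acc = {"a": 90.0, "b": 90.0, "c": 90.0}
        times = {"a": 0.5, "b": 0.2, "c": 0.9}
        assert select_backbones(acc, times, k=3) == ["b", "a", "c"]

    def test_rejects_nonpositive_time(self):
        with pytest.raises(ValueError):
            select_backbones({"a": 90.0, "b": 80.0}, {"a": 0.0, "b": 1.0}, k=1)
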