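import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alarmforest.metrics import (ConfusionCounts, auc, candidate_thresholds,
                                 challenge_score, confusion, roc_curve,
                                 tpr_tnr, youden_cutoff)


# -- independent oracles ----------------------------------------------------

def pair_count_auc(scores, labels):
    """P(score_pos > score_neg) with ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Max J over an exhaustive threshold sweep (strict-> rule)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    best = -np.inf
    for t in np.concatenate((np.unique(scores) - 1e-9, np.unique(scores),
                             [scores.min() - 1.0, scores.max() + 1.0])):
        tpr = (scores[y] > t).mean()
        fpr = (scores[~y] > t).mean()
        best = max(best, tpr + (1 - fpr))
    return best


def scores_labels(draw, n_max=30):
    n = draw(st.integers(3, n_max))
    scores = draw(st.lists(
        st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n))
    labels = draw(st.lists(st.booleans(), min_size=n, max_size=n)
                  .filter(lambda ls: any(ls) and not all(ls)))
    return np.asarray(scores, dtype=float), np.asarray(labels)


mixed_instances = st.composite(scores_labels)


# -- confusion matrix and score ---------------------------------------------

def test_confusion_hand_count():
    cc = confusion(["YES"] * 3 + ["NO"] * 2, ["YES", "YES", "NO", "NO", "NO"])
    assert (cc.tp, cc.fn, cc.tn, cc.fp) == (2, 1, 2, 0)
    assert challenge_score(cc) == pytest.approx(100 * 4 / 9)
    assert tpr_tnr(cc) == pytest.approx((2 / 3, 1.0))


def test_confusion_degenerate_cases():
    y = ["YES", "NO", "YES"]
    perfect = confusion(y, y)
    assert perfect.fp == perfect.fn == 0
    assert challenge_score(perfect) == 100.0
    flipped = confusion(y, ["NO", "YES", "NO"])
    assert flipped.tp == flipped.tn == 0
    assert challenge_score(flipped) == 0.0
    with pytest.raises(ValueError):
        confusion(["YES"], ["YES", "NO"])


def test_undefined_marginals_are_nan_not_zero():
    tpr, tnr = tpr_tnr(ConfusionCounts(tp=2, fp=0, tn=0, fn=1))
    assert tpr == pytest.approx(2 / 3) and np.isnan(tnr)
    tpr, tnr = tpr_tnr(ConfusionCounts(tp=0, fp=1, tn=3, fn=0))
    assert np.isnan(tpr) and tnr == pytest.approx(3 / 4)


def test_score_bounded_by_accuracy_with_equality_iff_no_fn():
    rng = np.random.default_rng(0)
    for _ in range(50):
        tp, fp, tn, fn = rng.integers(0, 8, size=4)
        if tp + fp + tn + fn == 0:
            continue
        cc = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
        accuracy = 100 * (cc.tp + cc.tn) / cc.total
        assert challenge_score(cc) <= accuracy + 1e-12
        assert (challenge_score(cc) == pytest.approx(accuracy)) == (
            fn == 0 or tp + tn == 0)


def test_score_monotone_nonincreasing_in_fn():
    scores = [challenge_score(ConfusionCounts(3, 2, 4, fn)) for fn in range(6)]
    assert all(a >= b for a, b in zip(scores, scores[1:]))


# -- ROC / AUC ---------------------------------------------------------------

def test_roc_curve_shape_and_endpoints():
    curve = roc_curve([0.1, 0.35, 0.4, 0.8], [False, False, True, True])
    assert ((curve["tpr"] == 1) & (curve["fpr"] == 0)).any()  # perfect corner
    # trivial endpoints present, monotone in threshold
    assert curve.iloc[0][["tpr", "fpr"]].tolist() == [1.0, 1.0]
    assert curve.iloc[-1][["tpr", "fpr"]].tolist() == [0.0, 0.0]
    assert (curve["tpr"].diff().dropna() <= 1e-12).all()
    assert (curve["fpr"].diff().dropna() <= 1e-12).all()


def test_constant_scores_give_chance_auc():
    assert auc([0.3] * 6, [True, False] * 3) == pytest.approx(0.5)
    assert auc([0.2, 0.2], [True, False]) == pytest.approx(0.5)


def test_auc_hand_examples():
    assert auc([0.6, 0.3, 0.4, 0.2], [True, True, False, False]) == pytest.approx(0.75)
    assert auc([0.9, 0.8, 0.1], [True, True, False]) == 1.0


def test_single_class_labels_raise():
    with pytest.raises(ValueError):
        auc([0.1, 0.2], [True, True])
    with pytest.raises(ValueError):
        youden_cutoff([0.1, 0.2], [False, False])


@settings(deadline=None, derandomize=True, max_examples=120)
@given(mixed_instances())
def test_auc_equals_pair_counting(case):
    scores, labels = case
    assert auc(scores, labels) == pytest.approx(pair_count_auc(scores, labels))


# -- Youden cutoff -----------------------------------------------------------

def test_youden_four_point_example():
    res = youden_cutoff([0.1, 0.35, 0.4, 0.8], [False, False, True, True])
    assert res.threshold == pytest.approx(0.375)
    assert res.j == pytest.approx(2.0)


def test_youden_constant_scores_uninformative():
    res = youden_cutoff([0.4] * 5, [True, False, True, False, False])
    assert res.j == pytest.approx(1.0)


def test_youden_prefers_smallest_maximizing_threshold():
    # J is maximal both below 0.3 and below 0.7; sensitivity-favoring tie rule
    res = youden_cutoff([0.1, 0.3, 0.7, 0.9], [False, True, False, True])
    assert res.threshold < 0.3


@settings(deadline=None, derandomize=True, max_examples=120)
@given(mixed_instances())
def test_youden_matches_brute_force(case):
    scores, labels = case
    res = youden_cutoff(scores, labels)
    assert res.j == pytest.approx(brute_force_youden(scores, labels))
    # the reported threshold actually achieves the reported J
    tpr = (scores[labels] > res.threshold).mean()
    fpr = (scores[~labels] > res.threshold).mean()
    assert tpr + (1 - fpr) == pytest.approx(res.j)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(mixed_instances())
def test_youden_j_invariant_under_monotone_transform(case):
    scores, labels = case
    transformed = np.exp(3.0 * scores) - 0.5
    a = youden_cutoff(scores, labels)
    b = youden_cutoff(transformed, labels)
    assert a.j == pytest.approx(b.j)


def test_fixed_grid_mode():
    grid = np.arange(0.0, 1.01, 0.02)
    res = youden_cutoff([0.1, 0.35, 0.4, 0.8], [False, False, True, True],
                        thresholds=grid)
    assert res.j == pytest.approx(2.0)
    assert res.threshold in grid


def test_candidate_thresholds_bracket_the_scores():
    cands = candidate_thresholds([0.2, 0.4, 0.4, 0.9])
    assert cands[0] < 0.2 and cands[-1] == 0.9
    assert np.isclose(cands, 0.3).any() and np.isclose(cands, 0.65).any()
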