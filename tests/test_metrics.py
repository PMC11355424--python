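"""The evaluation measures against an independent brute-force oracle.

The oracle below evaluates the printed formulas directly — per-class
precision/recall from counted TP/FP/FN, share-weighted averages, their
harmonic mean, and the one-hot covariance correlation — with no shared
code with the implementation.
"""

import math
import random

import pytest
from sklearn.metrics import f1_score, matthews_corrcoef

from scmarker_ifs import (
    ValidationError,
    accuracy,
    confusion,
    evaluate,
    macro_f1,
    multiclass_mcc,
    weighted_f1,
)


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def oracle_metrics(y_true, y_pred):
    classes = sorted(set(y_true) | set(y_pred))
    n = len(y_true)
    tp = {c: sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c) for c in classes}
    fp = {c: sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c) for c in classes}
    fn = {c: sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c) for c in classes}
    w = {c: sum(1 for t in y_true if t == c) / n for c in classes}
    prec = {c: tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else 0.0 for c in classes}
    rec = {c: tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else 0.0 for c in classes}
    pw = sum(w[c] * prec[c] for c in classes)
    rw = sum(w[c] * rec[c] for c in classes)
    wf1 = 2 * pw * rw / (pw + rw) if pw + rw else 0.0
    f1 = {
        c: 2 * prec[c] * rec[c] / (prec[c] + rec[c]) if prec[c] + rec[c] else 0.0
        for c in classes
    }
    mf1 = sum(f1.values()) / len(classes)
    acc = sum(1 for t, p in zip(y_true, y_pred) if t == p) / n
    # one-hot covariance MCC
    L = len(classes)
    X = [[1.0 if t == c else 0.0 for c in classes] for t in y_true]
    Y = [[1.0 if p == c else 0.0 for c in classes] for p in y_pred]
    mx = [sum(row[k] for row in X) / n for k in range(L)]
    my = [sum(row[k] for row in Y) / n for k in range(L)]
    cxy = sum((X[i][k] - mx[k]) * (Y[i][k] - my[k]) for i in range(n) for k in range(L))
    cxx = sum((X[i][k] - mx[k]) ** 2 for i in range(n) for k in range(L))
    cyy = sum((Y[i][k] - my[k]) ** 2 for i in range(n) for k in range(L))
    mcc = cxy / math.sqrt(cxx * cyy) if cxx and cyy else 0.0
    return acc, mcc, mf1, wf1


def random_pairs(n_pairs, seed=0):
    rng = random.Random(seed)
    for _ in range(n_pairs):
        n = rng.randint(1, 50)
        L = rng.randint(2, 6)
        classes = [chr(ord("A") + i) for i in range(L)]
        y_true = [rng.choice(classes) for _ in range(n)]
        y_pred = [rng.choice(classes) for _ in range(n)]
        yield y_true, y_pred


def test_oracle_equivalence_on_random_pairs():
    """All four measures match the brute-force formula evaluation to 1e-12."""
    for y_true, y_pred in random_pairs(1000, seed=123):
        counts = confusion(y_true, y_pred)
        acc_o, mcc_o, mf1_o, wf1_o = oracle_metrics(y_true, y_pred)
        assert accuracy(y_true, y_pred) == pytest.approx(acc_o, abs=1e-12)
        assert multiclass_mcc(y_true, y_pred) == pytest.approx(mcc_o, abs=1e-12)
        assert macro_f1(counts) == pytest.approx(mf1_o, abs=1e-12)
        assert weighted_f1(counts) == pytest.approx(wf1_o, abs=1e-12)


def test_weighted_f1_is_harmonic_mean_of_weighted_averages():
    """true=[A,A,A,B], pred=[A,A,B,B]: P_w=0.875, R_w=0.75 → 0.80769…,
    which differs from the weighted-average-of-per-class-F1 (0.76667)."""
    y_true, y_pred = ["A", "A", "A", "B"], ["A", "A", "B", "B"]
    counts = confusion(y_true, y_pred)
    wf1 = weighted_f1(counts)
    assert wf1 == pytest.approx(2 * 0.875 * 0.75 / 1.625, abs=1e-12)
    assert wf1 == pytest.approx(0.80769, abs=1e-5)
    conventional = f1_score(y_true, y_pred, average="weighted")
    assert conventional == pytest.approx(0.76667, abs=1e-5)
    assert abs(wf1 - conventional) > 0.01


def test_weighted_f1_majority_predictor():
    """2 classes with shares (0.9, 0.1), always predicting the majority."""
    y_true = ["M"] * 9 + ["m"]
    y_pred = ["M"] * 10
    wf1 = weighted_f1(confusion(y_true, y_pred))
    assert wf1 == pytest.approx(2 * 0.81 * 0.9 / (0.81 + 0.9), abs=1e-12)
    assert wf1 == pytest.approx(0.85263, abs=1e-5)


def test_worked_example_other_measures():
    y_true, y_pred = ["A", "A", "A", "B"], ["A", "A", "B", "B"]
    counts = confusion(y_true, y_pred)
    assert counts.tp.tolist() == [2, 1]
    assert counts.fn.tolist() == [1, 0]
    assert counts.fp.tolist() == [0, 1]
    assert counts.weights.tolist() == [0.75, 0.25]
    assert accuracy(y_true, y_pred) == 0.75
    assert macro_f1(counts) == pytest.approx((0.8 + 2 / 3) / 2, abs=1e-12)


@pytest.mark.parametrize(
    "y_true,y_pred,expected",
    [
        (["A", "B", "A", "B"], ["A", "B", "A", "B"], 1.0),     # perfect
        (["A", "A", "B", "B"], ["A", "B", "A", "B"], 0.0),     # TP=TN=FP=FN=1
        (["A", "B", "A", "B"], ["B", "A", "B", "A"], -1.0),    # total inversion
    ],
)
def test_mcc_reference_points(y_true, y_pred, expected):
    assert multiclass_mcc(y_true, y_pred) == pytest.approx(expected, abs=1e-12)


def test_mcc_matches_sklearn_multiclass():
    """The one-hot covariance form equals the Gorodkin R_K statistic."""
    for y_true, y_pred in random_pairs(50, seed=7):
        ours = multiclass_mcc(y_true, y_pred)
        theirs = matthews_corrcoef(y_true, y_pred)
        assert ours == pytest.approx(theirs, abs=1e-10)


def test_mcc_invariant_to_class_relabeling():
    rng = random.Random(5)
    y_true = [rng.choice("ABCD") for _ in range(40)]
    y_pred = [rng.choice("ABCD") for _ in range(40)]
    perm = {"A": "C", "B": "D", "C": "A", "D": "B"}
    assert multiclass_mcc(y_true, y_pred) == pytest.approx(
        multiclass_mcc([perm[t] for t in y_true], [perm[p] for p in y_pred]),
        abs=1e-12,
    )


def test_perfect_iff_all_metrics_one():
    ms = evaluate(["A", "B", "C"], ["A", "B", "C"])
    assert (ms.acc, ms.macro_f1, ms.weighted_f1) == (1.0, 1.0, 1.0)
    ms2 = evaluate(["A", "B", "C"], ["A", "B", "B"])
    assert ms2.acc < 1 and ms2.macro_f1 < 1 and ms2.weighted_f1 < 1


def test_errors():
    with pytest.raises(ValidationError):
        confusion(["A"], ["A", "B"])
    with pytest.raises(ValidationError):
        accuracy([], [])
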