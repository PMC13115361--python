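"""Binary gate, threshold tuner, stage head, routing and metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import balanced_accuracy_score

from ckdtriage.model import (
    BinaryHead,
    ModelConfig,
    STAGE_CLASS_ORDER,
    TrainingError,
    evaluate,
    predict_route,
    threshold_grid,
    train_binary,
    train_stage,
    tune_threshold,
)
from ckdtriage.cohort import default_cohort_spec, generate_cohort
from ckdtriage.preprocessing import apply_imputer, apply_scaler, fit_imputer, fit_scaler
from conftest import make_table


# --------------------------------------------------------- threshold tuner

def test_grid_has_81_points():
    grid = threshold_grid(0.10, 0.90, 0.01)
    assert len(grid) == 81
    assert grid[0] == pytest.approx(0.10) and grid[-1] == pytest.approx(0.90)


def test_tuner_hand_worked_example():
    # probs (0.1, 0.2, 0.8, 0.9), labels (0, 0, 1, 1): tau = 0.21 is the
    # smallest grid point with balanced accuracy 1.0 under the >= rule.
    tau = tune_threshold(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
    assert tau == pytest.approx(0.21)


def test_tuner_matches_brute_force_on_random_sets():
    rng = np.random.default_rng(42)
    grid = threshold_grid()
    for _ in range(50):
        probs = rng.random(50)
        labels = rng.integers(0, 2, 50)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        tau = tune_threshold(probs, labels)
        scores = [
            balanced_accuracy_score(labels, (probs >= t).astype(int)) for t in grid
        ]
        best = max(scores)
        expected = float(grid[int(np.argmax(np.array(scores) >= best - 1e-12))])
        assert tau == pytest.approx(expected)


def test_tuner_one_class_validation_raises():
    with pytest.raises(TrainingError):
        tune_threshold(np.array([0.2, 0.8]), np.array([1, 1]))


# -------------------------------------------------------------- binary head

def _prepared(separation, n=400, seed=0):
    cohort = generate_cohort(
        default_cohort_spec(n_patients=n, separation=separation, seed=seed,
                            include_sparse=False)
    )
    imp = fit_imputer(cohort, seed=seed)
    completed = apply_imputer(imp, cohort)
    scaler = fit_scaler(completed, "binary")
    return apply_scaler(scaler, completed)


def test_binary_head_separable_cohort_high_training_auc():
    table = _prepared(separation=3.0, seed=1)
    head = train_binary(table, table.labels, tuple(table.feature_names))
    from sklearn.metrics import roc_auc_score

    probs = head.predict_proba(table)
    assert roc_auc_score(table.binary_labels(), probs) >= 0.99


def test_binary_head_retains_training_probability_sets():
    table = _prepared(separation=1.0, seed=2)
    head = train_binary(table, table.labels, tuple(table.feature_names))
    assert len(head.p0_train) + len(head.p1_train) == table.n_patients
    assert len(head.p0_train) == int((table.labels == 0).sum())


def test_binary_single_class_raises():
    table = make_table({"A": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]}, labels=[1, 2, 3, 4, 1, 2])
    with pytest.raises(TrainingError):
        train_binary(table, table.labels, ("A",))


# --------------------------------------------------------------- stage head

def test_stage_head_probabilities_sum_to_one_and_fit_quality():
    cohort = generate_cohort(
        default_cohort_spec(n_patients=600, separation=3.0, seed=3,
                            include_sparse=False)
    )
    imp = fit_imputer(cohort, seed=3)
    completed = apply_imputer(imp, cohort)
    ckd_ids = completed.labels.index[completed.labels > 0]
    ckd = completed.subset(ckd_ids)
    scaler = fit_scaler(ckd, "stage")
    scaled = apply_scaler(scaler, ckd)
    head = train_stage(scaled, scaled.labels, tuple(scaled.feature_names))
    probs = head.predict_proba(scaled)
    assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-9
    from sklearn.metrics import f1_score

    pred = probs.argmax(axis=1) + 1
    assert f1_score(scaled.labels, pred, average="macro") >= 0.9
    assert set(head.fit_ids) == set(ckd_ids)


def test_stage_head_rejects_non_ckd_rows():
    table = make_table({"A": [0.1, 0.9, 0.2, 0.8]}, labels=[0, 1, 2, 3])
    with pytest.raises(TrainingError):
        train_stage(table, table.labels, ("A",))


def test_stage_head_warns_on_missing_class():
    rng = np.random.default_rng(0)
    table = make_table(
        {"A": rng.random(30)}, labels=[1, 2, 3] * 10
    )
    with pytest.warns(UserWarning, match="absent"):
        head = train_stage(table, table.labels, ("A",))
    probs = head.predict_proba(table)
    assert probs.shape == (30, 4)
    assert (probs[:, 3] == 0).all()  # stage 5 absent from training


# ------------------------------------------------------------------ routing

def _stub_heads(p_values, stage_probs):
    class B:
        def predict_proba(self, X):
            return np.column_stack([1 - np.asarray(p_values), p_values])

    class S:
        def predict_proba(self, X):
            return np.asarray(stage_probs)

    binary = BinaryHead(
        model=B(), family="stub", selected_features=("A",), threshold=0.5,
        p0_train=np.array([0.1]), p1_train=np.array([0.9]), fit_ids=(),
    )
    from ckdtriage.model import StageHead

    stage = StageHead(
        model=S(), family="stub", selected_features=("A",),
        class_order=STAGE_CLASS_ORDER, present_labels=(1, 2, 3, 4), fit_ids=(),
    )
    return binary, stage


def test_route_boundary_probability_is_ckd():
    table = make_table({"A": [0.0]})
    binary, stage = _stub_heads([0.5], [[0.1, 0.2, 0.3, 0.4]])
    routed = predict_route(table, table, binary, stage)[0]
    assert routed.path == "CKD"
    assert routed.stage == "stage 5"  # argmax of (0.1, 0.2, 0.3, 0.4)


def test_route_below_gate_has_no_stage():
    table = make_table({"A": [0.0]})
    binary, stage = _stub_heads([0.0], [[0.25, 0.25, 0.25, 0.25]])
    routed = predict_route(table, table, binary, stage)[0]
    assert routed.path == "non-CKD" and routed.stage is None
    assert routed.stage_probs is None


def test_route_stage_tie_breaks_toward_more_severe():
    table = make_table({"A": [0.0]})
    binary, stage = _stub_heads([0.9], [[0.4, 0.1, 0.1, 0.4]])
    routed = predict_route(table, table, binary, stage)[0]
    assert routed.stage == "stage 5"


def test_route_exclusivity_exactly_one_path():
    table = make_table({"A": [0.0] * 4})
    binary, stage = _stub_heads(
        [0.0, 0.49, 0.5, 1.0], [[0.7, 0.1, 0.1, 0.1]] * 4
    )
    for routed in predict_route(table, table, binary, stage):
        assert (routed.path == "CKD") == (routed.stage is not None)


# ------------------------------------------------------------------ metrics

def test_perfect_stage_predictions_score_one():
    y = np.array([1, 2, 3, 4, 1, 2, 3, 4])
    probs = np.eye(4)[y - 1]
    report = evaluate(y, y, "stage", probs=probs)
    for value in (report.accuracy, report.precision_macro, report.recall_macro,
                  report.f1_macro, report.auc_macro):
        assert value == pytest.approx(1.0)


def test_majority_classifier_closed_form():
    y = np.array([0] * 90 + [1] * 10)
    pred = np.zeros(100, dtype=int)
    report = evaluate(y, pred, "binary")
    assert report.accuracy == pytest.approx(0.9)
    assert report.balanced_accuracy == pytest.approx(0.5)


def test_macro_f1_matches_hand_confusion_matrix():
    # 4x4 confusion matrix laid out by hand:
    #        pred: 1  2  3  4
    # true 1:      3  1  0  0
    # true 2:      0  2  2  0
    # true 3:      1  0  3  0
    # true 4:      0  0  1  3
    y_true = [1]*4 + [2]*4 + [3]*4 + [4]*4
    y_pred = [1, 1, 1, 2] + [2, 2, 3, 3] + [1, 3, 3, 3] + [3, 4, 4, 4]
    report = evaluate(np.array(y_true), np.array(y_pred), "stage")
    # per-class precision: 3/4, 2/3, 3/6, 3/3; recall: 3/4, 2/4, 3/4, 3/4
    f1 = []
    for p, r in ((3/4, 3/4), (2/3, 2/4), (3/6, 3/4), (1.0, 3/4)):
        f1.append(2 * p * r / (p + r))
    assert report.f1_macro == pytest.approx(np.mean(f1))


def test_evaluate_length_mismatch_raises():
    with pytest.raises(ValueError):
        evaluate(np.array([1, 2]), np.array([1]), "stage")
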