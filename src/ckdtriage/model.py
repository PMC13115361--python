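"""Hierarchical two-level decision model.

A probabilistic binary gate first estimates p(CKD); records at or above a
validation-tuned threshold are routed to a four-class stage head (stages
3a, 3b, 4, 5), everything below the gate goes to the risk-assessment path.
The threshold is tuned once on validation data — by maximising balanced
accuracy over the grid 0.10–0.90 in steps of 0.01 — and then frozen, so
test-time routing can never silently re-tune it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.neural_network import MLPClassifier

from .cohort import CohortTable
from .selection import make_estimator

__all__ = [
    "ModelConfig",
    "BinaryHead",
    "StageHead",
    "RoutedPrediction",
    "MetricsReport",
    "train_binary",
    "tune_threshold",
    "threshold_grid",
    "train_stage",
    "predict_route",
    "evaluate",
    "STAGE_CLASS_ORDER",
]

#: Stage-head class order; index i maps to cohort label i + 1.
STAGE_CLASS_ORDER = ("stage 3a", "stage 3b", "stage 4", "stage 5")


@dataclass(frozen=True)
class ModelConfig:
    """Head families and sizes; defaults mirror the deployed configuration:
    a boosted-tree binary gate on 26 recursively selected features and a
    feed-forward stage head (hidden widths 128, 64, iteration cap 700) on
    the 22 top-scoring features."""

    binary_family: str = "xgboost"
    binary_selection: str = "rfe"
    binary_k: int = 26
    stage_hidden: tuple[int, int] = (128, 64)
    stage_max_iter: int = 700
    stage_k: int = 22
    threshold_lo: float = 0.10
    threshold_hi: float = 0.90
    threshold_step: float = 0.01
    seed: int = 0


class TrainingError(ValueError):
    pass


@dataclass
class BinaryHead:
    """Trained CKD-vs-non-CKD gate.

    Retains the training probability sets P0 (non-CKD rows) and P1 (CKD
    rows) for quantile-anchor fitting, and the tuned threshold tau once
    :func:`tune_threshold` has been applied.
    """

    model: object
    family: str
    selected_features: tuple[str, ...]
    threshold: float | None
    p0_train: np.ndarray
    p1_train: np.ndarray
    fit_ids: tuple

    def predict_proba(self, table: CohortTable) -> np.ndarray:
        X = table.features[list(self.selected_features)].to_numpy()
        return self.model.predict_proba(X)[:, 1]


@dataclass
class StageHead:
    """Four-class stage classifier fitted on CKD-labelled rows only."""

    model: object
    family: str
    selected_features: tuple[str, ...]
    class_order: tuple[str, ...]
    present_labels: tuple[int, ...]
    fit_ids: tuple

    def predict_proba(self, table: CohortTable) -> np.ndarray:
        """Per-record probabilities over the full class order.

        Classes absent from training receive probability 0 so the output
        shape is stable even on degenerate cohorts.
        """
        X = table.features[list(self.selected_features)].to_numpy()
        raw = self.model.predict_proba(X)
        out = np.zeros((len(X), len(self.class_order)))
        for j, lab in enumerate(self.present_labels):
            out[:, lab - 1] = raw[:, j]
        return out


@dataclass(frozen=True)
class RoutedPrediction:
    patient_id: object
    path: str  # "CKD" | "non-CKD"
    p_ckd: float
    stage: str | None
    stage_probs: tuple[float, ...] | None


def train_binary(
    train_table: CohortTable,
    labels: pd.Series,
    selected_features: tuple[str, ...],
    config: ModelConfig = ModelConfig(),
) -> BinaryHead:
    """Fit the gate on scaled, imputed training rows.

    ``labels`` are the 5-class cohort labels; they are binarised here
    (CKD = stages 3a-5).  Training predictions are split into P0/P1 and
    kept on the head for anchor fitting.
    """
    y = (labels.loc[train_table.patient_ids].to_numpy() > 0).astype(int)
    if len(np.unique(y)) < 2:
        raise TrainingError("binary training labels contain a single class")
    cols = list(selected_features)
    X = train_table.features[cols].to_numpy()
    if config.binary_family == "mlp":
        model = MLPClassifier(
            hidden_layer_sizes=config.stage_hidden,
            max_iter=config.stage_max_iter,
            random_state=config.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
    else:
        model = make_estimator(config.binary_family, seed=config.seed, n_classes=2)
        model.fit(X, y)
    probs = model.predict_proba(X)[:, 1]
    return BinaryHead(
        model=model,
        family=config.binary_family,
        selected_features=tuple(cols),
        threshold=None,
        p0_train=probs[y == 0].copy(),
        p1_train=probs[y == 1].copy(),
        fit_ids=tuple(train_table.patient_ids),
    )


def threshold_grid(lo: float = 0.10, hi: float = 0.90, step: float = 0.01) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.round(np.linspace(lo, hi, n), 10)


def tune_threshold(
    val_probs: np.ndarray,
    val_labels: np.ndarray,
    grid_lo: float = 0.10,
    grid_hi: float = 0.90,
    step: float = 0.01,
) -> float:
    """Smallest grid threshold maximising balanced accuracy on validation.

    A record is called positive when p(CKD) >= tau (boundary inclusive).
    Choosing the smallest maximiser favours sensitivity at the gate, which
    is the clinically conservative direction for a screening first stage.
    """
    val_probs = np.asarray(val_probs, dtype=float)
    val_labels = np.asarray(val_labels).astype(int)
    if len(np.unique(val_labels)) < 2:
        raise TrainingError(
            "balanced accuracy undefined: validation labels contain one class"
        )
    best_tau, best_score = None, -np.inf
    for tau in threshold_grid(grid_lo, grid_hi, step):
        score = balanced_accuracy_score(val_labels, (val_probs >= tau).astype(int))
        if score > best_score + 1e-12:
            best_tau, best_score = float(tau), score
    return best_tau


def train_stage(
    train_table: CohortTable,
    labels: pd.Series,
    selected_features: tuple[str, ...],
    config: ModelConfig = ModelConfig(),
) -> StageHead:
    """Fit the stage head on CKD-labelled training rows only.

    ``train_table`` must already be restricted to CKD rows and transformed
    with the stage scaler.  A missing stage class is tolerated with a
    warning (its probability is reported as 0), fewer than two classes is
    an error.
    """
    y = labels.loc[train_table.patient_ids].to_numpy()
    if (y == 0).any():
        raise TrainingError("stage training rows must all be CKD-labelled")
    present = tuple(int(c) for c in np.unique(y))
    if len(present) < 2:
        raise TrainingError("stage training requires at least two stage classes")
    if len(present) < 4:
        warnings.warn(
            f"stage classes absent from training: "
            f"{sorted(set((1, 2, 3, 4)) - set(present))}",
            stacklevel=2,
        )
    cols = list(selected_features)
    model = MLPClassifier(
        hidden_layer_sizes=config.stage_hidden,
        max_iter=config.stage_max_iter,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(train_table.features[cols].to_numpy(), y)
    return StageHead(
        model=model,
        family="mlp",
        selected_features=tuple(cols),
        class_order=STAGE_CLASS_ORDER,
        present_labels=present,
        fit_ids=tuple(train_table.patient_ids),
    )


def _argmax_severe(probs: np.ndarray) -> int:
    """Argmax with ties broken toward the more severe stage."""
    best = probs.max()
    return int(np.flatnonzero(probs >= best - 1e-12)[-1])


def predict_route(
    binary_input: CohortTable,
    stage_input: CohortTable,
    binary_head: BinaryHead,
    stage_head: StageHead,
) -> list[RoutedPrediction]:
    """Route preprocessed records through the two-level decision.

    ``binary_input`` and ``stage_input`` are the same records prepared with
    the binary and stage scalers respectively.  p(CKD) >= tau routes to the
    stage head (maximum-probability stage, ties toward the more severe
    stage); below the gate the record leaves with path "non-CKD" and no
    stage.
    """
    if binary_head.threshold is None:
        raise TrainingError("binary head has no tuned threshold")
    p = binary_head.predict_proba(binary_input)
    stage_probs = stage_head.predict_proba(stage_input)
    out = []
    for i, pid in enumerate(binary_input.patient_ids):
        if p[i] >= binary_head.threshold:
            idx = _argmax_severe(stage_probs[i])
            out.append(
                RoutedPrediction(
                    patient_id=pid,
                    path="CKD",
                    p_ckd=float(p[i]),
                    stage=stage_head.class_order[idx],
                    stage_probs=tuple(float(q) for q in stage_probs[i]),
                )
            )
        else:
            out.append(
                RoutedPrediction(
                    patient_id=pid,
                    path="non-CKD",
                    p_ckd=float(p[i]),
                    stage=None,
                    stage_probs=None,
                )
            )
    return out


@dataclass(frozen=True)
class MetricsReport:
    task: str
    n: int
    accuracy: float
    balanced_accuracy: float | None
    precision_macro: float
    recall_macro: float
    f1_macro: float
    auc: float | None
    auc_macro: float | None
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "n": self.n,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "auc": self.auc,
            "auc_macro": self.auc_macro,
            "per_class": self.per_class,
        }


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    task: str,
    probs: np.ndarray | None = None,
) -> MetricsReport:
    """Macro-averaged metrics; both positive-class and macro AUC variants
    are emitted for the binary task.

    ``probs`` is the positive-class probability vector for binary, or the
    (n, n_classes) probability matrix for the stage task.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be non-empty and aligned")
    labels = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    kwargs = dict(labels=labels, average="macro", zero_division=0)
    auc = auc_macro = None
    if probs is not None:
        probs = np.asarray(probs)
        if task == "binary":
            auc = float(roc_auc_score(y_true, probs))
            both = np.column_stack([1 - probs, probs])
            auc_macro = float(
                roc_auc_score(y_true, both[:, 1])
            )  # macro-ovr on two classes reduces to ROC-AUC
        else:
            # probs columns correspond to stage labels 1..4 in order
            present = sorted(np.unique(y_true).tolist())
            if len(present) >= 2:
                sub = probs[:, [lab - 1 for lab in present]]
                sub = sub / np.clip(sub.sum(axis=1, keepdims=True), 1e-12, None)
                auc_macro = float(
                    roc_auc_score(
                        y_true, sub, multi_class="ovr", average="macro", labels=present
                    )
                )
    per_class = {
        str(lab): {
            "precision": float(
                precision_score(y_true, y_pred, labels=[lab], average="macro", zero_division=0)
            ),
            "recall": float(
                recall_score(y_true, y_pred, labels=[lab], average="macro", zero_division=0)
            ),
            "f1": float(
                f1_score(y_true, y_pred, labels=[lab], average="macro", zero_division=0)
            ),
        }
        for lab in labels
    }
    return MetricsReport(
        task=task,
        n=len(y_true),
        accuracy=float(accuracy_score(y_true, y_pred)),
        balanced_accuracy=float(balanced_accuracy_score(y_true, y_pred)),
        precision_macro=float(precision_score(y_true, y_pred, **kwargs)),
        recall_macro=float(recall_score(y_true, y_pred, **kwargs)),
        f1_macro=float(f1_score(y_true, y_pred, **kwargs)),
        auc=auc,
        auc_macro=auc_macro,
        per_class=per_class,
    )
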