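"""Train-only feature selection: recursive elimination, its cross-validated
variant, and univariate top-k ranking, plus the k-grid search used to pick
subset sizes on validation data and a cross-fold selection-frequency report.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, RFECV, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .cohort import CohortTable

__all__ = [
    "SelectionResult",
    "select_rfe",
    "select_rfecv",
    "select_kbest",
    "grid_search_k",
    "selection_frequency",
    "make_estimator",
    "DEFAULT_K_GRID",
]

#: Candidate subset sizes evaluated during the k-grid search.
DEFAULT_K_GRID = (10, 12, 15, 18, 20, 22, 24, 26, 28, 30)


@dataclass(frozen=True)
class SelectionResult:
    method: str  # rfe | rfecv | kbest
    estimator_kind: str | None
    k: int
    selected_features: tuple[str, ...]
    fit_ids: tuple

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimator_kind": self.estimator_kind,
            "k": self.k,
            "features": list(self.selected_features),
        }


def make_estimator(kind: str, seed: int = 0, n_classes: int = 2):
    """Estimator families used for embedded selection and head training."""
    if kind == "xgboost":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            objective="binary:logistic" if n_classes == 2 else "multi:softprob",
        )
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if kind == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise ValueError(f"unknown estimator kind: {kind!r}")


def _xy(train_table: CohortTable, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    if not labels.index.equals(train_table.features.index):
        labels = labels.loc[train_table.patient_ids]
    return train_table.features.to_numpy(), labels.to_numpy()


def select_rfe(
    train_table: CohortTable,
    labels: pd.Series,
    estimator_kind: str = "xgboost",
    k: int = 26,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination down to exactly ``k`` features.

    One feature is eliminated per round (step=1), which makes the
    elimination path — and hence the nested-subset property
    rfe(k2) ⊆ rfe(k1) for k2 < k1 — reproducible.
    """
    n_features = len(train_table.feature_names)
    if not 1 <= k <= n_features:
        raise ValueError(f"k={k} outside [1, {n_features}]")
    X, y = _xy(train_table, labels)
    est = make_estimator(estimator_kind, seed=seed, n_classes=len(np.unique(y)))
    rfe = RFE(est, n_features_to_select=k, step=1)
    rfe.fit(X, y)
    selected = tuple(np.asarray(train_table.feature_names)[rfe.support_])
    return SelectionResult(
        "rfe", estimator_kind, k, selected, tuple(train_table.patient_ids)
    )


def select_rfecv(
    train_table: CohortTable,
    labels: pd.Series,
    estimator_kind: str = "xgboost",
    min_features: int = 5,
    cv: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Cross-validated elimination choosing k itself, floored at
    ``min_features`` so a single dominant marker can never strip the model
    down to a clinically uninformative singleton."""
    if min_features < 1:
        raise ValueError("min_features must be >= 1")
    X, y = _xy(train_table, labels)
    est = make_estimator(estimator_kind, seed=seed, n_classes=len(np.unique(y)))
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    rfecv = RFECV(
        est, step=1, cv=splitter, min_features_to_select=min_features, n_jobs=1
    )
    rfecv.fit(X, y)
    selected = tuple(np.asarray(train_table.feature_names)[rfecv.support_])
    return SelectionResult(
        "rfecv",
        estimator_kind,
        len(selected),
        selected,
        tuple(train_table.patient_ids),
    )


def _safe_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """ANOVA F scores with constant features scored 0 instead of NaN."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores, _ = f_classif(X, y)
    return np.nan_to_num(scores, nan=0.0, posinf=0.0, neginf=0.0)


def select_kbest(
    train_table: CohortTable,
    labels: pd.Series,
    k: int = 22,
    seed: int = 0,
) -> SelectionResult:
    """Univariate top-k by ANOVA F statistic.

    Ties are broken by column order (lower index preferred); a constant
    feature scores 0 and can never outrank a varying one.
    """
    n_features = len(train_table.feature_names)
    if not 1 <= k <= n_features:
        raise ValueError(f"k={k} outside [1, {n_features}]")
    X, y = _xy(train_table, labels)
    scores = _safe_f_scores(X, y)
    # Stable argsort on negated scores implements the column-order tie rule.
    order = np.argsort(-scores, kind="stable")[:k]
    order = np.sort(order)  # preserve original column order in the name list
    selected = tuple(np.asarray(train_table.feature_names)[order])
    return SelectionResult("kbest", None, k, selected, tuple(train_table.patient_ids))


def grid_search_k(
    train_table: CohortTable,
    train_labels: pd.Series,
    val_table: CohortTable,
    val_labels: pd.Series,
    method: str = "rfe",
    estimator_kind: str = "xgboost",
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    seed: int = 0,
) -> tuple[SelectionResult, pd.DataFrame]:
    """Search subset sizes on validation performance.

    For each k the selector and a head of the same estimator family are
    fitted on training rows, then scored on the validation split; the k
    maximising validation F1 wins, with AUC then smaller k as tie-breaks.
    Returns the winning SelectionResult and the per-k metric table.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    n_features = len(train_table.feature_names)
    rows = []
    results: dict[int, SelectionResult] = {}
    y_val = val_labels.loc[val_table.patient_ids].to_numpy()
    for k in sorted(set(k_grid)):
        k_eff = min(k, n_features)
        if method == "rfe":
            res = select_rfe(train_table, train_labels, estimator_kind, k_eff, seed)
        elif method == "kbest":
            res = select_kbest(train_table, train_labels, k_eff, seed)
        else:
            raise ValueError("grid search supports methods 'rfe' and 'kbest'")
        cols = list(res.selected_features)
        est = make_estimator(
            estimator_kind, seed=seed, n_classes=len(np.unique(train_labels))
        )
        est.fit(
            train_table.features[cols].to_numpy(),
            train_labels.loc[train_table.patient_ids].to_numpy(),
        )
        proba = est.predict_proba(val_table.features[cols].to_numpy())
        pred = est.predict(val_table.features[cols].to_numpy())
        if proba.shape[1] == 2:
            f1 = f1_score(y_val, pred)
            auc = roc_auc_score(y_val, proba[:, 1])
        else:
            f1 = f1_score(y_val, pred, average="macro")
            auc = roc_auc_score(y_val, proba, multi_class="ovr", average="macro")
        rows.append({"k": k, "val_f1": f1, "val_auc": auc})
        results[k] = res
    metrics = pd.DataFrame(rows)
    # F1, then AUC, then smaller k.
    best_row = metrics.sort_values(
        ["val_f1", "val_auc", "k"], ascending=[False, False, True], kind="stable"
    ).iloc[0]
    return results[int(best_row["k"])], metrics


def selection_frequency(fold_results: list[SelectionResult]) -> pd.DataFrame:
    """How often each feature was selected across folds, sorted descending.

    The stability of this table across folds is the package's analogue of
    the cross-fold consistency check on clinically established markers.
    """
    if not fold_results:
        raise ValueError("fold_results must be non-empty")
    counts = Counter()
    for res in fold_results:
        counts.update(res.selected_features)
    frame = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["feature", "n_folds"],
    )
    return frame
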