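"""Leakage-safe preprocessing: sparse-feature filtering, patient-level
stratified splits, chained-equation imputation and task-specific scaling.

Every state here is fitted on training rows only and then applied unchanged
to validation, test and inference data — the same fitted objects are reused
verbatim at deployment time.  Two MinMax scalers are kept: one fitted on
all training rows for the binary CKD gate, one fitted on CKD-labelled
training rows only for the stage head, so the two tasks never couple
through a shared normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import MinMaxScaler

from .cohort import CohortTable

__all__ = [
    "SplitPlan",
    "FoldPlan",
    "ImputerState",
    "ScalerState",
    "PreprocessorBundle",
    "SparseFilterResult",
    "drop_sparse_features",
    "split_holdout",
    "make_cv_folds",
    "fit_imputer",
    "apply_imputer",
    "fit_scaler",
    "apply_scaler",
]


class DegenerateInputError(ValueError):
    pass


class StratificationError(ValueError):
    pass


class SchemaError(ValueError):
    pass


# ----------------------------------------------------------------- filtering

@dataclass(frozen=True)
class SparseFilterResult:
    kept: tuple[str, ...]
    dropped: tuple[str, ...]
    max_missing: float

    def to_dict(self) -> dict:
        return {
            "kept": list(self.kept),
            "dropped": list(self.dropped),
            "max_missing": self.max_missing,
        }


def drop_sparse_features(
    table: CohortTable, max_missing: float = 0.70
) -> tuple[CohortTable, SparseFilterResult]:
    """Remove features whose missing fraction strictly exceeds ``max_missing``.

    A column missing in exactly 70% of rows survives a 0.70 threshold; only
    strictly sparser columns are dropped.  The kept/dropped decision is
    returned for serialization so inference applies the identical filter.
    """
    if not 0.0 < max_missing < 1.0:
        raise ValueError("max_missing must lie strictly between 0 and 1")
    frac = table.missing_fraction()
    dropped = tuple(frac.index[frac > max_missing])
    kept = tuple(frac.index[frac <= max_missing])
    if not kept:
        raise DegenerateInputError(
            "all features exceed the missingness threshold"
        )
    return table.select_columns(kept), SparseFilterResult(kept, dropped, max_missing)


# -------------------------------------------------------------------- splits

@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple
    ratios: tuple[float, float, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "train_ids": list(self.train_ids),
            "val_ids": list(self.val_ids),
            "test_ids": list(self.test_ids),
            "ratios": list(self.ratios),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitPlan":
        return cls(
            tuple(d["train_ids"]),
            tuple(d["val_ids"]),
            tuple(d["test_ids"]),
            tuple(d["ratios"]),
            int(d["seed"]),
        )


@dataclass(frozen=True)
class Fold:
    outer_train_ids: tuple
    inner_val_ids: tuple
    test_ids: tuple


@dataclass(frozen=True)
class FoldPlan:
    folds: tuple[Fold, ...]
    seed: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "folds": [
                {
                    "outer_train_ids": list(f.outer_train_ids),
                    "inner_val_ids": list(f.inner_val_ids),
                    "test_ids": list(f.test_ids),
                }
                for f in self.folds
            ],
        }


def _check_stratifiable(labels: pd.Series, n_parts: int) -> None:
    counts = labels.value_counts()
    too_small = counts[counts < n_parts]
    if not too_small.empty:
        raise StratificationError(
            "classes with fewer members than partitions: "
            + ", ".join(f"{c}({n})" for c, n in too_small.items())
        )


def split_holdout(
    table: CohortTable,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitPlan:
    """Patient-level stratified train/validation/test split.

    Stratification uses the full 5-class label so the binary and stage
    partitions stay aligned; no patient id appears in more than one part.
    """
    r = np.asarray(ratios, dtype=float)
    if r.shape != (3,) or (r <= 0).any() or abs(r.sum() - 1.0) > 1e-9:
        raise ValueError("ratios must be three positive numbers summing to 1")
    if table.labels is None:
        raise ValueError("split_holdout requires a labelled table")
    _check_stratifiable(table.labels, 3)

    ids = np.asarray(table.patient_ids)
    labels = table.labels.to_numpy()
    train_ids, rest_ids, _, rest_labels = train_test_split(
        ids,
        labels,
        test_size=float(r[1] + r[2]),
        random_state=seed,
        stratify=labels,
    )
    val_ids, test_ids = train_test_split(
        rest_ids,
        test_size=float(r[2] / (r[1] + r[2])),
        random_state=seed,
        stratify=rest_labels,
    )
    return SplitPlan(
        tuple(train_ids), tuple(val_ids), tuple(test_ids), tuple(r), seed
    )


def make_cv_folds(
    table: CohortTable,
    k: int = 5,
    inner_val_fraction: float = 0.176,
    seed: int = 0,
) -> FoldPlan:
    """Stratified k-fold plan with an inner validation split per fold.

    The inner validation set — used only for decision-threshold tuning — is
    carved out of each fold's training partition (default fraction 0.176,
    mirroring the 15/85 proportion of the hold-out design), so the outer
    test fold never touches any fitting or tuning step.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if table.labels is None:
        raise ValueError("make_cv_folds requires a labelled table")
    _check_stratifiable(table.labels, k)

    ids = np.asarray(table.patient_ids)
    labels = table.labels.to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (train_idx, test_idx) in enumerate(skf.split(ids, labels)):
        outer_train, inner_val = train_test_split(
            ids[train_idx],
            test_size=inner_val_fraction,
            random_state=seed + i,
            stratify=labels[train_idx],
        )
        folds.append(
            Fold(tuple(outer_train), tuple(inner_val), tuple(ids[test_idx]))
        )
    return FoldPlan(tuple(folds), seed)


# ------------------------------------------------------------------ imputing

@dataclass
class ImputerState:
    """Fitted chained-equation (MICE-style) imputation state.

    ``nonneg_features`` are features whose observed training values are
    essentially never negative; the non-negativity clamp applies only to
    entries this state imputes, never to originally observed measurements.
    """

    imputer: IterativeImputer
    feature_names: tuple[str, ...]
    nonneg_features: frozenset[str]
    unimputable: tuple[str, ...]
    train_means: dict[str, float]
    fit_ids: tuple


def fit_imputer(
    train_table: CohortTable,
    nonneg_rule_threshold: float = 0.005,
    max_iter: int = 10,
    seed: int = 0,
) -> ImputerState:
    """Fit the chained-equation imputer on training rows only.

    A feature is treated as physiologically non-negative when at most
    ``nonneg_rule_threshold`` of its observed training values are negative.
    Features with no observed training value at all are excluded from the
    imputation model and reported in ``unimputable``.
    """
    X = train_table.features
    observed_counts = X.notna().sum(axis=0)
    unimputable = tuple(observed_counts.index[observed_counts == 0])
    usable = [c for c in X.columns if c not in unimputable]

    nonneg = frozenset(
        c
        for c in usable
        if (X[c].dropna() < 0).mean() <= nonneg_rule_threshold
    )
    imputer = IterativeImputer(
        max_iter=max_iter,
        random_state=seed,
        sample_posterior=False,
        keep_empty_features=False,
    )
    imputer.fit(X[usable].to_numpy())
    means = {c: float(X[c].dropna().mean()) if c in usable else 0.0 for c in X.columns}
    return ImputerState(
        imputer=imputer,
        feature_names=tuple(usable),
        nonneg_features=nonneg,
        unimputable=unimputable,
        train_means=means,
        fit_ids=tuple(train_table.patient_ids),
    )


def apply_imputer(state: ImputerState, table: CohortTable) -> CohortTable:
    """Complete a table with the fitted imputer.

    Originally observed entries are preserved bit-for-bit; imputed entries
    of non-negative features are clamped at zero.  The returned table has
    no missing entries, and the original ``observed_mask`` is carried
    through unchanged so downstream reports can annotate imputed values.
    """
    unknown = set(table.feature_names) - set(state.feature_names) - set(
        state.unimputable
    )
    if unknown:
        raise SchemaError(f"unknown feature columns: {sorted(unknown)}")

    X = table.features
    usable = [c for c in state.feature_names if c in X.columns]
    if tuple(usable) != state.feature_names:
        missing_cols = set(state.feature_names) - set(usable)
        raise SchemaError(f"missing feature columns: {sorted(missing_cols)}")

    completed = pd.DataFrame(
        state.imputer.transform(X[list(state.feature_names)].to_numpy()),
        index=X.index,
        columns=list(state.feature_names),
    )
    # Clamp only entries this pass imputed, then restore observed values.
    was_missing = X[list(state.feature_names)].isna()
    for c in state.feature_names:
        if c in state.nonneg_features:
            imputed_here = was_missing[c]
            completed.loc[imputed_here, c] = completed.loc[imputed_here, c].clip(
                lower=0.0
            )
    completed = completed.where(was_missing, X[list(state.feature_names)])

    # Columns unseen by the imputation model fall back to a constant fill.
    for c in state.unimputable:
        if c in X.columns:
            fill = state.train_means.get(c, 0.0)
            completed[c] = X[c].fillna(fill)

    completed = completed[[c for c in table.feature_names if c in completed.columns]]
    return CohortTable(
        features=completed,
        labels=None if table.labels is None else table.labels.copy(),
        observed_mask=table.observed_mask.copy(),
    )


# ------------------------------------------------------------------- scaling

@dataclass
class ScalerState:
    """Per-feature MinMax state mapping the fit population into [0, 1].

    Out-of-range inference values pass through the same affine map and may
    legitimately fall outside [0, 1]; they are not clipped, so extreme
    pathology is not silently flattened onto the boundary.  Constant
    features map to 0.
    """

    scaler: MinMaxScaler
    feature_names: tuple[str, ...]
    task_tag: str
    fit_ids: tuple

    @property
    def data_min(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.scaler.data_min_))

    @property
    def data_max(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.scaler.data_max_))


def fit_scaler(
    train_subset: CohortTable, task_tag: str = "binary"
) -> ScalerState:
    """Fit a [0, 1] scaler on a training subset.

    For the stage head the caller passes the CKD-labelled training rows
    only, keeping the staging normalisation independent of non-CKD ranges.
    """
    if task_tag not in ("binary", "stage"):
        raise ValueError("task_tag must be 'binary' or 'stage'")
    scaler = MinMaxScaler(clip=False)
    scaler.fit(train_subset.features.to_numpy())
    return ScalerState(
        scaler=scaler,
        feature_names=tuple(train_subset.feature_names),
        task_tag=task_tag,
        fit_ids=tuple(train_subset.patient_ids),
    )


def apply_scaler(state: ScalerState, table: CohortTable) -> CohortTable:
    if tuple(table.feature_names) != state.feature_names:
        raise SchemaError(
            "table columns do not match the scaler's fitted feature set"
        )
    scaled = pd.DataFrame(
        state.scaler.transform(table.features.to_numpy()),
        index=table.features.index,
        columns=table.features.columns,
    )
    # MinMaxScaler maps a constant feature to its (constant) min => 0.
    return CohortTable(
        features=scaled,
        labels=None if table.labels is None else table.labels.copy(),
        observed_mask=table.observed_mask.copy(),
    )


# -------------------------------------------------------------------- bundle

@dataclass
class PreprocessorBundle:
    """Everything needed to replay training-time preprocessing at inference."""

    sparse_filter: SparseFilterResult
    imputer: ImputerState
    binary_scaler: ScalerState
    stage_scaler: ScalerState

    def prepare(self, table: CohortTable, task: str = "binary") -> CohortTable:
        """Filter -> impute -> scale a raw table for the given head."""
        kept = [c for c in self.sparse_filter.kept if c in table.feature_names]
        if tuple(kept) != self.sparse_filter.kept:
            missing = set(self.sparse_filter.kept) - set(kept)
            raise SchemaError(f"record lacks required features: {sorted(missing)}")
        filtered = table.select_columns(self.sparse_filter.kept)
        completed = apply_imputer(self.imputer, filtered)
        scaler = self.binary_scaler if task == "binary" else self.stage_scaler
        return apply_scaler(scaler, completed)

    def complete(self, table: CohortTable) -> CohortTable:
        """Filter -> impute only (feature-unit scale, for cutpoint flagging)."""
        filtered = table.select_columns(self.sparse_filter.kept)
        return apply_imputer(self.imputer, filtered)
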