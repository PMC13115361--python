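"""Cohort-derived reference ranges and directional CKD-like cutpoints.

Rather than asking whether a laboratory value is abnormal against textbook
reference intervals, this module asks whether it has shifted toward the
distribution observed in the cohort's CKD patients.  For each feature the
disease-associated direction is determined from class medians, then a
cutpoint is placed on the disease side; a patient value is flagged
"CKD-like" only when it crosses the cutpoint in that direction (boundary
inclusive).  The two notions deliberately dissociate: a value can sit
outside the non-CKD Q5-Q95 reference range yet be unflagged, and a
clinically "normal" value can be flagged when it resembles the CKD
population.

Cutpoints and ranges serialize to JSON and re-load without refitting, so
published thresholds can be applied verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "ReferenceRange",
    "Cutpoint",
    "FlaggedFeature",
    "fit_reference_ranges",
    "fit_direction",
    "fit_cutpoints",
    "flag_record",
    "CUTPOINT_RULES",
]

CUTPOINT_RULES = ("balanced", "disease_tail", "control_tail")


@dataclass(frozen=True)
class ReferenceRange:
    """Q5-Q95 interval of observed non-CKD training values for one feature."""

    feature: str
    q_low: float
    q_high: float

    def __post_init__(self) -> None:
        if self.q_low > self.q_high:
            raise ValueError("q_low must not exceed q_high")

    def contains(self, value: float) -> bool:
        return self.q_low <= value <= self.q_high

    def to_dict(self) -> dict:
        return {"feature": self.feature, "q_low": self.q_low, "q_high": self.q_high}

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceRange":
        return cls(d["feature"], float(d["q_low"]), float(d["q_high"]))


@dataclass(frozen=True)
class Cutpoint:
    """Directional disease-side threshold for one feature.

    ``direction`` is the disease-associated side: ">=" for markers that
    rise with CKD (e.g. creatinine), "<=" for markers that fall (e.g.
    hemoglobin).  ``rule`` names the derivation rule and parameters so
    every stored cutpoint is auditable.
    """

    feature: str
    direction: str  # ">=" | "<="
    threshold: float
    rule: str = "loaded"

    def __post_init__(self) -> None:
        if self.direction not in (">=", "<="):
            raise ValueError("direction must be '>=' or '<='")

    def crossed(self, value: float) -> bool:
        if self.direction == ">=":
            return value >= self.threshold
        return value <= self.threshold

    @property
    def rule_text(self) -> str:
        return f"{self.direction} {self.threshold:g}"

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "direction": self.direction,
            "threshold": self.threshold,
            "rule": self.rule,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Cutpoint":
        return cls(
            d["feature"], d["direction"], float(d["threshold"]), d.get("rule", "loaded")
        )


def _observed_values(table: CohortTable, feature: str, rows: np.ndarray) -> np.ndarray:
    col = table.features[feature].to_numpy()[rows]
    obs = table.observed_mask[feature].to_numpy()[rows]
    return col[obs & ~np.isnan(col)]


def fit_reference_ranges(
    train_table: CohortTable,
    binary_labels: pd.Series | np.ndarray,
    min_rows: int = 2,
) -> dict[str, ReferenceRange]:
    """(Q5, Q95) of observed non-CKD training values, per feature.

    Features with fewer than ``min_rows`` observed non-CKD values are
    skipped (absent from the returned mapping).  Quantiles use linear
    interpolation between order statistics.
    """
    y = np.asarray(binary_labels).astype(int)
    non_ckd = y == 0
    ranges: dict[str, ReferenceRange] = {}
    for feature in train_table.feature_names:
        values = _observed_values(train_table, feature, non_ckd)
        if len(values) < min_rows:
            continue
        q_low, q_high = np.quantile(values, [0.05, 0.95])
        ranges[feature] = ReferenceRange(feature, float(q_low), float(q_high))
    return ranges


def fit_direction(
    feature_values: np.ndarray, binary_labels: np.ndarray
) -> str | None:
    """Disease-associated direction from class medians.

    ">=" when the CKD-class median exceeds the non-CKD median, "<=" when it
    is lower; an exact tie returns None and the feature is excluded from
    flagging.
    """
    values = np.asarray(feature_values, dtype=float)
    y = np.asarray(binary_labels).astype(int)
    ok = ~np.isnan(values)
    m0 = np.median(values[ok & (y == 0)])
    m1 = np.median(values[ok & (y == 1)])
    if m1 > m0:
        return ">="
    if m1 < m0:
        return "<="
    return None


def _balanced_cutpoint(
    v0: np.ndarray, v1: np.ndarray, direction: str
) -> float | None:
    """Observed-value scan maximising balanced separation.

    Candidates are the observed values on the disease side of the non-CKD
    median; the winner maximises the mean of sensitivity (CKD flagged) and
    specificity (non-CKD unflagged) of the one-dimensional rule.  Ties go
    to the extreme observed disease-class value nearest the gap — for ">="
    the smallest maximising disease-class value, for "<=" the largest —
    so in a fully separable case the cutpoint sits on the disease side of
    the gap.  Returns None when no candidate beats chance.
    """
    m0 = np.median(v0)
    pooled = np.unique(np.concatenate([v0, v1]))
    if direction == ">=":
        candidates = pooled[pooled >= m0]
    else:
        candidates = pooled[pooled <= m0]
    if len(candidates) == 0:
        return None

    def balanced(t: float) -> float:
        if direction == ">=":
            sens = (v1 >= t).mean()
            spec = (v0 < t).mean()
        else:
            sens = (v1 <= t).mean()
            spec = (v0 > t).mean()
        return 0.5 * (sens + spec)

    scores = np.array([balanced(t) for t in candidates])
    best = scores.max()
    if best <= 0.5 + 1e-12:
        return None
    maximisers = candidates[scores >= best - 1e-12]
    disease_side = np.intersect1d(maximisers, np.unique(v1))
    pool = disease_side if len(disease_side) else maximisers
    return float(pool.min() if direction == ">=" else pool.max())


def fit_cutpoints(
    train_table: CohortTable,
    binary_labels: pd.Series | np.ndarray,
    rule: str = "balanced",
    tail: float = 0.05,
) -> dict[str, Cutpoint]:
    """Derive a directional CKD-like cutpoint per eligible feature.

    Rules:

    ``balanced`` (default)
        exhaustive scan over observed values maximising balanced
        separation between the class distributions.
    ``disease_tail``
        the CKD-class tail quantile facing the non-CKD population
        (Q(tail) for ">=", Q(1-tail) for "<=").
    ``control_tail``
        the non-CKD tail quantile facing the CKD population
        (Q(1-tail) for ">=", Q(tail) for "<=").

    Features with a median tie or with degenerate class overlap (balanced
    rule only) are excluded.  Every cutpoint records its rule and satisfies
    the median-side invariant: a ">=" threshold never sits below the
    non-CKD median, a "<=" threshold never above it.
    """
    if rule not in CUTPOINT_RULES:
        raise ValueError(f"rule must be one of {CUTPOINT_RULES}")
    y = np.asarray(binary_labels).astype(int)
    cutpoints: dict[str, Cutpoint] = {}
    for feature in train_table.feature_names:
        v0 = _observed_values(train_table, feature, y == 0)
        v1 = _observed_values(train_table, feature, y == 1)
        if len(v0) < 2 or len(v1) < 2:
            continue
        values = train_table.features[feature].to_numpy()
        direction = fit_direction(values, y)
        if direction is None:
            continue
        if rule == "balanced":
            threshold = _balanced_cutpoint(v0, v1, direction)
            label = "balanced"
        elif rule == "disease_tail":
            q = tail if direction == ">=" else 1.0 - tail
            threshold = float(np.quantile(v1, q))
            label = f"disease_tail(q={tail})"
        else:
            q = 1.0 - tail if direction == ">=" else tail
            threshold = float(np.quantile(v0, q))
            label = f"control_tail(q={tail})"
        if threshold is None:
            continue
        # median-side invariant
        m0 = float(np.median(v0))
        if direction == ">=":
            threshold = max(threshold, m0)
        else:
            threshold = min(threshold, m0)
        cutpoints[feature] = Cutpoint(feature, direction, threshold, label)
    return cutpoints


@dataclass(frozen=True)
class FlaggedFeature:
    feature: str
    value: float
    rule_text: str
    imputed: bool

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "value": self.value,
            "rule": self.rule_text,
            "imputed": self.imputed,
        }


def flag_record(
    record: CohortTable, cutpoints: dict[str, Cutpoint]
) -> list[FlaggedFeature]:
    """Flag the features of a completed single-row record that cross their
    cutpoint in the disease-associated direction (boundary inclusive).

    Flags arising from imputed entries are annotated so downstream reports
    can mark them as model-filled rather than measured.
    """
    if record.n_patients != 1:
        raise ValueError("flag_record expects a single-row record")
    row = record.features.iloc[0]
    observed = record.observed_mask.iloc[0]
    flagged = []
    for feature, cp in cutpoints.items():
        if feature not in row.index:
            continue
        value = float(row[feature])
        if np.isnan(value):
            raise ValueError(f"record not completed: {feature} is missing")
        if cp.crossed(value):
            flagged.append(
                FlaggedFeature(
                    feature=feature,
                    value=value,
                    rule_text=cp.rule_text,
                    imputed=not bool(observed[feature]),
                )
            )
    return flagged
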