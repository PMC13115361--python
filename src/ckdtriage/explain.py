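"""Shapley-value explanations for the binary gate, and the controlled
explanation policy that decides what a clinician actually sees.

Local attributions for boosted-tree gates are computed by an exact
path-dependent tree-Shapley algorithm operating on the parsed tree
ensemble in float64: for each tree the value of a feature coalition is the
cover-weighted conditional expectation obtained by following the record
down split nodes whose feature is in the coalition and averaging over both
branches otherwise, and the attribution is the exact Shapley value of that
game, accumulated in a single traversal per tree (polynomial time, no
coalition enumeration).  Attributions live on the margin (log-odds) scale,
where they are exactly additive: baseline + sum of contributions equals
the ensemble margin.  Probability-scale display is a presentation
transform, not an attribution scale.

Global weights are mean absolute attributions over a seeded training
subsample, normalised to sum to 1 (``weight_norm``), oriented at the
positive (CKD) class.  For non-tree heads a permutation-sampling
attribution with exact additivity is available behind ``method="sampling"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb

from .cohort import CohortTable
from .model import BinaryHead, RoutedPrediction
from .patterns import FlaggedFeature

__all__ = [
    "TreeEnsemble",
    "GlobalWeights",
    "LocalExplanation",
    "DriverReport",
    "DriverEntry",
    "compute_global_weights",
    "explain_record",
    "build_driver_report",
    "apply_output_policy",
    "render_report",
    "tree_shap_values",
    "sampling_shap_values",
    "IMPACT_EDGES",
]

#: Impact-label edges on a feature's share of the record's total absolute
#: contribution: High >= 25%, Moderate >= 10%, else Low.
IMPACT_EDGES = (0.25, 0.10)


# ===================================================================== trees

@dataclass
class _Tree:
    children_left: np.ndarray
    children_right: np.ndarray
    children_default: np.ndarray
    feature: np.ndarray  # -1 at leaves
    threshold: np.ndarray
    value: np.ndarray  # leaf values, 0 elsewhere
    cover: np.ndarray

    def goes_left(self, x: np.ndarray, node: int) -> bool:
        # mirror the booster's float32 comparison semantics exactly
        return bool(np.float32(x[self.feature[node]]) < np.float32(self.threshold[node]))

    def predict_one(self, x: np.ndarray) -> float:
        node = 0
        while self.children_left[node] != -1:
            f = self.feature[node]
            if np.isnan(x[f]):
                node = self.children_default[node]
            elif self.goes_left(x, node):
                node = self.children_left[node]
            else:
                node = self.children_right[node]
        return float(self.value[node])

    def expectation(self, x: np.ndarray, coalition: frozenset) -> float:
        """Cover-weighted conditional expectation given features in
        ``coalition`` fixed at the record's values (test-oracle helper)."""

        def rec(node: int) -> float:
            if self.children_left[node] == -1:
                return float(self.value[node])
            f = self.feature[node]
            left, right = self.children_left[node], self.children_right[node]
            if f in coalition:
                if np.isnan(x[f]):
                    return rec(self.children_default[node])
                return rec(left) if self.goes_left(x, node) else rec(right)
            wl = self.cover[left] / self.cover[node]
            wr = self.cover[right] / self.cover[node]
            return wl * rec(left) + wr * rec(right)

        return rec(0)

    def used_features(self) -> set[int]:
        return set(int(f) for f in self.feature[self.feature >= 0])


@dataclass
class TreeEnsemble:
    """Float64 view of a fitted boosted-tree gate (binary objective)."""

    trees: list[_Tree]
    intercept: float
    n_features: int

    @classmethod
    def from_booster(cls, booster: xgb.Booster, n_features: int) -> "TreeEnsemble":
        dumps = booster.get_dump(dump_format="json", with_stats=True)
        trees = [cls._parse_tree(json.loads(d)) for d in dumps]
        ens = cls(trees=trees, intercept=0.0, n_features=n_features)
        # Recover the additive intercept from a probe prediction rather
        # than parsing version-dependent base_score encodings.
        probe = np.zeros((1, n_features))
        margin = float(
            booster.predict(xgb.DMatrix(probe), output_margin=True)[0]
        )
        ens.intercept = margin - sum(t.predict_one(probe[0]) for t in trees)
        return ens

    @staticmethod
    def _parse_tree(root: dict) -> _Tree:
        nodes: dict[int, dict] = {}

        def walk(node: dict) -> None:
            nodes[node["nodeid"]] = node
            for child in node.get("children", ()):
                walk(child)

        walk(root)
        n = max(nodes) + 1
        left = np.full(n, -1, dtype=np.int64)
        right = np.full(n, -1, dtype=np.int64)
        default = np.full(n, -1, dtype=np.int64)
        feat = np.full(n, -1, dtype=np.int64)
        thr = np.zeros(n)
        val = np.zeros(n)
        cov = np.zeros(n)
        for i, node in nodes.items():
            cov[i] = float(node.get("cover", 0.0))
            if "leaf" in node:
                val[i] = float(node["leaf"])
            else:
                split = node["split"]
                feat[i] = int(split[1:]) if split.startswith("f") else int(split)
                thr[i] = float(node["split_condition"])
                left[i] = int(node["yes"])
                right[i] = int(node["no"])
                default[i] = int(node["missing"])
        return _Tree(left, right, default, feat, thr, val, cov)

    def margin(self, x: np.ndarray) -> float:
        return self.intercept + sum(t.predict_one(x) for t in self.trees)

    def baseline(self) -> float:
        """Expected margin with no features fixed (the Shapley baseline)."""
        empty = frozenset()
        probe = np.zeros(self.n_features)
        return self.intercept + sum(
            t.expectation(probe, empty) for t in self.trees
        )


# -------------------------- exact path-dependent tree-Shapley traversal ---

class _PathElement:
    __slots__ = ("d", "z", "o", "w")

    def __init__(self, d: int, z: float, o: float, w: float):
        self.d, self.z, self.o, self.w = d, z, o, w

    def copy(self) -> "_PathElement":
        return _PathElement(self.d, self.z, self.o, self.w)


def _extend(path: list[_PathElement], pz: float, po: float, pi: int) -> None:
    l = len(path)
    path.append(_PathElement(pi, pz, po, 1.0 if l == 0 else 0.0))
    for i in range(l - 1, -1, -1):
        path[i + 1].w += po * path[i].w * (i + 1) / (l + 1)
        path[i].w = pz * path[i].w * (l - i) / (l + 1)


def _unwind(path: list[_PathElement], index: int) -> None:
    l = len(path) - 1
    o, z = path[index].o, path[index].z
    n = path[l].w
    for j in range(l - 1, -1, -1):
        if o != 0.0:
            t = path[j].w
            path[j].w = n * (l + 1) / ((j + 1) * o)
            n = t - path[j].w * z * (l - j) / (l + 1)
        else:
            path[j].w = path[j].w * (l + 1) / (z * (l - j))
    for j in range(index, l):
        path[j].d = path[j + 1].d
        path[j].z = path[j + 1].z
        path[j].o = path[j + 1].o
    path.pop()


def _unwound_sum(path: list[_PathElement], index: int) -> float:
    l = len(path) - 1
    o, z = path[index].o, path[index].z
    total = 0.0
    n = path[l].w
    for j in range(l - 1, -1, -1):
        if o != 0.0:
            t = n * (l + 1) / ((j + 1) * o)
            total += t
            n = path[j].w - t * z * (l - j) / (l + 1)
        else:
            total += path[j].w * (l + 1) / (z * (l - j))
    return total


def _tree_shap_recurse(
    tree: _Tree,
    x: np.ndarray,
    phi: np.ndarray,
    node: int,
    path: list[_PathElement],
    pz: float,
    po: float,
    pi: int,
) -> None:
    path = [e.copy() for e in path]
    _extend(path, pz, po, pi)
    if tree.children_left[node] == -1:
        leaf = float(tree.value[node])
        for i in range(1, len(path)):
            w = _unwound_sum(path, i)
            phi[path[i].d] += w * (path[i].o - path[i].z) * leaf
        return
    f = int(tree.feature[node])
    left, right = int(tree.children_left[node]), int(tree.children_right[node])
    if np.isnan(x[f]):
        hot = int(tree.children_default[node])
    elif tree.goes_left(x, node):
        hot = left
    else:
        hot = right
    cold = right if hot == left else left
    w = tree.cover[node]
    hot_z = tree.cover[hot] / w
    cold_z = tree.cover[cold] / w
    iz = io = 1.0
    for k in range(1, len(path)):
        if path[k].d == f:
            iz, io = path[k].z, path[k].o
            _unwind(path, k)
            break
    _tree_shap_recurse(tree, x, phi, hot, path, hot_z * iz, io, f)
    _tree_shap_recurse(tree, x, phi, cold, path, cold_z * iz, 0.0, f)


def tree_shap_values(ensemble: TreeEnsemble, x: np.ndarray) -> np.ndarray:
    """Exact Shapley attributions of the ensemble margin for one record."""
    x = np.asarray(x, dtype=float)
    phi = np.zeros(ensemble.n_features)
    for tree in ensemble.trees:
        _tree_shap_recurse(tree, x, phi, 0, [], 1.0, 1.0, -1)
    return phi


def sampling_shap_values(
    predict_fn,
    x: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 128,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley attribution for arbitrary models.

    Each sampled permutation telescopes from a background row to the
    record, so the contributions are exactly additive around the sampled
    baseline: baseline + sum(phi) == predict_fn(x).  Used for non-tree
    heads (e.g. a feed-forward gate), behind an explicit flag.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    m = len(x)
    phi = np.zeros(m)
    base_acc = 0.0
    for _ in range(n_permutations):
        b = background[rng.integers(len(background))]
        z = b.astype(float).copy()
        prev = float(predict_fn(z[None, :])[0])
        base_acc += prev
        for f in rng.permutation(m):
            z[f] = x[f]
            cur = float(predict_fn(z[None, :])[0])
            phi[f] += cur - prev
            prev = cur
    return phi / n_permutations, base_acc / n_permutations


# ================================================================== reports

@dataclass(frozen=True)
class GlobalWeights:
    """Ranked global attribution table (mirrors a top-n weight report)."""

    mean_abs_shap: dict[str, float]
    weight_norm: dict[str, float]
    n_background: int

    def top(self, n: int = 15) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "feature": list(self.mean_abs_shap),
                "mean_abs_shap": list(self.mean_abs_shap.values()),
                "weight_norm": list(self.weight_norm.values()),
            }
        )
        return frame.head(n).reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "mean_abs_shap": self.mean_abs_shap,
            "weight_norm": self.weight_norm,
            "n_background": self.n_background,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GlobalWeights":
        return cls(
            dict(d["mean_abs_shap"]), dict(d["weight_norm"]), int(d["n_background"])
        )


def compute_global_weights(
    binary_head: BinaryHead,
    background: CohortTable,
    max_background: int = 200,
    seed: int = 0,
) -> GlobalWeights:
    """Mean absolute attribution per feature over a seeded background
    subsample of preprocessed training rows, normalised into weights.

    Tree gates use the exact tree-path attribution evaluated in batch via
    the booster's native contribution predictor; both routes compute the
    same quantity.
    """
    if background.n_patients == 0:
        raise ValueError("background sample is empty")
    cols = list(binary_head.selected_features)
    X = background.features[cols].to_numpy()
    if len(X) > max_background:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), size=max_background, replace=False)]
    if binary_head.family in ("xgboost",):
        booster = binary_head.model.get_booster()
        contribs = booster.predict(xgb.DMatrix(X), pred_contribs=True)[:, :-1]
    else:
        predict = lambda Z: binary_head.model.predict_proba(Z)[:, 1]
        rows = []
        for i in range(len(X)):
            phi, _ = sampling_shap_values(predict, X[i], X, seed=seed + i)
            rows.append(phi)
        contribs = np.asarray(rows)
    mean_abs = np.abs(contribs).mean(axis=0).astype(float)
    total = mean_abs.sum()
    if total <= 0:
        raise ValueError("all attributions are zero; cannot normalise weights")
    order = np.argsort(-mean_abs, kind="stable")
    mean_abs_shap = {cols[i]: float(mean_abs[i]) for i in order}
    weight_norm = {cols[i]: float(mean_abs[i] / total) for i in order}
    return GlobalWeights(mean_abs_shap, weight_norm, n_background=len(X))


@dataclass(frozen=True)
class LocalExplanation:
    """Signed per-feature contributions for one record.

    ``baseline + sum(contributions.values())`` equals ``output`` (the
    ensemble margin for tree gates) to numerical precision; a positive
    contribution pushes the prediction toward CKD.
    """

    baseline: float
    contributions: dict[str, float]
    output: float
    raw_values: dict[str, float]
    scale: str  # "margin" | "model-output"

    @property
    def probability(self) -> float:
        if self.scale == "margin":
            return 1.0 / (1.0 + math.exp(-self.output))
        return self.output


def explain_record(
    binary_head: BinaryHead,
    record: CohortTable,
    raw_record: CohortTable | None = None,
    method: str = "auto",
    background: CohortTable | None = None,
    seed: int = 0,
) -> LocalExplanation:
    """Exact local attribution of the gate's output for one record.

    ``record`` must be preprocessed with the bundle's binary path.  Tree
    gates get the exact float64 tree-path Shapley attribution on the margin
    scale; ``method="sampling"`` (required for non-tree gates) uses
    permutation sampling against ``background``.
    """
    cols = list(binary_head.selected_features)
    missing = set(cols) - set(record.feature_names)
    if missing:
        raise ValueError(f"record lacks head features: {sorted(missing)}")
    x = record.features[cols].to_numpy(dtype=float)[0]
    source = raw_record if raw_record is not None else record
    raw_vals = {
        c: float(source.features[c].iloc[0])
        for c in cols
        if c in source.feature_names
    }
    if method == "auto":
        method = "tree" if binary_head.family == "xgboost" else "sampling"
    if method == "tree":
        ensemble = TreeEnsemble.from_booster(
            binary_head.model.get_booster(), n_features=len(cols)
        )
        phi = tree_shap_values(ensemble, x)
        output = ensemble.margin(x)
        baseline = output - float(phi.sum())
        scale = "margin"
    elif method == "sampling":
        if background is None:
            raise ValueError("sampling attribution requires a background table")
        B = background.features[cols].to_numpy(dtype=float)
        predict = lambda Z: binary_head.model.predict_proba(Z)[:, 1]
        phi, baseline = sampling_shap_values(predict, x, B, seed=seed)
        output = float(predict(x[None, :])[0])
        scale = "model-output"
    else:
        raise ValueError("method must be 'auto', 'tree' or 'sampling'")
    return LocalExplanation(
        baseline=float(baseline),
        contributions={c: float(v) for c, v in zip(cols, phi)},
        output=float(output),
        raw_values=raw_vals,
        scale=scale,
    )


# ======================================================== driver reporting

@dataclass(frozen=True)
class DriverEntry:
    feature: str
    value: float
    rule_text: str
    impact: str  # High | Moderate | Low
    contribution: float
    share: float
    imputed: bool = False

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "value": self.value,
            "rule": self.rule_text,
            "impact": self.impact,
            "contribution": self.contribution,
            "share": self.share,
            "imputed": self.imputed,
        }


@dataclass(frozen=True)
class DriverReport:
    """Risk-path explanation for a gate-negative record.

    ``primary_drivers`` are features with positive attribution that also
    crossed their CKD-like cutpoint; ``additional_signals`` are CKD-like
    features that did not qualify (weak or negative attribution).  The two
    lists are disjoint and every entry carries its cutpoint rule text.
    """

    p_ckd: float
    decision: str
    risk_score: float
    primary_drivers: tuple[DriverEntry, ...]
    additional_signals: tuple[DriverEntry, ...]

    def to_dict(self) -> dict:
        return {
            "p_ckd": self.p_ckd,
            "decision": self.decision,
            "risk_score": self.risk_score,
            "primary_drivers": [d.to_dict() for d in self.primary_drivers],
            "additional_signals": [d.to_dict() for d in self.additional_signals],
        }


def _impact_label(share: float, edges: tuple[float, float] = IMPACT_EDGES) -> str:
    high, moderate = edges
    if share >= high:
        return "High"
    if share >= moderate:
        return "Moderate"
    return "Low"


def build_driver_report(
    local: LocalExplanation,
    flags: list[FlaggedFeature],
    risk: float,
    p_ckd: float,
    impact_edges: tuple[float, float] = IMPACT_EDGES,
) -> DriverReport:
    """Assemble the driver report for a non-CKD-routed record.

    Impact labels derive from each feature's share of the record's total
    absolute contribution; primary drivers are sorted by that share,
    descending.
    """
    total_abs = sum(abs(v) for v in local.contributions.values())
    flagged_by_name = {f.feature: f for f in flags}
    primary, additional = [], []
    for feature, flag in flagged_by_name.items():
        contribution = local.contributions.get(feature, 0.0)
        share = abs(contribution) / total_abs if total_abs > 0 else 0.0
        entry = DriverEntry(
            feature=feature,
            value=flag.value,
            rule_text=flag.rule_text,
            impact=_impact_label(share, impact_edges),
            contribution=contribution,
            share=share,
            imputed=flag.imputed,
        )
        if contribution > 0:
            primary.append(entry)
        else:
            additional.append(entry)
    primary.sort(key=lambda e: -e.share)
    additional.sort(key=lambda e: -e.share)
    return DriverReport(
        p_ckd=float(p_ckd),
        decision="non-CKD",
        risk_score=float(risk),
        primary_drivers=tuple(primary),
        additional_signals=tuple(additional),
    )


def apply_output_policy(
    routed: RoutedPrediction, report: DriverReport | None = None
) -> dict:
    """Shape the final payload under the controlled explanation policy.

    CKD-path records expose the decision and stage only — no risk-style
    fields.  Non-CKD records expose p(CKD) and the risk score, plus the
    driver lists only when the risk score is non-zero, so explanations
    appear exactly when there is a meaningful risk signal.
    """
    if routed.path == "CKD":
        return {"decision": "CKD", "stage": routed.stage}
    payload = {
        "decision": "non-CKD",
        "p_ckd": routed.p_ckd,
        "risk_score": 0.0 if report is None else report.risk_score,
    }
    if report is not None and report.risk_score > 0:
        payload["drivers"] = {
            "primary_drivers": [d.to_dict() for d in report.primary_drivers],
            "additional_signals": [d.to_dict() for d in report.additional_signals],
        }
    return payload


def render_report(payload: dict) -> str:
    """Human-readable rendering of a system output payload."""
    if "validation_error" in payload:
        return f"VALIDATION ERROR: {payload['message']}"
    if payload["decision"] == "CKD":
        return f"Decision: CKD | Predicted stage: {payload['stage']}"
    lines = [
        f"p(CKD) = {payload['p_ckd']:.3f} | Decision: non-CKD",
        f"CKD risk score = {payload['risk_score']:.1f}",
    ]
    drivers = payload.get("drivers")
    if drivers:
        lines.append("Primary drivers:")
        for d in drivers["primary_drivers"]:
            imp = " (imputed)" if d.get("imputed") else ""
            lines.append(
                f"  {d['feature']} value = {d['value']:g}, rule {d['rule']} "
                f"[{d['impact']} impact]{imp}"
            )
        if not drivers["primary_drivers"]:
            lines.append("  (none)")
        lines.append("Additional CKD-like signals:")
        for d in drivers["additional_signals"]:
            imp = " (imputed)" if d.get("imputed") else ""
            lines.append(
                f"  {d['feature']} value = {d['value']:g}, rule {d['rule']} "
                f"[{d['impact']} impact]{imp}"
            )
        if not drivers["additional_signals"]:
            lines.append("  (none)")
    return "\n".join(lines)
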