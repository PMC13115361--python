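"""End-to-end orchestration: training, cross-validated evaluation,
payload validation, inference and bundle serialization.

``run_training`` executes the full leakage-safe pipeline — sparse filter,
stratified 70/15/15 patient-level split, chained-equation imputation,
dual scaling, per-head feature selection, gate training, threshold tuning
on validation, stage training on CKD rows, risk-anchor fitting, cutpoint
derivation and global attribution weights — and freezes every fitted state
into a :class:`SystemBundle`.  A loaded bundle replays inference
bit-identically: nothing is refitted downstream of training.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd

from .cohort import CohortTable
from .explain import (
    GlobalWeights,
    apply_output_policy,
    build_driver_report,
    compute_global_weights,
    explain_record,
)
from .model import (
    BinaryHead,
    ModelConfig,
    StageHead,
    evaluate,
    predict_route,
    train_binary,
    train_stage,
    tune_threshold,
)
from .patterns import Cutpoint, ReferenceRange, fit_cutpoints, fit_reference_ranges, flag_record
from .preprocessing import (
    PreprocessorBundle,
    SplitPlan,
    apply_scaler,
    drop_sparse_features,
    fit_imputer,
    fit_scaler,
    make_cv_folds,
    split_holdout,
)
from .risk import RiskAnchors, fit_anchors, risk_score
from .selection import SelectionResult, select_kbest, select_rfe

__all__ = [
    "SystemBundle",
    "SystemConfig",
    "validate_payload",
    "run_training",
    "run_cv",
    "infer",
    "save_bundle",
    "load_bundle",
    "BUNDLE_FORMAT_VERSION",
]

BUNDLE_FORMAT_VERSION = "1"


@dataclass(frozen=True)
class SystemConfig:
    """Every tunable of the training pipeline, in one auditable place."""

    max_missing: float = 0.70
    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    nonneg_rule_threshold: float = 0.005
    imputer_max_iter: int = 10
    model: ModelConfig = field(default_factory=ModelConfig)
    cutpoint_rule: str = "balanced"
    background_size: int = 200
    min_ramp_width: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "max_missing": self.max_missing,
            "split_ratios": list(self.split_ratios),
            "nonneg_rule_threshold": self.nonneg_rule_threshold,
            "imputer_max_iter": self.imputer_max_iter,
            "cutpoint_rule": self.cutpoint_rule,
            "background_size": self.background_size,
            "min_ramp_width": self.min_ramp_width,
            "seed": self.seed,
            "model": {
                "binary_family": self.model.binary_family,
                "binary_selection": self.model.binary_selection,
                "binary_k": self.model.binary_k,
                "stage_hidden": list(self.model.stage_hidden),
                "stage_max_iter": self.model.stage_max_iter,
                "stage_k": self.model.stage_k,
                "threshold_lo": self.model.threshold_lo,
                "threshold_hi": self.model.threshold_hi,
                "threshold_step": self.model.threshold_step,
                "seed": self.model.seed,
            },
        }


@dataclass
class SystemBundle:
    """Frozen artifact set: preprocessing states, selectors, both heads
    with the tuned threshold, risk anchors, cutpoints and reference ranges,
    global weights, the split plan, and the config snapshot."""

    preprocessor: PreprocessorBundle
    binary_selection: SelectionResult
    stage_selection: SelectionResult
    binary_head: BinaryHead
    stage_head: StageHead
    anchors: RiskAnchors
    cutpoints: dict[str, Cutpoint]
    reference_ranges: dict[str, ReferenceRange]
    global_weights: GlobalWeights
    split_plan: SplitPlan
    config: SystemConfig
    known_ids: tuple
    metrics: dict = field(default_factory=dict)
    format_version: str = BUNDLE_FORMAT_VERSION

    def artifact_inventory(self) -> tuple[str, ...]:
        return (
            "imputer",
            "scalers",
            "feature_selectors",
            "classification_models",
            "decision_threshold",
            "risk_anchors",
            "ckd_like_cutpoints",
            "split_identifiers",
        )


# ------------------------------------------------------------- validation

def validate_payload(
    payload: object, known_ids: set | None = None, feature_names: tuple | None = None
) -> dict | None:
    """Structural validation of an inference payload.

    Returns None when the payload is acceptable, or a validation-error
    shape ``{"validation_error": True, "message": ...}`` naming the
    offending id or the missing/malformed fields.
    """
    if not isinstance(payload, dict):
        return {"validation_error": True, "message": "payload must be an object"}
    pid = payload.get("id")
    if not isinstance(pid, str) or not pid:
        return {
            "validation_error": True,
            "message": "payload missing a non-empty string 'id'",
        }
    features = payload.get("features")
    if features is None:
        if known_ids is not None and pid in known_ids:
            return None  # record will be fetched from the loaded cohort
        if known_ids is not None:
            return {
                "validation_error": True,
                "message": f"unknown patient id {pid!r} and no feature block supplied",
            }
        return {
            "validation_error": True,
            "message": "payload missing the 'features' block",
        }
    if not isinstance(features, dict) or not features:
        return {
            "validation_error": True,
            "message": "'features' must be a non-empty mapping of name -> value|null",
        }
    bad = [
        k
        for k, v in features.items()
        if not (v is None or isinstance(v, (int, float)) and not isinstance(v, bool))
    ]
    if bad:
        return {
            "validation_error": True,
            "message": f"non-numeric feature values for: {sorted(bad)}",
        }
    if feature_names is not None:
        unknown = set(features) - set(feature_names)
        if unknown:
            return {
                "validation_error": True,
                "message": f"unknown feature names: {sorted(unknown)}",
            }
    return None


# --------------------------------------------------------------- training

def _seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_training(
    cohort: CohortTable, config: SystemConfig = SystemConfig()
) -> SystemBundle:
    """Fit the complete system on a labelled cohort.

    Every fitted state touches training rows only; the decision threshold
    is tuned on the validation split and the test split is used once, for
    the hold-out metrics stored on the bundle.
    """
    if cohort.labels is None:
        raise ValueError("training requires a labelled cohort")
    seeds = _seeds(config.seed)

    filtered, sparse_filter = drop_sparse_features(cohort, config.max_missing)
    plan = split_holdout(filtered, config.split_ratios, seed=seeds[0])
    train = filtered.subset(plan.train_ids)
    val = filtered.subset(plan.val_ids)
    test = filtered.subset(plan.test_ids)

    imputer = fit_imputer(
        train,
        nonneg_rule_threshold=config.nonneg_rule_threshold,
        max_iter=config.imputer_max_iter,
        seed=seeds[1],
    )
    from .preprocessing import apply_imputer  # local import avoids cycle noise

    train_c = apply_imputer(imputer, train)
    val_c = apply_imputer(imputer, val)
    test_c = apply_imputer(imputer, test)

    binary_scaler = fit_scaler(train_c, "binary")
    ckd_train_ids = train_c.labels.index[train_c.labels > 0]
    stage_scaler = fit_scaler(train_c.subset(ckd_train_ids), "stage")

    pre = PreprocessorBundle(sparse_filter, imputer, binary_scaler, stage_scaler)

    train_b = apply_scaler(binary_scaler, train_c)
    val_b = apply_scaler(binary_scaler, val_c)
    test_b = apply_scaler(binary_scaler, test_c)

    # Binary head: embedded selection on binarised labels, then the gate.
    mc = config.model
    binary_labels = train_b.binary_labels()
    k_bin = min(mc.binary_k, len(train_b.feature_names))
    binary_selection = select_rfe(
        train_b, binary_labels, mc.binary_family, k_bin, seed=seeds[2]
    )
    head_cfg = ModelConfig(
        binary_family=mc.binary_family,
        binary_selection=mc.binary_selection,
        binary_k=k_bin,
        stage_hidden=mc.stage_hidden,
        stage_max_iter=mc.stage_max_iter,
        stage_k=mc.stage_k,
        threshold_lo=mc.threshold_lo,
        threshold_hi=mc.threshold_hi,
        threshold_step=mc.threshold_step,
        seed=seeds[3],
    )
    binary_head = train_binary(
        train_b, train_b.labels, binary_selection.selected_features, head_cfg
    )
    tau = tune_threshold(
        binary_head.predict_proba(val_b),
        val_b.binary_labels().to_numpy(),
        mc.threshold_lo,
        mc.threshold_hi,
        mc.threshold_step,
    )
    binary_head.threshold = tau

    # Stage head: CKD training rows, stage scaler, univariate top-k.
    stage_train = apply_scaler(stage_scaler, train_c.subset(ckd_train_ids))
    k_stage = min(mc.stage_k, len(stage_train.feature_names))
    stage_selection = select_kbest(
        stage_train, stage_train.labels, k_stage, seed=seeds[4]
    )
    stage_head = train_stage(
        stage_train, stage_train.labels, stage_selection.selected_features, head_cfg
    )

    # Risk anchors from the training probability sets retained on the head.
    train_probs = np.concatenate([binary_head.p0_train, binary_head.p1_train])
    train_flags = np.concatenate(
        [np.zeros(len(binary_head.p0_train)), np.ones(len(binary_head.p1_train))]
    )
    anchors = fit_anchors(train_probs, train_flags, config.min_ramp_width)

    # Pattern detection on completed, unscaled training data (feature units).
    reference_ranges = fit_reference_ranges(train_c, train_c.binary_labels())
    cutpoints = fit_cutpoints(
        train_c, train_c.binary_labels(), rule=config.cutpoint_rule
    )

    global_weights = compute_global_weights(
        binary_head, train_b, max_background=config.background_size, seed=seeds[5]
    )

    # Hold-out evaluation (test split used exactly once).
    test_probs = binary_head.predict_proba(test_b)
    binary_report = evaluate(
        test_b.binary_labels().to_numpy(),
        (test_probs >= tau).astype(int),
        "binary",
        probs=test_probs,
    )
    ckd_test_ids = test_c.labels.index[test_c.labels > 0]
    stage_report = None
    if len(ckd_test_ids) > 0:
        stage_test = apply_scaler(stage_scaler, test_c.subset(ckd_test_ids))
        stage_probs = stage_head.predict_proba(stage_test)
        stage_pred = stage_probs.argmax(axis=1) + 1
        stage_report = evaluate(
            stage_test.labels.to_numpy(), stage_pred, "stage", probs=stage_probs
        )

    return SystemBundle(
        preprocessor=pre,
        binary_selection=binary_selection,
        stage_selection=stage_selection,
        binary_head=binary_head,
        stage_head=stage_head,
        anchors=anchors,
        cutpoints=cutpoints,
        reference_ranges=reference_ranges,
        global_weights=global_weights,
        split_plan=plan,
        config=config,
        known_ids=tuple(cohort.patient_ids),
        metrics={
            "holdout_binary": binary_report.to_dict(),
            "holdout_stage": None if stage_report is None else stage_report.to_dict(),
        },
    )


# ------------------------------------------------------------------- CV

def run_cv(
    cohort: CohortTable, k: int = 5, config: SystemConfig = SystemConfig()
) -> dict:
    """k-fold cross-validated evaluation of both heads.

    Used purely for performance estimation: every preprocessing state,
    selector, head and threshold is refitted per fold on that fold's outer
    training partition (threshold on the inner validation split), and
    scored on the untouched outer test fold.  Returns per-fold reports and
    the mean +/- sd summary per metric.
    """
    if cohort.labels is None:
        raise ValueError("cross-validation requires a labelled cohort")
    seeds = _seeds(config.seed)
    plan = make_cv_folds(cohort, k=k, seed=seeds[0])
    from .preprocessing import apply_imputer

    fold_reports = []
    for i, fold in enumerate(plan.folds):
        fold_cfg = SystemConfig(
            max_missing=config.max_missing,
            split_ratios=config.split_ratios,
            nonneg_rule_threshold=config.nonneg_rule_threshold,
            imputer_max_iter=config.imputer_max_iter,
            model=config.model,
            cutpoint_rule=config.cutpoint_rule,
            background_size=config.background_size,
            min_ramp_width=config.min_ramp_width,
            seed=seeds[1] + i,
        )
        sub_train = cohort.subset(fold.outer_train_ids)
        sub_val = cohort.subset(fold.inner_val_ids)
        sub_test = cohort.subset(fold.test_ids)

        filtered_train, sparse_filter = drop_sparse_features(
            sub_train, fold_cfg.max_missing
        )
        kept = sparse_filter.kept
        imputer = fit_imputer(
            filtered_train,
            nonneg_rule_threshold=fold_cfg.nonneg_rule_threshold,
            max_iter=fold_cfg.imputer_max_iter,
            seed=seeds[2] + i,
        )
        train_c = apply_imputer(imputer, filtered_train)
        val_c = apply_imputer(imputer, sub_val.select_columns(kept))
        test_c = apply_imputer(imputer, sub_test.select_columns(kept))

        binary_scaler = fit_scaler(train_c, "binary")
        train_b = apply_scaler(binary_scaler, train_c)
        val_b = apply_scaler(binary_scaler, val_c)
        test_b = apply_scaler(binary_scaler, test_c)

        mc = fold_cfg.model
        k_bin = min(mc.binary_k, len(train_b.feature_names))
        bin_sel = select_rfe(
            train_b, train_b.binary_labels(), mc.binary_family, k_bin, seed=seeds[3] + i
        )
        head_cfg = ModelConfig(
            binary_family=mc.binary_family,
            stage_hidden=mc.stage_hidden,
            stage_max_iter=mc.stage_max_iter,
            seed=seeds[4] + i,
        )
        head = train_binary(train_b, train_b.labels, bin_sel.selected_features, head_cfg)
        tau = tune_threshold(
            head.predict_proba(val_b), val_b.binary_labels().to_numpy()
        )
        head.threshold = tau
        test_probs = head.predict_proba(test_b)
        binary_report = evaluate(
            test_b.binary_labels().to_numpy(),
            (test_probs >= tau).astype(int),
            "binary",
            probs=test_probs,
        )

        ckd_train_ids = train_c.labels.index[train_c.labels > 0]
        stage_scaler = fit_scaler(train_c.subset(ckd_train_ids), "stage")
        stage_train = apply_scaler(stage_scaler, train_c.subset(ckd_train_ids))
        k_stage = min(mc.stage_k, len(stage_train.feature_names))
        stage_sel = select_kbest(stage_train, stage_train.labels, k_stage)
        stage_head = train_stage(
            stage_train, stage_train.labels, stage_sel.selected_features, head_cfg
        )
        ckd_test_ids = test_c.labels.index[test_c.labels > 0]
        stage_report = None
        if len(ckd_test_ids) > 0 and len(np.unique(test_c.labels[ckd_test_ids])) > 1:
            stage_test = apply_scaler(stage_scaler, test_c.subset(ckd_test_ids))
            sp = stage_head.predict_proba(stage_test)
            stage_report = evaluate(
                stage_test.labels.to_numpy(), sp.argmax(axis=1) + 1, "stage", probs=sp
            )
        fold_reports.append(
            {
                "fold": i,
                "binary": binary_report.to_dict(),
                "stage": None if stage_report is None else stage_report.to_dict(),
                "binary_selection": bin_sel,
                "stage_selection": stage_sel,
                "threshold": tau,
            }
        )

    def summarise(task: str) -> dict:
        keys = ("accuracy", "balanced_accuracy", "precision_macro", "recall_macro",
                "f1_macro", "auc", "auc_macro")
        out = {}
        for key in keys:
            vals = [
                r[task][key]
                for r in fold_reports
                if r[task] is not None and r[task][key] is not None
            ]
            if vals:
                out[key] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
        return out

    return {
        "folds": fold_reports,
        "summary": {"binary": summarise("binary"), "stage": summarise("stage")},
        "fold_plan": plan,
    }


# -------------------------------------------------------------- inference

def _payload_to_record(payload: dict, bundle: SystemBundle, cohort: CohortTable | None) -> CohortTable:
    if "features" in payload and payload["features"] is not None:
        all_names = bundle.preprocessor.sparse_filter.kept
        values = {
            name: np.nan if payload["features"].get(name) is None
            else float(payload["features"].get(name, np.nan))
            for name in all_names
        }
        observed = {
            name: payload["features"].get(name) is not None for name in all_names
        }
        ids = pd.Index([payload["id"]], name="patient_id")
        features = pd.DataFrame([values], index=ids)
        return CohortTable(
            features=features,
            labels=None,
            observed_mask=pd.DataFrame([observed], index=ids),
        )
    record = cohort.subset([payload["id"]])
    return CohortTable(
        features=record.features.copy(),
        labels=None,
        observed_mask=record.observed_mask.copy(),
    )


def infer(
    bundle: SystemBundle, payload: dict, cohort: CohortTable | None = None
) -> dict:
    """Validate -> preprocess -> gate -> (stage | risk + flags + drivers).

    Returns exactly one of the three output shapes: a CKD decision with a
    stage, a non-CKD risk assessment (drivers only when risk > 0), or a
    validation-error message.  ``cohort`` acts as the patient-id registry
    for payloads that reference a stored record instead of carrying their
    own feature block.
    """
    known = set(cohort.patient_ids) if cohort is not None else set(bundle.known_ids)
    err = validate_payload(
        payload, known_ids=known, feature_names=None
    )
    if err is not None:
        return err
    if "features" not in payload or payload["features"] is None:
        if cohort is None or payload["id"] not in set(cohort.patient_ids):
            return {
                "validation_error": True,
                "message": f"patient id {payload['id']!r} not found in the loaded cohort",
            }

    try:
        raw = _payload_to_record(payload, bundle, cohort)
        binary_in = bundle.preprocessor.prepare(raw, task="binary")
        stage_in = bundle.preprocessor.prepare(raw, task="stage")
        completed = bundle.preprocessor.complete(raw)
    except Exception as exc:  # schema problems surface as validation shape
        return {"validation_error": True, "message": str(exc)}

    routed = predict_route(
        binary_in, stage_in, bundle.binary_head, bundle.stage_head
    )[0]
    if routed.path == "CKD":
        return apply_output_policy(routed, None)

    score = risk_score(routed.p_ckd, bundle.anchors)
    local = explain_record(bundle.binary_head, binary_in, raw_record=completed)
    flags = flag_record(completed, bundle.cutpoints)
    report = build_driver_report(local, flags, score, routed.p_ckd)
    return apply_output_policy(routed, report)


# ----------------------------------------------------------- serialization

_FIXED_ZIP_DATE = (2020, 1, 1, 0, 0, 0)  # deterministic archives


def _write_entry(zf: zipfile.ZipFile, name: str, data: bytes) -> None:
    info = zipfile.ZipInfo(name, date_time=_FIXED_ZIP_DATE)
    info.compress_type = zipfile.ZIP_DEFLATED
    zf.writestr(info, data)


def save_bundle(bundle: SystemBundle, path) -> None:
    """Serialize the bundle as a single versioned zip archive.

    Transparent decisions (threshold, anchors, cutpoints, reference
    ranges, selections, split ids, weights, config) are stored as
    diffable JSON manifests; fitted model/imputer/scaler states are opaque
    joblib blobs.  Archive metadata is fixed so identical bundles are
    byte-identical on disk.
    """
    manifest = {
        "format_version": bundle.format_version,
        "artifacts": list(bundle.artifact_inventory()),
        "threshold": bundle.binary_head.threshold,
        "binary_family": bundle.binary_head.family,
        "stage_family": bundle.stage_head.family,
    }
    json_parts = {
        "manifest.json": manifest,
        "config.json": bundle.config.to_dict(),
        "anchors.json": bundle.anchors.to_dict(),
        "cutpoints.json": {k: v.to_dict() for k, v in bundle.cutpoints.items()},
        "reference_ranges.json": {
            k: v.to_dict() for k, v in bundle.reference_ranges.items()
        },
        "selection.json": {
            "binary": bundle.binary_selection.to_dict(),
            "stage": bundle.stage_selection.to_dict(),
        },
        "split_plan.json": bundle.split_plan.to_dict(),
        "global_weights.json": bundle.global_weights.to_dict(),
        "sparse_filter.json": bundle.preprocessor.sparse_filter.to_dict(),
        "metrics.json": bundle.metrics,
        "known_ids.json": list(bundle.known_ids),
    }
    blob = io.BytesIO()
    joblib.dump(bundle, blob)
    with zipfile.ZipFile(path, "w") as zf:
        for name in sorted(json_parts):
            _write_entry(
                zf, name, json.dumps(json_parts[name], indent=1, sort_keys=True).encode()
            )
        _write_entry(zf, "models/bundle.joblib", blob.getvalue())


def load_bundle(path) -> SystemBundle:
    """Load a bundle, rejecting unknown format versions and corrupt files."""
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported bundle format version: "
                    f"{manifest.get('format_version')!r}"
                )
            blob = zf.read("models/bundle.joblib")
    except (zipfile.BadZipFile, KeyError) as exc:
        raise ValueError(f"corrupt or incomplete bundle: {exc}") from exc
    bundle = joblib.load(io.BytesIO(blob))
    if bundle.format_version != BUNDLE_FORMAT_VERSION:
        raise ValueError("bundle format version mismatch")
    return bundle
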