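"""End-to-end orchestration: payload validation, training determinism,
bundle completeness and round-trip, cross-validation protocol, inference
shapes and the leakage guard."""

import json
import pickle

import numpy as np
import pytest

from ckdtriage import (
    SystemConfig,
    default_cohort_spec,
    generate_cohort,
    infer,
    load_bundle,
    run_cv,
    run_training,
    save_bundle,
    validate_payload,
)
from ckdtriage.cohort import CohortTable
from ckdtriage.model import ModelConfig


# --------------------------------------------------------------- validation

def test_unknown_id_rejected_by_name():
    err = validate_payload({"id": "GHOST"}, known_ids={"P1", "P2"})
    assert err["validation_error"] and "GHOST" in err["message"]


def test_missing_feature_block_rejected():
    err = validate_payload({"id": "X"})
    assert err["validation_error"] and "features" in err["message"]


def test_well_formed_payloads_accepted():
    assert validate_payload({"id": "P1"}, known_ids={"P1"}) is None
    assert validate_payload({"id": "X", "features": {"CREA": 1.2, "BUN": None}}) is None


def test_non_numeric_feature_values_rejected():
    err = validate_payload({"id": "X", "features": {"CREA": "high"}})
    assert err["validation_error"] and "CREA" in err["message"]


def test_unknown_feature_names_rejected_when_schema_given():
    err = validate_payload(
        {"id": "X", "features": {"NOT_A_LAB": 1.0}}, feature_names=("CREA",)
    )
    assert err["validation_error"]


# ----------------------------------------------------------------- training

def test_bundle_contains_every_frozen_artifact(trained_bundle):
    b = trained_bundle
    assert b.binary_head.threshold is not None
    assert b.preprocessor.imputer is not None
    assert b.preprocessor.binary_scaler.task_tag == "binary"
    assert b.preprocessor.stage_scaler.task_tag == "stage"
    assert b.binary_selection.selected_features
    assert b.stage_selection.selected_features
    assert b.anchors.p0 < b.anchors.p1
    assert b.cutpoints and b.reference_ranges
    assert abs(sum(b.global_weights.weight_norm.values()) - 1.0) < 1e-9
    assert set(b.split_plan.train_ids) and set(b.split_plan.test_ids)
    assert set(b.artifact_inventory()) == {
        "imputer", "scalers", "feature_selectors", "classification_models",
        "decision_threshold", "risk_anchors", "ckd_like_cutpoints",
        "split_identifiers",
    }


def test_stage_scaler_fitted_on_ckd_training_rows_only(trained_bundle, separable_cohort):
    fit_ids = set(trained_bundle.preprocessor.stage_scaler.fit_ids)
    train_ids = set(trained_bundle.split_plan.train_ids)
    labels = separable_cohort.labels
    assert fit_ids <= train_ids
    assert all(labels[pid] > 0 for pid in fit_ids)


def test_training_deterministic_bit_identical_bundle(tmp_path):
    cohort = generate_cohort(default_cohort_spec(n_patients=250, separation=3.0, seed=5))
    cfg = SystemConfig(seed=11, model=ModelConfig(stage_max_iter=200))
    p1, p2 = tmp_path / "a.zip", tmp_path / "b.zip"
    save_bundle(run_training(cohort, cfg), p1)
    save_bundle(run_training(cohort, cfg), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_leakage_guard_test_rows_never_influence_fitting():
    cohort = generate_cohort(default_cohort_spec(n_patients=250, separation=3.0, seed=9))
    cfg = SystemConfig(seed=4, model=ModelConfig(stage_max_iter=200))
    bundle_a = run_training(cohort, cfg)
    # permute all feature values inside the test split before training
    rng = np.random.default_rng(0)
    mangled = cohort.features.copy()
    test_ids = list(bundle_a.split_plan.test_ids)
    perm = rng.permutation(len(test_ids))
    mangled.loc[test_ids] = mangled.loc[test_ids].to_numpy()[perm]
    mangled_mask = cohort.observed_mask.copy()
    mangled_mask.loc[test_ids] = mangled_mask.loc[test_ids].to_numpy()[perm]
    cohort_b = CohortTable(mangled, cohort.labels.copy(), mangled_mask)
    bundle_b = run_training(cohort_b, cfg)
    assert bundle_a.binary_head.threshold == bundle_b.binary_head.threshold
    assert bundle_a.binary_selection == bundle_b.binary_selection
    assert bundle_a.stage_selection == bundle_b.stage_selection
    assert pickle.dumps(bundle_a.preprocessor.imputer.imputer) == pickle.dumps(
        bundle_b.preprocessor.imputer.imputer
    )
    assert bundle_a.anchors == bundle_b.anchors
    assert {k: v.to_dict() for k, v in bundle_a.cutpoints.items()} == {
        k: v.to_dict() for k, v in bundle_b.cutpoints.items()
    }


# ------------------------------------------------------------ serialization

def test_bundle_round_trip_reproduces_inference(trained_bundle, separable_cohort, tmp_path):
    path = tmp_path / "bundle.zip"
    save_bundle(trained_bundle, path)
    loaded = load_bundle(path)
    rng = np.random.default_rng(1)
    ids = list(separable_cohort.patient_ids)
    picks = rng.choice(len(ids), size=50, replace=False)
    for i in picks:
        payload = {"id": ids[i]}
        a = infer(trained_bundle, payload, cohort=separable_cohort)
        b = infer(loaded, payload, cohort=separable_cohort)
        assert a == b


def test_tampered_version_rejected(trained_bundle, tmp_path):
    import zipfile

    path = tmp_path / "bundle.zip"
    save_bundle(trained_bundle, path)
    bad = tmp_path / "bad.zip"
    with zipfile.ZipFile(path) as src, zipfile.ZipFile(bad, "w") as dst:
        for item in src.namelist():
            data = src.read(item)
            if item == "manifest.json":
                manifest = json.loads(data)
                manifest["format_version"] = "999"
                data = json.dumps(manifest).encode()
            dst.writestr(item, data)
    with pytest.raises(ValueError, match="version"):
        load_bundle(bad)


def test_corrupt_file_rejected(tmp_path):
    path = tmp_path / "junk.zip"
    path.write_bytes(b"this is not an archive")
    with pytest.raises(ValueError, match="corrupt"):
        load_bundle(path)


# -------------------------------------------------------------- inference

def test_inference_routes_to_all_three_shapes(trained_bundle, separable_cohort):
    shapes = set()
    for pid in separable_cohort.patient_ids:
        out = infer(trained_bundle, {"id": pid}, cohort=separable_cohort)
        if "validation_error" in out:
            shapes.add("error")
        elif out["decision"] == "CKD":
            shapes.add("ckd")
            assert set(out) == {"decision", "stage"}
        else:
            shapes.add("non-ckd")
            assert "p_ckd" in out and "risk_score" in out
    assert shapes == {"ckd", "non-ckd"}
    out = infer(trained_bundle, {"id": "NOBODY"}, cohort=separable_cohort)
    assert "validation_error" in out


def test_policy_totality_on_fuzzed_payloads(trained_bundle, separable_cohort):
    rng = np.random.default_rng(2)
    kept = trained_bundle.preprocessor.sparse_filter.kept
    payloads = [
        None,
        [],
        {},
        {"id": ""},
        {"id": 17},
        {"id": "X"},
        {"id": "X", "features": {}},
        {"id": "X", "features": "CREA high"},
        {"id": "X", "features": {"CREA": "NaN-ish"}},
        {"id": "X", "features": {kept[0]: True}},
    ]
    for _ in range(30):
        features = {
            name: (None if rng.random() < 0.3 else float(rng.normal(50, 30)))
            for name in rng.choice(kept, size=rng.integers(1, len(kept)), replace=False)
        }
        payloads.append({"id": f"FUZZ{_}", "features": features})
    for payload in payloads:
        out = infer(trained_bundle, payload, cohort=separable_cohort)
        is_error = "validation_error" in out
        is_ckd = not is_error and out.get("decision") == "CKD"
        is_non = not is_error and out.get("decision") == "non-CKD"
        assert sum([is_error, is_ckd, is_non]) == 1
        if is_ckd:
            assert "risk_score" not in out and "drivers" not in out
        if is_non:
            assert ("drivers" in out) == (out["risk_score"] > 0)


def test_inference_with_partial_payload_missing_values_imputed(trained_bundle):
    kept = trained_bundle.preprocessor.sparse_filter.kept
    payload = {"id": "SPARSE", "features": {kept[0]: 1.0, kept[1]: None}}
    out = infer(trained_bundle, payload)
    assert "validation_error" not in out


# ---------------------------------------------------------------------- CV

def test_cv_protocol_structure_and_refits():
    cohort = generate_cohort(
        default_cohort_spec(n_patients=300, separation=3.0, seed=21)
    )
    cfg = SystemConfig(seed=3, model=ModelConfig(binary_k=10, stage_k=10,
                                                 stage_max_iter=200))
    result = run_cv(cohort, k=3, config=cfg)
    assert len(result["folds"]) == 3
    summary = result["summary"]
    assert "accuracy" in summary["binary"]
    for metric in summary["binary"].values():
        assert metric["sd"] >= 0.0
    # per-fold refits: thresholds/selections may differ between folds, and
    # fold metrics replay exactly from the recorded fold ids
    thresholds = [f["threshold"] for f in result["folds"]]
    assert len(thresholds) == 3
    plan = result["fold_plan"]
    all_test = [pid for f in plan.folds for pid in f.test_ids]
    assert len(all_test) == len(set(all_test)) == cohort.n_patients
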