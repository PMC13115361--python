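"""Shapley attribution: exactness against coalition enumeration, additivity,
agreement with the booster's native contribution predictor, global-weight
normalisation, driver reports and the controlled output policy."""

import itertools
import math

import numpy as np
import pytest
import xgboost as xgb

from ckdtriage.cohort import CohortTable
from ckdtriage.explain import (
    IMPACT_EDGES,
    TreeEnsemble,
    apply_output_policy,
    build_driver_report,
    compute_global_weights,
    explain_record,
    render_report,
    sampling_shap_values,
    tree_shap_values,
)
from ckdtriage.model import BinaryHead, RoutedPrediction
from ckdtriage.patterns import FlaggedFeature
from conftest import make_table


def _fit_head(X, y, n_estimators=15, max_depth=3, names=None):
    clf = xgb.XGBClassifier(
        n_estimators=n_estimators, max_depth=max_depth, random_state=0, n_jobs=1
    )
    clf.fit(X, y)
    probs = clf.predict_proba(X)[:, 1]
    names = names or tuple(f"F{i}" for i in range(X.shape[1]))
    return BinaryHead(
        model=clf, family="xgboost", selected_features=names, threshold=0.5,
        p0_train=probs[y == 0], p1_train=probs[y == 1], fit_ids=(),
    )


def _brute_force_shap(ensemble: TreeEnsemble, x: np.ndarray) -> np.ndarray:
    """Exhaustive Shapley values of the cover-weighted tree game."""
    phi = np.zeros(ensemble.n_features)
    for tree in ensemble.trees:
        feats = sorted(tree.used_features())
        for i in feats:
            others = [f for f in feats if f != i]
            for r in range(len(others) + 1):
                for S in itertools.combinations(others, r):
                    w = (
                        math.factorial(len(S))
                        * math.factorial(len(feats) - len(S) - 1)
                        / math.factorial(len(feats))
                    )
                    phi[i] += w * (
                        tree.expectation(x, frozenset(S) | {i})
                        - tree.expectation(x, frozenset(S))
                    )
    return phi


@pytest.fixture(scope="module")
def small_head():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(300, 8))
    y = (
        X[:, 0] + 0.8 * X[:, 1] - 0.6 * X[:, 2] + 0.3 * X[:, 5]
        + rng.normal(scale=0.5, size=300)
        > 0
    ).astype(int)
    return _fit_head(X, y), X


def test_contributions_match_exhaustive_enumeration(small_head):
    head, X = small_head
    ens = TreeEnsemble.from_booster(head.model.get_booster(), 8)
    for i in range(5):
        phi = tree_shap_values(ens, X[i])
        oracle = _brute_force_shap(ens, X[i])
        assert np.abs(phi - oracle).max() < 1e-9


def test_additivity_on_every_explained_record(small_head):
    head, X = small_head
    ens = TreeEnsemble.from_booster(head.model.get_booster(), 8)
    for i in range(20):
        phi = tree_shap_values(ens, X[i])
        margin = ens.margin(X[i])
        baseline = ens.baseline()
        assert abs(baseline + phi.sum() - margin) < 1e-6


def test_agreement_with_native_booster_contributions(small_head):
    head, X = small_head
    ens = TreeEnsemble.from_booster(head.model.get_booster(), 8)
    native = head.model.get_booster().predict(
        xgb.DMatrix(X[:10]), pred_contribs=True
    )
    for i in range(10):
        phi = tree_shap_values(ens, X[i])
        assert np.abs(phi - native[i, :-1]).max() < 1e-4


def test_explain_record_additivity_and_sign_meaning(small_head):
    head, X = small_head
    record = make_table({f"F{i}": [X[0, i]] for i in range(8)})
    local = explain_record(head, record)
    assert local.scale == "margin"
    total = local.baseline + sum(local.contributions.values())
    assert abs(total - local.output) < 1e-6
    assert 0.0 <= local.probability <= 1.0


def test_constant_feature_has_zero_contribution():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(200, 3))
    X[:, 2] = 1.0  # constant: never split on, never attributed
    y = (X[:, 0] > 0).astype(int)
    head = _fit_head(X, y)
    record = make_table({"F0": [0.4], "F1": [0.1], "F2": [1.0]})
    local = explain_record(head, record)
    assert local.contributions["F2"] == 0.0


def test_single_feature_model_takes_all_weight():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(200, 1))
    y = (X[:, 0] > 0).astype(int)
    head = _fit_head(X, y)
    background = make_table({"F0": X[:50, 0]})
    weights = compute_global_weights(head, background)
    assert weights.weight_norm["F0"] == pytest.approx(1.0)


def test_global_weights_normalised_and_rank_consistent(small_head):
    head, X = small_head
    background = make_table({f"F{i}": X[:100, i] for i in range(8)})
    weights = compute_global_weights(head, background, max_background=50, seed=0)
    assert sum(weights.weight_norm.values()) == pytest.approx(1.0, abs=1e-9)
    mas = list(weights.mean_abs_shap.values())
    assert mas == sorted(mas, reverse=True)
    assert list(weights.mean_abs_shap) == list(weights.weight_norm)


def test_dominant_injected_effect_ranks_first():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(400, 5))
    y = (2.5 * X[:, 3] + 0.2 * X[:, 0] + rng.normal(scale=0.3, size=400) > 0).astype(int)
    head = _fit_head(X, y)
    background = make_table({f"F{i}": X[:150, i] for i in range(5)})
    weights = compute_global_weights(head, background, seed=1)
    assert next(iter(weights.weight_norm)) == "F3"
    # permutation-importance oracle agrees on the top feature
    from sklearn.inspection import permutation_importance

    imp = permutation_importance(
        head.model, X, y, n_repeats=5, random_state=0, n_jobs=1
    )
    assert int(np.argmax(imp.importances_mean)) == 3


def test_sampling_attribution_exactly_additive():
    rng = np.random.default_rng(15)
    X = rng.normal(size=(100, 4))

    def predict(Z):
        return 1.0 / (1.0 + np.exp(-(Z[:, 0] + 0.5 * Z[:, 1] - Z[:, 2])))

    phi, baseline = sampling_shap_values(predict, X[0], X[1:], n_permutations=32, seed=0)
    assert abs(baseline + phi.sum() - predict(X[:1])[0]) < 1e-9


# ------------------------------------------------------------ driver report

def _local(contribs, baseline=0.0):
    from ckdtriage.explain import LocalExplanation

    return LocalExplanation(
        baseline=baseline,
        contributions=contribs,
        output=baseline + sum(contribs.values()),
        raw_values={},
        scale="margin",
    )


def _flag(feature, value, rule):
    return FlaggedFeature(feature=feature, value=value, rule_text=rule, imputed=False)


def test_primary_drivers_require_positive_contribution_and_flag():
    local = _local({"PROTEINUrine": 0.6, "HDL": -0.05, "CREA": 0.2, "AGE": 0.1})
    flags = [
        _flag("PROTEINUrine", 30.0, ">= 25.1"),
        _flag("HDL", 32.70, "<= 34.05"),
    ]
    report = build_driver_report(local, flags, risk=17.9, p_ckd=0.08)
    assert [d.feature for d in report.primary_drivers] == ["PROTEINUrine"]
    assert [d.feature for d in report.additional_signals] == ["HDL"]
    assert not {d.feature for d in report.primary_drivers} & {
        d.feature for d in report.additional_signals
    }
    assert all(d.rule_text for d in report.primary_drivers + report.additional_signals)


def test_weak_negative_flagged_feature_is_low_impact_signal():
    # total |contribution| = 1.0; HDL share 0.05 -> Low
    local = _local({"A": 0.7, "B": -0.25, "HDL": -0.05})
    report = build_driver_report(
        local, [_flag("HDL", 32.70, "<= 34.05")], risk=17.9, p_ckd=0.08
    )
    entry = report.additional_signals[0]
    assert entry.feature == "HDL" and entry.impact == "Low"


def test_impact_labels_follow_share_edges():
    local = _local({"A": 0.6, "B": 0.3, "C": 0.1})
    flags = [_flag(f, 1.0, ">= 0.5") for f in ("A", "B", "C")]
    report = build_driver_report(local, flags, risk=40.0, p_ckd=0.2)
    labels = {d.feature: d.impact for d in report.primary_drivers}
    assert labels == {"A": "High", "B": "High", "C": "Moderate"}
    assert IMPACT_EDGES == (0.25, 0.10)


def test_no_flags_still_reports_risk():
    local = _local({"A": 0.4})
    report = build_driver_report(local, [], risk=22.0, p_ckd=0.15)
    assert report.risk_score == 22.0
    assert report.primary_drivers == () and report.additional_signals == ()


# ------------------------------------------------------------ output policy

def _routed(path, p, stage=None):
    return RoutedPrediction(
        patient_id="P0", path=path, p_ckd=p, stage=stage,
        stage_probs=(0.1, 0.2, 0.3, 0.4) if path == "CKD" else None,
    )


def test_ckd_path_exposes_stage_only():
    payload = apply_output_policy(_routed("CKD", 0.95, "stage 4"))
    assert payload == {"decision": "CKD", "stage": "stage 4"}
    assert "risk_score" not in payload and "drivers" not in payload


def test_non_ckd_zero_risk_suppresses_drivers():
    local = _local({"A": 0.4})
    report = build_driver_report(local, [], risk=0.0, p_ckd=0.01)
    payload = apply_output_policy(_routed("non-CKD", 0.01), report)
    assert payload["risk_score"] == 0.0
    assert "drivers" not in payload


def test_non_ckd_positive_risk_includes_drivers():
    local = _local({"HDL": -0.05, "A": 0.5})
    report = build_driver_report(
        local, [_flag("HDL", 32.70, "<= 34.05")], risk=17.9, p_ckd=0.08
    )
    payload = apply_output_policy(_routed("non-CKD", 0.08), report)
    assert payload["risk_score"] == pytest.approx(17.9)
    assert "drivers" in payload
    text = render_report(payload)
    assert "HDL value = 32.7, rule <= 34.05 [Low impact]" in text
    assert "CKD risk score = 17.9" in text
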