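"""Synthetic laboratory cohorts for chronic kidney disease modelling.

Real CKD cohorts assembled from routine clinic panels cannot generally be
redistributed, so every downstream stage of the package is exercised on
synthetic cohorts that emulate the structure of such data: one row per
patient, ~60 demographic and laboratory features of which a third are so
rarely ordered that they exceed 70% missingness, five ordinal classes
(non-CKD and stages 3a/3b/4/5), and stage-monotone shifts in the renal and
hematologic markers (creatinine and urea rise with stage, hemoglobin and
hematocrit fall).

The generator is deliberately simple: class-conditional Gaussian features
with a per-feature signed shift scaled by a stage-severity profile and a
global ``separation`` knob, completely-at-random missingness at stated
per-feature rates, and truncated re-draws to honour physiological
non-negativity.  It does not attempt realistic inter-marker covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureSpec",
    "CohortSpec",
    "CohortTable",
    "generate_cohort",
    "make_worked_record",
    "default_cohort_spec",
    "load_cohort_spec",
    "save_cohort_spec",
    "CLASS_NAMES",
    "STAGE_SEVERITY",
]

#: Class encoding: 0 = non-CKD, 1..4 = stages 3a, 3b, 4, 5.
CLASS_NAMES = ("non-CKD", "stage 3a", "stage 3b", "stage 4", "stage 5")

#: Severity multipliers applied to each feature's signed shift, per class.
#: Strictly increasing over the CKD stages so that class-conditional means
#: are ordered in stage for every feature with a nonzero shift.
STAGE_SEVERITY = (0.0, 1.0, 1.5, 2.0, 2.8)

DEFAULT_LABEL_COLUMN = "ckd_stage"


class CohortConfigError(ValueError):
    """Raised when a cohort specification violates its invariants."""


@dataclass(frozen=True)
class FeatureSpec:
    """Distributional description of one laboratory or demographic feature.

    ``shift`` is the signed change in the feature mean per unit of stage
    severity (positive for markers that rise with CKD stage, negative for
    markers that fall); the realised class mean is
    ``base_mean + shift * STAGE_SEVERITY[label] * separation``.
    """

    name: str
    unit: str = ""
    base_mean: float = 0.0
    base_sd: float = 1.0
    shift: float = 0.0
    lower_bound: float | None = None
    missing_rate: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 500
    class_probs: tuple[float, ...] = (0.35, 0.15, 0.15, 0.15, 0.20)
    feature_specs: tuple[FeatureSpec, ...] = ()
    separation: float = 1.0
    seed: int = 0
    #: Optional per-class multiplier on every missing rate; hook for
    #: label-dependent-missingness stress tests (default: MCAR).
    class_missing_scale: tuple[float, ...] | None = None

    def validate(self) -> None:
        if self.n_patients < 5:
            raise CohortConfigError("n_patients must be at least 5")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (5,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise CohortConfigError(
                "class_probs must be 5 non-negative probabilities summing to 1"
            )
        if self.separation < 0:
            raise CohortConfigError("separation must be non-negative")
        if not self.feature_specs:
            raise CohortConfigError("feature_specs must be non-empty")
        for fs in self.feature_specs:
            if not 0.0 <= fs.missing_rate <= 1.0:
                raise CohortConfigError(
                    f"missing_rate for {fs.name!r} must lie in [0, 1]"
                )
        names = [fs.name for fs in self.feature_specs]
        if len(set(names)) != len(names):
            raise CohortConfigError("duplicate feature names in feature_specs")


@dataclass
class CohortTable:
    """Patient-indexed feature matrix with an explicit missingness mask.

    ``features`` holds NaN for missing entries; ``observed_mask`` is True
    where a value was originally measured.  ``labels`` is None for
    unlabeled (inference-only) tables.
    """

    features: pd.DataFrame
    labels: pd.Series | None
    observed_mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.features.index.has_duplicates:
            raise ValueError("patient ids must be unique")
        if self.observed_mask.shape != self.features.shape:
            raise ValueError("observed_mask shape must match features")
        if self.labels is not None:
            if not self.labels.index.equals(self.features.index):
                raise ValueError("labels index must match features index")
            bad = set(np.unique(self.labels)) - {0, 1, 2, 3, 4}
            if bad:
                raise ValueError(f"labels outside 0..4: {sorted(bad)}")

    @property
    def patient_ids(self) -> pd.Index:
        return self.features.index

    @property
    def n_patients(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def subset(self, ids) -> "CohortTable":
        ids = pd.Index(ids)
        labels = None if self.labels is None else self.labels.loc[ids]
        return CohortTable(
            features=self.features.loc[ids].copy(),
            labels=labels,
            observed_mask=self.observed_mask.loc[ids].copy(),
        )

    def select_columns(self, columns) -> "CohortTable":
        columns = list(columns)
        return CohortTable(
            features=self.features[columns].copy(),
            labels=None if self.labels is None else self.labels.copy(),
            observed_mask=self.observed_mask[columns].copy(),
        )

    def binary_labels(self) -> pd.Series:
        """CKD (stages 3a-5) = 1 vs non-CKD = 0."""
        if self.labels is None:
            raise ValueError("table is unlabeled")
        return (self.labels > 0).astype(int)

    def missing_fraction(self) -> pd.Series:
        return 1.0 - self.observed_mask.mean(axis=0)

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path, label_column: str = DEFAULT_LABEL_COLUMN) -> None:
        out = self.features.copy()
        if self.labels is not None:
            out[label_column] = self.labels
        out.to_csv(path, index=True, index_label="patient_id")

    @classmethod
    def from_csv(cls, path, label_column: str = DEFAULT_LABEL_COLUMN) -> "CohortTable":
        frame = pd.read_csv(path, index_col="patient_id")
        labels = None
        if label_column in frame.columns:
            labels = frame.pop(label_column).astype(int)
        frame = frame.astype(float)
        return cls(features=frame, labels=labels, observed_mask=frame.notna())


# --------------------------------------------------------------------------
# Default feature battery: 39 routinely ordered features plus 21 rarely
# ordered ones (missingness > 70%) so the sparse-feature filter has
# something to remove.  Units and magnitudes follow conventional lab scales;
# shifts encode the expected direction of change with CKD stage.
# --------------------------------------------------------------------------

def _routine_features() -> list[FeatureSpec]:
    f = FeatureSpec
    return [
        f("Gender", "", 0.5, 0.5, 0.0, 0.0, 0.02),
        f("Age", "years", 52.0, 14.0, 4.0, 18.0, 0.0),
        f("Hypertension", "", 0.4, 0.45, 0.12, 0.0, 0.05),
        f("Systolic_BP", "mmHg", 128.0, 15.0, 4.0, 70.0, 0.10),
        f("Diastolic_BP", "mmHg", 79.0, 10.0, 1.5, 40.0, 0.10),
        f("Diabetes", "", 0.35, 0.45, 0.10, 0.0, 0.05),
        f("CAD", "", 0.15, 0.35, 0.06, 0.0, 0.08),
        f("CREA", "mg/dL", 0.95, 0.22, 0.85, 0.1, 0.02),
        f("PROTEIN", "g/dL", 7.1, 0.5, -0.22, 3.0, 0.15),
        f("BUN", "mg/dL", 14.5, 4.5, 9.5, 2.0, 0.02),
        f("ALB", "g/dL", 4.3, 0.35, -0.22, 1.5, 0.10),
        f("ALP", "U/L", 82.0, 22.0, 7.0, 10.0, 0.12),
        f("ALT", "U/L", 26.0, 10.0, -1.2, 3.0, 0.12),
        f("AST", "U/L", 24.0, 8.0, -0.8, 3.0, 0.12),
        f("CA", "mg/dL", 9.4, 0.45, -0.18, 5.0, 0.08),
        f("CHOL", "mg/dL", 185.0, 35.0, -6.0, 80.0, 0.15),
        f("GLU", "mg/dL", 105.0, 28.0, 6.0, 40.0, 0.10),
        f("NA", "mmol/L", 139.5, 2.8, -0.5, 120.0, 0.05),
        f("P", "mg/dL", 3.6, 0.6, 0.45, 1.0, 0.10),
        f("TBIL", "mg/dL", 0.6, 0.25, -0.03, 0.05, 0.15),
        f("UA", "mg/dL", 5.3, 1.2, 0.55, 1.0, 0.12),
        f("K", "mmol/L", 4.3, 0.4, 0.17, 2.5, 0.05),
        f("MG", "mg/dL", 2.05, 0.25, 0.06, 0.8, 0.15),
        f("HDL", "mg/dL", 48.0, 11.0, -3.2, 10.0, 0.18),
        f("LDL", "mg/dL", 110.0, 28.0, -5.0, 30.0, 0.18),
        f("CL", "mmol/L", 103.0, 3.0, 0.5, 85.0, 0.08),
        f("TRIGLYCERIDE", "mg/dL", 135.0, 50.0, 9.0, 30.0, 0.18),
        f("HCT", "%", 41.5, 3.6, -2.6, 15.0, 0.02),
        f("HGB", "g/dL", 13.8, 1.3, -0.95, 5.0, 0.02),
        f("MCH", "pg", 28.5, 2.2, -0.35, 18.0, 0.05),
        f("MCHC", "g/dL", 33.3, 1.0, -0.15, 28.0, 0.05),
        f("MCV", "fL", 86.0, 5.0, -0.6, 60.0, 0.05),
        f("PLATELET", "10^3/uL", 265.0, 60.0, -12.0, 50.0, 0.05),
        f("RBC", "10^6/uL", 4.75, 0.45, -0.28, 2.0, 0.02),
        f("WBC", "10^3/uL", 7.1, 1.8, 0.25, 1.5, 0.02),
        f("RDW_CV", "%", 13.3, 1.0, 0.45, 10.0, 0.05),
        f("PROTEINUrine", "mg/dL", 12.0, 9.0, 26.0, 0.0, 0.20),
        f("RBCUrine", "/HPF", 2.0, 1.8, 2.2, 0.0, 0.20),
        f("WBCUrine", "/HPF", 3.0, 2.4, 2.6, 0.0, 0.20),
    ]


def _sparse_features(missing_rate: float = 0.8) -> list[FeatureSpec]:
    names = [
        ("BP_RECORD", "mmHg", 125.0, 14.0, 70.0),
        ("DBIL", "mg/dL", 0.2, 0.1, 0.0),
        ("LDH", "U/L", 190.0, 40.0, 50.0),
        ("NON_HDL", "mg/dL", 135.0, 32.0, 40.0),
        ("HBA1C", "%", 5.9, 0.9, 3.5),
        ("TROPONIN_I", "ng/mL", 0.02, 0.015, 0.0),
        ("IRON", "ug/dL", 85.0, 30.0, 10.0),
        ("GGT", "U/L", 30.0, 15.0, 3.0),
        ("LIPASE", "U/L", 35.0, 15.0, 3.0),
        ("AMYLASE", "U/L", 65.0, 20.0, 10.0),
        ("CK", "U/L", 110.0, 50.0, 10.0),
        ("CK_MB", "ng/mL", 2.5, 1.2, 0.0),
        ("VITAMIN_B12", "pg/mL", 420.0, 140.0, 50.0),
        ("FERRITIN", "ng/mL", 130.0, 80.0, 5.0),
        ("VITAMIN_D", "ng/mL", 24.0, 9.0, 2.0),
        ("PTH", "pg/mL", 48.0, 20.0, 5.0),
        ("TSH", "mIU/L", 2.1, 1.0, 0.05),
        ("FT4", "ng/dL", 1.2, 0.2, 0.3),
        ("FT3", "pg/mL", 3.1, 0.5, 1.0),
        ("SPECIFIC_GRAVITY", "", 1.016, 0.006, 1.0),
        ("GLUCOSE_Urine", "mg/dL", 4.0, 5.0, 0.0),
    ]
    return [
        FeatureSpec(n, u, m, s, 0.0, lb, missing_rate) for n, u, m, s, lb in names
    ]


#: Names of the 21 rarely ordered features in the default battery.
SPARSE_FEATURE_NAMES = tuple(fs.name for fs in _sparse_features())


def default_cohort_spec(
    n_patients: int = 500,
    separation: float = 1.0,
    seed: int = 0,
    class_probs: tuple[float, ...] = (0.35, 0.15, 0.15, 0.15, 0.20),
    include_sparse: bool = True,
    sparse_missing_rate: float = 0.8,
) -> CohortSpec:
    """Study-condition defaults: 39 routine + 21 sparse features."""
    specs = _routine_features()
    if include_sparse:
        specs += _sparse_features(sparse_missing_rate)
    return CohortSpec(
        n_patients=n_patients,
        class_probs=class_probs,
        feature_specs=tuple(specs),
        separation=separation,
        seed=seed,
    )


def _stratified_labels(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Exact largest-remainder allocation of class counts, then shuffle.

    Guarantees every class with nonzero probability is represented whenever
    ``n * prob >= 1``, which a plain multinomial draw does not.
    """
    probs = np.asarray(spec.class_probs, dtype=float)
    raw = spec.n_patients * probs
    counts = np.floor(raw).astype(int)
    remainder = spec.n_patients - counts.sum()
    if remainder > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1
    labels = np.repeat(np.arange(5), counts)
    rng.shuffle(labels)
    return labels


def _draw_bounded(
    rng: np.random.Generator,
    means: np.ndarray,
    sd: float,
    lower: float | None,
    max_attempts: int = 100,
) -> np.ndarray:
    values = rng.normal(means, sd)
    if lower is None:
        return values
    for _ in range(max_attempts):
        bad = values < lower
        if not bad.any():
            break
        values[bad] = rng.normal(means[bad], sd)
    return np.maximum(values, lower)


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a labelled cohort according to ``spec``.

    Deterministic for a fixed seed.  Missingness is applied per feature,
    completely at random at the stated rate (optionally rescaled per class
    through ``class_missing_scale``), and recorded in ``observed_mask``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = _stratified_labels(spec, rng)
    severity = np.asarray(STAGE_SEVERITY)[labels]
    n = spec.n_patients

    columns: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    for fs in spec.feature_specs:
        means = fs.base_mean + fs.shift * severity * spec.separation
        values = _draw_bounded(rng, means, fs.base_sd, fs.lower_bound)
        rates = np.full(n, fs.missing_rate)
        if spec.class_missing_scale is not None:
            rates = np.clip(
                rates * np.asarray(spec.class_missing_scale)[labels], 0.0, 1.0
            )
        observed = rng.random(n) >= rates
        values = np.where(observed, values, np.nan)
        columns[fs.name] = values
        mask[fs.name] = observed

    ids = pd.Index([f"P{i:05d}" for i in range(n)], name="patient_id")
    features = pd.DataFrame(columns, index=ids)
    return CohortTable(
        features=features,
        labels=pd.Series(labels, index=ids, name=DEFAULT_LABEL_COLUMN),
        observed_mask=pd.DataFrame(mask, index=ids),
    )


def make_worked_record(spec: CohortSpec | None = None) -> CohortTable:
    """Fixed single-patient record for exercising the flagging/report path.

    HDL is set to 32.70 mg/dL (a value below typical CKD-like HDL cutpoints,
    so it flags against a rule of the form ``HDL <= 34.05``); every other
    feature sits at its baseline mean.  The record is unlabeled and fully
    observed.  Calling this twice returns identical records.
    """
    if spec is None:
        spec = default_cohort_spec()
    values = {fs.name: float(fs.base_mean) for fs in spec.feature_specs}
    if "HDL" not in values:
        raise CohortConfigError("worked record requires an HDL feature")
    values["HDL"] = 32.70
    ids = pd.Index(["WORKED-0001"], name="patient_id")
    features = pd.DataFrame([values], index=ids)
    return CohortTable(
        features=features,
        labels=None,
        observed_mask=pd.DataFrame(True, index=ids, columns=features.columns),
    )


# ----------------------------------------------------------------- YAML I/O

def save_cohort_spec(spec: CohortSpec, path) -> None:
    payload = {
        "n_patients": spec.n_patients,
        "class_probs": list(spec.class_probs),
        "separation": spec.separation,
        "seed": spec.seed,
        "class_missing_scale": (
            None if spec.class_missing_scale is None else list(spec.class_missing_scale)
        ),
        "features": [
            {
                "name": fs.name,
                "unit": fs.unit,
                "base_mean": fs.base_mean,
                "base_sd": fs.base_sd,
                "shift": fs.shift,
                "lower_bound": fs.lower_bound,
                "missing_rate": fs.missing_rate,
            }
            for fs in spec.feature_specs
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_cohort_spec(path) -> CohortSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    features = tuple(
        FeatureSpec(
            name=item["name"],
            unit=item.get("unit", ""),
            base_mean=float(item.get("base_mean", 0.0)),
            base_sd=float(item.get("base_sd", 1.0)),
            shift=float(item.get("shift", 0.0)),
            lower_bound=item.get("lower_bound"),
            missing_rate=float(item.get("missing_rate", 0.0)),
        )
        for item in payload["features"]
    )
    scale = payload.get("class_missing_scale")
    return CohortSpec(
        n_patients=int(payload["n_patients"]),
        class_probs=tuple(payload["class_probs"]),
        feature_specs=features,
        separation=float(payload.get("separation", 1.0)),
        seed=int(payload.get("seed", 0)),
        class_missing_scale=None if scale is None else tuple(scale),
    )
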