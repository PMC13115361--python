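"""Quantile-anchored 0-100 risk scale for sub-threshold predictions.

A record routed non-CKD still carries a continuous gate probability
p(CKD).  The risk map contextualises it against the training population:
the lower anchor p0 is the 95th percentile of P0 (gate probabilities of
non-CKD training rows) and the upper anchor p1 is the 5th percentile of P1
(CKD training rows).  Probabilities at or below p0 score 0, at or above p1
score 100, and the ramp between the anchors is linear.  Quantiles rather
than extremes keep single outlying training predictions from inflating or
collapsing the transition region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RiskAnchors",
    "DegenerateAnchorsError",
    "fit_anchors",
    "risk_score",
    "count_flagged",
    "risk_band",
]

QUANTILE_CONVENTION = "linear"  # interpolation between order statistics


class DegenerateAnchorsError(ValueError):
    pass


@dataclass(frozen=True)
class RiskAnchors:
    """Anchors (p0, p1) of the probability-to-risk ramp.

    ``quantile_convention`` names the quantile rule used at fit time so a
    serialized bundle is reproducible across implementations.
    """

    p0: float
    p1: float
    quantile_convention: str = QUANTILE_CONVENTION

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.p1 <= 1.0):
            raise DegenerateAnchorsError("anchors must lie in [0, 1]")
        if self.p0 >= self.p1:
            raise DegenerateAnchorsError(
                f"non-degenerate map requires p0 < p1, got p0={self.p0}, p1={self.p1}"
            )

    def to_dict(self) -> dict:
        return {
            "p0": self.p0,
            "p1": self.p1,
            "convention": self.quantile_convention,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskAnchors":
        return cls(float(d["p0"]), float(d["p1"]), d.get("convention", QUANTILE_CONVENTION))


def fit_anchors(
    train_probs: np.ndarray,
    train_binary_labels: np.ndarray,
    min_ramp_width: float = 0.0,
) -> RiskAnchors:
    """Fit (p0, p1) from training gate probabilities and binary labels.

    p0 = Q0.95 of the non-CKD probabilities, p1 = Q0.05 of the CKD
    probabilities, both under the linear-interpolation quantile convention.
    Degenerate anchors (p0 >= p1, possible on tiny or poorly separated
    training sets) raise unless a positive ``min_ramp_width`` is supplied,
    in which case p1 is floored at p0 + width (robustness-harness hook).
    """
    probs = np.asarray(train_probs, dtype=float)
    y = np.asarray(train_binary_labels).astype(int)
    if probs.shape != y.shape:
        raise ValueError("probs and labels must be aligned")
    if not ((y == 0).any() and (y == 1).any()):
        raise ValueError("both classes required to fit anchors")
    p0 = float(np.quantile(probs[y == 0], 0.95))
    p1 = float(np.quantile(probs[y == 1], 0.05))
    if p0 >= p1 and min_ramp_width > 0:
        p1 = min(1.0, p0 + min_ramp_width)
    return RiskAnchors(p0=p0, p1=p1)


def risk_score(p_ckd: float, anchors: RiskAnchors) -> float:
    """Map a gate probability onto the 0-100 risk scale.

    0 at or below p0, 100 at or above p1, linear in between, clamped to
    [0, 100].  Monotone non-decreasing in p_ckd by construction.
    """
    p = float(p_ckd)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p_ckd must lie in [0, 1]")
    if p <= anchors.p0:
        return 0.0
    if p >= anchors.p1:
        return 100.0
    score = 100.0 * (p - anchors.p0) / (anchors.p1 - anchors.p0)
    return float(np.clip(score, 0.0, 100.0))


def count_flagged(non_ckd_probs: np.ndarray, anchors: RiskAnchors) -> int:
    """Number of gate-negative records carrying a non-zero risk score.

    Equivalently |{p : p > p0}| over the non-CKD-routed predictions — the
    early-warning layer's alert count.
    """
    probs = np.asarray(non_ckd_probs, dtype=float)
    return int((probs > anchors.p0).sum())


def risk_band(
    score: float, band_edges: tuple[float, float] = (20.0, 50.0)
) -> str:
    """Coarse clinical band for a risk score.

    Default edges (20, 50) are illustrative working values, not calibrated
    clinical rules: below the lower edge is "low", the closed interval
    [lower, upper] is "moderate", above the upper edge is "high".
    """
    lo, hi = band_edges
    if not lo < hi:
        raise ValueError("band edges must be strictly increasing")
    if not 0.0 <= score <= 100.0:
        raise ValueError("score must lie in [0, 100]")
    if score < lo:
        return "low"
    if score <= hi:
        return "moderate"
    return "high"
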