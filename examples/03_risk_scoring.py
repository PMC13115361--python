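"""The quantile-anchored 0-100 risk scale for gate-negative patients.

The lower anchor p0 is the 95th percentile of non-CKD training gate
probabilities, the upper anchor p1 the 5th percentile of CKD ones; risk is
0 at or below p0, 100 at or above p1, and linear in between.
"""

import numpy as np

from ckdtriage import count_flagged, fit_anchors, risk_band, risk_score

rng = np.random.default_rng(0)
non_ckd_probs = rng.beta(1.5, 8.0, 400)   # gate probabilities of non-CKD rows
ckd_probs = rng.beta(8.0, 1.5, 300)       # gate probabilities of CKD rows
probs = np.concatenate([non_ckd_probs, ckd_probs])
labels = np.concatenate([np.zeros(400), np.ones(300)])

anchors = fit_anchors(probs, labels)
print(f"anchors: p0 = {anchors.p0:.3f} (non-CKD Q95), p1 = {anchors.p1:.3f} (CKD Q5)")

for p in (0.05, anchors.p0, 0.45, 0.55, anchors.p1, 0.99):
    s = risk_score(p, anchors)
    print(f"  p(CKD) = {p:.3f}  ->  risk = {s:5.1f}  ({risk_band(s)})")

tau = 0.50
gate_negative = probs[probs < tau]
n_flagged = count_flagged(gate_negative, anchors)
print(f"\nof {len(gate_negative)} gate-negative records, {n_flagged} carry a "
      "non-zero risk score (the early-warning layer)")
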