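"""Patient-level driver reports under the controlled explanation policy.

Gate-positive patients get a stage and nothing else; gate-negative
patients get p(CKD), the 0-100 risk score and — only when the risk is
non-zero — the Shapley-attribution driver lists: primary drivers (positive
contribution AND CKD-like flag) and additional CKD-like signals.
"""

from ckdtriage import (
    SystemConfig,
    default_cohort_spec,
    generate_cohort,
    infer,
    render_report,
    run_training,
)

# Moderate separation leaves genuine borderline cases below the gate.
cohort = generate_cohort(default_cohort_spec(n_patients=500, separation=0.8, seed=11))
bundle = run_training(cohort, SystemConfig(seed=11))
print(f"tau = {bundle.binary_head.threshold:.2f}, "
      f"anchors p0 = {bundle.anchors.p0:.3f}, p1 = {bundle.anchors.p1:.3f}")

print("\ntop 5 global gate features by attribution weight:")
print(bundle.global_weights.top(5).round(4).to_string(index=False))

# scan held-out patients for one example of each decision path
seen = set()
for pid in bundle.split_plan.test_ids:
    out = infer(bundle, {"id": pid}, cohort=cohort)
    key = ("CKD" if out.get("decision") == "CKD"
           else "risk>0" if out.get("risk_score", 0) > 0 else "risk=0")
    if key in seen:
        continue
    seen.add(key)
    print(f"\n--- patient {pid} ---")
    print(render_report(out))
    if len(seen) == 3:
        break
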