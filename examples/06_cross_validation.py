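"""Cross-validated performance estimation.

Every preprocessing state, selector, head and decision threshold is
refitted per fold on that fold's outer training partition (the threshold
on an inner validation split carved from it), and scored on the untouched
outer test fold.  CV is evaluation-only: the deployable system comes from
the single hold-out training run.
"""

from ckdtriage import SystemConfig, default_cohort_spec, generate_cohort, run_cv
from ckdtriage.model import ModelConfig

cohort = generate_cohort(default_cohort_spec(n_patients=400, separation=3.0, seed=2))
config = SystemConfig(seed=2, model=ModelConfig(binary_k=15, stage_k=15,
                                                stage_max_iter=300))
result = run_cv(cohort, k=5, config=config)

print("5-fold cross-validated performance (mean +/- sd):")
for head in ("binary", "stage"):
    print(f"\n{head} head:")
    for metric, stats in result["summary"][head].items():
        print(f"  {metric:<18} {stats['mean']:.3f} +/- {stats['sd']:.3f}")
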