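"""Miniature four-method comparison study (runs in ~20 s).

GREIT, Gauss-Newton with background prior, and the DCT pipeline with contour
and detail priors, on two conductivity patterns and two atelectasis levels,
scored by the l2 difference to the normalized ground truth. The full-scale
study is what scripts/acceptance.py runs.
"""

from eitdct import GreitTrainingSpec, StudyConfig
from eitdct.studies import build_context, pooled_improvements, run_atelectasis_study, run_pattern_study

config = StudyConfig(
    forward_elements=4000,
    inverse_elements=1200,
    n_noise_seeds=3,
    patterns=("a", "e"),
    atelectasis_fractions=(0.0, 0.3),
    greit=GreitTrainingSpec(n_targets=300),
    seed=0,
)
ctx = build_context(config)
patterns = run_pattern_study(config, ctx)
atelectasis = run_atelectasis_study(config, ctx)

print("per-case mean l2 image difference (lower is better):")
print(patterns.case_means().round(2))
print(atelectasis.case_means().round(2))
print("\nmean relative improvement of the DCT reconstructions, pooled over "
      "all cases (positive = DCT better):")
for k, v in pooled_improvements(patterns, atelectasis).items():
    print(f"  {k}: {v:+.1f}%")
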