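"""How detection quality depends on laboratory sampling density.

Thins the observations of one seeded cohort by increasing factors and
re-runs detection and evaluation each time; the truth is unchanged, so
the sensitivity drop isolates the effect of sparser source data.
"""

from hemod import SimConfig, degrade_sampling, generate_cohort
from hemod.pipeline import detect_cohort, evaluate_episode_sets

cohort = generate_cohort(SimConfig(n_patients=120, seed=2718))

print("sampling-interval factor vs block sensitivity/specificity:")
for factor in (1, 2, 4, 8):
    degraded = degrade_sampling(cohort, factor)
    episodes = detect_cohort(degraded.patients)
    _, result = evaluate_episode_sets(degraded.patients, episodes, degraded.truth)
    print(f"  x{factor}: Se={result.sensitivity:.3f}  Sp={result.specificity:.3f}")

# Sensitivity falls monotonically as sampling gets sparser: episodes
# shorter than the effective sampling interval are missed outright, and
# late-detected onsets fall outside the 4 h snapping tolerance.
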