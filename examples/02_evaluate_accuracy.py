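"""Block-based accuracy of detected episodes against a reference standard.

Two patients: one where the detector fires 3 hours late (within the
+/-4 h tolerance, so the onset snaps and the whole episode counts as a
true positive) and one with a missed episode (a false-negative block).
"""

from datetime import datetime, timedelta

from hemod import (
    EvalConfig,
    ODCause,
    ODEpisode,
    PatientRecord,
    ReferenceEpisode,
    evaluate_episode_sets,
)

t0 = datetime(2024, 3, 1)
hh = lambda x: t0 + timedelta(hours=x)

patients = [
    PatientRecord("A", 2.0, t0, hh(72)),
    PatientRecord("B", 9.0, t0, hh(72)),
]
detected = [ODEpisode("A", hh(13), hh(30), ODCause.PLATELETS)]  # 3 h late
reference = [
    ReferenceEpisode("A", hh(10), hh(30)),
    ReferenceEpisode("B", hh(40), hh(60)),  # missed entirely
]

blocks, result = evaluate_episode_sets(patients, detected, reference, EvalConfig())

print("blocks:")
for b in blocks:
    print(f"  {b.patient_id} [{b.start:%d %H:%M} - {b.end:%d %H:%M}] {b.label.value}")
t = result.table
print(f"table: TP={t.tp} FP={t.fp} FN={t.fn} TN={t.tn} (total {t.total})")
print(f"sensitivity = {result.sensitivity:.3f}  95% CI {result.se_ci}")
print(f"specificity = {result.specificity:.3f}  95% CI {result.sp_ci}")

# Patient A's late onset was snapped onto the reference onset, so A
# contributes a clean TP block; patient B's missed episode contributes
# an FN block. Pooled over blocks, sensitivity is TP/(TP+FN) = 1/2.
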