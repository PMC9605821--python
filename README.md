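# hemod

Rule-based detection of **SIRS/sepsis-associated hematologic organ
dysfunction** in pediatric intensive-care patients, together with a
block-based diagnostic-accuracy evaluation and a synthetic PICU cohort
generator. It is written for clinical-informatics researchers who want
to prototype, stress-test, and evaluate laboratory-driven decision
rules on longitudinal ICU data without access to protected patient
records.

## The criteria and the method

Hematologic organ dysfunction is diagnosed from two parameters, per the
International Pediatric Sepsis Consensus Conference (IPSCC) criteria
with common site-level modifications:

* **platelet count** < 80,000/mm³ (strict), or
* a **relative decline** of ≥ 50% versus the *first platelet value
  after admission* (the baseline) — applied only to patients with a
  documented chronic hematology/oncology diagnosis, whose counts may
  stay above 80,000/mm³ while still collapsing, or
* **INR** > 2 (strict) — unless the patient has a primary disease known
  to raise INR (e.g., hereditary coagulation-factor deficiencies), in
  which case elevated INR is discounted.

Because labs are sparse and irregular, a point measurement becomes an
interval by persistence: an abnormal value holds from its specimen
timestamp until the next same-analyte observation with a different
alarm category, else until discharge. Alarm events of the same analyte
and category merge when they overlap or touch. Platelet alarms inside
**extended ECMO windows** (ECMO run ± 2 h before / 12 h after) are
suppressed, since circuit effects such as heparin depress platelets
independently of sepsis. Overlapping platelet and INR episodes
concatenate into a single episode attributed to both causes.

Detected episodes are evaluated against a clinician reference standard
by partitioning each stay into **blocks** at every change of diagnostic
status of either source, labeling each block TP/FP/FN/TN. Episodes
separated by < 24 h are merged first, and detector boundaries within
± 4 h of a reference boundary are snapped onto it. Sensitivity and
specificity are pooled block ratios, Se = ΣTP/Σ(TP+FN) and
Sp = ΣTN/Σ(TN+FP), with Wald 95% confidence intervals whose variance
treats patients as clusters (ratio-of-cluster-totals linearization),
since one patient contributes several blocks.

The synthetic cohort generator injects dysfunction episodes into latent
platelet/INR trajectories and records ground truth as the latent-curve
threshold crossings, so every rule branch is exercisable end to end and
detection quality under noise and sparse sampling is measurable.

## Worked example

```python
from hemod import SimConfig, run_pipeline

cohort, episodes, blocks, result = run_pipeline(SimConfig(n_patients=168, seed=7))
```

prints, via `examples/03_simulate_and_pipeline.py`:

```
cohort: 168 patients, 31 truth episodes in 31 patients
detected: 27 episodes
blocks: TP=24 FP=21 FN=28 TN=193 (total 266)
sensitivity = 0.462  95% CI (0.401, 0.522)
specificity = 0.902  95% CI (0.868, 0.935)
```

Each stay was cut into status-constant blocks; 24 of the 52
reference-positive blocks were matched by an alarm, giving a block
sensitivity of 0.462 — low because the default 6–24 h platelet sampling
makes onsets detectable only at the next blood draw, often beyond the
4 h snapping tolerance, so each episode's leading sliver scores as a
false-negative block. With dense hourly sampling and no noise the same
pipeline recovers the injected truth exactly (Se = Sp = 1.0, see
`tests/test_acceptance.py`).

The other scripts in `examples/` walk through single-patient detection
(alarm merging, BOTH-cause concatenation), the block evaluation with
boundary snapping, and the sampling-degradation experiment.

A thin CLI covers the same pipeline from the shell:

```bash
hemod simulate --out cohort/ --n-patients 168 --seed 7
hemod detect   --data cohort/ --out detected/
hemod evaluate --episodes episodes_labeled.csv --patients cohort/patients.csv --out eval/
hemod report   --data cohort/ --episodes detected/episodes.csv --out charts/
```

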