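# Methods

## Detection model

The rule engine operates on per-stay timelines of LOINC-coded
laboratory observations (platelets "777-3" in /mm³, INR "6301-6"),
ICD-10-GM diagnoses (stay-level attributes, never time-gated — the
gating conditions are chronic), and ECMO procedure intervals. Inference
proceeds in three steps: *specify* the normal range of each analyte,
*evaluate* every observation against it, and assemble abnormal
observations into alarm events and dysfunction episodes.

**Norm model.** The diagnostic criteria fix one boundary per analyte —
platelet minimum 80,000/mm³ and INR maximum 2. The respective other
boundary is a configurable plausibility bound (platelets 1,000,000/mm³,
INR 0.5). All four categories of limit violation are representable
("too low"/"too high" per analyte), but only platelet-low and INR-high
map to dysfunction; platelet-high and INR-low alarms can be surfaced
yet never produce episodes. Boundary values are normal: the criteria
read "< 80,000" and "> 2" strictly. The relative-decline rule is
inclusive at exactly 50% (`value ≤ 0.5 × baseline`), avoiding a
measure-zero dead zone; the baseline is the earliest platelet
observation at or after admission and never triggers the rule itself.
When absolute and relative criteria both hold, the event is attributed
to the absolute criterion.

**Interval semantics on sparse labs.** A point measurement holds from
its specimen timestamp until the next same-analyte observation with a
different alarm category, else until discharge. This persistence
semantics matches forward-chaining stream processing and gives alarm
merging meaning. Events of identical (analyte, category) merge when
they overlap or touch; touching intervals count as overlapping
throughout the package, so zero-gap fragmentation never occurs.

**ECMO suppression** applies to platelet alarms only (it exists to
avoid circuit-related thrombocytopenia false positives); INR alarms are
unaffected. Each ECMO run is extended by 2 h before and 12 h after;
overlapping extended windows merge. Partial overlaps truncate an alarm
rather than deleting it. Suppressed portions are retrievable via
`ecmo_suppressed_intervals` as non-diagnostic warnings but are never
episodes. The INR-exclusion diagnoses suppress only the INR branch:
platelet-caused episodes of such patients are unaffected.

**Diagnosis code lists.** The site-specific chronic hematology/oncology
and INR-raising code lists are configuration, not constants. The
shipped defaults are documented placeholders — prefixes C81–C96
(hematologic malignancies) for the chronic rule and D66–D68 (hereditary
factor deficiencies) for INR exclusion — matched by prefix by default
(`code_prefix_match`); sites substitute their own lists via YAML.

## Evaluation model

Each stay [admission, discharge] is cut at every status-change instant
of either the detector or the reference standard and each maximal
interval labeled TP/FP/FN/TN from the status pair; blocks partition the
stay exactly, with no missing or indeterminate labels possible.
Preprocessing: episodes separated by strictly less than 24 h merge
(applied to both sources by default, `apply_merge_to` can restrict it
to the reference), then every detector boundary within ± 4 h of a
reference onset/end snaps onto the nearest such boundary (earlier
anchor wins ties; the window is symmetric, so overshooting ends are
forgiven like late onsets). Snapping was chosen over post-hoc
relabeling of sliver blocks because it preserves the partition
property; episodes collapsed to zero length by snapping are dropped.
This construction is a reconstruction of the block procedure from its
published description; the original supplementary definition is not
public, so the exact block counts of the original study are not a
reproduction target. A consequence of dropping collapsed episodes is
that at large tolerances a very short true-positive detector episode
whose both ends snap to the same anchor can disappear; within the
default ± 4 h window and episode durations of clinical interest this
does not arise.

**Accuracy.** Point estimates are pooled block ratios. Blocks are
counted, not duration-weighted (duration weighting is available as a
labeled extra, off by default). The variance treats patients as
clusters: with per-patient totals (x_i, n_i) — detected-positive and
reference-positive blocks for sensitivity, and symmetrically for
specificity — the ratio R = Σx_i/Σn_i gets the linearization variance

    Var(R) = m/(m−1) · Σ_i (x_i − R·n_i)² / (Σ_i n_i)²

over the m patients with n_i > 0; the Wald interval is R ± 1.96·SE,
clipped to [0, 1]. Patients without reference-positive blocks
contribute nothing to the sensitivity variance. A pooled-binomial
variance that ignores clustering is available for comparison
(`variance="pooled"`). When no reference-positive (or -negative) blocks
exist the corresponding estimate is reported as absent with an
explanatory note, never as a silent division by zero. `ci_coverage_study`
checks calibration by Monte Carlo: clustered beta-binomial block counts
(about 21% of patients reference-positive, 1–4 positive blocks each,
beta random effect with concentration 10 around the true sensitivity)
with known marginal sensitivity, 1,000 replicates of 200 patients.

## Synthetic cohorts

The generator emulates the study conditions: ages 0–18, stays
lognormal with median 3 days (σ = 0.5, floor 0.5 days — 12 h is the
inclusion minimum), platelets sampled every 6–24 h and INR every
12–48 h (first draw within 2 h of admission, as admission labs are),
episode prevalence 0.21, 1–3 episodes per affected patient lasting
12–96 h, platelet baselines 150,000–450,000/mm³ with nadir at 20% of
baseline, INR baselines 0.9–1.3 peaking at 2.2–4.0, chronic-diagnosis
prevalence 0.10, INR-exclusion prevalence 0.05, ECMO prevalence 0.05,
and 5% multiplicative lognormal measurement noise. The real cohort's
sampling cadence is unreported; these are plausible PICU values and
are configuration, not claims about any site's practice.

Latent trajectories are trapezoidal: within an episode the parameter
moves linearly to its nadir/peak over the first quarter, plateaus over
the middle half, and recovers over the last quarter. The plateau makes
every detectable episode's threshold-crossing interval at least half
the episode duration, so detectability never hinges on a
measure-sampling race; an episode whose nadir/peak stays inside the
normal range crosses nothing, carries no ground truth, and is counted
and warned about (a degenerate configuration is a warning, not a
failure). Episodes start at least 6 h after admission when the stay
allows (a baseline window) — the first episode of an affected patient
is always fitted into the stay, so the affected fraction tracks the
configured prevalence — and successive episodes are at least 36 h
apart, keeping distinct injections distinct under the evaluation's
24 h merge even after sampling-induced boundary shifts.

**Ground truth** is defined on the noise-free latent curve, not the
noisy samples: the intervals where the curve crosses the rule
thresholds, including the chronic relative-decline rule (against the
latent baseline plateau) and the INR-exclusion gate, but *not* ECMO
suppression. ECMO windows therefore act as a false-negative source for
the detector — clinically, dysfunction during ECMO exists even when
the alarm is suppressed — while in confounder-free scenarios
(`SimConfig.dense_noise_free`: hourly sampling, zero noise, no
chronic/exclusion/ECMO draws) detection recovers the truth exactly and
the end-to-end pipeline attains Se = Sp = 1.0.

Randomness flows from a single seed through per-patient substreams
(`numpy.random.SeedSequence.spawn`), so enlarging a cohort never
perturbs existing patients, and the whole simulate → detect → evaluate
pipeline is bit-reproducible. `degrade_sampling` thins observations
deterministically by index (roughly every k-th sample kept) while
leaving the truth untouched, isolating the effect of source-data
quality on accuracy.

What passing tests on these cohorts do *not* show: the generator has no
pharmacokinetics, transfusion response, age-stratified norms, or
inter-parameter physiology; real-data accuracy additionally depends on
documentation quality, pre-analytic errors (`error_spike_rate` can
inject crude artifacts but defaults to 0), and clinician adjudication
behavior that no simulation here models.

## Numerical and formatting choices

Timestamps are timezone-naive ISO 8601 at minute resolution; platelet
values are canonicalized to /mm³ (×10⁹/L inputs multiplied by 1,000 by
the reader). Estimates are reported to 3 decimal places; 1.96 is used
for the 95% normal quantile. Problem sizes in the shipped checks —
50–168-patient cohorts, 120 patients for the degradation experiment,
1,000 × 200 for the coverage study — keep every run in seconds while
leaving binomial noise well inside the asserted bands.

## Known limitations

* The block-construction and CI procedures are reconstructions from
  published descriptions; original supplementary definitions and the
  real per-patient clustering structure are unavailable, so original
  CI bounds are not reproducible and are not targeted.
* Detection latency equals the lab sampling interval by construction;
  no interpolation or prediction between draws is attempted.
* Only the hematologic system is covered; SIRS detection and other
  organ systems are out of scope, as are live EHR connectivity and
  interactive interfaces (reports are static files).
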