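# Methods

This note documents the conventions, models and numerical choices behind
`wardews`: what is computed, under which assumptions, and where the design
was genuinely open.

## Time and data model

All times are integer minutes since the owning patient's recording start
(0-based). Events (treatment onset/end) and nurse observations share that
clock; nothing in the package consumes calendar dates. Windows are
half-open `[t, t+w)` anchored at minute 0 of the recording — a sample at
exactly `t+w` belongs to the next window. Anchoring at recording start
rather than wall clock is a convention: the analysis is defined relative
to recording and treatment intervals, and a fixed anchor is required for
bit-reproducibility.

On disk a cohort is four plain CSVs: long-format vitals
(`patient_id,time_min,parameter,value`), nurse observations (one column
per parameter, empty cell = not measured), events
(`patient_id,onset_min,end_min,clavien_dindo`, empty end = complication
assumed to last to the end of the recording), and a patients file carrying
each recording's duration — the duration cannot be recovered from the
vitals once trailing minutes are missing, and the events reader needs it
to resolve empty end times.

## Preprocessing

Plausibility bounds (HR 30–200 beats/min, RR 5–50 breaths/min, AT
30–50 °C, SpO₂ 70–100 %) are *exclusive*: only values strictly outside
are removed, so a boundary value such as HR 200 is kept. Resampling
averages the retained minute samples per window; availability is the
count of present minute-grid samples divided by the window length, and a
window is disregarded when data are missing for *more than* half of its
minutes — a window missing exactly 50 % is kept. Both edge conventions
are deliberate literal readings and are pinned by tests. No interpolation
or imputation is performed anywhere.

## Scoring

The band table combines the MEWS criteria with the NEWS SpO₂ band and is
shipped as an editable YAML config (`wardews/data/mews_bands.yaml`),
echoed into every output directory. Temperature is banded identically
whether measured axillary (sensor) or tympanic (nurse).

Printed band edges exist at integer resolution (0.1 °C for temperature),
so a real-valued window mean such as RR 8.4 falls between printed bands.
Values are rounded half-away-from-zero to the band resolution before
lookup: RR 8.4 → 8 (2 points), RR 8.5 → 9 (0 points). This closure makes
the bands cover the reals while preserving every printed boundary; it is
a package convention, not a property of the published criteria.

A score is computed only when at least two of the source's parameters are
present; otherwise the score is *absent* (NaN), never zero — zero would
be indistinguishable from "measured and normal". Sensor scores are bounded
by 11 and nurse scores by 14; the test suite confirms both maxima are
attained by brute-force enumeration over the bands. Nurse SpO₂ is scored
whenever charted.

## Alarm semantics

An EWS alarm is a *rising crossing*: at a present sample, score ≥
threshold while the previous present score was below it; the first
present sample of a series already at/above the threshold counts as the
first alarm. The alternative level-above-threshold reading would make
alarm counts monotone in the threshold, which contradicts the observed
behaviour of ward score processes that sit persistently between 2 and 4:
under crossing semantics such a process rarely alarms at thresholds below
3, exactly as the low-threshold alarm rates show.

Absent scores are skipped: the "previous measurement" is the last present
score and a data gap does not reset the alarm state, avoiding a spurious
re-alarm after every sensor dropout. Because the opposite convention is
also defensible, a `gap_reset` flag re-arms the detector across any gap in
the sensor grid. The same crossing rule is applied unchanged to the
irregularly timed nurse series.

Single-parameter alarms are simulated on 60-minute windows only, with
inclusive bounds at the outermost band edges (HR ≤40/≥130, RR ≤8/≥30,
SpO₂ ≤91, AT ≤34.9/≥38.5); several offending parameters in one window
produce a single alarm listing all offenders. The bounds test the raw
window mean (no rounding), so a mean of HR 129.5 does not trigger even
though it would score 3 points after rounding — the two subsystems
deliberately follow their own printed rules.

## Events, eligibility, classification

A complication enters the analysis when (a) its Clavien-Dindo class is
≥ II, (b) treatment started inside the recording, (c) it starts ≥24 h
after the previous *included* complication of the same patient, and
(d) HR and RR each retain ≥4 h of post-filter minute data in the 24 h
before onset. Patients then group as EVENT (≥1 included event), CONTROL
(no events at all) or EXCLUDED (only ineligible events); EXCLUDED
patients are dropped from all alarm statistics, and a sensitivity-analysis
regrouping merges them into the control group instead.

Alarm labels partition by timing: early true-positive in
`[onset − 1440, onset)`, late true-positive in `[onset, end]`,
false-positive otherwise (always, for control patients). The pre-onset
window is half-open at onset so the early and treatment windows cannot
overlap; an alarm at the onset minute is treatment-side. When two
included events' windows both match, early-TP wins and the earliest
matching event is recorded — included events are ≥24 h apart, so overlap
is rare, and the precedence keeps labels deterministic.

## Performance metrics

Sensitivity for early detection is the percentage of included events with
≥1 alarm in their pre-onset window; total sensitivity additionally counts
treatment-period alarms. TAR divides the total alarm count by pooled
patient-days over the analysed (EVENT + CONTROL) population; the phrase
"average daily number of alarms per patient" also admits a mean of
per-patient rates, available via `tar_variant="per_patient"` — pooling is
the default because it is robust to very short recordings. FDR is the
percentage of alarms labelled FP and is *undefined* (None), not zero,
when there are no alarms. Sensitivities are reported both raw and rounded
half-up to integer percent (12/15 → 80 %, 13/15 → 87 %).

Group comparisons use the two-sided Mann-Whitney U test with midrank
ties: exact enumeration when both samples have n ≤ 8 and no ties, else
the tie-corrected normal approximation (scipy). No multiplicity
correction is applied; p-values are reported raw.

Nurse-vs-sensor agreement pairs each nurse value with the mean of
retained sensor samples in the 5 minutes before the observation
(tympanic pairs with axillary temperature; systolic BP has no sensor
counterpart). Bland-Altman limits for repeated measures estimate
between- and within-patient variance components by one-way ANOVA on
patient-grouped differences (unbalanced design, negative between-patient
component clamped to zero); limits are bias ± 1.96·√(σ²ᵦ + σ²ᵥᵥ). With one
pair per patient this reduces algebraically to the classic Bland-Altman
limits, which the tests verify numerically; a `simple=True` variant pools
all differences.

## Synthetic cohort generator

The generator exists so that the pipeline can be exercised and its
estimators validated without patient data. Per patient and parameter:

    value(t) = baseline_i + A·sin(2π(t + φ)/1440) + AR(1) noise
             (+ effect·ramp(t) for event patients)

* **Baselines** HR 78 beats/min, RR 17 breaths/min, SpO₂ 95 %, AT 36.9 °C
  with between-patient SDs 8 / 2 / 1 / 0.3 — unremarkable postoperative
  ward values; the published criteria place them in the 0–1-point bands.
* **Noise** is stationary AR(1) on the minute grid (ρ = 0.9; marginal SDs
  6 / 3 / 1.8 / 0.25). The AR(1) choice gives realistic short-range
  autocorrelation so that window averaging behaves non-trivially; no
  published noise model exists for these sensors.
* **Circadian** amplitudes 5 / 1.5 / 0.5 / 0.3 with a random phase per
  patient.
* **Artifacts**: Poisson spikes (0.5/h per channel) with N(0, σ) offsets
  (σ = 90 / 30 / 25 / 10) large enough to routinely violate the
  plausibility bounds, exercising the filter.
* **Missingness**: Poisson-placed deletion blocks (0.15/h, 5–120 min)
  give HR/RR/AT availability near 84 %; SpO₂ receives extra deletion
  targeting a further 45 % of its remaining time (finger-probe
  detachment), landing near 46 % availability. Uniformly placed blocks
  overlap, so the extra block count is corrected by the coverage identity
  `covered = 1 − exp(−m·L/n)`.
* **Deterioration**: event patients ramp linearly from 0 to the effect
  sizes (+40 beats/min HR, +14 breaths/min RR, −6 % SpO₂, +1.7 °C AT)
  over the 24 h before treatment onset, hold the plateau through
  treatment, and revert afterwards. The ramp is the simplest monotone
  signature with controllable magnitude; the defaults move at least two
  parameters across two scoring bands, the regime the recovery tests
  require.
* **Nurse observations**: ~3/day at jittered times, per-parameter dropout
  matching charting practice (RR missing most often), systematic
  nurse-site offsets (sensor−nurse: HR +3, RR +9, SpO₂ −2.1, temperature
  −0.9) and small manual-reading noise; systolic BP is generated from its
  own per-patient baseline and is untouched by deterioration.
* Recording durations are drawn uniformly from 93–163 h, the
  interquartile range typical of multi-day postoperative stays; default
  cohort size is 9 event + 21 control patients (≈30 % event prevalence).

Generation is a pure function of the config (one root seed, per-patient
child streams): identical configs give bit-identical cohorts.

**What the generator does not emulate** — and hence what passing tests do
*not* show about real data: waveform-level artifacts and motion
correlation between channels, complication-specific deterioration shapes
(everything ramps linearly and monotonically), circadian disruption,
treatment effects on vitals during the recovery period, and measurement
error structure of specific devices. Tests on this cohort validate the
*pipeline arithmetic and estimators*, not clinical performance claims.

## Problem sizes used in the validation suite

The heavier checks run at sizes chosen to give stable statistics while
keeping the suite quick on a single CPU: oracle-equivalence scans use
10⁴ random instances; parameter-recovery and null-calibration use 20
replicate cohorts of 30 patients × 5 days (recovery pools ≥150 events);
the null-uniformity property of the generator itself uses 200 replicates
of 10+10-patient, 24 h cohorts (Kolmogorov–Smirnov test on the
Mann-Whitney p-values at α = 0.01); Bland-Altman recovery uses 500 pairs
over 50 patients. The 3-patient toy fixture (one event, one control, one
excluded patient, ≤48 h each) exercises every eligibility rule and every
alarm label class deterministically; its seed was selected once so that
all three label classes appear at the primary threshold.

## Known limitations

* The alarm definition is inherently ambiguous in prose ("increased to a
  higher level, thereby exceeding a threshold"); the crossing reading is
  adopted for the consistency argument above and the gap behaviour is
  configurable, but other readings exist.
* Treatment onset is a surrogate for complication onset; labels inherit
  any delay between physiological deterioration and the start of
  treatment.
* The EWS uses window means only; other summary statistics (extremes,
  trends) would yield different scores and alarms.
* Cohort-level medians and sweep magnitudes depend on the synthetic
  generator's defaults; only the qualitative shapes (alarm rate falling
  with window length, suppressed alarm rates at thresholds below a
  persistent score floor) are asserted, not magnitudes.
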