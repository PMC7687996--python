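# Methods

## Scope and data model

The package implements a complete hypotension-forecasting analysis on
minute-gridded ICU vital signs (heart rate, respiratory rate, SpO₂,
systolic/diastolic/mean arterial pressure), from raw tables to an
operational alert policy. Real bedside-monitor extracts are
access-restricted, so the package ships a synthetic cohort generator whose
output has the statistical structure the analysis assumes; every
quantitative claim made by the test suite and the acceptance script is a
claim about that synthetic cohort, not about hospital data.

Each ICU stay is a `VitalSeries`: a 0-based regular 1-minute grid with one
float column per channel and NaN for missing observations. Records are
taken to start at ICU admission, so a minute index is also a
time-from-admission.

## Synthetic cohort generator

Per channel, baseline noise is first-order autoregressive,
x_t = μ + φ(x_{t−1} − μ) + ε_t, with φ = 0.9 and innovation variance
scaled so the marginal SD equals the configured per-channel SD (HR 3 bpm,
RR 1.5 /min, SpO₂ 0.8 %, SBP 5 mmHg, DBP 4 mmHg around setpoints 80, 16,
97.5, 120, 70). AR(1) is the simplest process with realistic minute-scale
autocorrelation. MAP is derived, not independent:
MAP = (SBP + 2·DBP)/3 + N(0, 1), keeping the pressure channels
physiologically coupled.

A hypotensive subject receives a programmed onset drawn uniformly between a
quarter of the record and the last minute that still fits the event (for
24-hour records, [360, 1410]). Over the 90 minutes before onset
(`drift_onset_lead_min`), SBP ramps down linearly by `drift_depth_mmhg`
(default 35), HR ramps up 10 bpm and SpO₂ drifts down 1.5 %, while DBP
declines only 5 mmHg — so MAP stays above its 60 mmHg threshold throughout
the ramp and no event can fire early. At onset DBP steps down to the level
that puts MAP at `event_map_mmhg` (56); pressures hold for 30 minutes and
recover linearly over 60. Two hard caps make the construction provable
rather than merely probable: the first 10 post-onset minutes are capped at
SBP ≤ 89 / MAP ≤ 59 (so the clean series satisfies the event definition
from exactly the programmed minute), and outside the decompensation episode
— and everywhere in control subjects — MAP is floored at 61 mmHg (so clean
series can never produce spurious events). The floor binds several SDs
from the MAP mean and is invisible in ordinary noise.

Missingness is injected as whole-minute bursts (length ≤
`missing_burst_max_min`, default 5) placed until the masked fraction
reaches the requested rate (default 5 %); artifacts corrupt individual
observed cells at rate 0.2 % with values drawn strictly outside the
plausibility bounds (e.g. SBP in (400, 500]), so artifact removal
recovers exactly the injected positions. Admission datetimes are uniform
over 60 days, giving the chronological split a meaningful median.
Interventions (for exclusion-rule testing) are placed only on an explicitly
requested number of hypotensive subjects, 60 min before onset.

What the generator does **not** emulate: circadian and treatment-response
dynamics, waveform-resolution structure, repeated/secondary episodes,
inter-channel lag structure beyond the MAP identity, and the heavy-tailed
staffing/documentation gaps of real monitors. Passing tests therefore
demonstrate the *pipeline's* correctness and leakage-safety, and that the
modelling machinery can recover a genuinely present pre-event signature;
they do not certify performance on hospital data, where the signature is
weaker and noisier — on this cohort discrimination near the event
saturates (AUROC ≈ 1 at 15-min lead), which should be read as a
parameter-recovery check, not a clinical claim.

## Event detection

The three-step definition (inclusive thresholds SBP ≤ 90 ∧ MAP ≤ 60;
≥ 5-of-10 sliding-window density; ≤ 2-min gap merge) is implemented with a
convolution for window counts and a difference array for the coverage
union. Conventions: a minute with either pressure missing is *not* below
threshold (absent data never invents hypotension); event onset is the
first below-threshold minute of the merged period and the end is the last
covered minute; "readings" are minutes on the regular grid; stays shorter
than 10 minutes yield no events. One consequence of the definition worth
noting: when two long below-threshold runs flank a short gap, windows
straddling the gap can themselves satisfy 5-of-10, so the union step
bridges the runs before the gap-merge rule is ever consulted; the 2-vs-3
minute merge boundary is only observable for tight sub-window runs, and
the tests construct exactly that case. Equivalence with a brute-force
oracle (explicit window enumeration, set union, gap merge) is asserted on
1,000 random grids.

The intervention-exclusion boundary is inclusive: an intervention exactly
120 min before the first onset excludes the subject; 121+ retains them.

## Preprocessing

Plausibility bounds are strict inequalities — a value exactly at a bound
(SBP = 400, SpO₂ = 10) is kept. Imputation fills missing runs strictly
shorter than 10 minutes left-to-right with the mean of the 3 most recent
available values; filled values may serve as "previous values" later in
the same run (the signal-stability assumption), fewer than 3 but ≥ 1 prior
values use the mean of what exists, and leading gaps stay missing. The rule
is causal: truncating a series never changes earlier fills. On a linear
ramp of slope s, the 3-point trailing mean under-predicts a masked minute
by exactly 2s, which the masked-segment validator reproduces.

## Features

Windows end at the current minute ([t−W+1, t]); a row exists only when
every (channel, window) pair has ≥ 50 % of its minutes present. Variance
is the sample variance (n−1); quantiles interpolate linearly between order
statistics. DFT features are magnitudes of the 5 lowest non-constant
frequencies of the demeaned window (residual gaps filled with the window
mean so Parseval's identity is testable); windows too short for 5 distinct
frequencies (W = 5 has 2) are zero-padded. The EWMA uses α = 0.3 over
present values, seeded at the first present value; the recursion unrolls
to closed-form weights, which is how the rolling implementation vectorizes
it. Neither the retained DFT statistics nor the EWMA decay is canonical
for this kind of analysis; both are configuration with documented
defaults. Feature count: 6 channels × 4 windows × (7 + 5 + 1) = 312.

## Labeling and split

Positives: rows ending in [onset − 15, onset − 1]. The positive horizon is
15 minutes by default (5 is available in configuration). Hypotensive stays
additionally contribute a matched 15-min negative block ending 2 h before
the positive horizon (rows ending [onset − 150, onset − 136]); control
stays contribute negatives in the 15 min before a pseudo-onset drawn
uniformly within ±15 min of the mean time-to-first-event, computed on
**training** hypotensive subjects only. Either negative source can be
disabled. Pseudo-onsets are drawn once per stay. Rows between the blocks
stay unlabeled but are still scored for trajectories.

The split is by subject at the median admission datetime; ties at the
median go to training. With 60-min feature windows, a negative block ends
≥ 121 minutes before the first positive window opens, so no training
window overlaps across classes — asserted by the leakage tests.

## Modelling

Hyperparameters (unspecified in this analysis style by convention) default
to 500 trees for both forest families, k = 11 neighbours, C = 1.0 for the
L2 logistic model; distance/margin families train inside a standardizing
pipeline. Folds are `StratifiedGroupKFold` over subjects, stratified on
subject group, so no subject's rows straddle a fold. Family selection:
lowest mean CV Brier score among families whose mean CV AUROC is within
0.02 of the best. Class imbalance is handled by reporting AUPRC rather than
resampling. The second-stage model trains on **out-of-fold** first-stage
scores (each training stay scored by the fold model that held out its
subject), so the stacked model never sees optimistic in-sample scores.

## Trajectories, evaluation and alerting

Trajectories align each validation stay on its onset (hypotension) or
pseudo-onset (controls) and summarize groups with a normal-approximation
95 % CI (mean ± 1.96·SE; bootstrap would add nothing at the plotted
precision); lead times with < 2 stays in a group are omitted. Lead-time
curves evaluate AUROC (Mann-Whitney, ties half) and AUPRC (step-wise
average precision, chosen so small instances match threshold-enumeration
oracles exactly) on instantaneous lead-time slices, with a ±1-minute
nearest-scored fallback (earlier minute preferred) for missing minutes.
Calibration is the Brier score with 10 equal-width reliability bins.
Patient-level AUPRC aggregates each stay to its maximum score — over the
pre-onset span (whole-stay mode; the forecasting task ends at the event)
or over the last pre-onset hour vs a seeded random control hour
(random-hour mode).

Alerts: exceedance is inclusive (score ≥ threshold, default 0.5); the
lockout (15 min) is greedy relative to the last **emitted** alert;
post-onset minutes are excluded from alerting in the first-event framing.
An alert is a true positive when its stay's first onset is strictly later
(a finite true-positive horizon is available in configuration but
unbounded by default, consistent with reading an alert as "a future event
follows"). Alert rates are normalized by monitored (scored, pre-onset)
subject-hours; a full-stay-hours variant is also reported since either
denominator is defensible.

## Determinism and problem sizes

Every random draw descends from one master seed through
`numpy.random.SeedSequence` spawning: cohort generation, per-stay
missingness/artifact/pseudo-onset draws, fold shuffling, forest training
and the random-hour evaluation. Two runs with the same configuration and
seed produce bit-identical CSV artifacts, which a test asserts by byte
comparison.

Default study conditions: 200 subjects, 50 % hypotensive, 24-hour records,
tenfold CV — sized so the complete analysis runs in roughly two minutes on
one CPU while leaving every stage's sample sizes large enough for stable
metrics (≈ 50 hypotensive and 50 control subjects per split, ≈ 2,200
labeled training rows, ≈ 130,000 scored validation minutes). Integration
tests use a 40-subject, 12-hour cohort with fivefold CV.

## Known limitations

* The synthetic decompensation is a single stereotyped ramp; models
  trained on it saturate near the event, so metric *levels* are not
  transferable — only the pipeline's relative orderings (closer lead ⇒
  better discrimination; stacking ⇒ fewer/cleaner alerts; lockout ⇒ lower
  alert burden) are meaningful checks.
* Only first events are modelled; repeated episodes and post-event
  dynamics are out of scope.
* Cross-channel correlation features and waveform-derived features are
  deliberately absent.
* The generator emits one stay per subject; the classification and split
  logic accept multi-stay subjects, but that path is exercised only by
  unit tests.
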