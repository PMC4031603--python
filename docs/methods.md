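# Methods

`footroll` reimplements, as a tested pipeline, the analysis chain of a
two-arm exercise trial in diabetic polyneuropathy (DPN): regional
plantar-pressure metrics from insole recordings, sagittal ankle
kinematics and kinetics by bottom-up inverse dynamics, clinical
foot-function scoring, and the intention-to-treat repeated-measures
statistics. Because such trials deposit no raw data, a synthetic-data
module generates every input with known ground truth; the package's
claims are therefore about the correctness of the computations, not
about reproducing cohort-level results.

## Plantar-pressure metrics

A recording is a grid of pressure sensors (kPa) sampled at 100 Hz.
Stance phases are maximal runs where the summed pressure·area force
exceeds 5 % of the trial's maximum force for at least 0.2 s — common
gait-event practice; both numbers are parameters. Analysis steps drop
each trial's first and last stance (gait initiation/termination) and
keep the most central 25 per foot.

The footprint is divided into six regions by percentage bands: heel
0–27 % of foot length, midfoot 27–55 %, forefoot 55–80 % (split across
width 55 % medial / 45 % lateral), and toe band 80–100 % (split 33 %
hallux / 67 % toes). The band percentages 27+28+25+20 are the only
consistent reading of the standard scheme in which the "final 20 %" toe
band is carved out of the 45 % forefoot block. Conventions the scheme
itself leaves open were fixed as follows:

* **Long axis** — principal axis of the area-weighted loaded-sensor
  cloud, oriented heel→toe by the loading order (the heel loads first);
  if loading order carries no signal the grid's declared +y direction is
  used. Masks are therefore invariant under rigid rotation of the grid
  whenever loading order is informative.
* **Width per band** — each band's split uses the width of that band's
  own loaded sensors (whether vendor automasking measures width per band
  or globally is not documented anywhere we could verify).
* **Medial side** — the hallux and medial forefoot sit medially, which
  flips between left and right feet; medial is derived from the declared
  foot side and the walking direction.
* **Boundaries** — a sensor belongs to the region containing its centre;
  length intervals are half-open with the distal-most closed, width
  splits closed on the medial side. Deterministic tie-breaking.

Per region, the pressure curve is the per-frame *maximum* over the
region's sensors (the convention insole software uses for its peak-
pressure temporal series; a force–time integral would not have kPa·s
units). From it: PP = curve maximum (kPa); TPP = 100·argmax/(N−1) % of
stance, first occurrence on ties, so a last-frame peak reads exactly
100 %; PTI = trapezoidal integral over stance time (kPa·s). TPP uses
stance start as time zero (not first regional contact). The COP is the
pressure·area-weighted centroid of sensor positions; its mean velocity
is path length over elapsed time. Regional COP velocity — which has no
canonical definition — is computed from the region-restricted COP over
the region's nonzero-load window. Left and right feet are analysed
separately. Per-subject aggregation is the arithmetic mean and sample
SD (ddof = 1; a single step has SD 0 by convention) over the selected
steps.

## Ankle kinematics and inverse dynamics

Markers and force-plate signals (100 Hz, synchronised) are filtered with
zero-phase Butterworth low-passes: a net 4th-order response realised as
forward–backward application of a 2nd-order filter — the dominant
biomechanics convention, chosen because the outcome definitions
implicitly require zero phase lag — at 20 Hz for force and 6 Hz for
kinematics (defaults, exposed as parameters).

The marker set is simplified to sagittal-plane landmarks (heel, toe,
ankle, knee, hip): sufficient for the four sagittal outcomes, whereas a
full cluster-based protocol would add nothing testable here. The ankle
angle is the angle between the shank (ankle→knee) and foot (heel→toe)
axes re-zeroed to neutral standing, dorsiflexion positive — the zero
convention is stated because instruments differ and nothing pins it
down externally.

The net ankle moment comes from a Newton–Euler balance on the foot
segment: GRF applied at the plate COP, plus the foot's weight and
inertial terms. Anthropometrics are Dempster's classical fractions,
hard-coded but exposed: foot 1.45 %, shank 4.65 %, thigh 10.0 % of body
mass, with the standard COM (0.50/0.433/0.433 of segment length) and
radius-of-gyration (0.475/0.302/0.323) fractions; g = 9.81 m/s². The
moment is reported as 100·M/(m·g·h) in %BW·h, plantarflexor positive
(so the early-stance dorsiflexor peak is negative). All internal units
are SI (m, N, kg); the CSV dialects fix the same units, so there is no
unit autodetection and the %BW·h normalisation is exactly
length-scale-free in the static terms.

Outcomes per stance: sagittal ROM (max−min of the angle), the angle at
the final stance frame ("end of propulsion"), and the two moment peaks.
The "≈20 %" extensor and "≈80 %" flexor events are operationalised as
windowed extrema over [5, 40] % and [60, 95] % of stance — robust to
noise far from the events while equal to the global extrema whenever
each half of stance is unimodal (which the tests check). Frames whose
vertical force is below 5 % of its peak are excluded as non-contact;
with zero GRF throughout the series is the foot's gravity term and is
returned unmasked.

## Clinical scoring

MNSI questionnaire (0–13) and physical (0–10 in 0.5 steps) totals, the
ABC balance-confidence percentage, 0–5 manual muscle grades for the
eight tested muscle groups, and 30-second functional repetition counts
classed as 0 → not functional, 1–4 → barely, 5–9 → reasonably, 10–15 →
functional; counts above 15 also class as functional (the scale tops at
15 but 30-second trials can exceed it). Item-level MNSI rubrics belong
to the instrument, not this package: totals are validated, not derived.
Half-grades are not accepted for muscle tests (fractional medians arise
from aggregation, not grading). The eligibility screen encodes the
trial's criteria (age 45–65, BMI 18.5–29.9, diabetes ≥ 7 y, MNSI-Q > 2,
MNSI-physical > 1 with impaired vibration, no ulceration/amputation or
listed exclusions) and reports every failed criterion.

## Trial statistics

* **Imputation** — "mean of series" under MCAR: a missing value is
  replaced by the mean (parametric variables) or median (non-parametric)
  of the observed values in the same group × timepoint cell — the least
  biased reading of the method consistent with a groupwise ITT. Note
  that mean imputation is anticonservative: it shrinks within-cell
  variance while leaving the error df unchanged, which measurably
  inflates the interaction test's type-I error at the default 15.6 %
  missingness (≈ 0.08 instead of 0.05 in our simulations). This is a
  property of the method itself, so the calibration test runs on
  complete data, where the test is exact.
* **Assumption checks** — normality per cell via the Lilliefors variant
  of the Kolmogorov–Smirnov test (mean and SD estimated from the
  sample, the case that actually arises); homoscedasticity via Levene.
* **Mixed rm-ANOVA** — two groups × two timepoints (baseline vs 12
  weeks), between factor group, within factor time. With a two-level
  within factor, sphericity holds trivially and the model reduces to
  exact F tests on difference and mean scores; the time main effect
  uses the type-III (unweighted-means) convention for unbalanced
  groups. Exposed both as the `MixedRmAnova`/`MixedRmAnovaResults`
  model pair and the functional `rm_anova_interaction`. α = 0.05,
  two-sided, everywhere; no multiplicity correction across outcome
  variables (matching the trial's analysis plan).
* **Newman–Keuls** — stepwise studentized-range procedure on ordered
  cell means, harmonic-mean cell sizes for unequal n, with the
  containment rule (a range is significant only if every containing
  range is) enforced structurally.
* **Follow-up** — within the intervention arm over three timepoints:
  one-way rm-ANOVA for parametric variables, Friedman otherwise.
* **Rank tests** — Mann–Whitney U and Wilcoxon signed-rank with exact
  p-values for tie-free samples up to n = 12 per group, tie-corrected
  normal approximation otherwise; the exact path is verified against
  full enumeration in the tests.
* **Cohen's d** — |m₁−m₂| / √((s₁²+s₂²)/2). The unweighted pooled SD is
  used because the arms are nearly equal and several published values
  reproduce under it. Labels follow the usage calibrated to the trial's
  own tables — small < 0.4 ≤ medium < 0.7 ≤ large — rather than the
  textbook 0.2/0.5/0.8 (the tables label 0.3 small, 0.4–0.6 medium,
  0.7–0.8 large). Some published d values are not recoverable from the
  rounded table summaries and were presumably computed on unrounded
  data; those are outside what arithmetic on printed values can check.
* **Hodges–Lehmann** — median of pairwise differences with the
  distribution-free CI from order statistics at normal-approximation
  ranks.
* **Block randomization** — block sizes drawn uniformly from 1–8; an
  odd block's extra slot goes to the under-represented arm (coin flip on
  ties). Purely random odd remainders would random-walk past any fixed
  imbalance bound over hundreds of allocations, so this assignment rule
  is what guarantees the bounded-imbalance property (≤ 1 at block
  boundaries, ≤ 8 at any prefix).
* **Sample size** — noncentral-F power for the between×within
  repeated-measures design, λ = f²·N·m/(1+(m−1)ρ), df (g−1)(m−1) and
  (N−g)(m−1), under an explicitly reported uniform correlation
  assumption (default ρ = 0.5). With f = 0.36, α = 0.05, power 0.81 and
  10 % anticipated loss this gives N = 49 → 55 inflated; the correlation
  and nonsphericity assumptions behind any particular published
  calculation are unrecoverable, so no specific figure is asserted.

## Synthetic data

The generators exist to provide *known ground truth*, so closed-form
tractability drove the signal families.

**Rollover recordings.** Each region's sensors carry a trapezoidal
pulse — raised-cosine ramps around a flat plateau — riding on a small
constant contact pressure (default 15 kPa) present throughout stance.
Closed forms: PP = amplitude + contact, TPP = plateau onset, PTI =
amplitude·(support − (rise+fall)/2)/100·T + contact·T. The contact
pedestal makes the footprint visible to threshold-based stance
detection from the very first frame, which is what lets detection
recover the true stance window exactly and keeps the analytic TPP/PTI
valid end to end. Default pulse amplitudes and timings sit at the
magnitudes published for barefoot DPN gait (heel ≈ 300 kPa peaking near
18 % of stance, forefoot peaks near 80 %, stance 0.65 s, cadence
105 steps/min within the 96–116 band). Known departures from real data:
the uniform pedestal places the first/last COP samples at the footprint
centroid, inflating total COP velocity to ≈ 0.45 m/s against ≈ 0.35 in
published cohorts; pulses are unimodal per region whereas real regional
curves can be multi-peaked; and sensors within a region share one time
course up to a spatial taper. Passing recovery tests therefore
demonstrate correctness of the metric pipeline, not realism of every
waveform feature.

**Gait mechanics.** Vertical GRF is a sum of three raised-cosine lobes
(two humps plus a midstance fill), anteroposterior force a braking and
a propulsive lobe, the plate COP a smooth monotone heel→toe
progression, the foot flat until 60 % of stance then rotating about the
planted toe, and the ankle angle a prescribed lobe sum. Every curve is
analytically differentiable, so the Newton–Euler moment is available
with exact derivatives — the closed-form reference the finite-
difference pipeline is tested against (static trials to < 0.5 %,
dynamic to < 2 % RMS). Defaults (75 kg, 1.68 m) land the extracted
outcomes near published magnitudes: ROM ≈ 21°, end-propulsion ≈ −8°,
extensor peak ≈ −0.9 and flexor peak ≈ 8.3 %BW·h. The profile is not a
whole-body-consistent simulation: GRF and kinematics are prescribed
independently, which is irrelevant to the foot-segment balance being
tested.

**Trial tables.** 29 control / 26 intervention subjects; each variable
gets a shared subject intercept (variance ρσ², default ρ = 0.6, a
typical test-retest correlation for gait summary variables) plus
residual noise, giving uniform within-subject correlation ρ. The
group×time effect shifts the intervention arm's week-12 mean by a
prescribed number of baseline SDs (default 0.8, at which the
interaction test has ≈ 90 % power under the default correlation) and
reverts at week 24 unless configured otherwise. Week-24 rows exist only
for the intervention arm, as in the trial design. MCAR missingness
(default 15.6 %, the trial's observed loss fraction) applies to
post-baseline cells only.

## Numerical choices and degenerate inputs

Trapezoidal integration throughout; TPP's (N−1) denominator; COP frames
with zero load are excluded rather than interpolated; a one-sensor
footprint has zero length and classifies as heel; empty regions yield
all-zero series flagged inactive and NaN regional COP velocity, which
aggregation skips; constant samples short-circuit the normality test
(statistic 0, p 1) and all-tied rank tests return p = 1; all-zero
paired differences raise a degenerate-test signal rather than a number.
Seeds: every stochastic operation takes an explicit seed or generator;
all generators are pure functions of (scenario, seed).

## Problem sizes

Simulation-backed checks use 50 rollover scenarios, 5 dynamic gait
trials, 2000 trial replicates for the type-I calibration, 200 random
footprints for the partition property, and full enumeration of rank
tests up to total n = 8 — sizes at which every Monte-Carlo bound in the
test suite has comfortable margin while the whole suite stays fast.

## Known limitations

No pressure-to-force calibration or proprietary-format parsing; no
frontal/transverse moments, joint powers or proximal joints; no
multiple-testing correction (by design, matching the analysis plan);
the mixed ANOVA is restricted to the 2×2 design it is used for;
cohort-level outcome values are not reproducible without the trial's
raw data and are covered only by the realism smoke test.
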