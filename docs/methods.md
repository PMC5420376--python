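# Methods

## The measurement being modelled

A robotic lower-limb laxity test straps both feet into servomotor-driven
footplates, stabilises femur and patella, and rotates each lower limb
axially: toward external rotation (ER) until the torque reaches a limit
(5.65 Nm in the protocol this package implements), then toward internal
rotation (IR) until the opposite limit, then back — one full cycle.  The
recorded torque–angle trace is a hysteresis loop; stated device accuracy is
0.01° and 0.001 Nm.  Alongside, the KT-1000 arthrometer measures anterior
tibial translation at 67/89/133 N and at examiner manual-maximum force, and
patients report satisfaction on a 0–100 VAS.

No subject-level data are available for this study design, so the package
generates synthetic cohorts with the statistical structure the analysis
assumes, and every claim the test suite certifies is about the procedures
and their operating characteristics — not about real patients.

## Generative limb model

Each limb is an exponential-stiffening backbone with additive frictional
hysteresis.  With `d = angle − neutral`:

```
T_backbone(d) = S · sign(d) · (exp(β·|d|) − 1)
T_measured    = T_backbone + h·direction + ε,   ε ~ N(0, σ²)
```

`S` (Nm) and `β` (1/deg) are direction-specific (ER for d > 0, IR for
d < 0); `h` ≥ 0 (Nm) is the frictional half-width; `direction` is the
motion sign (+1 toward ER).  Motion reverses when the noiseless moving
branch reaches the torque limit `L`.  The model was chosen because it
reproduces the concave morphology of recorded load-deformation loops while
keeping every extracted feature in closed form:

| feature | closed form |
|---|---|
| max ER excursion | `D_er = ln(1 + (L−h)/S_er)/β_er` |
| half-play per side | `c = ln(1 + h/S)/β` |
| play at 0 Nm | `c_er + c_ir` |
| position at 0 Nm | `neutral + (c_er − c_ir)/2` |
| endpoint derivative | `β·(S + L − h)` |

The **endpoint-slope feature** is a least-squares line over the last 10 %
of the rotation range, not the instantaneous derivative.  Its analytic
value is the window-averaged derivative

```
slope_LS = β(S + L − h) · e^{−u/2} · F(u),    u = β·w,  w = window width
F(u) = (12/u³)·[(u/2 − 1)e^{u/2} + (u/2 + 1)e^{−u/2}]  →  1 as u → 0
```

(`closed_form_features` implements this; an independent dense-grid discrete
LS oracle confirms it in the tests).  The distinction matters: a monotone
curve capped at L = 5.65 Nm cannot *average* more than roughly `L/w` ≈ 0.6
Nm/deg over a ~9° window, so steep published stiffness values can only be
meaningful as derivatives, or in other units.

### Stiffness units

The group stiffness contrast reported for this protocol (1.6 stiffer vs 1.3
more compliant, units unstated) is arithmetically impossible as a window-LS
slope in Nm/deg (see the bound above) and, taken as a derivative, forces
β·D ≈ 13 "hockey-stick" curves whose hysteresis offset — solved from any
realistic play — collapses below the torque-noise floor, destroying the
play feature under noise.  The package therefore:

* inverts, by default, the **window-LS slope** (`slope_kind="window_ls"`),
  the quantity extraction actually measures;
* offers `slope_kind="endpoint_derivative"` for derivative targets (1.6 is
  feasible there);
* sets the generator's default slope means to **0.32 / 0.26 Nm/deg** —
  preserving the reported 1.6 : 1.3 stiffer-Group-1 ratio inside the
  curve-compatible regime (SD 0.04 Nm/deg, scaled accordingly).

## Inverse design (`params_from_features`)

Given target features (max ER/IR, play, endpoint slopes, optionally the
position at 0 Nm), the inverter solves per direction for `(S, β)` from the
excursion and the endpoint derivative (safeguarded Newton on a bracketed
monotone equation), finds `h` from the play by a failure-tolerant Brent
search, and runs two outer fixed-point corrections: one absorbing the
LS-window averaging of the slope, one (only when `pos0` is pinned) shifting
the neutral angle so the implied position at 0 Nm lands on target.
Feasibility is checked and violated targets raise `InfeasibleTargetError`
with a diagnostic: an endpoint slope at or below the secant `L/D` admits no
convex curve, and pinning `pos0` shrinks the feasible region further.

Cohort draws leave `pos0` free (the neutral stays at 0 and the 0 Nm
position falls where the asymmetric half-plays put it): this keeps the
drawn rotation/play/slope marginals exactly as specified.  Slope draws are
truncated below at `1.08·L/D` of the limb's own drawn excursion — a
stiffness–laxity coupling any physical limb obeys — so rotation draws are
never altered and group rotation means stay unbiased (verified to within
2 SE at n = 200/arm).

## Synthetic cohort defaults (the study conditions)

Groups of 9 / 6 / 2 subjects (higher satisfaction, lower satisfaction,
outliers), two limbs each.  Printed group means anchor what is anchorable:

* healthy max ER 48.7° (Group 1) vs 64.5° (Group 2);
* healthy total rotation 76.9° vs 95.8° (max IR fixed as the remainder:
  28.2° / 31.3°);
* reconstructed total rotation 70.4° vs 92.2°, with the Group 2
  reconstructed limb 8.7° short of its healthy ER (55.8°).

Unprinted cells carry defaults chosen once: play at 0 Nm 10° (SD 2°) —
consistent with the hysteresis widths the closed forms give for plausible
`h`; KT manual max 8 mm healthy, 9 mm Group 1 reconstructed, 13 mm Group 2
reconstructed (SD 1.5 mm), with the lower forces as noisy monotone
fractions (≈ 0.55/0.70/0.85) of manual max; pivot-shift positivity rates
0 / 0.2 / 0.7 for healthy / G1-recon / G2-recon limbs (grades 1–3 when
positive); VAS uniform within each group's range, kept strictly inside the
open boundaries.  Dispersions default to 8° for rotations, 0.04 Nm/deg for
slopes, 1.5 mm for KT.  Sampling step 0.1° (device floor 0.01°), torque
noise 0.001 Nm (the stated accuracy).  Manual-exam grades are *not*
correlated with curve features beyond the group structure — the generator
imposes no such coupling.

What the generator does **not** emulate: ligament-level mechanics, coupling
of anterior translation to rotation within a limb, multi-cycle
conditioning, examiner variability (a second-examiner KT column is
consumed if present but never synthesised), or the demographic covariates
of a real cohort.  Green tests therefore certify the pipeline's
correctness and calibration, not clinical validity.

## Feature extraction conventions

* Sign convention: ER positive; IR reported as a magnitude (signed output
  behind `FeatureConfig(signed_ir=True)`).
* Reversals are the extreme-angle samples; among ties, the first.
* Zero-torque crossings are linearly interpolated between straddling
  samples *within a run of constant direction* (never across a reversal);
  when noise produces several straddles the median of the interpolated
  crossings is used (unbiased under symmetric noise; exact when noiseless).
  Device-scale noise (≤ 0.01 Nm) perturbs features by < 0.5° /
  0.02 Nm/deg across 100 seeded replicates.
* Play = distance between the two branch crossings; a branch that never
  crosses 0 Nm leaves play/pos0 NaN with a flag, not 0.
* Endpoint slope: least-squares over the last 10 % of the branch's
  *rotation* range (not torque range — rotation windows stay stable where
  the curve is steep), on the loading branch by default (`endpoint_branch`
  switches); windows thinner than 3 samples are widened to 3 with a
  warning.  A percentage-change variant (endpoint / mid-curve slope × 100)
  is provided as `normalized_endpoint_slope`.
* Total rotation = max ER + max IR, exact by construction.

## Statistics

* **Screening descriptors** — sensitivity `tp/(tp+fn)`, specificity
  `tn/(tn+fp)`, PPV `tp/(tp+fp)`, NPV `tn/(tn+fn)`, as percentages; a zero
  denominator leaves the value undefined (None), never 0.  Published-table
  rounding is nearest integer, half away from zero.
* **Condition definition** — reconstructed limbs of Group 2 are
  condition-positive; all Group 1 limbs plus Group 2 healthy limbs are
  condition-negative (patients uniformly report full satisfaction with the
  healthy knee); Group 3 is excluded from inference but retained in data
  products.  The study shape gives 6 positives / 24 negatives, the split
  the published JPE and pivot-shift rows are arithmetically consistent
  with.
* **Fisher exact test** — two-sided by the probability-mass rule: the sum
  of hypergeometric point probabilities (log-factorial evaluation, full
  enumeration over the support) not exceeding the observed one within a
  1e-12 relative tie tolerance.  The tail-doubling definition is available
  (`method="doubling"`).  Degenerate margins give p = 1.  Agreement with
  exact rational enumeration is verified over every table with n ≤ 20.
* **Dichotomization** — test-positive strictly beyond the threshold; ties
  negative.  Pivot shift: grade ≥ 1 is positive.  For continuous criteria
  the default policy searches midpoints of sorted unique values for the
  minimum exact p, breaking ties toward fewer test-positives.  This
  selection inflates the null rejection rate (measured at roughly 20–30 %
  at α = 0.05 on permuted labels, vs ≈ 1 % for an a-priori threshold —
  Fisher on 6/24 splits is conservative); the acceptance script reports
  both numbers, and fixed thresholds should be preferred whenever one is
  defensible a priori.
* **recover_table** — exhaustive enumeration of integer 2×2 tables whose
  four descriptors round to given percentages, optionally constrained by
  total or diseased count.  An empty result is itself an audit finding:
  the published total-rotation row (29/92/83/59) matches no integer table
  at any n ≤ 120 — its sensitivity, PPV and specificity jointly force an
  NPV near 48 — and the KT row (56/95/83/83) admits no 6-positive table
  but exactly one 30-limb table with 9 positives (tp=5, fp=1, fn=4,
  tn=20).  The per-criterion denominators behind those rows are evidently
  not the 6/24 split; the package audits, and does not resolve, that
  discrepancy.
* **Group comparisons** — paired t within subject; Welch t between groups
  (small, unequal arms); both verified against textbook closed forms.
  Pointwise curve comparisons interpolate each limb's branch angle onto a
  common torque grid (registration by torque, the protocol's controlled
  variable; limbs not covering the grid are excluded with a warning) and
  test each grid point, uncorrected by default with a Bonferroni option.
  JPE is computed limb-wise (rotation and KT of the same limb); when two
  examiner columns are present the KT value is their mean
  (`examiner_policy="first"` switches).
* **VAS grouping** — ≥ 80 → Group 1; (50, 80) → Group 2; < 50 → Group 3.
  Exactly 50 falls in the gap left by the strict inequalities and goes to
  Group 3 (the gap closes downward, since Group 2's lower bound is
  strict); configurable via `vas50_group`.

## Pipeline reproducibility

A master seed spawns independent per-stage substreams
(`numpy.random.SeedSequence`), so disabling a late stage cannot perturb
earlier randomness.  Every CSV carries the seed and a hash of the
scientific configuration (output location and stage toggles excluded) in a
comment line; reruns under the same configuration are byte-identical, and
the acceptance script verifies this end to end.  Figures are always
rendered from the written CSVs, never from in-memory state.

## Numerical choices

* Root-finding: bracketed safeguarded Newton for the per-direction scale
  (tolerance 1e-13 relative), Brent for the hysteresis offset (1e-12),
  fixed-point outer loops to 1e-10 with divergence guards that convert
  pathological targets into clean `InfeasibleTargetError`s.
* `expm1`/`log1p` throughout, so the near-linear (β → 0) limit needs no
  special casing; the LS window factor switches to its series
  `e^{−u/2}(1 + u²/40)` below u = 1e-3 to avoid cancellation.
* Recordings place the reversal sample exactly at the closed-form
  excursion, so extracted extremes are exact and interpolation error is
  the only discretisation term (O(step²), bounded by 2·step in the
  acceptance checks).

## Problem sizes

Defaults keep everything desk-scale: the study-shaped cohort (17 subjects,
34 limbs, ~1500 samples per recording) generates in under a second; the
effect-recovery study uses 20 seeded cohorts at 200 subjects per arm
(~1 minute); the type-I study uses 400 label permutations at a fixed
threshold plus 200 with threshold search; the Fisher oracle sweep covers
all 10,626 tables with n ≤ 20.

## Known limitations

* The generative model is phenomenological; its parameters are not tissue
  properties, and inverse-designed limbs inherit whatever is unrealistic
  in the target means.
* Threshold search reports no confidence intervals and, as measured, has a
  substantially inflated type-I error; it is an exploratory device.
* The KT force–translation relationship is a monotone fraction model, not
  a compliance curve; only the manual-max value feeds the JPE.
* Pointwise curve tests are uncorrected by default and grid-dependent;
  registration requires all limbs to cover the grid, which trims the
  usable torque range to the cohort's common span.
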