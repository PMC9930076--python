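# Methods

`prokin` implements a reproducible version of the movement-analysis and
group-statistics workflow used to compare a multi-grip myoelectric hand
prosthesis (MHP) with a standard single-grip myoelectric hand (SHP) in
upper-limb prosthesis users. Users perform three timed functional tasks —
the refined clothespin relocation test upward and downward (RCRT up/down,
5 trials each) and a bimanual tray task (10 trials) — once with each hand,
while 7 Euler joint angles (3 trunk, 3 shoulder, 1 elbow) are recorded at
60 Hz. Questionnaires are compared between two independent user groups.

## Trial processing

**Segmentation.** Movement onset and offset are detected from the two
humeral-elevation angles (shoulder flexion/extension and
abduction/adduction), since all three tasks begin by elevating the humerus.
Onset is the first sample whose absolute angular velocity (central
differences) exceeds a threshold (default 5 deg/s) on either shoulder angle
and stays above it for a sustain window (default 100 ms); the onset is then
backtracked while the velocity remains above half the threshold. The
hysteresis backtrack matters with realistic noise: a transient dip in the
noisy velocity just after the true onset would otherwise restart the sustain
counter and bias the detected onset late. Dual-threshold onset detection is
the standard remedy in movement analysis. Offset is the first sample after
the last suprathreshold movement at which *both* shoulder angles are back
within a tolerance (default 2 deg) of their pre-onset baseline, defined as
the mean over the first 0.5 s of the recording. When the angles never return
to baseline the offset is approximated from the externally measured trial
completion time; the summary records which source was used.

**Artifact screen.** Euler-angle recordings near gimbal lock show spurious
discontinuities. A trial is excluded when any joint series jumps more than
`max_step_deg` between adjacent samples (default 30 deg at 60 Hz) or leaves
the plausible range (default ±180 deg). The original study excluded such
trials by visual inspection; these quantitative defaults are declared
substitutes, and both are configurable.

**Time normalization.** The movement segment of every included trial is
resampled to exactly 500 samples with a cubic spline: original sample
indices in `[start, end]` (both endpoints included) are mapped affinely to
`[0, 1]` and the spline is evaluated at 500 equally spaced normalized
times. Segments shorter than 4 samples cannot support a cubic spline and
are rejected.

## Kinematic metrics

* **Range of motion (RoM):** per-trial max − min of the *raw* (unnormalized)
  segment for each joint, averaged over included trials.
* **Kinematic variability (KV):** at each of the 500 normalized time points,
  the across-trial sample SD (denominator M−1, chosen because trial counts
  are small, 5–10); KV is the mean of these SDs over time points. Degrees.
* **Kinematic repeatability (KR):** the adjusted coefficient of multiple
  determination across the M normalized trials. With Y_mt the angle of trial
  m at time t, Ȳ_t the across-trial mean at t, and Ȳ the grand mean,

      KR = 1 − [ Σ_mt (Y_mt − Ȳ_t)² / (T(M−1)) ] / [ Σ_mt (Y_mt − Ȳ)² / (TM−1) ]

  KR ≤ 1, equals 1 exactly when all within-trial deviations vanish, and can
  be negative for waveforms less repeatable than noise; negative values are
  reported unclamped. A waveform set with zero total variance has no defined
  KR and is reported as NaN (degenerate).

KV and KR require at least 2 included trials; with a single trial the
summary reports RoM and completion time and flags KV/KR as unavailable.
Completion-time SD across trials uses denominator n−1.

## Coordination-pattern classification

Participants differ in how they orient the hand during the clothespin task:
most pair shoulder external rotation with abduction in both conditions
(JC_SIM, "joint coordination similar"), but some flip to internal rotation
with adduction when using the multi-grip hand (JC_DIFF). The qualitative
grouping is made reproducible by a signed-excursion rule: for each condition
the time-averaged deviation from each trial's initial value, averaged over
RCRT trials, is computed for shoulder internal(+)/external(−) rotation and
abduction(+)/adduction(−). A participant is JC_DIFF iff *both* excursion
signs differ between conditions; excursions within ±1 deg of zero are
indeterminate and resolve conservatively to JC_SIM. The assessment stores
the underlying excursions for audit.

## Statistics battery

All conventions match SPSS defaults so that results are comparable with the
published tables; the significance level is α = 0.01 throughout (a guard
against the large number of tests).

* **Normality routing:** Shapiro–Wilk at α = 0.05 is the routing authority;
  a Lilliefors-corrected Kolmogorov–Smirnov statistic is reported alongside
  for audit (SPSS prints the Lilliefors correction).
* **Paired t** (within-participant condition comparisons), effect size
  r = √(t²/(t²+df)) carrying the sign of t.
* **Unpaired t**, routed by Levene's test (center = mean, α = 0.05) to the
  pooled (df = n₁+n₂−2) or Welch (Welch–Satterthwaite df) variant; also
  available directly from printed group means ± SDs and sizes.
* **Mann–Whitney U:** U is reported under the smaller-group convention; z
  uses the normal approximation with the tie correction in the variance and
  *no* continuity correction (SPSS behavior); effect size r = z/√N with
  N = n₁+n₂. The z/√N convention is not universal, but it reproduces the
  published effect sizes (e.g. z = −3.7, N = 33 → r = −0.6).
* **Chi-squared:** Pearson without Yates correction by default (a Yates
  option exists); Cramér's V = √(χ²/(N·(min(r,c)−1))) with df-specific
  label thresholds.
* **Repeated-measures ANOVA (2 × 7, fully within):** complete two-way
  within-subject SS decomposition (subject; hand; joint; hand×joint; and the
  three subject-interaction error terms). Mauchly's W is computed per within
  effect with more than 2 levels from the orthonormal-contrast covariance;
  Greenhouse–Geisser ε = tr(S)²/(d·tr(S²)) corrects the dfs when Mauchly
  rejects at α = 0.05 (ε = 1 for the 2-level hand factor). Generalized
  η²_G = SS_effect / (SS_effect + SS_subject + Σ error SS), the
  fully-within form. The implementation is validated in the test suite
  against `pingouin`'s two-way rm_anova (F, ε, η²_G), and against the
  algebraic identity F_hand = (paired t)² on joint-averaged values.
* **Effect-size labels:** r 0.1/0.3/0.5, η²_G 0.02/0.13/0.26, V (df = 1)
  0.1/0.3/0.5, V (df = 3) 0.06/0.17/0.29. The published thresholds use
  strict inequalities that leave boundary values undefined; here a boundary
  value is assigned to the higher category.
* **Rounding:** presentation tables round statistics to 1 decimal, p to 2,
  effect sizes to 1, matching the published tables; a full-precision twin of
  every report is always written.

Degenerate inputs (zero-variance differences, constant pooled samples, zero
table margins) raise explicit errors rather than returning numbers, except
the RM-ANOVA null construction where an effect's SS and its error SS are
both exactly zero (identical data across levels): there F = 0 and p = 1 are
reported, which is the correct description of "no effect, no information".

## Questionnaire scoring

Sum scores (OPUS-UEFS 0–57; TAPES-upper subscales 9–45, 3–15, 4–20, 5–25,
2–10) and mean scores (D-QUEST device/service/total on 1–5) are computed
directly. RAND-36 subscales are min–max transformed to 0–100 via a shipped,
editable scoring-key CSV (item membership, level counts, reversal flags) —
the key ships with standard item counts and linear recodes and is meant to
be replaced/edited when a specific published recoding must be matched.
EQ-5D-5L utilities and PUF-ULP totals require external tables (the Dutch
tariff and the estimated item weights are not in the public summary): both
are pluggable CSV weight tables, validated only through range/boundary
behavior (full-health profile → tariff maximum; PUF-ULP total = weight sum
+ 12, spanning 0–12.1 with the study's endpoint sums). No numeric defaults
are invented for either. Missing items are never imputed; instruments raise
an explicit missing-item report (the study resolved missing data by phone
follow-up, so no imputation rule exists to copy).

## Synthetic data generator

The raw recordings are deposited externally, so the package ships a
generator that emulates the protocol's data shapes with known ground truth:

* **Waveforms:** each joint follows a smooth raised-cosine-edged plateau
  ("bell/trapezoid") profile with a signed per-joint peak amplitude (default
  45 deg shoulder flexion, −20 deg shoulder rotation i.e. external, +25 deg
  abduction, 50 deg elbow, 6–12 deg trunk), bracketed by 1 s of quiescent
  baseline padding. Real task waveforms are multiphasic; only their summary
  statistics matter downstream, so a smooth unimodal excursion is used and
  documented as a stand-in.
* **Completion times:** per condition and task, participant-level mean
  durations are drawn from the observed group statistics (MHP 23.8 ± 6.8,
  22.4 ± 8.8, 15.6 ± 3.8 s; SHP 16.3 ± 5.6, 17.7 ± 7.9, 14.5 ± 4.8 s for
  RCRT up/down and tray), with a shared "speed" trait (loading 0.7) so a
  participant's times correlate across conditions as they do in people.
  Within a participant, trial durations scatter with relative SD
  `time_warp_sd` (default 0.15). This split — between-participant scatter
  from the task-duration SDs, within-participant scatter from the warp —
  makes "all noise parameters zero" produce sample-identical trials.
* **Noise:** trial-to-trial amplitude scatter (relative SD 0.05) and smooth
  additive noise: white noise low-pass filtered at 6 Hz, rescaled to an
  exact sample SD (default 1 deg), tapered to zero over 0.3 s raised-cosine
  ramps at the segment edges so the padding stays quiescent and onset
  detection is well-posed. Because the additive noise is independent across
  trials with known SD, the KV estimator can be validated by parameter
  recovery (±10 % at 50 trials; in practice ≈3 %).
* **Coordination modes:** `JC_DIFF` flips the sign of the shoulder rotation
  and abduction excursions in the MHP condition only; `JC_SIM` leaves them
  alone.
* **Artifacts:** with probability `artifact_prob` per trial, one sample of
  one joint is displaced by `spike_magnitude_deg` (default 90 deg), a
  gimbal-lock-like single-sample spike. The artifact random draws are
  consumed unconditionally so that changing `artifact_prob` alters nothing
  else in the dataset.
* **Determinism:** all draws derive from one master seed through
  per-participant `SeedSequence` substreams; adding participants never
  perturbs earlier ones, and identical configs are byte-identical.

The generator does **not** emulate multiphasic task kinematics, EMG or
controller behavior, sensor-fusion drift, serially correlated day effects,
or real gimbal-lock geometry (spikes are injected, not produced by an
orientation model). Passing tests therefore demonstrate that the estimators
and the statistical machinery are correct and internally consistent under
controlled conditions, not that the published kinematic group values are
reproduced — those require the external recordings.

Questionnaire data are generated per group from declared distributions
(normal with mean/SD, or ordinal with level probabilities), resampled up to
100 times into the declared valid range and then clipped; the default
two-group spec mirrors the study's observed group statistics (n = 14 vs 19;
age 48.6 ± 12.4 vs 58.1 ± 15.7, etc.).

## Problem sizes and numerical choices

The default end-to-end run uses 14 participants × 2 conditions × 20 trials
× 7 joints (560 trials), which completes in a few seconds; tests use 1–10
participants and 2–50 trials per set depending on what they probe. Cubic
splines come from `scipy.interpolate.CubicSpline` (natural not-a-knot
boundaries); Mauchly's test is skipped (reported NaN, ε still computed and
usable) when the contrast covariance is singular (fewer subjects than
contrast variables + 1). The sphericity χ² approximation uses the standard
Box correction factor. Seeds derived from a master seed stay below 2³¹.

## Known limitations

* Segmentation thresholds replace visual inspection; with other data they
  may need retuning (all are configurable in `RunConfig`).
* The Mann–Whitney normal approximation without continuity correction
  (chosen for comparability with SPSS) is least accurate for mid-range
  p-values at small n; the exact-enumeration comparison in the tests holds
  in the decision-relevant tail.
* t statistics recomputed from printed rounded summaries (1 decimal) can
  differ from statistics computed on raw data by ~0.1 when group-mean
  differences are small relative to the rounding grid.
* The shipped RAND-36 key uses linear recodes; published non-linear item
  recodings (e.g. for pain) should be supplied via a custom key when exact
  instrument semantics are required.
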