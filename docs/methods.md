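# Methods

## Scope and data model

The pipeline analyzes reach-to-grasp trials from a 2 (verb type: action AV /
interaction IV) × 3 (pronoun: I, YOU, HE) within-subject design. A trial holds
three marker trajectories (wrist, index, thumb) on a common uniform time grid;
time is expressed in ms with t = 0 at verb-stem onset (the isolation point of
the verb), so anticipation QC is a sign test on movement-onset time. Units are
fixed at mm and ms throughout, including in the long-format CSV dialect
(`subject_id, trial_id, pronoun, verb_type, verb, is_catch, marker, t_ms,
x_mm, y_mm, z_mm`; UTF-8, LF, '.' decimal). Datasets round-trip bit-exactly
(`float_precision="round_trip"` on read).

## Signal processing and segmentation

Positions are low-passed with a zero-phase (forward–backward) Butterworth
filter, default order 2, cutoff 10 Hz. The source protocols describe the
filter only as a linear smoothing low-pass; order-2 / 10 Hz is the
conventional choice for arm transport (signal content ≤ ~5 Hz) and all three
settings are configurable. Speed is the Euclidean norm of per-axis derivatives
(central differences in the interior, one-sided at the ends).

Two reach-segmentation variants mirror the two recording setups:

* **displacement rule** (optical, 60 Hz): onset = first frame whose
  frame-to-frame displacement exceeds 0.3 mm on all three Cartesian axes;
  offset = among the three per-axis candidates (first post-peak frame whose
  per-axis displacement drops below 0.3 mm), the one closest in time to the
  grasp end (ties broken toward the earlier frame);
* **velocity rule** (electromagnetic, 200 Hz): onset/offset = first/last frame
  with speed above 1 mm/s.

Grasp scoring uses the index–thumb distance: onset = first frame whose change
from the *initial* aperture exceeds 0.3 mm (physical finger markers never
approach 0.3 mm absolute separation, so the threshold is read as change from
baseline); offset = first post-maximum frame whose frame-to-frame change falls
below 0.3 mm.

Interpretation choices the protocols leave open (both configurable):
"displacement" is read as frame-to-frame motion rather than cumulative
excursion, because the same 0.3 mm figure also defines end-of-motion, which is
only meaningful instantaneously; a cumulative onset mode exists behind
`SegmentationConfig.onset_displacement_mode`. Velocity-peak ties break to the
first qualifying frame and no sub-frame interpolation is performed — every
reported time is frame-quantized at the recording rate, as in the source data.

Per-trial scoring failures (no qualifying onset, peak on a window boundary,
never-exceeded threshold) set flags and mark the trial rejectable; they never
raise, so one bad trial cannot abort an experiment-level run.

## Synthetic trials

Wrist transport follows a beta-family speed profile
`v(τ) ∝ τ^a (1−τ)^b` with `a/(a+b)` equal to the intended peak fraction and
`a + b = 4`, so the symmetric case is exactly the minimum-jerk profile
(`v(τ) = 30 (D/T) τ²(1−τ)²`, peak speed `1.875 D/T`). Positions come from the
regularized incomplete beta function, so the noiseless path length equals the
reach amplitude exactly. Transport runs along a fixed 3-D direction
(≈ (0.78, 0.47, 0.39)) — a dominant forward axis with lift/curve components
large enough that the all-axis onset rule has steep, well-conditioned
threshold crossings. Index and thumb sit at ± half the aperture from the wrist
along a fixed grip axis orthogonal to the transport, so the inter-marker
distance equals the aperture profile by construction.

The aperture opens and closes at constant speed (triangular profile with the
apex on the sampling grid) and finishes closing at the end of the transport
(fingers close on the object at contact). A smooth aperture bell would break
the grasp-end rule at 60 Hz: near a smooth 80 mm maximum the frame-to-frame
change falls below 0.3 mm immediately after the peak, ending the grasp there.
Real maximum-grip-aperture profiles are smoother than a triangle; the
segmentation thresholds, not realism, dictate this choice, and grasp
magnitudes should be read as synthetic conventions. The calibration values the
protocols never report are fixed as: baseline aperture 5 mm (pinch start),
maximal aperture 85 mm, grasp window equal to the reach window, aperture peak
at 66% of it (which puts the time to maximal aperture near 490 ms for a 740 ms
reach, in the range reported qualitatively for these tasks).

### Realizing targets on the frame grid

Extracted windows are integer frame counts, so a single 60 Hz trial cannot
realize e.g. 742.6 ms / 49.4% exactly. Two mechanisms make the *extracted*
parameters land on the configured values:

1. **Quantization with error diffusion.** Each trial's (duration, % latency)
   target is snapped to the nearest feasible (frames, peak-frame) pair and the
   residual is carried to the next trial of the same (subject, cell), so cell
   means converge to the configured values far below one frame. Catch trials
   keep separate ledgers: they are excluded from analysis and must not consume
   critical-trial residuals.
2. **Pipeline calibration.** For each realized integer pair, the continuous
   support length, profile peak position and sub-frame grid phase are iterated
   against the actual filter + segmentation pipeline (noiseless) until
   detection returns exactly that pair; the result is cached per integer key.
   This compensates the inward bias of the threshold rules (~2–4 frames at
   60 Hz, more under the velocity rule). Among exact solutions the calibration
   maximizes the distance of every threshold crossing from its threshold —
   including the first post-apex aperture step and the reach-end candidate
   crossing — so that sensor noise rarely shifts detection by a frame; the
   reach-end tie-break is calibrated in the same regime as real trials (grasp
   end a few frames after the transport stop, i.e. beyond every per-axis
   candidate).

Reaction time is a constant-plus-Gaussian offset (default 300 ± 50 ms),
snapped to the frame grid at the calibrated phase. Catch trials are generated
with identical motion (the recorded participants still reached; only the
click differed) and flagged; linguistic errors and anticipations are planted
at configurable rates because wrong click decisions cannot be recomputed from
kinematics.

### Presets and noise

Two presets ship: `exp1_italian` (60 Hz, 330 mm reach, 12 subjects, 30
critical + 10 catch trials, Italian verb table) and `exp2_german` (200 Hz,
350 mm, 16 subjects, 84 critical + 16 catch, German verb table), each carrying
the corresponding per-cell calibration means for reach time and % time to
velocity peak. Noise defaults:

| source | exp1 | exp2 | unit |
| --- | --- | --- | --- |
| trial-level SD, % latency | 2.0 | 2.0 | pp |
| trial-level SD, reach/grasp time | 30 | 30 | ms |
| between-subject SD, % latency | 1.5 | 1.5 | pp |
| between-subject SD, times | 20 | 20 | ms |
| marker position noise | 0.1 | 0.005 | mm RMS |
| linguistic error / anticipation rate | 0.01 / 0.005 | 0.06 / 0.02 | — |

Position noise is bounded by rule feasibility: the >1 mm/s velocity rule at
200 Hz needs a post-filter velocity noise floor well below the threshold
(0.02 mm jitter already yields ≈ 1 mm/s velocity noise), and the 92% valid
rate reported for that setup implies such a floor; the preset therefore keeps
sensor noise small and produces rejections through the planted error rates.
Subject offsets are additive per parameter (no subject-by-condition random
slopes), so the preset injects the calibration cell means as fixed truth:
simulated interaction effect sizes are larger than in real data. Passing tests
on these presets demonstrates pipeline correctness and parameter recovery,
not realism of effect-size magnitudes.

Known noise limitation: the grasp-onset rule (change from initial aperture
> 0.3 mm) is fragile under marker noise — at 0.1 mm RMS roughly a quarter of
trials trigger early, inflating grasp time. This reproduces a fragility of the
rule itself; reach parameters and the grasp *end* (which feeds the reach-end
tie-break) are unaffected.

All randomness flows from one seed through a `SeedSequence` hierarchy
(experiment → subject → trial), so identical (config, seed) yields a
byte-identical dataset after serialization.

## QC

A trial is valid iff it is a critical trial with no linguistic error, no
anticipated movement (reach onset before verb-stem onset, t < 0), and
successful segmentation. Participants with *less than* 50% valid critical
trials are excluded; exactly 50% is retained (the rule is strict-less). The
exclusion report lists each subject's `n_critical`, `n_valid`, fraction and
decision.

## Inference

`condition_means` averages each parameter per subject × cell over valid
critical trials; subjects with an empty cell are dropped with a report entry.

`rm_anova` computes the classical fully-within decomposition: each effect's SS
from marginal means, tested against its subject-by-effect interaction stratum;
F, exact p from the F distribution, MSE, and
`η_p² = SS_eff/(SS_eff + SS_err) = F·df1/(F·df1 + df2)`. No sphericity
correction by default (uncorrected df are the convention the reported values
follow); Greenhouse–Geisser is available behind a flag. The implementation is
validated against an explicit loop-based sums-of-squares oracle (1e-10) and
against `statsmodels.stats.anova.AnovaRM`.

`planned_ttests` runs paired t-tests of AV vs IV within each pronoun,
one-sided in the predicted direction by default (interaction verbs reach the
velocity peak earlier, so AV > IV on % latency). One-sided defaults follow the
convention under which the reported pairs (t(11)=2.81 → p=0.008; 1.84 → 0.05;
0.56 → 0.3) are consistent — note those p-values are one-sided in the
*observed* direction, which for the I pronoun is opposite to the motor-chain
prediction; sidedness is configurable rather than silently resolved.
Zero-variance differences return a flagged degenerate result (t = 0, one-sided
p = 0.5 when all differences vanish) instead of NaN. The corrected alpha is
α/k by default; a `paper` preset fixes 0.01.

`jzs_bf_anova` computes a default-prior Bayes factor for the full model
(verb + pronoun + interaction + subject) against the subject-only null. Each
effect block gets orthonormal sum-to-zero contrasts and its own g parameter
with the Jeffreys–Zellner–Siow prior g ~ r²/χ²₁ (scales r = 1/2 for fixed
blocks, r = 1 for the subject block — the conventional defaults). Conditional
on g the marginal likelihood has the closed g-prior form (Jeffreys prior on
intercept and σ²); the g integrals are estimated by seeded Monte Carlo
(default 20 000 draws), vectorized over draws with batched Cholesky
factorizations. `BF01 = 1/BF10` by construction and `mc_error` is the
delta-method standard error of BF10 from the two integrals' relative Monte
Carlo errors; the integrand is bounded in g, so the estimator has finite
variance despite the heavy-tailed prior. Quadrature is deliberately avoided:
the dimension grows with the number of blocks, and only default-prior behavior
is required. A 1-D quadrature of the closed-form single-block integrand serves
as the numerical cross-check in the tests, alongside behavioral checks
(null simulations give median BF10 < 1, injected-interaction simulations
median BF10 > 1, and the error shrinks as draws grow).

## Numerical and reporting conventions

Report tables round means half-up to one decimal; the summary table lays
parameters out as rows against the six cells (I/You/He × Action/Interaction).
Filter application requires series longer than the filtfilt padding (9 samples
at order 2); the filter cutoff must sit below Nyquist and is validated before
any simulation in pipeline runs. The run manifest records config, seed and
package version only (no timestamps), so identical manifests imply
byte-identical bundles.

## Problem sizes

The test suite and the acceptance script use the study-scale design (12
subjects × 5 trials/cell at 60 Hz) and 200 simulation replicates for recovery
studies; inference-layer calibration properties (type-I rate, Bayes-factor
direction) simulate 500 and 100 experiments at the subject-by-cell means
level, the level the inference consumes. These sizes give standard errors
comfortably below the quantities being checked (e.g. ~0.04 pp on a recovered
% latency cell mean).

## Known limitations

* Grasp magnitudes (aperture, baseline) are synthetic conventions; no
  empirical aperture norms exist in the calibration source.
* No subject-by-condition random slopes: recovery and power checks on the
  presets say nothing about mixed-effects generalization.
* The anticipation criterion (onset < stem onset) is an operationalization;
  the source protocols never define "anticipated movement" quantitatively.
* The velocity-rule variant analyzes the wrist only (by design); grasp
  parameters are absent from 200 Hz outputs.
* Under marker noise the grasp onset fires early on a fraction of trials
  (see above); grasp-time statistics from noisy synthetic runs inherit that
  inflation.
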