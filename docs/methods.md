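# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `hemigait`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. Synthetic treadmill gait (`synthgait`)

### Kinematic construction

One participant-speed trial is generated in a lab frame with +X anterior,
+Y left, +Z up, the body stationary over the belt. Per limb:

- **Fore-aft malleolus trajectory.** During stance (duration s·T for stance
  fraction s and stride time T) the malleolus translates rearward at the
  belt speed v; during swing it advances with a half-sinusoid velocity
  profile that returns it to the foot-strike position. Foot strike and toe
  off are therefore exactly the anterior and posterior extrema of the
  trajectory, at known times. Left foot strikes fall at t₀ + kT, right foot
  strikes half a stride later.
- **Treadmill closure.** Stationarity over the belt ties the parameters
  together: step_length_left + step_length_right = v·T. `GaitParams` derives
  T from that identity (an explicitly inconsistent triple is rejected);
  asymmetric step lengths are realized by shifting the two limbs'
  foot-strike positions by ±(SL_L − SL_R)/4, which reproduces both step
  lengths exactly at the event frames.
- **Leg chain.** Thigh and shank (defaults 0.41 / 0.43 m) hang from a fixed
  hip. The knee-flexion profile is prescribed — zero in stance, a half-sine
  bump peaking at `knee_flexion_peak` in swing — and the hip angle is solved
  per frame (damped Newton, residual < 1e-8) so the chain's ankle matches
  the prescribed fore-aft trajectory. The greater-trochanter marker sits at
  the hip, the epicondyle at the knee, so the three-marker knee angle equals
  the prescribed flexion by construction (the lateral circumduction offset
  of the ankle perturbs the 3-D angle by < 0.1° at physiological
  amplitudes).
- **Trailing limb angle.** The fifth-metatarsal marker rides rigidly with
  the ankle; its fore-aft offset is solved once per limb so the vertical ↔
  (hip → MT5) angle at toe-off equals `tla_peak` exactly. Slow belts bound
  the realizable TLA (the ankle stays too far forward at toe-off); the
  geometric cap is computed and enforced, and cohort draws are clipped to
  it.
- **Circumduction and hip hiking.** The swing ankle gets a lateral half-sine
  excursion of amplitude `circumduction_amp`; the iliac-crest pair rotates
  in the frontal plane by a half-sine obliquity bump of amplitude
  `hip_hike_amp` during the ipsilateral swing (crest separation
  `pelvis_width`). Hip joints stay fixed — obliquity moves the crest markers
  only, a deliberate simplification that leaves the leg chain and therefore
  all other metrics untouched.
- **Noise** is i.i.d. Gaussian per marker, axis and frame (`noise_sd`,
  metres).

Ground truth records the exact event times and the closed-form metric
values: the three asymmetry indices follow from the step lengths and stance
fractions (single support of one limb equals the contralateral swing
duration (1 − s_c)·T; leading double support equals (s_c − ½)·T, which is
why stance fractions must exceed 0.5), and the four intralimb metrics equal
their parameters on the reference limb.

### What the generator does and does not emulate

It emulates: 100–150 Hz optical capture, 0.2–1.4 m/s belts, cyclic bilateral
stance/swing kinematics with independently controllable left-right
asymmetries, marker noise, and missing-marker spans (tests knock out the
iliac crests to exercise the missing-data path). It does **not** emulate:
soft-tissue artifact, stride-to-stride biological variability (within a
trial every stride is identical up to noise), double-bump knee flexion in
stance, pelvic translation, or foot-ground interaction. Passing the
recovery tests therefore demonstrates algorithmic correctness of the
pipeline, not robustness to every artifact of real capture data.

One structural artifact matters for testing: at each stance-swing boundary
the malleolus velocity jumps (belt constraint: constant −v in stance), so
the trajectory has a corner at every event. A zero-phase low-pass rounds
that corner and shifts the sampled extremum by ~2 frames, and even without
filtering the sampled extremum of a corner is biased half a frame toward
the flat (swing) side. Real trajectories have smooth velocity zero
crossings and neither bias. Consequently the exact-recovery sweeps (a) skip
the filter stage on noiseless data — the filter exists to reject noise — and
(b) draw stride and stance durations commensurate with the sampling grid
(`sample_params(grid_aligned=True)`), so the oracle comparison measures
correctness rather than sub-sample interpolation. Off-grid draws are kept
for the event-timing check, which asserts the one-frame tolerance.

### Cohort profiles

`GroupProfile` gives participant-level means and SDs at the self-selected
speed plus deterministic per-m/s slopes. The neurotypical defaults are
near-symmetric (SLA 0.02 ± 0.01, knee 58° ± 3°, hip hike 1.5° ± 0.7°,
circumduction 6 ± 3 mm, TLA 21° ± 2°). The hemiparetic profile is
heterogeneous: a latent severity factor (clipped normal, SD 0.45) co-varies
larger asymmetries, reduced knee flexion and TLA, and increased hip hiking
and circumduction, and drives a synthetic Lower-Extremity Fugl-Meyer score
(34 − 11.5·severity + noise, clipped to 0–34) — a linear plausibility map,
not a clinical claim, sufficient for the cluster-versus-Fugl-Meyer
contrast. Slope signs follow the directions reported for treadmill walking
(step-length-asymmetry and TLA deficits shrink with speed; temporal
asymmetries and hip hiking grow; knee flexion rises in both groups but less
post-stroke). No public dataset jointly provides these distributions, so
the numbers are plausibility-based and fixed; `well_separated_profiles`
additionally builds homogeneous groups at a requested pooled-SD separation
(optionally diverging with speed) for cluster-recovery experiments where
the structure must be known. Each participant draws from the substream
(seed, participant index), so excluding one participant leaves the rest
bit-identical.

## 2. Marker I/O (`markerio`)

TRC (OpenSim dialect) and long CSV are the native formats; both round-trip
missing samples as empty cells ↔ NaN and are exact to the written precision
(9 decimals, i.e. nanometres). C3D is feature-gated on the optional `ezc3d`
package. Axis maps are signed permutations (validated orthonormal), unit
conversion honours the file header (mm → m). Missing data are explicit NaNs
end to end and are never interpolated; metrics that need a missing marker
are flagged missing on the record rather than imputed. The bundled
`data/stroke_table1.csv` carries a 28-participant post-stroke demographics
table (sex, paretic side, age, device, LE Fugl-Meyer, four treadmill
speeds) used by the metadata-reader tests and the inclusion-rule check.

## 3. Preprocessing (`preprocess`)

Butterworth low-pass, default 6 Hz cutoff and 4th order, applied
forward-backward (`filtfilt`) for zero phase; odd-reflection padding of
max(3·order, fs/2) samples keeps edge transients inside the padding. Each
finite run of a series is filtered separately; NaN spans pass through
untouched. Analysis bins are half-open frame intervals — whole trial,
centred middle-n-seconds, or final-n-seconds — and a stride belongs to a bin
iff its initiating foot strike falls inside (start-inclusive).

## 4. Events (`events`)

Foot strikes are local maxima and toe offs local minima of the malleolus
fore-aft coordinate, found by `scipy.signal.find_peaks` with a minimum
prominence (default 0.02 m — above marker jitter, far below the smallest
stride excursion at 0.2 m/s) and a minimum inter-event interval (default
0.2 s). Alternation is enforced by keeping the more extreme of same-type
neighbours. The stride table derives stance/swing and, from contralateral
events, single-limb support (contralateral swing inside the ipsilateral
stance) and leading double support (own foot strike to contralateral toe
off); strides violating the physiological ordering are flagged and excluded
from averages but never silently dropped. stance + swing = stride holds
exactly by construction.

## 5. Metrics (`metrics`)

Choices made where the field uses several conventions, all config-exposed:

- **Asymmetry index** |p − n| / (p + n): bounded, unitless, limb-order
  invariant.
- **Step length** of limb L at its foot strike: fore-aft separation of L's
  malleolus ahead of the contralateral malleolus at that frame; negative
  values (step-to pattern) keep their magnitude.
- **TLA instant**: ipsilateral toe-off, the propulsion-relevant instant; a
  terminal-stance-peak variant would be a small extension.
- **Circumduction**: lateral-only (toward-midline excursion floors at zero)
  relative to the stride's mean stance-phase lateral position — the metric
  is a compensation magnitude, not a signed displacement.
- **Hip hiking**: frontal-plane obliquity of the inter-crest line,
  atan2(Δz, |Δy|), positive when the metric-side crest is higher; the
  reported value is the swing-phase peak minus a level reference, floored
  at zero. The default reference is the mean obliquity at the
  swing-bounding toe-off and foot-strike instants (double support, pelvis
  near level). A contralateral-mid-stance reference is implemented but not
  the default: in periodic gait the contralateral mid-stance coincides with
  the ipsilateral mid-swing — the very instant of the obliquity peak — so
  that reference subtracts the signal it should baseline.
- **Knee angle**: 180° minus the interior angle at the epicondyle between
  the thigh and shank marker vectors — a planar proxy forced by the
  five-marker set.

Missingness propagates per metric: a record with occluded iliac crests
keeps its six other metrics. Cohort inclusion requires the slowest listed
speed strictly above 0.20 m/s and a standing calibration.

## 6. Group statistics (`groupstats`)

The classical fit is REML for the random-intercept model, with the
likelihood profiled over the variance ratio τ²/σ² (1-D bounded search;
closed-form Woodbury algebra on per-participant sums, so fits take
milliseconds). Satterthwaite df per coefficient are computed as
2f²/(gᵀA g) with f the coefficient's variance as a function of (σ², τ²), g
its central-difference gradient, and A the inverse observed REML
information (central-difference Hessian). The implementation is verified
against `statsmodels` MixedLM (estimates) and R `lmerTest` (estimates, SEs,
df and p-values agree to ~1e-3 relative) in the test suite. A variance
ratio driven to the search boundary triggers a documented fall-back to
fixed-effects-only inference with a warning.

The robust estimator iterates Huber weights (ψ(z)/z, default tuning
c = 1.345) on both scaled residuals and predicted random intercepts around
weighted REML. Standardization uses robust MAD scales so an outlier cannot
inflate its own yardstick; weights are damped (averaged with the previous
iteration) to suppress limit cycles; convergence is a relative coefficient
change below 1e-8 (cap 200 iterations, warning on failure). At c = ∞ every
weight is one and the first pass reproduces the classical fit exactly.
Satterthwaite df for the robust path are borrowed from the classical fit on
the same design — a documented approximation; no exact robust recipe exists
for this estimator. Known property: the replicate-averaged displacement of
the robust coefficients caused by a single 10-residual-SD outlier is about
21% of the classical displacement — slightly above the naive ψ(10)/10 ≈ 13%
because the score normalization (1/E[ψ′] ≈ 1.22) and the cluster-level
absorption of the outlier into its participant's intercept both amplify the
bounded influence. This is a property of Huber weighting at c = 1.345 in a
random-intercept model, not an implementation defect; pure Huber M-
regression without cluster structure measures ≈ 17% on the same
construction.

## 7. Clustering pipeline (`clusterpipe`)

z-scoring uses sample SD (n − 1) and is done within each speed condition
separately; participants with any missing metric are excluded per
condition. k-means is Lloyd's with k-means++ starts, best of 25 restarts,
labels canonicalized by descending cluster size; k is chosen by mean
silhouette over k = 2..8 (ties toward smaller k). WSS/BSS follow the ANOVA
decomposition and are asserted against TSS. Variable importance is the
R-randomForest-style mean decrease in accuracy: per tree, OOB accuracy
minus OOB accuracy after permuting one predictor, averaged over trees; the
OOB sets are reconstructed from each tree's bootstrap seed. PCA (full SVD,
largest-loading-positive sign convention) is for visualization only.
Cross-condition cluster identity is resolved by assigning centroids
(Hungarian matching in scaled space), since k-means labels are arbitrary.
Clinical contrasts are two-sided Mann-Whitney U, exact when the combined
sample is ≤ 20 and tie-free, normal approximation with tie correction
otherwise — the exact/asymptotic switch matters at post-stroke subgroup
sizes.

## 8. Experiment sizes

The validation experiments (module `validation`, driven by the test suite
and `scripts/acceptance.py`) use: 100 noiseless trials spanning 0.2–1.4 m/s
for event timing; 50 draws (12 strides each) for metric recovery, plus a
30-draw sweep at 2 mm noise for graceful degradation; 400 simulated cohorts
(50 participants × 4 speeds) for coefficient coverage and 250 for type-I
calibration; 48 replicates for the outlier-displacement ratio; 20 cohort
seeds for cluster recovery; 20 seeds × 500 trees for the importance probe.
These sizes put Monte-Carlo error well below each criterion's margin while
keeping the whole suite in a few minutes on one core.

## 9. Limitations

- The synthetic cohort's metric distributions are plausibility-based; no
  claim is made that effect magnitudes match any clinical population, only
  that directions and relative structure do.
- Intralimb kinematics are computed for the paretic/right limb only, and
  the knee angle is a planar three-marker proxy, not a joint-coordinate-
  system angle.
- No kinetics, EMG, site/lab effects or random slopes; the mixed model is a
  random-intercept model by design.
- Gap handling is flag-and-exclude; no gap-filling is performed by default.
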