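# hemigait

Treadmill gait metrics, robust mixed-effects models, and k-means gait
phenotyping for hemiparetic versus neurotypical walking.

## The problem

After a stroke, walking typically becomes slower and asymmetric: the paretic
limb takes a different-length step, spends less time in single support, swings
with reduced knee flexion, and is often advanced by compensations such as hip
hiking and circumduction. Fast-walking training is a common intervention, but
whether walking faster actually moves a hemiparetic gait pattern *toward*
neurotypical gait — metric by metric, and as an overall pattern — is a
quantitative question. Answering it takes three ingredients, all implemented
here as a tested pipeline for motion-capture marker data:

1. **Marker trajectories → gait metrics.** From five bilateral markers
   (iliac crest, greater trochanter, lateral femoral epicondyle, lateral
   malleolus, fifth metatarsal), detect foot strike and toe off as the
   anterior/posterior extrema of the lateral-malleolus fore-aft trajectory
   (the standard kinematic definition for treadmill walking), segment
   strides, and compute seven metrics per participant-speed observation:

   | metric | definition |
   |---|---|
   | SLA | step-length asymmetry, \|p − n\| / (p + n) |
   | DLSTA | double-limb-support-time asymmetry (leading double support) |
   | SLSTA | single-limb-support-time asymmetry |
   | knee flexion | peak swing knee flexion (deg), 3-marker planar proxy |
   | TLA | trailing limb angle at toe-off (deg), vertical vs hip→MT5 line |
   | circumduction | peak lateral swing excursion of the malleolus (m) |
   | hip hiking | swing-phase pelvic-obliquity excursion (deg) |

   where p and n are the paretic and nonparetic limb (right limb for
   neurotypical participants); intralimb kinematics use the paretic/right
   limb only.

2. **Per-metric inference.** For each metric y, a robust linear
   mixed-effects model

   y_ij = β₀ + β_G·group_i + β_S·s̃_ij + β_GS·group_i·s̃_ij + u_i + ε_ij

   with grand-mean-centered speed s̃, group coded stroke = 1, a random
   intercept u_i per participant, Huber downweighting of residuals and
   predicted random intercepts (tuning constant 1.345), and Satterthwaite
   degrees of freedom for the fixed-effect tests (α = 0.05). β_G is the
   between-group difference at the average speed; β_GS says whether that
   difference grows or shrinks as the belt speeds up.

3. **Overall-gait-behavior phenotyping.** All seven metrics are z-scored
   within each speed condition and clustered with k-means (k chosen by the
   silhouette method); cluster structure is quantified by the within/between
   sum-of-squares decomposition (WSS + BSS = TSS), metric relevance by
   random-forest out-of-bag permutation importance (mean decrease in
   accuracy), clusters are visualized in PCA space, composition is compared
   across speed conditions, and the stroke participants of the two clusters
   are contrasted on Lower-Extremity Fugl-Meyer score and gait speed with
   Mann-Whitney U tests.

Because jointly-available clinical marker data are scarce, the package ships
a synthetic treadmill-gait generator (`hemigait.synthgait`) that produces
bilateral marker trajectories from a planar leg chain with *closed-form
ground truth* — exact event times and exact metric values — so every stage of
the pipeline is validated by parameter recovery rather than by eyeballing.

## Worked example

```python
from hemigait import synthgait, pipeline

params = synthgait.GaitParams(
    step_length_left=0.45, step_length_right=0.60,   # paretic-side shorter step
    stance_fraction_left=0.67, stance_fraction_right=0.60,
    knee_flexion_peak_left=40.0, hip_hike_amp_left=6.0,
    circumduction_amp_left=0.035, tla_peak_left=13.0,
    n_strides=10, noise_sd=0.0,
)
trial, truth = synthgait.generate_trial(params, group="stroke", paretic_side="left")
record = pipeline.process_trial(trial, apply_filter=False)
print(truth.true_metrics["sla"], record.sla)
```

prints `0.14285714285714282 0.13911183660843682`: the measured step-length
asymmetry recovers the generator's closed-form value
|0.45 − 0.60| / (0.45 + 0.60) = 0.1429 to the 100 Hz sampling resolution
(events here fall between samples; the recovery sweeps in the test suite
also verify exact agreement when events are grid-aligned). The full
analysis over a simulated cohort is driven by the numbered scripts:

```sh
python analysis/01_simulate_cohort.py     # cohort -> results/metrics.csv
python analysis/02_fit_group_models.py    # seven robust mixed models
python analysis/03_cluster_gait_behavior.py
```

On the default 48-participant cohort this prints, among other things,

```
  sla              group +0.047*  speed -0.020*  interaction -0.116*
  knee_flex_deg    group -14.147*  speed +12.245*  interaction -8.471*
  hip_hike_deg     group +3.753*  speed -0.699*  interaction +1.181*
...
self_selected: k=2, BSS=240.8, WSS=[24.6, 63.5], top metric: dlsta
Mann-Whitney le_fugl_meyer between stroke subgroups: U=95, p=0.0008
```

read as: at the average speed the stroke group has 0.047 more step-length
asymmetry and 14.1° less swing knee flexion; walking faster shrinks the SLA
gap (negative interaction) but widens the knee-flexion gap; the silhouette
method finds two gait-behavior clusters, and the stroke participants who
cluster with the neurotypical walkers have significantly higher (better)
Fugl-Meyer scores than those who do not.

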