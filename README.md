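# pitchchain

Kinetic-chain analysis of fastball pitching from 3-D motion capture: segment
kinematics, pelvis–trunk separation time, net elbow/shoulder moments and joint
power around maximal external rotation (MER), and clustered condition
contrasts — plus a synthetic pitching-trial generator so every stage can be
verified against known ground truth.

## Who this is for

Sports-biomechanics researchers studying the proximal-to-distal sequencing of
overhead throwing (the "summation of speed" chain): how the pelvis and trunk
generate and transfer rotational energy to the throwing arm, and what an
intervention at the pelvis–trunk link does to ball speed and to the mechanical
load on the elbow and shoulder. The package reduces per-pitch marker
trajectories to a tidy outcomes table and fits marginal condition effects that
respect the repeated-pitches-within-pitcher structure.

## What it computes

Given per-pitch marker trajectories (400 frames/s, metres, global frame with
+x right, +y along the throwing direction, +z up):

1. **Preprocessing** — occlusion gaps filled with a cubic polynomial through
   the neighbouring valid samples, then a zero-lag (forward–backward)
   Butterworth low-pass at 12.5 Hz.
2. **Segment frames** — ISB-convention local frames for pelvis, trunk, upper
   arm, forearm and hand (marker constructions in `docs/frames.md`).
3. **Angular velocity** — from the orientation matrices via the
   skew-symmetric matrix Ω = Ṙ Rᵀ; magnitude is the Euclidean norm ‖ω‖.
4. **Events** — peak instants refined by a second-order polynomial fit to 11
   samples around the discrete maximum; MER is the first frame at which the
   humerothoracic axial rotation (Y-X-Y decomposition) is maximal; separation
   time Δt = t_peak(trunk) − t_peak(pelvis), positive when the trunk peaks
   later.
5. **Inverse dynamics** — top-down (distal→proximal) Newton–Euler recursion
   from the free hand,

       F_p = m (a_com − g) + F_d
       M_p = I ω̇ + ω × (I ω) + (r_com − r_p) × F_p − (r_com − r_d) × F_d + M_d

   with segment inertial parameters from the de Leva-adjusted Zatsiorsky
   tables (longitudinal inertia set to zero). Joint power is
   P = M · (ω_distal − ω_proximal). Peak ‖M‖ and P are extracted in a window
   around MER (100 ms before to 50 ms after, configurable).
6. **Statistics** — per outcome, a GEE marginal model
   `outcome ~ 1 + condition` with pitchers as clusters, exchangeable working
   correlation and robust (sandwich) covariance; Wald 95% intervals; the
   Bonferroni–Holm step-down controls the familywise error within each
   outcome family.

## Worked example

```python
from pitchchain.synth import PitchProfile, generate_trial, generate_cohort, STUDY_SCALE_EFFECTS
from pitchchain.pipeline import compute_pitch_metrics
from pitchchain.stats import gee_fit

# one synthetic pitch with 32.7 ms pelvis-trunk separation and 0.5 mm noise
trial, truth = generate_trial(PitchProfile(sep_time_ms=32.7, noise_sigma=0.0005, seed=7))
row = compute_pitch_metrics(trial)
print(row["sep_time_ms"], row["peak_omega_pelvis_degs"])
# 32.4  671.0      (generated: 32.8 ms, 675.0 deg/s)

# an 11-pitcher cohort carrying a -12.4 ms impeded-condition shift
cohort = generate_cohort(effects=STUDY_SCALE_EFFECTS, seed=3)
print(gee_fit(cohort[["subject_id", "condition", "sep_time_ms"]], "sep_time_ms").summary())
```

```
GEE condition contrast — outcome: sep_time_ms
  clusters (pitchers): 11   pitches: 484
  working correlation (exchangeable): 0.210
  b0 (unimpeded mean): 22.11
  b1 (impeded − unimpeded): -14.98   robust SE: 3.98
  Wald 95% CI: (-22.78, -7.18)
  p (raw): 0.0001672
  EMM unimpeded: 22.11 [6.536, 37.69]
  EMM impeded: 7.134 [-6.347, 20.61]
```

The fitted contrast b1 ≈ −15.0 ms is this cohort draw's estimate of the
injected −12.4 ms effect (robust SE ≈ 4 ms); the estimated marginal means
(EMM) are the per-condition model means with their Wald intervals.

The same flow runs from a shell:

```sh
pitchchain all --out results/ --n-subjects 4 --pitches 4 --seed 1
```

which writes synthetic fixtures, `metrics.csv` (one row per qualified pitch),
`stats_summary.csv` / `emm_table.csv` (contrasts and marginal means),
`run.log` (per-trial qualification decisions) and `resolved_config.yaml`.

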