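# Methods

This note documents the models, numerical choices and limitations behind
`pitchchain`. It is written for someone who wants to reprocess their own
motion-capture pitching data or extend the analysis, and for reviewers who
want to know exactly what the tests demonstrate.

## Data model and conventions

A *trial* is one pitch: marker trajectories sampled at a common rate
(default 400 frames/s), in metres, in a global frame with +x to the
pitcher's right, +y along the throwing direction, +z up. Frames are
0-based; time is `frame / rate`; all index ranges are half-open. Left-handed
pitchers are mirrored across the global x-axis at ingestion so every
analysis runs in a right-handed throwing convention.

A pitch is *qualified* when every indispensable throwing-arm marker (ACR,
LEL, MEL, RS, US, MC3, HND2) is present and has no contiguous occlusion run
longer than `max_gap` frames (default 20 = 50 ms at 400 Hz; a run of exactly
`max_gap` still qualifies). Beyond that, cubic interpolation of a fast arm
is not trustworthy, and excluding such pitches mirrors standard practice.

## Preprocessing

**Gap filling.** Each interior occlusion run is filled with a cubic
polynomial through the two nearest valid samples on each side (four points
determine the cubic exactly; a least-squares cubic over a ±10-frame window
is the fallback when a side has fewer than two). Leading/trailing gaps are
not extrapolated — the trial must be trimmed. Filling is idempotent and
never touches valid samples.

**Filtering.** A zero-lag low-pass Butterworth: a second-order filter run
forward and backward (net order 4, zero phase), with the single-pass cutoff
raised by `(2^(1/2) − 1)^(−1/4)` so the −3 dB point of the cascade sits at
the nominal 12.5 Hz. This is the dominant convention in biomechanics when a
"fourth-order zero-lag" filter is specified without further detail; the
alternative reading (fourth-order per pass, net order 8) is available via
`FilterSpec(order_is_per_pass=True)`. Edge handling is odd-reflection
padding with `padlen = 3 × (order + 1)` samples. The filter is linear and
commutes with global translation; a symmetric pulse keeps its peak frame
exactly (verified by test).

## Segment frames and kinematics

Local frames follow the ISB convention (Y along the segment long axis
pointing proximally/superiorly, X anterior, Z right); the exact marker
constructions are listed in `docs/frames.md`. Joint centres are
deterministic marker constructions: glenohumeral centre = acromion marker
offset 7% of body height inferiorly along the trunk long axis; elbow centre
= epicondyle midpoint; wrist centre = styloid midpoint. Regression-based
joint-centre methods would be more accurate on real shoulders but are
deliberately out of scope — the constructions here are simple, documented
and exactly invertible, which is what the verification strategy needs.

Angular velocity comes from Ω = Ṙ Rᵀ with Ṙ by entry-wise central
differences (one-sided at the ends); Ω is antisymmetrised as (Ω − Ωᵀ)/2
before the vector is read off, suppressing numerical asymmetry. The
magnitude is the Euclidean norm. Central differencing biases a constant
rate Ω by a factor 1 − (Ωh)²/6 (h = sample period): at 400 Hz and
1000 deg/s that is 0.03% — negligible against marker noise, and the reason
closed-form checks in the tests sample densely when they assert 1e-6
agreement.

The humerothoracic axial-rotation angle uses the ISB shoulder Y-X-Y
sequence on R_trunkᵀ R_humerus; the third angle, unwrapped over time, is
reported with external rotation positive. Frames within 1e-3 rad of the
gimbal poles are flagged and interpolated from neighbours. MER is the first
frame (earliest, on exact ties) at which this angle attains its maximum.

**Peak refinement.** The discrete argmax of ‖ω‖ (searched between a
trunk-onset proxy — first frame with trunk ‖ω‖ > 50 deg/s — and 100 ms
after MER) is refined by a least-squares parabola over the 11 samples
centred on it; the vertex is accepted only if concave and within ±1 frame
of the discrete maximum, otherwise the discrete maximum is used and
flagged. Separation time is t_peak(trunk) − t_peak(pelvis) in ms, positive
for proximal-to-distal order.

## Inverse dynamics

Top-down Newton–Euler recursion from the free hand (zero distal load)
through wrist, elbow and shoulder, in the global frame, with the
proximal-on-distal sign convention. Inertial parameters are the de Leva
(1996) adjustment of the Zatsiorsky tables, male values, embedded as one
data table (`ZATSIORSKY_DELEVA_MALE`): segment mass as a fraction of body
mass, CoM position from the proximal end, and transverse radii of gyration.
The longitudinal moment of inertia is set to zero throughout — the
rotational term about each segment's long axis is treated as negligible, so
the local inertia tensor is diag(I_coronal, 0, I_sagittal).

CoM accelerations are double central differences of the (already filtered)
CoM positions — filtering precedes differentiation. The ball's mass is NOT
added to the hand by default, making the reported loads "arm-only"; a
`ball_mass_kg` config flag adds 0.145 kg at the hand CoM up to 10 ms after
MER for users who prefer a loaded-hand analysis.

Joint power is P = M · (ω_distal − ω_proximal). Peak ‖M‖ and peak P are the
maxima over [t_MER − 100 ms, t_MER + 50 ms] (clipped windows are flagged),
covering the late-cocking phase where arm loading peaks.

Verification rests on closed-form oracles (static arm: ‖M‖ = Σ mᵢ g dᵢ;
free fall: all loads zero; constant-rate rigid rotation: the gravity-only
closed form) and on an energy audit: with the arm driven only through the
shoulder, shoulder power equals d/dt(KE + PE) to 0.4% RMS; with distal
joints active, the sum of shoulder + elbow + wrist power balances the
energy rate to the same order.

## Statistics

Each outcome (ball speed mph, separation time ms, four segment peak angular
velocities deg/s, two peak net moments Nm, two peak joint powers W) is fit
with a GEE marginal model `outcome ~ 1 + condition`: identity link, Gaussian
working variance, exchangeable working correlation with the pitcher as
cluster, robust (sandwich) covariance. The unimpeded condition is the
reference, so b1 is the impeded effect; Wald 95% intervals use 1.96. The
sandwich covariance keeps the standard errors valid under non-normal
outcomes and misspecified correlation, which is the reason for choosing GEE
over a linear mixed model here.

Holm's step-down procedure is applied within two families: the primary
hypotheses (ball speed, separation time, two moments, two powers) and the
post-hoc segment angular-velocity family (pelvis, trunk, upper arm,
forearm), adjusted separately. When the exchangeable correlation parameter
is unidentifiable (no spare residual pairs, e.g. one observation pair per
cluster), the fit falls back to the independence working correlation; point
estimates remain consistent and the SEs stay cluster-robust.

**Small-cluster caveat.** Sandwich-based z-Wald inference is anticonservative
with few clusters. At the study scale (11 pitchers), the package's own
simulations measure per-test size ≈ 0.08 at nominal 0.05, Holm-family
type-I error ≈ 0.14–0.18, and 95% CI coverage ≈ 0.90; at 60 clusters size
and coverage are nominal. Small-sample corrections (bias-reduced sandwich,
t-with-G−1-df) are deliberately out of scope; users should read the
intervals at 11 clusters as approximate. The acceptance suite asserts the
nominal calibration values and therefore reports this as a failure by
design rather than hiding it.

## Synthetic data

The generator (`pitchchain.synth`) emulates the delivery phase of a
fastball as closed-form forward kinematics: pelvis and trunk rotate about
the global vertical axis with Gaussian angular-velocity pulses whose peak
times differ by the configurable separation time; the humerus carries a
Gaussian axial external-rotation bump peaking at the prescribed MER
instant; elbow extension and a wrist snap follow with later peak times.
Markers are rigidly attached to the segments, with the rest pose calibrated
through the analysis' own frame constructions so that noise-free recovery
is exact by construction. Gaussian marker noise (default studies use
0.5 mm) and intermittent occlusion runs can be injected; everything is
deterministic under a fixed seed.

Default pulse magnitudes are calibrated to the scales reported for elite
adolescent pitchers — pelvis peak ≈ 675 deg/s, trunk ≈ 1000 deg/s,
separation time ≈ 32.7 ms (impeded condition ≈ 20.3 ms), MER at 0.72 s of a
1.5 s trial. This is a calibration, not ground truth about any athlete. The
generator's ball speed is the hand-marker speed at a fixed release offset
(10 ms after MER) plus radar noise; with the default arm geometry this is
an order of magnitude below real fastball speeds — the trial-level
generator is built for kinematic/kinetic closure, not for matching absolute
ball speeds.

For the statistics stage, a separate outcome-level cohort generator draws
subject means Normal(grand mean, between-SD) and pitch outcomes
Normal(subject mean + condition shift, within-SD). Grand means and SDs are
calibrated from the printed summary statistics of the taped-impediment
experiment this analysis is designed around (e.g. ball speed 76.6 mph,
between-SD 2.6, within-SD 2.0); `STUDY_SCALE_EFFECTS` carries the reported
condition shifts (−0.6 mph, −12.4 ms, +45 deg/s pelvis, small
non-significant load decreases).

**What passing tests do and do not show.** The synthetic chain has rigid
segments, exact marker attachment, Gaussian noise and no soft-tissue
artifact, no stride or ground contact, and joint axes that match the frame
constructions exactly. Passing closure tests therefore demonstrates that
the pipeline inverts its own forward model correctly and degrades
gracefully with noise — not that it removes the systematic errors real
skin-mounted markers carry. The statistics simulations share the Gaussian
hierarchical form of the cohort generator; real outcome distributions
(which motivated the robust covariance in the first place) may be heavier
tailed.

## Problem sizes used in the checks

Single-trial checks run on 1.5 s trials (600 frames) at 400 Hz. The
statistics calibration uses 500 replicate cohorts of 11 pitchers × 22
pitches per condition (the study scale); asymptotic-validity checks use 60
clusters at 150 replicates; contrast-reproduction averages 24 replicate
cohorts. These sizes keep the full verification suite in the low minutes on
one CPU while holding Monte-Carlo error near one percentage point.

## Known limitations

- Joint centres are fixed marker offsets; no subject-specific calibration.
- No scapular kinematics; the humerothoracic Y-X-Y angle is the only joint
  angle computed.
- Inverse dynamics is arm-only and top-down; no ground-reaction path, no
  muscle or joint-contact forces, no segment power-flow decomposition.
- The C3D layer covers the Intel floating-point point-data variant only
  (which is also what it writes); integer-scaled or DEC/MIPS files are
  rejected rather than misread.
- Sandwich z-intervals are approximate below ~30 clusters (see above).
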