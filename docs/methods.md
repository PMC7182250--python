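# Methods

## The model

`cgmsens` re-implements the lower-limb kinematic chain of the
Conventional Gait Model (CGM, the "Plug-in-Gait" family) and uses it to
quantify how a misplacement of the lateral femoral epicondyle marker
(KNE) propagates into clinical joint angles.

The chain is hierarchical and top-down:

1. **Pelvis.** Origin at the mid-ASIS point; Y from RASI to LASI
   (pointing left), X anterior within the plane containing the mid-PSIS
   point, Z = X x Y up. All segment frames use this X-anterior /
   Y-left / Z-proximal column convention.
2. **Hip joint centres** from the Davis/Newington regression in pelvis
   coordinates: with leg length `LL` (mm), `C = 0.115 LL - 15.3`,
   ASIS-trochanter distance `0.1288 LL - 48.56`, theta = 0.5 rad,
   beta = 0.314 rad, half inter-ASIS distance `aa` and marker radius
   `r`:

       x = C cos(theta) sin(beta) - (d_at + r) cos(beta)
       y = +-(aa - C sin(theta))
       z = -C cos(theta) cos(beta) - (d_at + r) sin(beta)

3. **Chord joint centres.** The knee joint centre is the point `J` at
   distance `(knee width + marker diameter)/2` from KNE, inside the
   plane spanned by the HJC, KNE and the thigh wand marker, with a
   right angle at `J` between the directions to the HJC and to KNE. Of
   the two candidates, the CGM takes the one on the side of the
   HJC-KNE line *away* from the (lateral) wand - the anatomically
   medial solution. In closed form, with `u` the unit HJC-ward
   direction from the marker, `v` the in-plane normal pointing away
   from the wand, `d = |HJC - KNE|` and offset `o`:
   `J = KNE + (o^2/d) u + o sqrt(1 - o^2/d^2) v`. The ankle joint
   centre is the exact analogue (ANK marker, shank wand, knee centre
   as proximal point). The wand markers enter *only* through plane
   membership: displacing a wand within its coronal plane changes
   nothing, which is tested and exploited by the generator's jitter.
4. **Foot.** Longitudinal axis from TOE towards HEE, plane fixed by
   the ankle centre, origin at the ankle centre. The package uses the
   heel-toe axis for the static *and* the dynamic frames. This keeps
   the static offsets exactly zero for a neutral flat foot and - more
   importantly - keeps rotation about the foot long axis observable
   from markers, so all three ankle angles can be recovered from
   noise-free trials. (A dynamic axis through the ankle centre and
   TOE, as some CGM variants use, makes that degree of freedom
   marker-unobservable; it exists to guard against unreliable heel
   markers, a failure mode synthetic data does not have.)
5. **Angles.** Mobile Y-X'-Z'' Cardan decomposition of
   `R_prox^T R_dist`, sign-mapped per side and per joint so flexion
   (knee: flexion = the reversed sagittal sense), adduction and
   internal rotation are positive on both limbs. Dorsiflexion is
   referenced to the foot long axis + 90 deg; the static
   plantarflexion/rotation offsets are removed as a rotation
   composition (`A(t) A_static^-1`), which is exact, rather than by
   angle subtraction, which is not. Decompositions within 1e-6 rad of
   gimbal lock are flagged with a warning, not rejected: gait never
   approaches 90 deg adduction, but synthetic edge cases may.
6. **Cycles.** One gait cycle spans consecutive same-side
   foot-strikes; each angle series is linearly interpolated onto
   0-100 % at 1 % steps (101 samples); multi-cycle trials are averaged
   pointwise after normalization.

## The misplacement simulator

`KNE_misp = KNE_ori + E(eps, theta)` with
`E = eps (cos theta X_thigh + sin theta Z_thigh)`; theta = 0 is
anterior, 90 proximal, 180 posterior, 270 distal. The axes are the
*unperturbed* thigh's anatomical axes, recomputed per frame, so the
offset travels with the segment like a physically misplaced skin
marker and repeated perturbation with the same reference is additive.
The study grid is 8 directions x {5, 10, 15, 20, 30} mm = 40
misplacements.

By default the misplacement is applied to gait trials only and the
original static calibration is kept. The only calibration quantity a
KNE offset can reach is the foot offset pair; misplacing the marker in
the static trial too makes the static shank rotation cancel most of
the dynamic ankle-rotation deviation (stance-phase knee flexion is
close to the static pose), collapsing the ankle int-ext sensitivity by
a factor of ~4. The observed clinical sensitivities are consistent
with a calibration unaffected by the simulated error, so that is the
default; `apply_to_static=True` exposes the other convention.

## The deviation statistic

For each misplacement, every one of the nine angle curves is compared
with the reference run: `RMSD = sqrt(mean((Err_i - O_i)^2))` over the
101 cycle samples ("gait-cycle" records), plus a discrete parameter:
the per-cycle signed extremum (maximum flexion/adduction, maximum
*external* rotation), whose absolute change is root-mean-squared
across cycles ("peak" records). RMSDs are banded: < 2 deg optimal,
2-5 deg acceptable, > 5 deg too high for clinical interpretation.

The association layer expresses eps as a percentage of leg length
(knee width available as an alternative), pools records per angle and
direction, and reports Pearson r (two-sided p from the t transform;
Altman bands on |r|: poor <= 0.2 < fair <= 0.4 < moderate <= 0.6 <
good <= 0.8 < very good), and the OLS line `RMSD = m x + b` with x in
% leg length. `predict_deviation` evaluates that line for a given eps
and leg length and applies it as a +/- offset to the reference curve -
an offset model, which is adequate precisely for the angles whose
deviation the simulator shows to be offset-dominated (hip flexion and
rotation, knee flexion), not for the cross-talk-dominated knee
frontal plane.

## The synthetic generator

The generator inverts the model: segment-local marker positions are
placed so the analysis pipeline's own constructions return the
generating geometry exactly - ASIS markers realize the inter-ASIS
distance; KNE/ANK sit one chord offset lateral of the nominal joint
centres, perpendicular to the segment axis; wands sit on the lateral
lower third of their segment with seeded jitter confined to the
coronal plane; foot markers give a horizontal heel-toe axis in the
neutral pose. Driving the segments with known angle curves (hip ->
thigh, knee -> shank, ankle -> foot, each through the exact inverse
of the clinical-angle mapping) therefore guarantees that
`compute_kinematics(generate_trial(...))` recovers the input curves up
to time-normalization interpolation error; with the default cadence
(120 steps/min at 100 Hz, i.e. 100 frames per cycle aligned with the
1 % grid) the recovery is exact to ~1e-12 deg, and stays far below the
0.5 deg round-trip budget for any cadence.

Default study conditions: cohorts of 10 subjects, heights stepped
evenly over 1190-1875 mm (step ~76 mm); leg length 0.53 h, knee width
0.060 h, ankle width 0.039 h, inter-ASIS 0.145 h with +-2 % seeded
jitter (a stated convention for plausible child-to-adolescent bodies,
not an anthropometric authority); 100 Hz; 12.5 mm markers; three
cycles per gait trial in the CLI, two in the batch experiments (the
curves are periodic, so extra cycles add runtime, not information).
The "typical" profile is a low-order Fourier gait shape (hip flexion
30 -> -10 deg; double-bump knee flexion with stance peak ~18 deg,
trough ~5 deg at 40 %, swing peak ~59 deg at 72 %; ankle rocker);
"mild-crouch" adds +12 deg hip and +15 deg knee flexion offsets.

Marker noise is optional i.i.d. isotropic Gaussian per frame.
Soft-tissue artefact (correlated, task-dependent) is deliberately not
modelled, so passing noise tests says nothing about skin-motion
robustness on real data. Two further honesty notes on noise and
cohort effects:

* The foot frontal/transverse angles are read off a short lever - the
  ankle centre sits only ~25 mm off the heel-toe line on a child-sized
  foot - so their noise gain is ~2-3 deg per mm of marker noise, an
  order larger than the sagittal angles. Real pipelines low-pass
  filter trajectories before this step; this package does not.
* The sensitivity magnitudes depend on the wand lever arm. The +-8 mm
  placement jitter between subjects shifts them by ~+-7 %, which is
  comparable to the leg-length effect across the whole cohort range.
  Experiments that isolate stature (the size-effect and the held-out
  prediction checks) therefore use a matched design: one common
  placement template across the compared subjects. In real cohorts
  this confounder is absent because each subject is compared against
  their *own* reference processing.

## What the synthetic experiments reproduce

On a 700 mm-leg synthetic child at eps = 10 mm, the pipeline yields
(anterior-posterior direction, gait-cycle RMSD): hip int-ext rotation
~5.2 deg, knee flexion ~4.4 deg, ankle int-ext rotation ~4.0 deg, hip
flexion ~2.5 deg, knee ad-abduction ~2.1-2.5 deg (swing-concentrated
cross-talk), with hip angles identically zero under pure
proximal-distal misplacement (a pure along-axis displacement leaves
the chord plane, and hence the thigh orientation, unchanged - only
the knee-centre position slides) and knee int-ext rotation more
sensitive to proximal-distal than to anterior-posterior misplacement.
The AP/PD ratio is therefore infinite for hip rotation, ~6 for knee
flexion, and ~3 for ankle rotation; the ankle ratio cannot be pushed
much higher by any realistic geometry, because the proximal-distal
effect on the shank plane scales with sin(knee flexion) through the
same lever as the anterior-posterior effect.

RMSD grows linearly with eps in % leg length (pooled r > 0.97 for hip
flexion and rotation), smaller subjects deviate more at fixed eps, and
the fitted line predicts a held-out subject's hip-rotation RMSD at
10 mm to ~13 %.

## Numerical choices and degenerate inputs

* Chord: rejects offsets >= |P - M|, collinear wands (< 1e-9 relative
  in-plane component), and non-positive offsets; the offset -> 0 limit
  returns the marker itself.
* Frames are validated orthonormal to 1e-9 with det +1 at
  construction.
* Zero-magnitude perturbation takes the identical code path and
  yields bitwise-identical trials, so the zero-RMSD identity is exact,
  not approximate.
* Curves are constrained to (-180, 180] deg; cycle extraction requires
  at least two same-side foot-strikes; time normalization rejects
  cycles outside the trial.
* All randomness flows through explicit seeds
  (`numpy.random.default_rng`); every generator output is a pure
  function of (inputs, seed).

## Known limitations

* Kinetics, KAD and medial-marker CGM variants, upper body and pelvis
  progression angles are out of scope.
* Only the KNE marker is perturbed, in-plane; multi-marker and
  medial-lateral misplacements are not modelled.
* Trial exchange is CSV/JSON; motion-capture container formats are
  not read directly.
* The allometric cohort model is a convenience; it should not be used
  where real anthropometry is available.
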