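# Methods

This note documents the models, algorithms and numerical choices behind the
package, in the spirit of a statistical-software methods appendix: what is
computed, under which assumptions, and what the synthetic validation does and
does not establish.

## 1. Signal conditioning

**EMG envelopes.** Raw surface EMG (nominally 1925.925 Hz) is band-pass
filtered with a 4th-order Butterworth at 10–400 Hz, full-wave rectified, and
low-pass filtered with a 4th-order Butterworth at 20 Hz. Filtering is
zero-phase (forward–backward, effective 8th order) by default because
envelope timing feeds the waveform-level statistics; a causal variant is
available (`zero_phase=False`, CLI `--causal`). The low-pass can undershoot
slightly around sharp bursts, so the envelope is clamped at zero.
Normalization divides each muscle's envelope by that participant's maximum
envelope value across all successful perturbation trials; the normalization
set must contain successful trials only, and the set maximum maps to exactly
1. The maximum is taken from the *envelope* (not the raw rectified signal),
and no MVC normalization is provided.

**Electrode QC.** A channel passes if its quiet-baseline RMS is below 15 µV
and its SNR — `20·log10(RMS_contraction / RMS_baseline)` — exceeds 10 dB.
The rule is exactly this conjunction; both boundaries are strict.

**Perturbation onset.** The platform accelerometer (370.3704 Hz) is linearly
resampled to the EMG clock, thresholded at a configurable multiple (default
5×) of a robust baseline RMS (median-based; for noise-free synthetic
channels a fraction of the peak is used instead), suprathreshold samples are
grouped into bursts, and each onset is the time of peak |acceleration|
within its burst. For a sinusoidal displacement the acceleration extremum
falls a quarter period (negative lobe) or three quarters (positive lobe)
after motion start; the pipeline disambiguates by the sign of the
acceleration at the detected peak and subtracts the corresponding lead to
place the 1-s analysis window.

**Common time base.** All derived waveforms live on a 100-Hz base (the
kinematic rate), 101 samples across the 1-s perturbation window. Derived
quantities are computed over the full 5-s trial and only then windowed, so
filtering and differentiation never see window edges.

## 2. Mechanics

The body is an anthropometric three-segment frontal-plane model: a massless
foot on the plate (mass fraction 0.0145 of body mass, entering only the
vertical force balance), the stance shank+thigh as one rigid ankle-to-hip
link (fraction 0.1465, CoM at 55% of ankle–hip length, radius of gyration
0.30 of it), and the head–arms–trunk plus hanging swing leg lumped above the
hip (remainder; composite CoM 0.075 of stature above the hip — low because
the swing leg pulls it down — radius of gyration 0.25 of stature). +x is the
medial direction of the stance limb; "starting with a medial displacement"
therefore means an initial positive half-sine. Rotational inertias matter:
with point-mass links the hip wobble mode sits near 13 Hz, which 100-Hz
kinematics cannot support through double differentiation; with the segment
inertias it falls to ≈ 3.5 Hz.

* **CoM**: mass-weighted mean of the segment CoM channels.
* **XCoM**: `x + v/ω₀`, `ω₀ = √(g/l)` with `l` the model's whole-body CoM
  height above the ankle (≈ 0.53 of stature; configurable override).
  Velocity by central differences. As `ω₀ → ∞` (vanishing pendulum length)
  the XCoM collapses onto the CoM.
* **MoS**: `|XCoM − CoP|`, the base of support being the instantaneous CoP
  point. A signed variant (+ = XCoM medial of CoP) exists but default
  inference uses the absolute distance. The CoP is expressed in the
  platform-fixed frame by the force plate and shifted by the platform
  displacement into the lab frame before MoS.
* **Ankle torque**: bottom-up with the massless-foot assumption,
  `τ = F_z (CoP − x_ankle)`; quasi-static and dynamic solutions coincide.
  Positive = invertor (CoP medial of the ankle). Flight (`F_z ≤ 0`) is an
  error.
* **Hip torque**: Newton–Euler transport of the ankle solution across the
  single rigid stance-limb link. In the lean-positive sense,
  `τ_hip = τ_ankle − a₁F_{Ax} + (x₁−x_a)(F_z − m_f g) − (L₁−a₁)m₂ẍ₂ +
  (x_h−x₁)m₂g − J₁α₁`, with segment accelerations from double
  differentiation of the kinematic channels (a quasi-static option drops
  them). Reported with positive = adductor, the same mediolateral sign
  convention as the ankle. These conventions are the package's own; figure
  conventions in the literature vary and are rarely annotated numerically.

## 3. Co-contraction index

`CCI = (2/n) Σ min(ag, ant)/(ag + ant) × 100` over the windowed, normalized
envelope samples, for TA–PL and TA–SOL. The widely used printed form of this
index omits the 1/n factor, but a bare sum over a 101-sample window cannot
produce the familiar 50–70% range, so the mean form is implemented. Samples
where both envelopes are numerically zero (sum below 1e-12) carry no
information and are excluded. The index is symmetric, bounded in [0, 100],
equals 100 iff the envelopes coincide on every counted sample, and is
invariant to a common rescaling of both envelopes — but *not* to per-muscle
rescaling, which is exactly what per-muscle normalization does; a
metamorphic test documents this expected sensitivity.

## 4. Coupling

Zero-lag cross-correlation is operationalized as the Pearson correlation of
the two mean-removed windowed series (an unnormalized cross-covariance is
available behind a flag). The 101-sample window splits at 0.5 s into two
51-sample halves sharing the boundary sample. |r| is categorized strong
(≥ 0.5), moderate (≥ 0.3), weak otherwise, boundaries assigned upward.

## 5. Inference

**Scalar outcomes** (two CCIs, four coupling coefficients; block-1 value =
the single first-success trial, blocks 2–3 = mean of the first three
successes) go through a two-way mixed ANOVA — between factor group, within
factor session — via pingouin, with Greenhouse–Geisser correction applied
when Mauchly's test rejects sphericity (reported dfs are then ε-scaled),
partial eta squared per effect, and Bonferroni-adjusted pairwise session
contrasts within each group when the interaction is significant at α = 0.05.
No correction is applied across the six outcome families. Constant data
yields F = 0 for every effect by convention.

**Waveform outcomes** (MoS, ankle torque, hip torque) use a permutation 1D
repeated-measures ANOVA authored in this package: the classical
sums-of-squares F statistic is evaluated at each of the 101 nodes, and the
family-wise null distribution is that of the trace-wide maximum F under
label permutation — session labels permuted within participants for the
within effect and the interaction, group labels across participants for the
between effect. The identity permutation is always included, making the
test exact-level under exchangeability; with P permutations and
k = ⌊αP⌋, the critical F* is the (k+1)-th largest permuted maximum, so the
probability of any suprathreshold cluster under the null is exactly k/P.
Clusters are maximal suprathreshold runs; cluster p-values are upper-tail
fractions of the same max-F distribution (cluster-level, not set-level).
A permutation scheme was chosen over random-field-theory thresholds because
it is distribution-free while testing the same max-statistic geometry; a
null-simulation calibration (500 datasets) confirms the empirical
family-wise error rate sits at the nominal 5%.

The two-way design requires balance; `balance_design` trims the surplus
group (seeded-random or pinned choice) and `sensitivity_leave_one_out`
repeats the analysis for every possible exclusion, reporting cluster
intervals per replicate and their mean pairwise Jaccard overlap.

Pearson correlations relate CAIT scores to across-block mean CCIs within
the CAI group. Attempt counts are compared with a two-sided Mann–Whitney U
using the tie-corrected normal approximation; U is reported under the
smaller-of-the-two convention and Z without continuity correction, matching
common statistical-package output.

## 6. Synthetic-data generator

The generator is the package's ground-truth instrument: a linearized
two-link frontal-plane inverted pendulum (ankle→hip link, hip→HAT lump, the
segment parameters of §2) riding a translating platform, integrated by
fixed-step RK4 at 2000 Hz and emitted at the native channel rates (EMG
1925.925 Hz, plate 1 kHz, kinematics 100 Hz, accelerometer 370.3704 Hz).
Trials are 5 s: 2-s baseline, 1-s perturbation, 2-s recovery.

**Platform.** Displacement is the protocol sinusoid exactly
(A = 0.017 m, f = 1 Hz, first half-cycle medial). Its velocity steps at the
phase boundaries; a rigid body riding the base then receives an
angular-velocity impulse `Δw = −M⁻¹C·Δv̇`, which the integrator applies
exactly at the boundary steps rather than smoothing the profile.

**Control.** The ankle applies a PD law on the mediolateral XCoM error
(gain 1250 N·m per m, above the ≈ m·g stabilization threshold) and on the
body-relative CoM velocity (damping 320 N·m·s/m), passed through a 100-ms
first-order neuromuscular lag so the ankle torque — and hence the CoP,
back-computed as `CoP = x_platform − τ/F_z` via the massless-foot balance —
stays continuous across the velocity steps. The hip combines a passive
spring (250 N·m/rad on the inter-link angle), a reflexive damping pathway
(12 N·m·s/rad through a 30-ms lag), and an open-loop command described
below. Trials whose lean angle exceeds 0.6 rad are marked failed.

**Prescribed coupling.** Because the plant is linear, the emitted hip
torque and (to first order) the MoS are affine in the injected command. A
command-free reference pass yields the deterministic MoS template; per
analysis half-window the plant is probed with the smoothed template and its
derivative (supplying the phase lead the plant filters away), and the
window-restricted MoS shape is regressed onto the two torque responses.
Each trial then solves, window by window in causal order and with
fixed-point refinement of the predicted MoS, for template/noise
coefficients such that the total hip torque correlates with the trial's MoS
at the prescribed ρ with centred rms equal to the hip gain (9 N·m). The
prescription is accurate to ≈ 0.02 in the first window for ρ ≤ 0.6 and to
≈ 0.15 in the second (the command family cannot align further); prescribed
values above ≈ 0.6 saturate. ρ varies between participants (SD 0.08) and
trials (SD 0.12), matching the dispersion such studies report.

**Group/session structure (the study conditions).** Defaults encode:
22 CAI vs 23 HC participants (CAI CAIT scores integer 13–23, mean ≈ 17.6;
HC fixed at 30); a co-contraction floor c (the agonist-locked fraction of
TA activation) of 0.62 for HC declining 0.08 per session and 0.30 for CAI
with no decline plus 0.040 per CAIT point below 24 (which, combined with a
0.10 between-participant floor SD, yields a within-CAI CAIT–CCI
correlation near −0.6, the reliably-detectable neighbourhood of the
relation such cohorts report); MoS–hip coupling ρ of 0.30 rising 0.10
per session for CAI and 0.46 gently falling for HC; and an ankle damping
that declines 60 N·m·s/m per session in CAI only — empirically the dominant
MoS lever in this plant and the mechanism by which the CAI group's margin
of stability falls with practice, consistent with over-vigorous torque
responses being tuned down. Failure probabilities per attempt decline
steeply after the first block (CAI 0.60/0.22/0.18, HC 0.55/0.18/0.15),
matching higher first-block attempt counts alongside near-universal
completion within seven attempts in the practice blocks (about one
exclusion per 45-participant cohort).

**EMG synthesis.** Agonist activation (PL and SOL share one envelope) is a
tone (0.08) plus the positive half of the normalized ankle-torque demand
(reference 30 N·m); TA's own drive is the tone plus the negative half; the
emitted TA envelope is `c·agonist + (1−c)·TA_own`, so TA equals the
agonists exactly at c = 1 and shares nothing but the tone at c = 0.
Envelopes amplitude-modulate unit-RMS 20–450 Hz Gaussian carriers (the
amplifier bandwidth), scaled to 300 µV at unit activation, plus 5 µV RMS
baseline noise. The measured CCI also reflects burst overlap and
normalization, so floors are placed through the empirical floor→CCI map,
not the nominal 200c/(1+c).

**Determinism.** Every random element derives from `SimConfig.seed` plus
stable participant/session/attempt keys; identical inputs give bit-identical
trials.

**What the generator does not emulate.** No Hill-type muscle dynamics,
ligament laxity, 3D marker trajectories, realistic failed-trial kinematics
(failure is a Bernoulli flag), sagittal-plane dynamics, or inter-muscle
envelope differences between PL and SOL beyond carrier noise. Passing the
validation suite therefore demonstrates correctness of the *pipeline
computations* under known ground truth — not that the pipeline's outputs on
real data would be unbiased under marker noise, soft-tissue artifact or
model mismatch.

## 7. Validation scales and numerical choices

* Inverse-dynamics closure: recomputed ankle torque is exact by
  construction; hip torque matches the latent torque with batch RMSE ≈ 1%
  of the batch peak over a 50-trial batch (worst single trials ≈ 2%,
  dominated by the onset transient where double differentiation of the
  velocity-step kink is irreducibly lossy at 100 Hz).
* Permutation-SPM calibration: 500 null datasets × 500 permutations,
  12 participants per group, 101 nodes (≈ 30 s); empirical FWER within
  ±0.02 of the nominal 0.05.
* Parameter recovery: 25 full-cohort replicates at 300 permutations
  (≈ 7 min); each prescribed finding (CCI interaction, MoS–hip W1
  interaction with CAI rise, CAI MoS session decline, negative CAIT–CCI
  correlation) must recur in ≥ 80% of replicates.
* RK4 at 2000 Hz keeps integration error orders of magnitude below the
  closure tolerances; zero-variance nodes in the F computations are mapped
  to F = 0 via a magnitude-relative round-off floor (1e-22 of the data's
  sum of squares); envelope normalization rejects zero maxima; CCI skips
  zero-sum samples at 1e-12 of normalized units.
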