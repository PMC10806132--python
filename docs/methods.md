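# Methods

This note records the models behind `hybridgait`, the parameter choices
that matter, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want to know about.

## Orthosis model

The orthosis is a 1-DOF ankle mechanism driven by a ball screw through a
planar linkage: a triangle with fixed sides `l1` (ankle joint R1 to ball
nut R2) and `l2` (R1 to the screw-carrying joint R3), whose third side
follows from the nut travel `lscrew` and the moment arm `lR3`. The joint
angle is

    theta = arccos((l1² + l2² − lscrew² − lR3²) / (2 l1 l2)) + theta_P1.

The linkage lengths of a physical device are frame-specific; the defaults
(`l1 = 0.25 m`, `l2 = 0.06 m`, `lR3 = 0.03 m`, `theta_P1 = 0.35 rad`,
travel 0.20–0.30 m) were chosen once so that a ±30° ankle range maps
comfortably inside the screw travel of a 10 mm/2 mm-lead ball screw, and
are configurable. Angles live in the linkage frame internally; the
clinical dorsiflexion-positive convention is obtained by subtracting the
neutral-posture angle `π/2 + theta_P1`, and the single constant
`TORQUE_TO_ANGLE_SIGN = −1` bridges the plantar-flexion-positive torque
convention to dorsiflexion-positive angles.

The torque of the measured shank–cuff interaction force about the ankle is
resolved through the same triangle (two interior angles plus the prismatic
direction). Its implementation is validated against a coordinate-geometry
construction of the triangle angles rather than a second copy of the same
trigonometric identities.

### Control chain

The controller renders a spring–damper (`k_d`, `c_d`) around the reference
angle. The desired trajectory integrates the admittance model

    I θ̈_d = −(k_d e + c_d ė) + τ_ext,      e = θ_d − θ_ref,

and a PD loop (`K_P = 250`, `K_D = 8`, `I = 0.05 kg·m²`) tracks θ_d. Two
deliberate choices:

* **Error term.** The admittance uses `e = θ_d − θ_ref` so the equation is
  integrable on its own; using the measured angle instead is available via
  an argument (`theta_measured`), since either reading is defensible.
* **Integration.** Velocity-first (semi-implicit) Euler at 1 kHz, with the
  damping term handled implicitly (`v ← (v + dt·drive)/(1 + dt·c_d/I)`).
  The implicit damping matters because the rendered damping can reach
  `c_d ≈ 2ζk_d ≈ 200 Nm·s/rad` against `I = 0.05 kg·m²`, far beyond the
  explicit stability bound at 1 ms steps. The integrator conserves the
  equilibrium θ_d = θ_ref exactly and settles at the closed-form
  deflection τ_ext/k_d under constant load (verified to 1e−4 rad).

### Damping law

The damping setpoint `c_d = 2ζk_d` (damping as a stiffness scaling,
default mode `"literal"`) is kept as the coordination default. It has the
side effect of placing the admittance pole at `k_d/c_d = 1/(2ζ)` rad/s
independent of stiffness — about 0.7 rad/s at ζ = 0.7 — which makes the
desired trajectory lag a 2–3 s gait cycle severely. The dimensionally
consistent alternative `c_d = 2ζ√(I·k_d)` (`"critical"`) places the pair
of poles at `ω_n = √(k_d/I)` with damping ratio ζ and tracks gait-band
references faithfully; the closed-loop simulator therefore defaults to
`"critical"`, and both modes are selectable everywhere. ζ = 0.7 and the
stiffness band `k_min = 5`, `k_max = 150 Nm/rad` are package defaults.

## Gait events

Contact detection thresholds each foot-switch channel at 20 % of its
calibration-pass maximum with a ±10 % hysteresis band (one rising edge per
true contact on a chattering signal); heel contact is the OR of the two
heel channels. The gait cycle is heel strike to heel strike; cycle
duration is the median of the last three inter-strike intervals, which
tolerates a single mistimed strike. Walking speed comes from an affine
cadence map `v = slope/T` clamped to 1–5 km/h — the range over which the
reference profiles are defined — with `slope = 4.32 km·s/h` (a 1.44 s
cycle at 3 km/h), the same model the synthetic foot-switch generator uses.

## Reference inputs

**EMG envelopes.** Normalized TA and soleus activation profiles are stored
as order-6 Fourier series in gait phase at five speed nodes (1–5 km/h) and
linearly interpolated in speed. The packaged defaults are fitted from
analytic raised-cosine templates: soleus support centred at 42 % of the
cycle (propulsion in stance), TA support spanning late swing through early
stance (toe clearance and controlled lowering), with amplitude growing
with speed (0.45 → 0.91). `fit_envelope` refits the same representation
from user-sampled profiles (reconstruction RMSE ≤ 0.05 at order 6 on
smooth envelopes; a grid shorter than 2M+1 samples is rejected).

**Trajectory tables.** The reference angle is a periodic spline through
normative keypoints (range −10.4° to +12°). The reference torque is
generated by integrating a designed quasi-stiffness profile along that
angle trajectory, `τ′(φ) = k(φ)·θ′(φ)`, with a swing baseline of
12 Nm/rad and raised-cosine bumps at 30 % (loading response, 280 Nm/rad)
and 50 % (push-off, 380 Nm/rad scaled by a closure factor that zeroes the
net elastic work per cycle). Generating torque this way — rather than
splining torque independently — makes torque and angle reversals coincide,
so the stiffness recovered from the moment–angle slope is well defined
along the whole cycle and exhibits exactly the two stance peaks. The
slope computation itself is a centred finite difference along the cycle
with three guards: carry-over of the nearest defined slope where
`|dθ| < 1e−6 rad`, rectification to ≥ 0 (impedance control needs
nonnegative stiffness), and a 5-point moving average.

## EMG→torque regression

The regressor maps a 2-channel, 288-sample (≈0.29 s at 1 kHz) EMG window
to one torque value, plantar flexion positive. Architecture: three conv
stages (128 filters; kernels 13, 9, 6; max pools 6, 4, 2; stride 1; ReLU)
into an MLP of widths 129, 128, 128, 64, 1 — the first MLP width is an
independent layer width, not the flatten size (which is 256 at a
288-sample window). The Tanh output is scaled by τ_max = 60 Nm. Training:
Adam (lr 1e−3, batch 64), MSE loss, early stopping on validation loss
with patience 10; inputs are per-channel z-scored with training-split
statistics. The output layer is initialized small (0.1/√fan-in) so the
scaled Tanh starts near zero instead of saturated — with He-scaled output
weights the ±60 Nm output range swamps the loss landscape and training
stalls. Implementation is plain numpy (im2col convolutions, float32,
seeded `default_rng`), so seeded runs are bit-reproducible on one thread.

On the synthetic isometric dataset (n = 2000, seed 7, noise 0.5 Nm) the
network reaches a held-out RMSE ≈ 1.4 Nm, peak-magnitude agreement ≈ 96 %
and prediction–truth correlation ≈ 0.996; a ridge regression on
per-channel RMS features bounds the attainable error (≤ 1.5 Nm) and a
label-permutation control bounds it from below.

## Volitional-EMG extraction

Each FES pulse leaves a large artifact followed by an M-wave locked to the
pulse. The cascade: (1) blanking — 5 ms zero-order hold from each pulse
onset (must be shorter than the inter-pulse interval; 40 Hz stimulation
gives 25 ms); (2) comb filtering — consecutive inter-pulse segments
subtracted and halved, cancelling any pulse-stationary component exactly
(segments of unequal length are linearly resampled); (3) full-wave
rectification and a zero-phase (forward–backward) Butterworth low-pass,
order 4, 2 Hz cutoff. Rectification precedes the low-pass (standard
envelope practice — the 2 Hz filter then yields an amplitude envelope).

Two calibrations make the output an unbiased estimate of the volitional
RMS amplitude for interference-pattern (Gaussian) EMG: a gain of √π
(the comb halves the volitional variance: √2; rectification maps RMS to
mean by √(2/π)), and a per-segment duty-cycle factor compensating the
blanked fraction of each inter-pulse span, which otherwise biases the
envelope low by exactly that fraction (20 % at 5 ms/40 Hz). On an
M-wave-only stream the reconstructed envelope is < 2 % of the M-wave RMS;
on a gait-patterned volitional signal under 40 Hz stimulation the
envelope error is < 15 % RMS.

Volitional torque estimation embeds the two channel envelopes into a
2-channel window — each channel is a fixed, seeded unit-RMS broadband
carrier scaled by its envelope, so the window's channel RMS equals the
envelope — and applies the torque regressor.

## Coordination

FES amplitudes are proportional to the torque deficit the wearer leaves in
the direction of the reference torque, with the deficit fraction clamped
to [0, 1] so amplitudes respect the personalized [min, max] ⊂ [onset,
pain] band; the antagonist channel stays at its minimum (no
co-stimulation), and volitional torque in the antagonist direction does
not increase stimulation. The activation ratio compares magnitudes: when
the wearer meets or exceeds the demand, `r_v = max(|τ_ref|, |τ_v|)/τ_v,max`
clamped to [0, 1]; otherwise 0, so the gait is fully assisted. Desired
stiffness decreases linearly in `r_v` and is clamped to the band. Default
calibration: amplitudes 15–40 mA inside onset 10 mA / pain 50 mA,
`τ_ref,max± = 25 Nm` (matching the ±27 Nm range of the packaged
reference-EMG-derived torque), `τ_v,max = 40 Nm`.

## Closed-loop simulator

The plant is a torque balance on one ankle DOF (`I = 0.05 kg·m²`) with
passive viscoelasticity (3 Nm/rad, 0.4 Nm·s/rad), a phase-locked
dorsiflexing ground-reaction bump (20 Nm raised cosine over 10–55 % of
the cycle — the external moment the plantar flexors work against in
stance), linear FES recruitment `τ = 0.8 Nm/mA · max(0, A − 10 mA)` per
channel, and a participating wearer.

The wearer's effort has two faces, deliberately kept on different scales:

* an **EMG-visible volitional torque** `α·τ_ref,EMG(φ) + noise` on the
  isometric-equivalent scale of the torque model (τ_ref,EMG is the
  reference-envelope pair passed through the regressor, exactly what the
  coordinator uses as τ_ref) — this drives the synthetic EMG and is the
  ground truth the estimation chain should recover;
* a **mechanical torque**: the dynamically consistent feedforward
  `α·τ_ref,table(φ)` plus a tracking impedance `α·(60 Nm/rad, 1 Nm·s/rad)`
  toward the intended trajectory, standing in for stretch reflexes and
  short-latency corrections.

Isometrically calibrated EMG–torque models overestimate dynamic torque in
swing (high TA EMG, near-zero net moment); applying the EMG-scale torque
mechanically would over-drive the low-inertia joint. Splitting the scales
keeps the estimation chain realistic and the dynamics physical.
The volitional noise (0.8 Nm band-limited at full participation, scaled
by α) represents trial-to-trial motor variability.

Per control step (1 ms): foot-switch frame → contact detection → phase
(nominal-cadence playback before the second heel strike, which is why the
first cycle is discarded); reference lookups at the estimated phase; in
PFV mode, per-pulse (40 Hz) streaming blanking/comb/envelope with a
causal one-pole 2 Hz smoother and a torque-model call; coordination;
admittance + PD; plant integration (semi-implicit Euler, divergence
guard at |θ| > 10 rad). In PF mode the wearer still acts on the plant but
the controller sets τ_v = 0 (r_v = 0; FES follows the reference profile).
The reference torque grid is computed once per run at the commanded
treadmill speed (one batched model call over the phase grid); per-cycle
speed re-estimation feeds the gait-status log.

Powers are torque × angular velocity in the angle-consistent frame.
Per-cycle **net energies** per source satisfy the additivity identity
(total = orthosis + FES + volitional, to machine precision);
**consumption** (the time integral of |power|) is the measure used for
mode comparisons, matching the energy-consumption reading of the
PF-vs-PFV claim — net work per cycle of a roughly periodic joint is
near-cancelling and statistically fragile. `compare_modes` reports
per-source means ± sd across matched runs and a paired two-sided t-test
on device consumption (identical inputs short-circuit to p = 1).

Problem sizes used by the tests and reproduction runs: 3–4 cycles per run
at 1.8 km/h (the treadmill speed of the validation protocol), 20 matched
seeds for the PF-vs-PFV comparison and 10 seeds per participation level
for the monotonicity sweep — enough for the paired test while keeping a
full suite run comfortably on one CPU.

## What the synthetic data emulate — and what they do not

The generators reproduce the *structure* the algorithms rely on:
amplitude-modulated band-limited (20–450 Hz) Gaussian EMG, pulse-locked
biphasic M-waves (15 ms, 0.1 mV/mA above onset) with one-sample 50 mV
artifacts, contact traces with configurable load windows, and an
isometric torque target that is an exact monotone function of channel RMS
difference (gain 30 Nm) plus Gaussian noise. They do not emulate motor
unit statistics, M-wave shape change under fatigue, electrode lift-off,
cross-talk between channels, or the nonlinear and history-dependent
recruitment of real stimulated muscle. Passing tests therefore certify
the signal path and the control logic under the stated models — not
clinical performance on recorded human data. The printed accuracy of the
original isometric human experiments is likewise not a target the
synthetic mapping can or should reproduce.

## Known limitations

* The plant is a single DOF with a phase-locked ground torque; there is no
  foot–ground contact model, no belt dynamics and no balance coupling.
* FES recruitment is linear with a hard onset and no fatigue dynamics.
* The causal in-loop envelope estimator trades accuracy for latency (one
  pulse interval + one-pole smoothing); the offline zero-phase cascade is
  the reference implementation.
* The cadence→speed map is affine; non-treadmill gait would need its own
  calibration.
* Checkpoints are written as `.npz` archives with the architecture
  embedded as JSON; no other serialization formats are supported.
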