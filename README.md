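# hybridgait

Coordination control for hybrid gait rehabilitation: a powered ankle–foot
orthosis (PAFO) working together with functional electrical stimulation
(FES) of the tibialis anterior (TA) and soleus, sharing the ankle torque
with whatever the wearer can contribute on their own.

Post-stroke foot drop is commonly treated with either a motorized ankle
orthosis or FES. Combining the two creates an actuation-redundancy problem:
motor, stimulated muscle and volitional muscle all act on one joint. This
package implements an assist-as-needed resolution of that redundancy and a
closed-loop synthetic gait simulator to study it, entirely from generated
data:

* **Orthosis model and control** — screw-driven linkage kinematics
  (`linkage`): joint angle from ball-nut travel, torque resolution of the
  shank load cell, impedance control, an admittance model producing the
  desired joint angle from the external torque, and a PD position loop.
* **Gait events** (`gait`) — threshold/hysteresis foot-switch contact
  detection, heel-strike-anchored gait phase (0–100 %), cadence-based
  walking-speed estimation clamped to the validated 1–5 km/h envelope.
* **Reference generation** (`reference`) — speed-adaptive TA/soleus EMG
  envelopes as truncated Fourier series interpolated between five speed
  nodes, and reference angle/torque/stiffness tables over the gait cycle;
  joint stiffness is the slope of the moment–angle relation and shows the
  loading-response (~30 %) and push-off (~50 %) peaks.
* **EMG→torque regression** (`cnn`) — a 1-D convolutional network
  (conv 128×k13 – pool 6 – conv 128×k9 – pool 4 – conv 128×k6 – pool 2 –
  MLP 129/128/128/64/1 with a Tanh output scaled to ±τ_max) trained with
  Adam on MSE with early stopping, implemented in pure numpy and exposed
  as the sklearn-style estimator `CnnTorqueRegressor`.
* **Volitional-EMG extraction** (`filters`) — per-pulse blanking, the comb
  filter `y = (x_i − x_{i−1})/2` that cancels the pulse-locked M-wave, and
  rectification with a zero-phase 2 Hz low-pass yielding the volitional
  envelope; envelopes feed the torque model to estimate volitional torque.
* **Coordination** (`coordination`) — FES amplitudes proportional to the
  torque deficit the wearer leaves (per channel, no co-stimulation),

      A = (A_max − A_min) · clamp((|τ_ref| − |τ_v|)/τ_ref,max, 0, 1) + A_min,

  the activation ratio `r_v = max(|τ_ref|, |τ_v|)/τ_v,max` when the wearer
  meets the demand (0 otherwise), and desired stiffness/damping
  `k_d = clamp(k_max (k_ref − r_v k_ref,max)/k_ref,max + k_min, k_min, k_max)`,
  `c_d = 2ζk_d` (or `2ζ√(I k_d)`).
* **Closed-loop simulation** (`simulate`) — a 1-DOF ankle plant with linear
  FES recruitment above an onset amplitude and a participating wearer,
  driven through whole gait cycles in two controller modes: **PF** (assist
  without considering volition) and **PFV** (volition considered), with
  per-cycle joint power and energy accounting.
* **Synthetic data** (`synth`) — seeded generators for volitional EMG,
  stimulation artifacts and M-waves, foot-switch traces and isometric
  EMG–torque training sets, each returning ground truth for testing.

## Worked example

Train the torque model, then compare the two controller modes at 1.8 km/h
with a wearer contributing 80 % of the healthy pattern:

```bash
hybridgait gen-data  --out data.npz --n-samples 2000 --seed 7
hybridgait train-cnn --data data.npz --out model.npz
hybridgait simulate --mode pf  --speed 1.8 --cycles 4 --alpha 0.8 --seed 1 \
    --model model.npz --out run_pf.csv
hybridgait simulate --mode pfv --speed 1.8 --cycles 4 --alpha 0.8 --seed 1 \
    --model model.npz --out run_pfv.csv
hybridgait compare --pf run_pf.csv --pfv run_pfv.csv --report report.json
```

`train-cnn` prints the held-out metrics of the regressor, e.g.

```json
{
  "rmse": 1.4481002138781234,
  "peak_accuracy": 96.33804966950964,
  "correlation": 0.995574259648571,
  "n_epochs": 37
}
```

(test-split RMSE in Nm, agreement of peak torque magnitudes in percent,
prediction–truth correlation). The two `simulate` calls print the
per-cycle device energy consumption, e.g.

```
PF run: 3 cycles, device consumption 14.67 J/cycle
PFV run: 3 cycles, device consumption 5.85 J/cycle
```

— considering the wearer's volitional effort roughly halves the energy the
orthosis and stimulator spend, while the ankle still tracks the reference
gait trajectory. `compare` writes the per-source breakdown (orthosis, FES,
volitional) and the percentage reduction to `report.json`.

The same experiment is available from the library:

```python
from hybridgait.simulate import PlantParams, simulate_gait, compare_modes

pf  = simulate_gait("PF",  4, 1.8, PlantParams(participation_alpha=0.8, seed=1))
pfv = simulate_gait("PFV", 4, 1.8, PlantParams(participation_alpha=0.8, seed=1))
print(compare_modes(pf, pfv)["device_consumption_pfv"])
```

## Layout

```
src/hybridgait/   linkage, gait, reference, cnn, filters, coordination,
                  simulate, synth, config, cli
tests/            unit, property and acceptance tests
docs/methods.md   model assumptions, parameter choices, limitations
```
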