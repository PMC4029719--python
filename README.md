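# emgexo

Proportional myoelectric control pipeline for an antagonistic
pneumatic-muscle elbow joint, end to end:

1. **`emgexo.synth`** — seeded synthetic flexion–extension trials:
   4-channel surface EMG (biceps brachii, brachioradialis, triceps
   brachii, anconeus) plus a synchronized 0–90° elbow-angle trace,
   sampled at 1,024 Hz. Activation envelopes combine velocity-split
   agonist/antagonist drive, a gravitational load term, a
   co-contraction floor and two period-dependent degradations
   (acceleration-scaled amplitude instability, slow effort drift); each
   envelope amplitude-modulates band-limited (20–500 Hz) Gaussian
   noise, capped at 1,600 µV.
2. **`emgexo.processing`** — the causal conditioning chain (4th-order
   Butterworth high-pass at 50 Hz → rectify → 4th-order low-pass at
   10 Hz) and overlapped-window RMS features (200 ms windows, 50 ms
   step by default).
3. **`emgexo.network`** — a from-scratch 4-3-1 sigmoid
   backpropagation network mapping the 4-muscle RMS vector to elbow
   angle, with min-max input scaling, an explicit angle scaler,
   full-batch gradient descent (+ optional momentum), whole-trial
   80/20 splitting (60 trials → 48/12) and JSON persistence.
4. **`emgexo.actuator`** — the braided pneumatic-muscle force law
   `F = P[a(1−ε)² − b]`, the angle↔contraction-rate kinematics of the
   antagonistic pair, forward force computation at pressures `P0 ± ΔP`,
   the exact inverse back to ΔP, and target-angle → valve-voltage
   commands under selectable force closures.
5. **`emgexo.controller`** — the streaming loop: windowed RMS →
   threshold gate (sub-threshold ticks emit exactly 0 V) → angle
   prediction → clamp → differential-pressure command. Strictly causal.
6. **`emgexo.evaluation`** — RMSE, R², the predicted-on-actual
   regression line (k, j) and the powered/unpowered per-muscle RMS
   comparison.

## Test

```bash
python -m pytest -q tests/
```

The suite includes property tests (hypothesis), oracle equivalence
checks (brute-force RMS, finite-difference gradients, closed-form
pressure inversion) and `tests/test_acceptance.py` with one test per
acceptance criterion; the full run takes under a minute.

## CLI

```bash
# generate a 60-trial session at a 4-s motion period
emgexo synthesize --period 4 --trials 60 --seed 1 --out session/

# train the 4-3-1 network (whole-trial 80/20 split)
emgexo train --session session/ --seed 1 --out model.json

# evaluate on the held-out trials
emgexo evaluate --model model.json --session session/ --seed 1 --out report.json

# replay the streaming control loop over one trial
emgexo simulate-control --trial session/trial_000.csv --model model.json --out ticks.csv
```

Trial files are plain CSV (`time_s`, four `emg_*_uV` columns,
`angle_deg`); sessions carry a JSON manifest with the generating
configuration and per-trial seeds.

## Example (library API)

```python
from emgexo import (
    TrialConfig, WindowSpec, generate_session, make_dataset,
    split_data, train, evaluate_model,
)

cfg = TrialConfig(period_s=4.0, seed=1)
recs = generate_session(cfg, n_trials=60)
dataset = make_dataset(recs, WindowSpec(fs_hz=cfg.fs_hz))
train_set, test_set = split_data(dataset, 0.8, seed=1)
model, losses = train(train_set)
print(evaluate_model(model, test_set, period_s=4.0))
```
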