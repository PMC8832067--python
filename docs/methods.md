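# Methods

This document records the modeling assumptions, parameter choices, and
numerical decisions behind `marscrash`, and the known limitations of the
synthetic data generator.

## 1. Vehicle dynamics

State is (θ, ω) in degrees and °/s. The plant is an inverted pendulum

    θ̈ = k_P · sin(θ · π/180),   k_P = 600 °/s²

integrated with classical RK4 at dt = 20 ms (50 Hz). The small-angle
linearization θ̈ ≈ (k_P·π/180)·θ gives a divergence rate
√(k_P·π/180) ≈ 3.24 s⁻¹, i.e. a natural frequency of 0.515 Hz.

| Parameter | Default | Meaning |
|---|---|---|
| `pendulum_constant` | 600 °/s² | k_P |
| `dt` | 0.02 s | sample period |
| `crash_boundary` | ±60° | crash when \|θ\| reaches it |
| `omega_limit` | ±300 °/s | velocity clamp |
| `accel_limit` | ±180 °/s² | acceleration clamp |
| `joystick_gain` | 6 °/s per step | rate control: u∈[−1,1] adds u·gain to ω each step |
| `reset_rate` | 5 °/s | post-crash ramp back to 0° (12 s from 60°) |
| `trial_balance_seconds` | 100 s | cumulative *balancing* time per trial |

Clamps are applied inside the RK4 derivative evaluation (acceleration)
and to the state after each step (velocity). The acceleration clamp is
active for \|θ\| ≥ 30° (k_P·sin 30° = 300 > 180). Crashes latch the
final sample exactly on the boundary; reset samples are flagged
`control_enabled = False` and excluded from balancing time.

Numerics: RK4 at dt = 20 ms shows 4th-order convergence on the free
pendulum (error ratio ≈ 16 when dt is halved, verified in tests) and
energy drift < 10⁻⁶ over unclamped trajectories.

## 2. Synthetic pilot

The pilot senses only angular velocity (vestibular analogue), with:

1. additive Gaussian percept noise (`estimate_noise_sd`, default 8 °/s),
2. a reaction delay (`reaction_delay`, 0.4 s) applied to the percept,
3. a leaky position integrator: p̂ ← (1 − leak·dt)·p̂ + ω̂·dt
   (`position_leak`, 0.2 s⁻¹), modeling drift of the unreferenced
   position estimate,
4. a sampled PD policy u = −(k_p·p̂ + k_d·ω̂), clipped to [−1, 1],
   updated at `deflection_rate_hz` (1.5 Hz) and held between decisions,
5. **persistent disorientation**: a two-state Markov process, updated at
   decision instants, that inverts the sign of the command during
   exponentially distributed bouts (mean `disorientation_mean_s` =
   1.5 s). `sign_error_prob` (default 0.1) is the stationary occupancy
   of the inverted state. Inverted-sign commands with \|u\| above a
   small deadband are flagged as disorientation-judged deflections
   (DJD). Empirically the implementation hits occupancy 0.290 (target
   0.3) and mean bout 1.508 s over 10⁵ scripted decisions.

`make_cohort(n, difficulty_spread, seed)` draws per-pilot parameters
around these defaults so cohorts span stable to crash-prone pilots.

**Generator scope.** The generator is designed to reproduce the
qualitative signatures of the task — a 0.5 Hz unstable plant, drifting
position estimates, 1–2 Hz joystick activity, a substantial DJD
fraction among pre-crash deflections, and on the order of 10–15 crashes
per 100-s trial for difficult pilots — not to fit any individual
subject. Defaults were fixed once from those signatures and are not
tuned to downstream metrics.

## 3. Preprocessing

- **Episodes** are maximal `control_enabled` runs; their durations sum
  exactly to `trial_balance_seconds`. Episodes ending in a crash carry
  the crash sample (|θ| = 60) as their last sample.
- **Windows**: length L = round(window_ms/(dt·1000)) samples (50 for
  1000 ms), channels (θ, ω, joystick, DJD flag), slid with a stride in
  steps. An episode of n samples yields (n − L)//stride + 1 windows.
- **Labels** are *closed at the window end*: a window ending at index
  `e` in a crash episode of n samples is positive iff
  (n − 1) − e ≤ advance_steps. Thus each crash episode contributes
  advance_steps + 1 positive windows at stride 1 (e.g. 41 for a 3.00-s
  episode with 800 ms advance), and advance = 0 labels only the window
  whose final sample is the crash.
- **Splits and folds** are assigned at the episode level
  (`split_episodes`, `assign_folds`) so no window from a held-out
  episode can appear in training; `train()` re-checks this and raises
  on any overlap. `Standardizer` z-scores the three continuous channels
  with statistics fit on training windows only; the binary DJD channel
  is passed through.

## 4. Predictors

Seven families share a sigmoid-output binary head: LINEAR (flattened
logistic regression), MLP (two hidden ReLU layers), CNN (two
conv1d/ReLU/max-pool blocks + dense head), RNN_LSTM / RNN_GRU (single
recurrent layer, last hidden state → dense head), STACKED_LSTM /
STACKED_GRU (two recurrent layers).

The engine is pure numpy: Glorot initialization, inverted dropout,
BCE-with-logits loss in a numerically stable form, Adam
(β₁ 0.9, β₂ 0.999), mini-batches, early stopping on validation loss
with best-state restore, float32 by default. Every layer's analytic
backward pass is verified against central finite differences
(ε = 10⁻⁵, relative tolerance 5·10⁻⁵) in `tests/test_nnet.py`.
Training aborts with `FloatingPointError` if the loss goes non-finite.

Defaults (`ModelSpec()`): hidden 100, head 128, dropout 0.5, lr 10⁻³,
batch 256, ≤100 epochs, patience 10. `ModelSpec.scaled()` is a
CPU-budget profile (hidden 32, ≤14 epochs, patience 4, batch 512,
lr 3·10⁻³) used in the test suite; on the reference cohort it reaches
mean CV AUC 0.908 (STACKED_GRU) vs 0.582 (LINEAR).

## 5. Evaluation

- **AUC** is the exact pair statistic P(score₊ > score₋) + ½P(tie),
  computed via rank sums and verified against an O(P·N) pair count.
- **Precision at target recall** scans the distinct scores and returns
  the precision at the *largest* threshold whose recall meets the
  target (and that threshold); verified against an exhaustive sweep.
  Within a fixed prediction set, the best achievable precision is
  provably non-increasing in the target recall (the qualifying
  threshold set is nested), and this is tested.
- **Cross-validation** is k-fold grouped by episode; folds whose test
  split contains a single class are skipped and reported.

### Why AUC, not raw precision, for the advance-time trend

On this synthetic artifact, precision at 95 % recall *increases* with
the advance time even though the task gets harder. The reason is base
rate: each crash episode contributes advance_steps + 1 positive
windows, so prevalence grows roughly linearly with advance (e.g. ~4×
from 300 ms to 1000 ms at stride 1), and outside the near-ceiling-AUC
regime the prevalence effect on precision dominates the ranking
degradation. This was confirmed with trained MLP and LINEAR models
over multiple seeds, with a prevalence-corrected precision lift, and
with a noisy time-to-crash oracle. The prevalence-free statistic shows
the expected difficulty trend robustly: validation AUC of a fixed MLP
strictly decreases over advances 300/600/1000 ms (e.g. 0.921 > 0.767 >
0.687 at seed 0), and that is what the test suite asserts.

## 6. Crash analysis

- **Recoverable region**: a state (θ, ω) is recoverable if some
  admissible joystick policy keeps \|θ\| < 60° forever. Because control
  authority (300 °/s² at full deflection rate) exceeds the maximum
  pendulum acceleration (the 180 °/s² clamp), any interior state with
  ω = 0 is recoverable; hence the extremal policy "oppose velocity
  until stopped, then oppose position" decides recoverability exactly.
  Note that opposing *position* alone is not optimal — θ = +40°,
  ω = −100 °/s is saved by braking (u = +1) but crashed by u = −1. The
  region is precomputed on a 61×61 grid over [−60, 60]° × [−300, 300]
  °/s with a 10-s rollout horizon; it is symmetric under (θ, ω) →
  (−θ, −ω) and nested in joystick gain, and randomized-policy rollouts
  never save a state the extremal policy cannot (all tested).
- **Savability**: for each observed crash, the state `offset` ms before
  impact is tested against the region, sweeping offsets from 0 to the
  warning advance. At offset = advance (action starts at impact) the
  reference state lies on the boundary, so the savable share is exactly
  0 %; it is monotone non-increasing in the elapsed offset.
- **Failure stratification**: false-negative/false-positive rates by
  binned pre-crash \|θ\|, DJD prevalence by prediction type (TP/FP/
  FN/TN; "any-flag" and "fraction" modes), and normalized (θ, ω)
  density maps per prediction type.

## 7. Limitations

- The sampled PD pilot has an intrinsic limit cycle: even with perfect
  state feedback at the default 1.5-Hz decision rate it oscillates at
  roughly ±36°, so time-averaged \|θ\| reflects the limit cycle rather
  than estimator quality. Estimator degradation (leak, noise, sign
  inversion) is therefore measured by crash counts and by direct
  behavioral probes of the estimator, not by mean \|θ\|.
- Precision-based operating points (e.g. precision at 95 % recall)
  depend strongly on window prevalence and are not comparable across
  advance times or stride settings; compare AUC, or fix prevalence.
- The generator produces plausible, not subject-matched, behavior;
  absolute metric values on synthetic cohorts should not be read as
  human-performance estimates.
- The recoverable-region computation assumes the modeled plant and
  clamps; it is a property of the simulator, not of any physical
  vehicle.
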