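# Configuration schema

All `decode` subcommands accept `--config <file>` (YAML). Keys mirror the
library dataclasses; unknown keys are rejected before any stage runs.
Command-line flags (`--seed`, `--mode`, `--duration`) override file values,
which override the defaults listed here.

## model.* — decoder architecture (`NarxConfig`)

| key | default | meaning |
|---|---|---|
| `n_inputs` | 6 | exogenous EMG-envelope channels |
| `n_outputs` | 3 | decoded joints |
| `n_hidden` | 3 | tanh hidden units |
| `input_taps` | 1 | delay-line taps per envelope channel |
| `feedback_taps` | 2 | delay-line taps per output feedback |
| `m` | 2 | embedding lag count; prediction interval τ = m·dt_s |
| `dt_s` | 0.05 | decoded step, seconds |
| `hidden_activation` | `tanh` | only supported value |
| `output_activation` | `linear` | only supported value |

## train.* — optimizer (`TrainOptions`)

| key | default | meaning |
|---|---|---|
| `max_iters` | 500 | LM iterations per teacher-forced restart |
| `lm_mu0` / `lm_mu_up` / `lm_mu_down` | 1e-3 / 10 / 0.1 | damping schedule |
| `grad_tol` | 1e-7 | gradient ∞-norm stop (MSE scale) |
| `mse_tol` | 1e-10 | loss stop |
| `restarts` | 5 | seeded random initializations |
| `seed` | 0 | master seed for all randomness |
| `closed_loop_iters` | 300 | closed-loop LM budget (screen + continue) |
| `shooting_window_s` | 5.0 | multiple-shooting window, seconds |
| `screen_iters` | 80 | closed-loop iterations per restart screen |
| `polish_iters` | 200 | long-window polish iterations |
| `polish_window_s` | 60.0 | polish shooting window, seconds |
| `init_jitter` | 0.02 | sd of seeded window-start offsets (normalized) |
| `refine_top_k` | 2 | screened candidates refined to completion |
| `holdout_fraction` | 0.2 | internal selection slice (of training rows) |

## preprocess.* — envelope chain

| key | default | meaning |
|---|---|---|
| `order` | 6 | Butterworth low-pass order |
| `cutoff_hz` | 4.0 | low-pass cutoff |
| `fs_out` | 20.0 | decoding rate (must divide the raw rate) |

## plant.* — synthetic arm (`ArmPlantConfig`)

| key | default | meaning |
|---|---|---|
| `duration_s` | 180.0 | trial length (≥ 30) |
| `fs_raw` | 1000.0 | raw sampling rate |
| `joint_range_deg` | [90, 90, 90] | movement range per joint |
| `max_speed_dps` | 70.0 | strict speed bound |
| `emd_ms` | 100.0 | envelope-to-motion lead (electromechanical delay) |
| `carrier_band_hz` | [20, 450] | EMG carrier band |
| `noise_floor` | 0.02 | resting modulation fraction |
| `tonic_level` | 0.05 | tonic muscle baseline |
| `emg_amplitude_mv` | 0.5 | carrier scale, mV RMS at unit modulation |
| `envelope_order` / `envelope_cutoff_hz` | 6 / 4.0 | paired envelope extractor (group-delay compensation) |
| `seed` | 0 | generator seed |

## eval.* — evaluation protocol

| key | default | meaning |
|---|---|---|
| `folds` | 5 | contiguous cross-validation folds |
| `mode` | `closed_loop` | `closed_loop` or `teacher_forced` |
| `intervals_ms` | [50…300] | sweep grid, multiples of 1000/fs_out |
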