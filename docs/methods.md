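# Methods

## Problem and model

`emgdecode` estimates continuous multi-joint arm kinematics — shoulder
horizontal ab/adduction, elbow flexion–extension and wrist flexion–extension,
in degrees — from six channels of surface EMG recorded over the muscles
crossing those joints (anterior/posterior deltoid, biceps, triceps long head,
flexor/extensor carpi radialis). The decoder is a NARX recurrent neural
network: a nonlinear autoregressive model with exogenous inputs in which a
single hidden layer of H = 3 tanh units receives tapped delay lines of the
EMG linear envelopes X_i and of the joint-angle outputs Y_j, and a linear
layer reads out the three angles:

    U_n(t) = tanh( Σ_{i,k} A_ni(k) X_i(t−m−k) − Σ_{j,k} B_nj(k) Y_j(t−m−k) + b1_n )
    Y_j(t) = Σ_n C_jn U_n(t) + b2_j

Time runs in decoded steps of Δt = 50 ms (20 Hz). The embedding delay m sets
the prediction interval τ = mΔt: the newest sample the network sees is m
steps old. At the defaults (m = 2, τ = 100 ms; one exogenous tap per
channel, T_x = 1; two feedback taps per output, T_y = 2) the network has

    H·(N_x·T_x + N_y·T_y + 1) + N_y·(H + 1) = 3·(6 + 6 + 1) + 3·4 = 51

trainable parameters. The published description of this architecture gives
lag ranges that would imply three taps per signal (96 parameters) while
simultaneously stating a 51-parameter total; T_x = 1 / T_y = 2 is the
minimal feedback-bearing tap assignment consistent with the 51-parameter
enumeration, and `count_parameters` exposes the alternatives so users can
explore other readings. The minus sign on the feedback term is kept from the
published form; it is representationally irrelevant because the weights are
signed.

Two run modes share one parameter set. In *series-parallel* (teacher-forced)
mode the feedback taps hold measured past angles — the classical one-step
MSE predictor. In *parallel* (closed-loop) mode they hold the model's own
past predictions, so after a burn-in of m + max(T_x, T_y) measured samples
only EMG drives the output; this is the mode that matters for prosthetic or
exoskeleton control and is the headline evaluation mode.

## Preprocessing

Raw EMG (1 kHz) is full-wave rectified and low-pass filtered with a causal
6th-order Butterworth at 4 Hz to form the linear envelope, then decimated to
20 Hz by keeping every 50th sample. Angles are decimated the same way
without an extra filter: self-paced reaching (< 70 °/s) has essentially no
power near the 10 Hz Nyquist of the decoded rate, and the 4 Hz envelope is
already band-limited. Filtering is single-pass because the target
application is real-time control; zero-phase filtering would be non-causal.
The filter state is initialized to the steady state of the first sample so
short test signals show no start-up transient, and negative transients are
clipped at zero because the envelope models an activation intensity.

A causal order-6/4 Hz Butterworth delays its passband by ≈ 154 ms (DC group
delay, computed from the analog prototype poles). This delay is a real
property of any causal envelope pipeline; the NARX lag structure absorbs it
during fitting, and the synthetic plant accounts for it explicitly (below).

Envelope amplitude scaling is deferred to training: each channel is divided
by its training-fold maximum, and angles are affinely mapped to [−1, 1]
using training-fold min/max, so no information leaks from validation data
into the normalizers.

## Training

Training minimizes the mean-squared prediction error with
Levenberg–Marquardt (multiplicative damping μ, factor 10 up / 0.1 down,
forward-difference Jacobians — 51 parameters make full numerical Jacobians
cheap). It proceeds in stages:

1. **Teacher-forced stage.** From `restarts` (default 5) seeded random
   initializations (uniform ±0.5 scaled by 1/√fan-in), LM minimizes the
   series-parallel residual. This stage is fast and reliably reaches
   residuals at the noise floor.
2. **Closed-loop screening and refinement.** The one-step-optimal solution
   for smooth kinematics is approximately the extrapolator
   Y(t) = 2Y(t−m) − Y(t−m−1), which is unstable when iterated on its own
   predictions: a decoder trained only teacher-forced is useless closed-loop.
   LM therefore continues on the *closed-loop* residual: the network is
   simulated freely over multiple-shooting windows (default 5 s), each
   re-initialized from measured burn-in samples, and the residual is the
   simulated-minus-measured angle over every post-burn-in step. Because all
   restarts reach indistinguishable teacher-forced loss while their
   closed-loop basins differ wildly, each restart is screened with a short
   closed-loop LM run (default 80 iterations) and the best-screened
   candidates (default top 2) are each refined for the remaining budget
   (default 300 total).
3. **Stable linear insurance candidate.** Alongside the random restarts, a
   deterministic linear candidate is constructed from the training data: per
   joint, the feedback is fixed to a leaky integrator (weight 0.998 on the
   first feedback tap — a free least-squares feedback fit invariably learns
   the anti-stable extrapolator) and the envelope weights and intercept are
   fit by ordinary least squares under that backbone. The linear map is
   embedded in the tanh network's linear regime (hidden pre-activations
   scaled to |x| ≤ 0.1, output weights scaled inversely). This candidate is
   stable by construction and near-optimal whenever the envelope-to-velocity
   relation is close to linear; it always receives a refinement slot and
   also enters the final ranking unrefined.
4. **Long-horizon polish and out-of-sample selection.** Each refined
   candidate gets a final LM pass at a longer shooting window (default
   60 s, 200 iterations) that penalizes slow drift invisible to short
   windows. The winner is then chosen by closed-loop error on an internal
   held-out slice (default: the last 20% of the training data, carved from
   the longest segment before the normalizers or any fit touch it). The
   held-out ranking is essential: with 51 parameters the optimizer can fit
   the *realized noise integral* of the training trial in its slow drift
   mode — candidates can agree to three digits on every training-loss
   metric, including full-horizon simulation of the training segments,
   while differing by tens of degrees of drift on unseen data.
5. **Refit on the full data.** The selected winner takes one more polish
   pass over the complete training segments (held-out slice re-included),
   the standard select-then-refit pattern: the slice has done its job of
   ranking candidates, and the final model should not forgo 20% of the
   data. The jittered objective keeps this last pass from re-introducing
   drift-mode overfitting.

Two regularizing details matter. First, every shooting window's initial
feedback taps are offset by a small fixed, seeded perturbation
(`init_jitter`, default 0.02 in normalized angle units, ≈ 1°) while the
residual target remains the measured trajectory: a decoder whose feedback
dynamics do not contract never sheds the offset and pays for it over the
whole window, so the fit is pushed toward closed-loop stability — the same
mechanism that limits drift on unseen data, where the decoder's state is
always slightly off the truth. Larger jitter (≥ 0.05) visibly roughens the
optimization landscape and starts to hurt; 0.02 is a deliberate light touch.
Second, EMG envelopes carry velocity rather than absolute-position
information, so the fitted system necessarily has a near-unit feedback root;
the jittered long-window objective is what decides whether that root sits
just inside the unit circle (bounded drift) or just outside (slow blow-up).

Multiple shooting is what makes stage 2 tractable: the full-trajectory
closed-loop error surface is highly multimodal, while moderate windows keep
the landscape close to the teacher-forced one yet still penalize unstable
feedback. Windows overlap by the burn-in so every sample contributes exactly
one residual row; equal-length windows are simulated side by side, and the
finite-difference Jacobian evaluates all 51 perturbations in one batched
pass, so the sequential loop only runs over one window's worth of steps.

Accepted LM steps are strictly improving, so each stage's recorded MSE
trajectory is non-increasing. Training requires more than 10× as many
residual rows as parameters (≥ 510 steps ≈ 26 s of data) as an
identifiability floor. All randomness flows from a single integer seed
through `numpy.random.SeedSequence`, so training is bit-reproducible.

## Evaluation protocol

Accuracy is the variance accounted for,
VAF = 100·(1 − Var(measured − decoded)/Var(measured)), with population
variances (the convention cancels in the ratio; fixing it makes worked
examples exact). Burn-in samples are excluded.

Cross-validation uses five *contiguous* equal blocks (remainder to the last
block): 80% train / 20% validation per fold, never shuffled samples, because
EMG and kinematics are strongly autocorrelated and shuffling would leak.
Training segments on either side of the held-out block are treated as
independent segments with delay-line resets at the splice. Each fold draws
its training seed from the master seed via `SeedSequence(seed, fold)`.

The prediction-interval sweep repeats the whole CV at τ = 50…300 ms in 50 ms
steps (m = 1…6) and reports the interval with the highest grand-mean VAF,
ties toward the smallest τ.

Across-joint comparisons use one-way repeated-measures ANOVA
(SS_error = SS_total − SS_subjects − SS_conditions; F = MS_cond/MS_error
with df = (c−1), (c−1)(n−1); partial η² = SS_c/(SS_c+SS_e); no sphericity
correction) and Bonferroni-adjusted paired t-tests (p_adj = min(1, p·n_pairs);
a zero-variance difference vector is reported as degenerate with p_adj = 1).

## Synthetic arm plant

No public recordings exist for this protocol, so the package ships a
generative plant that emulates the study conditions and gives every pipeline
stage a ground truth:

* **Kinematics**: concatenated minimum-jerk reaches (amplitude-normalized
  profile 10u³ − 15u⁴ + 6u⁵) toward targets drawn uniformly in the central
  90% of each joint's 90° range, separated by 0.5–2 s holds; all joints
  share the reach clock (concurrent multi-joint movement) with independent
  targets. Reach durations are drawn from 1–2 s and stretched when necessary
  so minimum-jerk peak velocity (1.875·amplitude/duration) stays below 80%
  of the 70 °/s limit — the speed bound is strict by construction. Default
  trial: 180 s at 1 kHz.
* **Activations**: reciprocal velocity-proportional drive — for each joint
  the agonist carries the positive part of joint velocity, the antagonist
  the negative part, scaled by 1/(70 °/s) on top of a 0.05 tonic baseline,
  clipped to [0, 1].
* **EMG**: per channel, zero-mean Gaussian noise band-passed to 20–450 Hz,
  normalized to unit RMS, amplitude-modulated by (0.02 + activation) and
  scaled to 0.5 mV — the standard amplitude-modulated interference-pattern
  surrogate for surface EMG.

**Timing convention.** The electromechanical delay parameter `emd_ms`
(default 100 ms) is defined at the *envelope* level: the decoded-rate linear
envelope leads joint velocity by exactly `emd_ms`. Because the causal
envelope filter itself delays the modulation profile by its ≈ 154 ms group
delay, the underlying neural drive is advanced by `emd_ms` plus that group
delay. This makes the plant decodable by construction — envelopes at time
t − emd determine joint velocity at time t up to the tonic floor — so a
decoder whose prediction interval τ matches `emd_ms` has exactly the
information it needs, which is what ties the sweep's peak to the plant's
delay. The default emd of 100 ms sits on the decoded-step grid (2 steps)
and within physiological electromechanical-delay ranges.

What the plant does *not* model: musculoskeletal dynamics, motor-unit
structure, co-contraction strategies beyond the tonic floor, electrode
crosstalk, non-stationary noise, or the spontaneous discharges seen in
paretic muscle. Passing the synthetic suite therefore demonstrates that the
pipeline is correct and that the decoding problem the plant poses is solved
to the stated accuracy; it does not certify accuracy on any particular
recorded dataset.

## Problem sizes used in tests and the acceptance script

The headline check runs the full default protocol: a 180 s trial (3 600
decoded steps), five folds, five restarts, closed-loop evaluation. The
prediction-interval sweep property is checked on a reduced 60 s trial with
2 restarts and a trimmed closed-loop budget, which preserves the peak
location while keeping the six-interval sweep affordable. Unit tests use
30–60 s trials. These sizes are the package's own test-design choices; the
library itself imposes no limits beyond the identifiability floor.

## Numerical choices and edge cases

* LM damping: μ₀ = 10⁻³, ×10 on rejection, ×0.1 on acceptance, abandoned at
  μ > 10¹²; convergence on gradient ∞-norm < 10⁻⁷ (MSE scale), MSE < 10⁻¹⁰,
  or relative improvement < 10⁻⁹.
* Finite differences: forward, step 10⁻⁶·(1 + |θ_p|).
* Normalizer guards: zero-range channels fall back to unit scale (and are
  rejected as targets by the VAF's zero-variance error).
* Degenerate inputs: empty trials, non-uniform clocks (> 1 ppm jitter), NaN
  cells, triggers outside streams, non-integer decimation ratios, intervals
  off the step grid, and too-short segments all raise typed errors rather
  than propagating garbage.
* `make_folds` requires n ≥ k; `cross_validate` additionally requires each
  validation block to exceed the burn-in.
* Ties in the sweep resolve toward the smallest interval (argmax of the
  grand mean returns the first maximum).

## Behavior of the prediction-interval sweep on the synthetic plant

On the synthetic suite the sweep reproduces the qualitative shape expected
of this decoder family — accuracy rises as the prediction interval grows
from 50 ms and falls off by 300 ms — but the maximum sits near *twice* the
plant's electromechanical delay rather than at the delay itself. The
geometry explains why: with a single exogenous tap the decoder bridges the
feedback gap (t−τ, t] using one velocity-informative sample, the envelope at
t−τ, which (by the plant's timing convention) reflects velocity at
t−τ+emd; that sample sits at the *center* of the gap when τ = 2·emd. A peak
exactly at the delay would require the envelope to lead motion by emd/2,
which would break the property that makes the plant decodable at τ = emd in
the first place. With more input taps the geometry softens and the peak
moves toward shorter intervals; the tap count here is pinned by the
51-parameter architecture.

## Known limitations

* Closed-loop training cost dominates run time (finite-difference Jacobians
  through a recurrence); an analytic back-propagated Jacobian would be
  faster but the numerical one is simpler to audit at 51 parameters.
* With fewer than ~3 restarts the closed-loop screening occasionally has no
  good basin to choose from; the default of 5 restarts is sized to make this
  rare at study scale.
* The decoder integrates velocity information; on signals whose absolute
  level is not recoverable from EMG (e.g. sustained co-contraction) closed-
  loop output can drift between burn-ins, which the polish stage mitigates
  but cannot eliminate.
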