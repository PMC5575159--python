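"""NARX recurrent network mapping EMG envelopes to joint angles.

The decoder is a nonlinear autoregressive model with exogenous inputs: a
single tanh hidden layer fed by tapped delay lines of the six envelope
channels and of the three joint-angle outputs, followed by a linear output
layer. With an embedding delay of m steps, hidden unit n computes

    U_n(t) = tanh( sum_{i,k} A[n,i,k] X_i(t-m-k)
                 - sum_{j,k} B[n,j,k] Y_j(t-m-k) + b1[n] )

and output j is Y_j(t) = sum_n C[j,n] U_n(t) + b2[j]. Lag index k runs over
0..taps-1 on top of the embedding delay m, so the freshest sample the model
sees is m steps old: the model predicts tau = m * dt ahead of its newest
input (the prediction interval). The minus sign on the feedback term is kept
from the model's published form; since all weights are signed and trainable
it is representationally equivalent either way.

Two run modes share the same weights:

* series-parallel (teacher-forced): feedback taps hold *measured* past
  angles -- the classical one-step MSE predictor and the training mode;
* parallel (closed-loop): feedback taps hold the model's *own* past
  predictions, so after a short measured burn-in only EMG drives the output.

With the default architecture (6 inputs x 1 tap, 3 outputs x 2 feedback
taps, 3 hidden nodes, linear 3-output layer) the model has exactly 51
trainable parameters, which makes full numerical Jacobians cheap; training
is damped Gauss-Newton (Levenberg-Marquardt) on the series-parallel residual
with multiple seeded restarts.

Series-parallel optimization alone is not sufficient for a decoder that must
run closed-loop: the one-step-optimal solution for smooth kinematics is an
extrapolative feedback rule (approximately Y(t) = 2 Y(t-m) - Y(t-m-1)) whose
closed-loop dynamics are unstable, so its own prediction errors compound
until the tanh layer saturates. Training therefore follows the standard
two-stage recipe for this network family: teacher-forced LM from several
seeded restarts, then the loop is closed and LM continues on the *parallel*
(closed-loop) residual starting from the best open-loop solution, which
directly minimizes the error between the freely-running decoder output and
the measured angles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError, NumericalError, ParameterError, TrainingError

FORMAT_VERSION = 1


@dataclass(frozen=True)
class NarxConfig:
    """Architecture hyperparameters. tau = m * dt_s is the prediction interval."""

    n_inputs: int = 6
    n_outputs: int = 3
    n_hidden: int = 3
    input_taps: int = 1
    feedback_taps: int = 2
    m: int = 2
    dt_s: float = 0.05
    hidden_activation: str = "tanh"
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        if min(self.n_inputs, self.n_outputs, self.n_hidden, self.input_taps) < 1:
            raise ParameterError("n_inputs, n_outputs, n_hidden, input_taps must be >= 1")
        if self.feedback_taps < 0:
            raise ParameterError("feedback_taps must be >= 0")
        if self.m < 1:
            raise ParameterError("m (embedding lag count) must be >= 1")
        if self.dt_s <= 0:
            raise ParameterError("dt_s must be positive")
        if self.hidden_activation != "tanh":
            raise ParameterError("only the tanh sigmoid hidden activation is supported")
        if self.output_activation != "linear":
            raise ParameterError("only a linear output layer is supported")

    @property
    def tau_s(self) -> float:
        """Prediction interval in seconds."""
        return self.m * self.dt_s

    @property
    def burn_in(self) -> int:
        """Number of leading samples needed to fill all delay lines."""
        return self.m + max(self.input_taps, self.feedback_taps)


def count_parameters(config: NarxConfig) -> int:
    """Total trainable weights and biases: H*(Nx*Tx + Ny*Ty + 1) + Ny*(H+1)."""
    h, nx, tx = config.n_hidden, config.n_inputs, config.input_taps
    ny, ty = config.n_outputs, config.feedback_taps
    return h * (nx * tx + ny * ty + 1) + ny * (h + 1)


@dataclass
class NarxParameters:
    """Trainable weights plus the per-channel affine normalizers.

    Normalizers are fitted on training data only: envelopes are divided by
    their per-channel training maximum (input_scale), angles are mapped to
    [-1, 1] via (y - output_offset) / output_scale. Weights operate entirely
    in normalized space; predictions are mapped back to degrees on the way
    out.
    """

    config: NarxConfig
    A: np.ndarray  # (H, Nx, Tx)
    B: np.ndarray  # (H, Ny, Ty)
    C: np.ndarray  # (Ny, H)
    b1: np.ndarray  # (H,)
    b2: np.ndarray  # (Ny,)
    input_scale: np.ndarray = field(default=None)  # (Nx,)
    output_offset: np.ndarray = field(default=None)  # (Ny,)
    output_scale: np.ndarray = field(default=None)  # (Ny,)

    def __post_init__(self) -> None:
        c = self.config
        if self.input_scale is None:
            self.input_scale = np.ones(c.n_inputs)
        if self.output_offset is None:
            self.output_offset = np.zeros(c.n_outputs)
        if self.output_scale is None:
            self.output_scale = np.ones(c.n_outputs)
        for name, arr, shape in (
            ("A", self.A, (c.n_hidden, c.n_inputs, c.input_taps)),
            ("B", self.B, (c.n_hidden, c.n_outputs, c.feedback_taps)),
            ("C", self.C, (c.n_outputs, c.n_hidden)),
            ("b1", self.b1, (c.n_hidden,)),
            ("b2", self.b2, (c.n_outputs,)),
            ("input_scale", self.input_scale, (c.n_inputs,)),
            ("output_offset", self.output_offset, (c.n_outputs,)),
            ("output_scale", self.output_scale, (c.n_outputs,)),
        ):
            arr = np.asarray(arr, dtype=float)
            setattr(self, name, arr)
            if arr.shape != shape:
                raise ParameterError(f"{name} must have shape {shape}, got {arr.shape}")
        if np.any(self.input_scale == 0) or np.any(self.output_scale == 0):
            raise ParameterError("normalizer scales must be nonzero (invertible)")

    # -- normalized-space helpers ------------------------------------------
    def normalize_inputs(self, envelopes: np.ndarray) -> np.ndarray:
        return np.asarray(envelopes, dtype=float) / self.input_scale

    def normalize_outputs(self, angles: np.ndarray) -> np.ndarray:
        return (np.asarray(angles, dtype=float) - self.output_offset) / self.output_scale

    def denormalize_outputs(self, y_norm: np.ndarray) -> np.ndarray:
        return y_norm * self.output_scale + self.output_offset

    def n_parameters(self) -> int:
        return self.A.size + self.B.size + self.C.size + self.b1.size + self.b2.size


def init_parameters(config: NarxConfig, seed: int) -> NarxParameters:
    """Seeded random initialization: U(-0.5, 0.5) scaled by 1/sqrt(fan-in).

    Normalizers start as the identity; they are fitted by :func:`train`.
    """
    rng = np.random.default_rng(seed)
    h, nx, tx = config.n_hidden, config.n_inputs, config.input_taps
    ny, ty = config.n_outputs, config.feedback_taps
    fan_hidden = nx * tx + ny * ty
    s1 = 1.0 / np.sqrt(fan_hidden)
    s2 = 1.0 / np.sqrt(h)
    return NarxParameters(
        config=config,
        A=rng.uniform(-0.5, 0.5, (h, nx, tx)) * s1,
        B=rng.uniform(-0.5, 0.5, (h, ny, ty)) * s1,
        C=rng.uniform(-0.5, 0.5, (ny, h)) * s2,
        b1=rng.uniform(-0.5, 0.5, h) * s1,
        b2=rng.uniform(-0.5, 0.5, ny) * s2,
    )


# -- parameter vector packing ---------------------------------------------

def _pack(params: NarxParameters) -> np.ndarray:
    return np.concatenate([
        params.A.ravel(), params.B.ravel(), params.C.ravel(),
        params.b1.ravel(), params.b2.ravel(),
    ])


def _unpack(theta: np.ndarray, template: NarxParameters) -> NarxParameters:
    c = template.config
    sizes = [template.A.size, template.B.size, template.C.size,
             template.b1.size, template.b2.size]
    parts = np.split(np.asarray(theta, dtype=float), np.cumsum(sizes)[:-1])
    return NarxParameters(
        config=c,
        A=parts[0].reshape(template.A.shape),
        B=parts[1].reshape(template.B.shape),
        C=parts[2].reshape(template.C.shape),
        b1=parts[3].copy(),
        b2=parts[4].copy(),
        input_scale=template.input_scale.copy(),
        output_offset=template.output_offset.copy(),
        output_scale=template.output_scale.copy(),
    )


# -- forward passes ---------------------------------------------------------

def _lagged(z: np.ndarray, ts: np.ndarray, m: int, taps: int) -> np.ndarray:
    """Design matrix of z taps: column (i*taps + k) holds z[t - m - k, i]."""
    n_cols = z.shape[1] * taps
    out = np.empty((ts.size, n_cols))
    for i in range(z.shape[1]):
        for k in range(taps):
            out[:, i * taps + k] = z[ts - m - k, i]
    return out


def _forward(params: NarxParameters, x_design: np.ndarray,
             y_design: np.ndarray) -> np.ndarray:
    """Hidden tanh layer + linear output in normalized space."""
    c = params.config
    wa = params.A.reshape(c.n_hidden, -1)
    wb = params.B.reshape(c.n_hidden, -1)
    pre = x_design @ wa.T + params.b1
    if wb.size:
        pre = pre - y_design @ wb.T
    u = np.tanh(pre)
    return u @ params.C.T + params.b2


def _check_lengths(params: NarxParameters, envelopes: np.ndarray,
                   n_angles: int) -> np.ndarray:
    envelopes = np.asarray(envelopes, dtype=float)
    c = params.config
    if envelopes.ndim != 2 or envelopes.shape[1] != c.n_inputs:
        raise InputError(f"envelopes must be [n x {c.n_inputs}]")
    if envelopes.shape[0] != n_angles:
        raise InputError("envelopes and angles must be aligned (equal length)")
    if envelopes.shape[0] <= c.burn_in:
        raise InputError(
            f"need more than burn_in={c.burn_in} samples, got {envelopes.shape[0]}"
        )
    return envelopes


def predict_series_parallel(params: NarxParameters, envelopes: np.ndarray,
                            measured_angles: np.ndarray) -> np.ndarray:
    """One-step teacher-forced prediction: feedback taps hold measured angles.

    Returns an [n x Ny] matrix in degrees; the first burn_in rows copy the
    measured angles (no prediction is defined there) and should be excluded
    from any error metric.
    """
    measured_angles = np.asarray(measured_angles, dtype=float)
    envelopes = _check_lengths(params, envelopes, measured_angles.shape[0])
    c = params.config
    ts = np.arange(c.burn_in, envelopes.shape[0])
    xn = params.normalize_inputs(envelopes)
    yn = params.normalize_outputs(measured_angles)
    xd = _lagged(xn, ts, c.m, c.input_taps)
    yd = _lagged(yn, ts, c.m, c.feedback_taps) if c.feedback_taps else np.empty((ts.size, 0))
    out = measured_angles.copy()
    out[c.burn_in:] = params.denormalize_outputs(_forward(params, xd, yd))
    return out


def simulate_parallel(params: NarxParameters, envelopes: np.ndarray,
                      initial_angles: np.ndarray) -> np.ndarray:
    """Closed-loop decoding: feedback taps hold the model's own predictions.

    ``initial_angles`` must supply exactly the first burn_in measured samples;
    from there on only the EMG envelopes drive the output. Returns [n x Ny]
    in degrees with the first burn_in rows equal to ``initial_angles``.
    """
    initial_angles = np.asarray(initial_angles, dtype=float)
    c = params.config
    if initial_angles.shape != (c.burn_in, c.n_outputs):
        raise InputError(
            f"initial_angles must have shape ({c.burn_in}, {c.n_outputs}), "
            f"got {initial_angles.shape}"
        )
    envelopes = np.asarray(envelopes, dtype=float)
    envelopes = _check_lengths(params, envelopes, envelopes.shape[0])
    n = envelopes.shape[0]
    ts = np.arange(c.burn_in, n)
    xn = params.normalize_inputs(envelopes)
    xd = _lagged(xn, ts, c.m, c.input_taps)

    wa = params.A.reshape(c.n_hidden, -1)
    wb = params.B.reshape(c.n_hidden, -1)
    # feedback gather pattern, column order (j, k) matching _lagged
    if c.feedback_taps:
        lag_off = np.array([c.m + k for _ in range(c.n_outputs)
                            for k in range(c.feedback_taps)])
        col_j = np.array([j for j in range(c.n_outputs)
                          for _ in range(c.feedback_taps)])
    yn = np.empty((n, c.n_outputs))
    yn[:c.burn_in] = params.normalize_outputs(initial_angles)
    for i, t in enumerate(ts):
        pre = wa @ xd[i] + params.b1
        if c.feedback_taps:
            pre = pre - wb @ yn[t - lag_off, col_j]
        yn[t] = params.C @ np.tanh(pre) + params.b2
    out = np.empty((n, c.n_outputs))
    out[:c.burn_in] = initial_angles
    out[c.burn_in:] = params.denormalize_outputs(yn[c.burn_in:])
    return out


# -- training ---------------------------------------------------------------

@dataclass
class TrainOptions:
    """Levenberg-Marquardt settings.

    ``max_iters`` bounds the teacher-forced stage per restart.
    ``closed_loop_iters`` bounds the closed-loop refinement stage that
    follows, run on multiple-shooting windows of ``shooting_window_s``
    seconds. Because every restart reaches essentially the same teacher-forced
    loss while their closed-loop behavior differs wildly, each restart is
    first screened with ``screen_iters`` closed-loop iterations and the
    restart with the lowest *closed-loop* loss is selected and refined for
    the remaining budget. ``polish_iters`` bounds a final pass at the longer
    ``polish_window_s`` horizon that penalizes slow closed-loop drift.
    Setting closed_loop_iters = polish_iters = 0 leaves a purely
    series-parallel fit. The mse_trajectory fields in the report track
    accepted (strictly improving) steps only, separately per stage.
    """

    max_iters: int = 500
    lm_mu0: float = 1e-3
    lm_mu_up: float = 10.0
    lm_mu_down: float = 0.1
    grad_tol: float = 1e-7
    mse_tol: float = 1e-10
    restarts: int = 5
    seed: int = 0
    closed_loop_iters: int = 300
    shooting_window_s: float = 5.0
    screen_iters: int = 80
    polish_iters: int = 200
    polish_window_s: float = 60.0
    init_jitter: float = 0.02
    refine_top_k: int = 2
    holdout_fraction: float = 0.2

    def __post_init__(self) -> None:
        if min(self.max_iters, self.restarts) < 1:
            raise ParameterError("max_iters and restarts must be >= 1")
        if min(self.closed_loop_iters, self.screen_iters, self.polish_iters) < 0:
            raise ParameterError("closed-loop iteration counts must be >= 0")
        if self.shooting_window_s <= 0 or self.polish_window_s <= 0:
            raise ParameterError("shooting windows must be positive")
        if self.init_jitter < 0:
            raise ParameterError("init_jitter must be >= 0")
        if self.refine_top_k < 1:
            raise ParameterError("refine_top_k must be >= 1")
        if not 0 <= self.holdout_fraction < 0.5:
            raise ParameterError("holdout_fraction must be in [0, 0.5)")
        if min(self.lm_mu0, self.lm_mu_up, self.lm_mu_down,
               self.grad_tol, self.mse_tol) <= 0:
            raise ParameterError("LM constants and tolerances must be positive")
        if self.lm_mu_up <= 1 or self.lm_mu_down >= 1:
            raise ParameterError("need lm_mu_up > 1 and lm_mu_down < 1")


@dataclass
class TrainReport:
    final_mse: float
    iterations: int
    restart_index_selected: int
    mse_trajectory: list[float]
    closed_loop_mse_trajectory: list[float] = field(default_factory=list)
    open_loop_mse: float = float("nan")


_MU_MAX = 1e12


def _numerical_jacobian(fun, theta: np.ndarray, r0: np.ndarray) -> np.ndarray:
    """Forward-difference Jacobian of the residual vector."""
    jac = np.empty((r0.size, theta.size))
    for p in range(theta.size):
        h = 1e-6 * (1.0 + abs(theta[p]))
        tp = theta.copy()
        tp[p] += h
        jac[:, p] = (fun(tp) - r0) / h
    return jac


def _batched_jacobian(fun_batch, theta: np.ndarray, r0: np.ndarray) -> np.ndarray:
    """Forward-difference Jacobian via one batched residual evaluation."""
    steps = 1e-6 * (1.0 + np.abs(theta))
    thetas = theta[None, :] + np.diag(steps)
    return ((fun_batch(thetas) - r0[None, :]) / steps[:, None]).T


def _levenberg_marquardt(fun, theta0: np.ndarray, opts: TrainOptions,
                         max_iters: int | None = None, jac_fun=None):
    """Classic LM with multiplicative damping; returns (theta, trajectory, iters)."""
    if max_iters is None:
        max_iters = opts.max_iters
    if jac_fun is None:
        jac_fun = lambda th, r: _numerical_jacobian(fun, th, r)
    theta = np.asarray(theta0, dtype=float).copy()
    r = fun(theta)
    if not np.isfinite(r).all():
        raise NumericalError("non-finite loss at the initial parameters")
    n_res = r.size
    mse = float(np.mean(r**2))
    trajectory = [mse]
    mu = opts.lm_mu0
    eye = np.eye(theta.size)
    iterations = 0
    for it in range(1, max_iters + 1):
        iterations = it
        jac = jac_fun(theta, r)
        grad = jac.T @ r
        if np.max(np.abs(grad)) * 2.0 / n_res < opts.grad_tol:
            break
        jtj = jac.T @ jac
        accepted = False
        while mu <= _MU_MAX:
            try:
                delta = np.linalg.solve(jtj + mu * eye, -grad)
            except np.linalg.LinAlgError:
                mu *= opts.lm_mu_up
                continue
            theta_try = theta + delta
            r_try = fun(theta_try)
            mse_try = float(np.mean(r_try**2)) if np.isfinite(r_try).all() else np.inf
            if mse_try < mse:
                theta, r, mse = theta_try, r_try, mse_try
                trajectory.append(mse)
                mu = max(mu * opts.lm_mu_down, 1e-15)
                accepted = True
                break
            mu *= opts.lm_mu_up
        if not accepted or mse < opts.mse_tol:
            break
        # stagnation: the accepted step no longer improves the loss meaningfully
        if trajectory[-2] - mse < 1e-9 * max(mse, 1e-30):
            break
    return theta, trajectory, iterations


def _unpack_batch(thetas: np.ndarray, template: NarxParameters):
    """Split a (G, P) parameter batch into stacked weight tensors."""
    c = template.config
    sizes = [template.A.size, template.B.size, template.C.size,
             template.b1.size, template.b2.size]
    parts = np.split(np.asarray(thetas, dtype=float), np.cumsum(sizes)[:-1], axis=1)
    g = thetas.shape[0]
    wa = parts[0].reshape(g, c.n_hidden, c.n_inputs * c.input_taps)
    wb = parts[1].reshape(g, c.n_hidden, c.n_outputs * c.feedback_taps)
    cw = parts[2].reshape(g, c.n_outputs, c.n_hidden)
    return wa, wb, cw, parts[3], parts[4]


def _make_closed_loop_residuals(template: NarxParameters,
                                segments: list[tuple[np.ndarray, np.ndarray]],
                                init_jitter: float = 0.0):
    """Batched closed-loop residual function over training segments/windows.

    Each segment is simulated in parallel mode from its measured burn-in;
    residuals are (simulated - measured) normalized angles for every
    post-burn-in step of every segment. The returned callable evaluates G
    parameter vectors at once (so the finite-difference Jacobian is a single
    pass), and equal-length segments are simulated side by side, so the
    sequential loop only runs over one segment's worth of time steps.

    ``init_jitter`` adds a fixed, seeded offset (sd in normalized angle
    units) to each window's initial feedback taps while the residual target
    stays the measured trajectory. A decoder whose feedback dynamics do not
    contract never recovers from the offset and pays for it over the whole
    window, so the fitted solution is pushed toward closed-loop stability;
    an offset-agnostic (drifting) solution would otherwise look perfect on
    windows that start exactly on the data.
    """
    c = template.config
    burn = c.burn_in
    by_length: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for env, ang in segments:
        by_length.setdefault(env.shape[0], []).append((env, ang))
    groups = []
    jit_rng = np.random.default_rng(np.random.SeedSequence(181818))
    for n, segs in sorted(by_length.items()):
        xd = np.stack([
            _lagged(template.normalize_inputs(env), np.arange(burn, n),
                    c.m, c.input_taps)
            for env, _ in segs
        ])  # (S, n-burn, Nx*Tx)
        yn = np.stack([template.normalize_outputs(ang) for _, ang in segs])
        y0 = yn[:, :burn].copy()
        if init_jitter > 0:
            # one constant offset per window and joint: the slow mode a
            # drifting decoder cannot shed
            y0 = y0 + init_jitter * jit_rng.standard_normal(
                (len(segs), 1, c.n_outputs))
        groups.append((xd, yn, y0, n))
    if c.feedback_taps:
        lag_off = np.array([c.m + k for _ in range(c.n_outputs)
                            for k in range(c.feedback_taps)])
        col_j = np.array([j for j in range(c.n_outputs)
                          for _ in range(c.feedback_taps)])

    def residuals_batch(thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(thetas)
        g = thetas.shape[0]
        wa, wb, cw, b1, b2 = _unpack_batch(thetas, template)
        b1e = b1[:, None, :]
        b2e = b2[:, None, :]
        blocks = []
        for xd, yn, y0, n in groups:
            y = np.broadcast_to(yn, (g,) + yn.shape).copy()  # (G, S, n, Ny)
            y[:, :, :burn] = y0[None]
            for i, t in enumerate(range(burn, n)):
                pre = np.einsum("ghi,si->gsh", wa, xd[:, i]) + b1e
                if c.feedback_taps:
                    taps = y[:, :, t - lag_off, col_j]  # (G, S, Ny*Ty)
                    pre = pre - np.einsum("ghk,gsk->gsh", wb, taps)
                u = np.tanh(pre)
                y[:, :, t] = np.einsum("gjh,gsh->gsj", cw, u) + b2e
            blocks.append((y[:, :, burn:] - yn[None, :, burn:]).reshape(g, -1))
        return np.concatenate(blocks, axis=1)

    return residuals_batch


def _linear_warm_start(config: NarxConfig, template: NarxParameters,
                       x_design: np.ndarray, y_design: np.ndarray,
                       target: np.ndarray) -> np.ndarray | None:
    """Stable linear ARX decoder embedded in the tanh network's linear regime.

    The feedback is fixed to a leaky integrator -- weight 0.998 on each
    joint's first feedback tap, zero elsewhere -- which is stable by
    construction (free LS-fitted feedback invariably learns the anti-stable
    extrapolator). Under that backbone, the input map and intercept are fit
    per joint by ordinary least squares on y_j(t) - 0.998 y_j(t-m): the
    inputs absorb the velocity information, the leak bounds drift. The
    linear map is embedded with hidden pre-activations scaled into the
    near-linear region of tanh (one hidden unit per joint, output weights
    scaled inversely), giving a deterministic, data-driven,
    stability-guaranteed candidate for the closed-loop stage -- insurance
    against every random restart landing in a bad basin. Returns None for
    architectures it cannot represent.
    """
    h, ny, ty = config.n_hidden, config.n_outputs, config.feedback_taps
    nxt = config.n_inputs * config.input_taps
    if h < ny or ty < 1:
        return None
    leak = 0.998
    eps = 0.1  # hidden pre-activation scale: tanh(x) = x to ~0.3% at |x|<=0.1
    a_w = np.zeros((h, config.n_inputs, config.input_taps))
    b_w = np.zeros((h, ny, ty))
    c_w = np.zeros((ny, h))
    b1 = np.zeros(h)
    b2 = np.zeros(ny)
    ones = np.ones((x_design.shape[0], 1))
    for j in range(ny):
        w_fb = np.zeros(ty)
        w_fb[0] = leak
        fb = y_design[:, j * ty:(j + 1) * ty]
        design = np.concatenate([x_design, ones], axis=1)
        coef, *_ = np.linalg.lstsq(design, target[:, j] - fb @ w_fb,
                                   rcond=None)
        w_in, intercept = coef[:nxt], coef[-1]
        # normalize pre-activation amplitude into the tanh linear region
        pre = x_design @ w_in + fb @ w_fb + intercept
        scale = eps / max(np.abs(pre).max(), 1e-12)
        a_w[j] = (w_in * scale).reshape(config.n_inputs, config.input_taps)
        b_w[j, j] = -w_fb * scale  # minus: the hidden layer subtracts B taps
        b1[j] = intercept * scale
        c_w[j, j] = 1.0 / scale
    params = NarxParameters(
        config=config, A=a_w, B=b_w, C=c_w, b1=b1, b2=b2,
        input_scale=template.input_scale.copy(),
        output_offset=template.output_offset.copy(),
        output_scale=template.output_scale.copy(),
    )
    return _pack(params)


def _shooting_windows(segments: list[tuple[np.ndarray, np.ndarray]],
                      config: NarxConfig,
                      window_s: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Chop segments into multiple-shooting windows for closed-loop fitting.

    Full-trajectory closed-loop error surfaces are highly multimodal; fitting
    the closed loop over moderate windows, each re-initialized from measured
    burn-in samples, smooths the landscape while still penalizing unstable
    feedback. Consecutive windows overlap by the burn-in so every
    post-burn-in sample of the original segment contributes exactly one
    residual row.
    """
    burn = config.burn_in
    width = max(int(round(window_s / config.dt_s)), burn + 2)
    windows = []
    for env, ang in segments:
        n = env.shape[0]
        start = 0
        while start + burn < n:
            lo = max(start - burn, 0) if start else 0
            stop = min(start + width, n)
            if stop - lo > burn + 1:
                windows.append((env[lo:stop], ang[lo:stop]))
            start += width
    return windows


def _as_segments(envelopes, angles) -> list[tuple[np.ndarray, np.ndarray]]:
    if isinstance(envelopes, np.ndarray):
        envelopes, angles = [envelopes], [angles]
    if len(envelopes) != len(angles):
        raise InputError("need as many envelope segments as angle segments")
    segs = []
    for env, ang in zip(envelopes, angles):
        env = np.asarray(env, dtype=float)
        ang = np.asarray(ang, dtype=float)
        if env.shape[0] != ang.shape[0]:
            raise InputError("each segment needs aligned envelopes and angles")
        segs.append((env, ang))
    return segs


def fit_normalizers(params: NarxParameters,
                    segments: list[tuple[np.ndarray, np.ndarray]]) -> None:
    """Fit the affine normalizers on training segments only (in place)."""
    env_all = np.concatenate([e for e, _ in segments], axis=0)
    ang_all = np.concatenate([a for _, a in segments], axis=0)
    in_scale = env_all.max(axis=0)
    in_scale[in_scale <= 0] = 1.0
    lo, hi = ang_all.min(axis=0), ang_all.max(axis=0)
    out_scale = (hi - lo) / 2.0
    out_scale[out_scale <= 0] = 1.0
    params.input_scale = in_scale
    params.output_offset = (hi + lo) / 2.0
    params.output_scale = out_scale


def train(config: NarxConfig, train_envelopes, train_angles,
          opts: TrainOptions | None = None) -> tuple[NarxParameters, TrainReport]:
    """Fit the decoder by series-parallel (teacher-forced) Levenberg-Marquardt.

    ``train_envelopes`` / ``train_angles`` may be single matrices or lists of
    contiguous segments; delay lines are restarted at each segment boundary,
    so splicing non-adjacent data (as in cross-validation) never creates
    spurious lag vectors. Runs ``opts.restarts`` seeded initializations of
    teacher-forced LM, then (unless ``opts.closed_loop_iters`` is 0)
    continues LM on the closed-loop residual so the freely-running decoder
    itself fits the measured angles; the final model is chosen among the
    refined candidates by closed-loop error on an internal held-out slice of
    the training data (see TrainOptions.holdout_fraction).
    """
    opts = opts or TrainOptions()
    segments = _as_segments(train_envelopes, train_angles)
    burn = config.burn_in
    usable = [s for s in segments if s[0].shape[0] > burn]
    if not usable:
        raise TrainingError("no training segment longer than the burn-in")

    # carve an internal selection slice off the tail of the longest segment:
    # candidate models are ranked by closed-loop error on data the optimizer
    # never saw, which is the only reliable way to catch solutions that fit
    # the training trial's realized noise in their slow (drift) mode
    holdout = None
    full_segments = list(usable)
    if opts.closed_loop_iters > 0 and opts.holdout_fraction > 0:
        total_rows = sum(env.shape[0] for env, _ in usable)
        li = max(range(len(usable)), key=lambda i: usable[i][0].shape[0])
        env_l, ang_l = usable[li]
        n_l = env_l.shape[0]
        cut = int(round(opts.holdout_fraction * total_rows))
        cut = min(cut, n_l - (burn + 2))
        if cut >= burn + 2:
            holdout = (env_l[n_l - cut - burn:], ang_l[n_l - cut - burn:])
            usable[li] = (env_l[:n_l - cut], ang_l[:n_l - cut])

    template = init_parameters(config, 0)
    fit_normalizers(template, usable)

    x_blocks, y_blocks, targets = [], [], []
    for env, ang in usable:
        ts = np.arange(burn, env.shape[0])
        xn = template.normalize_inputs(env)
        yn = template.normalize_outputs(ang)
        x_blocks.append(_lagged(xn, ts, config.m, config.input_taps))
        y_blocks.append(_lagged(yn, ts, config.m, config.feedback_taps)
                        if config.feedback_taps else np.empty((ts.size, 0)))
        targets.append(yn[ts])
    x_design = np.concatenate(x_blocks, axis=0)
    y_design = np.concatenate(y_blocks, axis=0)
    target = np.concatenate(targets, axis=0)

    n_params = count_parameters(config)
    if x_design.shape[0] <= 10 * n_params:
        raise TrainingError(
            f"training length {x_design.shape[0]} must exceed 10 x "
            f"{n_params} parameters for identifiability"
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = _unpack(theta, template)
        return (_forward(p, x_design, y_design) - target).ravel()

    seeds = np.random.SeedSequence(opts.seed).generate_state(opts.restarts)
    open_fits = []  # (open_mse, idx, theta, trajectory, iters)
    for idx, restart_seed in enumerate(seeds):
        theta0 = _pack(init_parameters(config, int(restart_seed) % 2**31))
        theta, trajectory, iters = _levenberg_marquardt(residuals, theta0, opts)
        open_fits.append((trajectory[-1], idx, theta, trajectory, iters))
    total_iters = sum(f[4] for f in open_fits)

    cl_trajectory: list[float] = []
    if opts.closed_loop_iters > 0:
        # deterministic stable linear candidate joins the screening pool as
        # insurance against all random restarts refining into bad basins
        lin_theta = _linear_warm_start(config, template, x_design, y_design,
                                       target)
        lin_index = None
        if lin_theta is not None:
            lin_mse = float(np.mean(residuals(lin_theta) ** 2))
            lin_index = len(open_fits)
            open_fits.append((lin_mse, lin_index, lin_theta, [lin_mse], 0))
        windows = _shooting_windows(usable, config, opts.shooting_window_s)
        cl_batch = _make_closed_loop_residuals(template, windows,
                                               opts.init_jitter)

        def cl_residuals(th: np.ndarray) -> np.ndarray:
            return cl_batch(th)[0]

        def cl_jacobian(th: np.ndarray, r0: np.ndarray) -> np.ndarray:
            return _batched_jacobian(cl_batch, th, r0)

        # screen every restart closed-loop; open-loop loss cannot rank basins
        screen_iters = min(opts.screen_iters, opts.closed_loop_iters)
        screened = []
        for open_mse, idx, theta, trajectory, _ in open_fits:
            th, straj, n_it = _levenberg_marquardt(
                cl_residuals, theta, opts, max_iters=screen_iters,
                jac_fun=cl_jacobian)
            total_iters += n_it
            screened.append((straj[-1], idx, th, straj, open_mse, trajectory))
        screened.sort(key=lambda s: (s[0], s[1]))

        if opts.polish_iters > 0:
            p_windows = _shooting_windows(usable, config, opts.polish_window_s)
            p_batch = _make_closed_loop_residuals(template, p_windows,
                                                  opts.init_jitter)
            p_residuals = lambda th: p_batch(th)[0]
            p_jacobian = lambda th, r0: _batched_jacobian(p_batch, th, r0)
        # ranking metric: closed-loop error on the internal held-out slice
        # when available, otherwise full-horizon error on the training
        # segments (both simulated from measured burn-ins, no jitter)
        rank_batch = _make_closed_loop_residuals(
            template, [holdout] if holdout is not None else usable)

        def rank_metric(th: np.ndarray) -> float:
            return float(np.mean(rank_batch(th)[0] ** 2))

        # fully refine the best-screened candidates; short-horizon screening
        # cannot see slow drift. The stable linear candidate always gets a
        # refinement slot (guard against collectively bad restarts) and also
        # enters the final ranking unrefined, since refinement itself can
        # overfit the drift mode.
        refine_set = screened[:opts.refine_top_k]
        if lin_index is not None and all(s[1] != lin_index for s in refine_set):
            refine_set = refine_set + [s for s in screened
                                       if s[1] == lin_index]
        remaining = opts.closed_loop_iters - screen_iters
        finished = []
        for cl_mse, idx, theta, straj, open_mse, trajectory in refine_set:
            if remaining > 0:
                theta, cont_traj, n_it = _levenberg_marquardt(
                    cl_residuals, theta, opts, max_iters=remaining,
                    jac_fun=cl_jacobian)
                total_iters += n_it
                straj = straj + cont_traj[1:]
            if opts.polish_iters > 0:
                theta, p_traj, n_it = _levenberg_marquardt(
                    p_residuals, theta, opts, max_iters=opts.polish_iters,
                    jac_fun=p_jacobian)
                total_iters += n_it
                straj = p_traj
            rank = rank_metric(theta)
            finished.append((rank, idx, theta, straj, open_mse, trajectory))
        if lin_theta is not None:
            rank = rank_metric(lin_theta)
            finished.append((rank, lin_index, lin_theta, [lin_mse], lin_mse,
                             [lin_mse]))
        cl_mse, idx, theta, cl_trajectory, open_mse, trajectory = min(
            finished, key=lambda s: (s[0], s[1]))
        # final refit: the winner re-absorbs the held-out slice with one more
        # polish pass over the complete training segments
        if holdout is not None and opts.polish_iters > 0:
            r_windows = _shooting_windows(full_segments, config,
                                          opts.polish_window_s)
            r_batch = _make_closed_loop_residuals(template, r_windows,
                                                  opts.init_jitter)
            theta, r_traj, n_it = _levenberg_marquardt(
                lambda th: r_batch(th)[0], theta, opts,
                max_iters=opts.polish_iters,
                jac_fun=lambda th, r0: _batched_jacobian(r_batch, th, r0))
            total_iters += n_it
            cl_trajectory = r_traj
    else:
        open_mse, idx, theta, trajectory, _ = min(
            open_fits, key=lambda f: (f[0], f[1]))
    final_mse = cl_trajectory[-1] if cl_trajectory else open_mse

    params = _unpack(theta, template)
    report = TrainReport(final_mse=float(final_mse), iterations=total_iters,
                         restart_index_selected=idx,
                         mse_trajectory=[float(v) for v in trajectory],
                         closed_loop_mse_trajectory=[float(v) for v in cl_trajectory],
                         open_loop_mse=float(open_mse))
    return params, report


# -- serialization ----------------------------------------------------------

def params_to_dict(params: NarxParameters) -> dict:
    c = params.config
    return {
        "format_version": FORMAT_VERSION,
        "config": {
            "n_inputs": c.n_inputs, "n_outputs": c.n_outputs,
            "n_hidden": c.n_hidden, "input_taps": c.input_taps,
            "feedback_taps": c.feedback_taps, "m": c.m, "dt_s": c.dt_s,
            "hidden_activation": c.hidden_activation,
            "output_activation": c.output_activation,
        },
        "weights": {
            "A": params.A.tolist(), "B": params.B.tolist(),
            "C": params.C.tolist(), "b1": params.b1.tolist(),
            "b2": params.b2.tolist(),
        },
        "normalizers": {
            "input_scale": params.input_scale.tolist(),
            "output_offset": params.output_offset.tolist(),
            "output_scale": params.output_scale.tolist(),
        },
    }


def params_from_dict(doc: dict) -> NarxParameters:
    if doc.get("format_version") != FORMAT_VERSION:
        raise ParameterError(
            f"unsupported model format version {doc.get('format_version')!r}"
        )
    config = NarxConfig(**doc["config"])
    w, nrm = doc["weights"], doc["normalizers"]
    return NarxParameters(
        config=config,
        A=np.asarray(w["A"], dtype=float),
        B=np.asarray(w["B"], dtype=float).reshape(
            config.n_hidden, config.n_outputs, config.feedback_taps),
        C=np.asarray(w["C"], dtype=float),
        b1=np.asarray(w["b1"], dtype=float),
        b2=np.asarray(w["b2"], dtype=float),
        input_scale=np.asarray(nrm["input_scale"], dtype=float),
        output_offset=np.asarray(nrm["output_offset"], dtype=float),
        output_scale=np.asarray(nrm["output_scale"], dtype=float),
    )


def save_model(params: NarxParameters, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(params_to_dict(params), indent=2, sort_keys=True))
    return path


def load_model(path: str | Path) -> NarxParameters:
    return params_from_dict(json.loads(Path(path).read_text()))
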