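"""Synthetic arm plant: paired surface-EMG and joint-angle trials with known
ground truth.

The plant emulates the study conditions of self-paced horizontal-plane
reaching: a single ~3-minute trial, three joints (shoulder horizontal
ab/adduction, elbow flexion-extension, wrist flexion-extension) each moving
over a ~90 degree range at comfortable speeds strictly below 70 deg/s, with
six muscles (an agonist/antagonist pair per joint) whose activity precedes
motion by an electromechanical delay.

Generation is a three-stage cascade, each stage a pure function of
(config, seed):

1. Kinematics: concatenated minimum-jerk point-to-point reaches toward
   randomized targets inside each joint's range, separated by randomized
   0.5-2 s holds; all joints share the reach clock (as in concurrent
   multi-joint movements) but draw independent targets.
2. Activations: reciprocal velocity-proportional drive. The agonist of each
   pair is driven by the positive part of joint velocity and the antagonist
   by the negative part, on top of a small tonic baseline, with the drive
   *advanced* in time so that muscle activity leads motion.
3. EMG: per channel, a band-limited (20-450 Hz) zero-mean Gaussian carrier is
   amplitude-modulated by (noise_floor + activation) -- the standard surrogate
   for surface EMG interference patterns.

Timing convention: ``emd_ms`` is defined at the *envelope* level -- the
decoded-rate linear envelope leads joint velocity by exactly ``emd_ms``. The
causal envelope filter itself delays the modulation profile by its group
delay (~154 ms for the default order-6 / 4 Hz filter), so the underlying
neural drive is advanced by ``emd_ms`` plus that group delay. This makes the
plant decodable by construction: envelopes at time t - emd determine joint
velocity at time t up to the tonic floor, so a decoder whose prediction
interval equals ``emd_ms`` has access to exactly the information it needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .preprocess import DEFAULT_CUTOFF_HZ, DEFAULT_ORDER, envelope_group_delay
from .signal_io import TrialRecord

#: Fraction of max_speed_dps that reach peak velocities may actually use;
#: keeps the strict < max_speed_dps bound with a comfortable margin.
_SPEED_USE = 0.8

#: Minimum-jerk peak-velocity factor: v_peak = 1.875 * amplitude / duration.
_MINJERK_PEAK = 1.875


@dataclass
class ArmPlantConfig:
    """Generative settings for the synthetic arm plant.

    emd_ms is the envelope-to-motion lead (electromechanical delay) described
    in the module docstring; envelope_order / envelope_cutoff_hz describe the
    envelope extractor the plant is paired with (used only to compensate its
    group delay inside the drive stage).
    """

    duration_s: float = 180.0
    fs_raw: float = 1000.0
    joint_range_deg: tuple[float, float, float] = (90.0, 90.0, 90.0)
    max_speed_dps: float = 70.0
    emd_ms: float = 100.0
    carrier_band_hz: tuple[float, float] = (20.0, 450.0)
    noise_floor: float = 0.02
    tonic_level: float = 0.05
    emg_amplitude_mv: float = 0.5
    envelope_order: int = DEFAULT_ORDER
    envelope_cutoff_hz: float = DEFAULT_CUTOFF_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 30:
            raise ParameterError("duration_s must be >= 30 s")
        if self.fs_raw <= 0:
            raise ParameterError("fs_raw must be positive")
        if self.max_speed_dps <= 0:
            raise ParameterError("max_speed_dps must be positive")
        if self.emd_ms < 0:
            raise ParameterError("emd_ms must be nonnegative")
        lo, hi = self.carrier_band_hz
        if not 0 < lo < hi < self.fs_raw / 2:
            raise ParameterError("carrier band must satisfy 0 < lo < hi < Nyquist")
        if not 0 <= self.noise_floor < 1:
            raise ParameterError("noise_floor must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_raw))

    def drive_advance_s(self) -> float:
        """Neural-drive lead over motion: emd plus envelope-filter group delay."""
        return self.emd_ms / 1000.0 + envelope_group_delay(
            self.envelope_order, self.envelope_cutoff_hz
        )


def _rng(cfg: ArmPlantConfig, stream: int) -> np.random.Generator:
    # independent, reproducible sub-streams for kinematics (0) and EMG (1)
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def _minimum_jerk(n: int) -> np.ndarray:
    """Normalized minimum-jerk position profile on n samples, s(0)=0, s(1)=1."""
    u = np.linspace(0.0, 1.0, n, endpoint=True)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def generate_kinematics(cfg: ArmPlantConfig) -> np.ndarray:
    """Joint-angle traces [n x 3] in degrees at fs_raw.

    Reaches last 1-2 s (stretched when needed so that every joint's minimum-
    jerk peak velocity stays below 0.8 * max_speed_dps), holds last 0.5-2 s,
    targets are drawn uniformly inside the central 90% of each joint's range.
    """
    rng = _rng(cfg, 0)
    fs = cfg.fs_raw
    ranges = np.asarray(cfg.joint_range_deg, dtype=float)
    n_total = cfg.n_samples
    v_cap = _SPEED_USE * cfg.max_speed_dps

    current = ranges / 2.0
    blocks: list[np.ndarray] = []
    n_done = 0
    while n_done < n_total:
        hold_n = int(round(rng.uniform(0.5, 2.0) * fs))
        blocks.append(np.tile(current, (hold_n, 1)))
        n_done += hold_n
        if n_done >= n_total:
            break
        targets = rng.uniform(0.05, 0.95, size=3) * ranges
        deltas = targets - current
        d_max = np.abs(deltas).max()
        duration = max(rng.uniform(1.0, 2.0), _MINJERK_PEAK * d_max / v_cap)
        reach_n = max(int(round(duration * fs)), 2)
        s = _minimum_jerk(reach_n)
        blocks.append(current[None, :] + s[:, None] * deltas[None, :])
        current = targets
        n_done += reach_n
    return np.concatenate(blocks, axis=0)[:n_total]


def activations_from_kinematics(angles: np.ndarray, cfg: ArmPlantConfig) -> np.ndarray:
    """Muscle activations [n x 6] in [0, 1] from joint-angle traces at fs_raw.

    Reciprocal drive: channel 2j is the agonist of joint j (positive part of
    joint velocity), channel 2j+1 the antagonist (negative part), both scaled
    by 1/max_speed_dps and riding on the tonic baseline. The drive is advanced
    by ``cfg.drive_advance_s()`` so activity leads motion (see module
    docstring for the timing convention). Channel order matches the recorded
    muscle set: shoulder pair, elbow pair, wrist pair.
    """
    angles = np.asarray(angles, dtype=float)
    n, n_joints = angles.shape
    fs = cfg.fs_raw
    vel = np.gradient(angles, axis=0) * fs  # deg/s
    adv = int(round(cfg.drive_advance_s() * fs))
    if adv > 0:
        vel = np.concatenate([vel[adv:], np.tile(vel[-1], (min(adv, n), 1))], axis=0)[:n]
    gain = 1.0 / cfg.max_speed_dps
    act = np.empty((n, 2 * n_joints))
    act[:, 0::2] = cfg.tonic_level + gain * np.maximum(vel, 0.0)
    act[:, 1::2] = cfg.tonic_level + gain * np.maximum(-vel, 0.0)
    return np.clip(act, 0.0, 1.0)


def synthesize_emg(activations: np.ndarray, cfg: ArmPlantConfig) -> np.ndarray:
    """Raw EMG [n x 6] in mV at fs_raw by amplitude-modulating a band-limited
    Gaussian carrier with (noise_floor + activation)."""
    act = np.asarray(activations, dtype=float)
    if act.size and (act.min() < 0 or act.max() > 1):
        raise ParameterError("activations must lie in [0, 1]")
    rng = _rng(cfg, 1)
    white = rng.standard_normal(act.shape)
    sos = sps.butter(4, cfg.carrier_band_hz, btype="bandpass", fs=cfg.fs_raw,
                     output="sos")
    carrier = sps.sosfiltfilt(sos, white, axis=0)
    carrier /= np.sqrt(np.mean(carrier**2, axis=0, keepdims=True))
    return cfg.emg_amplitude_mv * carrier * (cfg.noise_floor + act)


def generate_trial(cfg: ArmPlantConfig) -> TrialRecord:
    """Compose the cascade into a synchronized TrialRecord (trigger at 0)."""
    angles = generate_kinematics(cfg)
    activations = activations_from_kinematics(angles, cfg)
    emg = synthesize_emg(activations, cfg)
    return TrialRecord(emg=emg, angles=angles, fs=cfg.fs_raw, trigger_index=0)
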