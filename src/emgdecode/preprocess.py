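"""EMG linear-envelope extraction and decimation to the decoding rate.

The envelope chain is the standard one for myoelectric decoding: full-wave
rectification followed by a causal low-pass Butterworth filter (default 6th
order, 4 Hz cutoff), then plain decimation to the decoding rate (default
20 Hz). Joint angles are decimated without additional filtering: self-paced
reaching (< 70 deg/s) is band-limited far below the 10 Hz Nyquist of the
decoded rate, and the 4 Hz envelope is likewise already band-limited, so no
anti-alias stage is needed.

Filtering is single-pass (causal), not zero-phase: the decoder targets
real-time robot control where future samples are unavailable. A causal
Butterworth carries a group delay (about 154 ms at DC for order 6 / 4 Hz,
see :func:`envelope_group_delay`); the lag structure of the decoder absorbs
it, and the synthetic plant accounts for it explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DataError, ParameterError
from .signal_io import CHANNEL_NAMES, JOINT_NAMES, TrialRecord

DEFAULT_ORDER = 6
DEFAULT_CUTOFF_HZ = 4.0
DEFAULT_FS_OUT = 20.0


@dataclass
class EnvelopeTrial:
    """Preprocessed trial at the decoding rate: envelopes (>= 0) and angles."""

    envelopes: np.ndarray
    angles: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    joint_names: tuple[str, ...] = JOINT_NAMES

    def __post_init__(self) -> None:
        self.envelopes = np.asarray(self.envelopes, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.envelopes.ndim != 2 or self.angles.ndim != 2:
            raise DataError("envelopes and angles must be 2-D")
        if self.envelopes.shape[0] != self.angles.shape[0]:
            raise DataError("envelopes and angles must have equal length")
        if not self.fs > 0:
            raise ParameterError("fs must be positive")
        if self.envelopes.size and self.envelopes.min() < 0:
            raise DataError("envelopes must be nonnegative")

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def n_steps(self) -> int:
        return self.envelopes.shape[0]


def rectify(signal: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(signal, dtype=float))


def design_envelope_filter(fs: float, order: int = DEFAULT_ORDER,
                           cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> np.ndarray:
    """Second-order sections of the envelope low-pass filter."""
    if not cutoff_hz < fs / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {fs / 2} Hz"
        )
    if order < 1:
        raise ParameterError("filter order must be >= 1")
    return sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")


def envelope_group_delay(order: int = DEFAULT_ORDER,
                         cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> float:
    """Low-frequency group delay of the causal envelope filter, in seconds.

    Computed from the analog Butterworth prototype: for unit-radius poles
    ``p_k``, the DC group delay is ``sum(-Re p_k) / omega_c``. For the default
    order-6 / 4 Hz filter this is about 0.154 s. Signals well below the cutoff
    (reach kinematics live below ~2 Hz) are delayed by essentially this amount.
    """
    if order < 1 or cutoff_hz <= 0:
        raise ParameterError("order must be >= 1 and cutoff positive")
    poles = sps.buttap(order)[1]
    return float(np.sum(-poles.real) / (2.0 * np.pi * cutoff_hz))


def linear_envelope(signal: np.ndarray, fs: float, order: int = DEFAULT_ORDER,
                    cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> np.ndarray:
    """Causal Butterworth low-pass of a rectified signal, clipped at 0.

    The filter state is initialized to the steady state matching the first
    input sample, which suppresses start-up transients on short signals.
    Negative post-filter transients are clipped to 0 so the output remains a
    valid activation-intensity proxy.
    """
    x = np.asarray(signal, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.shape[0] == 0:
        raise DataError("cannot filter an empty signal")
    sos = design_envelope_filter(fs, order, cutoff_hz)
    zi = sps.sosfilt_zi(sos)  # (n_sections, 2) for a unit step
    zi_full = zi[:, :, None] * x[0][None, None, :]
    y, _ = sps.sosfilt(sos, x, axis=0, zi=zi_full)
    y = np.clip(y, 0.0, None)
    return y[:, 0] if squeeze else y


def decimate_to(signal: np.ndarray, fs_in: float, fs_out: float = DEFAULT_FS_OUT) -> np.ndarray:
    """Keep every (fs_in/fs_out)-th sample starting at index 0.

    No extra anti-alias filter is applied; callers are responsible for the
    input being band-limited below fs_out/2 (true for 4 Hz envelopes and for
    self-paced reach kinematics).
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ParameterError("sampling rates must be positive")
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ParameterError(
            f"fs_out={fs_out} must divide fs_in={fs_in} exactly (got ratio {ratio})"
        )
    step = int(round(ratio))
    return np.asarray(signal, dtype=float)[::step]


def preprocess_trial(trial: TrialRecord, order: int = DEFAULT_ORDER,
                     cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                     fs_out: float = DEFAULT_FS_OUT) -> EnvelopeTrial:
    """Full chain: rectify -> linear envelope -> decimate, angles decimated too.

    Per-channel envelope scaling is deliberately deferred to training so that
    normalizers are fitted on training folds only.
    """
    envelopes_raw = linear_envelope(rectify(trial.emg), trial.fs, order, cutoff_hz)
    envelopes = decimate_to(envelopes_raw, trial.fs, fs_out)
    angles = decimate_to(trial.angles, trial.fs, fs_out)
    return EnvelopeTrial(
        envelopes=envelopes,
        angles=angles,
        fs=fs_out,
        channel_names=trial.channel_names,
        joint_names=trial.joint_names,
    )
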