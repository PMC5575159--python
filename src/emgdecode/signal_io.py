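"""Reading, writing and synchronizing paired EMG / joint-angle recordings.

A trial is a synchronized pair of matrices sampled at a common rate: six
surface-EMG channels (millivolts) and three joint angles (degrees, shoulder
horizontal ab/adduction, elbow flexion-extension, wrist flexion-extension).
Two on-disk formats are supported:

* CSV with header ``time,emg_adelt,emg_pdelt,emg_bic,emg_tri,emg_fcr,emg_ecr,
  ang_shoulder,ang_elbow,ang_wrist``; time in seconds from trial start.
  Channel order follows the electrode numbering on the arm: anterior deltoid,
  posterior deltoid, biceps brachii, triceps (long head), flexor carpi
  radialis, extensor carpi radialis.
* HDF5 with datasets ``/emg`` and ``/angles`` and root attributes ``fs``,
  ``channel_names``, ``joint_names`` (and ``trigger_index`` when present).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, FormatError, SamplingError

CHANNEL_NAMES: tuple[str, ...] = ("adelt", "pdelt", "bic", "tri", "fcr", "ecr")
JOINT_NAMES: tuple[str, ...] = ("shoulder", "elbow", "wrist")
EMG_COLUMNS: tuple[str, ...] = tuple(f"emg_{c}" for c in CHANNEL_NAMES)
ANGLE_COLUMNS: tuple[str, ...] = tuple(f"ang_{j}" for j in JOINT_NAMES)
CSV_COLUMNS: tuple[str, ...] = ("time",) + EMG_COLUMNS + ANGLE_COLUMNS

#: Maximum allowed relative deviation of the time step from its mean (1 ppm).
MAX_CLOCK_JITTER = 1e-6


@dataclass
class TrialRecord:
    """A synchronized raw recording: EMG in mV, joint angles in degrees.

    ``trigger_index`` is the sample index of the synchronization trigger, when
    one was recorded; streams aligned by :func:`align_streams` have it at 0.
    """

    emg: np.ndarray
    angles: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    joint_names: tuple[str, ...] = JOINT_NAMES
    trigger_index: int | None = None

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.emg.ndim != 2 or self.angles.ndim != 2:
            raise DataError("emg and angles must be 2-D [n_samples x n_columns]")
        if self.emg.shape[0] != self.angles.shape[0]:
            raise DataError(
                f"emg has {self.emg.shape[0]} rows but angles has "
                f"{self.angles.shape[0]}; streams must be aligned"
            )
        if not self.fs > 0:
            raise SamplingError(f"sampling rate must be positive, got {self.fs}")
        if not np.isfinite(self.emg).all() or not np.isfinite(self.angles).all():
            raise DataError("non-finite values in trial data")
        if len(self.channel_names) != self.emg.shape[1]:
            raise FormatError("channel_names length does not match EMG columns")
        if len(self.joint_names) != self.angles.shape[1]:
            raise FormatError("joint_names length does not match angle columns")

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.emg.shape[1]

    @property
    def n_joints(self) -> int:
        return self.angles.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "hdf5"):
            raise FormatError(f"unknown format {fmt!r}; expected 'csv' or 'hdf5'")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise FormatError(f"cannot infer format from suffix {suffix!r}")


def _fs_from_time(time: np.ndarray) -> float:
    if time.size < 2:
        raise SamplingError("need at least 2 samples to infer the sampling rate")
    steps = np.diff(time)
    mean_step = float(steps.mean())
    if mean_step <= 0:
        raise SamplingError("time column is not strictly increasing")
    if np.abs(steps - mean_step).max() > MAX_CLOCK_JITTER * mean_step:
        raise SamplingError(
            "non-uniform time step (beyond 1 ppm); resample before loading"
        )
    fs = 1.0 / mean_step
    # snap to an integer rate when the time column was printed at finite precision
    if abs(fs - round(fs)) < 1e-6 * fs:
        fs = float(round(fs))
    return fs


def read_trial(path: str | Path, format: str | None = None) -> TrialRecord:
    """Load a trial from CSV or HDF5 (format inferred from the suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        frame = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing columns in {path.name}: {missing}")
        extra = [c for c in frame.columns if c not in CSV_COLUMNS]
        if extra:
            raise FormatError(f"unexpected columns in {path.name}: {extra}")
        if frame.isna().any().any():
            raise DataError(f"NaN cells in {path.name}")
        fs = _fs_from_time(frame["time"].to_numpy(dtype=float))
        return TrialRecord(
            emg=frame[list(EMG_COLUMNS)].to_numpy(dtype=float),
            angles=frame[list(ANGLE_COLUMNS)].to_numpy(dtype=float),
            fs=fs,
        )
    with h5py.File(path, "r") as f:
        if "emg" not in f or "angles" not in f:
            raise FormatError(f"{path.name} lacks /emg or /angles datasets")
        emg = np.asarray(f["emg"], dtype=float)
        angles = np.asarray(f["angles"], dtype=float)
        if "fs" not in f.attrs:
            raise FormatError(f"{path.name} lacks the 'fs' attribute")
        fs = float(f.attrs["fs"])
        channel_names = tuple(str(c) for c in f.attrs.get("channel_names", CHANNEL_NAMES))
        joint_names = tuple(str(j) for j in f.attrs.get("joint_names", JOINT_NAMES))
        trigger = f.attrs.get("trigger_index", None)
        trigger_index = int(trigger) if trigger is not None else None
    if not np.isfinite(emg).all() or not np.isfinite(angles).all():
        raise DataError(f"non-finite values in {path.name}")
    return TrialRecord(
        emg=emg,
        angles=angles,
        fs=fs,
        channel_names=channel_names,
        joint_names=joint_names,
        trigger_index=trigger_index,
    )


def write_trial(trial: TrialRecord, path: str | Path, format: str | None = None) -> Path:
    """Write a trial to CSV or HDF5; the result round-trips through read_trial."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if trial.n_samples == 0:
        raise DataError("refusing to write an empty trial (0 samples)")
    if fmt == "csv":
        if trial.n_channels != len(EMG_COLUMNS) or trial.n_joints != len(ANGLE_COLUMNS):
            raise FormatError(
                "CSV layout is fixed to 6 EMG + 3 angle columns; "
                "use HDF5 for other shapes"
            )
        time = np.arange(trial.n_samples) / trial.fs
        frame = pd.DataFrame(
            np.column_stack([time, trial.emg, trial.angles]), columns=list(CSV_COLUMNS)
        )
        frame.to_csv(path, index=False, float_format="%.12g")
        return path
    with h5py.File(path, "w") as f:
        f.create_dataset("emg", data=trial.emg)
        f.create_dataset("angles", data=trial.angles)
        f.attrs["fs"] = trial.fs
        f.attrs["channel_names"] = list(trial.channel_names)
        f.attrs["joint_names"] = list(trial.joint_names)
        if trial.trigger_index is not None:
            f.attrs["trigger_index"] = int(trial.trigger_index)
    return path


def align_streams(
    emg_stream: np.ndarray,
    angle_stream: np.ndarray,
    emg_trigger: int,
    angle_trigger: int,
    fs: float,
    channel_names: tuple[str, ...] = CHANNEL_NAMES,
    joint_names: tuple[str, ...] = JOINT_NAMES,
) -> TrialRecord:
    """Synchronize two equally-sampled streams on a shared trigger event.

    Both streams are cropped so their trigger samples coincide at index 0 and
    truncated to the shorter remaining length. Idempotent when both triggers
    are already 0.
    """
    emg_stream = np.asarray(emg_stream, dtype=float)
    angle_stream = np.asarray(angle_stream, dtype=float)
    for name, trig, n in (
        ("EMG", emg_trigger, emg_stream.shape[0]),
        ("angle", angle_trigger, angle_stream.shape[0]),
    ):
        if not 0 <= trig < n:
            raise AlignmentError(
                f"{name} trigger index {trig} outside stream of length {n}"
            )
    emg_cut = emg_stream[emg_trigger:]
    ang_cut = angle_stream[angle_trigger:]
    n = min(emg_cut.shape[0], ang_cut.shape[0])
    return TrialRecord(
        emg=emg_cut[:n],
        angles=ang_cut[:n],
        fs=fs,
        channel_names=channel_names,
        joint_names=joint_names,
        trigger_index=0,
    )
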