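"""Reading and writing cuff recordings and cohort metadata.

A recording couples the Korotkoff microphone channel (arbitrary sensor
units) with the cuff-pressure channel (mmHg), both sampled at the same
rate.  Sample indices are 0-based and every window in the package is
half-open ``[start, end)``.

Containers are deliberately plain: WAV (float32 or PCM-16; channel 0 =
sound, channel 1 = pressure) or CSV with columns ``time_s, sound,
pressure_mmhg``.  Cohort metadata travels as a CSV with one row per
subject.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Recording",
    "Subject",
    "read_recording",
    "write_recording",
    "load_cohort",
    "write_cohort",
]

#: columns a cohort CSV must carry (``bapwv`` is optional)
COHORT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "bmi",
    "sbp",
    "dbp",
    "heart_rate",
    "diabetes",
    "smoking",
    "group_label",
]

GROUP_LABELS = {"older", "young", "high_baPWV", "low_baPWV", "none"}


@dataclass
class Recording:
    """Two-channel cuff recording: Korotkoff sound + cuff pressure.

    Parameters
    ----------
    sound : ndarray
        Microphone samples, arbitrary linear amplitude units.
    cuff_pressure : ndarray
        Cuff pressure in mmHg, same length and rate as ``sound``.
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Opaque subject identifier.
    annotations : (int, int), optional
        A marked Korotkoff window as a half-open sample range.
    """

    sound: np.ndarray
    cuff_pressure: np.ndarray
    fs: float
    subject_id: str = ""
    annotations: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.sound = np.asarray(self.sound, dtype=float)
        self.cuff_pressure = np.asarray(self.cuff_pressure, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.sound.ndim != 1 or self.sound.size < 1:
            raise ValueError("sound must be a non-empty 1-D array")
        if self.cuff_pressure.shape != self.sound.shape:
            raise ValueError(
                "channel length mismatch: sound has "
                f"{self.sound.size} samples, pressure {self.cuff_pressure.size}"
            )
        if not (np.all(np.isfinite(self.sound)) and np.all(np.isfinite(self.cuff_pressure))):
            raise ValueError("recording contains non-finite samples")
        if self.annotations is not None:
            start, end = self.annotations
            if not (0 <= start < end <= self.sound.size):
                raise ValueError(
                    f"annotation window [{start}, {end}) outside recording "
                    f"of length {self.sound.size}"
                )
            self.annotations = (int(start), int(end))

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.sound.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from record start."""
        return np.arange(self.sound.size) / self.fs


@dataclass
class Subject:
    """Per-subject covariates used by the statistical pipeline."""

    subject_id: str
    age: float
    sex: str  # "male" | "female"
    bmi: float
    sbp: float
    dbp: float
    heart_rate: float
    diabetes: bool
    smoking: bool
    group_label: str = "none"
    bapwv: Optional[float] = None  # cm/s

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"subject {self.subject_id}: age must be positive")
        if not (self.sbp > self.dbp > 0):
            raise ValueError(
                f"subject {self.subject_id}: requires sbp > dbp > 0, "
                f"got sbp={self.sbp}, dbp={self.dbp}"
            )
        if self.heart_rate <= 0:
            raise ValueError(f"subject {self.subject_id}: heart rate must be positive")
        if self.bapwv is not None and self.bapwv <= 0:
            raise ValueError(f"subject {self.subject_id}: bapwv must be positive")
        if self.group_label not in GROUP_LABELS:
            raise ValueError(
                f"subject {self.subject_id}: unknown group label {self.group_label!r}"
            )


def write_recording(rec: Recording, path: str, format: str = "wav") -> str:
    """Write a recording to ``path`` as WAV (float32 stereo) or CSV.

    WAV stores sound in channel 0 and pressure in channel 1 as float32,
    so amplitudes round-trip to single precision with no headroom rule.
    CSV stores ``time_s, sound, pressure_mmhg`` at full precision.
    """
    if rec.sound.size == 0:
        raise ValueError("refusing to write a zero-length recording")
    if format == "wav":
        data = np.stack([rec.sound, rec.cuff_pressure], axis=1).astype(np.float32)
        wavfile.write(path, int(round(rec.fs)), data)
    elif format == "csv":
        df = pd.DataFrame(
            {
                "time_s": rec.times,
                "sound": rec.sound,
                "pressure_mmhg": rec.cuff_pressure,
            }
        )
        df.to_csv(path, index=False, float_format="%.9g")
    else:
        raise ValueError(f"unknown recording format {format!r}")
    return path


def read_recording(path: str, format: Optional[str] = None, subject_id: str = "") -> Recording:
    """Read a recording written by :func:`write_recording`.

    For WAV, the sampling rate comes from the RIFF header; integer PCM
    is rescaled to [-1, 1).  For CSV, the rate is inferred from the
    (required, uniform) ``time_s`` column.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if str(path).lower().endswith(".csv") else "wav"
    if format == "wav":
        fs, data = wavfile.read(path)
        data = np.atleast_2d(data.T).T  # mono -> (n, 1)
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
        else:
            data = data.astype(float)
        sound = data[:, 0]
        pressure = data[:, 1] if data.shape[1] > 1 else np.zeros_like(sound)
        return Recording(sound, pressure, float(fs), subject_id=subject_id)
    if format == "csv":
        df = pd.read_csv(path)
        for col in ("time_s", "sound", "pressure_mmhg"):
            if col not in df.columns:
                raise ValueError(f"recording CSV missing column {col!r}")
        n_sound = df["sound"].notna().sum()
        n_press = df["pressure_mmhg"].notna().sum()
        if n_sound != n_press:
            raise ValueError(
                f"channel length mismatch: {n_sound} sound vs {n_press} pressure samples"
            )
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise ValueError("need at least two samples to infer the sampling rate")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time_s column is not uniformly sampled")
        fs = 1.0 / dt[0]
        return Recording(
            df["sound"].to_numpy(float),
            df["pressure_mmhg"].to_numpy(float),
            fs,
            subject_id=subject_id,
        )
    raise ValueError(f"unknown recording format {format!r}")


def _parse_bool(value, column: str, row: int) -> bool:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in {"1", "yes", "true"}:
            return True
        if v in {"0", "no", "false"}:
            return False
        raise ValueError(f"row {row}: cannot parse {column}={value!r} as a boolean")
    if value in (0, 1, True, False) or value in (0.0, 1.0):
        return bool(value)
    raise ValueError(f"row {row}: cannot parse {column}={value!r} as a boolean")


def load_cohort(path: str) -> list[Subject]:
    """Load per-subject metadata from a cohort CSV.

    The header must name every mandatory column; ``bapwv`` is optional
    and may be blank per row.  Booleans accept 0/1/yes/no.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing mandatory column(s): {missing}")
    subjects: list[Subject] = []
    for i, row in df.iterrows():
        for col in ("age", "bmi", "sbp", "dbp", "heart_rate"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise ValueError(f"row {i}: non-numeric {col}={row[col]!r}") from None
        bapwv = None
        if "bapwv" in df.columns and pd.notna(row["bapwv"]):
            bapwv = float(row["bapwv"])
        try:
            subjects.append(
                Subject(
                    subject_id=str(row["subject_id"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]).strip().lower(),
                    bmi=float(row["bmi"]),
                    sbp=float(row["sbp"]),
                    dbp=float(row["dbp"]),
                    heart_rate=float(row["heart_rate"]),
                    diabetes=_parse_bool(row["diabetes"], "diabetes", i),
                    smoking=_parse_bool(row["smoking"], "smoking", i),
                    group_label=str(row["group_label"]),
                    bapwv=bapwv,
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
    return subjects


def write_cohort(subjects: Sequence[Subject], path: str) -> str:
    """Write subjects to a cohort CSV readable by :func:`load_cohort`."""
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex,
                "bmi": s.bmi,
                "sbp": s.sbp,
                "dbp": s.dbp,
                "heart_rate": s.heart_rate,
                "diabetes": int(s.diabetes),
                "smoking": int(s.smoking),
                "group_label": s.group_label,
                "bapwv": "" if s.bapwv is None else s.bapwv,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
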