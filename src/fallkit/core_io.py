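"""Domain types, session file I/O and faller labelling.

Axis convention (fixed throughout the package): x = anteroposterior,
y = mediolateral, z = vertical for an upright subject.  Canonical units are
m/s^2 for acceleration and deg/s for angular velocity; orientation angles
are in degrees.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Location",
    "Subtest",
    "FallStatus",
    "SensorRecording",
    "Session",
    "SubjectRecord",
    "AppLog",
    "CRTTrial",
    "classify_fall_status",
    "read_session",
    "write_session",
    "read_cohort_table",
    "read_app_log",
    "write_app_log",
    "FormatError",
    "SamplingError",
    "ValidationError",
]

#: tolerance on successive time-step deviations, seconds
TIME_UNIFORMITY_TOL = 1e-6


class FormatError(ValueError):
    """A session/log file does not conform to the columnar format."""


class SamplingError(ValueError):
    """Timestamps are not uniform at the declared rate (e.g. dropped samples)."""

    def __init__(self, msg: str, gap_indices=None):
        super().__init__(msg)
        self.gap_indices = list(gap_indices) if gap_indices is not None else []


class ValidationError(ValueError):
    """A domain invariant is violated."""


class Location(str, enum.Enum):
    LOW_BACK = "low_back"
    LEFT_UPPER_LEG = "left_upper_leg"
    RIGHT_UPPER_LEG = "right_upper_leg"
    LEFT_LOWER_LEG = "left_lower_leg"
    RIGHT_LOWER_LEG = "right_lower_leg"


class Subtest(str, enum.Enum):
    SIT_EO_FIRM = "SIT_EO_FIRM"
    SIT_EC_FIRM = "SIT_EC_FIRM"
    SIT_EO_FOAM = "SIT_EO_FOAM"
    SIT_EC_FOAM = "SIT_EC_FOAM"
    LOS = "LOS"
    STS5 = "STS5"
    TUG = "TUG"
    MF_FLEXION = "MF_FLEXION"
    MF_EXTENSION = "MF_EXTENSION"


class FallStatus(str, enum.Enum):
    FALLER = "faller"
    NON_FALLER = "non_faller"


@dataclass
class SensorRecording:
    """Synchronized 9-DOF time series from one sensor location.

    ``acc`` and ``gyro`` are (n, 3) arrays in sensor frame (columns x, y, z);
    ``mag`` and ``orientation`` (roll, pitch, yaw in deg) are optional.
    """

    location: Location
    time: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    sampling_rate: float = 100.0
    mag: Optional[np.ndarray] = None
    orientation: Optional[np.ndarray] = None

    def __post_init__(self):
        self.location = Location(self.location)
        self.time = np.asarray(self.time, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        n = len(self.time)
        for name in ("acc", "gyro", "mag", "orientation"):
            arr = getattr(self, name)
            if arr is None:
                continue
            if arr.shape != (n, 3):
                raise ValidationError(
                    f"{name} shape {arr.shape} does not match {n} samples x 3 axes"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite samples in {name}")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise SamplingError(
                    "time must be strictly increasing",
                    gap_indices=np.nonzero(dt <= 0)[0],
                )
            expected = 1.0 / self.sampling_rate
            bad = np.nonzero(np.abs(dt - expected) > max(TIME_UNIFORMITY_TOL, 1e-9 * expected))[0]
            if bad.size:
                raise SamplingError(
                    f"non-uniform sampling at declared {self.sampling_rate} Hz: "
                    f"{bad.size} gap(s) at indices {bad[:10].tolist()}",
                    gap_indices=bad,
                )


@dataclass
class Session:
    """All recordings plus metadata for one subject performing one subtest."""

    subject_id: str
    subtest: Subtest
    recordings: dict[Location, SensorRecording]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.subtest = Subtest(self.subtest)
        self.recordings = {Location(k): v for k, v in self.recordings.items()}

    def recording(self, location: Location) -> SensorRecording:
        loc = Location(location)
        if loc not in self.recordings:
            raise ValidationError(
                f"session {self.subject_id}/{self.subtest.value} has no recording "
                f"for location {loc.value}"
            )
        return self.recordings[loc]


@dataclass
class SubjectRecord:
    """Demographics and fall history for one subject."""

    subject_id: str
    age: float
    height_cm: float
    weight_kg: float
    n_falls_past_year: int
    injurious_fall_past_year: bool

    def __post_init__(self):
        if self.n_falls_past_year < 0:
            raise ValidationError("n_falls_past_year must be >= 0")

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    @property
    def fall_status(self) -> FallStatus:
        return classify_fall_status(self.n_falls_past_year, self.injurious_fall_past_year)


@dataclass
class CRTTrial:
    n_alternatives: int
    reaction_time: float
    correct: bool

    def __post_init__(self):
        if self.n_alternatives < 1:
            raise ValidationError("n_alternatives must be >= 1")
        if self.reaction_time <= 0:
            raise ValidationError("reaction_time must be positive")


@dataclass
class AppLog:
    """Numeric log from a tablet subtest: choice-reaction trials or scale items."""

    kind: str  # "CRT" | "FES"
    crt_trials: list[CRTTrial] = field(default_factory=list)
    fes_items: list[int] = field(default_factory=list)
    fes_item_range: tuple[int, int] = (1, 4)
    fes_n_items: int = 7

    def __post_init__(self):
        if self.kind not in ("CRT", "FES"):
            raise ValidationError(f"unknown app log kind {self.kind!r}")
        lo, hi = self.fes_item_range
        for s in self.fes_items:
            if not lo <= s <= hi:
                raise ValidationError(f"FES item score {s} outside range [{lo}, {hi}]")


def classify_fall_status(n_falls_past_year: int, injurious_fall_past_year: bool) -> FallStatus:
    """Label a subject from fall history in the year before assessment.

    Faller: multiple falls, or at least one fall that was injurious enough to
    require medical attention.  Everyone else is a non-faller.
    """
    if n_falls_past_year < 0:
        raise ValidationError("n_falls_past_year must be >= 0")
    if n_falls_past_year >= 2 or (injurious_fall_past_year and n_falls_past_year >= 1):
        return FallStatus.FALLER
    return FallStatus.NON_FALLER


# ---------------------------------------------------------------------------
# Session file format: UTF-8 CSV, one file per subject x subtest.  Metadata is
# carried in leading '#'-prefixed YAML comment lines; data columns are time_s,
# location, acc_x..z, gyro_x..z, optional mag_x..z and roll/pitch/yaw_deg.
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = [
    "time_s", "location",
    "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
]
_MAG_COLUMNS = ["mag_x", "mag_y", "mag_z"]
_ORI_COLUMNS = ["roll_deg", "pitch_deg", "yaw_deg"]


def write_session(session: Session, path) -> Path:
    """Serialize a session to the columnar CSV format; returns the path."""
    if not session.recordings:
        raise ValidationError("cannot write a session with no recordings")
    path = Path(path)
    frames = []
    any_mag = any(r.mag is not None for r in session.recordings.values())
    any_ori = any(r.orientation is not None for r in session.recordings.values())
    for loc, rec in session.recordings.items():
        df = pd.DataFrame({"time_s": rec.time, "location": loc.value})
        for i, ax in enumerate("xyz"):
            df[f"acc_{ax}"] = rec.acc[:, i]
        for i, ax in enumerate("xyz"):
            df[f"gyro_{ax}"] = rec.gyro[:, i]
        if any_mag:
            for i, ax in enumerate("xyz"):
                df[f"mag_{ax}"] = rec.mag[:, i] if rec.mag is not None else np.nan
        if any_ori:
            for i, name in enumerate(_ORI_COLUMNS):
                df[name] = rec.orientation[:, i] if rec.orientation is not None else np.nan
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)

    meta = dict(session.metadata)
    meta["subject_id"] = session.subject_id
    meta["subtest"] = session.subtest.value
    meta["sampling_rate"] = float(next(iter(session.recordings.values())).sampling_rate)
    header = yaml.safe_dump(meta, default_flow_style=False, sort_keys=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header.strip().splitlines():
            fh.write(f"# {line}\n")
        data.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")
    return path


def _read_header_and_body(path) -> tuple[dict, pd.DataFrame]:
    meta_lines = []
    body_lines = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                meta_lines.append(line.lstrip("#").strip())
            else:
                body_lines.append(line)
    meta = yaml.safe_load("\n".join(meta_lines)) if meta_lines else {}
    if not body_lines:
        raise FormatError(f"{path}: no data rows")
    df = pd.read_csv(io.StringIO("".join(body_lines)))
    return meta or {}, df


def read_session(path, format_spec: Optional[dict] = None) -> Session:
    """Read a session CSV, validating invariants and unit conventions.

    ``format_spec`` may provide ``column_map`` (file column -> canonical
    column) and ``gyro_unit`` ("deg/s", default, or "rad/s" which is
    converted on load).
    """
    format_spec = format_spec or {}
    meta, df = _read_header_and_body(path)
    column_map = format_spec.get("column_map")
    if column_map:
        df = df.rename(columns=column_map)

    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    gyro_scale = 1.0
    if format_spec.get("gyro_unit", "deg/s") == "rad/s":
        gyro_scale = 180.0 / np.pi

    rate = float(meta.get("sampling_rate", format_spec.get("sampling_rate", 100.0)))
    subject_id = str(meta.get("subject_id", format_spec.get("subject_id", "unknown")))
    subtest = meta.get("subtest", format_spec.get("subtest"))
    if subtest is None:
        raise FormatError(f"{path}: subtest not declared in metadata or format_spec")

    has_mag = all(c in df.columns for c in _MAG_COLUMNS)
    has_ori = all(c in df.columns for c in _ORI_COLUMNS)

    recordings = {}
    for loc_value, group in df.groupby("location", sort=False):
        loc = Location(str(loc_value))
        time = group["time_s"].to_numpy(float)
        # Uniformity check against the declared rate before constructing the
        # recording so dropped samples are reported with their gap indices.
        if len(time) >= 2:
            dt = np.diff(time)
            expected = 1.0 / rate
            bad = np.nonzero(np.abs(dt - expected) > max(TIME_UNIFORMITY_TOL, 1e-9 * expected))[0]
            if bad.size:
                raise SamplingError(
                    f"{path}: location {loc.value} has non-uniform timestamps at "
                    f"declared {rate} Hz; gap indices {bad[:10].tolist()}",
                    gap_indices=bad,
                )
        acc = group[["acc_x", "acc_y", "acc_z"]].to_numpy(float)
        gyro = group[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(float) * gyro_scale
        mag = group[_MAG_COLUMNS].to_numpy(float) if has_mag else None
        if mag is not None and np.all(np.isnan(mag)):
            mag = None
        ori = group[_ORI_COLUMNS].to_numpy(float) if has_ori else None
        if ori is not None and np.all(np.isnan(ori)):
            ori = None
        recordings[loc] = SensorRecording(
            location=loc, time=time, acc=acc, gyro=gyro,
            sampling_rate=rate, mag=mag, orientation=ori,
        )

    meta_out = {k: v for k, v in meta.items()
                if k not in ("subject_id", "subtest", "sampling_rate")}
    return Session(subject_id=subject_id, subtest=Subtest(subtest),
                   recordings=recordings, metadata=meta_out)


def read_cohort_table(path) -> list[SubjectRecord]:
    """Read the cohort CSV: subject_id, age, height_cm, weight_kg,
    n_falls_past_year, injurious_fall (0/1)."""
    df = pd.read_csv(path)
    required = ["subject_id", "age", "height_cm", "weight_kg",
                "n_falls_past_year", "injurious_fall"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing cohort column(s): {', '.join(missing)}")
    return [
        SubjectRecord(
            subject_id=str(row.subject_id),
            age=float(row.age),
            height_cm=float(row.height_cm),
            weight_kg=float(row.weight_kg),
            n_falls_past_year=int(row.n_falls_past_year),
            injurious_fall_past_year=bool(row.injurious_fall),
        )
        for row in df.itertuples(index=False)
    ]


def read_app_log(path, kind: str) -> AppLog:
    """Read an app log CSV.  CRT columns: trial, n_alternatives, rt_s, correct.
    FES columns: item, score."""
    df = pd.read_csv(path)
    if kind == "CRT":
        required = ["n_alternatives", "rt_s", "correct"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing CRT column(s): {', '.join(missing)}")
        trials = [
            CRTTrial(int(r.n_alternatives), float(r.rt_s), bool(r.correct))
            for r in df.itertuples(index=False)
        ]
        return AppLog(kind="CRT", crt_trials=trials)
    if kind == "FES":
        missing = [c for c in ("item", "score") if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing FES column(s): {', '.join(missing)}")
        return AppLog(kind="FES", fes_items=[int(s) for s in df["score"]])
    raise ValidationError(f"unknown app log kind {kind!r}")


def write_app_log(log: AppLog, path) -> Path:
    path = Path(path)
    if log.kind == "CRT":
        df = pd.DataFrame(
            {
                "trial": np.arange(1, len(log.crt_trials) + 1),
                "n_alternatives": [t.n_alternatives for t in log.crt_trials],
                "rt_s": [t.reaction_time for t in log.crt_trials],
                "correct": [int(t.correct) for t in log.crt_trials],
            }
        )
    else:
        df = pd.DataFrame(
            {"item": np.arange(1, len(log.fes_items) + 1), "score": log.fes_items}
        )
    df.to_csv(path, index=False, lineterminator="\n")
    return path
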