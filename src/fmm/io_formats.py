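"""Readers/writers for recordings, annotations and cohort data records.

File dialects
-------------
Recording CSV
    One row per sample, header ``t,ac1..acN,ax,ay,az``.  ``t`` is redundant
    with the sampling rate but retained for audit.  Acoustic channels are raw
    sensor units (arbitrary; see :class:`RecordingConfig.units_note`),
    accelerometer axes in g.

Annotation CSV
    Header ``t_seconds,type,end_seconds``.  Movement rows carry a timestamp
    and a type in ``{breathe, general, startle}`` with ``end_seconds`` empty.
    Probe-repositioning events use type ``probe_move`` with ``t_seconds`` as
    the interval start and ``end_seconds`` as its end.

Cohort data record
    XLSX (first sheet) or CSV, one row per subject.  Column names are mapped
    through a user-supplied ``{canonical: actual}`` dict since deposited
    spreadsheets vary.  Gestational age uses "W+D" notation (completed weeks
    plus days, e.g. ``25+3``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError, ConfigurationError
from .intervals import Interval

__all__ = [
    "RecordingConfig",
    "SensorRecording",
    "MovementType",
    "Annotation",
    "AnnotationTimeline",
    "DataRecord",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "read_data_record",
    "parse_gestational_age",
]

ACCEL_COLUMNS = ("ax", "ay", "az")
ACCEL_LIMIT_G = 16.0  # tri-axis accelerometer full scale


@dataclass(frozen=True)
class RecordingConfig:
    """Static description of a recording's acquisition settings."""

    fs: float
    n_acoustic: int = 6
    mains_hz: float = 50.0
    units_note: str = "raw acoustic sensor units (uncalibrated)"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be > 0, got {self.fs}")
        if not 1 <= self.n_acoustic <= 8:
            raise ConfigurationError(
                f"n_acoustic must be in 1..8, got {self.n_acoustic}"
            )
        if self.mains_hz not in (0, 50, 60):
            raise ConfigurationError(
                f"mains_hz must be 50, 60 or 0 (disabled), got {self.mains_hz}"
            )


@dataclass
class SensorRecording:
    """Synchronized acoustic matrix plus accelerometer triplet at fixed fs."""

    subject_id: str
    acoustic: np.ndarray  # (n_acoustic, n_samples)
    accel: np.ndarray  # (3, n_samples), g
    fs: float

    def __post_init__(self) -> None:
        self.acoustic = np.atleast_2d(np.asarray(self.acoustic, dtype=float))
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        if self.accel.shape[0] != 3:
            raise ValidationError(
                f"accel must have 3 axes, got {self.accel.shape[0]}"
            )
        if self.acoustic.shape[1] != self.accel.shape[1]:
            raise ValidationError("acoustic and accel channel lengths differ")
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if self.accel.size and not np.all(np.isfinite(self.accel)):
            raise ValidationError("accelerometer contains non-finite samples")
        if self.accel.size and np.abs(self.accel).max() > ACCEL_LIMIT_G:
            raise ValidationError(
                f"accelerometer exceeds +/-{ACCEL_LIMIT_G} g full scale"
            )

    @property
    def n_acoustic(self) -> int:
        return self.acoustic.shape[0]

    @property
    def n_samples(self) -> int:
        return self.acoustic.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


class MovementType(str, enum.Enum):
    """The three physician-annotated fetal movement classes."""

    BREATHE = "breathe"
    GENERAL = "general"
    STARTLE = "startle"

    @classmethod
    def parse(cls, label: str) -> "MovementType":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown movement type {label!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class Annotation:
    """A physician call-out: time (s from recording start) and movement type."""

    t: float
    mtype: MovementType

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError(f"annotation time must be >= 0, got {self.t}")


@dataclass
class AnnotationTimeline:
    annotations: list[Annotation] = field(default_factory=list)
    probe_moves: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.annotations = sorted(self.annotations, key=lambda a: a.t)
        self.probe_moves = sorted(self.probe_moves)

    def of_type(self, mtype: MovementType) -> list[Annotation]:
        return [a for a in self.annotations if a.mtype == mtype]

    def counts(self) -> dict[MovementType, int]:
        out = {m: 0 for m in MovementType}
        for a in self.annotations:
            out[a.mtype] += 1
        return out

    def __len__(self) -> int:
        return len(self.annotations)


#: canonical column names for a cohort data record
DATA_RECORD_REQUIRED = (
    "subject_id",
    "gestational_age",
    "n_breathe",
    "n_general",
    "n_startle",
    "scan_duration_min",
)
DATA_RECORD_OPTIONAL = (
    "bmi",
    "deepest_vertical_pool",
    "estimated_fetal_weight",
    "mca_pi",
    "ua_pi",
)


@dataclass
class DataRecord:
    """Per-subject cohort table (one row per subject)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DATA_RECORD_REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"data record missing columns: {missing}")
        for c in ("n_breathe", "n_general", "n_startle"):
            if (self.table[c] < 0).any():
                raise ValidationError(f"negative count in column {c}")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def totals(self) -> dict[str, int]:
        return {
            c: int(self.table[c].sum())
            for c in ("n_breathe", "n_general", "n_startle")
        }


def parse_gestational_age(cell: object) -> float:
    """Parse "W+D" gestational-age notation into decimal weeks (W + D/7)."""
    s = str(cell).strip()
    if "+" in s:
        w_str, d_str = s.split("+", 1)
        try:
            weeks, days = int(w_str), int(d_str)
        except ValueError:
            raise ParseError(f"cannot parse gestational age {cell!r}") from None
        if not 0 <= days <= 6:
            raise ValidationError(
                f"gestational age days component must be 0-6, got {days} in {cell!r}"
            )
        if weeks < 0:
            raise ValidationError(f"negative gestational weeks in {cell!r}")
        return weeks + days / 7.0
    try:
        return float(s)
    except ValueError:
        raise ParseError(f"cannot parse gestational age {cell!r}") from None


# ---------------------------------------------------------------------------
# recording CSV


def _recording_columns(n_acoustic: int) -> list[str]:
    return ["t"] + [f"ac{i}" for i in range(1, n_acoustic + 1)] + list(ACCEL_COLUMNS)


def read_recording(path: str | Path, config: RecordingConfig) -> SensorRecording:
    """Read a recording CSV; sample ``i`` maps to time ``i / config.fs``."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    cols = header.split(",") if header else []
    expected = _recording_columns(config.n_acoustic)
    if cols != expected:
        missing = [c for c in expected if c not in cols]
        extra = [c for c in cols if c not in expected]
        raise FormatError(
            f"{path.name}: recording header mismatch; "
            f"missing columns {missing}, unexpected columns {extra}"
        )
    try:
        df = pd.read_csv(path, dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path.name}: non-numeric cell ({exc})") from exc
    bad = df.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        raise ParseError(
            f"{path.name}: non-numeric or empty cell at data row {row + 1}"
        )
    acoustic = df[expected[1 : 1 + config.n_acoustic]].to_numpy().T
    accel = df[list(ACCEL_COLUMNS)].to_numpy().T
    if acoustic.shape[1] == 0:
        acoustic = acoustic.reshape(config.n_acoustic, 0)
        accel = accel.reshape(3, 0)
    return SensorRecording(
        subject_id=path.stem, acoustic=acoustic, accel=accel, fs=config.fs
    )


def write_recording(recording: SensorRecording, path: str | Path) -> None:
    """Write the recording CSV dialect; round-trips with :func:`read_recording`."""
    if not np.all(np.isfinite(recording.acoustic)):
        raise ValidationError("refusing to write recording with non-finite samples")
    cols = _recording_columns(recording.n_acoustic)
    data = np.vstack([recording.times, recording.acoustic, recording.accel]).T
    df = pd.DataFrame(data, columns=cols)
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# annotation CSV

_PROBE_LABEL = "probe_move"


def read_annotations(path: str | Path) -> AnnotationTimeline:
    """Read the annotation CSV dialect into a time-sorted timeline."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return AnnotationTimeline()
    required = {"t_seconds", "type"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path.name}: annotation file must have columns "
            f"t_seconds,type[,end_seconds]; got {list(df.columns)}"
        )
    annotations: list[Annotation] = []
    probe_moves: list[Interval] = []
    for idx, row in df.iterrows():
        label = str(row["type"]).strip().lower()
        try:
            t = float(row["t_seconds"])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path.name}: non-numeric timestamp at data row {idx + 1}"
            ) from None
        if label == _PROBE_LABEL:
            if "end_seconds" not in df.columns or pd.isna(row["end_seconds"]):
                raise FormatError(
                    f"{path.name}: probe_move row {idx + 1} needs end_seconds"
                )
            probe_moves.append(Interval(t, float(row["end_seconds"])))
        else:
            annotations.append(Annotation(t=t, mtype=MovementType.parse(label)))
    return AnnotationTimeline(annotations=annotations, probe_moves=probe_moves)


def write_annotations(timeline: AnnotationTimeline, path: str | Path) -> None:
    rows: list[dict] = [
        {"t_seconds": a.t, "type": a.mtype.value, "end_seconds": math.nan}
        for a in timeline.annotations
    ]
    rows += [
        {"t_seconds": iv.start, "type": _PROBE_LABEL, "end_seconds": iv.end}
        for iv in timeline.probe_moves
    ]
    df = pd.DataFrame(rows, columns=["t_seconds", "type", "end_seconds"])
    df.sort_values("t_seconds").to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# cohort data record


def read_data_record(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> DataRecord:
    """Read a per-subject cohort spreadsheet (XLSX first sheet, or CSV).

    ``column_map`` maps canonical names (``subject_id``, ``gestational_age``,
    ``n_breathe``, ``n_general``, ``n_startle``, ``scan_duration_min`` and the
    optional maternal/fetal factors) onto the actual file headers.  Canonical
    headers already present in the file need no mapping entry.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, sheet_name=0)
    else:
        df = pd.read_csv(path)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in DATA_RECORD_REQUIRED if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"cannot map required columns {missing}; available headers: "
            f"{list(df.columns)}"
        )
    keep = [c for c in DATA_RECORD_REQUIRED + DATA_RECORD_OPTIONAL if c in df.columns]
    df = df[keep].copy()
    df["gestational_age"] = df["gestational_age"].map(parse_gestational_age)
    for c in ("n_breathe", "n_general", "n_startle"):
        df[c] = df[c].astype(int)
    df["subject_id"] = df["subject_id"].astype(str)
    return DataRecord(table=df.reset_index(drop=True))
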