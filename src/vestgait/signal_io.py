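"""Trial data model, on-disk layout, and signal preprocessing.

A *trial* is one participant x task x sensor recording of 3D linear
acceleration (m/s^2) and 3D angular velocity (deg/s) from a body-worn IMU.
Preprocessing follows a fixed order: edge trimming (drop the initial and
final 5% of the recording to remove initiation/termination artefacts),
then zero-phase 4th-order Butterworth low-pass filtering at 6 Hz.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "GROUPS",
    "SENSORS",
    "INGEST_ONLY_SENSORS",
    "TASKS",
    "DIFFICULTY_LEVELS",
    "GRAVITY_MS2",
    "TrialRecording",
    "TrialMetadata",
    "TrialFormatError",
    "DataValidationError",
    "read_trial",
    "write_trial",
    "read_metadata_table",
    "write_metadata_table",
    "trim_edges",
    "lowpass_filter",
    "preprocess",
    "trial_path",
]

#: The three comparison groups: bilateral vestibulopathy, unilateral
#: vestibulopathy, healthy subjects.
GROUPS = ("BV", "UV", "HS")

#: Sensors kept for analysis: head, trunk, sacrum, left/right foot.
SENSORS = ("HE", "TR", "SA", "LF", "RF")

#: Wrist and thigh sensors may appear in raw data; they are readable but
#: excluded from analysis by default.
INGEST_ONLY_SENSORS = ("LA", "RA", "LT", "RT")

#: The 15 daily-living tasks of the measurement protocol.
TASKS = (
    "Bed",
    "Pants",
    "Shoes",
    "Sorting",
    "Heavy load",
    "Bus",
    "Stairs",
    "Uneven ground",
    "Tray",
    "Walk",
    "Stepladder",
    "Wood beam",
    "Inclined plane",
    "Picture recognition",
    "Walk in the dark",
)

#: Ordinal encoding of perceived task difficulty.
DIFFICULTY_LEVELS = {"easy": 1, "medium": 2, "difficult": 3, "impossible": 4}

GRAVITY_MS2 = 9.80665


class TrialFormatError(ValueError):
    """Raised when a trial file does not follow the expected dialect."""


class DataValidationError(ValueError):
    """Raised when trial data violate a domain invariant (e.g. NaN samples)."""


@dataclass
class TrialRecording:
    """One participant x task x sensor 6-axis IMU time series.

    acc is T x 3 linear acceleration in m/s^2, gyr is T x 3 angular
    velocity in deg/s; duration_s is the full task duration before any
    trimming.
    """

    participant_id: str
    group: str
    task: str
    sensor: str
    acc: np.ndarray
    gyr: np.ndarray
    sample_rate: float = 128.0
    duration_s: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.group not in GROUPS:
            raise DataValidationError(f"unknown group {self.group!r}")
        if self.sensor not in SENSORS + INGEST_ONLY_SENSORS:
            raise DataValidationError(f"unknown sensor {self.sensor!r}")
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise DataValidationError("acc must be T x 3")
        if self.gyr.ndim != 2 or self.gyr.shape[1] != 3:
            raise DataValidationError("gyr must be T x 3")
        if len(self.acc) != len(self.gyr):
            raise DataValidationError("acc and gyr must have equal length")
        if len(self.acc) < 2:
            raise DataValidationError("recording must contain at least 2 samples")
        if self.sample_rate <= 0:
            raise DataValidationError("sample_rate must be positive")
        if self.duration_s == 0.0:
            self.duration_s = len(self.acc) / self.sample_rate
        if self.duration_s <= 0:
            raise DataValidationError("duration_s must be positive")
        for name, arr in (("acc", self.acc), ("gyr", self.gyr)):
            bad = ~np.isfinite(arr)
            if bad.any():
                row = int(np.argwhere(bad)[0, 0])
                raise DataValidationError(
                    f"non-finite sample in {name} at row {row}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.acc)


@dataclass(frozen=True)
class TrialMetadata:
    """Per-trial metadata: duration and the participant's difficulty rating."""

    participant_id: str
    group: str
    task: str
    duration_s: float
    difficulty: int
    completed: bool

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataValidationError(f"unknown group {self.group!r}")
        if self.difficulty not in (1, 2, 3, 4):
            raise DataValidationError("difficulty must be 1..4")
        if self.difficulty == 4 and self.completed:
            raise DataValidationError("an impossible task cannot be completed")
        if self.completed and not self.duration_s > 0:
            raise DataValidationError("completed trial needs duration_s > 0")


# ---------------------------------------------------------------------------
# Trial CSV dialect
#
# Header line:
#   # participant=<id> group=<BV|UV|HS> task=<name> sensor=<code> fs=<Hz>
#     acc_unit=<g|ms2> gyr_unit=<dps>
# then columns t_s,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z.
# Task names may contain spaces, so the header is parsed on key= anchors.
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("participant", "group", "task", "sensor", "fs", "acc_unit", "gyr_unit")
_COLUMNS = ("t_s", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")


def _parse_header(line: str) -> dict[str, str]:
    if not line.startswith("#"):
        raise TrialFormatError("missing '#' header line")
    body = line.lstrip("#").strip()
    matches = list(re.finditer(r"(\w+)=", body))
    fields: dict[str, str] = {}
    for i, m in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(body)
        fields[m.group(1)] = body[m.end():end].strip()
    missing = [k for k in _HEADER_KEYS if k not in fields]
    if missing:
        raise TrialFormatError(f"header missing keys: {', '.join(missing)}")
    return fields


def read_trial(path: str | Path) -> TrialRecording:
    """Read one trial CSV, converting units to m/s^2 and deg/s."""
    path = Path(path)
    with open(path) as fh:
        header = _parse_header(fh.readline())
        df = pd.read_csv(fh)
    if tuple(df.columns) != _COLUMNS:
        raise TrialFormatError(
            f"expected columns {','.join(_COLUMNS)}, got {','.join(df.columns)}"
        )
    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
    gyr = df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(dtype=float)
    acc_unit = header["acc_unit"]
    if acc_unit == "g":
        acc = acc * GRAVITY_MS2
    elif acc_unit != "ms2":
        raise TrialFormatError(f"unknown acc_unit {acc_unit!r}")
    if header["gyr_unit"] != "dps":
        raise TrialFormatError(f"unknown gyr_unit {header['gyr_unit']!r}")
    for name, arr in (("acc", acc), ("gyr", gyr)):
        bad = ~np.isfinite(arr)
        if bad.any():
            row = int(np.argwhere(bad)[0, 0])
            raise DataValidationError(
                f"{path.name}: non-finite sample in {name} at row {row}"
            )
    return TrialRecording(
        participant_id=header["participant"],
        group=header["group"],
        task=header["task"],
        sensor=header["sensor"],
        acc=acc,
        gyr=gyr,
        sample_rate=float(header["fs"]),
    )


def write_trial(rec: TrialRecording, path: str | Path) -> None:
    """Write a trial in the CSV dialect (always m/s^2 / deg/s)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.n_samples) / rec.sample_rate
    df = pd.DataFrame(
        np.column_stack([t, rec.acc, rec.gyr]), columns=list(_COLUMNS)
    )
    header = (
        f"# participant={rec.participant_id} group={rec.group} task={rec.task} "
        f"sensor={rec.sensor} fs={rec.sample_rate:g} acc_unit=ms2 gyr_unit=dps\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.9g")


def trial_path(root: str | Path, rec_or_meta, sensor: str | None = None) -> Path:
    """Canonical location ``<root>/<participant>/<task>/<sensor>.csv``."""
    sensor = sensor or rec_or_meta.sensor
    return Path(root) / rec_or_meta.participant_id / rec_or_meta.task / f"{sensor}.csv"


_META_COLUMNS = ["participant_id", "group", "task", "duration_s", "difficulty", "completed"]


def write_metadata_table(metadata: Iterable[TrialMetadata], path: str | Path) -> None:
    rows = [
        {
            "participant_id": m.participant_id,
            "group": m.group,
            "task": m.task,
            "duration_s": m.duration_s,
            "difficulty": m.difficulty,
            "completed": m.completed,
        }
        for m in metadata
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)


def read_metadata_table(path: str | Path) -> list[TrialMetadata]:
    df = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"metadata table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TrialMetadata(
                participant_id=str(row.participant_id),
                group=row.group,
                task=row.task,
                duration_s=float(row.duration_s),
                difficulty=int(row.difficulty),
                completed=bool(row.completed),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def trim_edges(rec: TrialRecording, fraction: float = 0.05) -> TrialRecording:
    """Drop ``floor(fraction * T)`` samples from each end of the recording.

    Removes task initiation and termination phases. Metadata (including
    duration_s, the full pre-trim duration) is unchanged.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError(f"trim fraction must be in [0, 0.5), got {fraction}")
    n = rec.n_samples
    k = math.floor(fraction * n)
    if n - 2 * k < 2:
        raise ValueError("trimming would leave fewer than 2 samples")
    if k == 0:
        return replace(rec, acc=rec.acc.copy(), gyr=rec.gyr.copy())
    return replace(rec, acc=rec.acc[k : n - k].copy(), gyr=rec.gyr[k : n - k].copy())


def lowpass_filter(
    rec: TrialRecording, order: int = 4, cutoff_hz: float = 6.0
) -> TrialRecording:
    """Zero-phase Butterworth low-pass filter on all 6 channels.

    Forward-backward filtering keeps amplitude features unbiased by phase
    lag; the effective attenuation is the squared one-pass magnitude
    response. DC gain is exactly 1.
    """
    nyq = rec.sample_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie below the Nyquist frequency {nyq} Hz"
        )
    sos = _sig.butter(order, cutoff_hz, btype="low", fs=rec.sample_rate, output="sos")
    acc = _sig.sosfiltfilt(sos, rec.acc, axis=0)
    gyr = _sig.sosfiltfilt(sos, rec.gyr, axis=0)
    return replace(rec, acc=np.ascontiguousarray(acc), gyr=np.ascontiguousarray(gyr))


def preprocess(
    rec: TrialRecording,
    trim_fraction: float = 0.05,
    order: int = 4,
    cutoff_hz: float = 6.0,
) -> TrialRecording:
    """Canonical preprocessing chain: trim edges, then low-pass filter.

    The order matters (filter transients interact with the trimmed edges),
    so the pipeline always goes through this function.
    """
    return lowpass_filter(trim_edges(rec, trim_fraction), order, cutoff_hz)
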