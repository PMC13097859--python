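"""Per-trial movement parameters and cohort feature matrix assembly.

For each preprocessed trial the pipeline computes three sensor-level
parameters — RMS of the 3D linear-acceleration norm (movement intensity,
m/s^2), RMS of the 3D angular-velocity norm (rotational intensity, deg/s),
and the RMS of the jerk norm (movement smoothness, m/s^3) — plus three
between-segment attenuation coefficients computed from linear-acceleration
RMS (trunk->head AC_TH, sacrum->head AC_SH, sacrum->trunk AC_ST, in %) and
the task duration (s). One participant x task therefore yields 19 named
variables: 5 sensors x 3 parameters + 3 AC + duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signal_io import SENSORS, TrialMetadata, TrialRecording

__all__ = [
    "PARAMETERS",
    "AC_PAIRS",
    "FeatureRecord",
    "vector_norm_series",
    "rms",
    "jerk_scalar",
    "jerk_rms",
    "attenuation_coefficient",
    "extract_trial_features",
    "task_variables",
    "build_feature_matrix",
    "matrix_to_long",
    "write_feature_matrix",
    "read_feature_matrix",
]

#: Sensor-level parameter names, in canonical column order.
PARAMETERS = ("NormLinAcc_RMS", "NormAngVel_RMS", "JERK_RMS")

#: Attenuation-coefficient pairs as (lower segment i, upper segment j);
#: the lower segment's RMS is the denominator.
AC_PAIRS = {"AC_TH": ("TR", "HE"), "AC_SH": ("SA", "HE"), "AC_ST": ("SA", "TR")}


@dataclass
class FeatureRecord:
    """All movement variables for one participant x task.

    ``values`` maps variable names (``<task>|<sensor>|<parameter>``,
    ``<task>|AC_*`` or ``<task>|duration``) to scalars. A trial the
    participant rated impossible yields an empty map — missingness is
    explicit, never encoded as 0.
    """

    participant_id: str
    group: str
    task: str
    values: dict[str, float] = field(default_factory=dict)
    completed: bool = True


def vector_norm_series(x: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a T x 3 signal."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("expected a T x 3 array")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite samples")
    return np.sqrt(np.einsum("ij,ij->i", x, x))


def rms(series: np.ndarray) -> float:
    """Root mean square of a 1-D series."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("rms of an empty series is undefined")
    return float(np.sqrt(np.mean(series**2)))


def _jerk_components(acc: np.ndarray, sample_rate: float) -> np.ndarray:
    acc = np.asarray(acc, dtype=float)
    if acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("expected a T x 3 acceleration array")
    if len(acc) < 3:
        raise ValueError("jerk needs at least 3 samples")
    return np.gradient(acc, 1.0 / sample_rate, axis=0)


def jerk_scalar(acc: np.ndarray, sample_rate: float) -> float:
    """Half the time-integral of the summed squared acceleration derivatives.

    Derivatives are central differences (one-sided at the ends) and the
    integral is trapezoidal over the trial.
    """
    d = _jerk_components(acc, sample_rate)
    integrand = np.einsum("ij,ij->i", d, d)
    return 0.5 * float(np.trapezoid(integrand, dx=1.0 / sample_rate))


def jerk_rms(acc: np.ndarray, sample_rate: float) -> float:
    """RMS of the 3D jerk-norm time series (the JERK_RMS matrix feature)."""
    d = _jerk_components(acc, sample_rate)
    return rms(np.sqrt(np.einsum("ij,ij->i", d, d)))


def attenuation_coefficient(rms_lower: float, rms_upper: float) -> float:
    """``(1 - RMS_upper / RMS_lower) * 100``.

    Positive values mean the upper body segment attenuates the lower
    segment's accelerations; negative values mean amplification. Bounded
    above by 100.
    """
    if rms_lower <= 0:
        raise ValueError("lower-segment RMS must be positive")
    if rms_upper < 0:
        raise ValueError("upper-segment RMS must be non-negative")
    return (1.0 - rms_upper / rms_lower) * 100.0


def task_variables(task: str) -> list[str]:
    """Canonical ordered variable names for one task (19 names)."""
    names = [f"{task}|{s}|{p}" for s in SENSORS for p in PARAMETERS]
    names += [f"{task}|{ac}" for ac in AC_PAIRS]
    names.append(f"{task}|duration")
    return names


def extract_trial_features(
    recordings: Mapping[str, TrialRecording], metadata: TrialMetadata
) -> FeatureRecord:
    """Compute the 19 variables for one participant x task.

    ``recordings`` maps sensor code -> preprocessed TrialRecording for the
    five analysis sensors. When the task was not completed the record is
    returned with no values (explicitly missing).
    """
    if not metadata.completed:
        return FeatureRecord(
            participant_id=metadata.participant_id,
            group=metadata.group,
            task=metadata.task,
            values={},
            completed=False,
        )
    missing = [s for s in SENSORS if s not in recordings]
    if missing:
        raise ValueError(
            f"{metadata.participant_id}/{metadata.task}: missing sensors "
            f"{', '.join(missing)}"
        )
    task = metadata.task
    values: dict[str, float] = {}
    acc_norm_rms: dict[str, float] = {}
    for s in SENSORS:
        rec = recordings[s]
        acc_norm = vector_norm_series(rec.acc)
        gyr_norm = vector_norm_series(rec.gyr)
        acc_norm_rms[s] = rms(acc_norm)
        values[f"{task}|{s}|NormLinAcc_RMS"] = acc_norm_rms[s]
        values[f"{task}|{s}|NormAngVel_RMS"] = rms(gyr_norm)
        values[f"{task}|{s}|JERK_RMS"] = jerk_rms(rec.acc, rec.sample_rate)
    for ac_name, (lower, upper) in AC_PAIRS.items():
        values[f"{task}|{ac_name}"] = attenuation_coefficient(
            acc_norm_rms[lower], acc_norm_rms[upper]
        )
    values[f"{task}|duration"] = float(metadata.duration_s)
    return FeatureRecord(
        participant_id=metadata.participant_id,
        group=metadata.group,
        task=task,
        values=values,
        completed=True,
    )


def build_feature_matrix(
    records: Iterable[FeatureRecord], tasks: Sequence[str]
) -> pd.DataFrame:
    """Assemble participants x variables matrix for the selected tasks.

    Returns a DataFrame indexed by participant_id with a leading ``group``
    column followed by the task variables in deterministic order (task,
    then sensor, then parameter). Missing trials stay NaN.
    """
    records = [r for r in records if r.task in tasks]
    if not records:
        raise ValueError("no feature records for the requested tasks")
    seen: set[tuple[str, str]] = set()
    groups: dict[str, str] = {}
    cells: dict[str, dict[str, float]] = {}
    for rec in records:
        key = (rec.participant_id, rec.task)
        if key in seen:
            raise ValueError(f"duplicate record for participant {key[0]} task {key[1]}")
        seen.add(key)
        prev = groups.setdefault(rec.participant_id, rec.group)
        if prev != rec.group:
            raise ValueError(f"conflicting group labels for {rec.participant_id}")
        cells.setdefault(rec.participant_id, {}).update(rec.values)
    columns = [v for task in tasks for v in task_variables(task)]
    participants = sorted(cells)
    df = pd.DataFrame(index=pd.Index(participants, name="participant_id"), columns=columns, dtype=float)
    for pid, vals in cells.items():
        for name, value in vals.items():
            df.loc[pid, name] = value
    df.insert(0, "group", [groups[p] for p in participants])
    return df


def matrix_to_long(matrix: pd.DataFrame) -> pd.DataFrame:
    """Tidy form: participant_id, group, task, sensor, parameter, value."""
    rows = []
    for pid, row in matrix.iterrows():
        for col in matrix.columns:
            if col == "group":
                continue
            parts = col.split("|")
            task = parts[0]
            if len(parts) == 3:
                sensor, parameter = parts[1], parts[2]
            else:
                sensor, parameter = "", parts[1]
            rows.append(
                {
                    "participant_id": pid,
                    "group": row["group"],
                    "task": task,
                    "sensor": sensor,
                    "parameter": parameter,
                    "value": row[col],
                }
            )
    return pd.DataFrame(rows)


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id")
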