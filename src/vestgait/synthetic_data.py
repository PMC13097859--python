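"""Synthetic IMU cohort generator with planted, registered group effects.

Generates gravity-free oscillatory gait-like signals for three groups
(bilateral vestibulopathy BV, unilateral vestibulopathy UV, healthy
subjects HS) x ~20 participants x 15 daily-living tasks x 5 sensors, plus
per-trial metadata (duration, ordinal perceived difficulty). Every group
effect is planted through an explicit registry, and the generator returns
the matching ground truth (which feature-matrix variables should differ,
and in which direction), so the entire analysis chain is testable without
any recorded data.

Signal model per trial: each acceleration axis is a sum of the 1st-3rd
harmonics of the participant's step frequency (sensor-specific base
amplitude x group/task effect multiplier x participant random effects),
plus white noise and a band-limited (sub-cutoff) "jitter" component whose
amplitude degrades movement smoothness and therefore controls the jerk
features. Angular velocity is built the same way on a deg/s scale.
Durations are lognormal with group shifts; difficulty comes from a
latent-normal threshold model (a rating of "impossible" marks the trial
as not completed, yielding difficulty without duration or signals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import signal as _sig

from .signal_io import (
    GROUPS,
    SENSORS,
    TASKS,
    TrialMetadata,
    TrialRecording,
    trial_path,
    write_metadata_table,
    write_trial,
)

__all__ = [
    "Effect",
    "SimulationConfig",
    "GroundTruth",
    "ParticipantProfile",
    "simulate_trial",
    "iter_cohort",
    "simulate_cohort",
    "simulate_metadata",
    "default_paper_scenario",
    "null_scenario",
    "LOCOMOTOR_TASKS",
]

#: Tasks dominated by locomotion; they share a participant-level
#: locomotor random factor (common PC1-style variance).
LOCOMOTOR_TASKS = (
    "Walk",
    "Uneven ground",
    "Inclined plane",
    "Walk in the dark",
    "Picture recognition",
    "Heavy load",
)

_DEFAULT_DURATIONS = {
    "Bed": 12.0,
    "Pants": 22.0,
    "Shoes": 25.0,
    "Sorting": 35.0,
    "Heavy load": 18.0,
    "Bus": 20.0,
    "Stairs": 16.0,
    "Uneven ground": 14.0,
    "Tray": 14.0,
    "Walk": 10.0,
    "Stepladder": 12.0,
    "Wood beam": 18.0,
    "Inclined plane": 32.0,
    "Picture recognition": 20.0,
    "Walk in the dark": 11.0,
}

# Latent difficulty level an average healthy subject experiences per task;
# thresholds at (1.5, 2.5, 3.5) map the latent scale to easy..impossible.
_DEFAULT_DIFFICULTY = {
    "Bed": 0.8,
    "Pants": 1.6,
    "Shoes": 1.4,
    "Sorting": 1.0,
    "Heavy load": 1.7,
    "Bus": 0.9,
    "Stairs": 1.5,
    "Uneven ground": 1.8,
    "Tray": 1.3,
    "Walk": 0.6,
    "Stepladder": 1.6,
    "Wood beam": 2.2,
    "Inclined plane": 1.9,
    "Picture recognition": 1.5,
    "Walk in the dark": 2.0,
}

# Sensor base amplitudes; feet move hardest, the head is the most
# stabilized segment, giving naturally positive attenuation coefficients.
_ACC_AMP = {"HE": 0.8, "TR": 1.0, "SA": 1.3, "LF": 3.0, "RF": 3.0}
_GYR_AMP = {"HE": 25.0, "TR": 18.0, "SA": 22.0, "LF": 120.0, "RF": 120.0}


@dataclass(frozen=True)
class Effect:
    """One planted group effect.

    ``channel`` says what the multiplier scales: ``amplitude`` (harmonic
    amplitudes of acc and gyr -> intensity features), ``jitter`` (the
    band-limited smoothness-degradation component -> jerk features) or
    ``duration`` (task duration; ``sensor`` is None then).
    """

    group: str
    task: str
    sensor: str | None
    channel: Literal["amplitude", "jitter", "duration"]
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("effect multipliers must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class GroundTruthEntry:
    variable: str
    group: str
    multiplier: float

    @property
    def direction(self) -> str:
        return "decrease" if self.multiplier < 1 else "increase"


@dataclass
class GroundTruth:
    """Registry of feature-matrix variables carrying planted effects."""

    entries: list[GroundTruthEntry]

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.variable not in seen:
                seen.append(e.variable)
        return seen

    def variables_for_tasks(self, tasks: Sequence[str]) -> list[str]:
        return [v for v in self.variables if v.split("|")[0] in tasks]


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort; a pure function of ``seed``."""

    n_per_group: int = 20
    tasks: tuple[str, ...] = TASKS
    sensors: tuple[str, ...] = SENSORS
    sample_rate: float = 128.0
    step_freq_hz: float = 1.8
    base_duration_s: dict = field(default_factory=lambda: dict(_DEFAULT_DURATIONS))
    base_difficulty: dict = field(default_factory=lambda: dict(_DEFAULT_DIFFICULTY))
    acc_amplitude: dict = field(default_factory=lambda: dict(_ACC_AMP))
    gyr_amplitude: dict = field(default_factory=lambda: dict(_GYR_AMP))
    harmonic_weights: tuple[float, ...] = (1.0, 0.45, 0.2)
    axis_weights: tuple[float, float, float] = (0.757, 0.530, 0.379)
    noise_sd_acc: float = 0.05  # m/s^2, white, per axis
    noise_sd_gyr: float = 2.0  # deg/s, white, per axis
    jitter_band_hz: tuple[float, float] = (4.2, 5.8)
    jitter_base: float = 0.22  # fraction of the sensor amplitude
    between_subject_sd: dict = field(
        default_factory=lambda: {"BV": 0.06, "UV": 0.11, "HS": 0.05}
    )
    locomotor_factor_sd: float = 0.25
    locomotor_group_mean: dict = field(
        default_factory=lambda: {"BV": 1.0, "UV": 1.0, "HS": 1.0}
    )
    locomotor_upper_scale: float = 0.3  # upper-body share of the locomotor factor
    postural_factor_sd: float = 0.08
    smoothness_factor_sd: float = 0.25
    trial_amp_sd: float = 0.12  # per-trial lognormal amplitude variability
    trial_jitter_sd: float = 0.15
    slowness_sd: float = 0.08
    duration_sigma: float = 0.12
    step_freq_sd: float = 0.05
    frailty_sd: float = 0.30
    difficulty_noise_sd: float = 0.50
    difficulty_thresholds: tuple[float, float, float] = (1.5, 2.5, 3.5)
    effects: tuple[Effect, ...] = ()
    difficulty_shifts: dict = field(default_factory=dict)  # (group, task) -> latent shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("need at least 3 participants per group")
        unknown = [t for t in self.tasks if t not in self.base_duration_s]
        if unknown:
            raise ValueError(f"tasks without base duration: {unknown}")

    # -- effect lookups ----------------------------------------------------
    def multiplier(self, group: str, task: str, sensor: str | None, channel: str) -> float:
        m = 1.0
        for e in self.effects:
            if (
                e.group == group
                and e.task == task
                and e.channel == channel
                and (e.sensor == sensor or e.channel == "duration")
            ):
                m *= e.multiplier
        return m

    def ground_truth(self) -> GroundTruth:
        entries: list[GroundTruthEntry] = []
        for group, mean in self.locomotor_group_mean.items():
            if mean == 1.0:
                continue
            for task in LOCOMOTOR_TASKS:
                if task not in self.tasks:
                    continue
                for sensor in ("LF", "RF"):
                    extra = self.multiplier(group, task, sensor, "amplitude")
                    for param in ("NormLinAcc_RMS", "NormAngVel_RMS"):
                        entries.append(
                            GroundTruthEntry(
                                f"{task}|{sensor}|{param}", group, mean * extra
                            )
                        )
        for e in self.effects:
            if e.channel == "amplitude" and e.sensor in ("LF", "RF") and (
                e.task in LOCOMOTOR_TASKS
                and self.locomotor_group_mean.get(e.group, 1.0) != 1.0
            ):
                continue  # already covered (combined) above
            if e.channel == "amplitude":
                names = [
                    f"{e.task}|{e.sensor}|NormLinAcc_RMS",
                    f"{e.task}|{e.sensor}|NormAngVel_RMS",
                ]
            elif e.channel == "jitter":
                names = [f"{e.task}|{e.sensor}|JERK_RMS"]
            else:
                names = [f"{e.task}|duration"]
            for name in names:
                entries.append(GroundTruthEntry(name, e.group, e.multiplier))
        return GroundTruth(entries=entries)


@dataclass
class ParticipantProfile:
    """Per-participant latent traits shared across tasks and sensors.

    The multiplicative factors form a hierarchy: a weak global intensity
    factor on everything, a locomotor factor loading strongly on the foot
    sensors during locomotor tasks (and weakly on the upper body), a
    postural factor on non-locomotor tasks, and a smoothness factor on
    the jitter component only (jerk-specific variance).
    """

    participant_id: str
    group: str
    step_freq_hz: float
    intensity: float  # lognormal multiplier on all amplitudes
    locomotor: float  # foot-sensor multiplier in locomotor tasks
    postural: float  # multiplier in non-locomotor tasks
    smoothness: float  # multiplier on the jitter (jerk) component
    slowness: float  # additive log-duration offset
    frailty: float  # additive latent-difficulty offset


def _profile(config: SimulationConfig, group: str, index: int) -> ParticipantProfile:
    pid = f"{group}{index + 1:02d}"
    gi = GROUPS.index(group)
    rng = np.random.default_rng([config.seed, 1, gi, index])
    sd = config.between_subject_sd[group]
    return ParticipantProfile(
        participant_id=pid,
        group=group,
        step_freq_hz=config.step_freq_hz * float(np.exp(rng.normal(0, config.step_freq_sd))),
        intensity=float(np.exp(rng.normal(0, sd))),
        locomotor=config.locomotor_group_mean.get(group, 1.0)
        * float(np.exp(rng.normal(0, config.locomotor_factor_sd))),
        postural=float(np.exp(rng.normal(0, config.postural_factor_sd))),
        smoothness=float(np.exp(rng.normal(0, config.smoothness_factor_sd))),
        slowness=float(rng.normal(0, config.slowness_sd)),
        frailty=float(rng.normal(0, config.frailty_sd)),
    )


def simulate_trial(
    profile: ParticipantProfile,
    task: str,
    sensor: str,
    rng: np.random.Generator,
    config: SimulationConfig,
    duration_s: float | None = None,
) -> TrialRecording:
    """Simulate one 6-axis recording for a participant x task x sensor."""
    if duration_s is None:
        duration_s = _draw_duration(profile, task, rng, config)
    fs = config.sample_rate
    n = max(int(round(duration_s * fs)), 3)
    t = np.arange(n) / fs
    amp_mult = (
        config.multiplier(profile.group, task, sensor, "amplitude")
        * profile.intensity
    )
    if task in LOCOMOTOR_TASKS:
        exponent = 1.0 if sensor in ("LF", "RF") else config.locomotor_upper_scale
        amp_mult *= profile.locomotor**exponent
    else:
        amp_mult *= profile.postural
    # separate per-trial wobble for the acceleration and gyroscope channels,
    # so the three parameters of one trial correlate strongly but not
    # degenerately
    acc_mult, gyr_mult = amp_mult, amp_mult
    if config.trial_amp_sd > 0:
        acc_mult *= float(np.exp(rng.normal(0, config.trial_amp_sd)))
        gyr_mult *= float(np.exp(rng.normal(0, config.trial_amp_sd)))
    jit_mult = (
        config.multiplier(profile.group, task, sensor, "jitter")
        * profile.smoothness
    )
    if config.trial_jitter_sd > 0:
        jit_mult *= float(np.exp(rng.normal(0, config.trial_jitter_sd)))

    def channels(base_amp: float, noise_sd: float, amp_mult: float) -> np.ndarray:
        out = np.empty((n, 3))
        for k, w_axis in enumerate(config.axis_weights):
            axis = np.zeros(n)
            for h, w_h in enumerate(config.harmonic_weights, start=1):
                phase = rng.uniform(0, 2 * np.pi)
                axis += (
                    base_amp * amp_mult * w_axis * w_h
                    * np.cos(2 * np.pi * h * profile.step_freq_hz * t + phase)
                )
            out[:, k] = axis
        if noise_sd > 0:
            out += rng.normal(0, noise_sd, size=(n, 3))
        jitter_sd = config.jitter_base * base_amp * amp_mult * jit_mult
        if jitter_sd > 0:
            out += _band_noise(n, fs, config.jitter_band_hz, jitter_sd / np.sqrt(3), rng)
        return out

    acc = channels(config.acc_amplitude[sensor], config.noise_sd_acc, acc_mult)
    gyr = channels(config.gyr_amplitude[sensor], config.noise_sd_gyr, gyr_mult)
    return TrialRecording(
        participant_id=profile.participant_id,
        group=profile.group,
        task=task,
        sensor=sensor,
        acc=acc,
        gyr=gyr,
        sample_rate=fs,
        duration_s=duration_s,
    )


def _band_noise(
    n: int,
    fs: float,
    band: tuple[float, float],
    sd_per_axis: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited Gaussian noise with the requested per-axis sd."""
    white = rng.normal(0, 1.0, size=(n, 3))
    if n < 30:
        return white * sd_per_axis
    sos = _sig.butter(2, band, btype="bandpass", fs=fs, output="sos")
    shaped = _sig.sosfiltfilt(sos, white, axis=0)
    scale = shaped.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return shaped / scale * sd_per_axis


def _draw_duration(
    profile: ParticipantProfile,
    task: str,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> float:
    base = config.base_duration_s[task]
    mult = config.multiplier(profile.group, task, None, "duration")
    log_d = (
        np.log(base * mult)
        + profile.slowness
        + rng.normal(0, config.duration_sigma)
    )
    return max(float(np.exp(log_d)), 2.0)


def _draw_difficulty(
    profile: ParticipantProfile,
    task: str,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> int:
    latent = (
        config.base_difficulty[task]
        + config.difficulty_shifts.get((profile.group, task), 0.0)
        + profile.frailty
        + rng.normal(0, config.difficulty_noise_sd)
    )
    return 1 + int(np.sum(latent > np.asarray(config.difficulty_thresholds)))


def iter_cohort(
    config: SimulationConfig,
    signals: bool = True,
    tasks: Sequence[str] | None = None,
) -> Iterator[tuple[TrialMetadata, dict[str, TrialRecording] | None]]:
    """Yield (metadata, {sensor: recording} | None) per participant x task.

    Trials rated impossible carry no recordings (and no duration). With
    ``signals=False`` only metadata is generated (cheap path for
    duration/difficulty-level simulations); ``tasks`` restricts the yield
    to a subset without changing any trial's random stream. Generation is
    fully deterministic given ``config.seed`` and independent of
    consumption order (every trial derives its own random stream).
    """
    wanted = set(config.tasks if tasks is None else tasks)
    for gi, group in enumerate(GROUPS):
        for i in range(config.n_per_group):
            profile = _profile(config, group, i)
            for ti, task in enumerate(config.tasks):
                if task not in wanted:
                    continue
                meta_rng = np.random.default_rng([config.seed, 2, gi, i, ti])
                difficulty = _draw_difficulty(profile, task, meta_rng, config)
                if difficulty == 4:
                    meta = TrialMetadata(
                        participant_id=profile.participant_id,
                        group=group,
                        task=task,
                        duration_s=float("nan"),
                        difficulty=4,
                        completed=False,
                    )
                    yield meta, None
                    continue
                duration = _draw_duration(profile, task, meta_rng, config)
                meta = TrialMetadata(
                    participant_id=profile.participant_id,
                    group=group,
                    task=task,
                    duration_s=duration,
                    difficulty=difficulty,
                    completed=True,
                )
                if not signals:
                    yield meta, None
                    continue
                recordings = {}
                for si, sensor in enumerate(config.sensors):
                    trial_rng = np.random.default_rng([config.seed, 3, gi, i, ti, si])
                    recordings[sensor] = simulate_trial(
                        profile, task, sensor, trial_rng, config, duration_s=duration
                    )
                yield meta, recordings


def simulate_metadata(config: SimulationConfig) -> list[TrialMetadata]:
    """Metadata-only cohort (durations + difficulty ratings, no signals)."""
    return [meta for meta, _ in iter_cohort(config, signals=False)]


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[list[tuple[TrialMetadata, dict[str, TrialRecording] | None]], GroundTruth]:
    """Materialize the full cohort, optionally writing the on-disk layout.

    When ``out_dir`` is given, trial CSVs are written under
    ``<out_dir>/<participant>/<task>/<sensor>.csv`` with a
    ``metadata.csv`` table at the root.
    """
    trials = []
    metas = []
    for meta, recordings in iter_cohort(config):
        trials.append((meta, recordings))
        metas.append(meta)
        if out_dir is not None and recordings is not None:
            for rec in recordings.values():
                write_trial(rec, trial_path(out_dir, rec))
    if out_dir is not None:
        write_metadata_table(metas, Path(out_dir) / "metadata.csv")
    return trials, config.ground_truth()


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

#: Tasks carrying planted duration + difficulty effects in the default
#: scenario (the dual-criterion filter should recover these; walking in
#: the dark additionally gets a difficulty shift but essentially no
#: duration effect, so it relies on forced inclusion).
SCENARIO_EFFECT_TASKS = (
    "Pants",
    "Heavy load",
    "Uneven ground",
    "Stepladder",
    "Wood beam",
    "Inclined plane",
    "Picture recognition",
)


def default_paper_scenario(seed: int = 0) -> SimulationConfig:
    """The reference synthetic scenario with planted vestibulopathy effects.

    Plants the qualitative pattern the analysis is designed to detect:
    reduced foot-movement intensity for patients on sensory-challenging
    locomotor tasks (plus a trunk reduction on the inclined plane),
    elevated head jerk while dressing and sacrum jerk on the beam for BV,
    longer patient durations and higher perceived difficulty on the
    challenging tasks, with UV intermediate between BV and HS but more
    heterogeneous.
    """
    effects: list[Effect] = []
    for task in ("Uneven ground", "Inclined plane", "Walk in the dark"):
        for sensor in ("LF", "RF"):
            effects.append(Effect("BV", task, sensor, "amplitude", 0.70))
            effects.append(Effect("UV", task, sensor, "amplitude", 0.85))
    effects.append(Effect("BV", "Inclined plane", "TR", "amplitude", 0.80))
    effects.append(Effect("UV", "Inclined plane", "TR", "amplitude", 0.90))
    for task, sensor in (("Pants", "HE"), ("Wood beam", "SA")):
        effects.append(Effect("BV", task, sensor, "jitter", 2.5))
        effects.append(Effect("UV", task, sensor, "jitter", 1.6))
    for task in SCENARIO_EFFECT_TASKS:
        effects.append(Effect("BV", task, None, "duration", 1.40))
        effects.append(Effect("UV", task, None, "duration", 1.15))
    shifts: dict = {}
    for task in SCENARIO_EFFECT_TASKS + ("Walk in the dark",):
        shifts[("BV", task)] = 0.9
        shifts[("UV", task)] = 0.45
    return SimulationConfig(
        effects=tuple(effects),
        difficulty_shifts=shifts,
        locomotor_group_mean={"BV": 0.80, "UV": 0.90, "HS": 1.0},
        seed=seed,
    )


def null_scenario(seed: int = 0) -> SimulationConfig:
    """Same cohort structure with every group effect removed."""
    return SimulationConfig(effects=(), difficulty_shifts={}, seed=seed)
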