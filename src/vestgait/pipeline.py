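"""End-to-end orchestration of the staged analysis.

Stage order mirrors the analysis flow: preprocess trials, compute
features, reduce the 15 tasks by the dual duration/difficulty criterion,
run the correlation PCA with permutation retention, cumulative-VAF cut,
top-loading variable selection and bootstrap stability, then screen the
selected variables for three-group differences.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .component_analysis import (
    LoadingSelection,
    PCAModel,
    StabilityReport,
    bootstrap_stability,
    cumulative_vaf_cut,
    fit_pca,
    impute_missing,
    permutation_vaf_test,
    select_loading_variables,
    standardize,
)
from .discriminant import GroupScreenResult, screen_variables
from .features import FeatureRecord, build_feature_matrix, extract_trial_features
from .signal_io import GROUPS, TASKS, TrialMetadata, preprocess
from .task_selection import GroupSamples, TaskSelection, select_tasks

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "metadata_group_samples",
    "select_tasks_from_metadata",
    "extract_cohort_features",
    "run_pipeline",
    "config_hash",
    "write_manifest",
]


@dataclass
class PipelineConfig:
    """All tunable analysis settings; round-trips losslessly through YAML."""

    alpha: float = 0.05
    trim_fraction: float = 0.05
    filter_order: int = 4
    cutoff_hz: float = 6.0
    forced_tasks: tuple[str, ...] = ("Walk in the dark",)
    imputation: str = "group_median"
    n_perm: int = 1000
    n_boot: int = 1000
    loading_pct: float = 0.10
    loading_cap: int = 10
    cumulative_vaf: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must lie in [0, 0.5)")
        if self.cutoff_hz <= 0 or self.filter_order < 1:
            raise ValueError("invalid filter settings")
        if self.imputation not in ("group_median", "overall_median", "complete_case"):
            raise ValueError(f"unknown imputation strategy {self.imputation!r}")
        if not 0 < self.loading_pct <= 1 or self.loading_cap < 1:
            raise ValueError("invalid loading-selection settings")
        if not 0 < self.cumulative_vaf <= 1:
            raise ValueError("cumulative_vaf must lie in (0, 1]")
        if self.n_perm < 1 or self.n_boot < 1:
            raise ValueError("n_perm and n_boot must be positive")
        self.forced_tasks = tuple(self.forced_tasks)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["forced_tasks"] = list(self.forced_tasks)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data)

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        perm, boot = ss.spawn(2)
        return {
            "permutation": int(perm.generate_state(1)[0] % (2**31)),
            "bootstrap": int(boot.generate_state(1)[0] % (2**31)),
        }


def config_hash(config: PipelineConfig) -> str:
    data = asdict(config)
    data["forced_tasks"] = list(config.forced_tasks)
    blob = json.dumps(data, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: str | Path, stage: str, config: PipelineConfig, **extra) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": __version__,
        **extra,
    }
    with open(out_dir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def metadata_group_samples(
    metadata: Sequence[TrialMetadata],
) -> tuple[dict[str, GroupSamples], dict[str, GroupSamples]]:
    """Per-task duration and difficulty samples split by group.

    Incomplete (impossible) trials contribute their difficulty rating of
    4 but no duration observation.
    """
    tasks = sorted({m.task for m in metadata}, key=lambda t: TASKS.index(t) if t in TASKS else 99)
    durations, difficulties = {}, {}
    for task in tasks:
        dur = {g: [] for g in GROUPS}
        diff = {g: [] for g in GROUPS}
        for m in metadata:
            if m.task != task:
                continue
            diff[m.group].append(float(m.difficulty))
            if m.completed:
                dur[m.group].append(float(m.duration_s))
        durations[task] = GroupSamples(f"{task}|duration", {g: np.array(v) for g, v in dur.items()})
        difficulties[task] = GroupSamples(f"{task}|difficulty", {g: np.array(v) for g, v in diff.items()})
    return durations, difficulties


def select_tasks_from_metadata(
    metadata: Sequence[TrialMetadata],
    alpha: float = 0.05,
    forced: Sequence[str] = ("Walk in the dark",),
) -> TaskSelection:
    durations, difficulties = metadata_group_samples(metadata)
    return select_tasks(durations, difficulties, alpha=alpha, forced=forced)


def extract_cohort_features(
    trials: Iterable[tuple[TrialMetadata, Mapping | None]],
    config: PipelineConfig,
) -> list[FeatureRecord]:
    """Preprocess (trim then filter) and extract features trial by trial."""
    records = []
    for meta, recordings in trials:
        if not meta.completed or recordings is None:
            records.append(
                FeatureRecord(
                    participant_id=meta.participant_id,
                    group=meta.group,
                    task=meta.task,
                    values={},
                    completed=False,
                )
            )
            continue
        processed = {
            sensor: preprocess(
                rec, config.trim_fraction, config.filter_order, config.cutoff_hz
            )
            for sensor, rec in recordings.items()
        }
        records.append(extract_trial_features(processed, meta))
    return records


@dataclass
class PipelineResult:
    """Everything the staged analysis produces for one cohort."""

    task_selection: TaskSelection
    selected_tasks: list[str]
    feature_matrix: pd.DataFrame
    imputed_matrix: pd.DataFrame
    imputation_log: list[dict]
    model: PCAModel
    n_components_permutation: int
    n_components_final: int
    loading_selection: LoadingSelection
    stability: StabilityReport | None
    screen: list[GroupScreenResult]

    @property
    def significant_variables(self) -> list[str]:
        return [r.variable for r in self.screen if r.significant]


def variable_sources(selection: LoadingSelection) -> dict[str, str]:
    """Map each selected variable to the first component that picked it."""
    sources: dict[str, str] = {}
    for comp, names in selection.per_component.items():
        for name in names:
            sources.setdefault(name, comp)
    return sources


def run_pipeline(sim_config, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis in memory on a synthetic cohort.

    Task selection runs first on metadata alone; signals are then only
    generated and featurized for the selected tasks (the variables of
    unselected tasks never enter the analysis).
    """
    from .synthetic_data import SimulationConfig, iter_cohort, simulate_metadata

    config = config or PipelineConfig()
    metadata = simulate_metadata(sim_config)
    selection = select_tasks_from_metadata(
        metadata, alpha=config.alpha, forced=config.forced_tasks
    )
    selected = [t for t in sim_config.tasks if t in selection.selected_tasks]
    if not selected:
        raise ValueError("no task passed the dual criterion (and none was forced)")
    records = extract_cohort_features(
        iter_cohort(sim_config, tasks=selected), config
    )
    matrix = build_feature_matrix(records, selected)
    imputed, imp_log = impute_missing(matrix, config.imputation)
    z = standardize(imputed)
    model = fit_pca(z)
    seeds = config.stage_seeds()
    n_perm_ret = permutation_vaf_test(
        z, n_perm=config.n_perm, alpha=config.alpha, seed=seeds["permutation"]
    )
    n_final = cumulative_vaf_cut(model.vaf, config.cumulative_vaf, n_perm_ret)
    loading_sel = select_loading_variables(
        model, n_final, pct=config.loading_pct, cap=config.loading_cap
    )
    stability = None
    if n_final > 0:
        stability = bootstrap_stability(
            imputed, model, n_final, n_boot=config.n_boot, seed=seeds["bootstrap"]
        )
    screen = screen_variables(
        imputed,
        loading_sel.union,
        alpha=config.alpha,
        sources=variable_sources(loading_sel),
    )
    return PipelineResult(
        task_selection=selection,
        selected_tasks=selected,
        feature_matrix=matrix,
        imputed_matrix=imputed,
        imputation_log=imp_log,
        model=model,
        n_components_permutation=n_perm_ret,
        n_components_final=n_final,
        loading_selection=loading_sel,
        stability=stability,
        screen=screen,
    )
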