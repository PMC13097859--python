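"""Nonparametric three-group tests and the dual-criterion task filter.

Tasks enter the downstream analysis only if both the task duration and the
perceived difficulty differ significantly between the three groups
(Kruskal-Wallis, alpha = 0.05), with pairwise Dunn post-hoc tests
(Holm-corrected within the three-pair family) computed whenever the
omnibus test is significant. Clinically essential tasks can be forced in
regardless of the dual criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .signal_io import GROUPS

__all__ = [
    "PAIRS",
    "GroupSamples",
    "TaskTestResult",
    "TaskSelection",
    "kruskal_wallis",
    "dunn_posthoc",
    "holm_adjust",
    "select_tasks",
    "shapiro_wilk",
    "selection_report",
    "write_selection_report",
]

#: The three pairwise comparisons, in reporting order.
PAIRS = (("BV", "HS"), ("UV", "HS"), ("BV", "UV"))


@dataclass
class GroupSamples:
    """Observations of one variable split by group (fixed order BV, UV, HS)."""

    variable: str
    samples: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.samples = {
            g: np.asarray(self.samples.get(g, ()), dtype=float) for g in GROUPS
        }

    def arrays(self) -> list[np.ndarray]:
        return [self.samples[g] for g in GROUPS]

    def require_min_n(self, n: int = 2) -> None:
        for g in GROUPS:
            if len(self.samples[g]) < n:
                raise ValueError(
                    f"{self.variable}: group {g} has fewer than {n} observations"
                )


def kruskal_wallis(groups: GroupSamples) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    When every observation is identical the test statistic is undefined;
    by convention this returns (0.0, 1.0).
    """
    groups.require_min_n(2)
    arrays = groups.arrays()
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = _st.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(groups: GroupSamples) -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's pairwise z tests on pooled ranks, Holm-adjusted two-sided p.

    z for a pair (a, b) is ``(Rbar_a - Rbar_b) / se`` with
    ``se = sqrt((N(N+1)/12 - T) * (1/n_a + 1/n_b))`` and the tie term
    ``T = sum(t^3 - t) / (12 (N - 1))``. Returns
    ``{(a, b): (z, holm-adjusted p)}`` for the three pairs.
    """
    groups.require_min_n(2)
    arrays = groups.arrays()
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = _st.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for g, arr in zip(GROUPS, arrays):
        sizes[g] = len(arr)
        mean_ranks[g] = float(ranks[start : start + len(arr)].mean())
        start += len(arr)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var0 = n_total * (n_total + 1) / 12.0 - tie_term
    if var0 <= 0:
        raise ValueError(f"{groups.variable}: degenerate rank variance (all ties)")
    zs, ps = [], []
    for a, b in PAIRS:
        se = np.sqrt(var0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        zs.append(float(z))
        ps.append(float(2.0 * _st.norm.sf(abs(z))))
    adjusted = holm_adjust(ps)
    return {pair: (z, p) for pair, z, p in zip(PAIRS, zs, adjusted)}


def holm_adjust(pvals: Sequence[float]) -> list[float]:
    """Step-down Holm adjustment, order-preserving and capped at 1."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="holm")
    return [float(p) for p in adjusted]


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality diagnostic (W, p); not used for gating."""
    w, p = _st.shapiro(np.asarray(values, dtype=float))
    return float(w), float(p)


@dataclass
class TaskTestResult:
    """Dual-criterion test outcome for one task."""

    task: str
    kw_p_duration: float
    kw_p_difficulty: float
    posthoc_duration: dict[tuple[str, str], tuple[float, float]] | None
    posthoc_difficulty: dict[tuple[str, str], tuple[float, float]] | None
    selected: bool
    forced: bool


@dataclass
class TaskSelection:
    """Per-task results plus the ordered list of tasks entering the analysis."""

    alpha: float
    results: dict[str, TaskTestResult]

    @property
    def selected_tasks(self) -> list[str]:
        return [t for t, r in self.results.items() if r.selected]


def select_tasks(
    durations: Mapping[str, GroupSamples],
    difficulties: Mapping[str, GroupSamples],
    alpha: float = 0.05,
    forced: Sequence[str] = ("Walk in the dark",),
) -> TaskSelection:
    """Apply the dual criterion to every task.

    A task is selected iff both the duration and the difficulty
    Kruskal-Wallis p-values fall below ``alpha``, or the task appears in
    ``forced`` (clinically essential tasks kept regardless). Post-hoc
    Dunn tests are run only for significant omnibus tests.
    """
    if set(durations) != set(difficulties):
        raise ValueError("duration and difficulty task sets differ")
    unknown = [t for t in forced if t not in durations]
    if unknown:
        raise ValueError(f"forced tasks not in the task set: {', '.join(unknown)}")
    results: dict[str, TaskTestResult] = {}
    for task in durations:
        _, p_dur = kruskal_wallis(durations[task])
        _, p_diff = kruskal_wallis(difficulties[task])
        ph_dur = dunn_posthoc(durations[task]) if p_dur < alpha else None
        ph_diff = dunn_posthoc(difficulties[task]) if p_diff < alpha else None
        is_forced = task in forced
        selected = (p_dur < alpha and p_diff < alpha) or is_forced
        results[task] = TaskTestResult(
            task=task,
            kw_p_duration=p_dur,
            kw_p_difficulty=p_diff,
            posthoc_duration=ph_dur,
            posthoc_difficulty=ph_diff,
            selected=selected,
            forced=is_forced,
        )
    return TaskSelection(alpha=alpha, results=results)


def selection_report(selection: TaskSelection) -> pd.DataFrame:
    """Tabular report: one row per task x parameter, pairwise Holm p's."""
    rows = []
    for task, res in selection.results.items():
        for param, kw_p, ph in (
            ("duration", res.kw_p_duration, res.posthoc_duration),
            ("difficulty", res.kw_p_difficulty, res.posthoc_difficulty),
        ):
            row = {"task": task, "parameter": param, "kw_p": kw_p}
            for pair in PAIRS:
                key = f"p_{pair[0].lower()}_{pair[1].lower()}"
                row[key] = ph[pair][1] if ph is not None else np.nan
            row["selected"] = res.selected
            row["forced"] = res.forced
            rows.append(row)
    return pd.DataFrame(rows)


def write_selection_report(selection: TaskSelection, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    selection_report(selection).to_csv(path, index=False)
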