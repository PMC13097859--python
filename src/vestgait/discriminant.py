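"""Three-group screening of the PCA-selected variables.

Each variable from the component-analysis union is tested with a
Kruskal-Wallis omnibus test; when significant, Dunn's pairwise post-hoc
tests with Holm correction follow. No correction is applied across
variables — each variable is reported on its own, with per-group medians
and interquartile ranges for context.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signal_io import GROUPS
from .task_selection import PAIRS, GroupSamples, dunn_posthoc, kruskal_wallis

__all__ = ["GroupScreenResult", "screen_variables", "summarize_screen", "stars"]


@dataclass
class GroupScreenResult:
    """Outcome of the omnibus + post-hoc screen for one variable."""

    variable: str
    component: str | None
    kw_p: float
    pairwise: dict[tuple[str, str], tuple[float, float]] | None
    significant: bool
    medians: dict[str, float]
    iqrs: dict[str, float]


def _group_samples(matrix: pd.DataFrame, variable: str) -> GroupSamples:
    samples = {}
    for g in GROUPS:
        vals = matrix.loc[matrix["group"] == g, variable].dropna().to_numpy(float)
        samples[g] = vals
    return GroupSamples(variable=variable, samples=samples)


def screen_variables(
    matrix: pd.DataFrame,
    variables: Sequence[str],
    alpha: float = 0.05,
    sources: Mapping[str, str] | None = None,
) -> list[GroupScreenResult]:
    """Kruskal-Wallis screen over ``variables`` of the feature matrix.

    ``sources`` optionally maps variable -> originating component (for
    reporting). Post-hoc Dunn-Holm p-values are computed only when the
    omnibus test is significant at ``alpha``.
    """
    missing = [v for v in variables if v not in matrix.columns]
    if missing:
        raise ValueError(f"variables absent from the matrix: {', '.join(missing)}")
    results: list[GroupScreenResult] = []
    for var in variables:
        gs = _group_samples(matrix, var)
        _, kw_p = kruskal_wallis(gs)
        significant = kw_p < alpha
        pairwise = dunn_posthoc(gs) if significant else None
        medians, iqrs = {}, {}
        for g in GROUPS:
            vals = gs.samples[g]
            medians[g] = float(np.median(vals))
            q1, q3 = np.percentile(vals, [25, 75])
            iqrs[g] = float(q3 - q1)
        results.append(
            GroupScreenResult(
                variable=var,
                component=sources.get(var) if sources else None,
                kw_p=float(kw_p),
                pairwise=pairwise,
                significant=significant,
                medians=medians,
                iqrs=iqrs,
            )
        )
    return results


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize_screen(results: Sequence[GroupScreenResult]) -> pd.DataFrame:
    """Report table ordered by source component then ascending KW p."""
    rows = []
    for r in results:
        row = {
            "variable": r.variable,
            "component": r.component or "",
            "kw_p": r.kw_p,
            "kw_stars": stars(r.kw_p),
            "significant": r.significant,
        }
        for pair in PAIRS:
            key = f"p_{pair[0].lower()}_{pair[1].lower()}"
            row[key] = r.pairwise[pair][1] if r.pairwise is not None else np.nan
        for g in GROUPS:
            row[f"median_{g}"] = r.medians[g]
            row[f"iqr_{g}"] = r.iqrs[g]
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["component", "kw_p"], kind="stable").reset_index(drop=True)
    return df


def write_screen_report(results: Sequence[GroupScreenResult], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    summarize_screen(results).to_csv(path, index=False)
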