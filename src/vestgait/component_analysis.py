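"""Correlation-matrix PCA with permutation retention and bootstrap stability.

The feature matrix mixes units (m/s^2, deg/s, %, s), so PCA is performed
on z-scored columns (equivalently, on the correlation matrix). Loadings
are correlation-scaled (eigenvector x sqrt(eigenvalue)), so a loading is
the correlation between a variable and a component score.

Component retention is decided in two stages:

1. a nonparametric permutation test on the variance accounted for (VAF):
   component k is kept while its observed VAF exceeds the (1 - alpha)
   quantile of VAF_k over matrices whose columns were independently
   permuted (retention stops at the first failure);
2. a cumulative-VAF cut keeping only the leading components that together
   explain at least 50% of the total variance.

Robustness of the retained components is quantified by a stratified
bootstrap over participants: each resample is refitted, components are
greedily matched to the originals by absolute Tucker congruence, and the
mean Pearson r, RMS loading difference, congruence coefficient (CC) and
Cattell's salient-similarity s are reported per component.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "LoadingSelection",
    "StabilityReport",
    "impute_missing",
    "standardize",
    "fit_pca",
    "permutation_vaf_test",
    "cumulative_vaf_cut",
    "select_loading_variables",
    "congruence_coefficient",
    "cattell_s",
    "bootstrap_stability",
    "write_pca_report",
]


# ---------------------------------------------------------------------------
# Missing data and standardization
# ---------------------------------------------------------------------------


def _split(matrix: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    if "group" not in matrix.columns:
        raise ValueError("feature matrix must carry a 'group' column")
    return matrix["group"], matrix.drop(columns="group")


def impute_missing(
    matrix: pd.DataFrame, strategy: str = "group_median"
) -> tuple[pd.DataFrame, list[dict]]:
    """Fill missing cells (tasks rated impossible leave NaNs).

    Strategies: ``group_median`` (median within the participant's group,
    keeps everyone and respects group structure), ``overall_median``, and
    ``complete_case`` (drop incomplete participants). Returns the filled
    matrix and a log of imputed cells (or dropped rows).
    """
    if strategy not in ("group_median", "overall_median", "complete_case"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    group, values = _split(matrix)
    log: list[dict] = []
    all_missing = values.columns[values.isna().all()]
    if len(all_missing):
        raise ValueError(f"columns entirely missing: {', '.join(all_missing)}")
    if strategy == "complete_case":
        keep = ~values.isna().any(axis=1)
        for pid in values.index[~keep]:
            log.append({"action": "dropped_row", "participant_id": pid})
        out = matrix.loc[keep].copy()
        if out.shape[0] == 0:
            raise ValueError("complete_case removed every participant")
        return out, log
    frac_missing = values.isna().mean()
    too_sparse = frac_missing.index[frac_missing >= 0.5]
    if len(too_sparse):
        raise ValueError(
            f"columns with >= 50% missing (median imputation unsafe): "
            f"{', '.join(too_sparse)}"
        )
    filled = values.copy()
    for col in values.columns[values.isna().any()]:
        if strategy == "group_median":
            fill = values.groupby(group)[col].transform("median")
        else:
            fill = pd.Series(values[col].median(), index=values.index)
        mask = values[col].isna()
        filled.loc[mask, col] = fill[mask]
        for pid in values.index[mask]:
            log.append(
                {
                    "action": "imputed",
                    "participant_id": pid,
                    "variable": col,
                    "value": float(filled.loc[pid, col]),
                }
            )
    out = filled.copy()
    out.insert(0, "group", group)
    return out, log


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """z-score every feature column (mean 0, sd 1 with ddof=1).

    The matrix must already be complete (see :func:`impute_missing`).
    """
    group, values = _split(matrix)
    if values.isna().any().any():
        raise ValueError("matrix has missing cells; impute before standardizing")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 participants to standardize")
    sd = values.std(ddof=1)
    dead = sd.index[(sd == 0) | ~np.isfinite(sd)]
    if len(dead):
        raise ValueError(f"zero-variance columns: {', '.join(dead)}")
    z = (values - values.mean()) / sd
    out = z.copy()
    out.insert(0, "group", group)
    return out


# ---------------------------------------------------------------------------
# PCA core
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Correlation-scaled loadings, VAF per component, participant scores."""

    loadings: pd.DataFrame  # variables x components
    vaf: np.ndarray  # percent per component, descending
    scores: pd.DataFrame  # participants x components
    variable_names: list[str]
    n_components: int


def fit_pca(matrix: pd.DataFrame) -> PCAModel:
    """PCA of a standardized matrix via SVD.

    Components are ordered by decreasing VAF; the sign of each component
    is fixed so that its largest-|loading| entry is positive, which makes
    the fit fully deterministic. The number of components is capped at
    min(n_participants, n_variables); because the columns are centred the
    discarded dimensions carry exactly zero variance, so VAF still sums
    to 100%.
    """
    _, z = _split(matrix)
    if z.isna().any().any():
        raise ValueError("standardized matrix contains missing cells")
    n, p = z.shape
    zv = z.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(zv, full_matrices=False)
    eig = s**2 / (n - 1)
    vaf = eig / p * 100.0
    loadings = vt.T * np.sqrt(eig)
    scores = u * s
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
            scores[:, k] = -scores[:, k]
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAModel(
        loadings=pd.DataFrame(loadings, index=z.columns, columns=comp_names),
        vaf=vaf,
        scores=pd.DataFrame(scores, index=z.index, columns=comp_names),
        variable_names=list(z.columns),
        n_components=len(comp_names),
    )


def _vaf_of(zv: np.ndarray) -> np.ndarray:
    s = np.linalg.svd(zv, compute_uv=False)
    return s**2 / (zv.shape[0] - 1) / zv.shape[1] * 100.0


def permutation_vaf_test(
    matrix: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> int:
    """Number of leading components whose VAF beats the permutation null.

    Each permuted dataset shuffles every column independently, destroying
    between-variable correlation while preserving marginals. Component k
    is retained iff its observed VAF exceeds the (1 - alpha) quantile of
    the k-th null VAF; testing stops at the first failure (sequential
    testing, respecting the VAF ordering).
    """
    if n_perm < 100:
        logger.warning("permutation test with n_perm=%d < 100 is unreliable", n_perm)
    rng = np.random.default_rng(seed)
    _, z = _split(matrix)
    zv = z.to_numpy(dtype=float)
    observed = _vaf_of(zv)
    null = np.empty((n_perm, len(observed)))
    for i in range(n_perm):
        null[i] = _vaf_of(rng.permuted(zv, axis=0))
    thresholds = np.quantile(null, 1.0 - alpha, axis=0)
    retained = 0
    for k in range(len(observed)):
        if observed[k] > thresholds[k]:
            retained += 1
        else:
            break
    return retained


def cumulative_vaf_cut(
    vaf: Sequence[float], threshold: float = 0.50, permutation_retained: int = 0
) -> int:
    """Smallest k <= permutation_retained whose cumulative VAF >= threshold.

    If even the full permutation-retained set does not reach the
    threshold, all of it is kept (with a warning).
    """
    vaf = np.asarray(vaf, dtype=float)
    cumulative = np.cumsum(vaf)
    for k in range(1, permutation_retained + 1):
        if cumulative[k - 1] >= threshold * 100.0 - 1e-12:
            return k
    logger.warning(
        "cumulative VAF %.1f%% of the %d permutation-retained components "
        "stays below %.0f%%; keeping all of them",
        cumulative[permutation_retained - 1] if permutation_retained else 0.0,
        permutation_retained,
        threshold * 100,
    )
    return permutation_retained


@dataclass
class LoadingSelection:
    """Top-loading variables per retained component and their union."""

    per_component: dict[str, list[str]]
    thresholds: dict[str, float]
    union: list[str]


def select_loading_variables(
    model: PCAModel, components: int, pct: float = 0.10, cap: int = 10
) -> LoadingSelection:
    """Keep the ``pct`` highest |loading| variables per component, capped.

    The per-component count is ``min(ceil(pct * n_vars), cap)``; exact
    ties at the cut are all included (and logged). The reported threshold
    is the smallest retained |loading|.
    """
    if components > model.n_components:
        raise ValueError("more components requested than the model holds")
    n_vars = len(model.variable_names)
    m = min(math.ceil(pct * n_vars), cap)
    per_component: dict[str, list[str]] = {}
    thresholds: dict[str, float] = {}
    union: list[str] = []
    for k in range(components):
        comp = model.loadings.columns[k]
        abs_load = model.loadings[comp].abs().sort_values(ascending=False, kind="stable")
        cut_value = float(abs_load.iloc[m - 1])
        selected = abs_load.index[abs_load >= cut_value].tolist()
        if len(selected) > m:
            logger.info(
                "%s: %d variables tied at |loading|=%.6f; keeping all %d",
                comp, len(selected) - m + 1, cut_value, len(selected),
            )
        per_component[comp] = selected
        thresholds[comp] = cut_value
        for v in selected:
            if v not in union:
                union.append(v)
    return LoadingSelection(per_component=per_component, thresholds=thresholds, union=union)


# ---------------------------------------------------------------------------
# Component similarity metrics
# ---------------------------------------------------------------------------


def congruence_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Tucker congruence: sum(x*y) / sqrt(sum(x^2) sum(y^2)), in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("loading vectors must have equal length")
    denom = math.sqrt(float(x @ x) * float(y @ y))
    if denom == 0:
        raise ValueError("congruence undefined for a zero vector")
    return float(x @ y) / denom


def cattell_s(x: np.ndarray, y: np.ndarray, hyperplane_cut: float = 0.1) -> float:
    """Cattell's salient-variable similarity between two loading vectors.

    Loadings are classified as salient-positive (> cut), salient-negative
    (< -cut) or hyperplane. With c_ab the joint classification counts,
    ``s = (c_pp + c_nn - c_pn - c_np) / (n - c_hh)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("loading vectors must have equal length")
    cx = np.where(x > hyperplane_cut, 1, np.where(x < -hyperplane_cut, -1, 0))
    cy = np.where(y > hyperplane_cut, 1, np.where(y < -hyperplane_cut, -1, 0))
    c_hh = int(np.sum((cx == 0) & (cy == 0)))
    denom = len(x) - c_hh
    if denom == 0:
        raise ValueError("Cattell's s undefined: all loadings in the hyperplane")
    agree = int(np.sum((cx == 1) & (cy == 1)) + np.sum((cx == -1) & (cy == -1)))
    disagree = int(np.sum((cx == 1) & (cy == -1)) + np.sum((cx == -1) & (cy == 1)))
    return (agree - disagree) / denom


# ---------------------------------------------------------------------------
# Bootstrap stability
# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    """Mean bootstrap similarity of each retained component to the original."""

    components: list[str]
    pearson_r: dict[str, float]
    rms: dict[str, float]
    cc: dict[str, float]
    cattell: dict[str, float]
    n_boot: int
    seed: int | None
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": self.components,
                "r": [self.pearson_r[c] for c in self.components],
                "rms": [self.rms[c] for c in self.components],
                "cc": [self.cc[c] for c in self.components],
                "cattell_s": [self.cattell[c] for c in self.components],
                "n_boot": self.n_boot,
                "seed": self.seed,
            }
        )


def _stratified_resample(groups: pd.Series, rng: np.random.Generator) -> np.ndarray:
    idx = np.arange(len(groups))
    out = []
    for g in pd.unique(groups):
        members = idx[(groups == g).to_numpy()]
        out.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(out)


def bootstrap_stability(
    matrix: pd.DataFrame,
    model: PCAModel,
    components: int,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    hyperplane_cut: float = 0.1,
) -> StabilityReport:
    """Bootstrap the participants and measure loading reproducibility.

    ``matrix`` is the complete (imputed, unstandardized) feature matrix
    with its group column; each bootstrap draw resamples participants
    with replacement within groups, is re-standardized and refitted, and
    each original component is matched to the bootstrap component with
    the highest |CC| (greedy from PC1, without replacement), sign-aligned
    to positive congruence. Resamples that kill a column's variance are
    redrawn (counted in ``n_redrawn``).
    """
    rng = np.random.default_rng(seed)
    group, values = _split(matrix)
    if components > model.n_components:
        raise ValueError("more components requested than the model holds")
    comp_names = list(model.loadings.columns[:components])
    orig = model.loadings.to_numpy(dtype=float)[:, :components]
    acc = {name: {"r": [], "rms": [], "cc": [], "s": []} for name in comp_names}
    n_redrawn = 0
    vals = values.to_numpy(dtype=float)
    for _ in range(n_boot):
        for _attempt in range(100):
            take = _stratified_resample(group, rng)
            sample = vals[take]
            sd = sample.std(axis=0, ddof=1)
            if np.all(sd > 0):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a bootstrap sample with full variance")
        z = (sample - sample.mean(axis=0)) / sd
        n = z.shape[0]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = s**2 / (n - 1)
        boot_loadings = vt.T * np.sqrt(eig)
        available = list(range(boot_loadings.shape[1]))
        for k, name in enumerate(comp_names):
            ccs = [
                congruence_coefficient(orig[:, k], boot_loadings[:, j])
                for j in available
            ]
            best_pos = int(np.argmax(np.abs(ccs)))
            j = available.pop(best_pos)
            b = boot_loadings[:, j]
            if ccs[best_pos] < 0:
                b = -b
            acc[name]["cc"].append(abs(ccs[best_pos]))
            acc[name]["r"].append(float(np.corrcoef(orig[:, k], b)[0, 1]))
            acc[name]["rms"].append(float(np.sqrt(np.mean((orig[:, k] - b) ** 2))))
            acc[name]["s"].append(cattell_s(orig[:, k], b, hyperplane_cut))
    return StabilityReport(
        components=comp_names,
        pearson_r={c: float(np.mean(acc[c]["r"])) for c in comp_names},
        rms={c: float(np.mean(acc[c]["rms"])) for c in comp_names},
        cc={c: float(np.mean(acc[c]["cc"])) for c in comp_names},
        cattell={c: float(np.mean(acc[c]["s"])) for c in comp_names},
        n_boot=n_boot,
        seed=seed if isinstance(seed, int) else None,
        n_redrawn=n_redrawn,
    )


def write_pca_report(
    out_dir: str | Path,
    model: PCAModel,
    permutation_retained: int,
    final_components: int,
    selection: LoadingSelection,
    stability: StabilityReport | None = None,
) -> None:
    """Write the PCA interface files: JSON report, loadings CSV, stability CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {
        "vaf_pct": [float(v) for v in model.vaf],
        "n_components_permutation": permutation_retained,
        "n_components_final": final_components,
        "selected_variables": selection.per_component,
        "loading_thresholds": selection.thresholds,
        "union": selection.union,
    }
    with open(out_dir / "pca_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    model.loadings.to_csv(out_dir / "loadings.csv")
    if stability is not None:
        stability.to_frame().to_csv(out_dir / "stability.csv", index=False)
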