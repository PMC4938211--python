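"""Per-voxel ordinary-least-squares fitting, contrast t-maps, thresholding.

A single GLM covers one run or a concatenation of runs.  For concatenated
sessions the task regressors are stacked across runs while drift regressors
(DCT basis including the run mean) enter block-diagonally per run, so each
run keeps its own baseline and slow-drift model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .design import RunSchedule
from .hrf import DesignMatrix, FilterSpec, HRFModel, build_design_matrix, drift_basis


@dataclass(frozen=True)
class BetaEstimates:
    """OLS coefficients per voxel with the pieces needed for t-statistics."""

    betas: np.ndarray  # voxels x regressors
    residual_variance: np.ndarray  # per voxel, SSR / dof
    dof: int
    design: np.ndarray  # volumes x regressors
    regressor_labels: tuple[str, ...]

    def column(self, label: str) -> np.ndarray:
        """Beta vector (one value per voxel) for a named regressor."""
        return self.betas[:, self.regressor_labels.index(label)]


@dataclass(frozen=True)
class ContrastMap:
    t_values: np.ndarray
    dof: int
    contrast_vector: np.ndarray


@dataclass(frozen=True)
class ThresholdSpec:
    """Voxelwise threshold: Benjamini-Hochberg FDR or uncorrected p."""

    method: str = "fdr_q"
    level: float = 0.001

    def __post_init__(self) -> None:
        if self.method not in ("fdr_q", "uncorrected_p"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if not 0 < self.level < 1:
            raise ValueError("level must lie strictly between 0 and 1")


def _collinear_columns(design: np.ndarray, labels: tuple[str, ...]) -> list[str]:
    """Columns whose removal does not reduce the design rank (best effort)."""
    rank = np.linalg.matrix_rank(design)
    flagged = []
    for j in range(design.shape[1]):
        reduced = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            flagged.append(labels[j] if j < len(labels) else f"col{j}")
    return flagged


def fit_glm(
    data: np.ndarray,
    design: np.ndarray | DesignMatrix,
    regressor_labels: tuple[str, ...] | None = None,
) -> BetaEstimates:
    """OLS fit of every voxel's time series against a shared design.

    ``data`` is voxels x volumes.  The design must be full column rank;
    a rank-deficient design raises an error naming the collinear columns.
    Residual variance is unbiased (SSR / dof with dof = volumes - rank).
    """
    if isinstance(design, DesignMatrix):
        regressor_labels = design.regressor_labels
        design = design.values
    design = np.asarray(design, dtype=float)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if regressor_labels is None:
        regressor_labels = tuple(f"col{j}" for j in range(design.shape[1]))
    n_volumes, n_reg = design.shape
    if data.shape[1] != n_volumes:
        raise ValueError(
            f"data has {data.shape[1]} volumes but design has {n_volumes}"
        )
    rank = np.linalg.matrix_rank(design)
    if rank < n_reg:
        raise ValueError(
            "rank-deficient design; collinear columns: "
            + ", ".join(_collinear_columns(design, regressor_labels))
        )
    betas, _, _, _ = np.linalg.lstsq(design, data.T, rcond=None)
    residuals = data.T - design @ betas
    dof = n_volumes - rank
    ssr = np.sum(residuals**2, axis=0)
    return BetaEstimates(
        betas=betas.T,
        residual_variance=ssr / dof,
        dof=dof,
        design=design,
        regressor_labels=tuple(regressor_labels),
    )


def contrast_t_map(estimates: BetaEstimates, contrast_vector: np.ndarray) -> ContrastMap:
    """t(v) = c'b(v) / sqrt(sigma2(v) * c'(X'X)^-1 c), with an infinite-t
    sentinel where the residual variance is zero but the numerator is not."""
    c = np.asarray(contrast_vector, dtype=float)
    if c.shape != (len(estimates.regressor_labels),):
        raise ValueError(
            f"contrast length {c.size} != regressor count "
            f"{len(estimates.regressor_labels)}"
        )
    xtx_inv = np.linalg.pinv(estimates.design.T @ estimates.design)
    scale = float(c @ xtx_inv @ c)
    numer = estimates.betas @ c
    denom2 = estimates.residual_variance * scale
    # a residual variance that is zero to machine precision relative to the
    # contrast magnitude marks an exact fit: report the infinite-t sentinel
    degenerate = denom2 <= numer**2 * 1e-24
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, numer) / np.where(degenerate, 1.0, np.sqrt(denom2))
    sentinel = np.where(numer > 0, np.inf, np.where(numer < 0, -np.inf, 0.0))
    t = np.where(degenerate, sentinel, t)
    return ContrastMap(t_values=t, dof=estimates.dof, contrast_vector=c)


def threshold_map(cmap: ContrastMap, spec: ThresholdSpec) -> np.ndarray:
    """Binary voxel mask from two-sided p-values.

    ``uncorrected_p`` keeps voxels with p < level; ``fdr_q`` applies
    Benjamini-Hochberg across all in-analysis voxels at rate ``level``.
    """
    t = np.asarray(cmap.t_values, dtype=float)
    if t.size == 0:
        raise ValueError("cannot threshold an empty map")
    p = 2.0 * sp_stats.t.sf(np.abs(t), cmap.dof)
    p = np.where(np.isinf(t), 0.0, p)
    if spec.method == "uncorrected_p":
        return p < spec.level
    reject, _, _, _ = multipletests(p, alpha=spec.level, method="fdr_bh")
    return reject


def session_design(
    schedules: list[RunSchedule],
    scheme: str,
    hrf: HRFModel,
    filter_spec: FilterSpec = FilterSpec(),
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Concatenated multi-run design: stacked task columns plus per-run
    block-diagonal drift/mean regressors."""
    per_run = [build_design_matrix(s, scheme, hrf) for s in schedules]
    task_labels = per_run[0].task_labels
    task = np.vstack([d.task_values for d in per_run])
    blocks, drift_labels = [], []
    offset = 0
    total = sum(s.n_volumes for s in schedules)
    for r, s in enumerate(schedules):
        basis = drift_basis(s.n_volumes, filter_spec)
        block = np.zeros((total, basis.shape[1]))
        block[offset : offset + s.n_volumes] = basis
        blocks.append(block)
        drift_labels += [f"drift{k}_run{r}" for k in range(basis.shape[1])]
        offset += s.n_volumes
    design = np.hstack([task] + blocks)
    return design, task_labels + tuple(drift_labels)


def fit_session(
    runs_data: list[np.ndarray],
    schedules: list[RunSchedule],
    scheme: str,
    hrf: HRFModel,
    filter_spec: FilterSpec = FilterSpec(),
) -> BetaEstimates:
    """Fit one GLM to the concatenation of several runs."""
    if len(runs_data) != len(schedules):
        raise ValueError("one schedule per run is required")
    design, labels = session_design(schedules, scheme, hrf, filter_spec)
    data = np.hstack([np.atleast_2d(d) for d in runs_data])
    return fit_glm(data, design, labels)


def fit_run(
    data: np.ndarray,
    schedule: RunSchedule,
    scheme: str,
    hrf: HRFModel,
    filter_spec: FilterSpec = FilterSpec(),
) -> BetaEstimates:
    """Fit a single run with its own drift/mean regressors."""
    return fit_session([data], [schedule], scheme, hrf, filter_spec)


def baseline_level(estimates: BetaEstimates, voxel_indices: np.ndarray | None = None) -> float:
    """Mean constant-regressor estimate over the given voxels, averaged over
    runs; the denominator for percent-signal-change normalization.

    Drift bases are orthonormal, so each run's mean signal is the drift0
    coefficient divided by sqrt(n_volumes); the stored design column encodes
    that scale, hence the reconstruction below.
    """
    levels = []
    for j, label in enumerate(estimates.regressor_labels):
        if label.startswith("drift0_run"):
            col = estimates.design[:, j]
            scale = float(col[col > 0][0])  # 1/sqrt(n_volumes of that run)
            b = estimates.betas[:, j] * scale
            levels.append(b if voxel_indices is None else b[voxel_indices])
    if not levels:
        if "constant" in estimates.regressor_labels:
            b = estimates.column("constant")
            levels.append(b if voxel_indices is None else b[voxel_indices])
        else:
            raise ValueError("no baseline/constant regressor in this fit")
    return float(np.mean(levels))
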