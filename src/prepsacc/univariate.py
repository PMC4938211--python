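"""ROI construction, beta pooling, normalization, and univariate statistics.

The analysis unit is a hemisphere-ROI instance (e.g. 6 participants x 2
hemispheres = 12 units, matching the t(11) / F(1,11) degrees of freedom of a
within-unit design).  Betas are converted to percent signal change against
the run-mean baseline, rescaled to remove between-unit gain, and compared by
paired t-tests and a 2x2 repeated-measures ANOVA (saccade type x phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.anova import AnovaRM

from .glm import BetaEstimates, baseline_level

HEMISPHERES = ("left", "right")


@dataclass(frozen=True)
class ROIMask:
    name: str
    hemisphere: str
    voxel_indices: np.ndarray
    definition: str  # functional_map | anatomical_label

    def __post_init__(self) -> None:
        if self.voxel_indices.size == 0:
            raise ValueError("ROI mask must be nonempty")
        if self.definition not in ("functional_map", "anatomical_label"):
            raise ValueError(f"unknown ROI definition {self.definition!r}")


@dataclass(frozen=True)
class StatResult:
    """A single two-sided test statistic with its degrees of freedom."""

    statistic: float
    dof: tuple[int, ...]
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def define_roi(
    threshold_mask: np.ndarray | None,
    template_label: np.ndarray,
    name: str = "ROI",
    hemisphere: str = "left",
    definition: str = "functional_map",
) -> ROIMask:
    """Functional mode: intersect a thresholded activation mask with the
    anatomical template label (the synthetic stand-in for manual delineation
    of an activation patch at a known location).  Anatomical mode: the
    template label itself."""
    template_label = np.asarray(template_label, dtype=bool)
    if definition == "anatomical_label":
        idx = np.flatnonzero(template_label)
    else:
        if threshold_mask is None:
            raise ValueError("functional ROI definition needs a thresholded mask")
        idx = np.flatnonzero(np.asarray(threshold_mask, dtype=bool) & template_label)
    if idx.size == 0:
        raise ValueError(f"empty ROI for {name}/{hemisphere}")
    return ROIMask(name=name, hemisphere=hemisphere, voxel_indices=idx, definition=definition)


def roi_condition_table(
    fits: list[BetaEstimates],
    rois: list[dict[str, ROIMask]],
    conditions: dict[str, tuple[str, ...]],
    participant_ids: list | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Raw per-unit condition means (one row per hemisphere-ROI instance).

    ``conditions`` maps an output column to the regressor labels averaged
    into it (e.g. exec_pro -> the two direction-resolved execution
    regressors).  Returns the beta table and the per-unit baseline levels.
    """
    if participant_ids is None:
        participant_ids = list(range(len(fits)))
    rows, baselines, index = [], [], []
    for pid, fit, roi_pair in zip(participant_ids, fits, rois):
        for hemi in HEMISPHERES:
            if hemi not in roi_pair:
                raise ValueError(f"missing hemisphere {hemi!r} for participant {pid}")
            roi = roi_pair[hemi]
            row = {
                col: float(
                    np.mean([fit.column(l)[roi.voxel_indices].mean() for l in labels])
                )
                for col, labels in conditions.items()
            }
            rows.append(row)
            baselines.append(baseline_level(fit, roi.voxel_indices))
            index.append((pid, hemi))
    idx = pd.MultiIndex.from_tuples(index, names=["participant", "hemisphere"])
    return pd.DataFrame(rows, index=idx), pd.Series(baselines, index=idx, name="baseline")


def pool_ipsi_contra(table: pd.DataFrame) -> pd.DataFrame:
    """Relabel direction-resolved execution columns to ipsi/contra per
    hemisphere and stack hemispheres as analysis units.

    Rightward saccades are ipsilateral for right-hemisphere ROIs and
    contralateral for left-hemisphere ROIs (and vice versa for leftward).
    Expects columns ``exec_<cls>_left`` / ``exec_<cls>_right``.
    """
    hemis = table.index.get_level_values("hemisphere")
    for hemi in HEMISPHERES:
        if hemi not in set(hemis):
            raise ValueError(f"missing hemisphere {hemi!r} in table")
    out = {}
    for cls in ("pro", "anti"):
        left = table[f"exec_{cls}_left"]
        right = table[f"exec_{cls}_right"]
        is_left_hemi = hemis == "left"
        # leftward saccade: ipsilateral to the left hemisphere
        out[f"exec_{cls}_ipsi"] = np.where(is_left_hemi, left, right)
        out[f"exec_{cls}_contra"] = np.where(is_left_hemi, right, left)
    return pd.DataFrame(out, index=table.index)


def normalize_signal_change(
    beta_table: pd.DataFrame, baseline: pd.Series | float
) -> pd.DataFrame:
    """Percent signal change with between-unit gain removed.

    Each unit's betas are scaled to 100 * beta / baseline, then divided by
    the unit's grand mean across conditions and multiplied by the group
    grand mean (a mean-preserving rescaling that removes per-unit gain).
    """
    if np.isscalar(baseline):
        baseline = pd.Series(float(baseline), index=beta_table.index)
    if (baseline <= 0).any():
        raise ValueError("baseline level must be positive for every unit")
    psc = 100.0 * beta_table.div(baseline, axis=0)
    unit_means = psc.mean(axis=1)
    if (unit_means == 0).any():
        raise ValueError("unit grand mean is zero; gain rescaling undefined")
    grand = float(psc.values.mean())
    return psc.div(unit_means, axis=0) * grand


def paired_t_test(values_a: np.ndarray, values_b: np.ndarray) -> StatResult:
    """Classical paired t-test on differences, two-sided, dof = n - 1."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired samples must be equal-length 1-D with n >= 2")
    diff = a - b
    if np.allclose(diff, diff[0]) and np.std(diff) == 0 and diff[0] != 0:
        raise ValueError("zero variance of differences; t undefined")
    if np.all(diff == 0):
        return StatResult(statistic=0.0, dof=(a.size - 1,), p_value=1.0)
    res = sp_stats.ttest_rel(a, b)
    return StatResult(
        statistic=float(res.statistic), dof=(a.size - 1,), p_value=float(res.pvalue)
    )


def rm_anova_2x2(table: pd.DataFrame) -> dict[str, StatResult]:
    """Two-way repeated-measures ANOVA: saccade type x saccade phase.

    ``table`` has one row per unit and the four cell columns ``prep_pro``,
    ``prep_anti``, ``exec_pro``, ``exec_anti``.  Each effect is tested
    against its effect-by-unit interaction mean square, dof (1, n-1).
    """
    cells = ("prep_pro", "prep_anti", "exec_pro", "exec_anti")
    missing = [c for c in cells if c not in table.columns]
    if missing:
        raise ValueError(f"incomplete 2x2 table; missing cells: {missing}")
    if table[list(cells)].isna().any().any():
        raise ValueError("incomplete cells (NaN) in the 2x2 table")
    long = (
        table[list(cells)]
        .reset_index(drop=True)
        .rename_axis("unit")
        .reset_index()
        .melt(id_vars="unit", var_name="cell", value_name="value")
    )
    long["phase"] = long["cell"].str.split("_").str[0]
    long["saccade_type"] = long["cell"].str.split("_").str[1]
    fitted = AnovaRM(
        long, depvar="value", subject="unit", within=["saccade_type", "phase"]
    ).fit()
    tbl = fitted.anova_table
    # effect sums of squares, used to recognise the degenerate case where a
    # factor has (numerically) no effect SS at all: its F is then 0 by
    # convention, not the 0/0 ratio a regression route may return
    n = len(table)
    y = table[list(cells)].values.reshape(n, 2, 2)  # (unit, phase, type)
    grand = y.mean()
    scale = max(np.sum((y - grand) ** 2), 1.0)
    ss_effect = {
        "phase": 2 * n * np.sum((y.mean(axis=(0, 2)) - grand) ** 2),
        "saccade_type": 2 * n * np.sum((y.mean(axis=(0, 1)) - grand) ** 2),
        "interaction": n
        * np.sum(
            (
                y.mean(axis=0)
                - y.mean(axis=(0, 2))[:, None]
                - y.mean(axis=(0, 1))[None, :]
                + grand
            )
            ** 2
        ),
    }
    out = {}
    for key, row_name in (
        ("saccade_type", "saccade_type"),
        ("phase", "phase"),
        ("interaction", "saccade_type:phase"),
    ):
        row = tbl.loc[row_name]
        f = float(row["F Value"])
        p = float(row["Pr > F"])
        if ss_effect[key] < 1e-12 * scale:
            f, p = 0.0, 1.0
        elif np.isinf(f):
            p = 0.0
        elif np.isnan(f):
            f, p = 0.0, 1.0
        out[key] = StatResult(
            statistic=f, dof=(int(row["Num DF"]), int(row["Den DF"])),
            p_value=float(min(max(p, 0.0), 1.0)),
        )
    return out


def table_summary(values: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error per condition (the printed-table layout)."""
    n = len(values)
    return pd.DataFrame(
        {"mean": values.mean(axis=0), "sem": values.std(axis=0, ddof=1) / np.sqrt(n)}
    )
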