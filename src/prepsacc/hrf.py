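"""Hemodynamic response models, design-matrix construction, high-pass filtering.

The BOLD impulse response is modelled as a difference of two gamma densities
("dual-gamma"): a positive lobe and a delayed undershoot scaled by a ratio.
Two variants are provided: the canonical cortical parameterization (positive
lobe peaking at 5 s, undershoot shape 16, ratio 1/6, unit dispersion) and an
early-peak variant for subcortical (superior colliculus) data whose positive
lobe peaks at 4.5 s.

Event regressors are 0.5 s boxcars placed at event onsets on a 0.1 s grid,
convolved with the HRF, sampled at the volume acquisition times, and scaled
so each task column has unit maximum.  Low-frequency drift is removed by
projecting out a discrete-cosine basis (all DCT-II components below the
cutoff, default 3 cycles/run, plus the mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import RunSchedule

CONVOLUTION_GRID_STEP = 0.1  # s; finer than every event-duration quantization


@dataclass(frozen=True)
class HRFModel:
    """Dual-gamma hemodynamic impulse response.

    ``time_to_peak`` is the mode of the positive lobe in seconds;
    ``undershoot_delay`` the shape parameter of the undershoot lobe (its mode
    is ``undershoot_delay - 1`` at unit dispersion); ``undershoot_ratio``
    scales the undershoot relative to the positive lobe.
    """

    variant: str = "dual_gamma"
    time_to_peak: float = 5.0
    undershoot_delay: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    dispersion: float = 1.0
    grid_step: float = CONVOLUTION_GRID_STEP
    support: float = 32.0

    def __post_init__(self) -> None:
        if self.time_to_peak <= 0:
            raise ValueError("time_to_peak must be positive")
        if self.dispersion <= 0 or self.support <= 0 or self.grid_step <= 0:
            raise ValueError("dispersion, support and grid_step must be positive")


def dual_gamma_hrf() -> HRFModel:
    """Canonical cortical dual-gamma model (positive-lobe peak at 5 s)."""
    return HRFModel(variant="dual_gamma", time_to_peak=5.0)


def early_peak_hrf() -> HRFModel:
    """Early-peak variant (4.5 s) suited to superior-colliculus responses."""
    return HRFModel(variant="early_peak", time_to_peak=4.5)


def evaluate_hrf(model: HRFModel, t_grid: np.ndarray) -> np.ndarray:
    """Evaluate the dual-gamma response on a non-negative, increasing grid.

    The positive lobe is a gamma density with mode ``time_to_peak``
    (shape = time_to_peak/dispersion + 1); the undershoot a gamma density of
    shape ``undershoot_delay``, scaled by ``undershoot_ratio``.  h(0) = 0
    because both shapes exceed 1.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or (t.size > 1 and np.any(np.diff(t) <= 0)) or np.any(t < 0):
        raise ValueError("t_grid must be non-negative and strictly increasing")
    shape_pos = model.time_to_peak / model.dispersion + 1.0
    pos = stats.gamma.pdf(t, a=shape_pos, scale=model.dispersion)
    under = stats.gamma.pdf(t, a=model.undershoot_delay, scale=model.dispersion)
    return pos - model.undershoot_ratio * under


def hrf_time_to_peak(model: HRFModel, grid_step: float = 0.001) -> float:
    """Peak time found by dense grid search over [0, support]."""
    t = np.arange(0.0, model.support + grid_step, grid_step)
    return float(t[np.argmax(evaluate_hrf(model, t))])


#: Regressor label -> contributing event kinds, per design scheme.
SCHEMES: dict[str, dict[str, tuple[str, ...]]] = {
    # direction-resolved scheme for the univariate analysis: 6 task
    # regressors (2 preparation + 4 execution) plus the return saccade
    "univariate_6reg": {
        "prep_pro": ("prep_pro",),
        "prep_anti": ("prep_anti",),
        "exec_pro_left": ("exec_pro_left",),
        "exec_pro_right": ("exec_pro_right",),
        "exec_anti_left": ("exec_anti_left",),
        "exec_anti_right": ("exec_anti_right",),
        "return_saccade": ("return_saccade",),
    },
    # directions collapsed for pattern analysis: preparation and execution
    # per class, plus the return saccade (5 regressors)
    "mvpa_5reg": {
        "prep_pro": ("prep_pro",),
        "prep_anti": ("prep_anti",),
        "exec_pro": ("exec_pro_left", "exec_pro_right"),
        "exec_anti": ("exec_anti_left", "exec_anti_right"),
        "return_saccade": ("return_saccade",),
    },
}


@dataclass(frozen=True)
class DesignMatrix:
    """Sampled, unity-scaled task regressors plus a constant column."""

    values: np.ndarray  # volumes x (task regressors + constant)
    regressor_labels: tuple[str, ...]
    tr: float
    scheme: str
    empty_regressors: tuple[str, ...] = field(default_factory=tuple)

    @property
    def task_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.regressor_labels if l != "constant")

    @property
    def task_values(self) -> np.ndarray:
        idx = [i for i, l in enumerate(self.regressor_labels) if l != "constant"]
        return self.values[:, idx]


def _convolved_column(
    onsets: np.ndarray,
    impulse_s: float,
    hrf_curve: np.ndarray,
    grid_step: float,
    n_grid: int,
    volume_index: np.ndarray,
) -> np.ndarray:
    train = np.zeros(n_grid)
    for onset in onsets:
        i0 = int(round(onset / grid_step))
        i1 = int(round((onset + impulse_s) / grid_step))
        train[i0 : max(i1, i0 + 1)] = 1.0
    conv = np.convolve(train, hrf_curve)[:n_grid] * grid_step
    return conv[volume_index]


def build_design_matrix(
    schedule: RunSchedule,
    scheme: str,
    hrf: HRFModel,
    tr: float | None = None,
    impulse_s: float = 0.5,
) -> DesignMatrix:
    """Convolve each regressor's event train with the HRF and sample at TR.

    Boxcars of ``impulse_s`` at member-event onsets on a 0.1 s grid are
    convolved with the HRF, sampled at volume times (k * TR), and each task
    column is scaled to unit maximum.  Regressors whose event set is empty
    stay all-zero and are flagged in ``empty_regressors``.  A constant column
    is appended.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    mapping = SCHEMES[scheme]
    mapped_kinds = {k for kinds in mapping.values() for k in kinds}
    present = {e.kind for e in schedule.events}
    unmapped = present - mapped_kinds
    if unmapped:
        raise ValueError(f"event kinds not mapped by scheme {scheme!r}: {sorted(unmapped)}")

    tr = schedule.tr if tr is None else tr
    grid_step = hrf.grid_step
    n_grid = int(np.ceil((schedule.total_duration + hrf.support) / grid_step)) + 1
    hrf_curve = evaluate_hrf(hrf, np.arange(0.0, hrf.support + grid_step, grid_step))
    volume_times = np.arange(schedule.n_volumes) * tr
    volume_index = np.round(volume_times / grid_step).astype(int)

    cols, labels, empty = [], [], []
    for label, kinds in mapping.items():
        onsets = np.concatenate([schedule.onsets_of(k) for k in kinds]) if kinds else np.array([])
        col = _convolved_column(
            np.sort(onsets), impulse_s, hrf_curve, grid_step, n_grid, volume_index
        )
        peak = np.max(np.abs(col))
        if peak > 0:
            col = col / np.max(col)
        else:
            empty.append(label)
        cols.append(col)
        labels.append(label)
    cols.append(np.ones(schedule.n_volumes))
    labels.append("constant")
    return DesignMatrix(
        values=np.column_stack(cols),
        regressor_labels=tuple(labels),
        tr=tr,
        scheme=scheme,
        empty_regressors=tuple(empty),
    )


@dataclass(frozen=True)
class FilterSpec:
    """High-pass cutoff expressed in cycles per run."""

    cutoff_cycles_per_run: int = 3

    def __post_init__(self) -> None:
        if self.cutoff_cycles_per_run < 1:
            raise ValueError("cutoff must be at least 1 cycle/run")


def drift_basis(n_volumes: int, spec: FilterSpec) -> np.ndarray:
    """Constant plus DCT-II components with frequency below the cutoff.

    Component k has frequency k / (2 * run_duration) cycles/s, so components
    k = 1 .. 2*cutoff - 1 lie strictly below cutoff cycles/run.
    """
    n = np.arange(n_volumes)
    k_max = 2 * spec.cutoff_cycles_per_run - 1
    cols = [np.ones(n_volumes) / np.sqrt(n_volumes)]
    for k in range(1, k_max + 1):
        cols.append(np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (n + 0.5) / n_volumes))
    return np.column_stack(cols)


def high_pass_filter(
    series_matrix: np.ndarray,
    run_duration: float,
    spec: FilterSpec = FilterSpec(),
    time_axis: int = 0,
) -> np.ndarray:
    """Project out the drift basis (idempotent high-pass filtering).

    ``run_duration`` must be positive; the number of time points must exceed
    the drift-basis size.
    """
    if run_duration <= 0:
        raise ValueError("run_duration must be positive")
    x = np.asarray(series_matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]  # a single series: time runs along its only axis
    else:
        x = np.moveaxis(x, time_axis, 0)
    n = x.shape[0]
    basis = drift_basis(n, spec)
    if n <= basis.shape[1]:
        raise ValueError(
            f"{n} volumes cannot support a drift basis of size {basis.shape[1]}"
        )
    filtered = x - basis @ (basis.T @ x)
    return np.moveaxis(filtered, 0, time_axis).reshape(np.shape(series_matrix))
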