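"""Synthetic BOLD datasets with controllable class structure.

Three scenarios encode the hypotheses under study:

``cortex_like``
    Pro- and anti-saccade conditions drive distinct multivoxel patterns and
    anti-saccades carry a larger mean amplitude (gain) than pro-saccades, in
    both the preparation and the execution phase — the regime in which both
    the univariate anti > pro effect and pattern decoding should succeed.

``sc_like``
    Both conditions drive the *same* pattern with the *same* gain (execution
    roughly twice preparation), i.e. vigorous but class-undifferentiated
    responses — decoding and the univariate difference should both fail.

``null``
    No evoked response at all; used for type-I calibration.

The forward model is linear: each voxel's series is the unity-scaled
convolved event regressors (exactly the GLM design columns) weighted by the
voxel's ground-truth amplitudes, plus a baseline level, optional
low-frequency cosine drift, and Gaussian noise (optionally AR(1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import (
    EVENT_KINDS,
    DesignConfig,
    RunSchedule,
    build_run_schedule,
)
from .hrf import FilterSpec, HRFModel, build_design_matrix, drift_basis, dual_gamma_hrf

SCENARIOS = ("cortex_like", "sc_like", "null")


@dataclass(frozen=True)
class ScenarioParams:
    """Ground-truth effect sizes, in units of peak regressor response.

    Defaults were calibrated once by forward simulation at the default design
    (6 runs x 20 trials) so that cortex_like sits in the qualitative regime
    of a decodable, anti-dominant preparatory set while sc_like matches the
    amplitude profile (execution ~ twice preparation) without any class
    difference.
    """

    g_prep_pro: float = 0.8
    g_prep_anti: float = 1.2
    g_exec_pro: float = 2.0
    g_exec_anti: float = 2.4
    g_return: float = 1.0
    pattern_scale: float = 0.15  # sd of per-voxel pattern modulation
    lateralization: float = 0.0  # contra/ipsi execution asymmetry, L >= 0
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0
    ar1: float = 0.0
    baseline: float = 100.0


@dataclass(frozen=True)
class GroundTruthPatterns:
    """Per-voxel true amplitudes a(v, kind) for one participant's ROI pair.

    ``hemispheres`` labels each voxel 'left' or 'right'; execution amplitudes
    may be direction-lateralized (contralateral gain 1+L, ipsilateral 1-L).
    """

    amplitudes: dict[str, np.ndarray]
    hemispheres: np.ndarray
    scenario: str
    gains: dict[str, float]

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        n = len(self.hemispheres)
        for kind, amp in self.amplitudes.items():
            if amp.shape != (n,):
                raise ValueError(f"amplitude map for {kind!r} has wrong shape")

    @property
    def n_voxels(self) -> int:
        return len(self.hemispheres)

    def prep_pattern(self, cls: str) -> np.ndarray:
        return self.amplitudes[f"prep_{cls}"]


@dataclass(frozen=True)
class BOLDRun:
    """One run's voxel time series (voxels x volumes) with ROI labels."""

    data: np.ndarray
    tr: float
    roi_names: np.ndarray
    hemispheres: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data must be finite")


@dataclass(frozen=True)
class ParticipantData:
    runs: tuple[BOLDRun, ...]
    schedules: tuple[RunSchedule, ...]
    patterns: GroundTruthPatterns


@dataclass(frozen=True)
class SyntheticDataset:
    participants: tuple[ParticipantData, ...]
    config: DesignConfig
    params: ScenarioParams
    scenario: str
    seed: int

    @property
    def ground_truth(self) -> tuple[GroundTruthPatterns, ...]:
        return tuple(p.patterns for p in self.participants)


def make_patterns(
    scenario: str,
    n_voxels_per_hemisphere: int,
    rng: np.random.Generator,
    params: ScenarioParams = ScenarioParams(),
    roi_name: str = "ROI",
) -> GroundTruthPatterns:
    """Draw one participant's ground-truth amplitude maps.

    cortex_like draws independent pattern vectors per class (and per phase);
    sc_like shares a single pattern vector per phase across classes with
    equal gains; null zeroes every amplitude.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    n = 2 * n_voxels_per_hemisphere
    hemis = np.array(["left"] * n_voxels_per_hemisphere + ["right"] * n_voxels_per_hemisphere)
    s = params.pattern_scale

    def modulated(gain: float, z: np.ndarray) -> np.ndarray:
        return gain * (1.0 + s * z)

    amplitudes: dict[str, np.ndarray] = {}
    if scenario == "null":
        gains = {k: 0.0 for k in ("prep_pro", "prep_anti", "exec_pro", "exec_anti", "return")}
        for kind in EVENT_KINDS:
            amplitudes[kind] = np.zeros(n)
    else:
        if scenario == "sc_like":
            g_prep = 0.5 * (params.g_prep_pro + params.g_prep_anti)
            g_exec = 0.5 * (params.g_exec_pro + params.g_exec_anti)
            gains = {
                "prep_pro": g_prep,
                "prep_anti": g_prep,
                "exec_pro": g_exec,
                "exec_anti": g_exec,
                "return": params.g_return,
            }
            z_prep = rng.standard_normal(n)
            z_exec = rng.standard_normal(n)
            z = {"prep_pro": z_prep, "prep_anti": z_prep,
                 "exec_pro": z_exec, "exec_anti": z_exec}
        else:  # cortex_like: class-specific patterns, anti gain dominant
            gains = {
                "prep_pro": params.g_prep_pro,
                "prep_anti": params.g_prep_anti,
                "exec_pro": params.g_exec_pro,
                "exec_anti": params.g_exec_anti,
                "return": params.g_return,
            }
            if not gains["prep_anti"] > gains["prep_pro"]:
                raise ValueError("cortex_like requires g_prep_anti > g_prep_pro")
            z = {k: rng.standard_normal(n)
                 for k in ("prep_pro", "prep_anti", "exec_pro", "exec_anti")}

        amplitudes["prep_pro"] = modulated(gains["prep_pro"], z["prep_pro"])
        amplitudes["prep_anti"] = modulated(gains["prep_anti"], z["prep_anti"])
        z_ret = rng.standard_normal(n)
        amplitudes["return_saccade"] = modulated(params.g_return, z_ret)
        # contralaterality: leftward saccades are contralateral for the
        # right hemisphere and ipsilateral for the left
        L = params.lateralization
        contra_left = np.where(hemis == "right", 1.0 + L, 1.0 - L)
        contra_right = np.where(hemis == "left", 1.0 + L, 1.0 - L)
        for cls in ("pro", "anti"):
            base = modulated(gains[f"exec_{cls}"], z[f"exec_{cls}"])
            amplitudes[f"exec_{cls}_left"] = base * contra_left
            amplitudes[f"exec_{cls}_right"] = base * contra_right
    return GroundTruthPatterns(
        amplitudes=amplitudes, hemispheres=hemis, scenario=scenario, gains=gains
    )


def simulate_bold_run(
    schedule: RunSchedule,
    patterns: GroundTruthPatterns,
    hrf: HRFModel,
    noise_sd: float = 1.0,
    drift_amplitude: float = 0.0,
    rng: np.random.Generator | None = None,
    baseline: float = 100.0,
    ar1: float = 0.0,
    roi_name: str = "ROI",
    filter_spec: FilterSpec = FilterSpec(),
) -> BOLDRun:
    """Forward-simulate one run as design @ amplitudes + baseline + drift + noise.

    The deterministic part uses the same unity-scaled convolved regressors as
    the GLM design matrix, so a zero-noise, zero-drift run is recovered
    exactly by OLS.  Drift is a random combination of the sub-cutoff cosine
    components scaled by ``drift_amplitude``; noise is Gaussian per volume,
    optionally AR(1).
    """
    if rng is None:
        rng = np.random.default_rng()
    design = build_design_matrix(schedule, "univariate_6reg", hrf)
    missing = [l for l in design.task_labels if l not in patterns.amplitudes]
    if missing:
        raise ValueError(f"patterns missing amplitude entries for: {missing}")
    amp = np.column_stack([patterns.amplitudes[l] for l in design.task_labels])
    signal = amp @ design.task_values.T + baseline

    n_vox, n_vol = signal.shape
    if drift_amplitude > 0:
        basis = drift_basis(n_vol, filter_spec)[:, 1:]  # exclude the mean
        coef = rng.standard_normal((n_vox, basis.shape[1])) * drift_amplitude
        signal = signal + coef @ basis.T * np.sqrt(n_vol)
    if noise_sd > 0:
        eps = rng.standard_normal((n_vox, n_vol)) * noise_sd
        if ar1 != 0.0:
            for t in range(1, n_vol):
                eps[:, t] += ar1 * eps[:, t - 1]
        signal = signal + eps
    return BOLDRun(
        data=signal,
        tr=schedule.tr,
        roi_names=np.array([roi_name] * n_vox),
        hemispheres=patterns.hemispheres.copy(),
    )


def make_dataset(
    scenario: str,
    n_participants: int = 6,
    n_runs: int = 6,
    rng: np.random.Generator | int | None = None,
    config: DesignConfig = DesignConfig(),
    params: ScenarioParams = ScenarioParams(),
    n_voxels_per_hemisphere: int = 30,
    hrf: HRFModel | None = None,
    roi_name: str = "ROI",
) -> SyntheticDataset:
    """Generate a full multi-participant dataset for one scenario.

    A fixed integer seed fully determines the dataset.  ``n_runs`` must be
    at least 2 (leave-one-run-out cross-validation is undefined otherwise).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 for leave-one-run-out analysis")
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    elif rng is None:
        seed = 0
        rng = np.random.default_rng(seed)
    else:
        seed = -1  # externally managed generator
    hrf = dual_gamma_hrf() if hrf is None else hrf

    participants = []
    for _ in range(n_participants):
        patterns = make_patterns(
            scenario, n_voxels_per_hemisphere, rng, params, roi_name
        )
        runs, schedules = [], []
        for _ in range(n_runs):
            schedule = build_run_schedule(rng, config)
            run = simulate_bold_run(
                schedule,
                patterns,
                hrf,
                noise_sd=params.noise_sd,
                drift_amplitude=params.drift_amplitude,
                rng=rng,
                baseline=params.baseline,
                ar1=params.ar1,
                roi_name=roi_name,
            )
            runs.append(run)
            schedules.append(schedule)
        participants.append(
            ParticipantData(tuple(runs), tuple(schedules), patterns)
        )
    return SyntheticDataset(
        participants=tuple(participants),
        config=config,
        params=params,
        scenario=scenario,
        seed=seed,
    )
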