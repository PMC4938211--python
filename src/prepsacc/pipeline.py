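"""Configuration and orchestration of the full simulate→GLM→stats→MVPA pipeline.

A single master seed drives named, order-independent child streams (one per
stage), so every table in a report is regenerable from config + seed and
adding a stage never perturbs earlier ones.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DesignConfig
from .glm import (
    ThresholdSpec,
    contrast_t_map,
    fit_run,
    fit_session,
    threshold_map,
)
from .hrf import HRFModel, dual_gamma_hrf, early_peak_hrf
from .mvpa import (
    DecodingCurve,
    PermutationNull,
    PValueHistogram,
    build_exemplars,
    concatenate_participants,
    decoding_curve,
    loro_cv_decode,
    normalize_exemplars,
    permutation_null,
    pvalue_histogram,
)
from .simulate import ScenarioParams, SyntheticDataset, make_dataset
from .univariate import (
    define_roi,
    normalize_signal_change,
    paired_t_test,
    pool_ipsi_contra,
    rm_anova_2x2,
    roi_condition_table,
    table_summary,
)

HRF_VARIANTS = {"dual_gamma": dual_gamma_hrf, "early_peak": early_peak_hrf}

#: conditions for the direction-collapsed univariate table
COLLAPSED_CONDITIONS = {
    "prep_pro": ("prep_pro",),
    "prep_anti": ("prep_anti",),
    "exec_pro": ("exec_pro_left", "exec_pro_right"),
    "exec_anti": ("exec_anti_left", "exec_anti_right"),
    "return": ("return_saccade",),
}

#: direction-resolved execution conditions for the ipsi/contra analysis
DIRECTION_CONDITIONS = {
    "exec_pro_left": ("exec_pro_left",),
    "exec_pro_right": ("exec_pro_right",),
    "exec_anti_left": ("exec_anti_left",),
    "exec_anti_right": ("exec_anti_right",),
}


@dataclass(frozen=True)
class MVPAParams:
    """Decoding-stage settings (defaults mirror the protocol)."""

    sizes: tuple[int, ...] | None = None  # None -> automatic ladder
    n_repeats: int = 20
    n_permutations: int = 1000
    curve_permutations: int = 200
    sample_voxels: int = 500
    n_iterations: int = 1000
    C: float = 1.0
    max_voxels: int = 500  # 500 cortex / 200 SC


@dataclass(frozen=True)
class PipelineConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    params: ScenarioParams = field(default_factory=ScenarioParams)
    mvpa: MVPAParams = field(default_factory=MVPAParams)
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    scenario: str = "cortex_like"
    n_participants: int = 6
    n_runs: int = 6
    n_voxels_per_hemisphere: int = 30
    hrf_variant: str = "dual_gamma"
    roi_definition: str = "anatomical_label"
    roi_name: str = "ROI"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hrf_variant not in HRF_VARIANTS:
            raise ValueError(f"unknown hrf_variant {self.hrf_variant!r}")

    def hrf(self) -> HRFModel:
        return HRF_VARIANTS[self.hrf_variant]()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        nested = {
            "design": DesignConfig,
            "params": ScenarioParams,
            "mvpa": MVPAParams,
            "threshold": ThresholdSpec,
        }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in d.items():
            if key in nested:
                sub_cls = nested[key]
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(value) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown config keys under {key}: {sorted(sub_unknown)}"
                    )
                value = sub_cls(
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in value.items()
                    }
                )
            kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def seed_stream(master_seed: int, name: str) -> np.random.Generator:
    """Named child stream: independent of the order streams are created in."""
    child = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([master_seed, child]))


@dataclass
class RunReport:
    config: dict
    scenario: str
    seed: int
    condition_table_raw: pd.DataFrame
    condition_table: pd.DataFrame  # normalized percent signal change
    ipsi_contra_table: pd.DataFrame
    stats: pd.DataFrame
    curves: dict[str, DecodingCurve]
    nulls: dict[str, PermutationNull]
    true_accuracy: dict[str, float]
    decoding_significant: dict[str, bool]
    histograms: dict[str, PValueHistogram]
    provenance: dict


def _default_sizes(n_voxels: int, max_voxels: int) -> list[int]:
    top = min(n_voxels, max_voxels)
    ladder = [s for s in (10, 20, 40, 80, 160, 320) if s < top]
    return ladder + [top]


def _participant_rois(dataset: SyntheticDataset, config: PipelineConfig, fits):
    """One ROI per hemisphere per participant, functional or anatomical."""
    rois = []
    for part, fit in zip(dataset.participants, fits):
        hemis = part.runs[0].hemispheres
        pair = {}
        for hemi in ("left", "right"):
            template = hemis == hemi
            if config.roi_definition == "functional_map":
                contrast = np.array(
                    [
                        1.0 if l.startswith("exec_") else 0.0
                        for l in fit.regressor_labels
                    ]
                )
                contrast /= contrast.sum()
                mask = threshold_map(contrast_t_map(fit, contrast), config.threshold)
                pair[hemi] = define_roi(
                    mask, template, config.roi_name, hemi, "functional_map"
                )
            else:
                pair[hemi] = define_roi(
                    None, template, config.roi_name, hemi, "anatomical_label"
                )
        rois.append(pair)
    return rois


def run_pipeline(config: PipelineConfig) -> RunReport:
    """simulate → design/GLM → ROI univariate statistics → MVPA decoding."""
    hrf = config.hrf()
    dataset = make_dataset(
        config.scenario,
        n_participants=config.n_participants,
        n_runs=config.n_runs,
        rng=seed_stream(config.seed, "simulate"),
        config=config.design,
        params=config.params,
        n_voxels_per_hemisphere=config.n_voxels_per_hemisphere,
        hrf=hrf,
        roi_name=config.roi_name,
    )

    # session-level direction-resolved GLM per participant
    session_fits = [
        fit_session(
            [r.data for r in part.runs], list(part.schedules), "univariate_6reg", hrf
        )
        for part in dataset.participants
    ]
    rois = _participant_rois(dataset, config, session_fits)

    conditions = dict(COLLAPSED_CONDITIONS)
    conditions.update(DIRECTION_CONDITIONS)
    raw, baselines = roi_condition_table(session_fits, rois, conditions)
    collapsed_raw = raw[list(COLLAPSED_CONDITIONS)]
    normalized = normalize_signal_change(collapsed_raw, baselines)
    ipsi_contra = pool_ipsi_contra(raw)

    stats_rows = []

    def add_stat(name: str, result) -> None:
        stats_rows.append(
            {
                "test": name,
                "statistic": result.statistic,
                "dof": "x".join(str(d) for d in result.dof),
                "p_value": result.p_value,
            }
        )

    add_stat(
        "prep_anti_vs_pro",
        paired_t_test(normalized["prep_anti"].values, normalized["prep_pro"].values),
    )
    add_stat(
        "exec_anti_vs_pro",
        paired_t_test(normalized["exec_anti"].values, normalized["exec_pro"].values),
    )
    for cls in ("pro", "anti"):
        add_stat(
            f"exec_{cls}_ipsi_vs_contra",
            paired_t_test(
                ipsi_contra[f"exec_{cls}_ipsi"].values,
                ipsi_contra[f"exec_{cls}_contra"].values,
            ),
        )
    for name, res in rm_anova_2x2(normalized).items():
        add_stat(f"anova_{name}", res)
    stats = pd.DataFrame(stats_rows)

    # per-run direction-collapsed GLMs feed the decoder
    run_fits_per_participant = [
        [
            fit_run(run.data, schedule, "mvpa_5reg", hrf)
            for run, schedule in zip(part.runs, part.schedules)
        ]
        for part in dataset.participants
    ]

    curves: dict[str, DecodingCurve] = {}
    nulls: dict[str, PermutationNull] = {}
    true_acc: dict[str, float] = {}
    significant: dict[str, bool] = {}
    histograms: dict[str, PValueHistogram] = {}
    for phase in ("preparation", "execution"):
        sets = [
            normalize_exemplars(build_exemplars(fits, phase, participant=p))
            for p, fits in enumerate(run_fits_per_participant)
        ]
        pooled = concatenate_participants(sets)
        rng = seed_stream(config.seed, f"mvpa_{phase}")
        sizes = (
            list(config.mvpa.sizes)
            if config.mvpa.sizes
            else _default_sizes(pooled.n_voxels, config.mvpa.max_voxels)
        )
        curves[phase] = decoding_curve(
            pooled,
            sizes,
            n_repeats=config.mvpa.n_repeats,
            rng=rng,
            n_permutations=config.mvpa.curve_permutations,
            C=config.mvpa.C,
        )
        nulls[phase] = permutation_null(
            pooled, n_permutations=config.mvpa.n_permutations, rng=rng, C=config.mvpa.C
        )
        true_acc[phase] = loro_cv_decode(pooled, C=config.mvpa.C).accuracy
        significant[phase] = true_acc[phase] > nulls[phase].percentile_95
        histograms[phase] = pvalue_histogram(
            pooled,
            sample_voxels=min(config.mvpa.sample_voxels, pooled.n_voxels),
            n_iterations=config.mvpa.n_iterations,
            rng=rng,
            C=config.mvpa.C,
        )

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": zlib.crc32(
            json.dumps(asdict(config), sort_keys=True).encode()
        ),
        "n_units": len(normalized),
    }
    return RunReport(
        config=asdict(config),
        scenario=config.scenario,
        seed=config.seed,
        condition_table_raw=collapsed_raw,
        condition_table=normalized,
        ipsi_contra_table=ipsi_contra,
        stats=stats,
        curves=curves,
        nulls=nulls,
        true_accuracy=true_acc,
        decoding_significant=significant,
        histograms=histograms,
        provenance=provenance,
    )


def summarize_tables(report: RunReport, outdir: Path) -> list[Path]:
    """Mean ± SE condition tables (one per analysis), written as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in (
        ("conditions_normalized", report.condition_table),
        ("conditions_ipsi_contra", report.ipsi_contra_table),
    ):
        path = outdir / f"summary_{name}.tsv"
        table_summary(table).to_csv(path, sep="\t")
        written.append(path)
    return written


def write_report(report: RunReport, outdir: Path) -> None:
    """All report tables as TSV plus a JSON provenance/summary block."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.condition_table_raw.to_csv(outdir / "condition_table_raw.tsv", sep="\t")
    report.condition_table.to_csv(outdir / "condition_table_normalized.tsv", sep="\t")
    report.ipsi_contra_table.to_csv(outdir / "ipsi_contra_table.tsv", sep="\t")
    report.stats.to_csv(outdir / "stats.tsv", sep="\t", index=False)
    for phase, curve in report.curves.items():
        pd.DataFrame(
            {
                "size": curve.sizes,
                "mean_accuracy": curve.mean_accuracy,
                "null_percentile_95": curve.null_percentile_95,
            }
        ).to_csv(outdir / f"decoding_curve_{phase}.tsv", sep="\t", index=False)
    for phase, null in report.nulls.items():
        pd.DataFrame({"accuracy": null.accuracies}).to_csv(
            outdir / f"permutation_null_{phase}.tsv", sep="\t", index=False
        )
    for phase, hist in report.histograms.items():
        pd.DataFrame({"p_value": hist.p_values}).to_csv(
            outdir / f"pvalue_histogram_{phase}.tsv", sep="\t", index=False
        )
    summarize_tables(report, outdir)
    summary = {
        "scenario": report.scenario,
        "seed": report.seed,
        "true_accuracy": report.true_accuracy,
        "null_percentile_95": {
            phase: null.percentile_95 for phase, null in report.nulls.items()
        },
        "decoding_significant": report.decoding_significant,
        "pvalues_below_alpha": {
            phase: hist.count_below_alpha for phase, hist in report.histograms.items()
        },
        "provenance": report.provenance,
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
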