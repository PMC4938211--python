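"""ROI univariate analysis: condition tables, paired t-tests, 2x2 RM-ANOVA.

For the cortex-like scenario the preparation-phase anti > pro amplitude
difference should be significant across the 12 hemisphere-ROI units and the
saccade-type and phase main effects strong; for the sc-like scenario the
type effect should vanish while the phase effect (execution ~ twice
preparation) remains.  Tables are written under results/univariate/.
"""

import sys
from pathlib import Path

from prepsacc.pipeline import (
    MVPAParams,
    PipelineConfig,
    run_pipeline,
    summarize_tables,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

# decoding is not the object here: keep the MVPA stage minimal
LIGHT_MVPA = MVPAParams(
    sizes=(10, 360), n_repeats=2, n_permutations=20, curve_permutations=10,
    n_iterations=10, sample_voxels=100,
)


def main() -> None:
    outdir = ROOT / "results" / "univariate"
    outdir.mkdir(parents=True, exist_ok=True)
    for scenario in ("cortex_like", "sc_like"):
        config = PipelineConfig(scenario=scenario, seed=SEED, mvpa=LIGHT_MVPA)
        report = run_pipeline(config)
        report.condition_table.to_csv(
            outdir / f"conditions_{scenario}.tsv", sep="\t"
        )
        report.stats.to_csv(outdir / f"stats_{scenario}.tsv", sep="\t", index=False)
        summarize_tables(report, outdir / scenario)
        print(f"\n=== {scenario} (12 hemisphere-ROI units) ===")
        print(report.stats.to_string(index=False))
    print(
        "\nExpected pattern: prep_anti_vs_pro and anova_saccade_type significant "
        "only for cortex_like; anova_phase significant in both (execution "
        "amplitude ~ twice preparation); ipsi/contra tests null in both."
    )


if __name__ == "__main__":
    main()
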