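"""MVPA decoding curves with permutation criteria for both scenarios.

Reproduces the qualitative contrast between decodable cortical patterns and
non-decodable collicular patterns: accuracy vs voxel-sample size with the
95th percentile of the label-permutation null as significance criterion.
Curves and nulls are written under results/decoding/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from prepsacc.glm import fit_run
from prepsacc.hrf import dual_gamma_hrf, early_peak_hrf
from prepsacc.mvpa import (
    build_exemplars,
    concatenate_participants,
    decoding_curve,
    loro_cv_decode,
    normalize_exemplars,
    permutation_null,
)
from prepsacc.pipeline import seed_stream
from prepsacc.simulate import make_dataset

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
SIZES = [10, 20, 40, 80, 160, 360]


def pooled(dataset, phase, hrf):
    sets = []
    for p, part in enumerate(dataset.participants):
        fits = [
            fit_run(r.data, s, "mvpa_5reg", hrf)
            for r, s in zip(part.runs, part.schedules)
        ]
        sets.append(normalize_exemplars(build_exemplars(fits, phase, p)))
    return concatenate_participants(sets)


def main() -> None:
    outdir = ROOT / "results" / "decoding"
    outdir.mkdir(parents=True, exist_ok=True)
    verdicts = []
    for scenario, hrf in (("cortex_like", dual_gamma_hrf()), ("sc_like", early_peak_hrf())):
        dataset = make_dataset(
            scenario, n_participants=6, n_runs=6,
            rng=seed_stream(SEED, f"decode-{scenario}"), hrf=hrf,
        )
        for phase in ("preparation", "execution"):
            exemplars = pooled(dataset, phase, hrf)
            rng = seed_stream(SEED, f"decode-{scenario}-{phase}")
            curve = decoding_curve(
                exemplars, SIZES, n_repeats=20, rng=rng, n_permutations=100
            )
            acc = loro_cv_decode(exemplars).accuracy
            null = permutation_null(exemplars, 500, rng)
            pd.DataFrame(
                {
                    "size": curve.sizes,
                    "mean_accuracy": curve.mean_accuracy,
                    "null_percentile_95": curve.null_percentile_95,
                }
            ).to_csv(outdir / f"curve_{scenario}_{phase}.tsv", sep="\t", index=False)
            sig = acc > null.percentile_95
            verdicts.append((scenario, phase, acc, null.percentile_95, sig))
            print(
                f"{scenario:12s} {phase:12s} full-sample accuracy {acc:.3f} "
                f"vs criterion {null.percentile_95:.3f} -> "
                f"{'significant' if sig else 'not significant'}"
            )
    pd.DataFrame(
        verdicts,
        columns=["scenario", "phase", "accuracy", "criterion_95", "significant"],
    ).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    print(
        "\nExpected pattern: cortex_like decodes in both phases (accuracy rises "
        "with voxel count and beats the permutation criterion); sc_like stays "
        "within the null band at every sample size."
    )


if __name__ == "__main__":
    main()
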