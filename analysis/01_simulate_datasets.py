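"""Generate the three synthetic scenario datasets and summarize their designs.

Scenarios: cortex_like (class-specific patterns, anti-dominant gains),
sc_like (shared patterns, matched gains), null (no evoked signal).
Volumes and event files are written under scratch/datasets/; the design
summary (trial counts, delay statistics, run durations) goes to
results/design_summary.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from prepsacc.io import write_dataset
from prepsacc.pipeline import seed_stream
from prepsacc.simulate import make_dataset

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    rows = []
    for scenario in ("cortex_like", "sc_like", "null"):
        ds = make_dataset(
            scenario, n_participants=6, n_runs=6,
            rng=seed_stream(SEED, f"simulate-{scenario}"),
        )
        write_dataset(ds, ROOT / "scratch" / "datasets" / scenario)
        durations, delays = [], []
        for part in ds.participants:
            for schedule in part.schedules:
                durations.append(schedule.total_duration)
                execs = sorted(
                    e.onset for e in schedule.events if e.kind.startswith("exec_")
                )
                rets = sorted(schedule.onsets_of("return_saccade"))
                delays += [r - e for e, r in zip(execs, rets)]
        rows.append(
            {
                "scenario": scenario,
                "n_runs": 36,
                "mean_run_duration_s": np.mean(durations),
                "mean_volumes": np.mean([np.ceil(d / 1.5) for d in durations]),
                "mean_hold_delay_s": np.mean(delays),
                "min_hold_delay_s": np.min(delays),
                "max_hold_delay_s": np.max(delays),
            }
        )
    summary = pd.DataFrame(rows)
    out = ROOT / "results" / "design_summary.tsv"
    out.parent.mkdir(exist_ok=True)
    summary.to_csv(out, sep="\t", index=False, float_format="%.2f")
    print(summary.to_string(index=False))
    print(
        f"\n36 runs per scenario written to scratch/datasets/; summary -> {out}.\n"
        "Hold delays respect the 2-12 s truncation with mean ~4 s; run length "
        "is emergent from the sampled trial timings."
    )


if __name__ == "__main__":
    main()
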