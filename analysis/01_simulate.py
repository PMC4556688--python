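#!/usr/bin/env python
"""Generate one example of each synthetic input and report its ground truth.

Writes an example micrograph (16-bit TIFF) and its annotations, a thermogram
and a per-eye thickness table under scratch/example/, and prints the ground
truth each carries.  Downstream analysis scripts regenerate their own inputs
deterministically from seeds, so nothing here is a dependency — this script
exists to show what the generators produce.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fibrilquant.fixtures import load_cct_table
from fibrilquant.pipeline import RunConfig, _write_micrograph_tiff
from fibrilquant.synthetic import (
    ThermogramSpec,
    generate_group_table,
    generate_scene,
    generate_thermogram,
    render_micrograph,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("scratch/example"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=args.seed)

    scene = generate_scene(
        density_per_um2=cfg.density_per_um2,
        n_artifacts=5,
        image_shape_px=(cfg.sim_image_px, cfg.sim_image_px),
        calibration_nm_per_px=cfg.calibration_nm_per_px,
        seed=args.seed,
    )
    image = render_micrograph(scene, noise_sd=0.05, blur_sigma_px=1.0)
    _write_micrograph_tiff(args.out / "micrograph.tiff", image)
    pd.DataFrame(
        {
            "center_row_px": scene.fibril_centers[:, 0],
            "center_col_px": scene.fibril_centers[:, 1],
            "radius_px": scene.fibril_radii_px,
        }
    ).to_csv(args.out / "annotations.csv", index=False)
    print(
        f"micrograph: {scene.n_fibrils} fibrils at "
        f"{scene.true_density_per_um2:.1f}/um^2, true mean diameter "
        f"{scene.true_diameters_nm.mean():.2f} nm, 5 elongated artifacts"
    )

    thermo = generate_thermogram(
        ThermogramSpec(peak_temp_C=71.99, noise_sd=0.02, seed=args.seed)
    )
    pd.DataFrame(
        {"temperature_C": thermo.temperature_C, "heat_flow": thermo.heat_flow}
    ).to_csv(args.out / "thermogram.csv", index=False)
    print(f"thermogram: {len(thermo)} points, 10-95 C, true peak at 71.99 C")

    fixture = load_cct_table()
    specs = [
        (r["group"], r["swelled_cct_um_mean"], r["swelled_cct_um_sd"], 3)
        for _, r in fixture.iterrows()
    ]
    table = generate_group_table(specs, seed=args.seed, measure="swelled_cct_um")
    table.to_csv(args.out / "group_table.csv", index=False)
    print(f"group table: {len(table)} eyes across {table['group'].nunique()} groups")
    print(f"wrote example inputs to {args.out}")


if __name__ == "__main__":
    main()
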