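"""End-to-end run orchestration: simulate -> segment -> measure -> dsc -> report.

Every stage writes its intermediate artifacts into the run directory, together
with a parameter-echo log and a machine-readable provenance record (config,
per-stage sub-seeds, library versions) sufficient to reproduce any output.
The single config seed is expanded into independent per-stage sub-seeds with
``numpy.random.SeedSequence([seed, stage_index])`` so any stage can be rerun
in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .fixtures import load_cct_table
from .morphometry import MorphometryConfig, summarize_image
from .segmentation import (
    Micrograph,
    adaptive_binarize,
    filter_by_area,
    filter_by_eccentricity,
    label_components,
    morphological_open,
)
from .stats_report import build_report, percent_swelling_reduction
from .synthetic import (
    ThermogramSpec,
    generate_group_table,
    generate_scene,
    generate_thermogram,
    render_micrograph,
)
from .thermal import Thermogram, find_transition_temperature

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]

_STAGES = ("simulate", "segment", "measure", "dsc", "report")

log = logging.getLogger("fibrilquant")


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run; every downstream constraint is checked here.

    Segmentation and morphometry parameters mirror the individual operations'
    defaults; the ``sim_*`` block parameterizes the synthetic inputs when no
    input manifest is supplied (density is given in the per-window count
    convention that group tables use).
    """

    calibration_nm_per_px: float = 2.0
    block_size_px: int = 35
    threshold_offset: float = 0.10
    opening_radius_px: int = 1
    max_eccentricity: float = 0.9
    min_area_px2: int = 50
    window_size_px: int = 300
    n_windows: int = 200
    seed: int = 0
    polarity: str = "bright_objects"
    # synthetic-input block
    sim_density_per_window: float = 18.0
    sim_diam_mean_nm: float = 40.67
    sim_diam_sd_nm: float = 2.0
    sim_min_gap_nm: float = 4.0
    sim_n_artifacts: int = 5
    sim_image_px: int = 1024
    sim_noise_sd: float = 0.05
    sim_blur_px: float = 1.0
    sim_peak_temp_C: float = 71.99

    def __post_init__(self) -> None:
        if self.calibration_nm_per_px is None or self.calibration_nm_per_px <= 0:
            raise ValueError("calibration_nm_per_px must be a positive number")
        if self.block_size_px % 2 == 0 or self.block_size_px < 3:
            raise ValueError("block_size_px must be an odd integer >= 3")
        if self.opening_radius_px < 0:
            raise ValueError("opening_radius_px must be >= 0")
        if not (0.0 < self.max_eccentricity <= 1.0):
            raise ValueError("max_eccentricity must lie in (0, 1]")
        if self.min_area_px2 < 1:
            raise ValueError("min_area_px2 must be >= 1")
        if self.window_size_px < 1 or self.n_windows < 1:
            raise ValueError("window_size_px and n_windows must be >= 1")
        if self.window_size_px > self.sim_image_px:
            raise ValueError("density window does not fit inside the simulated image")
        if self.polarity not in ("bright_objects", "dark_objects"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat key-value config file (YAML syntax)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must be a flat key-value mapping")
        if "calibration_nm_per_px" not in raw:
            # no nm/px calibration can be inferred from a micrograph itself,
            # so config files must state it before any image is read
            raise ValueError("config file must supply calibration_nm_per_px")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def density_per_um2(self) -> float:
        window_um2 = (self.window_size_px * self.calibration_nm_per_px / 1e3) ** 2
        return self.sim_density_per_window / window_um2


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic sub-seed for a named stage (< 2^31)."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _write_micrograph_tiff(path: Path, image: Micrograph) -> None:
    data = np.round(image.pixels * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_micrograph(path: str | Path, calibration_nm_per_px: float) -> Micrograph:
    """Read a TIFF/PNG micrograph and rescale intensities to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:  # drop any color axis
        data = data.mean(axis=-1)
    scale = 65535.0 if data.max() > 255 else (255.0 if data.max() > 1 else 1.0)
    return Micrograph(
        pixels=data / scale,
        calibration_nm_per_px=calibration_nm_per_px,
        source_id=path.name,
    )


def segment_micrograph(image: Micrograph, config: RunConfig):
    """Run the full binarize -> open -> label -> filter chain on one image."""
    mask = adaptive_binarize(
        image,
        block_size_px=config.block_size_px,
        offset=config.threshold_offset,
        polarity=config.polarity,
    )
    mask = morphological_open(mask, config.opening_radius_px)
    comps = label_components(mask, image.calibration_nm_per_px)
    comps = filter_by_area(comps, config.min_area_px2)
    comps = filter_by_eccentricity(comps, config.max_eccentricity)
    return mask, comps


def _components_frame(comps) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": c.label,
                "row": c.centroid[0],
                "col": c.centroid[1],
                "area_px2": c.area_px2,
                "eccentricity": c.eccentricity,
                "diameter_nm": c.equivalent_diameter_nm,
                "border_flag": c.touches_border,
            }
            for c in comps
        ]
    )


def run_pipeline(config: RunConfig, outdir: str | Path, inputs: dict | None = None) -> Path:
    """Execute all stages in order, writing artifacts and provenance to ``outdir``.

    ``inputs`` may supply pre-existing files (keys ``micrograph``,
    ``thermogram``, ``group_table``); missing keys are synthesized by the
    simulate stage.  Fails fast, naming the stage and offending file, on any
    parse or validation problem.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir, inputs or {})
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, inputs: dict) -> Path:
    log.info("config: %s", dataclasses.asdict(config))
    seeds = {s: stage_seed(config.seed, s) for s in _STAGES}
    log.info("stage sub-seeds: %s", seeds)

    for key, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"stage simulate: input {key!r} not found: {path}")

    # --- simulate -----------------------------------------------------------
    if "micrograph" in inputs:
        micro_path = Path(inputs["micrograph"])
    else:
        scene = generate_scene(
            density_per_um2=config.density_per_um2,
            diam_mean_nm=config.sim_diam_mean_nm,
            diam_sd_nm=config.sim_diam_sd_nm,
            min_gap_nm=config.sim_min_gap_nm,
            n_artifacts=config.sim_n_artifacts,
            image_shape_px=(config.sim_image_px, config.sim_image_px),
            calibration_nm_per_px=config.calibration_nm_per_px,
            seed=seeds["simulate"],
        )
        image = render_micrograph(
            scene, noise_sd=config.sim_noise_sd, blur_sigma_px=config.sim_blur_px
        )
        micro_path = outdir / "micrograph.tiff"
        _write_micrograph_tiff(micro_path, image)
        ann = pd.DataFrame(
            {
                "center_row_px": scene.fibril_centers[:, 0],
                "center_col_px": scene.fibril_centers[:, 1],
                "radius_px": scene.fibril_radii_px,
                "is_artifact": False,
            }
        )
        for (a, b), t in [((np.array(s[0]), np.array(s[1])), s[2]) for s in scene.artifact_segments]:
            mid = (a + b) / 2.0
            ann.loc[len(ann)] = [mid[0], mid[1], t / 2.0, True]
        ann.to_csv(outdir / "annotations.csv", index=False)
        log.info("simulate: %d fibrils, %d artifacts", scene.n_fibrils,
                 len(scene.artifact_segments))

    if "thermogram" in inputs:
        thermo_path = Path(inputs["thermogram"])
    else:
        thermo = generate_thermogram(
            ThermogramSpec(
                peak_temp_C=config.sim_peak_temp_C,
                noise_sd=0.02,
                seed=seeds["simulate"],
            )
        )
        thermo_path = outdir / "thermogram.csv"
        pd.DataFrame(
            {"temperature_C": thermo.temperature_C, "heat_flow": thermo.heat_flow}
        ).to_csv(thermo_path, index=False)

    if "group_table" in inputs:
        group_path = Path(inputs["group_table"])
    else:
        fixture = load_cct_table()
        specs = [
            (row["group"], row["swelled_cct_um_mean"], row["swelled_cct_um_sd"], 3)
            for _, row in fixture.iterrows()
        ]
        group = generate_group_table(specs, seed=seeds["simulate"], measure="swelled_cct_um")
        group_path = outdir / "group_table.csv"
        group.to_csv(group_path, index=False)

    # --- segment ------------------------------------------------------------
    try:
        image = read_micrograph(micro_path, config.calibration_nm_per_px)
    except Exception as exc:  # pragma: no cover - error path formatting
        raise RuntimeError(f"stage segment: cannot read {micro_path}: {exc}") from exc
    mask, comps = segment_micrograph(image, config)
    tifffile.imwrite(outdir / "mask.tiff", mask.pixels.astype(np.uint8) * 255)
    _components_frame(comps).to_csv(outdir / "components.csv", index=False)
    log.info("segment: %d components retained", len(comps))

    # --- measure ------------------------------------------------------------
    mcfg = MorphometryConfig(
        window_size_px=config.window_size_px,
        n_windows=config.n_windows,
        seed=seeds["measure"],
    )
    result = summarize_image(comps, image, mcfg)
    pd.DataFrame(
        [
            {
                "image_id": result.image_id,
                "n_fibrils": result.n_fibrils,
                "diameter_nm_mean": float(np.mean(result.diameters_nm))
                if result.diameters_nm
                else np.nan,
                "nn_distance_nm_mean": float(np.mean(result.nn_distances_nm))
                if result.nn_distances_nm
                else np.nan,
                "density_median": result.density_median,
                "density_per_um2": result.density_per_um2,
                "window_size_px": result.window_size_px,
                "n_windows": result.n_windows,
                "seed": result.seed,
            }
        ]
    ).to_csv(outdir / "morphometry.csv", index=False)
    log.info("measure: median window density %.2f", result.density_median)

    # --- dsc ----------------------------------------------------------------
    try:
        tdf = pd.read_csv(thermo_path)
        thermo = Thermogram(
            temperature_C=tdf["temperature_C"].to_numpy(),
            heat_flow=tdf["heat_flow"].to_numpy(),
            sample_id=Path(thermo_path).name,
        )
    except Exception as exc:
        raise RuntimeError(f"stage dsc: cannot parse {thermo_path}: {exc}") from exc
    transition = find_transition_temperature(thermo)
    pd.DataFrame(
        [
            {
                "sample_id": thermo.sample_id,
                "transition_temp_C": transition.transition_temp_C,
                "peak_height": transition.peak_height,
            }
        ]
    ).to_csv(outdir / "transition.csv", index=False)
    log.info("dsc: transition at %.2f C", transition.transition_temp_C)

    # --- report -------------------------------------------------------------
    try:
        gdf = pd.read_csv(group_path)
    except Exception as exc:
        raise RuntimeError(f"stage report: cannot parse {group_path}: {exc}") from exc
    report = build_report({"swelled_cct_um": gdf})
    for name, frame in report.items():
        frame.to_csv(outdir / f"report_{name.replace('+', '')}.csv", index=False)
    reductions = pd.DataFrame(
        [
            {
                "family": base,
                "group_a": f"{base}-CXL+Col",
                "group_b": f"{base}-CXL",
                "percent_reduction": percent_swelling_reduction(
                    gdf, f"{base}-CXL+Col", f"{base}-CXL"
                ),
            }
            for base in ("Control", "COLG", "ChaseABC")
        ]
    )
    reductions.to_csv(outdir / "swelling_reduction.csv", index=False)

    provenance = {
        "fibrilquant_version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": seeds,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "tifffile": tifffile.__version__,
        },
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    log.info("run complete: %s", outdir)
    return outdir
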