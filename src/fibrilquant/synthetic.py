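"""Ground-truth-annotated synthetic data: micrographs, thermograms, group tables.

No micrographs or thermograms were deposited with the study this package
re-implements, so every downstream stage is validated against synthetic inputs
whose ground truth is known exactly:

* TEM-like scenes of collagen-fibril cross-sections: bright quasi-circular
  disks of calibrated diameter placed by random sequential adsorption under a
  hard-disk (no-overlap) constraint, contaminated by elongated artifacts,
  Gaussian blur, additive noise and an illumination gradient.
* Single-endotherm DSC thermograms: a Gaussian transition peak on a sloped
  linear baseline with additive noise.
* Per-eye group measurement tables (e.g. central corneal thickness) drawn
  normal(mean, sd) per group.

All randomness in a call flows from one integer seed; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .segmentation import Micrograph

__all__ = [
    "SyntheticScene",
    "ThermogramSpec",
    "InfeasibleDensityError",
    "generate_scene",
    "render_micrograph",
    "generate_thermogram",
    "generate_group_table",
]

#: rejection cap for random sequential adsorption
_RSA_MAX_REJECTIONS = 10_000


class InfeasibleDensityError(RuntimeError):
    """Raised when hard-disk placement cannot reach the requested density."""


@dataclass(frozen=True)
class SyntheticScene:
    """A fully annotated fibril scene: the ground truth behind a micrograph.

    ``fibril_centers`` are (row, col) pixel coordinates inside the frame;
    disks may clip at the border (the segmentation stage flags and censors
    border-touching components from diameter statistics, exactly as it must on
    real micrographs).  ``artifact_segments`` are elongated non-fibril objects
    given as ((r0, c0), (r1, c1), thickness_px).
    """

    image_height_px: int
    image_width_px: int
    calibration_nm_per_px: float
    fibril_centers: np.ndarray  # (n, 2) float
    fibril_radii_px: np.ndarray  # (n,) float
    artifact_segments: tuple[tuple[tuple[float, float], tuple[float, float], float], ...]
    seed: int

    @property
    def n_fibrils(self) -> int:
        return len(self.fibril_radii_px)

    @property
    def area_um2(self) -> float:
        return (
            self.image_height_px
            * self.image_width_px
            * self.calibration_nm_per_px**2
            / 1e6
        )

    @property
    def true_density_per_um2(self) -> float:
        return self.n_fibrils / self.area_um2

    @property
    def true_diameters_nm(self) -> np.ndarray:
        return 2.0 * self.fibril_radii_px * self.calibration_nm_per_px


@dataclass(frozen=True)
class ThermogramSpec:
    """Parameters of a synthetic single-peak DSC curve.

    heat_flow(T) = baseline_slope * (T - T_low)
                   + peak_amplitude * exp(-(T - peak_temp_C)^2 / (2 peak_width_C^2))
                   + normal(0, noise_sd)

    sampled on ``arange(T_low, T_high, step_C)`` inclusive of the upper end.
    """

    peak_temp_C: float
    peak_width_C: float = 3.0
    peak_amplitude: float = 1.0
    baseline_slope: float = -0.02
    noise_sd: float = 0.0
    temp_range_C: tuple[float, float] = (10.0, 95.0)
    step_C: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.temp_range_C
        if not (10.0 <= low < high <= 95.0):
            raise ValueError(f"temp_range_C must lie within [10, 95], got {self.temp_range_C}")
        if not (10.0 <= self.peak_temp_C <= 95.0):
            raise ValueError("peak_temp_C must lie in [10, 95]")
        if self.peak_width_C <= 0 or self.step_C <= 0:
            raise ValueError("peak_width_C and step_C must be positive")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _point_segment_distance(
    points: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Euclidean distance from each point (n,2) to the segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def generate_scene(
    density_per_um2: float,
    diam_mean_nm: float = 40.67,
    diam_sd_nm: float = 2.0,
    min_gap_nm: float = 4.0,
    n_artifacts: int = 0,
    image_shape_px: tuple[int, int] = (1024, 1024),
    calibration_nm_per_px: float = 2.0,
    seed: int = 0,
) -> SyntheticScene:
    """Place non-overlapping fibril disks by random sequential adsorption.

    The realized fibril count is the nearest integer to ``density * area``.
    Diameters are drawn from a normal truncated at zero (group tables report
    mean +- SD only, so a truncated normal is the minimal faithful model).
    Centers are uniform over the whole frame subject to the hard-disk
    condition: every pair of disks is separated by at least
    ``r_i + r_j + min_gap``.  Artifacts are thick line segments at least five
    mean fibril diameters long, placed with the same clearance from every
    fibril so ground-truth identity stays unambiguous.

    Raises
    ------
    InfeasibleDensityError
        After 10^4 consecutive rejected placements (requested packing too
        dense for the hard-disk constraint).
    ValueError
        Nonpositive calibration, negative parameters, or a requested disk
        packing fraction >= 0.5 (geometrically infeasible for RSA).
    """
    if calibration_nm_per_px <= 0:
        raise ValueError("calibration_nm_per_px must be positive")
    if density_per_um2 < 0 or diam_mean_nm <= 0 or diam_sd_nm < 0 or min_gap_nm < 0:
        raise ValueError("invalid generator parameters")
    h, w = image_shape_px
    rng = np.random.default_rng(seed)
    area_um2 = h * w * calibration_nm_per_px**2 / 1e6
    n = int(round(density_per_um2 * area_um2))

    if diam_sd_nm > 0:
        a = (0.0 - diam_mean_nm) / diam_sd_nm
        diam_nm = stats.truncnorm.rvs(
            a, np.inf, loc=diam_mean_nm, scale=diam_sd_nm, size=n, random_state=rng
        )
    else:
        diam_nm = np.full(n, diam_mean_nm)
    radii_px = diam_nm / 2.0 / calibration_nm_per_px
    gap_px = min_gap_nm / calibration_nm_per_px

    packing = float(np.sum(np.pi * radii_px**2)) / (h * w) if n else 0.0
    if packing >= 0.5:
        raise ValueError(
            f"requested packing fraction {packing:.2f} >= 0.5 is infeasible"
        )

    centers = np.empty((n, 2))
    placed = 0
    rejections = 0
    while placed < n:
        cand = rng.uniform((0.0, 0.0), (h, w))
        if placed:
            d = np.linalg.norm(centers[:placed] - cand, axis=1)
            if np.any(d < radii_px[:placed] + radii_px[placed] + gap_px):
                rejections += 1
                if rejections >= _RSA_MAX_REJECTIONS:
                    raise InfeasibleDensityError(
                        f"placed {placed}/{n} fibrils before {_RSA_MAX_REJECTIONS} "
                        "consecutive rejections"
                    )
                continue
        centers[placed] = cand
        placed += 1
        rejections = 0

    mean_diam_px = diam_mean_nm / calibration_nm_per_px
    artifacts: list[tuple[tuple[float, float], tuple[float, float], float]] = []
    rejections = 0
    while len(artifacts) < n_artifacts:
        length = mean_diam_px * rng.uniform(5.0, 8.0)
        thickness = rng.uniform(2.0, max(3.0, 0.3 * mean_diam_px))
        mid = rng.uniform((0.0, 0.0), (h, w))
        theta = rng.uniform(0.0, np.pi)
        half = 0.5 * length * np.array([np.sin(theta), np.cos(theta)])
        a_pt, b_pt = mid - half, mid + half
        ok = True
        if n:
            d = _point_segment_distance(centers, a_pt, b_pt)
            ok = bool(np.all(d >= radii_px + thickness / 2.0 + gap_px))
        if ok:
            artifacts.append(((float(a_pt[0]), float(a_pt[1])),
                              (float(b_pt[0]), float(b_pt[1])), float(thickness)))
            rejections = 0
        else:
            rejections += 1
            if rejections >= _RSA_MAX_REJECTIONS:
                raise InfeasibleDensityError("could not place artifacts with clearance")

    return SyntheticScene(
        image_height_px=h,
        image_width_px=w,
        calibration_nm_per_px=float(calibration_nm_per_px),
        fibril_centers=centers,
        fibril_radii_px=np.asarray(radii_px, dtype=float),
        artifact_segments=tuple(artifacts),
        seed=seed,
    )


def _paint_disk(img: np.ndarray, center: np.ndarray, radius: float, value: float) -> None:
    h, w = img.shape
    r0, c0 = center
    rmin = max(int(np.floor(r0 - radius)) - 1, 0)
    rmax = min(int(np.ceil(r0 + radius)) + 2, h)
    cmin = max(int(np.floor(c0 - radius)) - 1, 0)
    cmax = min(int(np.ceil(c0 + radius)) + 2, w)
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.ogrid[rmin:rmax, cmin:cmax]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    img[rmin:rmax, cmin:cmax][inside] = value


def _paint_capsule(
    img: np.ndarray, a: np.ndarray, b: np.ndarray, thickness: float, value: float
) -> None:
    h, w = img.shape
    half = thickness / 2.0
    rmin = max(int(np.floor(min(a[0], b[0]) - half)) - 1, 0)
    rmax = min(int(np.ceil(max(a[0], b[0]) + half)) + 2, h)
    cmin = max(int(np.floor(min(a[1], b[1]) - half)) - 1, 0)
    cmax = min(int(np.ceil(max(a[1], b[1]) + half)) + 2, w)
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.meshgrid(np.arange(rmin, rmax), np.arange(cmin, cmax), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    inside = (_point_segment_distance(pts, a, b) <= half).reshape(rr.shape)
    img[rmin:rmax, cmin:cmax][inside] = value


def render_micrograph(
    scene: SyntheticScene,
    noise_sd: float = 0.0,
    blur_sigma_px: float = 0.0,
    gradient_amplitude: float = 0.0,
    background: float = 0.25,
    foreground: float = 0.75,
    seed: int | None = None,
) -> Micrograph:
    """Rasterize a scene as bright fibrils on a darker background.

    A pixel belongs to a fibril iff its center lies within the disk radius
    (per-pixel center-distance test), then an optional Gaussian blur, a linear
    illumination gradient across columns (zero-mean, amplitude = full swing)
    and additive Gaussian noise are applied, and intensities are clipped to
    [0, 1].  ``seed`` defaults to the scene's own seed so a scene renders
    reproducibly.
    """
    if noise_sd < 0 or blur_sigma_px < 0:
        raise ValueError("noise_sd and blur_sigma_px must be nonnegative")
    h, w = scene.image_height_px, scene.image_width_px
    img = np.full((h, w), background, dtype=float)
    for center, radius in zip(scene.fibril_centers, scene.fibril_radii_px):
        _paint_disk(img, center, radius, foreground)
    for a_pt, b_pt, thickness in scene.artifact_segments:
        _paint_capsule(img, np.asarray(a_pt), np.asarray(b_pt), thickness, foreground)
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px, mode="reflect")
    if gradient_amplitude != 0.0 and w > 1:
        img = img + gradient_amplitude * (np.arange(w) / (w - 1) - 0.5)
    if noise_sd > 0:
        rng = np.random.default_rng(scene.seed if seed is None else seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return Micrograph(
        pixels=img,
        calibration_nm_per_px=scene.calibration_nm_per_px,
        source_id=f"synthetic-seed{scene.seed}",
    )


def generate_thermogram(spec: ThermogramSpec):
    """Sample a single-endotherm DSC curve from its spec.

    Returns a :class:`fibrilquant.thermal.Thermogram` on the grid
    ``T_low, T_low + step, ..., T_high``.
    """
    from .thermal import Thermogram

    low, high = spec.temp_range_C
    temps = np.arange(low, high + spec.step_C / 2.0, spec.step_C)
    heat = spec.baseline_slope * (temps - low) + spec.peak_amplitude * np.exp(
        -((temps - spec.peak_temp_C) ** 2) / (2.0 * spec.peak_width_C**2)
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        heat = heat + rng.normal(0.0, spec.noise_sd, temps.shape)
    return Thermogram(
        temperature_C=temps, heat_flow=heat, sample_id=f"synthetic-seed{spec.seed}"
    )


def generate_group_table(
    group_specs: list[tuple[str, float, float, int]],
    seed: int = 0,
    measure: str = "cct_um",
) -> pd.DataFrame:
    """Draw per-eye values normal(mean, sd) for each (name, mean_um, sd_um, n).

    Returns a tidy table with columns ``group, eye_id, value, measure`` — the
    shape consumed by the statistics layer.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, mean, sd, n in group_specs:
        if sd < 0:
            raise ValueError(f"group {name!r}: sd must be nonnegative")
        if n < 2:
            raise ValueError(f"group {name!r}: n must be >= 2")
        values = rng.normal(mean, sd, n) if sd > 0 else np.full(n, float(mean))
        for i, v in enumerate(values, start=1):
            rows.append((name, f"{name}-{i:03d}", float(v), measure))
    return pd.DataFrame(rows, columns=["group", "eye_id", "value", "measure"])
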