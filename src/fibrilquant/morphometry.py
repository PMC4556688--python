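"""Structural readouts from segmented fibril components.

Three measurements characterize stromal ultrastructure in a transverse TEM
section: the equivalent-circle diameter of each fibril cross-section, the
center-to-center distance from each fibril to its nearest neighbor
(interfibrillar spacing), and the areal density of fibrils estimated as the
median count over many randomly placed fixed-size square windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .segmentation import FibrilComponent, Micrograph

__all__ = [
    "MorphometryConfig",
    "MorphometryResult",
    "diameters",
    "nearest_neighbor_distances",
    "window_density",
    "summarize_image",
]


@dataclass(frozen=True)
class MorphometryConfig:
    """Parameters of the density-window protocol and spacing convention.

    ``window_size_px`` / ``n_windows`` default to the standard protocol of a
    300x300-pixel window repeated 200 times with the median count reported.
    ``nn_mode`` selects center-to-center spacing (default) or edge-to-edge
    (center distance minus both equivalent radii).
    """

    window_size_px: int = 300
    n_windows: int = 200
    seed: int = 0
    nn_mode: str = "center"

    def __post_init__(self) -> None:
        if self.window_size_px < 1 or self.n_windows < 1:
            raise ValueError("window_size_px and n_windows must be >= 1")
        if self.nn_mode not in ("center", "edge"):
            raise ValueError(f"unknown nn_mode {self.nn_mode!r}")


@dataclass(frozen=True)
class MorphometryResult:
    """Per-image summary: diameters, spacings and randomized-window density.

    ``density_median`` is the unitless median spot count per window (the form
    group tables report); ``density_per_um2`` is the same number divided by
    the window area in um^2, for portability across calibrations.
    """

    image_id: str
    n_fibrils: int
    diameters_nm: tuple[float, ...]
    nn_distances_nm: tuple[float, ...]
    density_median: float
    density_per_um2: float
    window_size_px: int
    n_windows: int
    seed: int


def diameters(components: list[FibrilComponent]) -> list[float]:
    """Equivalent-circle diameters (nm) of non-border components.

    Border-touching components are censored by the frame (their area is
    incomplete) and would bias the diameter distribution downward, so they
    are excluded here but still counted for density.
    """
    return [c.equivalent_diameter_nm for c in components if not c.touches_border]


def nearest_neighbor_distances(
    centroids: list[tuple[float, float]] | np.ndarray,
    calibration_nm_per_px: float,
) -> list[float]:
    """Distance from each point to its nearest other point, in nm.

    Output order matches input order.  Raises ``ValueError`` with fewer than
    two points — a single fibril has no neighbor.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("nearest-neighbor distances need at least two centroids")
    if calibration_nm_per_px <= 0:
        raise ValueError("calibration_nm_per_px must be positive")
    d, _ = cKDTree(pts).query(pts, k=2)
    return list(d[:, 1] * calibration_nm_per_px)


def window_density(
    centroids: list[tuple[float, float]] | np.ndarray,
    image_shape_px: tuple[int, int],
    window_size_px: int = 300,
    n_windows: int = 200,
    seed: int = 0,
) -> tuple[float, list[int]]:
    """Median fibril count over randomly placed square windows.

    Windows are axis-aligned squares drawn uniformly at random with the window
    fully inside the image (no partial windows, no edge correction); a
    centroid at (r, c) is counted for a window at (r0, c0) iff it falls in the
    half-open square [r0, r0+w) x [c0, c0+w), so a point on a shared edge is
    never double-counted.  With an even number of windows the median is the
    midpoint of the two central order statistics.
    """
    h, w = image_shape_px
    if window_size_px > h or window_size_px > w:
        raise ValueError(
            f"window {window_size_px} px does not fit inside image {image_shape_px}"
        )
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = np.random.default_rng(seed)
    r0 = rng.uniform(0.0, h - window_size_px, n_windows)
    c0 = rng.uniform(0.0, w - window_size_px, n_windows)
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        counts = np.zeros(n_windows, dtype=int)
    else:
        in_r = (pts[:, 0][None, :] >= r0[:, None]) & (
            pts[:, 0][None, :] < r0[:, None] + window_size_px
        )
        in_c = (pts[:, 1][None, :] >= c0[:, None]) & (
            pts[:, 1][None, :] < c0[:, None] + window_size_px
        )
        counts = np.sum(in_r & in_c, axis=1)
    return float(np.median(counts)), [int(c) for c in counts]


def summarize_image(
    components: list[FibrilComponent],
    image: Micrograph,
    config: MorphometryConfig = MorphometryConfig(),
) -> MorphometryResult:
    """Fill a full per-image morphometry record from filtered components.

    ``n_fibrils`` and the density windows use every retained component
    (including border-touching ones — density counts spots); diameters use
    non-border components only; nearest-neighbor spacings need at least two
    fibrils and are empty otherwise.
    """
    cal = image.calibration_nm_per_px
    centroids = np.asarray([c.centroid for c in components], dtype=float).reshape(-1, 2)
    n = len(components)
    diams = diameters(components)
    if n >= 2:
        nn = nearest_neighbor_distances(centroids, cal)
        if config.nn_mode == "edge":
            radii = np.array([c.equivalent_diameter_nm / 2.0 for c in components])
            d, idx = cKDTree(centroids).query(centroids, k=2)
            nn = list(d[:, 1] * cal - radii - radii[idx[:, 1]])
    else:
        nn = []
    median, _counts = window_density(
        centroids,
        image.shape,
        window_size_px=config.window_size_px,
        n_windows=config.n_windows,
        seed=config.seed,
    )
    window_area_um2 = (config.window_size_px * cal / 1e3) ** 2
    return MorphometryResult(
        image_id=image.source_id,
        n_fibrils=n,
        diameters_nm=tuple(diams),
        nn_distances_nm=tuple(nn),
        density_median=median,
        density_per_um2=median / window_area_um2,
        window_size_px=config.window_size_px,
        n_windows=config.n_windows,
        seed=config.seed,
    )
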