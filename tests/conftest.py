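import numpy as np
import pytest

from fibrilquant.synthetic import generate_scene, render_micrograph


@pytest.fixture(scope="session")
def small_scene():
    """A modest hard-disk scene with artifacts, reused across tests."""
    return generate_scene(
        density_per_um2=50.0,
        diam_mean_nm=40.0,
        diam_sd_nm=2.0,
        n_artifacts=5,
        image_shape_px=(512, 512),
        calibration_nm_per_px=2.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_image(small_scene):
    """Noise-free render of ``small_scene``."""
    return render_micrograph(small_scene)


def rasterize_disk(shape, center, radius):
    """Per-pixel center-distance rasterization oracle."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
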