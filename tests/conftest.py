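import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sgaphen.synthetic_data import (
    CellFieldConfig,
    ScreenConfig,
    generate_cell_field,
    generate_screen,
    render_plate_image,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_screen():
    """16-gene, 4x4, hand-checkable screen: no noise, no plate effects."""
    cfg = ScreenConfig(
        n_genes=16, rows=4, cols=4, n_isolates=2, n_replicates=2,
        plate_scale_sd=0.0, edge_effect=1.0, noise_cv=0.0,
        interaction_fractions=(0.125, 0.125), effect_magnitudes=(0.5, 1.5),
        base_sizes=np.linspace(100, 400, 16), seed=7,
    )
    return generate_screen(cfg)


@pytest.fixture(scope="session")
def rendered_plate():
    """Noise-free rendered 16x24 plate plus its generating truth."""
    cfg = ScreenConfig(n_genes=384, rows=16, cols=24, noise_cv=0.0,
                       plate_scale_sd=0.0, seed=21)
    plate = generate_screen(cfg).plates[0]
    pitch = 26  # photograph-like resolution: smallest colonies span >4 px radius
    scale = ((pitch / 2 - 4) ** 2 * np.pi) / plate.sizes.max()
    img, geometry, truth_areas = render_plate_image(
        plate, pitch=pitch, area_scale=scale, noise_sd=0.0
    )
    return img, geometry, truth_areas


@pytest.fixture(scope="session")
def ellipse_field():
    """Forty 2:1 ellipses with truth masks (elongation/segmentation oracle)."""
    cfg = CellFieldConfig(n_cells=40, axis_ratio_mean=2.0, seed=5)
    return generate_cell_field(cfg)


@pytest.fixture(scope="session")
def circle_field():
    """Round cells at >= 30 px radius (circle limit of the elongation score)."""
    cfg = CellFieldConfig(n_cells=12, axis_ratio_mean=1.0, minor_diameter_um=3.5,
                          pixel_size=0.05, image_shape=(1024, 1024), seed=9)
    return generate_cell_field(cfg)
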