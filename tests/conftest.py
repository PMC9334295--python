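import numpy as np
import pytest

from colonynet.synthetic import ColonyConfig, render_colony, sample_centers_uniform, sample_shapes


@pytest.fixture
def well_separated_colony():
    """Noiseless colony of 50 circular nuclei with separation >= 3x radius,
    kept clear of the border, plus its ground truth."""
    radius = 5.0
    margin = 20.0
    cfg = ColonyConfig(
        field_width_px=700,
        field_height_px=700,
        n_cells=50,
        nucleus_mean_radius_px=radius,
        nucleus_radius_cv=0.0,
        nucleus_axis_ratio=1.0,
        noise_sigma=0.0,
        seed=11,
    )
    inner = sample_centers_uniform(
        cfg.n_cells, 700 - 2 * margin, 700 - 2 * margin, min_separation=3 * radius * 2, seed=11
    )
    centers = inner + margin
    shapes = sample_shapes(cfg.n_cells, cfg, seed=12)
    img, truth = render_colony(centers, shapes, cfg)
    return img, truth, cfg
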