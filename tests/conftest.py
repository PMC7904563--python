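import numpy as np
import pytest

from tjperm.synthetic import (
    CellTessellation,
    FieldSpec,
    RenderParams,
    generate_tessellation,
)


@pytest.fixture(scope="session")
def small_tess():
    """64x64 field, 5 cells: quick geometry for rendering tests."""
    return generate_tessellation(FieldSpec(64, 64, 5, rng_seed=11), relaxation_steps=1)


@pytest.fixture(scope="session")
def medium_tess():
    """256x256 field, ~40 cells: realistic density at moderate cost."""
    return generate_tessellation(FieldSpec(256, 256, 40, rng_seed=7), relaxation_steps=2)


@pytest.fixture(scope="session")
def noiseless_render_params():
    return RenderParams(border_width_px=3.0, border_peak_intensity=0.8,
                        blur_sigma_px=0.0, noise_sd=0.0)


def rotate_tessellation_90(tess: CellTessellation) -> CellTessellation:
    """Rotate a square-field tessellation by 90 deg: (x, y) -> (y, W-1-x).

    Matches np.rot90 on the rendered image grid.
    """
    w = tess.field.width_px - 1.0

    def rot(pts):
        pts = np.atleast_2d(pts)
        return np.column_stack([pts[:, 1], w - pts[:, 0]])

    return CellTessellation(
        field=tess.field,
        cell_seeds=rot(tess.cell_seeds),
        edges=[rot(seg) for seg in tess.edges],
        vertices=rot(tess.vertices) if len(tess.vertices) else tess.vertices,
        vertex_degrees=tess.vertex_degrees,
    )
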