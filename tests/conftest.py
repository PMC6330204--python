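import numpy as np
import pytest
from hypothesis import settings

from understorey import hemiphoto as hp
from understorey import synthdata as sd

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def hemi_l2():
    """A simulated hemisphere of true LAI 2 at moderate resolution."""
    return sd.gen_hemiphoto(sd.CanopySceneParams(true_lai=2.0, image_size=512,
                                                 seed=11))


@pytest.fixture(scope="session")
def mask_l2(hemi_l2):
    band = hp.extract_blue_band(hemi_l2)
    return hp.binarize(band, hp.ridler_calvard_threshold(band))


def closed_form_profile(lai, g=0.5, ring_width=5.0, n_cells=8, count=10_000):
    """Gap-fraction profile following P(theta) = exp(-g L / cos theta)
    exactly at the ring midpoints, homogeneous across azimuth cells."""
    edges = np.arange(0.0, 60.0 + 1e-9, ring_width)
    rings = [(float(edges[i]), float(edges[i + 1])) for i in range(len(edges) - 1)]
    theta = np.deg2rad([(a + b) / 2 for a, b in rings])
    p = np.exp(-g * lai / np.cos(theta))
    n_rings = len(rings)
    cell_count = count // n_cells
    return hp.GapFractionProfile(
        rings=rings,
        gap_fraction=p,
        ring_counts=np.full(n_rings, cell_count * n_cells),
        ring_sky=np.round(p * cell_count * n_cells).astype(int),
        cell_gap_fraction=np.tile(p[:, None], (1, n_cells)),
        cell_counts=np.full((n_rings, n_cells), cell_count),
        cell_sky=np.round(np.tile(p[:, None], (1, n_cells)) * cell_count).astype(int),
    )
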