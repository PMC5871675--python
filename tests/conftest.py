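import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import proportionator as pp

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_tiles(weights, counts=None, usable=None, frame_um=200.0, pair_id=1):
    """Minimal valid tile table from a weight vector."""
    weights = np.asarray(weights)
    m = len(weights)
    return pd.DataFrame({
        "tile_id": np.arange(m),
        "pair_id": pair_id,
        "x_um": np.arange(m, dtype=float) * frame_um,
        "y_um": 0.0,
        "frame_um": frame_um,
        "weight_px": weights,
        "count": np.zeros(m, dtype=int) if counts is None else np.asarray(counts),
        "usable": np.ones(m, dtype=int) if usable is None else np.asarray(usable),
    })


def make_organ(cells, height_um=72.0, w=400.0, d=400.0, diameter=8.0):
    """Organ with handcrafted cell centroids (x, y, z)."""
    cells = np.asarray(cells, dtype=float).reshape(-1, 3)
    arr = np.column_stack([cells, np.full(len(cells), diameter)])
    return pp.OrganTruth(height_um=height_um, cross_section_w_um=w,
                         cross_section_d_um=d, cells=arr, n_true=len(cells))


@pytest.fixture(scope="session")
def default_organ():
    """The study-condition organ: ~3 mm tall, ~1e7 um^2 cross section,
    50 cells clustered toward the endplates."""
    return pp.generate_organ(3000.0, 3200.0, 3200.0, 50, seed=7)


@pytest.fixture(scope="session")
def default_supersection(default_organ):
    """Mouse-pilot-like fractionator sample (sf = 1/6) of the default organ."""
    return pp.build_supersection(default_organ, pp.StainModel(), 6.0, 83,
                                 200.0, seed=11)
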