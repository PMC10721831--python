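"""Shared fixtures: small synthetic datasets and tiled training pairs."""

import numpy as np
import pytest

from phasepaint import imaging_io as io
from phasepaint import synthetic_organoid as so


@pytest.fixture(scope="session")
def scene_records():
    """Three deterministic synthetic fields with ground truth."""
    return so.make_dataset(3, so.OrganoidSceneParams(), seed=11)


@pytest.fixture(scope="session")
def nuclei_tiles(scene_records):
    """(x, y) pairs of 64x64 phase tiles and binary nuclei masks."""
    spec = io.ChannelSpec("nuclei", background_threshold=0.2)
    xs, ys = [], []
    for rec in scene_records:
        grid = io.make_tile_grid(rec.phase.height, rec.phase.width, 64, 0.5)
        mask = io.binarize_target(rec.targets["nuclei"], spec)
        xs += io.extract_tiles(rec.phase.pixels, grid)
        ys += [t.astype(np.float64) for t in io.extract_tiles(mask.pixels, grid)]
    return np.stack(xs), np.stack(ys)
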