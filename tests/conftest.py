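import numpy as np
import pytest

from hemosaic.distortion import DistortionParams
from hemosaic.synthscan import SceneParams, ScanConfig, make_grid, make_tissue_scene, simulate_scan


@pytest.fixture(scope="session")
def tissue_scene():
    """Small two-channel scene with ground truth, shared across tests."""
    thg, tpef, nuclei = make_tissue_scene(SceneParams(900, 900, seed=11))
    return thg, tpef, nuclei


@pytest.fixture(scope="session")
def distorted_grid_pair():
    """Two adjacent grid tiles carrying the distortion reported for the
    real instrument: A = 51 deg, X_off = -49, Y_off = -47 (flips on both
    axes), S = 60. Tiles are 400 px with a 100 px shared strip.
    """
    truth = DistortionParams(51.0, -49.0, -47.0)
    w, ov = 400, 120
    scene = make_grid(2 * w - ov, w, 50, 7)
    tile_a = scene[:, :w]
    tile_b = scene[:, w - ov :]
    assert tile_b.shape == (w, w)
    from hemosaic.distortion import induce

    da = induce(tile_a, truth)
    db = induce(tile_b, truth)
    overlap = ((w - ov, 0, w, w), (0, 0, ov, w))
    return da, db, overlap, truth


@pytest.fixture(scope="session")
def small_scan(tissue_scene):
    """Noiseless jittered 2x2 scan of the shared scene (300 px tiles)."""
    thg, tpef, _ = tissue_scene
    cfg = ScanConfig(tile_px=300, jitter_px=8, noise_sigma=0.0, seed=5)
    tiles, truth, plan = simulate_scan((thg, tpef), cfg, tiles_x=2, tiles_y=2)
    return tiles, truth, plan


def placements_as_dict(placements):
    return {
        p.tile_id: {"placed_x_px": p.placed_x_px, "placed_y_px": p.placed_y_px}
        for p in placements
    }


def truth_as_dict(truth):
    return {t["tile_id"]: t for t in truth}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
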