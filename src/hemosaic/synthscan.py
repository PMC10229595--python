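"""Synthetic scenes and a scan simulator with ground truth.

Everything the rest of the package needs to be exercised without real
microscope data: a grid calibration target for the distortion model, a
two-channel "tissue" scene (nuclei-like ellipses in channel 1 standing
in for the THG/hematoxylin signal, vessel ribbons plus band-limited
texture in channel 2 for the TPEF/eosin signal), and a tiling simulator
that emulates the acquisition chain — stage stepping with ~9% FOV
overlap, per-tile stage jitter, induced radial distortion, cosinusoidal
fast-axis resampling, and additive noise — while recording the true
tile positions the stitcher is later asked to recover.

The stage log reports the *nominal* (jitter-free) positions: jitter
models stage repeatability error, the unknown that makes content-based
alignment necessary. The first tile is not jittered; it anchors the
mosaic coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .core import MosaicPlan, Tile, plan_mosaic
from .distortion import DistortionParams, apply_resonant, induce

__all__ = [
    "SceneParams",
    "ScanConfig",
    "make_grid",
    "make_tissue_scene",
    "simulate_scan",
    "scene_shape_for_plan",
]

TRUTH_COLUMNS = ("tile_id", "grid_col", "grid_row", "true_x_px", "true_y_px")


@dataclass(frozen=True)
class SceneParams:
    """Parameters of the synthetic two-channel tissue scene.

    Densities and sizes are loosely modelled on H&E brain histology at
    sub-micron pixel pitch, scaled so that features remain resolvable at
    the small test-scene sizes used in the suite.
    """

    width_px: int = 1200
    height_px: int = 1200
    nuclei_density_per_mm2: float = 1500.0
    nuclei_radius_px: tuple[float, float] = (6.0, 14.0)
    nuclei_eccentricity: tuple[float, float] = (1.0, 1.8)
    nuclei_intensity: tuple[int, int] = (120, 230)
    vessel_count: int = 4
    vessel_width_px: tuple[float, float] = (8.0, 20.0)
    vessel_intensity: int = 160
    haze_level: tuple[int, int] = (20, 30)
    #: optical point-spread blur applied to both channels; a
    #: Nyquist-satisfied scan oversamples the PSF, so per-pixel
    #: gradients are band-limited in any real acquisition
    psf_sigma_px: float = 1.5
    pixel_pitch_nm: float = 167.0
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.nuclei_radius_px, self.nuclei_eccentricity,
                       self.nuclei_intensity, self.vessel_width_px):
            if lo > hi:
                raise ValueError("ranges must satisfy min <= max")
        if self.nuclei_density_per_mm2 < 0:
            raise ValueError("density must be non-negative")


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition-chain parameters of the simulated scan."""

    tile_px: int = 400
    overlap_frac: float = 0.09
    jitter_px: int = 8
    distortion: DistortionParams | None = None
    resonant_beta: float | None = None
    noise_sigma: float = 5.0
    poisson: bool = False
    pixel_pitch_nm: float = 167.0
    seed: int = 0

    def __post_init__(self) -> None:
        overlap_px = self.tile_px - round((1 - self.overlap_frac) * self.tile_px)
        if self.jitter_px >= max(1, overlap_px):
            raise ValueError(
                "jitter must stay below the overlap extent or alignment "
                "becomes unidentifiable"
            )


def make_grid(width_px: int, height_px: int, spacing_px: int, line_px: int) -> np.ndarray:
    """Calibration target: white lines (255) on black at exact spacing.

    Line centres sit at every multiple of ``spacing_px`` along both
    axes, including the image borders (clipped lines included).
    """
    if line_px < 1 or spacing_px <= line_px:
        raise ValueError("require spacing_px > line_px >= 1")
    img = np.zeros((height_px, width_px), dtype=np.uint8)
    half = line_px // 2
    for x in range(0, width_px + 1, spacing_px):
        img[:, max(0, x - half) : min(width_px, x - half + line_px)] = 255
    for y in range(0, height_px + 1, spacing_px):
        img[max(0, y - half) : min(height_px, y - half + line_px), :] = 255
    return img


def _draw_ellipse(canvas: np.ndarray, cx, cy, a, b, theta, intensity) -> None:
    """Accumulate an anti-aliased filled ellipse (1-px soft edge)."""
    r = int(np.ceil(max(a, b))) + 2
    y0, y1 = max(0, int(cy) - r), min(canvas.shape[0], int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(canvas.shape[1], int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    e = np.sqrt(u * u + v * v)
    alpha = np.clip((1.0 - e) * min(a, b) + 0.5, 0.0, 1.0)
    patch = canvas[y0:y1, x0:x1]
    np.maximum(patch, intensity * alpha, out=patch)


def make_tissue_scene(params: SceneParams | None = None):
    """Render the two ground-truth channels and the nuclei table.

    Returns ``(thg_truth, tpef_truth, nuclei)`` where ``nuclei`` is a
    list of dicts with centre, axes and orientation of each ellipse.
    Deterministic for a fixed seed.
    """
    params = params or SceneParams()
    rng = np.random.default_rng(params.seed)
    h, w = params.height_px, params.width_px
    pitch_mm = params.pixel_pitch_nm * 1e-6
    area_mm2 = (w * pitch_mm) * (h * pitch_mm)

    # channel 1: nuclei over haze
    thg = np.full((h, w), float(params.haze_level[0]))
    n_nuclei = int(rng.poisson(params.nuclei_density_per_mm2 * area_mm2))
    nuclei: list[dict] = []
    placed: list[tuple[float, float, float]] = []
    for _ in range(n_nuclei):
        for _attempt in range(200):
            cx = rng.uniform(0, w)
            cy = rng.uniform(0, h)
            a = rng.uniform(*params.nuclei_radius_px)
            ecc = rng.uniform(*params.nuclei_eccentricity)
            b = a / ecc
            if all((cx - px) ** 2 + (cy - py) ** 2 > (0.8 * (a + pr)) ** 2
                   for px, py, pr in placed):
                break
        else:
            raise ValueError("nuclei density too high: placement failed")
        theta = rng.uniform(0, np.pi)
        inten = rng.uniform(*params.nuclei_intensity)
        _draw_ellipse(thg, cx, cy, a, b, theta, inten)
        placed.append((cx, cy, a))
        nuclei.append(
            {"cx": cx, "cy": cy, "a": a, "b": b, "theta": theta, "intensity": inten}
        )

    # channel 2: vessel ribbons + band-limited texture over haze
    tpef = np.full((h, w), float(params.haze_level[1]))
    path = np.zeros((h, w), dtype=bool)
    widths = []
    for _ in range(params.vessel_count):
        # smooth polyline across the scene
        n_ctrl = 5
        xs = np.sort(rng.uniform(0, w, n_ctrl))
        ys = rng.uniform(0, h, n_ctrl)
        t = np.linspace(0, 1, n_ctrl)
        tt = np.linspace(0, 1, 4 * max(h, w))
        px = np.interp(tt, t, xs)
        py = np.interp(tt, t, ys)
        py = gaussian_filter(py, sigma=len(tt) / 40.0, mode="nearest")
        ix = np.clip(np.rint(px).astype(int), 0, w - 1)
        iy = np.clip(np.rint(py).astype(int), 0, h - 1)
        path[iy, ix] = True
        widths.append(rng.uniform(*params.vessel_width_px))
    if params.vessel_count:
        dist = distance_transform_edt(~path)
        ribbon = np.clip((np.mean(widths) / 2.0 + 0.5) - dist, 0.0, 1.0)
        tpef += params.vessel_intensity * ribbon
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=5.0)
    texture *= 20.0 / max(texture.std(), 1e-9)
    tpef += texture

    if params.psf_sigma_px > 0:
        thg = gaussian_filter(thg, params.psf_sigma_px)
        tpef = gaussian_filter(tpef, params.psf_sigma_px)
    clip8 = lambda a: np.clip(np.rint(a), 0, 255).astype(np.uint8)
    return clip8(thg), clip8(tpef), nuclei


def scene_shape_for_plan(plan: MosaicPlan) -> tuple[int, int]:
    """(height, width) a scene must have to cover a mosaic plan exactly."""
    return plan.mosaic_h_px, plan.mosaic_w_px


def simulate_scan(
    scene: tuple[np.ndarray, ...],
    config: ScanConfig | None = None,
    tiles_x: int | None = None,
    tiles_y: int | None = None,
) -> tuple[list[Tile], list[dict], MosaicPlan]:
    """Cut a scene into jittered, distorted, noisy tiles.

    Per tile: crop at the planned position plus an integer jitter drawn
    uniformly from ``[-jitter_px, jitter_px]`` per axis (zero for the
    first tile), apply the forward distortion, resample the fast axis
    cosinusoidally, then add noise. Returns the tiles, a truth table of
    the actual crop positions, and the mosaic plan. The tiles'
    stage coordinates are the nominal (jitter-free) positions.
    """
    config = config or ScanConfig()
    channels = [np.asarray(c) for c in scene]
    h, w = channels[0].shape
    plan_probe = plan_mosaic(1, 1, config.tile_px, config.overlap_frac,
                             config.pixel_pitch_nm)
    stride = round((1 - config.overlap_frac) * config.tile_px)
    if tiles_x is None:
        tiles_x = (w - config.tile_px) // stride + 1
    if tiles_y is None:
        tiles_y = (h - config.tile_px) // stride + 1
    if tiles_x < 1 or tiles_y < 1:
        raise ValueError("scene smaller than one tile")
    plan = plan_mosaic(tiles_x, tiles_y, config.tile_px, config.overlap_frac,
                       config.pixel_pitch_nm)
    del plan_probe

    rng = np.random.default_rng(config.seed)
    j = config.jitter_px
    tiles: list[Tile] = []
    truth: list[dict] = []
    pitch_um = config.pixel_pitch_nm / 1000.0
    for row in range(tiles_y):
        for col in range(tiles_x):
            nx, ny = plan.tile_origin(col, row)
            if row == 0 and col == 0:
                jx = jy = 0
            else:
                jx = int(rng.integers(-j, j + 1)) if j else 0
                jy = int(rng.integers(-j, j + 1)) if j else 0
            tx = min(max(0, nx + jx), w - config.tile_px)
            ty = min(max(0, ny + jy), h - config.tile_px)
            chans = []
            for ch in channels:
                crop = ch[ty : ty + config.tile_px, tx : tx + config.tile_px]
                if config.distortion is not None:
                    crop = induce(crop, config.distortion)
                if config.resonant_beta is not None:
                    crop = apply_resonant(crop, config.resonant_beta)
                out = crop.astype(np.float64)
                if config.poisson:
                    out = rng.poisson(np.maximum(out, 0)).astype(np.float64)
                if config.noise_sigma > 0:
                    out = out + rng.normal(0, config.noise_sigma, out.shape)
                chans.append(np.clip(np.rint(out), 0, 255).astype(np.uint8))
            tile_id = f"t_{row:02d}_{col:02d}"
            tiles.append(
                Tile(
                    tile_id, col, row,
                    stage_x_um=nx * pitch_um, stage_y_um=ny * pitch_um,
                    channels=chans, pixel_pitch_nm=config.pixel_pitch_nm,
                )
            )
            truth.append(
                {"tile_id": tile_id, "grid_col": col, "grid_row": row,
                 "true_x_px": tx, "true_y_px": ty}
            )
    return tiles, truth, plan


def write_truth(path, truth: list[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in truth:
            fh.write(
                f"{r['tile_id']}\t{r['grid_col']}\t{r['grid_row']}\t"
                f"{r['true_x_px']}\t{r['true_y_px']}\n"
            )


def read_truth(path) -> dict[str, dict]:
    out: dict[str, dict] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            vals["true_x_px"] = int(vals["true_x_px"])
            vals["true_y_px"] = int(vals["true_y_px"])
            out[vals["tile_id"]] = vals
    return out
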