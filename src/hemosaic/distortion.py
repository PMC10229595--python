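"""Radial FOV-distortion model, grid-search parameter estimation, and
resonant-scanner cosinusoidal resampling.

The distortion model
--------------------
A tile of ``C x R`` pixels (``C`` columns, ``R`` rows) is remapped through
two pixel-coordinate maps ``M_x``, ``M_y``. With coordinate arrays
``F_x[y, x] = x`` and ``F_y[y, x] = y``, a distortion centre

    c1 = 0.5 * C * (1 + |X_off| / S_x)
    c2 = 0.5 * R * (1 + |Y_off| / S_y)

and normalised radial coordinates

    r_x = (F_x - c1) / c1,   r_y = (F_y - c2) / c2,
    r_u = sqrt(r_x**2 + r_y**2),

the distorted radius is

    r_d = (360 / (A * pi)) * arctan(2 * r_u * tan(A * pi / 720)),

where ``A`` (degrees) governs the distortion strength. A multiplicative
factor ``f = r_u / r_d`` (pincushion) or ``f = r_d / r_u`` (barrel), with
``f = 1`` at the centre ``r_u = 0``, then yields

    M_x = c1 * (1 + r_x * f),   M_y = c2 * (1 + r_y * f).

The output image samples the input at ``(M_x, M_y)`` with bilinear
interpolation. A negative ``X_off`` (resp. ``Y_off``) encodes a flip of
the image along that axis before remapping (undone afterwards), which
moves the distortion centre into any of the four quadrants while the
centre formula itself only uses the offset magnitudes.

``induce`` applies the exact functional inverse of the ``compensate``
remap (the monotone radial sampling function inverted numerically), so
the pair round-trips to bilinear-interpolation error; the scan simulator
uses it to create realistically distorted tiles. The opposite-mode remap
(pincushion <-> barrel swap) is available through
``DistortionParams.opposite()`` and agrees with the exact inverse to
first order in the distortion strength.

Parameter estimation
--------------------
Given two adjacent, identically distorted tiles with a known overlap
region R12, every candidate parameter triple (A, X_off, Y_off, including
the sign-encoded flips) is scored by

    d_k = sum_{R12} |T1_U - T2_U| / Area(R12),

the mean absolute difference of the two compensated tiles over R12,
evaluated on opened-and-thresholded copies so that high-frequency noise
does not dominate, and restricted to pixels whose remap samples inside
both acquired frames (zero-filled border samples carry no information
about the parameters). The argmin candidate is returned. Because only
R12 pixels enter ``d_k``, the maps are evaluated on the overlap region
alone, which makes an exhaustive grid search tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.filters import threshold_otsu
from skimage.morphology import opening, footprint_rectangle

__all__ = [
    "DistortionParams",
    "PixelMaps",
    "SearchGrid",
    "compute_pixel_maps",
    "compensate",
    "induce",
    "estimate_params",
    "correct_resonant",
    "apply_resonant",
    "save_params_toml",
    "load_params_toml",
]

PINCUSHION = "pincushion"
BARREL = "barrel"


@dataclass(frozen=True)
class DistortionParams:
    """Parameters of the radial FOV-distortion model.

    ``a_deg`` is the distortion angle in degrees (> 0, < 360); ``x_off``
    and ``y_off`` are signed spatial offsets in pixels, a negative sign
    encoding a flip along that axis; ``s_x``/``s_y`` are dimensionless
    scaling constants, fixed at 60 throughout; ``mode`` selects the
    compensation direction.
    """

    a_deg: float
    x_off: float
    y_off: float
    s_x: float = 60.0
    s_y: float = 60.0
    mode: str = PINCUSHION

    def __post_init__(self) -> None:
        if not 0.0 < self.a_deg < 360.0:
            raise ValueError("a_deg must lie in (0, 360)")
        if self.s_x <= 0 or self.s_y <= 0:
            raise ValueError("s_x and s_y must be positive")
        if self.mode not in (PINCUSHION, BARREL):
            raise ValueError(f"mode must be '{PINCUSHION}' or '{BARREL}'")

    @property
    def flip_x(self) -> bool:
        return self.x_off < 0

    @property
    def flip_y(self) -> bool:
        return self.y_off < 0

    def opposite(self) -> "DistortionParams":
        other = BARREL if self.mode == PINCUSHION else PINCUSHION
        return replace(self, mode=other)


@dataclass
class PixelMaps:
    """Precomputed coordinate maps for one image shape ``(R rows, C cols)``."""

    m_x: np.ndarray
    m_y: np.ndarray
    f_x: np.ndarray
    f_y: np.ndarray
    c1: float
    c2: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.m_x.shape


def _centres(params: DistortionParams, C: int, R: int) -> tuple[float, float]:
    c1 = 0.5 * C * (1.0 + abs(params.x_off) / params.s_x)
    c2 = 0.5 * R * (1.0 + abs(params.y_off) / params.s_y)
    return c1, c2


def _eval_maps(
    params: DistortionParams,
    f_x: np.ndarray,
    f_y: np.ndarray,
    C: int,
    R: int,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Evaluate (M_x, M_y) at arbitrary coordinate arrays f_x, f_y."""
    c1, c2 = _centres(params, C, R)
    r_x = (f_x - c1) / c1
    r_y = (f_y - c2) / c2
    r_u = np.sqrt(r_x * r_x + r_y * r_y)
    a_rad = params.a_deg * math.pi
    half_tan = math.tan(a_rad / 720.0)
    r_d = (360.0 / a_rad) * np.arctan(2.0 * r_u * half_tan)
    # f has a removable singularity at r_u = 0 where f -> 1.
    with np.errstate(divide="ignore", invalid="ignore"):
        if params.mode == PINCUSHION:
            f = np.where(r_u > 0, r_u / np.where(r_d > 0, r_d, 1.0), 1.0)
        else:
            f = np.where(r_u > 0, r_d / np.where(r_u > 0, r_u, 1.0), 1.0)
    m_x = c1 * (1.0 + r_x * f)
    m_y = c2 * (1.0 + r_y * f)
    return m_x, m_y, c1, c2


def compute_pixel_maps(params: DistortionParams, C: int, R: int) -> PixelMaps:
    """Build full-image coordinate maps for a ``C x R`` (cols x rows) tile."""
    if C < 2 or R < 2:
        raise ValueError("image must be at least 2 x 2 pixels")
    f_x, f_y = np.meshgrid(
        np.arange(C, dtype=np.float64), np.arange(R, dtype=np.float64)
    )
    m_x, m_y, c1, c2 = _eval_maps(params, f_x, f_y, C, R)
    return PixelMaps(m_x=m_x, m_y=m_y, f_x=f_x, f_y=f_y, c1=c1, c2=c2)


def _snap(coords: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Round coordinates within float tolerance of an integer.

    A coordinate like ``n - 1 + 1e-9`` would otherwise fall into the
    constant-fill region of the interpolator and darken border pixels
    even for an analytically exact identity map.
    """
    nearest = np.rint(coords)
    return np.where(np.abs(coords - nearest) < tol, nearest, coords)


def _remap_bilinear(image: np.ndarray, m_x: np.ndarray, m_y: np.ndarray) -> np.ndarray:
    """Sample ``image`` at real coordinates (m_x, m_y); out of bounds -> 0."""
    vals = map_coordinates(
        np.asarray(image, dtype=np.float64),
        [_snap(m_y).ravel(), _snap(m_x).ravel()],
        order=1,
        mode="constant",
        cval=0.0,
    )
    return vals.reshape(m_x.shape)


def compensate(
    image: np.ndarray,
    maps: PixelMaps | None = None,
    params: DistortionParams | None = None,
) -> np.ndarray:
    """Remap an 8-bit tile through the distortion model.

    When ``maps`` is omitted it is computed from ``params`` for the image
    shape. Negative offsets flip the image along the corresponding axis
    before remapping and flip the result back.
    """
    if params is None:
        raise ValueError("params are required")
    R, C = image.shape
    if maps is None:
        maps = compute_pixel_maps(params, C, R)
    if maps.shape != image.shape:
        raise ValueError(
            f"map shape {maps.shape} does not match image shape {image.shape}"
        )
    src = image
    if params.flip_x:
        src = src[:, ::-1]
    if params.flip_y:
        src = src[::-1, :]
    out = _remap_bilinear(src, maps.m_x, maps.m_y)
    if params.flip_x:
        out = out[:, ::-1]
    if params.flip_y:
        out = out[::-1, :]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _radial_sample_scale(params: DistortionParams, r_u: np.ndarray) -> np.ndarray:
    """Radius each output pixel samples at, as a function of its own radius.

    ``compensate`` samples the source at radius ``r_u * f``; this returns
    that product (``r_u**2 / r_d`` for pincushion, ``r_d`` for barrel).
    """
    a_rad = params.a_deg * math.pi
    half_tan = math.tan(a_rad / 720.0)
    r_d = (360.0 / a_rad) * np.arctan(2.0 * r_u * half_tan)
    if params.mode == PINCUSHION:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(r_u > 0, r_u * r_u / np.where(r_d > 0, r_d, 1.0), 0.0)
    return r_d


def _eval_inverse_maps(
    params: DistortionParams,
    f_x: np.ndarray,
    f_y: np.ndarray,
    C: int,
    R: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate maps of the exact inverse of the ``compensate`` remap.

    The radial sampling function of ``compensate`` is strictly monotone,
    so its functional inverse is tabulated on a dense radius grid and
    interpolated; composing the two remaps is then the identity up to
    bilinear-interpolation error.
    """
    c1, c2 = _centres(params, C, R)
    r_x = (f_x - c1) / c1
    r_y = (f_y - c2) / c2
    r_u = np.sqrt(r_x * r_x + r_y * r_y)
    r_max = float(r_u.max()) * 1.5 + 1e-6
    grid = np.linspace(0.0, r_max, 8193)
    sigma = _radial_sample_scale(params, grid)
    src_r = np.interp(r_u, sigma, grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(r_u > 0, src_r / np.where(r_u > 0, r_u, 1.0), 1.0)
    return c1 * (1.0 + r_x * f), c2 * (1.0 + r_y * f)


def induce(image: np.ndarray, params: DistortionParams) -> np.ndarray:
    """Apply the forward distortion (exact inverse of ``compensate``).

    ``compensate(induce(img, p), params=p)`` recovers ``img`` up to
    bilinear-interpolation error; used by the scan simulator and the
    distortion-model self-consistency checks. The flip scheme mirrors
    ``compensate`` (flips are involutions, so the same pre/post flips
    invert themselves).
    """
    R, C = image.shape
    f_x, f_y = np.meshgrid(
        np.arange(C, dtype=np.float64), np.arange(R, dtype=np.float64)
    )
    m_x, m_y = _eval_inverse_maps(params, f_x, f_y, C, R)
    src = image
    if params.flip_x:
        src = src[:, ::-1]
    if params.flip_y:
        src = src[::-1, :]
    out = _remap_bilinear(src, m_x, m_y)
    if params.flip_x:
        out = out[:, ::-1]
    if params.flip_y:
        out = out[::-1, :]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class SearchGrid:
    """Candidate grid for distortion-parameter estimation.

    ``a_range`` and ``off_range`` are ``(min, max, step)`` tuples; the
    offset range covers magnitudes, expanded to both signs through
    ``flip_variants`` (subset of {"none", "flip_x", "flip_y", "flip_xy"}).
    """

    a_range: tuple[float, float, float] = (5.0, 60.0, 1.0)
    off_range: tuple[float, float, float] = (0.0, 60.0, 1.0)
    flip_variants: tuple[str, ...] = ("none", "flip_x", "flip_y", "flip_xy")

    def __post_init__(self) -> None:
        for lo, hi, step in (self.a_range, self.off_range):
            if step <= 0:
                raise ValueError("grid steps must be positive")
            if lo > hi:
                raise ValueError("grid min must not exceed max")
        bad = set(self.flip_variants) - {"none", "flip_x", "flip_y", "flip_xy"}
        if bad:
            raise ValueError(f"unknown flip variants: {sorted(bad)}")
        if not self.flip_variants:
            raise ValueError("at least one flip variant is required")

    def a_values(self, step: float | None = None) -> np.ndarray:
        lo, hi, st = self.a_range
        st = step if step is not None else st
        return np.arange(lo, hi + st / 2, st)

    def off_values(self, axis: str, step: float | None = None) -> np.ndarray:
        """Signed offset candidates along 'x' or 'y' for the allowed flips."""
        lo, hi, st = self.off_range
        st = step if step is not None else st
        mags = np.arange(lo, hi + st / 2, st)
        pos = any(v in self.flip_variants for v in ("none", f"flip_{'y' if axis == 'x' else 'x'}"))
        neg = any(v in self.flip_variants for v in (f"flip_{axis}", "flip_xy"))
        vals: set[float] = set()
        if pos:
            vals.update(mags.tolist())
        if neg:
            vals.update((-mags).tolist())
        return np.array(sorted(vals))

    def candidates(self, a_step=None, off_step=None) -> Iterator[tuple[float, float, float]]:
        for a in self.a_values(a_step):
            for xo in self.off_values("x", off_step):
                for yo in self.off_values("y", off_step):
                    yield float(a), float(xo), float(yo)


def _preprocess_for_scoring(image: np.ndarray, opening_px: int = 5) -> np.ndarray:
    """Opening + Otsu binarisation; suppresses high-frequency noise."""
    opened = opening(image, footprint_rectangle((opening_px, opening_px)))
    if opened.min() == opened.max():
        return np.zeros_like(opened, dtype=np.float64)
    thr = threshold_otsu(opened)
    return np.where(opened > thr, 255.0, 0.0)


def _roi_coords(rect: tuple[int, int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    x0, y0, x1, y1 = rect
    return np.meshgrid(
        np.arange(x0, x1, dtype=np.float64), np.arange(y0, y1, dtype=np.float64)
    )


def _remap_roi(
    image: np.ndarray,
    params: DistortionParams,
    f_x: np.ndarray,
    f_y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Values of ``compensate(image, params)`` on the ROI grid only,
    plus the mask of pixels whose source coordinate lies inside the tile.

    The flip scheme is folded into the coordinates: a flip along x maps
    output column x to C-1-x before the model and mirrors the sampled
    source column afterwards, so no full-image remap is needed.
    """
    R, C = image.shape
    fx = (C - 1) - f_x if params.flip_x else f_x
    fy = (R - 1) - f_y if params.flip_y else f_y
    m_x, m_y, _, _ = _eval_maps(params, fx, fy, C, R)
    if params.flip_x:
        m_x = (C - 1) - m_x
    if params.flip_y:
        m_y = (R - 1) - m_y
    valid = (
        (m_x >= -1e-6) & (m_x <= C - 1 + 1e-6)
        & (m_y >= -1e-6) & (m_y <= R - 1 + 1e-6)
    )
    return _remap_bilinear(image, m_x, m_y), valid


def _dk(
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    coords_a: tuple[np.ndarray, np.ndarray],
    coords_b: tuple[np.ndarray, np.ndarray],
    params: DistortionParams,
) -> float:
    """Mean absolute difference of the compensated tiles over R12.

    The area is restricted to pixels whose remap samples inside both
    tiles: near the tile border the compensation map reaches outside
    the acquired frame, and the zero-filled samples there would swamp
    the score with a content-independent term.
    """
    ua, ok_a = _remap_roi(tile_a, params, *coords_a)
    ub, ok_b = _remap_roi(tile_b, params, *coords_b)
    ok = ok_a & ok_b
    if not ok.any():
        return math.inf
    return float(np.mean(np.abs(ua - ub)[ok]))


def estimate_params(
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    overlap: tuple[tuple[int, int, int, int], tuple[int, int, int, int]],
    grid: SearchGrid | None = None,
    *,
    mode: str = PINCUSHION,
    coarse_to_fine: bool = True,
    coarse_step: float = 5.0,
    coarse_downscale: int = 2,
    opening_px: int = 5,
    preprocess: bool = True,
) -> tuple[DistortionParams, float]:
    """Estimate distortion parameters from two identically distorted tiles.

    Parameters
    ----------
    tile_a, tile_b : ndarray
        Adjacent 8-bit tiles with a known shared region.
    overlap : pair of rects
        ``(rect_a, rect_b)`` as half-open ``(x0, y0, x1, y1)`` rectangles
        of identical size, delimiting the shared region R12 in each
        tile's own coordinates.
    grid : SearchGrid
        Candidate ranges; defaults bracket angles 5-60 degrees and
        offset magnitudes 0-60 with all four flip variants.
    coarse_to_fine : bool
        If true (default), scan the grid at ``coarse_step`` first —
        scoring on ``coarse_downscale``-fold block-mean downsampled
        copies, which the scale-free parameters allow — then refine at
        the grid's own step and full resolution within one coarse step
        of the coarse argmin. The exhaustive full-resolution scan is
        available with ``coarse_to_fine=False`` and is the reference
        behaviour.

    Returns
    -------
    (DistortionParams, float)
        The argmin candidate (signed offsets, compensation ``mode``) and
        its ``d_k`` score. Ties break toward the first candidate in scan
        order (increasing A, then x_off, then y_off).
    """
    if tile_a.shape != tile_b.shape:
        raise ValueError("tiles must share one shape")
    if grid is None:
        grid = SearchGrid()
    rect_a, rect_b = overlap
    if (rect_a[2] - rect_a[0]) != (rect_b[2] - rect_b[0]) or (
        rect_a[3] - rect_a[1]
    ) != (rect_b[3] - rect_b[1]):
        raise ValueError("overlap rectangles must have identical size")
    if rect_a[2] <= rect_a[0] or rect_a[3] <= rect_a[1]:
        raise ValueError("overlap region is empty")

    if preprocess:
        sa = _preprocess_for_scoring(tile_a, opening_px)
        sb = _preprocess_for_scoring(tile_b, opening_px)
    else:
        sa = tile_a.astype(np.float64)
        sb = tile_b.astype(np.float64)
    coords_a = _roi_coords(rect_a)
    coords_b = _roi_coords(rect_b)

    def scan(a_vals, xo_vals, yo_vals, ta, tb, ca, cb):
        best = None
        for a in a_vals:
            for xo in xo_vals:
                for yo in yo_vals:
                    p = DistortionParams(
                        a_deg=float(a), x_off=float(xo), y_off=float(yo), mode=mode
                    )
                    d = _dk(ta, tb, ca, cb, p)
                    if best is None or d < best[1]:
                        best = (p, d)
        if best is None:
            raise ValueError("empty search grid")
        return best

    fine_step_a = grid.a_range[2]
    if not coarse_to_fine:
        return scan(
            grid.a_values(), grid.off_values("x"), grid.off_values("y"),
            sa, sb, coords_a, coords_b,
        )

    k = max(1, int(coarse_downscale))
    from skimage.measure import block_reduce

    sa_k = block_reduce(sa, (k, k), np.mean)
    sb_k = block_reduce(sb, (k, k), np.mean)

    def shrink(rect):
        x0, y0, x1, y1 = rect
        # anchor at the scaled origin and share one scaled size so the
        # two ROIs keep identical shapes
        return (x0 // k, y0 // k,
                x0 // k + (x1 - x0) // k, y0 // k + (y1 - y0) // k)

    coords_a_k = _roi_coords(shrink(rect_a))
    coords_b_k = _roi_coords(shrink(rect_b))
    p0, _ = scan(
        grid.a_values(coarse_step),
        grid.off_values("x", coarse_step),
        grid.off_values("y", coarse_step),
        sa_k, sb_k, coords_a_k, coords_b_k,
    )

    def refine_axis(centre, lo, hi, step, window):
        vals = np.arange(centre - window, centre + window + step / 2, step)
        return vals[(vals >= lo) & (vals <= hi)]

    a_lo, a_hi, _ = grid.a_range
    xo_all = grid.off_values("x")
    yo_all = grid.off_values("y")

    def off_subset(all_vals, centre, window, step):
        sel = all_vals[np.abs(all_vals - centre) <= window + 1e-9]
        # thin to the requested step, keeping the centre on-grid
        return sel[np.isclose((sel - centre) % step, 0) | np.isclose((sel - centre) % step, step)]

    # mid-level refinement at doubled offset step keeps the full-resolution
    # candidate count manageable; the basin is wide and smooth, so the final
    # unit-step pass around the mid argmin still reaches the grid optimum
    mid_step = max(2 * grid.off_range[2], fine_step_a)
    p1, _ = scan(
        refine_axis(p0.a_deg, a_lo, a_hi, fine_step_a, coarse_step),
        off_subset(xo_all, p0.x_off, coarse_step, mid_step),
        off_subset(yo_all, p0.y_off, coarse_step, mid_step),
        sa, sb, coords_a, coords_b,
    )
    return scan(
        refine_axis(p1.a_deg, a_lo, a_hi, fine_step_a, fine_step_a),
        off_subset(xo_all, p1.x_off, mid_step, grid.off_range[2]),
        off_subset(yo_all, p1.y_off, mid_step, grid.off_range[2]),
        sa, sb, coords_a, coords_b,
    )


# ---------------------------------------------------------------------------
# Resonant-scanner cosinusoidal resampling
# ---------------------------------------------------------------------------

def _resonant_phase_bounds(beta: float) -> tuple[float, float]:
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must lie in (0, 1]")
    half = (1.0 - beta) / 2.0
    return half * math.pi, (1.0 - half) * math.pi


def _x_of_theta(theta: np.ndarray) -> np.ndarray:
    return (1.0 - np.cos(theta)) / 2.0


def _interp_rows(image: np.ndarray, src_cols: np.ndarray) -> np.ndarray:
    """Per-row 1-D linear interpolation at fractional column positions."""
    w = image.shape[1]
    cols = np.arange(w, dtype=np.float64)
    out = np.empty_like(image, dtype=np.float64)
    img = image.astype(np.float64)
    for r in range(image.shape[0]):
        out[r] = np.interp(src_cols, cols, img[r])
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def correct_resonant(image: np.ndarray, beta: float = 0.9) -> np.ndarray:
    """Resample a raw resonant-scan image to uniform pixel spacing.

    The resonant mirror sweeps the fast axis with position
    ``x(theta) = (1 - cos(theta)) / 2`` while samples arrive uniformly in
    phase ``theta`` over the central ``beta`` fraction of ``[0, pi]``
    (the turnaround extremes are discarded in hardware). This maps the
    raw columns back to uniform spatial positions; output width equals
    input width.
    """
    t0, t1 = _resonant_phase_bounds(beta)
    w = image.shape[1]
    x0, x1 = _x_of_theta(np.array([t0, t1]))
    # output column i sits at uniform position x_i; invert x(theta) to
    # find the raw column (uniform in theta) holding that position
    xi = x0 + np.arange(w) / (w - 1) * (x1 - x0)
    theta = np.arccos(np.clip(1.0 - 2.0 * xi, -1.0, 1.0))
    src = (theta - t0) / (t1 - t0) * (w - 1)
    return _interp_rows(image, src)


def apply_resonant(image: np.ndarray, beta: float = 0.9) -> np.ndarray:
    """Forward model of cosinusoidal sampling (inverse of ``correct_resonant``).

    Takes a uniformly sampled row and produces the raw columns a
    resonant scanner would record; used by the scan simulator.
    """
    t0, t1 = _resonant_phase_bounds(beta)
    w = image.shape[1]
    x0, x1 = _x_of_theta(np.array([t0, t1]))
    theta_j = t0 + np.arange(w) / (w - 1) * (t1 - t0)
    xj = _x_of_theta(theta_j)
    src = (xj - x0) / (x1 - x0) * (w - 1)
    return _interp_rows(image, src)


# ---------------------------------------------------------------------------
# TOML persistence of estimated parameters
# ---------------------------------------------------------------------------

def save_params_toml(path, params: DistortionParams) -> None:
    """Persist parameters as a ``[distortion]`` TOML block."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "[distortion]\n"
            f"a_deg = {params.a_deg}\n"
            f"x_off = {params.x_off}\n"
            f"y_off = {params.y_off}\n"
            f"s_x = {params.s_x}\n"
            f"s_y = {params.s_y}\n"
            f'mode = "{params.mode}"\n'
        )


def load_params_toml(path) -> DistortionParams:
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    d = doc["distortion"]
    return DistortionParams(
        a_deg=float(d["a_deg"]),
        x_off=float(d["x_off"]),
        y_off=float(d["y_off"]),
        s_x=float(d.get("s_x", 60.0)),
        s_y=float(d.get("s_y", 60.0)),
        mode=str(d.get("mode", PINCUSHION)),
    )


def compensation_valid_mask(params: DistortionParams, C: int, R: int) -> np.ndarray:
    """Boolean mask of pixels whose ``compensate`` remap samples inside
    the acquired frame (the rest are zero-filled border bands)."""
    f_x, f_y = np.meshgrid(
        np.arange(C, dtype=np.float64), np.arange(R, dtype=np.float64)
    )
    fx = (C - 1) - f_x if params.flip_x else f_x
    fy = (R - 1) - f_y if params.flip_y else f_y
    m_x, m_y, _, _ = _eval_maps(params, fx, fy, C, R)
    return (
        (m_x >= -1e-6) & (m_x <= C - 1 + 1e-6)
        & (m_y >= -1e-6) & (m_y <= R - 1 + 1e-6)
    )
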