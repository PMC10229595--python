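"""Shared domain types, coordinate conventions, and mosaic capacity arithmetic.

Coordinate convention used throughout the package: 0-based indices,
``x`` is the column (fast scan axis), ``y`` is the row (slow axis).
Rectangles are half-open ``[x0, x1) x [y0, y1)``. Images are numpy
arrays indexed ``[row, col]`` (i.e. ``[y, x]``), dtype ``uint8``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Tile",
    "MosaicPlan",
    "ConfusionMatrix",
    "plan_mosaic",
    "area_pixel_count",
    "data_volume",
    "read_stage_log",
    "write_stage_log",
]

#: Column names of the tab-separated stage log, one row per tile.
STAGE_LOG_COLUMNS = ("tile_id", "grid_col", "grid_row", "stage_x_um", "stage_y_um")


@dataclass
class Tile:
    """One acquired image frame.

    Parameters
    ----------
    tile_id : str
        Unique identifier, e.g. ``"t_03_01"``.
    grid_col, grid_row : int
        0-based tile indices on the acquisition grid.
    stage_x_um, stage_y_um : float
        Motorized-stage position of the tile origin, in micrometres.
    channels : list of ndarray
        One 8-bit grayscale image per detection channel (e.g. THG,
        TPEF); all share the same ``(rows, cols)`` shape.
    pixel_pitch_nm : float
        Physical size of one pixel, in nanometres.
    """

    tile_id: str
    grid_col: int
    grid_row: int
    stage_x_um: float
    stage_y_um: float
    channels: list[np.ndarray] = field(default_factory=list)
    pixel_pitch_nm: float = 167.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.channels) <= 3:
            raise ValueError("a tile carries between 1 and 3 channels")
        shape = self.channels[0].shape
        for c in self.channels:
            if c.shape != shape or c.ndim != 2:
                raise ValueError("all channel images must be 2-D and share one shape")
            if c.dtype != np.uint8:
                raise ValueError("channel images must be 8-bit (uint8)")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of each channel image."""
        return self.channels[0].shape

    def scoring_image(self) -> np.ndarray:
        """Unweighted mean of channels as float64, used for alignment scoring."""
        return np.mean(np.stack([c.astype(np.float64) for c in self.channels]), axis=0)


@dataclass(frozen=True)
class MosaicPlan:
    """Geometry of a regular tile grid with fractional overlap."""

    tiles_x: int
    tiles_y: int
    tile_px: int
    overlap_frac: float
    stride_px: int
    mosaic_w_px: int
    mosaic_h_px: int
    pixel_pitch_nm: float

    @property
    def total_pixels(self) -> int:
        return self.mosaic_w_px * self.mosaic_h_px

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical (width, height) of the mosaic in millimetres."""
        return (
            self.mosaic_w_px * self.pixel_pitch_nm * 1e-6,
            self.mosaic_h_px * self.pixel_pitch_nm * 1e-6,
        )

    def tile_origin(self, col: int, row: int) -> tuple[int, int]:
        """Nominal top-left (x, y) of tile (col, row) in mosaic pixels."""
        return col * self.stride_px, row * self.stride_px


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary-decision counts of a diagnostic comparison."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        counts = (self.TP, self.FP, self.TN, self.FN)
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be non-negative")
        if sum(counts) < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def plan_mosaic(
    tiles_x: int,
    tiles_y: int,
    tile_px: int,
    overlap_frac: float,
    pixel_pitch_nm: float,
) -> MosaicPlan:
    """Lay out a regular tile grid with a fractional FOV overlap.

    The stride between adjacent tile origins is ``round((1 - overlap) *
    tile_px)`` (round half up), so the mosaic spans ``tile_px +
    (n - 1) * stride`` pixels per axis.
    """
    if tiles_x < 1 or tiles_y < 1:
        raise ValueError("tile counts must be >= 1")
    if tile_px < 2:
        raise ValueError("tile_px must be >= 2")
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError("overlap_frac must lie in [0, 1)")
    if pixel_pitch_nm <= 0:
        raise ValueError("pixel_pitch_nm must be positive")
    stride = _round_half_up((1.0 - overlap_frac) * tile_px)
    return MosaicPlan(
        tiles_x=tiles_x,
        tiles_y=tiles_y,
        tile_px=tile_px,
        overlap_frac=overlap_frac,
        stride_px=stride,
        mosaic_w_px=tile_px + (tiles_x - 1) * stride,
        mosaic_h_px=tile_px + (tiles_y - 1) * stride,
        pixel_pitch_nm=pixel_pitch_nm,
    )


def area_pixel_count(width_mm: float, height_mm: float, pixel_pitch_nm: float) -> int:
    """Number of pixels needed to cover an area at a given pixel pitch.

    Each axis contributes ``floor(extent_nm / pitch_nm)`` pixels.
    """
    if width_mm <= 0 or height_mm <= 0 or pixel_pitch_nm <= 0:
        raise ValueError("all arguments must be positive")
    nx = math.floor(width_mm * 1e6 / pixel_pitch_nm)
    ny = math.floor(height_mm * 1e6 / pixel_pitch_nm)
    return nx * ny


def data_volume(pixel_count: int, bit_depth: int) -> int:
    """Uncompressed data volume in bits (8-bit grayscale or 24-bit color)."""
    if pixel_count < 0:
        raise ValueError("pixel_count must be non-negative")
    if bit_depth not in (8, 24):
        raise ValueError("bit_depth must be 8 or 24")
    return int(pixel_count) * bit_depth


def write_stage_log(path, rows) -> None:
    """Write a stage log TSV: tile_id, grid indices, stage position in um."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(STAGE_LOG_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r[0]}\t{int(r[1])}\t{int(r[2])}\t{float(r[3]):.3f}\t{float(r[4]):.3f}\n"
            )


def read_stage_log(path) -> dict[str, dict]:
    """Read a stage log TSV into ``{tile_id: row dict}``."""
    out: dict[str, dict] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != STAGE_LOG_COLUMNS:
            raise ValueError(f"unexpected stage-log header: {header!r}")
        for line in fh:
            if not line.strip():
                continue
            tile_id, col, row, sx, sy = line.rstrip("\n").split("\t")
            if tile_id in out:
                raise ValueError(f"duplicate tile_id in stage log: {tile_id}")
            out[tile_id] = {
                "tile_id": tile_id,
                "grid_col": int(col),
                "grid_row": int(row),
                "stage_x_um": float(sx),
                "stage_y_um": float(sy),
            }
    return out
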