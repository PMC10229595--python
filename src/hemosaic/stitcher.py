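"""Stage-informed tile placement with sigma-scored coarse-to-fine alignment.

Each incoming tile gets an initial mosaic offset from the motorized-stage
displacement, then a local search refines it against the already-placed
neighbours. A candidate offset is scored by extracting the overlap region
with each major neighbour (left and/or top), 2x block-mean downsampling
both sides, taking the per-pixel absolute difference and summing the
standard deviations:

    sigma_k = sigma(|d_A|) + sigma(|d_B|)

A coarse scan (10 px steps over +-RangeX/+-RangeY around the stage
estimate) runs first; if the spread max(sigma) - min(sigma) reaches the
gate threshold (1.5 intensity levels by default) a fine scan at 2 px
steps runs within one coarse step of the coarse argmin, otherwise the
stage estimate is kept (flagged as a fallback — a featureless overlap
cannot be aligned by content).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import block_reduce

from .core import MosaicPlan, Tile, plan_mosaic
from .distortion import (
    DistortionParams,
    compensate,
    compensation_valid_mask,
    compute_pixel_maps,
    correct_resonant,
)

__all__ = [
    "AlignmentSearch",
    "AlignmentResult",
    "MosaicCanvas",
    "initial_offset",
    "score_placement",
    "align_tile",
    "composite",
    "stitch_all",
    "write_placements",
    "read_placements",
]

PLACEMENT_COLUMNS = (
    "tile_id",
    "placed_x_px",
    "placed_y_px",
    "x_ov",
    "y_al",
    "sigma_min",
    "sigma_max",
    "refined",
    "fallback",
)


@dataclass(frozen=True)
class AlignmentSearch:
    """Search-window and gating parameters of the alignment scan."""

    range_x_px: int = 30
    range_y_px: int = 30
    coarse_step_px: int = 10
    fine_step_px: int = 2
    sigma_spread_threshold: float = 1.5
    downscale_factor: int = 2
    #: candidates whose overlap with any placed neighbour shrinks below
    #: this extent are rejected: the standard deviation of a sliver a few
    #: pixels wide is spuriously small and would hijack the argmin
    min_overlap_px: int = 16

    def __post_init__(self) -> None:
        if min(self.range_x_px, self.range_y_px, self.coarse_step_px,
               self.fine_step_px, self.downscale_factor) <= 0:
            raise ValueError("search parameters must be positive")
        if self.fine_step_px > self.coarse_step_px:
            raise ValueError("fine step must not exceed coarse step")


@dataclass
class AlignmentResult:
    tile_id: str
    placed_x_px: int
    placed_y_px: int
    x_ov: int = 0
    y_al: int = 0
    sigma_min: float = 0.0
    sigma_max: float = 0.0
    refined: bool = False
    fallback: bool = False


class MosaicCanvas:
    """Growing composite image plus the placement record.

    The canvas is allocated from a :class:`MosaicPlan` with a margin on
    every side so that alignment shifts up to the search range (plus
    stage jitter) stay in bounds. Placement coordinates are in mosaic
    space (first tile's origin at (0, 0)); ``margin`` translates them to
    array indices.
    """

    def __init__(self, plan: MosaicPlan, n_channels: int, margin: int = 64):
        self.plan = plan
        self.margin = margin
        h = plan.mosaic_h_px + 2 * margin
        w = plan.mosaic_w_px + 2 * margin
        self.composite = np.zeros((h, w, n_channels), dtype=np.uint8)
        self.occupied = np.zeros((h, w), dtype=bool)
        # occupied AND genuinely sampled (excludes zero-filled bands left
        # by distortion compensation near tile borders)
        self.valid = np.zeros((h, w), dtype=bool)
        self.weight = np.zeros((h, w), dtype=np.float32)
        self.placements: list[AlignmentResult] = []
        self._by_grid: dict[tuple[int, int], AlignmentResult] = {}

    @property
    def n_channels(self) -> int:
        return self.composite.shape[2]

    def ensure(self, x0: int, y0: int, x1: int, y1: int) -> None:
        """Grow the canvas so the mosaic-space rect fits (pads all arrays)."""
        m = self.margin
        h, w = self.occupied.shape
        before_x = max(0, -(x0 + m))
        before_y = max(0, -(y0 + m))
        after_x = max(0, x1 + m - w)
        after_y = max(0, y1 + m - h)
        if not (before_x or before_y or after_x or after_y):
            return
        # margin is one scalar for both axes, so grow the leading side of
        # both axes by the same amount
        before = max(before_x, before_y)
        pad2 = ((before, after_y), (before, after_x))
        self.composite = np.pad(self.composite, pad2 + ((0, 0),))
        self.occupied = np.pad(self.occupied, pad2)
        self.valid = np.pad(self.valid, pad2)
        self.weight = np.pad(self.weight, pad2)
        self.margin += before

    def record(self, tile: Tile, result: AlignmentResult) -> None:
        if any(p.tile_id == result.tile_id for p in self.placements):
            raise ValueError(f"duplicate tile_id: {result.tile_id}")
        self.placements.append(result)
        self._by_grid[(tile.grid_col, tile.grid_row)] = result

    def neighbor_results(self, tile: Tile) -> list[AlignmentResult]:
        """Placed left and top neighbours of a tile, in that order."""
        out = []
        for key in ((tile.grid_col - 1, tile.grid_row), (tile.grid_col, tile.grid_row - 1)):
            if key in self._by_grid:
                out.append(self._by_grid[key])
        return out

    def scoring_view(self, x0: int, y0: int, x1: int, y1: int) -> tuple[np.ndarray, np.ndarray]:
        """Mean-of-channels float view of a mosaic-space rectangle plus
        its validity mask."""
        m = self.margin
        roi = self.composite[y0 + m : y1 + m, x0 + m : x1 + m, :]
        return roi.mean(axis=2), self.valid[y0 + m : y1 + m, x0 + m : x1 + m]

    def region(self, rect: tuple[int, int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Composite and occupancy mask over a mosaic-space half-open
        rectangle ``(x0, y0, x1, y1)`` (first tile's origin at (0, 0))."""
        x0, y0, x1, y1 = rect
        m = self.margin
        return (
            self.composite[y0 + m : y1 + m, x0 + m : x1 + m],
            self.occupied[y0 + m : y1 + m, x0 + m : x1 + m],
        )

    def trimmed(self) -> np.ndarray:
        """Composite cropped to the bounding box of all placed tiles."""
        if not self.placements:
            return self.composite[:0, :0]
        ys, xs = np.nonzero(self.occupied)
        return self.composite[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]


def initial_offset(tile: Tile, prev_tile: Tile) -> tuple[int, int, int]:
    """Stage-estimated displacement (dx, dy) of ``tile`` from ``prev_tile``
    in pixels, plus the implied overlap width X_OV.
    """
    for t in (tile, prev_tile):
        if t.stage_x_um is None or t.stage_y_um is None:
            raise ValueError(f"tile {t.tile_id} is missing stage coordinates")
    pitch = tile.pixel_pitch_nm
    dx = int(round((tile.stage_x_um - prev_tile.stage_x_um) * 1000.0 / pitch))
    dy = int(round((tile.stage_y_um - prev_tile.stage_y_um) * 1000.0 / pitch))
    width = tile.shape[1]
    x_ov = max(0, width - abs(dx))
    return dx, dy, x_ov


def _downsample(a: np.ndarray, k: int) -> np.ndarray:
    """k x k block-mean downsample, trimming to whole blocks."""
    h, w = a.shape
    a = a[: h - h % k, : w - w % k]
    if a.size == 0:
        return a
    return block_reduce(a, (k, k), np.mean)


def _downsample_mask(a: np.ndarray, k: int) -> np.ndarray:
    """Strict k x k downsample of a bool mask (block must be all-valid)."""
    h, w = a.shape
    a = a[: h - h % k, : w - w % k]
    if a.size == 0:
        return a.astype(bool)
    return block_reduce(a, (k, k), np.min).astype(bool)


def score_placement(
    candidate: tuple[int, int],
    tile_img: np.ndarray,
    canvas: MosaicCanvas,
    neighbor_rects: list[tuple[int, int, int, int]],
    downscale: int = 2,
    min_overlap_px: int = 16,
    tile_valid: np.ndarray | None = None,
) -> float:
    """Sum of overlap-difference standard deviations at one candidate offset.

    ``tile_img`` is the tile's scoring image (mean of channels, float);
    ``neighbor_rects`` are the placed neighbours' mosaic-space rectangles.
    Every neighbour must overlap the candidate placement by at least
    ``min_overlap_px`` on both axes; otherwise the candidate is invalid
    and scores ``inf`` (so one-term sums never compete with two-term
    sums, and sliver overlaps never win on variance starvation).
    ``tile_valid`` marks the tile pixels that carry real signal; it and
    the canvas validity mask restrict the comparison so that the
    zero-filled bands distortion compensation leaves near tile borders
    cannot bias the score.
    """
    cx, cy = candidate
    th, tw = tile_img.shape
    sigma_k = 0.0
    for (nx0, ny0, nx1, ny1) in neighbor_rects:
        x0, y0 = max(cx, nx0), max(cy, ny0)
        x1, y1 = min(cx + tw, nx1), min(cy + th, ny1)
        if x1 - x0 < min_overlap_px or y1 - y0 < min_overlap_px:
            return math.inf
        tile_roi = tile_img[y0 - cy : y1 - cy, x0 - cx : x1 - cx]
        canvas_roi, canvas_ok = canvas.scoring_view(x0, y0, x1, y1)
        d = np.abs(_downsample(tile_roi, downscale) - _downsample(canvas_roi, downscale))
        ok = _downsample_mask(canvas_ok, downscale)
        if tile_valid is not None:
            ok &= _downsample_mask(
                tile_valid[y0 - cy : y1 - cy, x0 - cx : x1 - cx], downscale
            )
        vals = d[ok]
        if vals.size * downscale**2 < min_overlap_px**2:
            return math.inf
        sigma_k += float(vals.std())  # population (N) normalisation
    return sigma_k if neighbor_rects else math.inf


def _scan(
    offsets_x: np.ndarray,
    offsets_y: np.ndarray,
    tile_img: np.ndarray,
    canvas: MosaicCanvas,
    rects: list,
    init: tuple[int, int],
    search: AlignmentSearch,
    tile_valid: np.ndarray | None = None,
):
    """Evaluate sigma_k over a candidate set; return scores and the argmin.

    Ties break toward the smallest displacement from the stage estimate,
    then row-major (smaller dy, then dx).
    """
    best = None
    sigmas = []
    for cy in offsets_y:
        for cx in offsets_x:
            s = score_placement(
                (int(cx), int(cy)), tile_img, canvas, rects,
                search.downscale_factor, search.min_overlap_px, tile_valid,
            )
            if math.isinf(s):
                continue
            sigmas.append(s)
            d2 = (cx - init[0]) ** 2 + (cy - init[1]) ** 2
            key = (s, d2, cy, cx)
            if best is None or key < best[0]:
                best = (key, (int(cx), int(cy)))
    return sigmas, best


def align_tile(
    tile: Tile,
    canvas: MosaicCanvas,
    search: AlignmentSearch,
    init: tuple[int, int],
    tile_img: np.ndarray | None = None,
    tile_valid: np.ndarray | None = None,
) -> AlignmentResult:
    """Coarse-to-fine placement of one tile against the canvas.

    ``init`` is the stage-estimated mosaic offset of the tile's top-left
    corner. The first tile of a mosaic is placed at ``init`` verbatim.
    """
    if tile_img is None:
        tile_img = tile.scoring_image()
    if not canvas.placements:
        res = AlignmentResult(tile.tile_id, init[0], init[1])
        res.x_ov = 0
        return res

    neighbors = canvas.neighbor_results(tile)
    th, tw = tile_img.shape
    rects = [
        (n.placed_x_px, n.placed_y_px, n.placed_x_px + tw, n.placed_y_px + th)
        for n in neighbors
    ]
    cs = search.coarse_step_px
    ox = init[0] + np.arange(-search.range_x_px, search.range_x_px + 1, cs)
    oy = init[1] + np.arange(-search.range_y_px, search.range_y_px + 1, cs)
    sigmas, best = _scan(ox, oy, tile_img, canvas, rects, init, search, tile_valid)
    if best is None:
        raise ValueError(
            f"tile {tile.tile_id}: no canvas overlap anywhere in the search window"
        )
    s_min, s_max = float(min(sigmas)), float(max(sigmas))
    refined = (s_max - s_min) >= search.sigma_spread_threshold
    if refined:
        bx, by = best[1]
        fs = search.fine_step_px
        # the fine window must cover the whole coarse cell on either side:
        # when the score valley straddles the midpoint between two coarse
        # nodes, the argmin choice between them is a near-tie and the
        # valley bottom can sit just past one coarse step away
        half = cs + fs
        fx = bx + np.arange(-half, half + 1, fs)
        fy = by + np.arange(-half, half + 1, fs)
        _, fine_best = _scan(fx, fy, tile_img, canvas, rects, init, search, tile_valid)
        px, py = fine_best[1]
    else:
        px, py = init  # featureless overlap: keep the stage estimate

    res = AlignmentResult(
        tile.tile_id, px, py,
        sigma_min=s_min, sigma_max=s_max,
        refined=refined, fallback=not refined,
    )
    # overlap extent / off-axis shift against the primary neighbour
    # (left neighbour if placed, else the top one; for a vertical pair
    # the roles of the axes swap: x_ov holds Y_OV and y_al holds X_AL)
    left_key = (tile.grid_col - 1, tile.grid_row)
    if left_key in canvas._by_grid:
        n = canvas._by_grid[left_key]
        res.x_ov = max(0, (n.placed_x_px + tw) - px)
        res.y_al = py - n.placed_y_px
    else:
        n = neighbors[0]
        res.x_ov = max(0, (n.placed_y_px + th) - py)
        res.y_al = px - n.placed_x_px
    return res


def composite(
    canvas: MosaicCanvas,
    tile: Tile,
    result: AlignmentResult,
    blend: str = "overwrite",
    tile_valid: np.ndarray | None = None,
) -> MosaicCanvas:
    """Paint a placed tile onto the canvas.

    ``overwrite`` lets the newest tile win inside overlaps; ``feather``
    accumulates an edge-distance-weighted average so seams fade linearly
    across the overlap width. ``tile_valid`` (e.g. the distortion
    compensation's sampling mask) restricts painting to pixels that
    carry real signal, so a zero-filled border band never overwrites a
    neighbour's content.
    """
    if len(tile.channels) != canvas.n_channels:
        raise ValueError(
            f"tile {tile.tile_id} has {len(tile.channels)} channels, "
            f"canvas has {canvas.n_channels}"
        )
    if blend not in ("overwrite", "feather"):
        raise ValueError("blend must be 'overwrite' or 'feather'")
    th, tw = tile.shape
    canvas.ensure(result.placed_x_px, result.placed_y_px,
                  result.placed_x_px + tw, result.placed_y_px + th)
    m = canvas.margin
    y0, x0 = result.placed_y_px + m, result.placed_x_px + m
    data = np.stack(tile.channels, axis=2)
    region = (slice(y0, y0 + th), slice(x0, x0 + tw))
    if tile_valid is None:
        tile_valid = np.ones((th, tw), dtype=bool)
    if blend == "overwrite":
        view = canvas.composite[region]
        view[tile_valid] = data[tile_valid]
    else:
        ov = max(1, tile.shape[1] - canvas.plan.stride_px)
        yy = np.minimum(np.arange(th), th - 1 - np.arange(th))
        xx = np.minimum(np.arange(tw), tw - 1 - np.arange(tw))
        edge = np.minimum.outer(yy, xx).astype(np.float32)
        w_new = np.clip((edge + 1.0) / ov, 0.0, 1.0) * tile_valid
        w_old = canvas.weight[region]
        total = w_old + w_new
        safe = np.where(total > 0, total, 1.0)
        blended = (
            canvas.composite[region].astype(np.float32) * w_old[..., None]
            + data.astype(np.float32) * w_new[..., None]
        ) / safe[..., None]
        keep = total > 0
        view = canvas.composite[region]
        view[keep] = np.clip(np.rint(blended), 0, 255).astype(np.uint8)[keep]
        canvas.weight[region] = np.maximum(w_old, w_new)
    canvas.occupied[region] = True
    canvas.valid[region] |= tile_valid
    canvas.record(tile, result)
    return canvas


def stitch_all(
    tiles: list[Tile],
    stage_log: dict | None = None,
    search: AlignmentSearch | None = None,
    distortion: DistortionParams | None = None,
    resonant_beta: float | None = None,
    blend: str = "overwrite",
    plan: MosaicPlan | None = None,
    overlap_frac: float = 0.09,
) -> tuple[MosaicCanvas, list[AlignmentResult]]:
    """Run the full placement pipeline over a row-major tile sequence.

    Per tile: optional resonant-scan correction, optional distortion
    compensation, sigma-scored alignment, then compositing. Stage
    positions come from the tiles themselves or from a parsed stage log
    (``{tile_id: row}``), which overrides them. Deterministic for fixed
    inputs.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    search = search or AlignmentSearch()
    ids = [t.tile_id for t in tiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate tile_id in input tiles")
    if stage_log is not None:
        for t in tiles:
            if t.tile_id not in stage_log:
                raise ValueError(f"tile {t.tile_id} missing from stage log")
            row = stage_log[t.tile_id]
            t.grid_col = row["grid_col"]
            t.grid_row = row["grid_row"]
            t.stage_x_um = row["stage_x_um"]
            t.stage_y_um = row["stage_y_um"]

    tiles = sorted(tiles, key=lambda t: (t.grid_row, t.grid_col))
    tile_px = tiles[0].shape[1]
    if plan is None:
        plan = plan_mosaic(
            max(t.grid_col for t in tiles) + 1,
            max(t.grid_row for t in tiles) + 1,
            tile_px,
            overlap_frac,
            tiles[0].pixel_pitch_nm,
        )
    margin = max(search.range_x_px, search.range_y_px) + search.coarse_step_px + 8
    canvas = MosaicCanvas(plan, len(tiles[0].channels), margin=margin)
    by_grid: dict[tuple[int, int], Tile] = {}

    maps = None
    valid_mask = None
    if distortion is not None:
        r, c = tiles[0].shape
        maps = compute_pixel_maps(distortion, c, r)
        valid_mask = compensation_valid_mask(distortion, c, r)

    for tile in tiles:
        chans = tile.channels
        if resonant_beta is not None:
            chans = [correct_resonant(c, resonant_beta) for c in chans]
        if distortion is not None:
            chans = [compensate(c, maps, distortion) for c in chans]
        proc = Tile(
            tile.tile_id, tile.grid_col, tile.grid_row,
            tile.stage_x_um, tile.stage_y_um, chans, tile.pixel_pitch_nm,
        )
        if not canvas.placements:
            init = (0, 0)
        else:
            # stage-displacement estimate relative to the primary neighbour
            for key in ((proc.grid_col - 1, proc.grid_row), (proc.grid_col, proc.grid_row - 1)):
                if key in by_grid:
                    prev = by_grid[key]
                    break
            else:
                raise ValueError(f"tile {proc.tile_id} has no placed neighbour")
            prev_res = canvas._by_grid[(prev.grid_col, prev.grid_row)]
            dx, dy, _ = initial_offset(proc, prev)
            init = (prev_res.placed_x_px + dx, prev_res.placed_y_px + dy)
        result = align_tile(proc, canvas, search, init, tile_valid=valid_mask)
        composite(canvas, proc, result, blend=blend, tile_valid=valid_mask)
        by_grid[(proc.grid_col, proc.grid_row)] = proc
    return canvas, canvas.placements


def write_placements(path, placements: list[AlignmentResult]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PLACEMENT_COLUMNS) + "\n")
        for p in placements:
            fh.write(
                f"{p.tile_id}\t{p.placed_x_px}\t{p.placed_y_px}\t{p.x_ov}\t{p.y_al}\t"
                f"{p.sigma_min:.4f}\t{p.sigma_max:.4f}\t{int(p.refined)}\t{int(p.fallback)}\n"
            )


def read_placements(path) -> dict[str, dict]:
    out: dict[str, dict] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            vals["placed_x_px"] = int(vals["placed_x_px"])
            vals["placed_y_px"] = int(vals["placed_y_px"])
            out[vals["tile_id"]] = vals
    return out
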