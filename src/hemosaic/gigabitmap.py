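"""Custom uncompressed bitmap container for gigapixel mosaics (``.rfpb``).

Layout (little-endian):

* a fixed 4096-byte header block — magic ``RFPB``, version, image
  dimensions, channel count and bit depth, tile-grid shape, pixel pitch,
  preview dimensions and the byte offsets of the two data sections,
  zero-padded to 4096 bytes;
* a 10x block-mean downscaled preview (``ceil(dim / 10)`` per axis,
  partial edge blocks averaged over their actual extent) for instant
  low-resolution display;
* the full payload, row-major, pixel-interleaved in B, G, R order.

No compression is applied — sequential reads hit the disk's raw
bandwidth and a region of interest can be fetched with row-wise seeks
without touching the rest of the payload.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BitmapHeader",
    "write_bitmap",
    "read_header",
    "read_preview",
    "read_roi",
    "export_standard",
    "predicted_size",
]

MAGIC = b"RFPB"
VERSION = 1
HEADER_SIZE = 4096
PREVIEW_FACTOR = 10
#: magic, version, width, height, channels, bit depth, tiles_x, tiles_y,
#: pixel pitch (nm, f64), preview_w, preview_h, payload_offset, preview_offset
_FIELDS = struct.Struct("<4sIIIIIIIdIIQQ")

PNG_PIXEL_CAP = 100_000_000  # PNG export refused above 100 MP


@dataclass(frozen=True)
class BitmapHeader:
    width_px: int
    height_px: int
    channels: int = 3
    bit_depth_per_channel: int = 8
    tiles_x: int = 1
    tiles_y: int = 1
    pixel_pitch_nm: float = 167.0
    version: int = VERSION

    @property
    def preview_w(self) -> int:
        return math.ceil(self.width_px / PREVIEW_FACTOR)

    @property
    def preview_h(self) -> int:
        return math.ceil(self.height_px / PREVIEW_FACTOR)

    @property
    def preview_offset(self) -> int:
        return HEADER_SIZE

    @property
    def payload_offset(self) -> int:
        return HEADER_SIZE + self.channels * self.preview_w * self.preview_h

    @property
    def total_bytes(self) -> int:
        return self.payload_offset + self.channels * self.width_px * self.height_px


def predicted_size(width_px: int, height_px: int, channels: int = 3) -> int:
    """Exact on-disk byte count of a bitmap with these dimensions."""
    return BitmapHeader(width_px, height_px, channels=channels).total_bytes


def _block_mean_partial(image: np.ndarray, k: int) -> np.ndarray:
    """k x k block mean; edge blocks average over their partial extent."""
    h, w = image.shape[:2]
    ys = np.arange(0, h, k)
    xs = np.arange(0, w, k)
    acc = np.add.reduceat(np.add.reduceat(image.astype(np.float64), ys, axis=0), xs, axis=1)
    ny = np.diff(np.append(ys, h))
    nx = np.diff(np.append(xs, w))
    counts = np.multiply.outer(ny, nx).astype(np.float64)
    if image.ndim == 3:
        counts = counts[..., None]
    return np.clip(np.rint(acc / counts), 0, 255).astype(np.uint8)


def _as_bgr(image: np.ndarray) -> np.ndarray:
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be 2-D grayscale or (H, W, 3)")
    if image.dtype != np.uint8:
        raise ValueError("image must be 8-bit per channel")
    return image


def write_bitmap(image: np.ndarray, path, meta: BitmapHeader | None = None) -> int:
    """Write an image (assumed already in B, G, R channel order) to
    ``path``; returns the total byte count written.
    """
    image = _as_bgr(image)
    h, w, _ = image.shape
    if meta is None:
        meta = BitmapHeader(width_px=w, height_px=h)
    if (meta.width_px, meta.height_px) != (w, h):
        raise ValueError("header dimensions do not match the image")
    if w >= 2**32 or h >= 2**32:
        raise ValueError("dimension overflows the 32-bit header field")
    header = _FIELDS.pack(
        MAGIC, meta.version, w, h, 3, 8, meta.tiles_x, meta.tiles_y,
        meta.pixel_pitch_nm, meta.preview_w, meta.preview_h,
        meta.payload_offset, meta.preview_offset,
    )
    preview = _block_mean_partial(image, PREVIEW_FACTOR)
    with open(path, "wb") as fh:
        fh.write(header.ljust(HEADER_SIZE, b"\0"))
        fh.write(np.ascontiguousarray(preview).tobytes())
        fh.write(np.ascontiguousarray(image).tobytes())
        total = fh.tell()
    assert total == meta.total_bytes
    return total


def read_header(path) -> BitmapHeader:
    with open(path, "rb") as fh:
        raw = fh.read(_FIELDS.size)
    if len(raw) < _FIELDS.size:
        raise ValueError("file too short for a bitmap header")
    (magic, version, w, h, channels, depth, tx, ty, pitch, pw, ph,
     payload_off, preview_off) = _FIELDS.unpack(raw)
    if magic != MAGIC:
        raise ValueError(f"bad magic {magic!r}; not a bitmap file")
    if version != VERSION:
        raise ValueError(f"unsupported bitmap version {version}")
    hdr = BitmapHeader(
        width_px=w, height_px=h, channels=channels,
        bit_depth_per_channel=depth, tiles_x=tx, tiles_y=ty,
        pixel_pitch_nm=pitch, version=version,
    )
    if (hdr.preview_w, hdr.preview_h) != (pw, ph) or (
        hdr.payload_offset, hdr.preview_offset
    ) != (payload_off, preview_off):
        raise ValueError("inconsistent header offsets")
    return hdr


def read_preview(path) -> np.ndarray:
    """Decode the 10x preview without touching the payload."""
    hdr = read_header(path)
    n = 3 * hdr.preview_w * hdr.preview_h
    with open(path, "rb") as fh:
        fh.seek(hdr.preview_offset)
        raw = fh.read(n)
    return np.frombuffer(raw, dtype=np.uint8).reshape(hdr.preview_h, hdr.preview_w, 3)


def read_roi(path, rect: tuple[int, int, int, int]) -> np.ndarray:
    """Read the half-open rectangle ``(x0, y0, x1, y1)`` via row-wise seeks."""
    hdr = read_header(path)
    x0, y0, x1, y1 = rect
    if not (0 <= x0 < x1 <= hdr.width_px and 0 <= y0 < y1 <= hdr.height_px):
        raise ValueError(f"rect {rect} out of bounds for {hdr.width_px}x{hdr.height_px}")
    w = x1 - x0
    out = np.empty((y1 - y0, w, 3), dtype=np.uint8)
    row_bytes = 3 * hdr.width_px
    with open(path, "rb") as fh:
        for i, y in enumerate(range(y0, y1)):
            fh.seek(hdr.payload_offset + y * row_bytes + 3 * x0)
            out[i] = np.frombuffer(fh.read(3 * w), dtype=np.uint8).reshape(w, 3)
    return out


def export_standard(source, out_path, fmt: str = "bigtiff", strip_rows: int = 512):
    """Lossless export to tiled BigTIFF or PNG.

    ``source`` is either a ``.rfpb`` path (streamed strip-wise, bounded
    memory) or an in-memory B,G,R array (converted to R,G,B on export).
    PNG is refused above 100 megapixels — use BigTIFF for gigascale.
    """
    import tifffile

    if isinstance(source, np.ndarray):
        img = _as_bgr(source)
        hdr = BitmapHeader(width_px=img.shape[1], height_px=img.shape[0])
        def rows(y0, y1):
            return img[y0:y1]
    else:
        hdr = read_header(source)
        def rows(y0, y1):
            return read_roi(source, (0, y0, hdr.width_px, y1))

    npix = hdr.width_px * hdr.height_px
    if fmt == "png":
        if npix > PNG_PIXEL_CAP:
            raise ValueError("image too large for PNG export; use fmt='bigtiff'")
        import imageio.v3 as iio

        iio.imwrite(out_path, rows(0, hdr.height_px)[:, :, ::-1])
        return out_path
    if fmt != "bigtiff":
        raise ValueError("fmt must be 'bigtiff' or 'png'")

    tile_sz = 512

    def gen():
        # one 512-row band in memory at a time, split into 512x512 tiles
        for y0 in range(0, hdr.height_px, tile_sz):
            band = rows(y0, min(y0 + tile_sz, hdr.height_px))[:, :, ::-1]
            for x0 in range(0, hdr.width_px, tile_sz):
                t = band[:, x0 : x0 + tile_sz]
                if t.shape[:2] != (tile_sz, tile_sz):
                    pad = np.zeros((tile_sz, tile_sz, 3), dtype=np.uint8)
                    pad[: t.shape[0], : t.shape[1]] = t
                    t = pad
                yield t

    with tifffile.TiffWriter(out_path, bigtiff=True) as tw:
        tw.write(
            gen(),
            shape=(hdr.height_px, hdr.width_px, 3),
            dtype=np.uint8,
            tile=(tile_sz, tile_sz),
            photometric="rgb",
            compression=None,
        )
    return out_path
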