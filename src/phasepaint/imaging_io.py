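"""Image I/O, overlapping tiling, target binarization, and tile merging.

Full-resolution phase-contrast frames (nominally 1536x1024) and their paired
fluorescent channels are decomposed into fixed-size square tiles with 50 %
overlap; fluorescent targets are thresholded into binary supervision masks;
per-tile network predictions are reassembled into a full-size probability map.

Conventions: row-major, 0-based, half-open slices; internal computation on
[0, 1] floats with conversion to 8-bit only at write/colorize time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, DimensionError, FormatError

CHANNELS = ("phase", "nuclei", "lgr5", "ueai")

#: default color fill per fluorescent channel (nuclei blue, LGR5 green,
#: UEA-I red)
DEFAULT_COLORS = {
    "nuclei": (0, 0, 255),
    "lgr5": (0, 255, 0),
    "ueai": (255, 0, 0),
}


@dataclass
class RasterImage:
    """A single-channel 2-D image plus channel metadata.

    ``pixels`` are stored either as integers on the native 0..2**bit_depth-1
    scale or as floats in [0, 1]; ``is_float`` records which.
    """

    pixels: np.ndarray
    channel_name: str = "phase"
    bit_depth: int = 8

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DimensionError(
                f"RasterImage requires a 2-D array, got shape {self.pixels.shape}"
            )
        if self.height < 1 or self.width < 1:
            raise DimensionError("image must be at least 1x1")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_float(self) -> bool:
        return self.pixels.dtype.kind == "f"

    def to_float(self) -> np.ndarray:
        """Pixels rescaled to [0, 1] float64."""
        if self.is_float:
            return self.pixels.astype(np.float64)
        return self.pixels.astype(np.float64) / (2**self.bit_depth - 1)

    def to_uint8(self) -> np.ndarray:
        if self.is_float:
            return np.clip(np.floor(self.pixels * 255 + 0.5), 0, 255).astype(np.uint8)
        if self.bit_depth == 8:
            return self.pixels.astype(np.uint8)
        return (self.pixels.astype(np.float64) / (2**self.bit_depth - 1) * 255).round().astype(np.uint8)


@dataclass
class ChannelSpec:
    """Rendering and thresholding parameters for one fluorescent channel."""

    channel_name: str
    display_color: tuple[int, int, int] | None = None
    background_threshold: float | None = None

    def __post_init__(self):
        if self.display_color is None:
            self.display_color = DEFAULT_COLORS.get(self.channel_name, (255, 255, 255))
        if any(not (0 <= c <= 255) for c in self.display_color):
            raise ConfigurationError("display_color components must be in 0-255")


@dataclass
class BinaryMask:
    """A {0,1} mask with the same geometry as its source image."""

    pixels: np.ndarray
    channel_name: str = "nuclei"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ConfigurationError("BinaryMask values must be exactly 0 or 1")


@dataclass
class TileGrid:
    """Deterministic decomposition into overlapping square tiles.

    ``origins`` lists (row, col) top-left corners in row-major order; an
    edge-flush final origin is added per axis when the image dimension is not
    an exact multiple of the stride, so the union of tiles always covers the
    image without padding.
    """

    tile_size: int
    stride: int
    source_height: int
    source_width: int
    origins: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.origins)

    def to_json(self) -> str:
        return json.dumps(
            {
                "tile_size": self.tile_size,
                "stride": self.stride,
                "source_height": self.source_height,
                "source_width": self.source_width,
                "origins": [list(o) for o in self.origins],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "TileGrid":
        d = json.loads(s)
        return cls(
            tile_size=d["tile_size"],
            stride=d["stride"],
            source_height=d["source_height"],
            source_width=d["source_width"],
            origins=[tuple(o) for o in d["origins"]],
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}
_PNG_SUFFIXES = {".png"}


def read_image(path, channel_name: str = "phase"):
    """Read a TIFF or PNG image.

    Returns a :class:`RasterImage` for single-channel files; a list of
    per-channel RasterImages for multi-channel files.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in _TIFF_SUFFIXES:
            arr = tifffile.imread(path)
        elif suffix in _PNG_SUFFIXES:
            arr = np.asarray(Image.open(path))
        else:
            raise FormatError(f"unsupported image format: {path}")
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise IOError(f"could not read image {path}: {exc}") from exc
    bit_depth = 16 if arr.dtype == np.uint16 else 8
    if arr.ndim == 2:
        return RasterImage(arr, channel_name=channel_name, bit_depth=bit_depth)
    if arr.ndim == 3:
        axis = int(np.argmin(arr.shape))
        return [
            RasterImage(np.take(arr, i, axis=axis), channel_name=channel_name, bit_depth=bit_depth)
            for i in range(arr.shape[axis])
        ]
    raise FormatError(f"unsupported image dimensionality {arr.ndim} in {path}")


def write_image(path, image: RasterImage | np.ndarray) -> None:
    """Write an image as TIFF or PNG, preserving 8/16-bit integer data."""
    path = Path(path)
    if isinstance(image, RasterImage):
        arr = image.pixels
        if image.is_float:
            arr = image.to_uint8()
        elif image.bit_depth == 16:
            arr = arr.astype(np.uint16)
        else:
            arr = arr.astype(np.uint8)
    else:
        arr = np.asarray(image)
        if arr.dtype.kind == "f":
            arr = np.clip(np.floor(arr * 255 + 0.5), 0, 255).astype(np.uint8)
    suffix = path.suffix.lower()
    if suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr)
    elif suffix in _PNG_SUFFIXES:
        Image.fromarray(arr).save(path)
    else:
        raise FormatError(f"unsupported image format: {path}")


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------


def _axis_origins(dim: int, tile_size: int, stride: int) -> list[int]:
    origins = list(range(0, dim - tile_size + 1, stride))
    if origins[-1] != dim - tile_size:
        origins.append(dim - tile_size)
    return origins


def make_tile_grid(
    height: int,
    width: int,
    tile_size: int = 256,
    overlap_fraction: float = 0.5,
) -> TileGrid:
    """Build the overlapping tile decomposition of a height x width image."""
    if tile_size > min(height, width):
        raise DimensionError(
            f"tile_size {tile_size} exceeds image dimensions {height}x{width}"
        )
    if not 0 <= overlap_fraction < 1:
        raise ConfigurationError("overlap_fraction must be in [0, 1)")
    stride_f = tile_size * (1.0 - overlap_fraction)
    stride = int(round(stride_f))
    if stride <= 0 or abs(stride - stride_f) > 1e-9:
        raise ConfigurationError(
            f"tile_size*(1-overlap) must be a positive integer, got {stride_f}"
        )
    rows = _axis_origins(height, tile_size, stride)
    cols = _axis_origins(width, tile_size, stride)
    origins = [(r, c) for r in rows for c in cols]
    return TileGrid(
        tile_size=tile_size,
        stride=stride,
        source_height=height,
        source_width=width,
        origins=origins,
    )


def _check_grid(grid: TileGrid, height: int, width: int):
    if grid.source_height != height or grid.source_width != width:
        raise DimensionError(
            f"grid is for {grid.source_height}x{grid.source_width}, "
            f"image is {height}x{width}"
        )


def extract_tiles(image: RasterImage | np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Slice the image into one tile per grid origin (values copied)."""
    arr = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    _check_grid(grid, arr.shape[0], arr.shape[1])
    t = grid.tile_size
    return [arr[r : r + t, c : c + t].copy() for r, c in grid.origins]


def merge_tiles(
    tiles: list[np.ndarray],
    grid: TileGrid,
    aggregate: str = "mean",
) -> np.ndarray:
    """Reassemble tiles into a full-size array.

    Overlapping pixels are combined by the unweighted mean of the contributing
    tiles (so merge after extract is the identity), or by the elementwise
    maximum when ``aggregate="max"``.
    """
    if len(tiles) != len(grid.origins):
        raise DimensionError(
            f"{len(tiles)} tiles supplied for {len(grid.origins)} origins"
        )
    t = grid.tile_size
    h, w = grid.source_height, grid.source_width
    if aggregate == "mean":
        acc = np.zeros((h, w), dtype=np.float64)
        cnt = np.zeros((h, w), dtype=np.float64)
        for (r, c), tile in zip(grid.origins, tiles):
            if tile.shape != (t, t):
                raise DimensionError(f"tile shape {tile.shape} != ({t}, {t})")
            acc[r : r + t, c : c + t] += tile
            cnt[r : r + t, c : c + t] += 1.0
        return acc / cnt
    if aggregate == "max":
        acc = np.full((h, w), -np.inf)
        for (r, c), tile in zip(grid.origins, tiles):
            if tile.shape != (t, t):
                raise DimensionError(f"tile shape {tile.shape} != ({t}, {t})")
            region = acc[r : r + t, c : c + t]
            np.maximum(region, tile, out=region)
        return acc
    raise ConfigurationError(f"unknown aggregate rule {aggregate!r}")


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def estimate_background_threshold(image: RasterImage) -> float:
    """Data-driven background threshold (Otsu) on one target image."""
    return float(threshold_otsu(image.to_float()))


def binarize_target(image: RasterImage, spec: ChannelSpec) -> BinaryMask:
    """Threshold a fluorescent target into the {0,1} supervision mask.

    A pixel is foreground iff its intensity exceeds ``spec.background_threshold``
    (compared on the image's own scale; None means estimate by Otsu).
    """
    if spec.channel_name != image.channel_name:
        raise ConfigurationError(
            f"spec is for channel {spec.channel_name!r}, image is "
            f"{image.channel_name!r}"
        )
    thr = spec.background_threshold
    if thr is None:
        thr = estimate_background_threshold(image)
        arr = image.to_float()
    else:
        arr = image.pixels
        lo, hi = (0.0, 1.0) if image.is_float else (0, 2**image.bit_depth - 1)
        if not lo <= thr <= hi:
            raise ConfigurationError(
                f"threshold {thr} outside intensity range [{lo}, {hi}]"
            )
    return BinaryMask(
        (np.asarray(arr) > thr).astype(np.uint8), channel_name=image.channel_name
    )
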