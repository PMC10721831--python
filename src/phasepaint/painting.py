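"""Full-image virtual painting: tile, predict, merge, colorize, smooth seams.

Inference runs the trained generator over the overlapping tile grid, averages
the per-tile probabilities back into a full-size map, fills the channel color
by multiplying each pixel probability by the display intensity (probability
1.0 in the nuclei channel -> pure blue 255), and finally smooths residual
tile-boundary seams with an aggregated-contextual-transformation (AOT) style
operator applied only inside a binary seam mask.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate

from .errors import ConfigurationError, DimensionError
from .imaging_io import BinaryMask, ChannelSpec, RasterImage, TileGrid, extract_tiles, merge_tiles
from .segnet import SegNet


def predict_image(
    model: SegNet,
    phase: RasterImage | np.ndarray,
    grid: TileGrid,
    batch_size: int = 16,
) -> np.ndarray:
    """Tile the phase image, run eval-mode forward passes, and merge.

    Overlapping predictions are combined by their unweighted mean; the result
    is a full-size probability map in [0, 1].
    """
    arr = phase.to_float() if isinstance(phase, RasterImage) else np.asarray(phase, np.float64)
    tiles = extract_tiles(arr, grid)
    preds: list[np.ndarray] = []
    for i in range(0, len(tiles), batch_size):
        batch = np.stack(tiles[i : i + batch_size])
        preds.extend(np.asarray(model.predict(batch), dtype=np.float64))
    merged = merge_tiles(preds, grid)
    return np.clip(merged, 0.0, 1.0)


def colorize(prob: np.ndarray, spec: ChannelSpec) -> np.ndarray:
    """Color-fill a probability map into an 8-bit RGB image.

    Channel c intensity = round(prob * display_color_c), rounding half away
    from zero, so probability 1.0 in a blue channel gives (0, 0, 255).
    """
    prob = np.asarray(prob, dtype=np.float64)
    rgb = np.empty(prob.shape + (3,), dtype=np.uint8)
    for c, level in enumerate(spec.display_color):
        rgb[..., c] = np.floor(prob * level + 0.5).astype(np.uint8)
    return rgb


def compose_multiplex(colorized: list[np.ndarray]) -> np.ndarray:
    """Overlay several colorized channels by per-channel maximum."""
    out = colorized[0]
    for img in colorized[1:]:
        out = np.maximum(out, img)
    return out


def make_seam_mask(grid: TileGrid, width: int = 4) -> BinaryMask:
    """Binary mask of pixels within width/2 of any internal tile boundary."""
    if width < 1:
        raise ConfigurationError("seam width must be >= 1")
    h, w = grid.source_height, grid.source_width
    mask = np.zeros((h, w), dtype=np.uint8)
    lo, hi = width // 2, width - width // 2
    t = grid.tile_size
    row_edges = set()
    col_edges = set()
    for r, c in grid.origins:
        if r > 0:
            row_edges.add(r)
        if r + t < h:
            row_edges.add(r + t)
        if c > 0:
            col_edges.add(c)
        if c + t < w:
            col_edges.add(c + t)
    for e in row_edges:
        mask[max(0, e - lo) : min(h, e + hi), :] = 1
    for e in col_edges:
        mask[:, max(0, e - lo) : min(w, e + hi)] = 1
    return BinaryMask(mask)


def _dilated_box_kernel(rate: int) -> np.ndarray:
    """3x3 tap pattern dilated by ``rate``, normalized to sum 1."""
    size = 2 * rate + 1
    k = np.zeros((size, size))
    k[::rate, ::rate] = 1.0 / 9.0
    return k


def smooth_seams(
    image: np.ndarray,
    seam: BinaryMask,
    n_blocks: int = 1,
    dilation_rates: tuple[int, ...] = (1, 2, 4, 8),
    gate: float = 0.5,
) -> np.ndarray:
    """AOT-style seam smoothing restricted to the seam mask.

    Each block follows the split-transformation-merge pattern: the input is
    routed through parallel dilated 3x3 transformations (fixed normalized
    kernels, one per dilation rate), the branches are merged by averaging,
    and a gated residual update blends the merged context with the input.
    Only pixels inside the seam mask are replaced; everything else is
    returned bit-identical.  Constants are preserved and the output stays in
    [0, 1].
    """
    if len(dilation_rates) == 0:
        raise ConfigurationError("dilation_rates must not be empty")
    arr = np.asarray(image, dtype=np.float64)
    if arr.shape != seam.pixels.shape:
        raise DimensionError(
            f"image shape {arr.shape} != seam mask shape {seam.pixels.shape}"
        )
    out = arr.copy()
    smoothed = arr.copy()
    for _ in range(n_blocks):
        branches = [
            correlate(smoothed, _dilated_box_kernel(r), mode="reflect")
            for r in dilation_rates
        ]
        merged = np.mean(branches, axis=0)
        smoothed = (1.0 - gate) * smoothed + gate * merged
    inside = seam.pixels.astype(bool)
    out[inside] = np.clip(smoothed[inside], 0.0, 1.0)
    return out


def paint(
    model: SegNet,
    phase: RasterImage,
    spec: ChannelSpec,
    grid: TileGrid | None = None,
    tile_size: int = 256,
    overlap_fraction: float = 0.5,
    seam_width: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """End-to-end virtual painting of one channel.

    Returns ``(probability_map, colorized_rgb)`` after tile inference,
    merging, seam smoothing, and color fill.
    """
    from .imaging_io import make_tile_grid

    if grid is None:
        grid = make_tile_grid(phase.height, phase.width, tile_size, overlap_fraction)
    prob = predict_image(model, phase, grid)
    seam = make_seam_mask(grid, seam_width)
    prob = smooth_seams(prob, seam)
    return prob, colorize(prob, spec)
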