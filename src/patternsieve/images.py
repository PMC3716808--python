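"""Image binarization, 3x3 patch statistics, and sketch rendering.

The vision-side pipeline: convert a raster to relative luminance, threshold
it at its own median to one bit per pixel, slide a 3x3 window over every
interior pixel to accumulate the 512-bin pattern histogram, and render
"sketches" that keep only the pixels whose local patch belongs to a chosen
pattern set, blanking everything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v2 as iio
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .patterns import _CODE_WEIGHTS, GRID_SIDE, N_PATTERNS, PatternDistribution

__all__ = [
    "BLACK",
    "WHITE",
    "BLANK",
    "LuminanceImage",
    "BinaryImage",
    "Sketch",
    "SketchStats",
    "load_image",
    "to_luminance",
    "binarize_median",
    "window_codes",
    "pattern_histogram",
    "make_sketch",
    "sketch_stats",
    "sketch_to_uint8",
    "save_sketch",
]

# in-memory sketch values; exported as 0 / 255 / 128 grey levels
BLACK = 0
WHITE = 1
BLANK = -1

# ITU-R BT.709 luma weights for collapsing RGB to relative luminance
_RGB_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class LuminanceImage:
    """Single-channel relative-luminance raster (nonnegative floats)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("luminance image must be 2-D")
        if not np.isfinite(self.pixels).all() or (self.pixels < 0).any():
            raise ValueError("luminance values must be finite and nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryImage:
    """One-bit image produced by median thresholding."""

    bits: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        self.bits = self.bits.astype(np.uint8)


@dataclass
class Sketch:
    """Ternary image: BLACK/WHITE where a patch was retained, BLANK elsewhere."""

    values: np.ndarray
    selected_set: frozenset
    mode: str


@dataclass
class SketchStats:
    matched_windows: int
    total_windows: int
    retained_fraction: float
    compression_factor: float


def to_luminance(raster) -> LuminanceImage:
    """Collapse a 1- or 3-channel raster to relative luminance.

    Three channels are combined with fixed BT.709 weights
    (0.2126, 0.7152, 0.0722); a single channel passes through unchanged.
    """
    arr = np.asarray(raster, dtype=float)
    if arr.ndim == 2:
        return LuminanceImage(arr)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return LuminanceImage(arr @ _RGB_WEIGHTS)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return LuminanceImage(arr[:, :, 0])
    raise ValueError(f"unsupported raster shape {arr.shape}; expected HxW or HxWx{{1,3}}")


def load_image(path: str | Path) -> LuminanceImage:
    """Read a PNG/TIFF/PGM/PPM raster and convert it to luminance."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return to_luminance(arr)


def binarize_median(img: LuminanceImage) -> BinaryImage:
    """Threshold an image at its own median luminance.

    A pixel becomes white (1) only if it strictly exceeds the median
    (midpoint of the two central order statistics for even pixel counts),
    so a constant image binarizes to all black and at most half the pixels
    of a duplicate-free image are white.
    """
    pixels = img.pixels if isinstance(img, LuminanceImage) else np.asarray(img, float)
    if pixels.size == 0:
        raise ValueError("cannot binarize an empty image")
    median = float(np.median(pixels))
    return BinaryImage(bits=(pixels > median).astype(np.uint8), threshold_used=median)


def window_codes(bits: np.ndarray) -> np.ndarray:
    """Patch code of every fully-interior 3x3 window.

    Returns an ``(H-2, W-2)`` int array; entry ``(r, c)`` is the code of
    the window centered on source pixel ``(r+1, c+1)``.
    """
    bits = np.asarray(bits)
    if bits.shape[0] < GRID_SIDE or bits.shape[1] < GRID_SIDE:
        raise ValueError("image must be at least 3x3 for pattern extraction")
    windows = sliding_window_view(bits.astype(np.int64), (GRID_SIDE, GRID_SIDE))
    return np.einsum("ijkl,kl->ij", windows, _CODE_WEIGHTS)


def pattern_histogram(images: Iterable[BinaryImage]) -> PatternDistribution:
    """Pooled 512-bin pattern distribution over a corpus of binary images.

    Every interior 3x3 window of every image contributes one count
    (windows overlap); counts are pooled across the corpus before
    normalizing, so each image contributes in proportion to its window
    count ``(H-2)(W-2)``.
    """
    counts = np.zeros(N_PATTERNS, dtype=np.int64)
    n_images = 0
    for img in images:
        bits = img.bits if isinstance(img, BinaryImage) else np.asarray(img)
        codes = window_codes(bits)
        counts += np.bincount(codes.ravel(), minlength=N_PATTERNS)
        n_images += 1
    if n_images == 0:
        raise ValueError("need at least one image")
    return PatternDistribution.from_counts(
        {int(i): int(c) for i, c in enumerate(counts) if c > 0},
        source=f"pooled 3x3 histogram over {n_images} images",
    )


def _selection_lut(selected: Iterable[int]) -> np.ndarray:
    lut = np.zeros(N_PATTERNS, dtype=bool)
    ids = list(selected)
    if ids:
        arr = np.asarray(ids, dtype=np.int64)
        if ((arr < 0) | (arr >= N_PATTERNS)).any():
            raise ValueError("selected ids must lie in [0, 512)")
        lut[arr] = True
    return lut


def make_sketch(img: BinaryImage, selected: Iterable[int], mode: str = "center") -> Sketch:
    """Blank every pixel whose neighbourhood does not match the selection.

    ``center`` mode (default) keeps a pixel iff the 3x3 window centered on
    it matches a selected pattern; the one-pixel border, which has no full
    window, is always blank.  ``union`` mode keeps all nine pixels of every
    matching window, so retained regions are thicker and may touch the
    border.
    """
    if mode not in ("center", "union"):
        raise ValueError(f"unknown sketch mode {mode!r}")
    bits = img.bits
    lut = _selection_lut(selected)
    match = lut[window_codes(bits)]  # (H-2, W-2) at window centers
    keep = np.zeros(bits.shape, dtype=bool)
    keep[1:-1, 1:-1] = match
    if mode == "union":
        keep = ndimage.binary_dilation(keep, structure=np.ones((3, 3), bool))
    values = np.full(bits.shape, BLANK, dtype=np.int8)
    values[keep] = bits[keep]
    return Sketch(values=values, selected_set=frozenset(int(i) for i in selected), mode=mode)


def sketch_stats(img: BinaryImage, selected: Iterable[int]) -> SketchStats:
    """Window-level match statistics of a selection on one image.

    ``retained_fraction`` is the fraction of interior windows whose patch
    is in the selected set; its inverse is the compression factor achieved
    on this image (infinity when nothing matches).
    """
    lut = _selection_lut(selected)
    match = lut[window_codes(img.bits)]
    matched = int(match.sum())
    total = int(match.size)
    fraction = matched / total
    compression = 1.0 / fraction if fraction > 0 else float("inf")
    return SketchStats(
        matched_windows=matched,
        total_windows=total,
        retained_fraction=fraction,
        compression_factor=compression,
    )


def sketch_to_uint8(sketch: Sketch) -> np.ndarray:
    """Render a sketch as an 8-bit raster: black=0, white=255, blank=128."""
    out = np.full(sketch.values.shape, 128, dtype=np.uint8)
    out[sketch.values == BLACK] = 0
    out[sketch.values == WHITE] = 255
    return out


def save_sketch(sketch: Sketch, path: str | Path) -> None:
    """Write a sketch as an 8-bit PNG/PGM raster."""
    iio.imwrite(Path(path), sketch_to_uint8(sketch))


def corpus_histogram_from_paths(paths: Sequence[str | Path]) -> PatternDistribution:
    """Load, binarize and pool a list of raster files into one distribution."""
    return pattern_histogram(binarize_median(load_image(p)) for p in paths)
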