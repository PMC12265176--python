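"""Histogram-of-Oriented-Gradients descriptor at the pipeline's fixed geometry.

On the 64x64 working image: central-difference gradients, unsigned
orientations in [0, 180) binned into 9 bins per non-overlapping 8x8 cell
(magnitude votes split linearly between the two nearest bin centers, with
circular wrap), then L2 normalization over overlapping 2x2-cell blocks at an
8-pixel stride. 7x7 = 49 blocks of 36 values give the 1,764-dim descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ChannelImage, ImageRecord, split_channels

CELL_SIZE = 8
BLOCK_CELLS = 2
N_BINS = 9
EPS = 1e-6
HOG_DIM = 49 * 36


@dataclass
class GradientField:
    Gx: np.ndarray
    Gy: np.ndarray
    M: np.ndarray      # magnitude, sqrt(Gx^2 + Gy^2)
    theta: np.ndarray  # unsigned orientation, degrees in [0, 180)


@dataclass
class HOGFeatureVector:
    values: np.ndarray
    source: str = field(default="HOG")


def compute_gradients(gray: ChannelImage | np.ndarray) -> GradientField:
    """Central-difference gradients with replicate border padding.

    Gx(x, y) = I(x+1, y) - I(x-1, y) along columns, Gy along rows. The
    orientation is folded into [0, 180) (unsigned gradients) and set to 0
    where the gradient vanishes.
    """
    values = gray.values if isinstance(gray, ChannelImage) else np.asarray(gray)
    I = values.astype(np.float64)
    pad = np.pad(I, 1, mode="edge")
    Gx = pad[1:-1, 2:] - pad[1:-1, :-2]
    Gy = pad[2:, 1:-1] - pad[:-2, 1:-1]
    M = np.hypot(Gx, Gy)
    theta = np.degrees(np.arctan2(Gy, Gx)) % 180.0
    theta[M == 0] = 0.0
    return GradientField(Gx=Gx, Gy=Gy, M=M, theta=theta)


def cell_histograms(
    field: GradientField, cell_size: int = CELL_SIZE, n_bins: int = N_BINS
) -> np.ndarray:
    """Per-cell orientation histograms, shape (rows, cols, n_bins).

    Each pixel's magnitude is split between the two nearest bin centers
    (centers at 10, 30, ..., 170 degrees for 9 bins) by linear interpolation,
    wrapping circularly between the last and first bin, so per-cell bin sums
    equal per-cell magnitude sums.
    """
    h, w = field.M.shape
    if h % cell_size or w % cell_size:
        raise ValueError(f"image shape {(h, w)} not divisible by cell size {cell_size}")
    bin_width = 180.0 / n_bins
    # fractional bin position relative to the first bin center (bin_width/2)
    pos = (field.theta - bin_width / 2.0) / bin_width
    lo = np.floor(pos).astype(np.int64)
    frac = pos - lo
    lo_bin = lo % n_bins
    hi_bin = (lo + 1) % n_bins

    rows, cols = h // cell_size, w // cell_size
    cell_r = np.repeat(np.arange(rows), cell_size)[:, None] * np.ones((1, w), dtype=np.int64)
    cell_c = np.ones((h, 1), dtype=np.int64) * np.repeat(np.arange(cols), cell_size)[None, :]
    hist = np.zeros((rows, cols, n_bins))
    np.add.at(hist, (cell_r.ravel(), cell_c.ravel(), lo_bin.ravel()),
              (field.M * (1.0 - frac)).ravel())
    np.add.at(hist, (cell_r.ravel(), cell_c.ravel(), hi_bin.ravel()),
              (field.M * frac).ravel())
    return hist


def block_normalize(
    cells: np.ndarray, block_cells: int = BLOCK_CELLS, eps: float = EPS
) -> HOGFeatureVector:
    """L2-normalize overlapping blocks of cells and concatenate row-major.

    Each block concatenates its cell histograms (row-major) into v and emits
    v / sqrt(||v||^2 + eps^2). For the 8x8 cell grid this yields 49 blocks
    of 36 values each.
    """
    rows, cols, _ = cells.shape
    out = []
    for i in range(rows - block_cells + 1):
        for j in range(cols - block_cells + 1):
            v = cells[i : i + block_cells, j : j + block_cells].ravel()
            out.append(v / np.sqrt(np.dot(v, v) + eps * eps))
    return HOGFeatureVector(np.concatenate(out))


def extract_hog(rec: ImageRecord) -> HOGFeatureVector:
    """Full descriptor for a preprocessed (64x64) record: grayscale ->
    gradients -> cell histograms -> block normalization."""
    gray = split_channels(rec)[3]
    return block_normalize(cell_histograms(compute_gradients(gray)))
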