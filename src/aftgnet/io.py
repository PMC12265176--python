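"""Image and manifest loading, color-space handling, and the working geometry.

Every feature extractor in the pipeline operates on a fixed 64x64 RGB working
image, so HOG and topological features stay spatially co-registered. Labels
are binary: 0 = non-disease, 1 = disease.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

WORKING_SIZE = 64

#: ITU-R BT.601 luma weights used for the grayscale channel.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

CHANNEL_ORDER = ("R", "G", "B", "GRAY")


@dataclass
class ImageRecord:
    """One unit of work: an RGB image with an identifier and optional label."""

    id: str
    pixels: np.ndarray  # H x W x 3 uint8
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"record {self.id!r}: pixels must be HxWx3, got {self.pixels.shape}")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 255):
            raise ValueError(f"record {self.id!r}: pixel values outside [0, 255]")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")


@dataclass
class ChannelImage:
    """A single 2-D channel (R, G, B or derived grayscale) in [0, 255]."""

    values: np.ndarray  # H x W uint8
    channel_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"channel must be 2-D, got shape {self.values.shape}")
        if self.channel_tag not in CHANNEL_ORDER:
            raise ValueError(f"unknown channel tag {self.channel_tag!r}")


def load_manifest(path: str) -> list[ImageRecord]:
    """Read a ``id,image_path,label`` CSV manifest into ImageRecords.

    Relative image paths are resolved against the manifest's directory.
    Row order is preserved. Labels must be 0 or 1.
    """
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "image_path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest {path}: missing required column {col!r}")
    base = os.path.dirname(os.path.abspath(path))
    records: list[ImageRecord] = []
    for row in df.itertuples(index=False):
        label = int(row.label)
        if label not in (0, 1):
            raise ValueError(f"manifest {path}: row {row.id!r} has label {row.label!r}, expected 0 or 1")
        img_path = row.image_path
        if not os.path.isabs(img_path):
            img_path = os.path.join(base, img_path)
        if not os.path.exists(img_path):
            raise FileNotFoundError(f"image file not found: {img_path} (manifest row {row.id!r})")
        with Image.open(img_path) as im:
            pixels = np.asarray(im.convert("RGB"))
        records.append(ImageRecord(id=str(row.id), pixels=pixels, label=label))
    return records


def to_working_size(rec: ImageRecord, size: int = WORKING_SIZE) -> ImageRecord:
    """Resize a record to the size x size working geometry (bilinear).

    A record already at the working size is returned unchanged.
    """
    h, w = rec.pixels.shape[:2]
    if h == 0 or w == 0:
        raise ValueError(f"record {rec.id!r}: zero-area image")
    if (h, w) == (size, size):
        return rec
    im = Image.fromarray(rec.pixels.astype(np.uint8), mode="RGB")
    resized = np.asarray(im.resize((size, size), Image.BILINEAR))
    return ImageRecord(id=rec.id, pixels=resized, label=rec.label)


def split_channels(rec: ImageRecord) -> tuple[ChannelImage, ChannelImage, ChannelImage, ChannelImage]:
    """Split into the four fixed channels (R, G, B, GRAY).

    GRAY uses BT.601 luma weights rounded to the nearest integer.
    """
    px = rec.pixels.astype(np.int64)
    # integer form of round(0.299 R + 0.587 G + 0.114 B): exact, and shifting
    # all channels by a constant shifts the result by exactly that constant
    gray = (299 * px[..., 0] + 587 * px[..., 1] + 114 * px[..., 2] + 500) // 1000
    gray = gray.astype(np.uint8)
    return (
        ChannelImage(rec.pixels[..., 0], "R"),
        ChannelImage(rec.pixels[..., 1], "G"),
        ChannelImage(rec.pixels[..., 2], "B"),
        ChannelImage(gray, "GRAY"),
    )
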