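"""Image containers, RoI cropping and intensity-profile extraction.

A strip image is reduced to a 1-D *intensity profile*: the image is cropped to
the region of interest (RoI) around the membrane window, converted to
grayscale, and averaged across the transverse axis so that each position along
the flow axis carries the mean of many pixels. Averaging improves the
signal-to-noise ratio by roughly the square root of the number of transverse
pixels; the test and control lines then appear as two dips in the profile.

Coordinates are 0-based and half-open on both axes. The flow axis (the
direction the sample wicks along the strip) defaults to the image width.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ImageFormatError, RoiError

__all__ = [
    "StripImage",
    "RoiRect",
    "IntensityProfile",
    "load_image",
    "save_image",
    "to_grayscale",
    "crop_roi",
    "average_profile",
    "smooth_profile",
    "profile_to_csv",
]

#: BT.601 luminance weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class StripImage:
    """A single strip image: 8-bit grayscale (H, W) or RGB (H, W, 3)."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            raise ImageFormatError(
                f"expected 8-bit pixel counts, got dtype {px.dtype}"
            )
        if px.ndim == 3 and px.shape[2] != 3:
            raise ImageFormatError(
                f"expected 3 colour channels, got {px.shape[2]}"
            )
        if px.ndim not in (2, 3):
            raise ImageFormatError(f"expected 2-D or 3-D pixel grid, got {px.ndim}-D")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError("image must be at least 1x1")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_grayscale(self) -> bool:
        return self.pixels.ndim == 2

    @property
    def depth(self) -> int:
        """Bits per pixel: 8 for grayscale, 24 for RGB."""
        return 8 if self.is_grayscale else 24


@dataclass(frozen=True)
class RoiRect:
    """Region of interest: (row0, col0) corner plus height and width.

    Half-open on both axes: rows ``row0 .. row0+height-1`` inclusive.
    """

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise RoiError("RoI height and width must be >= 1")
        if self.row0 < 0 or self.col0 < 0:
            raise RoiError("RoI origin must be non-negative")

    def check_within(self, img: StripImage) -> None:
        if self.row0 + self.height > img.height:
            raise RoiError(
                f"RoI bottom edge {self.row0 + self.height} exceeds image "
                f"height {img.height}"
            )
        if self.col0 + self.width > img.width:
            raise RoiError(
                f"RoI right edge {self.col0 + self.width} exceeds image "
                f"width {img.width}"
            )


@dataclass(frozen=True)
class IntensityProfile:
    """Column-averaged intensity versus position along the flow axis."""

    values: np.ndarray  # mean counts, fractional allowed
    positions: np.ndarray  # pixel indices along the flow axis
    n_averaged: int  # transverse pixels averaged per position

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        p = np.asarray(self.positions, dtype=int)
        if v.shape != p.shape or v.ndim != 1:
            raise ValueError("values and positions must be 1-D and equal length")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "positions", p)

    def __len__(self) -> int:
        return len(self.values)


def load_image(path: str | os.PathLike) -> StripImage:
    """Read a PNG, TIFF or PGM strip image, preserving pixel values exactly.

    Only 8-bit-per-channel images are accepted; higher bit depths raise
    :class:`ImageFormatError`.
    """
    try:
        px = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # truncated / unreadable file
        raise ImageFormatError(f"could not read image {path}: {exc}") from exc
    if px.dtype != np.uint8:
        raise ImageFormatError(
            f"{path}: unsupported bit depth (dtype {px.dtype}); "
            "only 8 bits per channel are supported"
        )
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha written by some tools
        px = px[:, :, :3]
    return StripImage(px)


def save_image(img: StripImage, path: str | os.PathLike) -> None:
    """Write the image losslessly (format chosen from the file extension)."""
    iio.imwrite(path, img.pixels)


def to_grayscale(img: StripImage) -> StripImage:
    """Convert RGB to grayscale with BT.601 luminance weights.

    Grayscale input is returned unchanged. Conversion rounds half-up, e.g.
    RGB (100, 150, 200) -> 140.75 -> 141 counts.
    """
    if img.is_grayscale:
        return img
    wr, wg, wb = LUMA_WEIGHTS
    y = (
        wr * img.pixels[:, :, 0].astype(float)
        + wg * img.pixels[:, :, 1].astype(float)
        + wb * img.pixels[:, :, 2].astype(float)
    )
    return StripImage(np.floor(y + 0.5).clip(0, 255).astype(np.uint8))


def crop_roi(img: StripImage, roi: RoiRect) -> StripImage:
    """Crop to the region of interest; an exact sub-grid copy."""
    roi.check_within(img)
    sub = img.pixels[
        roi.row0 : roi.row0 + roi.height, roi.col0 : roi.col0 + roi.width
    ].copy()
    return StripImage(sub)


def average_profile(img: StripImage, flow_axis: str = "width") -> IntensityProfile:
    """Collapse a grayscale image to the mean intensity along the flow axis.

    ``flow_axis="width"`` averages each column over the rows (the default
    reader orientation: the sample flows left to right); ``"height"`` averages
    each row over the columns.
    """
    if not img.is_grayscale:
        raise ValueError("average_profile requires a grayscale image")
    if flow_axis == "width":
        values = img.pixels.mean(axis=0, dtype=float)
        n_avg = img.height
    elif flow_axis == "height":
        values = img.pixels.mean(axis=1, dtype=float)
        n_avg = img.width
    else:
        raise ValueError(f"flow_axis must be 'width' or 'height', got {flow_axis!r}")
    return IntensityProfile(values, np.arange(len(values)), n_avg)


def smooth_profile(p: IntensityProfile, window: int) -> IntensityProfile:
    """Centered moving average; near the edges the window shrinks one-sided.

    ``window`` must be odd and no longer than the profile; ``window=1`` is the
    identity. Output value at position i is the mean of the raw values in
    ``[i-h, i+h]`` intersected with the profile, where ``h = window // 2``.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > len(p):
        raise ValueError(f"window {window} exceeds profile length {len(p)}")
    if window == 1:
        return p
    h = window // 2
    v = p.values
    csum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.maximum(np.arange(len(v)) - h, 0)
    hi = np.minimum(np.arange(len(v)) + h + 1, len(v))
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return IntensityProfile(out, p.positions, p.n_averaged)


def profile_to_csv(p: IntensityProfile, path: str | os.PathLike) -> None:
    """Export a profile as CSV: position_px, mean_intensity, n_averaged."""
    pd.DataFrame(
        {
            "position_px": p.positions,
            "mean_intensity": p.values,
            "n_averaged": p.n_averaged,
        }
    ).to_csv(path, index=False)
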