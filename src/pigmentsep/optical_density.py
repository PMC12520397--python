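"""Log-space channel differences of an RGB skin image.

In the optical-density domain the two skin chromophores (melanin and
hemoglobin) contribute linearly to each color channel, together with a
multiplicative shading term and the baseline illumination.  Taking the
differences ``ln B - ln R`` and ``ln G - ln R`` cancels the shading term
per pixel, leaving a 2-D linear mixture of the two pigment concentration
fields — the observation matrix that blind source separation operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "RGBImage",
    "LogDiffSamples",
    "FormatError",
    "load_image",
    "channel_differences",
    "samples_to_csv",
]


class FormatError(ValueError):
    """Raised when an input image is not a plain 3-channel 8/16-bit image."""


@dataclass
class RGBImage:
    """An H×W×3 intensity array with all values in (0, 1].

    ``region`` records the rectangle (row0, col0, height, width) that was
    cropped out of the source file, 0-based and half-open.  ``meta`` carries
    renderer bookkeeping such as the global rescale factor applied by the
    synthetic forward model.
    """

    pixels: np.ndarray
    bit_depth_origin: int = 8
    region: tuple[int, int, int, int] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LogDiffSamples:
    """n×2 matrix of per-pixel (ln B − ln R, ln G − ln R) values.

    ``pixel_index`` maps each row back to its (row, col) position inside the
    analysed region; rows are in raster (row-major) order unless the samples
    were re-assembled from selected sub-blocks.
    """

    data: np.ndarray
    pixel_index: np.ndarray

    def __len__(self) -> int:
        return self.data.shape[0]


_MAX_CODE = {np.dtype(np.uint8): 255, np.dtype(np.uint16): 65535}


def load_image(path: str | Path, region: tuple[int, int, int, int] | None = None) -> RGBImage:
    """Load a PNG/TIFF image, normalize intensities into (0, 1], crop ``region``.

    Intensities are divided by the bit-depth maximum (255 or 65535); exact
    zeros are clamped to half a code value, ``1/(2*max_code)``, so that the
    subsequent log transform stays finite.
    """
    arr = iio.imread(path)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"expected a 3-channel RGB image, got shape {arr.shape} from {path}"
        )
    max_code = _MAX_CODE.get(arr.dtype)
    if max_code is None:
        raise FormatError(f"unsupported dtype {arr.dtype}; expected uint8 or uint16")
    pixels = arr.astype(np.float64) / max_code
    pixels = np.maximum(pixels, 1.0 / (2.0 * max_code))
    if region is not None:
        pixels = _crop(pixels, region)
    return RGBImage(
        pixels=pixels,
        bit_depth_origin=8 if max_code == 255 else 16,
        region=region,
    )


def _crop(pixels: np.ndarray, region: tuple[int, int, int, int]) -> np.ndarray:
    r0, c0, h, w = region
    H, W = pixels.shape[:2]
    if r0 < 0 or c0 < 0 or h <= 0 or w <= 0 or r0 + h > H or c0 + w > W:
        raise ValueError(f"region {region} outside image of shape {(H, W)}")
    return pixels[r0 : r0 + h, c0 : c0 + w]


def channel_differences(image: RGBImage) -> LogDiffSamples:
    """Per-pixel (ln B − ln R, ln G − ln R) in raster order.

    A global multiplicative factor on the pixel values (exposure, shading)
    cancels exactly in these differences.
    """
    logp = np.log(image.pixels)
    d = np.stack(
        [logp[..., 2] - logp[..., 0], logp[..., 1] - logp[..., 0]], axis=-1
    ).reshape(-1, 2)
    H, W = image.shape
    rows, cols = np.divmod(np.arange(H * W), W)
    return LogDiffSamples(data=d, pixel_index=np.column_stack([rows, cols]))


def samples_to_csv(samples: LogDiffSamples, path: str | Path) -> None:
    """Dump samples as CSV with columns row, col, dBR, dGR."""
    pd.DataFrame(
        {
            "row": samples.pixel_index[:, 0],
            "col": samples.pixel_index[:, 1],
            "dBR": samples.data[:, 0],
            "dGR": samples.data[:, 1],
        }
    ).to_csv(path, index=False)
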