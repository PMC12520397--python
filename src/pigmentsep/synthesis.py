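"""Column ordering, concentration inversion and pigment image rendering.

Given the estimated 2×2 pigment coefficient matrix V (unit-norm, nonnegative
columns), decide which column is melanin and which is hemoglobin from the
empirical ratio intervals, invert the mixture per pixel over the *full*
original region, and re-render a melanin-only and a hemoglobin-only image
that share the input's red channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .optical_density import RGBImage, channel_differences

__all__ = [
    "OrderedCoefficients",
    "PigmentMaps",
    "MELANIN_RATIO_RANGE",
    "HEMOGLOBIN_RATIO_RANGE",
    "order_columns",
    "concentrations",
    "concentrations_from_samples",
    "render_pigment_images",
]

logger = logging.getLogger(__name__)

# Empirical ratio intervals identifying the melanin column (v21/v11 in
# (1, 6.33]) and the hemoglobin column (v22/v12 in [0.48, 1)).
MELANIN_RATIO_RANGE: tuple[float, float] = (1.0, 6.33)
HEMOGLOBIN_RATIO_RANGE: tuple[float, float] = (0.48, 1.0)


@dataclass
class OrderedCoefficients:
    V_star: np.ndarray  # columns [v_m, v_h]
    ordering_swapped: bool
    ratios: tuple[float, float]  # (v21/v11, v22/v12) of the chosen order


@dataclass
class PigmentMaps:
    c: np.ndarray  # 2×H×W concentrations (melanin, hemoglobin)
    melanin_image: RGBImage
    hemoglobin_image: RGBImage
    clipped: tuple[int, int]  # clip counts (melanin, hemoglobin)


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den != 0 else np.inf


def _ratios(V: np.ndarray) -> tuple[float, float]:
    return _safe_ratio(V[1, 0], V[0, 0]), _safe_ratio(V[1, 1], V[0, 1])


def _conditions_met(r1: float, r2: float) -> bool:
    lo_m, hi_m = MELANIN_RATIO_RANGE
    lo_h, hi_h = HEMOGLOBIN_RATIO_RANGE
    return (lo_m < r1 <= hi_m) and (lo_h <= r2 < hi_h)


def _interval_distance(x: float, lo: float, hi: float) -> float:
    if not np.isfinite(x):
        return np.inf
    if lo <= x <= hi:
        return 0.0
    return min(abs(x - lo), abs(x - hi))


def _misfit(r1: float, r2: float) -> float:
    return _interval_distance(r1, *MELANIN_RATIO_RANGE) + _interval_distance(
        r2, *HEMOGLOBIN_RATIO_RANGE
    )


def order_columns(V: np.ndarray) -> OrderedCoefficients:
    """Order V's columns as [melanin, hemoglobin] via the ratio intervals.

    Keep the order if v21/v11 ∈ (1, 6.33] and v22/v12 ∈ [0.48, 1); otherwise
    swap.  If neither arrangement satisfies both conditions, keep the one
    whose ratios are closest to the intervals and log a warning.  A zero
    denominator counts as a condition failure, not an error.
    """
    V = np.asarray(V, dtype=float)
    swapped = V[:, ::-1]
    r_keep = _ratios(V)
    r_swap = _ratios(swapped)
    if _conditions_met(*r_keep):
        return OrderedCoefficients(V_star=V, ordering_swapped=False, ratios=r_keep)
    if _conditions_met(*r_swap):
        return OrderedCoefficients(V_star=swapped, ordering_swapped=True, ratios=r_swap)
    logger.warning(
        "neither column order satisfies the ratio conditions "
        "(as-is %s, swapped %s); keeping the closer order", r_keep, r_swap
    )
    if _misfit(*r_keep) <= _misfit(*r_swap):
        return OrderedCoefficients(V_star=V, ordering_swapped=False, ratios=r_keep)
    return OrderedCoefficients(V_star=swapped, ordering_swapped=True, ratios=r_swap)


def concentrations_from_samples(V_star: np.ndarray, H_mat: np.ndarray) -> np.ndarray:
    """Solve c = (V*)^{-1} H for each sample row of H (n×2) → 2×n."""
    if abs(np.linalg.det(V_star)) < 1e-10:
        raise np.linalg.LinAlgError("V* is numerically singular")
    return np.linalg.solve(V_star, H_mat.T)


def concentrations(V_star: np.ndarray, image: RGBImage) -> np.ndarray:
    """Per-pixel concentrations c = (V*)^{-1} H over the full original region.

    H is the (ln B − ln R, ln G − ln R) observation of the original image;
    the baseline-illumination offset Ē is taken as 0.  Returns a 2×H×W array
    (melanin, hemoglobin).
    """
    Hpx, Wpx = image.shape
    Hm = channel_differences(image).data
    c = concentrations_from_samples(V_star, Hm)
    return c.reshape(2, Hpx, Wpx)


def render_pigment_images(V_star: np.ndarray, c: np.ndarray, image: RGBImage) -> PigmentMaps:
    """Render melanin-only and hemoglobin-only images.

    The B and G channels of the melanin image are
    exp(V*·diag(1,0)·c + (ln R, ln R)) per pixel — the first row of V* feeds
    the B channel and the second the G channel, matching the (B−R, G−R)
    observation ordering; the hemoglobin image uses diag(0,1).  The R channel
    is copied bit-identically from the input.  Values above 1 are clipped to
    1 with the clip count logged.
    """
    Hpx, Wpx = image.shape
    c2 = c.reshape(2, -1)
    ln_r = np.log(image.pixels[..., 0]).reshape(-1)
    outputs = []
    clip_counts = []
    for pig in (0, 1):
        sel = np.zeros((2, 2))
        sel[pig, pig] = 1.0
        comp = V_star @ sel @ c2  # rows: (B−R part, G−R part)
        b = np.exp(comp[0] + ln_r)
        g = np.exp(comp[1] + ln_r)
        n_clip = int(np.count_nonzero(b > 1.0) + np.count_nonzero(g > 1.0))
        clip_counts.append(n_clip)
        pix = np.stack(
            [
                image.pixels[..., 0],
                np.minimum(g, 1.0).reshape(Hpx, Wpx),
                np.minimum(b, 1.0).reshape(Hpx, Wpx),
            ],
            axis=-1,
        )
        outputs.append(
            RGBImage(pixels=pix, bit_depth_origin=image.bit_depth_origin, region=image.region)
        )
    total = sum(clip_counts)
    if total:
        logger.info("pigment rendering clipped %d channel values above 1", total)
    return PigmentMaps(
        c=c,
        melanin_image=outputs[0],
        hemoglobin_image=outputs[1],
        clipped=(clip_counts[0], clip_counts[1]),
    )
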