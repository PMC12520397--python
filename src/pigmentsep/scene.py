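"""Synthetic skin forward model.

Renders RGB skin images from the log-linear reflectance model

    log C_i(x, y) = −v_m(i)·c_m − v_h(i)·c_h + log p(x, y) + log Ē_i,

with smooth blob-like melanin/hemoglobin concentration fields c_m, c_h placed
independently at random, a low-frequency shading field log p, per-channel
pigment coefficients v_m(i), v_h(i) (extinction coefficient × mean photon
path length, absorbed into one constant per channel and pigment), and a
per-channel baseline log irradiance.  Camera gain and spectral response are
not modeled separately: only the log-channel differences are observable to
the separation pipeline, and those depend solely on coefficient differences
between channels.

Every scene carries its ground truth, so each downstream stage — channel
differences, sub-block selection, clustering, FastICA, synthesis — can be
validated by round trip.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .optical_density import RGBImage

__all__ = [
    "SyntheticScene",
    "DEFAULT_V_CHANNEL",
    "v_true_from_channels",
    "make_concentration_maps",
    "make_shading_field",
    "make_scene",
    "render_skin_image",
    "capture_image",
    "save_scene",
]

# Per-channel pigment coefficients, rows R, G, B; columns (melanin, hemoglobin).
# Chosen so the derived difference matrix v_true = [[0.3, 1.0], [0.9, 0.7]]
# satisfies the column-ordering ratio intervals (v21/v11 = 3.0 ∈ (1, 6.33],
# v22/v12 = 0.7 ∈ [0.48, 1)), making synthesis ordering deterministic.
DEFAULT_V_CHANNEL = np.array(
    [
        [1.0, 1.2],  # R
        [0.1, 0.5],  # G
        [0.7, 0.2],  # B
    ]
)


def v_true_from_channels(v_channel: np.ndarray) -> np.ndarray:
    """2×2 difference-coefficient matrix: rows (B−R, G−R), columns (m, h).

    Row i of the observable mixing matrix is v(R) − v(channel), because the
    log-channel difference is log C_B − log C_R = [v_m(R) − v_m(B)]·c_m + … .
    """
    v = np.asarray(v_channel, dtype=float)
    return np.array([v[0] - v[2], v[0] - v[1]])


@dataclass
class SyntheticScene:
    """Ground-truth description of one synthetic skin patch."""

    height: int
    width: int
    c_m: np.ndarray  # H×W nonnegative melanin concentration, arbitrary units
    c_h: np.ndarray  # H×W nonnegative hemoglobin concentration
    shading_log: np.ndarray  # H×W log p(x, y)
    v_channel: np.ndarray  # 3×2 per-channel coefficients, rows R, G, B
    e_bar_log: np.ndarray = field(default_factory=lambda: np.zeros(3))
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.c_m < 0) or np.any(self.c_h < 0):
            raise ValueError("concentration fields must be nonnegative")
        if not np.all(np.isfinite(self.shading_log)):
            raise ValueError("shading field must be finite")

    @property
    def v_true(self) -> np.ndarray:
        return v_true_from_channels(self.v_channel)

    @property
    def e_bar_diff(self) -> np.ndarray:
        """Baseline offsets of the (B−R, G−R) observations."""
        return np.array(
            [self.e_bar_log[2] - self.e_bar_log[0], self.e_bar_log[1] - self.e_bar_log[0]]
        )


def _blob_field(
    height: int,
    width: int,
    n_spots: int,
    spot_scale: float,
    base_level: float,
    rng: np.random.Generator,
    widen: float = 1.0,
    amp_scale: float = 1.0,
) -> np.ndarray:
    # multi-scale feature population: sizes log-uniform over [0.7, 4]×scale,
    # amplitudes lognormal (many weak features, few strong) capped at 1 and
    # damped ~1/sqrt(size) so broad patches stay low-contrast
    f = np.full((height, width), float(base_level))
    if n_spots == 0:
        return f
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    for _ in range(n_spots):
        cy = rng.uniform(0, height)
        cx = rng.uniform(0, width)
        mult = np.exp(rng.uniform(np.log(0.7), np.log(4.0)))
        s = spot_scale * widen * mult
        amp = amp_scale * min(rng.lognormal(np.log(0.08), 1.0), 1.0) * mult**-0.5
        f += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * s * s))
    return f


def make_concentration_maps(
    height: int,
    width: int,
    n_spots: int = 200,
    spot_scale: float = 4.0,
    base_level: float = 0.3,
    seed: int | None = None,
    amp_scale: float = 1.0,
    hemoglobin_widen: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth nonnegative melanin and hemoglobin concentration fields.

    Each field is a constant baseline plus ``n_spots`` Gaussian features with
    log-uniform sizes and heavy-tailed amplitudes, emulating diffuse skin
    mottling with occasional focal spots.  Melanin and hemoglobin features
    are drawn from independent RNG streams, so the two fields are
    statistically independent by construction (the assumption ICA relies
    on); hemoglobin features are broader by ``hemoglobin_widen``, mimicking
    diffuse vascular regions versus focal melanin spots.  ``amp_scale``
    scales all feature amplitudes (useful for constructing strongly
    non-Gaussian, well-identified scenes).  With ``n_spots=0`` both maps are
    constant at ``base_level``.
    """
    if height < 16 or width < 16:
        raise ValueError(f"scene must be at least 16×16, got {height}×{width}")
    if n_spots < 0:
        raise ValueError("n_spots must be >= 0")
    child_m, child_h = np.random.SeedSequence(seed).spawn(2)
    c_m = _blob_field(
        height, width, n_spots, spot_scale, base_level,
        np.random.default_rng(child_m), amp_scale=amp_scale,
    )
    c_h = _blob_field(
        height, width, n_spots, spot_scale, base_level,
        np.random.default_rng(child_h), widen=hemoglobin_widen, amp_scale=amp_scale,
    )
    return c_m, c_h


def make_shading_field(
    height: int,
    width: int,
    amplitude: float = 0.3,
    smoothness: float = 32.0,
    seed: int | None = None,
) -> np.ndarray:
    """Low-frequency zero-mean shading field log p(x, y).

    Gaussian-filtered white noise rescaled so the peak-to-peak range equals
    2×``amplitude`` (log units).  ``amplitude=0`` gives the uniform
    illumination case log p ≡ 0.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return np.zeros((height, width))
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.standard_normal((height, width)), sigma=smoothness, mode="reflect")
    f -= f.mean()
    ptp = f.max() - f.min()
    if ptp == 0:
        return np.zeros((height, width))
    f *= 2.0 * amplitude / ptp
    return f - f.mean()


def make_scene(
    height: int,
    width: int,
    n_spots: int = 200,
    spot_scale: float = 4.0,
    base_level: float = 0.3,
    shading_amplitude: float = 0.3,
    shading_smoothness: float = 32.0,
    amp_scale: float = 1.0,
    v_channel: np.ndarray | None = None,
    e_bar_log: np.ndarray | None = None,
    seed: int | None = None,
) -> SyntheticScene:
    """Assemble a full synthetic scene from one seed."""
    ss = np.random.SeedSequence(seed)
    seed_maps, seed_shading = (int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(2))
    c_m, c_h = make_concentration_maps(
        height, width, n_spots=n_spots, spot_scale=spot_scale, base_level=base_level,
        seed=seed_maps, amp_scale=amp_scale,
    )
    shading = make_shading_field(
        height, width, amplitude=shading_amplitude, smoothness=shading_smoothness, seed=seed_shading
    )
    return SyntheticScene(
        height=height,
        width=width,
        c_m=c_m,
        c_h=c_h,
        shading_log=shading,
        v_channel=DEFAULT_V_CHANNEL.copy() if v_channel is None else np.asarray(v_channel, float),
        e_bar_log=np.zeros(3) if e_bar_log is None else np.asarray(e_bar_log, float),
        seed=seed,
    )


def render_skin_image(scene: SyntheticScene) -> RGBImage:
    """Render the scene to an RGB image with intensities in (0, 1].

    Channel i is exp(−v_m(i)·c_m − v_h(i)·c_h + log p + log Ē_i), then all
    three channels are multiplied by a single recorded global factor bringing
    the maximum to 1.  A global factor adds the same constant to every log
    channel and therefore leaves the (B−R, G−R) observables unchanged.
    """
    v = scene.v_channel
    log_im = (
        -v[None, None, :, 0] * scene.c_m[..., None]
        - v[None, None, :, 1] * scene.c_h[..., None]
        + scene.shading_log[..., None]
        + scene.e_bar_log[None, None, :]
    )
    im = np.exp(log_im)
    factor = 1.0 / im.max()
    im = im * factor
    if im.max() - im.min() < 1e-12:
        warnings.warn("rendered image has degenerate (constant) dynamic range", stacklevel=2)
    return RGBImage(pixels=im, bit_depth_origin=16, meta={"rescale_factor": factor})


def capture_image(
    image: RGBImage,
    bit_depth: int = 8,
    noise_sigma: float = 0.005,
    seed: int | None = None,
) -> RGBImage:
    """Emulate camera acquisition of a rendered image.

    Adds zero-mean Gaussian sensor noise (``noise_sigma`` in units of full
    scale; the default 0.005 is ≈1.3 LSB at 8 bits), quantizes to
    ``bit_depth`` bits and re-normalizes to (0, 1] with zeros clamped to half
    a code value — the same normalization :func:`load_image` applies to
    files.  In log space the quantization/noise floor is largest for dark
    pixels, which is what makes shadowed, weakly pigmented regions the least
    reliable input for separation.
    """
    max_code = 2**bit_depth - 1
    rng = np.random.default_rng(seed)
    px = image.pixels + rng.normal(0.0, noise_sigma, image.pixels.shape)
    px = np.clip(np.round(px * max_code), 0, max_code) / max_code
    px = np.maximum(px, 1.0 / (2.0 * max_code))
    meta = dict(image.meta)
    meta.update(bit_depth=bit_depth, noise_sigma=noise_sigma, capture_seed=seed)
    return RGBImage(pixels=px, bit_depth_origin=bit_depth, region=image.region, meta=meta)


def save_scene(scene: SyntheticScene, outdir: str | Path, image: RGBImage | None = None) -> dict:
    """Write image (16-bit PNG), ground-truth maps (float32 TIFF) and a JSON
    sidecar with the rendering constants.  Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if image is None:
        image = render_skin_image(scene)
    paths = {
        "image": outdir / "skin.png",
        "image16": outdir / "skin_16bit.tif",
        "c_m": outdir / "c_m.tif",
        "c_h": outdir / "c_h.tif",
        "shading": outdir / "shading_log.tif",
        "meta": outdir / "scene.json",
    }
    # 8-bit PNG for viewing; 16-bit TIFF keeps the full dynamic range
    png8 = np.clip(np.round(image.pixels * 255), 1, 255).astype(np.uint8)
    iio.imwrite(paths["image"], png8)
    tif16 = np.clip(np.round(image.pixels * 65535), 1, 65535).astype(np.uint16)
    tifffile.imwrite(paths["image16"], tif16, photometric="rgb")
    tifffile.imwrite(paths["c_m"], scene.c_m.astype(np.float32))
    tifffile.imwrite(paths["c_h"], scene.c_h.astype(np.float32))
    tifffile.imwrite(paths["shading"], scene.shading_log.astype(np.float32))
    meta = {
        "height": scene.height,
        "width": scene.width,
        "v_channel": scene.v_channel.tolist(),
        "v_true": scene.v_true.tolist(),
        "e_bar_log": scene.e_bar_log.tolist(),
        "seed": scene.seed,
        "rescale_factor": image.meta.get("rescale_factor"),
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}
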