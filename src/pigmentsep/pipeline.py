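"""End-to-end separation pipeline and its evaluation protocols.

Three method variants share the optical-density front end:

* ``plain_dlica`` — channel differences of the whole region straight into
  FastICA (the unfiltered baseline);
* ``subblock_only`` — sub-block selection before FastICA;
* ``subblock_plus_cluster`` — sub-block selection, then local clustering and
  per-cluster feature sampling of the whitened data (the full method).

Whatever subset feeds FastICA, the pigment images are always synthesized
over the full original region using the estimated coefficient matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import cluster, sample_feature_points
from .config import PipelineConfig
from .fastica import DegenerateInputError, SeparationResult, center, coefficient_matrix, \
    fastica_unmix, whiten
from .optical_density import LogDiffSamples, RGBImage, channel_differences
from .subblocks import partition_blocks, score_blocks, select_blocks
from .synthesis import OrderedCoefficients, PigmentMaps, concentrations, order_columns, \
    render_pigment_images

__all__ = [
    "VARIANTS",
    "SeparationRun",
    "benchmark_suite",
    "run_separation",
    "convergence_rate",
    "sensitivity_sweep",
]

logger = logging.getLogger(__name__)

VARIANTS = ("plain_dlica", "subblock_only", "subblock_plus_cluster")


@dataclass
class SeparationRun:
    result: SeparationResult
    ordered: OrderedCoefficients | None  # None when FastICA failed to converge
    maps: PigmentMaps | None  # withheld on non-convergence
    info: dict


def _derive_seed(master: int | None, *key: int) -> int:
    """Stable per-run seed below 2^31 derived from a master seed and a key."""
    entropy = [0 if master is None else int(master), *key]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] & 0x7FFFFFFF)


def benchmark_suite(
    n_scenes: int = 5,
    height: int = 300,
    width: int = 300,
    shading_amplitude: float = 0.3,
    seed: int = 0,
    scene_seeds: list[int] | None = None,
    bit_depth: int = 8,
    noise_sigma: float = 0.005,
) -> list[RGBImage]:
    """Synthetic evaluation suite: default-texture scenes rendered through the
    camera-capture model (quantization + sensor noise).

    Scene content is controlled by ``scene_seeds`` (default 1..n_scenes, so the
    suite is comparable across runs); the capture noise derives from ``seed``.
    """
    from .scene import capture_image, make_scene, render_skin_image

    if scene_seeds is None:
        scene_seeds = list(range(1, n_scenes + 1))
    return [
        capture_image(
            render_skin_image(
                make_scene(height, width, shading_amplitude=shading_amplitude, seed=s)
            ),
            bit_depth=bit_depth,
            noise_sigma=noise_sigma,
            seed=_derive_seed(seed, 100 + i),
        )
        for i, s in enumerate(scene_seeds)
    ]


def _ica_input_stream(image: RGBImage, config: PipelineConfig, variant: str) -> LogDiffSamples:
    """The variant's sample stream entering the whitening/ICA stage."""
    samples = channel_differences(image)
    if variant == "plain_dlica":
        return samples
    shape = image.shape
    origins = partition_blocks(shape, config.q)
    scores = score_blocks(samples, shape, origins, config.q)
    return select_blocks(samples, shape, scores, config.q, config.fraction).samples


def run_separation(
    image: RGBImage,
    config: PipelineConfig | None = None,
    variant: str = "subblock_plus_cluster",
    seed: int | None = None,
) -> SeparationRun:
    """Run the full flow on one image: channel differences, optional sub-block
    selection, centering/whitening, optional clustering + feature sampling,
    FastICA, column ordering and pigment synthesis.

    On FastICA non-convergence the pigment outputs are withheld (``maps`` and
    ``ordered`` are None) and the failure is recorded in ``info``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    config = (config or PipelineConfig()).validated()
    stream = _ica_input_stream(image, config, variant)
    Xc, mean = center(stream.data)
    wh = whiten(Xc, mean)
    info: dict = {
        "variant": variant,
        "config": config,
        "n_region_pixels": image.shape[0] * image.shape[1],
        "n_ica_input": len(stream),
        "seed": seed,
    }
    if variant == "subblock_plus_cluster":
        state = cluster(wh.Z, k=config.k, r=config.r, max_iter=config.cluster_max_iter,
                        change_tol=config.cluster_tol)
        fs = sample_feature_points(wh.Z, state, m=config.m, seed=_derive_seed(seed, 0))
        Z_in = fs.points
        info.update(cluster_iterations=state.iteration,
                    cluster_converged=state.converged,
                    n_feature_points=len(fs.points))
    else:
        Z_in = wh.Z
    W, converged, iters = fastica_unmix(
        Z_in, tol=config.ica_tol, max_iter=config.ica_max_iter, seed=_derive_seed(seed, 1)
    )
    V = coefficient_matrix(W, wh)
    result = SeparationResult(W=W, V=V, converged=converged,
                              iterations_per_component=iters, seed=seed)
    info["ica_iterations"] = iters
    if not converged:
        logger.warning("FastICA did not converge (%s); pigment outputs withheld", variant)
        return SeparationRun(result=result, ordered=None, maps=None, info=info)
    ordered = order_columns(V)
    c = concentrations(ordered.V_star, image)
    maps = render_pigment_images(ordered.V_star, c, image)
    return SeparationRun(result=result, ordered=ordered, maps=maps, info=info)


def convergence_rate(
    images: list[RGBImage],
    input_sizes: list[int] = (4000, 8000, 12000, 16000, 20000),
    repeats: int = 20,
    variants: tuple[str, ...] = VARIANTS,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Success convergence rate per (scene, variant, input size).

    "Input size" is the number of samples entering the FastICA stage before
    clustering; it is realized as a contiguous raster prefix of the variant's
    sample stream (selection happens first, then subsampling).  Each repeat
    re-runs the fixed-point iteration with a fresh seeded initialization and
    counts as a success when all unmixing vectors converge.  Sizes exceeding
    a stream are skipped with a warning.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    config = (config or PipelineConfig()).validated()
    rows = []
    for img_idx, image in enumerate(images):
        for variant in variants:
            stream = _ica_input_stream(image, config, variant).data
            for size in input_sizes:
                if size > stream.shape[0]:
                    warnings.warn(
                        f"input size {size} exceeds the {variant} stream "
                        f"({stream.shape[0]} samples); skipped", stacklevel=2)
                    continue
                Xc, mean = center(stream[:size])
                try:
                    wh = whiten(Xc, mean)
                except DegenerateInputError:
                    # the subsample is too uniform to whiten: every repeat of
                    # this cell fails before the fixed-point iteration starts
                    rows.append({
                        "scene": img_idx, "variant": variant, "input_size": size,
                        "repeats": repeats, "successes": 0, "rate": 0.0,
                        "seed": seed, "degenerate": True,
                    })
                    continue
                state = None
                if variant == "subblock_plus_cluster":
                    state = cluster(wh.Z, k=config.k, r=config.r,
                                    max_iter=config.cluster_max_iter,
                                    change_tol=config.cluster_tol)
                successes = 0
                for rep in range(repeats):
                    # each repeat re-runs the stochastic tail of the method:
                    # per-cluster feature sampling and the FastICA init
                    if state is not None:
                        fs = sample_feature_points(
                            wh.Z, state, m=config.m,
                            seed=_derive_seed(seed, img_idx, size, 1 + rep, 7))
                        Z_in = fs.points
                    else:
                        Z_in = wh.Z
                    run_seed = _derive_seed(seed, img_idx, size, 1 + rep,
                                            VARIANTS.index(variant))
                    _, converged, _ = fastica_unmix(
                        Z_in, tol=config.ica_tol, max_iter=config.ica_max_iter, seed=run_seed)
                    successes += int(converged)
                rows.append({
                    "scene": img_idx,
                    "variant": variant,
                    "input_size": size,
                    "repeats": repeats,
                    "successes": successes,
                    "rate": successes / repeats,
                    "seed": seed,
                    "degenerate": False,
                })
    return pd.DataFrame(rows)


def sensitivity_sweep(
    parameter: str,
    values: list,
    images: list[RGBImage],
    repeats: int = 10,
    seed: int = 0,
    config: PipelineConfig | None = None,
    variant: str = "subblock_plus_cluster",
) -> pd.DataFrame:
    """Convergence rate while varying one of q, k or fraction, the other two
    held at their defaults.  Each value is evaluated per scene over
    ``repeats`` seeded FastICA runs on the scene's full sample stream."""
    if parameter not in {"q", "k", "fraction"}:
        raise ValueError(f"parameter must be one of q, k, fraction; got {parameter!r}")
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    base = config or PipelineConfig()
    rows = []
    for value in values:
        if parameter == "q" and (int(value) != value or value < 1):
            raise ValueError(f"invalid q={value}")
        if parameter == "k" and (int(value) != value or value < 1):
            raise ValueError(f"invalid k={value}")
        if parameter == "fraction" and not 0 < value <= 1:
            raise ValueError(f"invalid fraction={value}")
        cfg = base.replace(**{parameter: int(value) if parameter in ("q", "k") else float(value)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # sweeps deliberately leave the ranges
            cfg = cfg.validated()
            for img_idx, image in enumerate(images):
                stream = _ica_input_stream(image, cfg, variant).data
                Xc, mean = center(stream)
                wh = whiten(Xc, mean)
                state = None
                if variant == "subblock_plus_cluster":
                    k_eff = min(cfg.k, wh.Z.shape[0])
                    state = cluster(wh.Z, k=k_eff, r=cfg.r, max_iter=cfg.cluster_max_iter,
                                    change_tol=cfg.cluster_tol)
                successes = 0
                for rep in range(repeats):
                    if state is not None:
                        fs = sample_feature_points(wh.Z, state, m=cfg.m,
                                                   seed=_derive_seed(seed, img_idx, 1 + rep, 7))
                        Z_in = fs.points
                    else:
                        Z_in = wh.Z
                    run_seed = _derive_seed(seed, img_idx, 1 + rep)
                    _, converged, _ = fastica_unmix(
                        Z_in, tol=cfg.ica_tol, max_iter=cfg.ica_max_iter, seed=run_seed)
                    successes += int(converged)
                rows.append({
                    "parameter": parameter,
                    "value": value,
                    "scene": img_idx,
                    "repeats": repeats,
                    "successes": successes,
                    "rate": successes / repeats,
                    "seed": seed,
                })
    return pd.DataFrame(rows)
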