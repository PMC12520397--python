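"""Sub-block scoring and selection.

Uniformly shaded or near-gray regions carry small log-channel differences,
so any shading estimation error there leaks into the separated pigment maps.
Scoring q×q tiles by the sum of absolute mean channel differences and keeping
only the top fraction discards those shadow-dominated tiles before ICA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .optical_density import LogDiffSamples

__all__ = [
    "BlockScore",
    "SelectionResult",
    "partition_blocks",
    "block_score_values",
    "score_blocks",
    "select_blocks",
    "scores_to_csv",
]


@dataclass
class BlockScore:
    block_id: int
    block_origin: tuple[int, int]
    d_bar_BR: float
    d_bar_GR: float
    d_BGR: float


@dataclass
class SelectionResult:
    selected_block_ids: list[int]
    samples: LogDiffSamples
    fraction: float
    q: int


def partition_blocks(region_shape: tuple[int, int], q: int) -> list[tuple[int, int]]:
    """Origins (row, col) of non-overlapping q×q tiles in raster order.

    Partial tiles at the right/bottom borders are discarded, so the count is
    ``(H//q) * (W//q)``.
    """
    H, W = region_shape
    if q < 1:
        raise ValueError(f"block size q must be >= 1, got {q}")
    if q > min(H, W):
        raise ValueError(f"block size q={q} exceeds region shape {region_shape}")
    return [(r * q, c * q) for r in range(H // q) for c in range(W // q)]


def block_score_values(dbr: np.ndarray, dgr: np.ndarray) -> tuple[float, float, float]:
    """Mean channel differences over one block and their absolute sum."""
    d_bar_br = float(np.mean(dbr))
    d_bar_gr = float(np.mean(dgr))
    return d_bar_br, d_bar_gr, abs(d_bar_br) + abs(d_bar_gr)


def score_blocks(
    samples: LogDiffSamples,
    region_shape: tuple[int, int],
    origins: list[tuple[int, int]],
    q: int,
) -> list[BlockScore]:
    """Score every block: d̄_{B−R}, d̄_{G−R} and d_{B,G−R} = |d̄_{B−R}| + |d̄_{G−R}|.

    ``samples`` must be the full-region raster-order log differences.
    """
    H, W = region_shape
    D = samples.data.reshape(H, W, 2)
    scores = []
    for bid, (r, c) in enumerate(origins):
        block = D[r : r + q, c : c + q]
        d_bar_br, d_bar_gr, d_bgr = block_score_values(block[..., 0], block[..., 1])
        scores.append(BlockScore(bid, (r, c), d_bar_br, d_bar_gr, d_bgr))
    return scores


def select_blocks(
    samples: LogDiffSamples,
    region_shape: tuple[int, int],
    scores: list[BlockScore],
    q: int,
    fraction: float,
) -> SelectionResult:
    """Retain the ``ceil(fraction * N)`` blocks with largest d_{B,G−R}.

    Ties are broken toward lower block id (raster order).  The retained
    samples are concatenated in selected-block raster order, raster order
    within each block.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_blocks = len(scores)
    n_sel = math.ceil(fraction * n_blocks)
    if n_sel < 1:
        raise ValueError("selection fraction retains zero blocks")
    d = np.array([s.d_BGR for s in scores])
    order = np.argsort(-d, kind="stable")  # stable: ties keep raster order
    selected = sorted(int(i) for i in order[:n_sel])

    H, W = region_shape
    D = samples.data.reshape(H, W, 2)
    data_parts, index_parts = [], []
    for bid in selected:
        r, c = scores[bid].block_origin
        data_parts.append(D[r : r + q, c : c + q].reshape(-1, 2))
        rr, cc = np.meshgrid(np.arange(r, r + q), np.arange(c, c + q), indexing="ij")
        index_parts.append(np.column_stack([rr.ravel(), cc.ravel()]))
    out = LogDiffSamples(
        data=np.concatenate(data_parts, axis=0),
        pixel_index=np.concatenate(index_parts, axis=0),
    )
    return SelectionResult(selected_block_ids=selected, samples=out, fraction=fraction, q=q)


def scores_to_csv(scores: list[BlockScore], selected_ids: list[int], path) -> None:
    sel = set(selected_ids)
    pd.DataFrame(
        {
            "block_id": [s.block_id for s in scores],
            "row": [s.block_origin[0] for s in scores],
            "col": [s.block_origin[1] for s in scores],
            "d_bar_BR": [s.d_bar_BR for s in scores],
            "d_bar_GR": [s.d_bar_GR for s in scores],
            "d_BGR": [s.d_BGR for s in scores],
            "selected": [s.block_id in sel for s in scores],
        }
    ).to_csv(path, index=False)
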