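"""Pipeline configuration with the empirically recommended defaults."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Stage parameters for the separation pipeline.

    Defaults follow the recommended operating point: 5×5 sub-blocks with the
    top 25% retained, k=1200 cluster centers with a ±2 center search window,
    m=3 feature points per cluster, and a 1e-6 fixed-point tolerance with a
    200-iteration budget.
    """

    q: int = 5  # sub-block side, pixels
    fraction: float = 0.25  # retained sub-block fraction
    k: int = 1200  # cluster centers
    r: int = 2  # neighbor search radius, center-index units
    m: int = 3  # feature points per cluster
    cluster_max_iter: int = 100
    cluster_tol: float = 0.01  # label-change fraction defining convergence
    ica_tol: float = 1e-6
    ica_max_iter: int = 200

    def validated(self) -> "PipelineConfig":
        """Raise on invalid values; warn outside the recommended ranges."""
        if self.q < 1:
            raise ValueError(f"q must be >= 1, got {self.q}")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.m < 1 or self.r < 0:
            raise ValueError("m must be >= 1 and r >= 0")
        if not 3 <= self.q <= 8:
            warnings.warn(f"sub-block size q={self.q} outside the recommended range [3, 8]",
                          stacklevel=2)
        if not 0.2 <= self.fraction <= 0.3:
            warnings.warn(
                f"selection fraction {self.fraction} outside the recommended range [0.2, 0.3]",
                stacklevel=2)
        if not 900 <= self.k <= 1500:
            warnings.warn(f"cluster count k={self.k} outside the recommended range [900, 1500]",
                          stacklevel=2)
        return self

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a nested mapping with subblock/cluster/ica sections."""
        sub = d.get("subblock", {})
        clu = d.get("cluster", {})
        ica = d.get("ica", {})
        defaults = cls()
        return cls(
            q=int(sub.get("q", defaults.q)),
            fraction=float(sub.get("fraction", defaults.fraction)),
            k=int(clu.get("k", defaults.k)),
            r=int(clu.get("r", defaults.r)),
            m=int(clu.get("m", defaults.m)),
            cluster_max_iter=int(clu.get("max_iter", defaults.cluster_max_iter)),
            cluster_tol=float(clu.get("tol", defaults.cluster_tol)),
            ica_tol=float(ica.get("tol", defaults.ica_tol)),
            ica_max_iter=int(ica.get("max_iter", defaults.ica_max_iter)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
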