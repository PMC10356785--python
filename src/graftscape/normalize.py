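"""Per-region Z-score normalization of marker intensities.

Mean fluorescence intensities are standardized within each staining region
(z = (x - mean) / sd per region x marker) and the resulting Z-scores are
trimmed to a fixed range (default [0, 5]) so that extreme outliers cannot
dominate downstream clustering.  Degenerate regions (a single cell, or a
marker with zero spread) yield z = 0 for that region x marker: the cells
stay usable and the marker is simply uninformative there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NormalizationConfig", "normalize_mfi", "z_columns"]

Z_SUFFIX = "_z"


@dataclass
class NormalizationConfig:
    """Trim bounds and grouping for MFI normalization."""

    lower: float = 0.0
    upper: float = 5.0
    group_key: str = "region_id"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("trim lower bound must be < upper bound")


def z_columns(markers: list[str]) -> list[str]:
    """Column names holding trimmed Z-scores for ``markers``."""
    return [m + Z_SUFFIX for m in markers]


def normalize_mfi(
    cells: pd.DataFrame,
    markers: list[str],
    cfg: NormalizationConfig | None = None,
) -> pd.DataFrame:
    """Append trimmed per-region Z-score columns for every marker.

    Returns a copy of ``cells`` with one ``<marker>_z`` column per marker.
    Z-scores use the sample standard deviation (ddof=1) within each group
    defined by ``cfg.group_key`` and are clipped to ``[cfg.lower, cfg.upper]``.
    """
    cfg = cfg or NormalizationConfig()
    missing = [m for m in markers if m not in cells.columns]
    if missing:
        raise KeyError(f"missing marker columns: {missing}")
    if cfg.group_key not in cells.columns:
        raise KeyError(f"missing grouping column {cfg.group_key!r}")

    out = cells.copy()
    values = out[markers].to_numpy(dtype=float)
    zs = np.zeros_like(values)
    for _, idx in out.groupby(cfg.group_key, sort=False).indices.items():
        block = values[idx]
        if len(idx) < 2:
            warnings.warn("region with a single cell: Z-scores set to 0")
            continue
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        safe = sd > 0
        z = np.zeros_like(block)
        z[:, safe] = (block[:, safe] - mean[safe]) / sd[safe]
        zs[idx] = z
    zs = np.clip(zs, cfg.lower, cfg.upper)
    for j, m in enumerate(markers):
        out[m + Z_SUFFIX] = zs[:, j]
    return out
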