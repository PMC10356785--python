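"""Stratified proportional random sampling of cells across samples.

Clustering is run on a subset of cells drawn proportionally to each
sample's share of the full dataset: the real-valued quota for sample i is
``S_i = S * N_i / M`` with ``M = sum(N_i)``.  Quotas are rounded with the
largest-remainder (Hamilton) method so that the rounded quotas still sum
to S exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SamplingPlan", "largest_remainder", "stratified_sample"]


@dataclass
class SamplingPlan:
    """Record of a stratified sampling draw.

    Attributes
    ----------
    total : int
        S, the total number of cells requested.
    sizes : dict
        N_i, cells available per sample.
    quotas : dict
        S_i, integer cells drawn per sample (sum to S exactly).
    seed : int or None
        Seed of the random draw.
    """

    total: int
    sizes: dict = field(default_factory=dict)
    quotas: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sizes)

    @property
    def pool_size(self) -> int:
        return int(sum(self.sizes.values()))


def largest_remainder(real_quotas: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative real quotas to integers summing to ``total``.

    Floors every quota, then hands the remaining units to the largest
    fractional remainders; remainder ties are broken by index order.
    """
    real_quotas = np.asarray(real_quotas, dtype=float)
    if np.any(real_quotas < 0):
        raise ValueError("quotas must be non-negative")
    floors = np.floor(real_quotas).astype(int)
    leftover = int(round(total - floors.sum()))
    if leftover < 0:
        raise ValueError("total smaller than sum of quota floors")
    remainders = real_quotas - floors
    # stable sort on -remainder keeps index order among ties
    order = np.argsort(-remainders, kind="stable")
    out = floors.copy()
    out[order[:leftover]] += 1
    return out


def stratified_sample(
    cells: pd.DataFrame,
    total: int,
    seed: int | None = None,
    group_key: str = "sample_id",
) -> tuple[pd.DataFrame, SamplingPlan]:
    """Draw ``total`` cells without replacement, proportionally per sample.

    Parameters
    ----------
    cells : DataFrame
        One row per cell; must contain ``group_key``.
    total : int
        S, number of cells to draw.  Must not exceed the pool size M.
    seed : int, optional
        Seed for the per-sample draws.
    group_key : str
        Column defining the strata (default: sample id).

    Returns
    -------
    (subset, plan)
        Subset keeps the original index; the plan records N_i and S_i.
    """
    if group_key not in cells.columns:
        raise KeyError(f"missing column {group_key!r}")
    sizes = cells.groupby(group_key, sort=True).size()
    nonempty = sizes[sizes > 0]
    if len(nonempty) < len(sizes):
        warnings.warn("empty samples skipped in stratified sampling")
        sizes = nonempty
    pool = int(sizes.sum())
    if total > pool:
        raise ValueError(f"requested S={total} exceeds pool M={pool}")
    real = total * sizes.to_numpy(dtype=float) / pool
    quotas = largest_remainder(real, total)
    plan = SamplingPlan(
        total=int(total),
        sizes={k: int(v) for k, v in sizes.items()},
        quotas={k: int(q) for k, q in zip(sizes.index, quotas)},
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    picks = []
    for key, quota in zip(sizes.index, quotas):
        idx = cells.index[cells[group_key] == key].to_numpy()
        if quota >= len(idx):
            picks.append(idx)
        else:
            picks.append(rng.choice(idx, size=quota, replace=False))
    chosen = np.concatenate(picks) if picks else np.array([], dtype=int)
    return cells.loc[chosen], plan
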