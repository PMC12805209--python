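"""Deletion-based balancing of unbalanced two-level data.

The estimator's derivations assume equal group sizes.  For unbalanced input,
groups larger than the minimum size are trimmed by seeded random deletion so
the same rows are removed on every run with the same seed.  If more than a
threshold fraction (default 20%) of the rows would have to be deleted, the
procedure aborts with a warning instead, since the remaining data may no
longer represent the original sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import BalanceAbortedError, DegenerateGroupError
from .model import GroupedData

__all__ = ["BalanceReport", "balance_data"]


@dataclass(frozen=True)
class BalanceReport:
    """What balancing did (or would have done)."""

    original_sizes: tuple
    target_size: int
    rows_removed: int
    fraction_removed: float
    threshold: float
    seed: Optional[int]
    aborted: bool


def balance_data(data: GroupedData, threshold: float = 0.2,
                 seed: Optional[int] = None
                 ) -> tuple[GroupedData, BalanceReport]:
    """Trim every group to the minimum group size by seeded random deletion.

    Groups already at the minimum size are never touched.  Raises
    :class:`BalanceAbortedError` (carrying the report) when the deletion
    fraction exceeds ``threshold``.
    """
    idx = data.group_index
    sizes = np.bincount(idx)
    if len(sizes) < 2:
        raise DegenerateGroupError("need at least 2 groups to balance")
    if np.any(sizes == 0):
        raise DegenerateGroupError("empty group encountered")
    target = int(sizes.min())
    total = int(sizes.sum())
    removed = total - target * len(sizes)
    fraction = removed / total
    aborted = fraction > threshold
    report = BalanceReport(original_sizes=tuple(int(s) for s in sizes),
                           target_size=target, rows_removed=removed,
                           fraction_removed=fraction, threshold=threshold,
                           seed=seed, aborted=aborted)
    if aborted:
        raise BalanceAbortedError(
            f"balancing would delete {removed}/{total} rows "
            f"({fraction:.1%}) > threshold {threshold:.0%}", report)
    if removed == 0:
        return data, report

    rng = np.random.default_rng(seed)
    keep = np.ones(len(idx), dtype=bool)
    for j, size in enumerate(sizes):
        if size > target:
            members = np.flatnonzero(idx == j)
            drop = rng.choice(members, size=size - target, replace=False)
            keep[drop] = False
    balanced = GroupedData(x=data.x[keep], y=data.y[keep],
                           group=data.group[keep])
    return balanced, report
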