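"""Three-way segmentation consensus: the IoU decomposition.

For three binary masks A1, A2, A3 on one grid, the union is partitioned by
membership multiplicity: iou3 is the fraction of the union covered by all
three masks, iou2 the fraction covered by exactly two, and iou1 the fraction
covered by exactly one, so iou3 + iou2 + iou1 = 1 identically.  Areas are
pixel counts (pixel spacing cancels in the ratios).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .synthetic_cohort import BinaryMask

__all__ = ["IoUDecomposition", "decompose_triplet", "mean_decomposition"]


@dataclass(frozen=True)
class IoUDecomposition:
    iou3: float
    iou2: float
    iou1: float

    def __post_init__(self):
        total = self.iou3 + self.iou2 + self.iou1
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"components must sum to 1, got {total!r}")
        for v in (self.iou3, self.iou2, self.iou1):
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError("components must lie in [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.iou3, self.iou2, self.iou1)


def _as_grid(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.grid
    return np.asarray(mask, dtype=bool)


def decompose_triplet(*masks) -> IoUDecomposition:
    """Decompose the union of three masks by agreement multiplicity.

    Accepts a single sequence of three masks or three mask arguments; each may
    be a :class:`BinaryMask` or a boolean array.  Invariant under permutation
    of the three masks.
    """
    if len(masks) == 1:
        masks = tuple(masks[0])
    if len(masks) != 3:
        raise ValueError("exactly three masks are required")
    grids = [_as_grid(m) for m in masks]
    shape = grids[0].shape
    if any(g.shape != shape for g in grids[1:]):
        raise ValueError("masks must share one grid shape")
    multiplicity = grids[0].astype(np.int8) + grids[1] + grids[2]
    union = int((multiplicity > 0).sum())
    if union == 0:
        raise ValueError("union of the three masks is empty; no ROI to assess")
    n3 = int((multiplicity == 3).sum())
    n2 = int((multiplicity == 2).sum())
    iou3 = n3 / union
    iou2 = n2 / union
    return IoUDecomposition(iou3=iou3, iou2=iou2, iou1=1.0 - iou2 - iou3)


def mean_decomposition(decompositions: Iterable[IoUDecomposition]) -> IoUDecomposition:
    """Component-wise arithmetic mean over a dataset of decompositions."""
    decs = list(decompositions)
    if not decs:
        raise ValueError("cannot average an empty list of decompositions")
    arr = np.array([d.as_tuple() for d in decs], dtype=float)
    m3, m2, _ = arr.mean(axis=0)
    return IoUDecomposition(iou3=float(m3), iou2=float(m2), iou1=float(1.0 - m3 - m2))
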