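"""Connectivity-based parcellation of the seed region.

Each seed voxel is labeled with the target of maximum connection
probability (winner take all); voxels whose maximum probability falls below
a minimum-probability threshold (default 0.5) are discarded (label 0), on
the grounds that they are more likely connected to regions outside the
target set. Ties break deterministically to the first target in the
configured order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grid import require_aligned
from .tracking import ConnectionProbabilityMap
from .volumes import LabelVolume, MaskVolume, ScalarVolume

logger = logging.getLogger(__name__)

#: default seed-atlas binarisation threshold (25% probability of connection)
DEFAULT_ATLAS_THRESHOLD = 0.25
#: default minimum winning probability below which seed voxels are discarded
DEFAULT_MIN_PROBABILITY = 0.5


def build_seed_mask(
    atlas_probability: ScalarVolume, threshold: float = DEFAULT_ATLAS_THRESHOLD
) -> MaskVolume:
    """Binarize a probabilistic seed atlas at ``threshold`` (inclusive).

    The atlas scale is auto-detected: any value above 1 means the volume is
    in percent and is divided by 100 before thresholding.
    """
    vals = atlas_probability.values
    if vals.min() < 0:
        raise ValueError("atlas probabilities must be non-negative")
    if vals.max() > 1.0:
        if vals.max() > 100.0:
            raise ValueError("atlas values exceed 100; neither [0,1] nor percent scale")
        vals = vals / 100.0
    if threshold > 0:
        mask = vals >= threshold
    else:
        mask = vals > 0  # degenerate threshold: support of the atlas
    if not np.any(mask):
        raise ValueError(f"binarizing at {threshold} produced an empty seed mask")
    return MaskVolume(atlas_probability.grid, mask)


@dataclass
class ParcellationResult:
    """Winner-take-all labels plus the winning-probability map."""

    labels: LabelVolume
    max_probability: ScalarVolume
    threshold_used: float
    target_order: list[int]
    tie_count: int = 0

    def __post_init__(self) -> None:
        labeled = self.labels.values > 0
        if np.any(self.max_probability.values[labeled] < self.threshold_used):
            raise ValueError("labeled voxel with winning probability below the threshold")


def classify_winner_take_all(
    cpm: ConnectionProbabilityMap,
    min_probability: float = DEFAULT_MIN_PROBABILITY,
    target_order: Sequence[int] | None = None,
) -> ParcellationResult:
    """Label each seed voxel with its maximum-probability target.

    ``target_order`` (default: the map's own target order) is the
    tie-break precedence: among tied maxima the earliest target wins.
    Voxels whose winning probability is below ``min_probability`` are
    discarded to label 0; the threshold applies to the per-voxel maximum,
    not to each target independently.
    """
    if not 0.0 <= min_probability <= 1.0:
        raise ValueError("min_probability must be in [0, 1]")
    order = list(target_order) if target_order is not None else list(cpm.targets)
    if sorted(order) != sorted(cpm.targets):
        raise ValueError("target_order must be a permutation of the map's targets")
    col = [cpm.targets.index(t) for t in order]
    probs = cpm.probabilities[:, col]  # columns in precedence order

    win_col = np.argmax(probs, axis=1)  # first max wins -> tie-break by order
    win_p = probs[np.arange(len(probs)), win_col]
    ties = int(np.sum((probs == win_p[:, None]).sum(axis=1) > 1))
    if ties:
        logger.info("winner-take-all: %d voxels had tied maxima (first in order wins)", ties)

    labels = np.zeros(cpm.grid.dims, dtype=np.int32)
    maxp = np.zeros(cpm.grid.dims)
    keep = win_p >= min_probability
    idx = tuple(cpm.seed_voxels.T)
    winner = np.asarray(order)[win_col]
    lab_flat = np.where(keep, winner, 0)
    labels[idx] = lab_flat
    maxp[idx] = win_p
    table = {t: cpm.target_names[cpm.targets.index(t)] for t in order}
    return ParcellationResult(
        labels=LabelVolume(cpm.grid, labels, table),
        max_probability=ScalarVolume(cpm.grid, maxp),
        threshold_used=min_probability,
        target_order=order,
        tie_count=ties,
    )


def parcellation_dice(
    result: ParcellationResult, truth: LabelVolume
) -> dict[int, float]:
    """Per-label Dice overlap between a parcellation and ground truth.

    ``Dice(t) = 2 |A_t & B_t| / (|A_t| + |B_t|)``. Labels absent from both
    volumes are omitted from the result.
    """
    require_aligned(result.labels.grid, truth.grid, "parcellation and truth")
    out: dict[int, float] = {}
    labels = sorted(set(result.labels.labels_present()) | set(truth.labels_present()))
    a = result.labels.values
    b = truth.values
    for t in labels:
        at = a == t
        bt = b == t
        denom = int(at.sum()) + int(bt.sum())
        out[t] = 2.0 * int((at & bt).sum()) / denom if denom else float("nan")
    return out
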