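"""Lesion-disconnection mapping: superimpose normalized lesion masks on the
connectivity parcellation and report, per lesion, the percentage of its
voxels falling in each target-connected subregion.

The percent denominator is the whole lesion — including voxels outside the
seed structure — so the per-target percentages plus the unassigned share
always sum to 100, while individual target rows typically do not (lesions
extend beyond frontally-connected tissue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid, require_aligned
from .parcellation import ParcellationResult
from .template import AffineTransform
from .volumes import MaskVolume

logger = logging.getLogger(__name__)


def warp_lesion_mask(
    mask: MaskVolume, transform: AffineTransform, target_grid: VolumeGrid
) -> MaskVolume:
    """Resample a binary lesion mask onto the template grid.

    Nearest-neighbour pull-back through the inverse transform keeps the
    output strictly binary. An empty result is legal (a small lesion can
    fall between voxel centres under resampling) but is logged.
    """
    centers = target_grid.voxel_centers_world()
    src_vox = np.rint(mask.grid.world_to_voxel(transform.inverse.apply(centers))).astype(int)
    inside = np.all((src_vox >= 0) & (src_vox < np.asarray(mask.grid.dims)), axis=-1)
    out = np.zeros(target_grid.dims, dtype=bool)
    idx = src_vox[inside]
    out[inside] = mask.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    if not np.any(out):
        logger.warning("warped lesion mask is empty on the target grid")
    return MaskVolume(target_grid, out)


@dataclass
class OverlapReport:
    """Per-lesion overlap with the connectivity-defined subregions.

    ``target_percents`` maps target name -> percent of lesion voxels
    carrying that label; ``unassigned_percent`` covers label-0 voxels
    (discarded seed voxels and everything outside the seed mask). The
    percents sum to 100 exactly.
    """

    lesion_id: str
    lesion_volume_mm3: float
    target_percents: dict[str, float]
    unassigned_percent: float

    def __post_init__(self) -> None:
        vals = list(self.target_percents.values()) + [self.unassigned_percent]
        if any(v < 0 or v > 100 for v in vals):
            raise ValueError("percentages must lie in [0, 100]")
        if abs(sum(vals) - 100.0) > 1e-9:
            raise ValueError(f"percentages sum to {sum(vals)!r}, expected 100")


def compute_overlap_report(
    lesion: MaskVolume, parcellation: ParcellationResult, lesion_id: str
) -> OverlapReport:
    """Percent overlap of one lesion with each target-connected subregion."""
    labels = parcellation.labels
    require_aligned(lesion.grid, labels.grid, "lesion and parcellation")
    n = lesion.n_true
    if n == 0:
        raise ValueError("empty lesion mask")
    lab = labels.values[lesion.values]
    percents: dict[str, float] = {}
    assigned = 0
    for t in parcellation.target_order:
        count = int(np.sum(lab == t))
        assigned += count
        percents[labels.label_table[t]] = 100.0 * count / n
    unassigned = 100.0 * (n - assigned) / n
    return OverlapReport(
        lesion_id=lesion_id,
        lesion_volume_mm3=lesion.volume_mm3,
        target_percents=percents,
        unassigned_percent=unassigned,
    )


def format_report_tsv(reports: list[OverlapReport]) -> str:
    """Render overlap reports as TSV, one row per lesion.

    Columns: lesion id, volume in mm^3, one percent column per target (in
    the shared configured order), then the unassigned percent. Percentages
    print with one decimal place; volumes with one decimal place.
    """
    if not reports:
        raise ValueError("no reports to format")
    targets = list(reports[0].target_percents)
    for r in reports[1:]:
        if list(r.target_percents) != targets:
            raise ValueError("inconsistent target sets across reports")
    if not targets:
        raise ValueError("reports carry an empty target list")
    header = ["lesion_id", "lesion_volume_mm3"] + [f"{t}_percent" for t in targets] + [
        "unassigned_percent"
    ]
    lines = ["\t".join(header)]
    for r in reports:
        row = [r.lesion_id, f"{r.lesion_volume_mm3:.1f}"]
        row += [f"{r.target_percents[t]:.1f}" for t in targets]
        row.append(f"{r.unassigned_percent:.1f}")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def reports_to_json_dict(reports: list[OverlapReport]) -> dict:
    """Full-precision JSON-serialisable form of the overlap reports."""
    return {
        "lesions": [
            {
                "lesion_id": r.lesion_id,
                "lesion_volume_mm3": r.lesion_volume_mm3,
                "target_percents": dict(r.target_percents),
                "unassigned_percent": r.unassigned_percent,
            }
            for r in reports
        ]
    }
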