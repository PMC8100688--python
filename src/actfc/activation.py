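"""Activated-voxel masks from z-scored component maps.

A voxel counts as activated for a subject when |z| passes the threshold in
at least one retained component (union rule; a stricter minimum number of
components is configurable). Group masks are the intersection over
subjects, and the cross-group common mask is the intersection of the two
group masks — the voxel set on which functional connectivity is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("actfc.activation")

__all__ = ["ActivationMask", "subject_mask", "group_common", "cross_group_common"]

LEVELS = ("subject", "group", "common")


@dataclass
class ActivationMask:
    """A set of activated voxels, identified by canonical linear indices."""

    level: str
    voxels: np.ndarray
    threshold: float = 2.0
    provenance: list[str] = field(default_factory=list)
    universe: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        self.voxels = np.unique(np.asarray(self.voxels, dtype=np.int64))

    def __len__(self) -> int:
        return int(self.voxels.size)

    def jaccard(self, other) -> float:
        a = np.asarray(getattr(other, "voxels", other), dtype=np.int64)
        union = np.union1d(self.voxels, a).size
        if union == 0:
            return 1.0
        return np.intersect1d(self.voxels, a).size / union


def subject_mask(
    components,
    voxel_lin: np.ndarray,
    z_threshold: float = 2.0,
    min_components: int = 1,
    universe: tuple[int, int, int] | None = None,
) -> ActivationMask:
    """Threshold a subject's z-scored maps into an activation mask.

    ``voxel_lin`` maps map columns to canonical linear voxel indices.
    A voxel is activated when |z| >= z_threshold in at least
    ``min_components`` of the retained components.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    maps = np.asarray(components.spatial_maps, dtype=np.float64)
    voxel_lin = np.asarray(voxel_lin, dtype=np.int64)
    if maps.shape[1] != voxel_lin.size:
        raise ValueError("spatial maps and voxel index disagree on V")
    hits = (np.abs(maps) >= z_threshold).sum(axis=0)
    active = voxel_lin[hits >= min_components]
    if active.size == 0:
        logger.info("subject mask empty at |z| >= %g", z_threshold)
    return ActivationMask(
        level="subject",
        voxels=active,
        threshold=z_threshold,
        provenance=[getattr(components, "subject_id", "")],
        universe=universe,
    )


def group_common(
    masks: list[ActivationMask], min_subject_fraction: float = 1.0
) -> ActivationMask:
    """Voxels activated in (a fraction of) all subjects of a group.

    The default ``min_subject_fraction=1.0`` is the strict intersection over
    every subject; lower values keep voxels present in at least that
    fraction of subjects.
    """
    if not masks:
        raise ValueError("need at least one subject mask")
    universes = {m.universe for m in masks}
    if len(universes) > 1:
        raise ValueError(f"mixed voxel universes: {universes}")
    if not (0.0 < min_subject_fraction <= 1.0):
        raise ValueError("min_subject_fraction must lie in (0, 1]")
    need = int(np.ceil(min_subject_fraction * len(masks)))
    allvox = np.concatenate([m.voxels for m in masks])
    vox, cnt = np.unique(allvox, return_counts=True)
    common = vox[cnt >= need]
    prov = [p for m in masks for p in m.provenance]
    return ActivationMask(
        level="group",
        voxels=common,
        threshold=masks[0].threshold,
        provenance=prov,
        universe=masks[0].universe,
    )


def cross_group_common(mask_a: ActivationMask, mask_b: ActivationMask) -> ActivationMask:
    """Voxels activated in both groups: the FC analysis universe."""
    if mask_a.universe != mask_b.universe:
        raise ValueError("group masks live on different voxel universes")
    return ActivationMask(
        level="common",
        voxels=np.intersect1d(mask_a.voxels, mask_b.voxels),
        threshold=mask_a.threshold,
        provenance=mask_a.provenance + mask_b.provenance,
        universe=mask_a.universe,
    )
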