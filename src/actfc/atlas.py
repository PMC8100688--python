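"""Region localization of voxel sets against an integer-labelled atlas.

Accepts any AAL-style parcellation: an integer label volume (0 =
background) plus a label -> name table, so a genuine atlas NIfTI and its
TSV can be dropped in without code changes. Reports activated-voxel counts
and ratios per region under the strict ">10 voxels and >1% of the region"
filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("actfc.atlas")

__all__ = ["Atlas", "RegionActivationRow", "region_table", "rows_to_frame"]


@dataclass
class Atlas:
    """Integer-labelled parcellation plus the affine used for reporting.

    ``label_volume`` holds one integer label per voxel (0 = background);
    ``affine`` maps voxel indices to reporting (mm-like) coordinates.
    """

    label_volume: np.ndarray
    names: dict[int, str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label_volume must be 3-D")
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValueError("label_volume must be integer-typed")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        present = set(np.unique(self.label_volume).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.label_volume.shape

    @property
    def labels_flat(self) -> np.ndarray:
        """Labels in canonical linear-voxel order (x fastest)."""
        return np.asarray(self.label_volume).ravel(order="F")

    @property
    def sizes(self) -> dict[int, int]:
        lab, cnt = np.unique(self.label_volume, return_counts=True)
        return {int(l): int(c) for l, c in zip(lab, cnt) if l != 0}

    @property
    def foreground_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels_flat != 0)

    def voxel_coords(self, linear: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.grid_shape
        linear = np.asarray(linear, dtype=np.int64)
        x = linear % nx
        y = (linear // nx) % ny
        z = linear // (nx * ny)
        return np.column_stack([x, y, z])

    def to_world(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
        hom = np.column_stack([coords, np.ones(len(coords))])
        return (self.affine @ hom.T).T[:, :3]

    # ---- IO -------------------------------------------------------------
    def to_files(self, nifti_path: str | Path, names_path: str | Path) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(self.label_volume.astype(np.int32), self.affine)
        nib.save(img, str(nifti_path))
        pd.DataFrame(
            {"label": list(self.names), "name": list(self.names.values())}
        ).to_csv(names_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, nifti_path: str | Path, names_path: str | Path) -> "Atlas":
        import nibabel as nib

        img = nib.load(str(nifti_path))
        vol = np.asarray(img.dataobj).astype(np.int32)
        tab = pd.read_csv(names_path, sep="\t")
        names = {int(r.label): str(r.name) for r in tab.itertuples(index=False)}
        return cls(label_volume=vol, names=names, affine=np.asarray(img.affine))


@dataclass
class RegionActivationRow:
    """One row of a region report: how much of a region a voxel set covers."""

    region: str
    label: int
    centroid: tuple[float, float, float]
    count: int
    ratio: float


def region_table(
    mask,
    atlas: Atlas,
    min_count: int = 10,
    min_ratio: float = 0.01,
) -> list[RegionActivationRow]:
    """Per-region counts of mask voxels under the strict region filter.

    A region is reported only when its mask-voxel count is strictly greater
    than ``min_count`` AND the count/region-size ratio strictly exceeds
    ``min_ratio``. The centroid is the affine-transformed mean coordinate of
    the region's mask voxels. Mask voxels falling on background (label 0)
    are excluded and summarized in a log message.
    """
    voxels = np.asarray(getattr(mask, "voxels", mask), dtype=np.int64)
    labels = atlas.labels_flat
    if voxels.size and voxels.max() >= labels.size:
        raise ValueError("mask voxel index outside the atlas grid")
    vox_labels = labels[voxels] if voxels.size else np.array([], dtype=labels.dtype)
    n_bg = int(np.sum(vox_labels == 0))
    if n_bg:
        logger.info("region_table: %d mask voxel(s) on background excluded", n_bg)
    sizes = atlas.sizes
    rows: list[RegionActivationRow] = []
    for label in sorted(sizes):
        sel = voxels[vox_labels == label]
        count = int(sel.size)
        ratio = count / sizes[label]
        if count > min_count and ratio > min_ratio:
            centroid = atlas.to_world(atlas.voxel_coords(sel).mean(axis=0))[0]
            rows.append(
                RegionActivationRow(
                    region=atlas.names[label],
                    label=label,
                    centroid=tuple(float(c) for c in centroid),
                    count=count,
                    ratio=ratio,
                )
            )
    return rows


def rows_to_frame(rows: list[RegionActivationRow]) -> pd.DataFrame:
    """Tabular (TSV-ready) form of a region report."""
    return pd.DataFrame(
        {
            "region": [r.region for r in rows],
            "x": [r.centroid[0] for r in rows],
            "y": [r.centroid[1] for r in rows],
            "z": [r.centroid[2] for r in rows],
            "count": [r.count for r in rows],
            "ratio": [round(r.ratio, 6) for r in rows],
        }
    )
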