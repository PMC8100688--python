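"""NIfTI and sidecar IO in the canonical voxel order.

All volumes use the same convention: grid axes (x, y, z), canonical linear
voxel index x-fastest (Fortran ravel), TR stored in the NIfTI header time
zoom. Masks and ground truth are JSON with sorted linear indices so every
artifact is diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .activation import ActivationMask
from .preprocess import BoldRun

__all__ = [
    "write_bold_run",
    "read_bold_run",
    "write_mask",
    "read_mask",
    "write_components",
]


def write_bold_run(run: BoldRun, path: str | Path) -> None:
    """Write a run as 4D NIfTI (full grid; voxels outside the run are 0)."""
    nx, ny, nz = run.grid_shape
    vol = np.zeros((nx, ny, nz, run.n_volumes), dtype=np.float64, order="F")
    flat = vol.reshape(nx * ny * nz, run.n_volumes, order="F")  # view (F-contiguous)
    flat[run.linear_index] = run.data
    img = nib.Nifti1Image(vol, np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr_seconds))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_bold_run(
    path: str | Path,
    subject_id: str = "",
    group_id: str = "",
    voxel_subset: np.ndarray | None = None,
) -> BoldRun:
    """Read a 4D NIfTI as a BoldRun (all grid voxels, canonical order)."""
    img = nib.load(str(path))
    data4 = np.asarray(img.dataobj, dtype=np.float64)
    if data4.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data4.ndim}D")
    nx, ny, nz, t = data4.shape
    flat = data4.reshape(nx * ny * nz, t, order="F")
    lin = (
        np.arange(nx * ny * nz, dtype=np.int64)
        if voxel_subset is None
        else np.asarray(voxel_subset, dtype=np.int64)
    )
    x = lin % nx
    y = (lin // nx) % ny
    z = lin // (nx * ny)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return BoldRun(
        data=flat[lin],
        voxel_index=np.column_stack([x, y, z]),
        tr_seconds=tr,
        subject_id=subject_id,
        group_id=group_id,
        grid_shape=(nx, ny, nz),
    )


def write_mask(mask: ActivationMask, json_path: str | Path,
               nifti_path: str | Path | None = None) -> None:
    payload = {
        "level": mask.level,
        "threshold": mask.threshold,
        "voxels": mask.voxels.tolist(),
        "provenance": mask.provenance,
        "universe": list(mask.universe) if mask.universe else None,
    }
    Path(json_path).write_text(json.dumps(payload, sort_keys=True))
    if nifti_path is not None and mask.universe is not None:
        nx, ny, nz = mask.universe
        flat = np.zeros(nx * ny * nz, dtype=np.uint8)
        flat[mask.voxels] = 1
        nib.save(nib.Nifti1Image(flat.reshape((nx, ny, nz), order="F"), np.eye(4)),
                 str(nifti_path))


def read_mask(json_path: str | Path) -> ActivationMask:
    payload = json.loads(Path(json_path).read_text())
    return ActivationMask(
        level=payload["level"],
        voxels=np.asarray(payload["voxels"], dtype=np.int64),
        threshold=payload["threshold"],
        provenance=payload["provenance"],
        universe=tuple(payload["universe"]) if payload["universe"] else None,
    )


def write_components(components, grid_shape, voxel_lin, nifti_path, json_path) -> None:
    """Component maps as 4D NIfTI (component axis last) + metadata JSON."""
    nx, ny, nz = grid_shape
    k = components.n_components
    vol = np.zeros((nx, ny, nz, k), order="F")
    flat = vol.reshape(nx * ny * nz, k, order="F")  # view (F-contiguous)
    flat[np.asarray(voxel_lin)] = components.spatial_maps.T
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(nifti_path))
    Path(json_path).write_text(json.dumps({
        "subject_id": components.subject_id,
        "order_estimate": int(components.order_estimate),
        "stability_index": components.stability_index.tolist(),
        "seed": int(components.seed),
        "converged": bool(components.converged),
    }, sort_keys=True))
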