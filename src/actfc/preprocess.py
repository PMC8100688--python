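"""Temporal preprocessing of voxel x time BOLD matrices.

Covers the steps that apply to already-registered data: dropping initial
volumes (magnetization equilibrium), linear detrending, nuisance regression,
and zero-phase band-pass filtering. Spatial steps (slice timing, motion
correction, normalization, smoothing) require raw scanner data and are out
of scope; synthetic runs are generated already registered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger("actfc.preprocess")

__all__ = [
    "BoldRun",
    "linear_indices",
    "drop_initial_volumes",
    "detrend",
    "bandpass",
    "bandpass_timeseries",
    "regress_nuisance",
    "default_pipeline",
]


def linear_indices(coords: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Canonical linear voxel index: x fastest, then y, then z."""
    coords = np.asarray(coords, dtype=np.int64)
    nx, ny, _ = grid_shape
    return coords[:, 0] + nx * (coords[:, 1] + ny * coords[:, 2])


@dataclass
class BoldRun:
    """One subject's BOLD run as a voxel x time matrix.

    Parameters
    ----------
    data : ndarray, shape (V, T)
        One row per voxel, one column per volume.
    voxel_index : ndarray, shape (V, 3)
        Integer grid coordinates of each row. Rows must be unique and sorted
        by canonical linear index (x fastest) — the single voxel order every
        downstream module relies on.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    """

    data: np.ndarray
    voxel_index: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    group_id: str = ""
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.int64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D voxel x time matrix")
        v, t = self.data.shape
        if v < 2 or t < 2:
            raise ValueError(f"need at least 2 voxels and 2 timepoints, got {v}x{t}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.voxel_index.shape != (v, 3):
            raise ValueError("voxel_index must have shape (V, 3)")
        if self.grid_shape is None:
            self.grid_shape = tuple(int(m) + 1 for m in self.voxel_index.max(axis=0))
        lin = linear_indices(self.voxel_index, self.grid_shape)
        if len(np.unique(lin)) != v:
            raise ValueError("voxel_index entries must be unique")
        if not np.all(np.diff(lin) > 0):
            raise ValueError("voxels must be sorted by canonical linear index")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def linear_index(self) -> np.ndarray:
        return linear_indices(self.voxel_index, self.grid_shape)

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=np.asarray(data, dtype=np.float64))


def drop_initial_volumes(run: BoldRun, n_drop: int) -> BoldRun:
    """Remove the first `n_drop` volumes (magnetization-equilibrium discard)."""
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if n_drop >= run.n_volumes:
        raise ValueError(
            f"cannot drop {n_drop} volumes from a run with {run.n_volumes}"
        )
    if n_drop == 0:
        return run
    return run.with_data(run.data[:, n_drop:])


def detrend(run: BoldRun) -> BoldRun:
    """Remove each voxel's least-squares linear trend (and mean)."""
    if run.n_volumes < 3:
        raise ValueError("detrending needs at least 3 timepoints")
    return run.with_data(signal.detrend(run.data, axis=1, type="linear"))


def bandpass_timeseries(
    x: np.ndarray, fs: float, low_hz: float, high_hz: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Forward-backward (``sosfiltfilt``) filtering of a Butterworth design of
    the given order: no phase distortion, effective magnitude response is the
    square of the single-pass response (pass-band loss < 1 dB, stop-band
    attenuation > 20 dB within one octave of the cut-offs).
    """
    nyq = fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid: need 0 < low < high < "
            f"Nyquist = {nyq:g} Hz at sampling rate {fs:g} Hz"
        )
    sos = signal.butter(order, [low_hz / nyq, high_hz / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def bandpass(run: BoldRun, low_hz: float, high_hz: float, order: int = 4) -> BoldRun:
    """Band-pass every voxel's time series with a zero-phase filter."""
    fs = 1.0 / run.tr_seconds
    return run.with_data(bandpass_timeseries(run.data, fs, low_hz, high_hz, order))


def regress_nuisance(run: BoldRun, covariates: np.ndarray | None) -> BoldRun:
    """Regress nuisance covariates out of every voxel's time series.

    A column of ones (intercept) is always included, so residuals are
    mean-centred. Rank-deficient covariate matrices are repaired by dropping
    linearly dependent columns, with a logged warning.
    """
    t = run.n_volumes
    if covariates is None or np.size(covariates) == 0:
        design = np.ones((t, 1))
    else:
        covariates = np.asarray(covariates, dtype=np.float64)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != t:
            raise ValueError(
                f"covariates have {covariates.shape[0]} rows but run has {t} volumes"
            )
        if covariates.shape[1] >= t:
            raise ValueError("need fewer covariates than timepoints")
        if not np.all(np.isfinite(covariates)):
            raise ValueError("covariates contain non-finite values")
        design = np.column_stack([np.ones(t), covariates])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # greedy left-to-right column selection keeps an independent subset
            kept = [0]
            for j in range(1, design.shape[1]):
                trial = design[:, kept + [j]]
                if np.linalg.matrix_rank(trial) > len(kept):
                    kept.append(j)
            logger.warning(
                "covariate matrix rank-deficient: dropped %d dependent column(s)",
                design.shape[1] - len(kept),
            )
            design = design[:, kept]
    beta, *_ = np.linalg.lstsq(design, run.data.T, rcond=None)
    resid = run.data.T - design @ beta
    return run.with_data(resid.T)


def default_pipeline(
    run: BoldRun,
    n_drop: int = 10,
    band: tuple[float, float] = (0.01, 0.08),
    covariates: np.ndarray | str | None = "global_mean",
) -> BoldRun:
    """Default order: drop -> detrend -> nuisance -> band-pass.

    ``covariates="global_mean"`` regresses the whole-volume mean signal, the
    only nuisance trace that exists for synthetic data.
    """
    run = drop_initial_volumes(run, n_drop)
    run = detrend(run)
    if isinstance(covariates, str):
        if covariates != "global_mean":
            raise ValueError(f"unknown covariate preset {covariates!r}")
        covariates = run.data.mean(axis=0)[:, None]
    run = regress_nuisance(run, covariates)
    return bandpass(run, band[0], band[1])
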