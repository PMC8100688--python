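"""Voxel-level functional connectivity and edge-wise group testing.

Per subject, the FC feature vector holds the Pearson correlation of every
unordered pair of common activated voxels, in a canonical lexicographic
edge order shared across subjects. Group differences are assessed edge by
edge with a two-sample t test and Benjamini-Hochberg FDR correction; the
surviving edges (DFCs) are summarised as counts per unordered atlas region
pair and as the set of voxels incident to at least one significant edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activation import ActivationMask
from .atlas import Atlas, RegionActivationRow, region_table
from .preprocess import BoldRun

logger = logging.getLogger("actfc.fc")

__all__ = ["FcFeatures", "DfcResult", "fc_matrix", "edgewise_test", "dfc_region_summary"]


@dataclass
class FcFeatures:
    """One subject's FC values over the canonical edge list.

    ``edge_index`` is the (E, 2) array of unordered voxel pairs (linear
    indices, first < second) ordered lexicographically; ``values`` the
    matching Pearson correlations.
    """

    subject_id: str
    group_id: str
    edge_index: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.edge_index.shape != (self.values.size, 2):
            raise ValueError("edge_index and values disagree on edge count")


@dataclass
class DfcResult:
    """Edge-wise test results and the significant (DFC) edge set."""

    edge_index: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    significant: np.ndarray
    alpha: float
    region_pair_counts: dict[tuple[int, int], int] | None = None
    dfc_voxels: ActivationMask | None = None

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def fc_matrix(run: BoldRun, mask: ActivationMask) -> FcFeatures:
    """Pearson FC of every unordered pair of mask voxels.

    Constant time series yield r = 0 for all their edges (logged), so a
    flat voxel never spuriously drives group statistics.
    """
    vox = np.asarray(mask.voxels, dtype=np.int64)
    if vox.size < 2:
        raise ValueError("mask must contain at least 2 voxels")
    if run.n_volumes < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    lin = run.linear_index
    pos = np.searchsorted(lin, vox)
    if pos.max() >= lin.size or not np.array_equal(lin[pos], vox):
        raise ValueError("mask voxels missing from the run")
    sub = run.data[pos]
    sd = sub.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d constant voxel series; their correlations set to 0", flat.sum())
        sub = sub.copy()
        sub[flat] = 0.0
        sub[flat, 0] = 1.0  # placeholder variance; rows zeroed below
    r = np.corrcoef(sub)
    if flat.any():
        r[flat, :] = 0.0
        r[:, flat] = 0.0
    iu, ju = np.triu_indices(vox.size, k=1)
    edges = np.column_stack([vox[iu], vox[ju]])
    return FcFeatures(
        subject_id=run.subject_id,
        group_id=run.group_id,
        edge_index=edges,
        values=np.clip(r[iu, ju], -1.0, 1.0),
    )


def _stack(group: list[FcFeatures], edge_index: np.ndarray) -> np.ndarray:
    for f in group:
        if not np.array_equal(f.edge_index, edge_index):
            raise ValueError(f"subject {f.subject_id}: edge index differs")
    return np.vstack([f.values for f in group])


def edgewise_test(
    group_a: list[FcFeatures],
    group_b: list[FcFeatures],
    alpha: float = 0.05,
    welch: bool = False,
    fisher_z: bool = False,
    fdr_method: str = "fdr_bh",
) -> DfcResult:
    """Two-sample t test per edge with FDR correction over all edges.

    The default is the pooled-variance (Student) t statistic on raw
    correlations; ``welch=True`` drops the equal-variance assumption and
    ``fisher_z=True`` applies the variance-stabilising atanh transform
    first. Edges with zero variance in both groups are assigned p = 1.
    The significant set is Benjamini-Hochberg (or ``fdr_by``) step-up at
    q <= alpha.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    edge_index = group_a[0].edge_index
    a = _stack(group_a, edge_index)
    b = _stack(group_b, edge_index)
    if fisher_z:
        a = np.arctanh(np.clip(a, -1 + 1e-12, 1 - 1e-12))
        b = np.arctanh(np.clip(b, -1 + 1e-12, 1 - 1e-12))
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-variance edges
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    bad = ~np.isfinite(p)
    if bad.any():
        logger.warning("%d edge(s) with zero variance in both groups: p set to 1", bad.sum())
        t = np.where(bad, 0.0, t)
        p = np.where(bad, 1.0, p)
    reject, q, *_ = multipletests(p, alpha=alpha, method=fdr_method)
    return DfcResult(
        edge_index=edge_index,
        t_stat=np.asarray(t),
        p_value=np.asarray(p),
        q_value=np.asarray(q),
        significant=np.asarray(reject),
        alpha=alpha,
    )


def dfc_region_summary(
    dfc: DfcResult,
    atlas: Atlas,
    min_count: int = 10,
    min_ratio: float = 0.01,
    universe: tuple[int, int, int] | None = None,
) -> tuple[dict[tuple[int, int], int], list[RegionActivationRow]]:
    """Region-pair counts of significant edges and the DFC-voxel table.

    Counts significant edges per unordered region pair (within-region pairs
    allowed); the voxels touched by at least one significant edge are run
    through :func:`region_table` with the same strict filter. Results are
    also stored on ``dfc``.
    """
    labels = atlas.labels_flat
    sig_edges = dfc.edge_index[dfc.significant]
    counts: dict[tuple[int, int], int] = {}
    for a, b in sig_edges:
        la, lb = int(labels[a]), int(labels[b])
        key = (min(la, lb), max(la, lb))
        counts[key] = counts.get(key, 0) + 1
    vox = np.unique(sig_edges.ravel()) if sig_edges.size else np.array([], dtype=np.int64)
    dfc_mask = ActivationMask(level="common", voxels=vox, universe=universe)
    rows = region_table(dfc_mask, atlas, min_count=min_count, min_ratio=min_ratio)
    dfc.region_pair_counts = counts
    dfc.dfc_voxels = dfc_mask
    return counts, rows
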