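"""Per-subject spatial ICA with MDL order estimation and stability selection.

Spatial ICA treats the spatial maps as the independent sources and the
timecourses as mixing weights: the voxel x time matrix X is modelled as
X = S A^T with S (V x K) sparse spatial sources and A (T x K) timecourses.
The number of components K is estimated by the classic minimum description
length criterion on the eigenvalues of the temporal covariance, and the
decomposition is stabilised ICASSO-style: FastICA is run repeatedly from
different initialisations, the pooled maps are clustered by absolute
spatial correlation, and each cluster's centrotype is returned with a
stability index.

MDL assumes white (i.i.d.) noise, which temporal band-pass filtering
destroys, so the pipeline estimates the order on the pre-filter series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .preprocess import BoldRun

logger = logging.getLogger("actfc.ica")

__all__ = ["ComponentSet", "estimate_order_mdl", "fastica_once", "icasso_select"]


@dataclass
class ComponentSet:
    """Stability-selected spatial components of one subject.

    ``spatial_maps`` (K x V) are z-scored over analysis voxels with each
    map's sign oriented so its skewness is non-negative; ``timecourses``
    (T x K) are the matching mixing columns.
    """

    spatial_maps: np.ndarray
    timecourses: np.ndarray
    stability_index: np.ndarray
    order_estimate: int
    seed: int
    subject_id: str = ""
    converged: bool = True

    def __post_init__(self) -> None:
        self.spatial_maps = np.asarray(self.spatial_maps, dtype=np.float64)
        self.timecourses = np.asarray(self.timecourses, dtype=np.float64)
        self.stability_index = np.asarray(self.stability_index, dtype=np.float64)

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]


def _zscore_orient(maps: np.ndarray, timecourses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each map over voxels and flip signs to non-negative skewness."""
    maps = maps - maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = maps / sd
    flip = np.where(skew(maps, axis=1) < 0, -1.0, 1.0)
    return maps * flip[:, None], timecourses * flip[None, :]


def estimate_order_mdl(run: BoldRun) -> int:
    """Number of components by the classic MDL criterion.

    Uses the eigenvalues of the temporal covariance (voxels as samples):
    for each candidate order k the criterion trades the log ratio of the
    geometric to the arithmetic mean of the trailing eigenvalues against a
    free-parameter penalty; the estimate is the argmin, floored at 1.
    """
    v, t = run.data.shape
    if v <= t:
        logger.warning(
            "V=%d <= T=%d: outside the spatial-ICA regime, MDL sample size "
            "is the voxel count regardless", v, t,
        )
    x = run.data - run.data.mean(axis=0, keepdims=True)
    cov = (x.T @ x) / v
    lam = np.linalg.eigvalsh(cov)[::-1]
    lam = np.clip(lam, 0.0, None)
    # restrict to the numerical rank: centring/detrending leaves exact-zero
    # eigenvalues that would otherwise drag the geometric tail mean to zero
    m = int(np.sum(lam > lam[0] * 1e-9))
    if m < 2:
        raise ValueError("data rank < 2: MDL order estimation is degenerate")
    lam = lam[:m]
    p = m
    n = v
    # suffix log-sums / sums for geometric and arithmetic tail means
    crit = np.empty(p - 1)
    logs = np.log(lam)
    for k in range(p - 1):
        tail = p - k
        g = logs[k:].sum() / tail
        a = lam[k:].sum() / tail
        crit[k] = -n * tail * (g - np.log(a)) + 0.5 * k * (2 * p - k + 1) * np.log(n)
    return max(int(np.argmin(crit)), 1)


def fastica_once(run: BoldRun, k: int, seed: int, max_iter: int = 1000,
                 tol: float = 1e-5) -> ComponentSet:
    """One FastICA decomposition at a fixed order and seed.

    PCA-whitening to k dimensions followed by the symmetric (parallel)
    fixed-point iteration with the log-cosh contrast. Non-convergence
    returns the final iterate with a logged warning and ``converged=False``.
    """
    v, t = run.data.shape
    if not (1 <= k <= min(v, t)):
        raise ValueError(f"k={k} out of range for {v}x{t} data")
    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % (2**32),
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(run.data)  # (V, k) spatial maps
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            logger.warning(
                "FastICA did not converge for %s (k=%d, seed=%d); "
                "returning final iterate", run.subject_id, k, seed,
            )
    maps = sources.T                      # (k, V)
    timecourses = ica.mixing_             # (T, k)
    maps, timecourses = _zscore_orient(maps, timecourses)
    return ComponentSet(
        spatial_maps=maps,
        timecourses=timecourses,
        stability_index=np.ones(k),
        order_estimate=k,
        seed=seed,
        subject_id=run.subject_id,
        converged=converged,
    )


def _centrotype(sim: np.ndarray, members: np.ndarray) -> int:
    """Member with maximal total similarity to its cluster."""
    sub = sim[np.ix_(members, members)]
    return int(members[np.argmax(sub.sum(axis=1))])


def icasso_select(
    run: BoldRun, k: int, n_runs: int = 20, seed: int = 0,
    max_iter: int = 1000, tol: float = 1e-5,
) -> ComponentSet:
    """Stability-selected components from repeated FastICA runs.

    Pools the maps of ``n_runs`` decompositions started from distinct
    derived seeds, clusters them by 1 - |spatial correlation| with
    average-linkage agglomeration into k clusters, and returns each
    cluster's centrotype. The stability index of a cluster is its mean
    within-cluster |r| minus the mean |r| between its members and all other
    pooled maps; all-identical runs therefore score 1 minus the
    between-cluster term, and exactly 1 when clusters are orthogonal.
    Components are ordered by decreasing stability. If clustering yields
    fewer than k clusters the component count is reduced with a warning.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    runs_out = [
        fastica_once(run, k, int(s), max_iter=max_iter, tol=tol) for s in child_seeds
    ]
    pooled_maps = np.vstack([r.spatial_maps for r in runs_out])       # (R*k, V)
    pooled_tc = np.hstack([r.timecourses for r in runs_out])          # (T, R*k)
    sim = np.abs(np.corrcoef(pooled_maps))
    np.fill_diagonal(sim, 1.0)
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(z, t=k, criterion="maxclust")
    cluster_ids = np.unique(assign)
    if cluster_ids.size < k:
        logger.warning(
            "%s: only %d stable clusters for k=%d; reducing component count",
            run.subject_id, cluster_ids.size, k,
        )
    n_pool = pooled_maps.shape[0]
    centro, stab = [], []
    for cid in cluster_ids:
        members = np.flatnonzero(assign == cid)
        others = np.flatnonzero(assign != cid)
        if members.size == 1:
            within = 1.0
        else:
            sub = sim[np.ix_(members, members)]
            within = (sub.sum() - members.size) / (members.size * (members.size - 1))
        between = sim[np.ix_(members, others)].mean() if others.size else 0.0
        centro.append(_centrotype(sim, members))
        stab.append(within - between)
    order = np.argsort(stab)[::-1]
    centro = [centro[i] for i in order]
    stab = np.asarray([stab[i] for i in order])
    maps = pooled_maps[centro]
    timecourses = pooled_tc[:, centro]
    maps, timecourses = _zscore_orient(maps, timecourses)
    return ComponentSet(
        spatial_maps=maps,
        timecourses=timecourses,
        stability_index=stab,
        order_estimate=k,
        seed=seed,
        subject_id=run.subject_id,
        converged=all(r.converged for r in runs_out),
    )
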