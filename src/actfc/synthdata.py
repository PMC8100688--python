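"""Synthetic resting-state BOLD generator with known ground truth.

Each group's data follows the same generative view the analysis assumes:
sparse spatial components mixed with band-limited timecourses plus white
noise. Group differences in connectivity are planted on chosen voxel pairs
by replacing part of the two voxels' private noise with a shared latent
signal in one group only, which changes that pair's correlation by a
calibrated amount while leaving every other pairwise correlation (and every
voxel's variance) untouched.

Planted quantities — per-group activation masks, the cross-group common
mask, and the signed correlation deltas of the planted edges — are returned
as :class:`GroundTruth` so every downstream stage can be scored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .atlas import Atlas
from .preprocess import BoldRun, bandpass_timeseries

logger = logging.getLogger("actfc.synthdata")

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "make_toy_atlas",
    "component_layout",
    "simulate_group",
    "simulate_study",
    "max_achievable_delta",
    "plan_edges_between_regions",
]

#: group order is meaningful: edge latents are injected into the second group
DEFAULT_GROUPS = ("A", "B")


@dataclass
class SimulationDesign:
    """Parameters of one synthetic two-group study.

    Defaults are desk-scale study conditions: a 20x20x10 grid partitioned
    into 12 regions, 10 subjects per group, 160 volumes at TR 2.0 s (the
    first 10 are dropped downstream), 8 sparse components, and band-limited
    (0.01-0.08 Hz) source timecourses. ``noise_sigma`` is the white-noise
    standard deviation relative to unit-variance component signals; the
    default 1.0 puts per-voxel signal and noise power on an equal footing.
    """

    grid_shape: tuple[int, int, int] = (20, 20, 10)
    n_regions: int = 12
    subjects_per_group: int = 10
    n_volumes: int = 160
    tr_seconds: float = 2.0
    n_components: int = 8
    activation_fraction: float = 0.12
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    noise_sigma: float = 1.0
    band: tuple[float, float] = (0.01, 0.08)
    seed: int = 0
    group_ids: tuple[str, str] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be 3 positive integers")
        for name in ("n_regions", "subjects_per_group", "n_volumes", "n_components"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not (0.0 < self.activation_fraction < 1.0):
            raise ValueError("activation_fraction must lie in (0, 1)")
        if self.tr_seconds <= 0 or self.noise_sigma <= 0:
            raise ValueError("tr_seconds and noise_sigma must be positive")
        if not (0.0 < self.band[0] < self.band[1] < 0.5 / self.tr_seconds):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.grid_shape
        return nx * ny * nz


@dataclass
class GroundTruth:
    """Planted truth for one simulated study."""

    planted_masks: dict[str, np.ndarray]          # group -> sorted linear indices
    planted_common_mask: np.ndarray               # sorted linear indices
    planted_edge_list: list[tuple[int, int, float]]
    component_maps: dict[str, np.ndarray]         # group -> (K, V_grid) 0/1 maps

    def to_json(self) -> str:
        payload = {
            "planted_masks": {g: m.tolist() for g, m in self.planted_masks.items()},
            "planted_common_mask": self.planted_common_mask.tolist(),
            "planted_edge_list": [[int(a), int(b), float(d)] for a, b, d in self.planted_edge_list],
            "component_supports": {
                g: [np.flatnonzero(row).tolist() for row in maps]
                for g, maps in self.component_maps.items()
            },
        }
        return json.dumps(payload, indent=1)


def max_achievable_delta(noise_sigma: float) -> float:
    """Largest |delta_r| plantable at a given noise level.

    The latent can at most replace all of a voxel's private noise, so
    ``|delta_r| <= sigma^2 / (1 + sigma^2)``.
    """
    s2 = noise_sigma**2
    return s2 / (1.0 + s2)


def make_toy_atlas(design: SimulationDesign) -> Atlas:
    """Deterministic integer-labelled parcellation of the grid.

    Foreground voxels (all voxels of the toy grid) are split into
    ``n_regions`` near-equal contiguous blocks of the canonical linear
    order. With the default design every region holds >= 12 voxels, so the
    downstream ">10 voxels and >1%" region filter can fire both ways.
    """
    v = design.n_voxels
    if design.n_regions > v:
        raise ValueError(
            f"grid with {v} voxels too small for {design.n_regions} regions"
        )
    bounds = np.linspace(0, v, design.n_regions + 1).astype(int)
    labels_flat = np.zeros(v, dtype=np.int32)
    for r in range(design.n_regions):
        labels_flat[bounds[r]:bounds[r + 1]] = r + 1
    nx, ny, nz = design.grid_shape
    label_volume = labels_flat.reshape((nx, ny, nz), order="F")
    names = {r + 1: f"Region_{r + 1:02d}" for r in range(design.n_regions)}
    return Atlas(label_volume=label_volume, names=names, affine=np.eye(4))


def _full_grid_coords(grid_shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = grid_shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    # canonical order: x fastest
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


def component_layout(design: SimulationDesign) -> dict:
    """Seed-determined component supports, exposed so callers can plant edges.

    The first ``n_components - 1`` component supports are shared by both
    groups; the last one is drawn per group (disjoint from everything else),
    so the two groups' activation masks genuinely differ while their
    intersection equals the union of the shared supports. With a single
    component the support is fully shared.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xFACE]))
    v = design.n_voxels
    k = design.n_components
    n_act = max(k, int(round(design.activation_fraction * v)))
    per_comp = n_act // k
    n_shared = k - 1 if k >= 2 else 1
    need = per_comp * (n_shared + 2 * (k - n_shared))
    if need > v:
        raise ValueError("activation_fraction too large for disjoint supports")
    perm = rng.permutation(v)
    pos = 0
    shared: list[np.ndarray] = []
    for _ in range(n_shared):
        shared.append(np.sort(perm[pos:pos + per_comp]))
        pos += per_comp
    unique: dict[str, list[np.ndarray]] = {g: [] for g in design.group_ids}
    for g in design.group_ids:
        for _ in range(k - n_shared):
            unique[g].append(np.sort(perm[pos:pos + per_comp]))
            pos += per_comp
    supports = {g: shared + unique[g] for g in design.group_ids}
    shared_mask = np.sort(np.concatenate(shared)) if shared else np.array([], dtype=np.int64)
    return {"supports": supports, "shared_voxels": shared_mask, "per_component": per_comp}


def plan_edges_between_regions(
    design: SimulationDesign,
    atlas: Atlas,
    region_a: int,
    region_b: int,
    n_edges: int,
    delta_r: float,
) -> list[tuple[int, int, float]]:
    """Choose plantable edges whose endpoints sit in two given atlas regions.

    Edges connect shared-support voxels from *different* components (so the
    baseline correlation is zero and the delta calibrates exactly), one
    endpoint per region, each voxel used at most once.
    """
    layout = component_layout(design)
    labels = atlas.labels_flat
    supports = layout["supports"][design.group_ids[0]]
    n_shared = len(layout["shared_voxels"]) and (
        design.n_components - 1 if design.n_components >= 2 else 1
    )
    shared_supports = supports[:n_shared]
    edges: list[tuple[int, int, float]] = []
    used: set[int] = set()
    for ci in range(len(shared_supports)):
        for cj in range(len(shared_supports)):
            if ci == cj:
                continue
            cand_a = [int(v) for v in shared_supports[ci]
                      if labels[v] == region_a and v not in used]
            cand_b = [int(v) for v in shared_supports[cj]
                      if labels[v] == region_b and v not in used]
            while cand_a and cand_b and len(edges) < n_edges:
                a, b = cand_a.pop(0), cand_b.pop(0)
                if a == b:
                    continue
                edges.append((min(a, b), max(a, b), delta_r))
                used.update((a, b))
            if len(edges) == n_edges:
                return edges
    if len(edges) < n_edges:
        raise ValueError(
            f"only {len(edges)} plantable edges between regions "
            f"{region_a} and {region_b}; requested {n_edges}"
        )
    return edges


def _validate_edges(design: SimulationDesign, layout: dict) -> None:
    shared = set(int(i) for i in layout["shared_voxels"])
    comp_of: dict[int, int] = {}
    for ci, sup in enumerate(layout["supports"][design.group_ids[0]]):
        for vi in sup:
            comp_of[int(vi)] = ci
    dmax = max_achievable_delta(design.noise_sigma)
    seen: set[int] = set()
    for a, b, d in design.planted_edges:
        edge = f"edge ({a}, {b}, delta_r={d})"
        if a == b:
            raise ValueError(f"{edge}: endpoints must differ")
        if a not in shared or b not in shared:
            raise ValueError(
                f"{edge}: both endpoints must lie in the shared (both-group) "
                "activated voxels"
            )
        if comp_of[a] == comp_of[b]:
            raise ValueError(
                f"{edge}: endpoints share a component support, so the baseline "
                "correlation is nonzero and the delta cannot be calibrated"
            )
        if abs(d) >= 1.0:
            raise ValueError(f"{edge}: |delta_r| must be < 1")
        if abs(d) > dmax + 1e-12:
            raise ValueError(
                f"{edge}: unachievable at noise_sigma={design.noise_sigma:g} "
                f"(max |delta_r| = {dmax:.4f})"
            )
        if a in seen or b in seen:
            raise ValueError(f"{edge}: a voxel may anchor at most one planted edge")
        seen.update((a, b))


def _band_limited(rng: np.random.Generator, n: int, t: int, fs: float,
                  band: tuple[float, float]) -> np.ndarray:
    """(n, t) unit-variance band-limited Gaussian timecourses."""
    raw = rng.standard_normal((n, t))
    flt = bandpass_timeseries(raw, fs, band[0], band[1])
    sd = flt.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return flt / sd


def simulate_group(
    design: SimulationDesign, group_id: str
) -> tuple[list[BoldRun], GroundTruth]:
    """Generate all subjects of one group plus the study's ground truth.

    Deterministic in (design, seed): each subject's RNG stream is derived
    from the design seed, the group's position, and the subject index.
    """
    if group_id not in design.group_ids:
        raise ValueError(f"unknown group {group_id!r}; design has {design.group_ids}")
    layout = component_layout(design)
    _validate_edges(design, layout)
    g_idx = design.group_ids.index(group_id)
    v, t = design.n_voxels, design.n_volumes
    fs = 1.0 / design.tr_seconds
    sigma = design.noise_sigma
    coords = _full_grid_coords(design.grid_shape)

    # gamma^2: fraction of private noise variance replaced by the edge latent
    inject = g_idx == 1
    gammas = []
    for a, b, d in design.planted_edges:
        g2 = abs(d) * (1.0 + sigma**2) / sigma**2
        gammas.append((int(a), int(b), np.sign(d), np.sqrt(min(g2, 1.0))))

    supports = layout["supports"][group_id]
    runs: list[BoldRun] = []
    for s in range(design.subjects_per_group):
        rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1 + g_idx, s]))
        sources = _band_limited(rng, design.n_components, t, fs, design.band)
        noise = rng.standard_normal((v, t))
        # like the sources, edge latents are band-limited: a neural
        # connectivity effect lives in the BOLD band and must survive the
        # band-pass stage (a white latent would be mostly filtered away)
        latents = _band_limited(rng, len(gammas), t, fs, design.band)
        data = sigma * noise
        for ci, sup in enumerate(supports):
            data[sup] += sources[ci]
        if inject:
            for (a, b, sign, gamma), lat in zip(gammas, latents):
                keep = np.sqrt(1.0 - gamma**2)
                data[a] += sigma * (gamma * lat - (1.0 - keep) * noise[a])
                data[b] += sigma * (sign * gamma * lat - (1.0 - keep) * noise[b])
        runs.append(
            BoldRun(
                data=data,
                voxel_index=coords,
                tr_seconds=design.tr_seconds,
                subject_id=f"{group_id}{s:02d}",
                group_id=group_id,
                grid_shape=design.grid_shape,
            )
        )

    masks = {
        g: np.sort(np.concatenate(layout["supports"][g]))
        for g in design.group_ids
    }
    common = np.intersect1d(masks[design.group_ids[0]], masks[design.group_ids[1]])
    comp_maps = {}
    for g in design.group_ids:
        maps = np.zeros((design.n_components, v))
        for ci, sup in enumerate(layout["supports"][g]):
            maps[ci, sup] = 1.0
        comp_maps[g] = maps
    truth = GroundTruth(
        planted_masks=masks,
        planted_common_mask=common,
        planted_edge_list=[(int(a), int(b), float(d)) for a, b, d in design.planted_edges],
        component_maps=comp_maps,
    )
    return runs, truth


def simulate_study(design: SimulationDesign) -> tuple[dict[str, list[BoldRun]], GroundTruth]:
    """Both groups of one study; the ground truth is shared."""
    groups: dict[str, list[BoldRun]] = {}
    truth: GroundTruth | None = None
    for g in design.group_ids:
        groups[g], truth = simulate_group(design, g)
    return groups, truth
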