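"""Discrete 3D spine ROIs from the spine probability map.

Two builders are provided. The flood-fill builder seeds at the highest
unvisited probability above a seed threshold and grows a region over
26-neighbors whose probability stays above a fraction ρ of the seed value
and whose physical distance to the seed stays below a cap — so each ROI
is one probability peak. The connected-component builder simply
binarizes the map and takes each 26-connected component as one ROI.

Either way, ROIs then pass acceptance filters: minimum/maximum voxel
count, minimum number of z-planes spanned, and (optionally) a maximum
physical distance to the nearest dendrite voxel. All distances are µm,
computed with the stack's anisotropic voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Roi3D:
    """One spine ROI: voxel indices, centroid and summary statistics."""

    voxels: np.ndarray           # (n, 3) int array of (z, y, x)
    centroid_um: tuple[float, float, float]  # (x, y, z)
    plane_span: int
    mean_prob: float
    max_prob: float

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.size == 0:
            raise ValueError("ROI must contain at least one voxel")
        assert self.plane_span == len(np.unique(self.voxels[:, 0]))

    @property
    def size(self) -> int:
        return len(self.voxels)


class RoiSet(list):
    """An ordered collection of :class:`Roi3D`."""

    def sizes(self) -> np.ndarray:
        return np.array([r.size for r in self])

    def centroids_um(self) -> np.ndarray:
        return np.array([r.centroid_um for r in self]).reshape(-1, 3)


@dataclass
class RoiBuildConfig:
    seed_threshold: float = 0.25
    area_threshold: float = 0.25
    seed_relation: float = 0.5          # ρ: floor = ρ · seed probability
    max_distance_to_seed_um: float = 3.0
    min_roi_size_vox: int = 10
    max_roi_size_vox: int = 10_000
    # at 0.5 µm z-steps a ~1 µm spine head often occupies a single plane of
    # the per-plane prediction maps, so the default does not require a
    # multi-plane span; raise for finer z sampling
    min_planes: int = 1
    max_dist_to_dendrite_um: Optional[float] = None  # None → implicit gating

    def __post_init__(self):
        if not (0 < self.seed_threshold < 1 and 0 < self.area_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if not (0 < self.seed_relation <= 1):
            raise ValueError("seed_relation must be in (0, 1]")
        if self.min_roi_size_vox < 1 or self.max_roi_size_vox < self.min_roi_size_vox:
            raise ValueError("need 1 ≤ min_roi_size_vox ≤ max_roi_size_vox")
        if self.min_planes < 1:
            raise ValueError("min_planes must be ≥ 1")


def _make_roi(voxels: np.ndarray, probs: np.ndarray, voxel_size) -> Roi3D:
    sx, sy, sz = voxel_size
    centroid = (
        float((voxels[:, 2] + 0.5).mean() * sx),
        float((voxels[:, 1] + 0.5).mean() * sy),
        float((voxels[:, 0] + 0.5).mean() * sz),
    )
    return Roi3D(
        voxels=voxels,
        centroid_um=centroid,
        plane_span=int(len(np.unique(voxels[:, 0]))),
        mean_prob=float(probs.mean()),
        max_prob=float(probs.max()),
    )


def flood_fill_rois(spine_map: np.ndarray, config: RoiBuildConfig,
                    voxel_size: tuple[float, float, float]) -> RoiSet:
    """Seeded region growing over the spine probability map.

    Seeds are visited in strictly decreasing probability (ties broken by
    (z, y, x) order, making the result deterministic); each region grows
    over 26-neighbors with probability ≥ ρ·seed and physical distance to
    the seed ≤ the configured cap. Voxels are visited at most once, so
    ROIs are pairwise disjoint.
    """
    prob = np.asarray(spine_map, dtype=np.float64)
    nz, ny, nx = prob.shape
    sx, sy, sz = voxel_size
    visited = np.zeros(prob.shape, dtype=bool)
    candidates = np.argwhere(prob >= config.seed_threshold)
    if candidates.size == 0:
        return RoiSet()
    order = np.lexsort((candidates[:, 2], candidates[:, 1], candidates[:, 0],
                        -prob[tuple(candidates.T)]))
    candidates = candidates[order]

    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)]
    max_d2 = config.max_distance_to_seed_um ** 2
    rois = RoiSet()
    for seed in candidates:
        k0, j0, i0 = (int(v) for v in seed)
        if visited[k0, j0, i0]:
            continue
        seed_p = prob[k0, j0, i0]
        floor = config.seed_relation * seed_p
        region = [(k0, j0, i0)]
        visited[k0, j0, i0] = True
        frontier = [(k0, j0, i0)]
        while frontier:
            k, j, i = frontier.pop()
            for dz, dy, dx in offsets:
                kk, jj, ii = k + dz, j + dy, i + dx
                if not (0 <= kk < nz and 0 <= jj < ny and 0 <= ii < nx):
                    continue
                if visited[kk, jj, ii] or prob[kk, jj, ii] < floor:
                    continue
                d2 = (((ii - i0) * sx) ** 2 + ((jj - j0) * sy) ** 2
                      + ((kk - k0) * sz) ** 2)
                if d2 > max_d2:
                    continue
                visited[kk, jj, ii] = True
                region.append((kk, jj, ii))
                frontier.append((kk, jj, ii))
        vox = np.array(region, dtype=int)
        rois.append(_make_roi(vox, prob[tuple(vox.T)], voxel_size))
    return rois


def connected_component_rois(spine_map: np.ndarray, config: RoiBuildConfig,
                             voxel_size: tuple[float, float, float]) -> RoiSet:
    """Threshold-based 3D connected-component ROIs (26-connectivity)."""
    prob = np.asarray(spine_map, dtype=np.float64)
    mask = prob >= config.area_threshold
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    rois = RoiSet()
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        rois.append(_make_roi(vox, prob[tuple(vox.T)], voxel_size))
    return rois


def filter_rois(rois: RoiSet, config: RoiBuildConfig,
                dendrite_mask: Optional[np.ndarray] = None,
                voxel_size: Optional[tuple[float, float, float]] = None) -> RoiSet:
    """Apply the ROI acceptance filters.

    Keeps an ROI iff its voxel count is within [min, max], it spans at
    least ``min_planes`` z-planes and — when an explicit distance gate is
    configured — its nearest voxel lies within ``max_dist_to_dendrite_um``
    of a dendrite voxel.
    """
    dist = None
    if config.max_dist_to_dendrite_um is not None:
        if dendrite_mask is None or voxel_size is None:
            raise ValueError(
                "explicit dendrite-distance filtering needs dendrite_mask "
                "and voxel_size")
        dmask = np.asarray(dendrite_mask, dtype=bool)
        if dmask.any():
            sx, sy, sz = voxel_size
            dist = ndimage.distance_transform_edt(~dmask, sampling=(sz, sy, sx))
        else:
            dist = np.full(dmask.shape, np.inf)
    out = RoiSet()
    for roi in rois:
        if not (config.min_roi_size_vox <= roi.size <= config.max_roi_size_vox):
            continue
        if roi.plane_span < config.min_planes:
            continue
        if dist is not None:
            dmin = dist[tuple(roi.voxels.T)].min()
            if dmin > config.max_dist_to_dendrite_um:
                continue
        out.append(roi)
    return out


def rois_to_label_volume(rois: RoiSet, shape: tuple[int, int, int]) -> np.ndarray:
    """Integer label volume: 0 background, ROI index i at ROI i's voxels.

    Overlaps are resolved in ROI order (the first ROI wins).
    """
    out = np.zeros(shape, dtype=np.int32)
    for idx in range(len(rois) - 1, -1, -1):
        vox = rois[idx].voxels
        if (vox < 0).any() or (vox >= np.asarray(shape)).any():
            raise ValueError(f"ROI {idx} has voxels outside the volume")
        out[tuple(vox.T)] = idx + 1
    return out
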