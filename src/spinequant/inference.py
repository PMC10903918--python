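"""Full-stack prediction and probability-map post-processing.

Prediction is plane-separable: each z-plane is normalized, reflect-padded
to a multiple of 2^depth, run through the network in evaluation mode and
cropped back, yielding dendrite and spine probability maps with the input
stack's exact geometry. Post-processing removes small dendrite fragments
(2D and 3D connected-component size filters) and gates spine probability
by proximity to the cleaned dendrite (dilation in physical units), an
implicit distance-to-dendrite criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .network import SegmentationModel
from .stack_io import ImageStack, rescale_stack
from .training import normalize_intensity

_STRUCT_3D_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_2D_8 = np.ones((3, 3), dtype=bool)


@dataclass
class PredictionMaps:
    """Paired probability maps with the source stack's geometry."""

    dendrite_map: ImageStack
    spine_map: ImageStack

    def __post_init__(self):
        if self.dendrite_map.voxels.shape != self.spine_map.voxels.shape:
            raise ValueError("dendrite and spine maps must share shape")


def _pad_to_multiple(plane: np.ndarray, div: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = plane.shape
    ph = (-h) % div
    pw = (-w) % div
    if ph or pw:
        plane = np.pad(plane, ((0, ph), (0, pw)), mode="reflect")
    return plane, (h, w)


def predict_stack(model: SegmentationModel, stack: ImageStack,
                  target_xy_um: float | None = None,
                  batch_planes: int = 4) -> PredictionMaps:
    """Predict dendrite/spine probability maps for every plane.

    If ``target_xy_um`` is given, planes are resampled to that pixel
    pitch before prediction (e.g. the resolution the model was trained
    at) and the maps are resampled back to the native geometry.
    """
    work = stack if target_xy_um is None else rescale_stack(stack, target_xy_um)
    div = 2 ** model.config.depth
    nz = work.voxels.shape[0]
    d_out = np.empty(work.voxels.shape, dtype=np.float64)
    s_out = np.empty(work.voxels.shape, dtype=np.float64)
    for start in range(0, nz, batch_planes):
        planes = [normalize_intensity(work.voxels[k].astype(np.float64))
                  for k in range(start, min(start + batch_planes, nz))]
        padded = [_pad_to_multiple(p, div) for p in planes]
        x = np.stack([p for p, _ in padded])
        d_map, s_map = model.predict(x)
        for i, (_, (h, w)) in enumerate(padded):
            d_out[start + i] = d_map[i, :h, :w]
            s_out[start + i] = s_map[i, :h, :w]
    if target_xy_um is not None:
        d_back = rescale_stack(ImageStack(d_out, work.voxel_size), stack.voxel_size[0])
        s_back = rescale_stack(ImageStack(s_out, work.voxel_size), stack.voxel_size[0])
        # rounding in the forward resample can differ by one pixel; crop/pad back
        d_out = _fit_shape(d_back.voxels, stack.voxels.shape)
        s_out = _fit_shape(s_back.voxels, stack.voxels.shape)
    return PredictionMaps(
        dendrite_map=ImageStack(np.clip(d_out, 0, 1), stack.voxel_size),
        spine_map=ImageStack(np.clip(s_out, 0, 1), stack.voxel_size),
    )


def _fit_shape(arr: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=arr.dtype)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(arr.shape, shape))
    out[sl] = arr[sl]
    return out


def clean_dendrite_map(maps: PredictionMaps, threshold: float = 0.5,
                       min_size_2d: int = 10, min_size_3d: int = 50
                       ) -> PredictionMaps:
    """Remove small dendrite prediction fragments.

    The dendrite map is binarized at ``threshold``; per-plane (8-connected)
    components smaller than ``min_size_2d`` pixels and volumetric
    (26-connected) components smaller than ``min_size_3d`` voxels are
    removed and their probabilities zeroed. Idempotent.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    d = maps.dendrite_map.voxels.copy()
    mask = d >= threshold
    for k in range(mask.shape[0]):
        labels, n = ndimage.label(mask[k], structure=_STRUCT_2D_8)
        if n:
            sizes = np.bincount(labels.ravel())
            small = np.flatnonzero(sizes < min_size_2d)
            mask[k] &= ~np.isin(labels, small[small > 0])
    labels, n = ndimage.label(mask, structure=_STRUCT_3D_26)
    if n:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_size_3d)
        mask &= ~np.isin(labels, small[small > 0])
    d[~mask] = 0.0
    return PredictionMaps(
        dendrite_map=maps.dendrite_map.copy_with(d),
        spine_map=maps.spine_map.copy_with(maps.spine_map.voxels.copy()),
    )


def _ellipsoid_structure(radius_um: float, voxel_size) -> np.ndarray:
    sx, sy, sz = voxel_size
    rz = max(0, int(np.floor(radius_um / sz)))
    ry = max(0, int(np.floor(radius_um / sy)))
    rx = max(0, int(np.floor(radius_um / sx)))
    zz, yy, xx = np.meshgrid(
        np.arange(-rz, rz + 1) * sz,
        np.arange(-ry, ry + 1) * sy,
        np.arange(-rx, rx + 1) * sx,
        indexing="ij",
    )
    return zz ** 2 + yy ** 2 + xx ** 2 <= radius_um ** 2 + 1e-12


def gate_spines_by_dendrite(maps: PredictionMaps, dilation_um: float = 1.0,
                            dendrite_threshold: float = 0.5) -> PredictionMaps:
    """Zero spine probability far from the (cleaned) dendrite.

    The binarized dendrite mask is dilated by ``dilation_um`` with an
    anisotropic physical-unit ellipsoid; spine probabilities outside the
    dilated mask are set to 0. The dendrite map is unchanged. Spine
    probability mass retained is monotone non-decreasing in the dilation
    radius.
    """
    if dilation_um < 0:
        raise ValueError("dilation must be ≥ 0")
    dmask = maps.dendrite_map.voxels >= dendrite_threshold
    if dilation_um > 0:
        struct = _ellipsoid_structure(dilation_um, maps.dendrite_map.voxel_size)
        dmask = ndimage.binary_dilation(dmask, structure=struct)
    s = maps.spine_map.voxels.copy()
    s[~dmask] = 0.0
    return PredictionMaps(
        dendrite_map=maps.dendrite_map.copy_with(maps.dendrite_map.voxels.copy()),
        spine_map=maps.spine_map.copy_with(s),
    )
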