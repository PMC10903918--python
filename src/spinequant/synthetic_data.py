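"""Ground-truthed synthetic dendrite/spine scenes and simulated raters.

A scene is one or more smooth tubular dendrites running through a 3D
volume, decorated with dendritic spines: a bulbous head connected to the
tube by a thin neck, protruding outward. The generator returns exact
binary masks (spines and dendrites disjoint, spine heads non-touching)
plus the true head centers, then renders a realistic image by Gaussian
PSF blurring and adding shot-like and read noise. A rater model turns
ground truth into noisy multi-expert point annotations: probabilistic
detection, anisotropic center jitter and spurious (false-positive) points.

Default geometry mirrors two-photon imaging of hippocampal pyramidal
neurons: 94 nm xy pixels, 0.5 µm z steps, sub-µm spine heads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .stack_io import (
    ImageStack,
    PointAnnotationSet,
    SwcNode,
    SwcTracing,
    rasterize_tracing,
    write_stack,
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene (all lengths in µm)."""

    n_dendrites: int = 1
    dendrite_radius_um: float = 0.5
    n_spines: int = 5
    spine_head_radius_um: tuple[float, float] = (0.4, 0.6)
    neck_length_um: tuple[float, float] = (0.4, 1.0)
    neck_radius_um: float = 0.12
    voxel_size: tuple[float, float, float] = (0.094, 0.094, 0.5)
    stack_shape: tuple[int, int, int] = (10, 96, 96)
    psf_sigma_um: tuple[float, float, float] = (0.1, 0.1, 0.35)
    noise_gaussian_sd: float = 4.0
    photon_scale: float = 0.5
    baseline: float = 10.0
    amplitude: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.n_spines < 0 or self.n_dendrites < 1:
            raise ValueError("n_spines must be ≥ 0 and n_dendrites ≥ 1")
        geometric = (self.dendrite_radius_um, self.neck_radius_um,
                     *self.spine_head_radius_um, *self.neck_length_um,
                     *self.voxel_size)
        if any(g <= 0 for g in geometric):
            raise ValueError("all geometric parameters must be positive")


@dataclass
class GroundTruth:
    """Exact labels for one scene."""

    spine_mask: ImageStack
    dendrite_mask: ImageStack
    spine_centers: list[tuple[float, float, float]]  # (x, y, z) µm


@dataclass
class RaterModel:
    """Behavioral model of a human spine annotator.

    ``detection_prob`` is either a constant in [0, 1] or a callable
    mapping a spine center (x, y, z µm) to a probability, letting
    detectability depend on position/contrast. ``false_positive_rate`` is
    the expected number of spurious annotations per stack (Poisson),
    placed at least 1 µm away from any true structure.
    """

    n_raters: int = 7
    detection_prob: Union[float, Callable[[tuple], float]] = 0.85
    jitter_sd_um: tuple[float, float] = (0.1, 0.25)  # (xy, z)
    false_positive_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.detection_prob, (int, float)):
            if not 0.0 <= self.detection_prob <= 1.0:
                raise ValueError("detection_prob must be in [0, 1]")
        if any(j < 0 for j in self.jitter_sd_um) or self.false_positive_rate < 0:
            raise ValueError("jitter and false-positive rate must be ≥ 0")

    def prob_for(self, center) -> float:
        if callable(self.detection_prob):
            return float(self.detection_prob(center))
        return float(self.detection_prob)


# --------------------------------------------------------------------------
# scene geometry
# --------------------------------------------------------------------------

def _dendrite_path(rng, spec: SceneSpec, index: int) -> np.ndarray:
    """Smooth curve (n, 3) of (x, y, z) µm spanning the volume in x."""
    sx, sy, sz = spec.voxel_size
    nz, ny, nx = spec.stack_shape
    ex, ey, ez = nx * sx, ny * sy, nz * sz
    margin = spec.dendrite_radius_um
    n_pts = 64
    t = np.linspace(0.0, 1.0, n_pts)
    x = margin + t * (ex - 2 * margin)
    # low-order sinusoidal wander in y, gentle drift in z
    cy = ey * (0.25 + 0.5 * (index + rng.uniform(0.3, 0.7)) / max(1, spec.n_dendrites))
    amp_y = rng.uniform(0.05, 0.12) * ey
    phase = rng.uniform(0, 2 * np.pi)
    y = np.clip(cy + amp_y * np.sin(2 * np.pi * rng.uniform(0.5, 1.0) * t + phase),
                margin, ey - margin)
    cz = ez / 2 + rng.uniform(-0.1, 0.1) * ez
    z = np.clip(cz + rng.uniform(-0.05, 0.05) * ez * np.sin(2 * np.pi * t + phase),
                margin, ez - margin)
    return np.stack([x, y, z], axis=1)


def _path_to_tracing(path_um: np.ndarray, radius: float) -> SwcTracing:
    nodes = [SwcNode(i + 1, 0, *path_um[i], radius,
                     None if i == 0 else i) for i in range(len(path_um))]
    return SwcTracing(nodes)


def generate_scene(spec: SceneSpec) -> GroundTruth:
    """Build ground-truth masks and spine centers for one scene.

    Spine placement is rejection-sampled so that head centers are
    separated by more than twice the maximum head radius and every spine
    forms its own connected component, disjoint from the dendrite label.
    Raises if the volume cannot hold the requested number of spines,
    reporting the feasible maximum.
    """
    rng = np.random.default_rng(spec.seed)
    sx, sy, sz = spec.voxel_size
    nz, ny, nx = spec.stack_shape
    extent = np.array([nx * sx, ny * sy, nz * sz])
    template = ImageStack(np.zeros(spec.stack_shape, dtype=np.uint8), spec.voxel_size)

    paths = [_dendrite_path(rng, spec, i) for i in range(spec.n_dendrites)]
    dendrite = np.zeros(spec.stack_shape, dtype=bool)
    for p in paths:
        dendrite |= rasterize_tracing(
            _path_to_tracing(p, spec.dendrite_radius_um), template).voxels

    r_lo, r_hi = spec.spine_head_radius_um
    min_sep = 2.0 * r_hi
    centers: list[np.ndarray] = []
    spine_tracings: list[SwcTracing] = []
    max_tries = 400
    tries = 0
    while len(centers) < spec.n_spines and tries < max_tries:
        tries += 1
        path = paths[rng.integers(len(paths))]
        i = int(rng.integers(2, len(path) - 2))
        p, p_next = path[i], path[i + 1]
        tangent = p_next - p
        tangent = tangent / np.linalg.norm(tangent)
        # protrusion direction: perpendicular to the tube, mostly in-plane
        theta = rng.uniform(0, 2 * np.pi)
        side = np.array([-tangent[1], tangent[0], 0.0])
        side /= np.linalg.norm(side) + 1e-12
        up = np.array([0.0, 0.0, 1.0])
        direction = np.cos(theta) * side + 0.35 * np.sin(theta) * up
        direction /= np.linalg.norm(direction)

        head_r = rng.uniform(r_lo, r_hi)
        neck_len = rng.uniform(*spec.neck_length_um)
        base = p + direction * spec.dendrite_radius_um
        head = p + direction * (spec.dendrite_radius_um + neck_len + head_r)

        pad = np.array([head_r + sx, head_r + sy, head_r + sz])
        if np.any(head < pad) or np.any(head > extent - pad):
            continue
        if any(np.linalg.norm(head - c) <= min_sep for c in centers):
            continue
        bases = [np.array([t.nodes[0].x_um, t.nodes[0].y_um, t.nodes[0].z_um])
                 for t in spine_tracings]
        min_base_sep = 2 * spec.neck_radius_um + 2 * min(sx, sy)
        if any(np.linalg.norm(base - b) < min_base_sep for b in bases):
            continue
        nodes = [
            SwcNode(1, 0, *base, spec.neck_radius_um, None),
            SwcNode(2, 0, *head, head_r, 1),
        ]
        centers.append(head)
        spine_tracings.append(SwcTracing(nodes))

    if len(centers) < spec.n_spines:
        raise ValueError(
            f"stack too small for {spec.n_spines} spines; feasible maximum "
            f"here is {len(centers)}"
        )

    spines = np.zeros(spec.stack_shape, dtype=bool)
    for tr in spine_tracings:
        spines |= rasterize_tracing(tr, template).voxels
    spines &= ~dendrite  # disjoint labels: necks belong to the spine class

    n_comp = ndimage.label(spines, structure=_STRUCT_26)[1]
    if n_comp != spec.n_spines:
        # heads non-touching by construction; any residual merge/fragment
        # (borderline voxelization) is resolved by re-drawing the scene
        if spec.seed < 2 ** 31 - 1000:
            return generate_scene(replace(spec, seed=spec.seed + 1_000_003))
        raise RuntimeError("could not voxelize spines into distinct components")

    return GroundTruth(
        spine_mask=ImageStack(spines, spec.voxel_size),
        dendrite_mask=ImageStack(dendrite, spec.voxel_size),
        spine_centers=[tuple(map(float, c)) for c in centers],
    )


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def render_stack(gt: GroundTruth, spec: SceneSpec) -> ImageStack:
    """Render an intensity stack from ground truth.

    intensity = baseline + amplitude · (masks), blurred with an
    anisotropic Gaussian PSF (σ per axis in µm), plus shot-like noise
    (Gaussian, variance ∝ intensity · photon_scale) and Gaussian read
    noise. Deterministic for a fixed spec seed.
    """
    sx, sy, sz = spec.voxel_size
    img = spec.baseline + spec.amplitude * (
        gt.dendrite_mask.voxels.astype(float) + gt.spine_mask.voxels.astype(float)
    )
    sig_x, sig_y, sig_z = spec.psf_sigma_um
    sigma_px = (sig_z / sz, sig_y / sy, sig_x / sx)
    if any(s > 0 for s in sigma_px):
        img = ndimage.gaussian_filter(img, sigma=sigma_px)
    rng = np.random.default_rng([spec.seed, 7919])
    if spec.photon_scale > 0:
        img = img + rng.normal(0.0, 1.0, img.shape) * np.sqrt(
            np.maximum(img, 0.0) * spec.photon_scale)
    if spec.noise_gaussian_sd > 0:
        img = img + rng.normal(0.0, spec.noise_gaussian_sd, img.shape)
    return ImageStack(img, spec.voxel_size)


# --------------------------------------------------------------------------
# simulated raters
# --------------------------------------------------------------------------

def simulate_raters(gt: GroundTruth, model: RaterModel,
                    annotation_round: int = 1) -> PointAnnotationSet:
    """Simulate independent human annotators on a ground-truth scene.

    Each rater detects each spine with its detection probability, places
    the annotation at the true head center plus anisotropic Gaussian
    jitter, and adds a Poisson number of false positives placed ≥ 1 µm
    from any labeled structure.
    """
    vs = gt.spine_mask.voxel_size
    structure = gt.spine_mask.voxels | gt.dendrite_mask.voxels
    far_idx = None
    if model.false_positive_rate > 0:
        dist = ndimage.distance_transform_edt(
            ~structure, sampling=(vs[2], vs[1], vs[0]))
        far_idx = np.argwhere(dist >= 1.0)

    jxy, jz = model.jitter_sd_um
    records = []
    for r in range(model.n_raters):
        rng = np.random.default_rng([model.seed, annotation_round, r])
        label = f"rater{r + 1}"
        for center in gt.spine_centers:
            if rng.random() >= model.prob_for(center):
                continue
            x = center[0] + rng.normal(0, jxy)
            y = center[1] + rng.normal(0, jxy)
            z = center[2] + rng.normal(0, jz)
            records.append((x, y, z, label, annotation_round))
        if far_idx is not None and len(far_idx):
            for _ in range(rng.poisson(model.false_positive_rate)):
                k, j, i = far_idx[rng.integers(len(far_idx))]
                records.append((
                    (i + 0.5) * vs[0], (j + 0.5) * vs[1], (k + 0.5) * vs[2],
                    label, annotation_round,
                ))
    df = pd.DataFrame(records, columns=list(PointAnnotationSet.REQUIRED))
    if df.empty:
        df = pd.DataFrame(columns=list(PointAnnotationSet.REQUIRED))
    return PointAnnotationSet(df)


# --------------------------------------------------------------------------
# training-set export
# --------------------------------------------------------------------------

def make_training_set(scenes: Sequence[SceneSpec], out_dir) -> Path:
    """Render scenes to disk as a training dataset.

    Writes ``scene###_{raw,spines,dendrites}.tif`` per scene plus a YAML
    manifest recording paths and per-entry voxel sizes; returns the
    manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, spec in enumerate(scenes):
        gt = generate_scene(spec)
        raw = render_stack(gt, spec)
        names = {}
        for kind, stack in (("raw", raw),
                            ("spines", gt.spine_mask),
                            ("dendrites", gt.dendrite_mask)):
            fname = f"scene{i:03d}_{kind}.tif"
            arr = stack.voxels
            if arr.dtype == bool:
                stack = ImageStack(arr.astype(np.uint8), stack.voxel_size)
            elif kind == "raw":
                stack = ImageStack(arr.astype(np.float32), stack.voxel_size)
            write_stack(stack, out_dir / fname)
            names[kind] = fname
        entries.append({
            "raw": names["raw"],
            "spines": names["spines"],
            "dendrites": names["dendrites"],
            "voxel_size_um": [float(v) for v in spec.voxel_size],
            "n_spines": spec.n_spines,
        })
    manifest = out_dir / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"entries": entries}, sort_keys=False))
    return manifest
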