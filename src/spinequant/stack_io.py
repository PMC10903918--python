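"""Reading, writing and rescaling of image stacks, tracings and annotations.

The universal in-memory carrier is :class:`ImageStack`: a 3D intensity
volume indexed ``(z, y, x)`` together with its physical voxel size in µm.
Physical coordinates are always µm, with the center of voxel ``(k, j, i)``
at ``((i + 0.5)·sx, (j + 0.5)·sy, (k + 0.5)·sz)``.

Supported on-disk formats: multi-page grayscale TIFF (stacks, label masks,
probability maps), SWC neuron tracings, CSV point-annotation tables and
ImageJ/FIJI ``.roi`` archives.
"""

from __future__ import annotations

import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A 3D grayscale volume with physical voxel size.

    Parameters
    ----------
    voxels
        Array of shape ``(nz, ny, nx)``. A single plane is a stack with
        ``nz == 1``.
    voxel_size
        ``(x, y, z)`` edge lengths of one voxel in µm; all positive.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"stack must be 3D (z, y, x); got shape {self.voxels.shape}"
            )
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive reals, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_centers_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates (x, y, z arrays in µm) of every voxel."""
        sx, sy, sz = self.voxel_size
        nz, ny, nx = self.voxels.shape
        z, y, x = np.meshgrid(
            (np.arange(nz) + 0.5) * sz,
            (np.arange(ny) + 0.5) * sy,
            (np.arange(nx) + 0.5) * sx,
            indexing="ij",
        )
        return x, y, z

    def copy_with(self, voxels: np.ndarray) -> "ImageStack":
        return ImageStack(voxels, self.voxel_size)


@dataclass(frozen=True)
class SwcNode:
    id: int
    type_code: int
    x_um: float
    y_um: float
    z_um: float
    radius_um: float
    parent_id: Optional[int]


@dataclass
class SwcTracing:
    """A neuron tracing: nodes with radii linked into a tree by parent ids."""

    nodes: list[SwcNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate node ids in tracing")
        id_set = set(ids)
        for n in self.nodes:
            if n.parent_id is not None and n.parent_id not in id_set:
                raise ValueError(f"node {n.id} references absent parent {n.parent_id}")
            if n.radius_um < 0:
                raise ValueError(f"node {n.id} has negative radius")

    def __len__(self) -> int:
        return len(self.nodes)

    def by_id(self) -> dict[int, SwcNode]:
        return {n.id: n for n in self.nodes}


@dataclass
class PointAnnotationSet:
    """Spine-center point annotations with rater identity and round."""

    points: pd.DataFrame  # columns x_um, y_um, z_um, rater, round

    REQUIRED = ("x_um", "y_um", "z_um", "rater", "round")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.points.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        df = self.points
        coords = df[["x_um", "y_um", "z_um"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("annotation coordinates must be finite")
        if (df["rater"].astype(str).str.len() == 0).any():
            raise ValueError("rater labels must be non-empty")
        self.points = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "PointAnnotationSet":
        df = pd.DataFrame(records, columns=list(cls.REQUIRED))
        return cls(df)

    def coords(self) -> np.ndarray:
        """(n, 3) array of (x, y, z) in µm."""
        return self.points[["x_um", "y_um", "z_um"]].to_numpy(float)


# --------------------------------------------------------------------------
# TIFF stacks
# --------------------------------------------------------------------------

def read_stack(path, voxel_size: tuple[float, float, float]) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Planes are taken in file order; intensities are returned unmodified.
    Multi-channel (RGB) files are rejected: the pipeline operates on
    single-channel fluorescence data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"unsupported TIFF layout with shape {arr.shape}; expected grayscale pages")
    # an RGB single page comes back as (h, w, 3|4)
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise ValueError("multi-channel/RGB TIFF not supported; provide single-channel pages")
    return ImageStack(arr, voxel_size)


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as a multi-page grayscale TIFF."""
    arr = stack.voxels
    if arr.dtype == np.float64:
        arr = arr.astype(np.float32)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


# --------------------------------------------------------------------------
# SWC tracings
# --------------------------------------------------------------------------

def read_swc(path, unit_scale_um: float = 1.0) -> SwcTracing:
    """Parse a whitespace-delimited SWC file.

    ``unit_scale_um`` converts file coordinates/radii to µm — 1.0 for files
    already in µm (NeuTube convention), or the pixel pitch for pixel-unit
    files.
    """
    nodes: list[SwcNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"{path}:{lineno}: malformed SWC line: {line!r}")
            try:
                nid, tcode = int(parts[0]), int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed SWC line: {line!r}") from e
            s = unit_scale_um
            nodes.append(
                SwcNode(nid, tcode, x * s, y * s, z * s, r * s,
                        None if parent == -1 else parent)
            )
    return SwcTracing(nodes)


def write_swc(tracing: SwcTracing, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent (um)\n")
        for n in tracing.nodes:
            parent = -1 if n.parent_id is None else n.parent_id
            fh.write(f"{n.id} {n.type_code} {n.x_um:g} {n.y_um:g} {n.z_um:g} "
                     f"{n.radius_um:g} {parent}\n")


def rasterize_tracing(tracing: SwcTracing, template: ImageStack) -> ImageStack:
    """Rasterize a tracing into a binary volume on the template's grid.

    Every parent–child segment is swept by spheres whose center and radius
    are linearly interpolated between the two anchor nodes; a voxel is set
    iff its physical center falls inside any such sphere. Distances are in
    µm, so anisotropic voxel sizes are handled correctly. A radius-0 node
    marks exactly the voxel containing it.
    """
    sx, sy, sz = template.voxel_size
    nz, ny, nx = template.voxels.shape
    out = np.zeros((nz, ny, nx), dtype=bool)
    if not tracing.nodes:
        return template.copy_with(out)

    by_id = tracing.by_id()
    min_step = 0.25 * min(sx, sy, sz)

    segments: list[tuple[np.ndarray, np.ndarray, float, float]] = []
    for n in tracing.nodes:
        p0 = np.array([n.x_um, n.y_um, n.z_um])
        if n.parent_id is None:
            segments.append((p0, p0, n.radius_um, n.radius_um))
        else:
            par = by_id[n.parent_id]
            p1 = np.array([par.x_um, par.y_um, par.z_um])
            segments.append((p0, p1, n.radius_um, par.radius_um))

    scale = np.array([sx, sy, sz])
    for p0, p1, r0, r1 in segments:
        length = float(np.linalg.norm(p1 - p0))
        n_steps = max(2, int(np.ceil(length / min_step)) + 1) if length > 0 else 1
        ts = np.linspace(0.0, 1.0, n_steps)
        centers = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
        radii = r0 + ts * (r1 - r0)

        rmax = float(radii.max())
        lo_um = centers.min(axis=0) - rmax
        hi_um = centers.max(axis=0) + rmax
        lo = np.maximum(np.floor(lo_um / scale - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil(hi_um / scale - 0.5).astype(int) + 1, [nx, ny, nz])
        if np.any(lo >= hi):
            continue
        xs = (np.arange(lo[0], hi[0]) + 0.5) * sx
        ys = (np.arange(lo[1], hi[1]) + 0.5) * sy
        zs = (np.arange(lo[2], hi[2]) + 0.5) * sz
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        pts = np.stack([xx, yy, zz], axis=-1)  # (z,y,x,3)
        inside = np.zeros(pts.shape[:3], dtype=bool)
        for c, r in zip(centers, radii):
            d2 = np.sum((pts - c) ** 2, axis=-1)
            if r == 0:
                # degenerate sphere: the voxel containing the point
                idx = np.floor(c / scale).astype(int)
                if np.all(idx >= lo) and np.all(idx < hi):
                    inside[idx[2] - lo[2], idx[1] - lo[1], idx[0] - lo[0]] = True
            else:
                inside |= d2 <= r * r
        out[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] |= inside
    return template.copy_with(out)


# --------------------------------------------------------------------------
# annotation tables
# --------------------------------------------------------------------------

def read_annotations(path) -> PointAnnotationSet:
    """Read a CSV annotation table (columns x_um, y_um, z_um, rater, round).

    Extra columns are ignored; the required fields roundtrip losslessly.
    """
    df = pd.read_csv(path)
    missing = [c for c in PointAnnotationSet.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df["rater"] = df["rater"].astype(str)
    df["round"] = df["round"].astype(int)
    return PointAnnotationSet(df[list(PointAnnotationSet.REQUIRED)])


def write_annotations(annotations: PointAnnotationSet, path) -> None:
    annotations.points.to_csv(path, index=False)


# --------------------------------------------------------------------------
# ImageJ ROI export
# --------------------------------------------------------------------------

_ROI_VERSION = 228
_ROI_TYPE_FREEHAND = 7


def _encode_imagej_roi(name: str, xs: np.ndarray, ys: np.ndarray, z_position: int) -> bytes:
    """Encode one closed 2D outline as an ImageJ ``.roi`` record.

    Layout follows the public ImageJ1 RoiDecoder byte map: 64-byte header1,
    header2 with the stack position and name, then relative polygon
    coordinates as big-endian shorts.
    """
    xs = np.asarray(xs, dtype=int)
    ys = np.asarray(ys, dtype=int)
    top, left = int(ys.min()), int(xs.min())
    bottom, right = int(ys.max()), int(xs.max())
    n = len(xs)

    header2_offset = 64 + 4 * n
    name_offset = header2_offset + 64
    header1 = struct.pack(
        ">4sh b b hhhh h",
        b"Iout", _ROI_VERSION, _ROI_TYPE_FREEHAND, 0,
        top, left, bottom, right, n,
    )
    header1 += b"\x00" * (60 - len(header1))
    header1 += struct.pack(">i", header2_offset)  # HEADER2_OFFSET field at byte 60
    assert len(header1) == 64

    coords = struct.pack(f">{n}h", *(xs - left)) + struct.pack(f">{n}h", *(ys - top))

    name_bytes = name.encode("utf-16-be")
    header2 = bytearray(64)
    # header2 byte map: C/Z/T positions at offsets 4/8/12, name at 16/20
    struct.pack_into(">i", header2, 8, z_position + 1)  # 1-based slice
    struct.pack_into(">i", header2, 16, name_offset)
    struct.pack_into(">i", header2, 20, len(name))
    return header1 + coords + bytes(header2) + name_bytes


def _plane_outline(mask2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Outer boundary polygon of a 2D pixel mask in corner coordinates.

    Boundary edges are oriented so the region interior lies to the left
    (shared edges between adjacent pixels cancel) and chained by always
    taking the sharpest left turn, which resolves single-vertex pinches.
    The loop with the largest enclosed area is the outer outline; every
    pixel center of the mask's largest 4-connected part lies inside it.
    Interior holes are not represented (the record outlines the filled
    region).
    """
    ys_px, xs_px = np.nonzero(mask2d)
    if len(xs_px) == 0:
        raise ValueError("cannot outline an empty plane mask")
    edges: set[tuple[tuple[int, int], tuple[int, int]]] = set()

    def toggle(a, b):
        if (b, a) in edges:
            edges.remove((b, a))
        else:
            edges.add((a, b))

    for x, y in zip(xs_px.tolist(), ys_px.tolist()):
        # counter-clockwise around the unit square (interior on the left)
        toggle((x, y), (x + 1, y))
        toggle((x + 1, y), (x + 1, y + 1))
        toggle((x + 1, y + 1), (x, y + 1))
        toggle((x, y + 1), (x, y))

    out_map: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a, b in edges:
        out_map.setdefault(a, []).append(b)

    def left_turn_key(din, dout):
        # rank continuations: sharpest left turn first
        cross = din[0] * dout[1] - din[1] * dout[0]
        dot = din[0] * dout[0] + din[1] * dout[1]
        import math
        return math.atan2(cross, dot)

    unused = set(edges)
    loops: list[list[tuple[int, int]]] = []
    while unused:
        first = next(iter(unused))
        loop = [first[0]]
        a, b = first
        unused.remove(first)
        while b != loop[0]:
            loop.append(b)
            din = (b[0] - a[0], b[1] - a[1])
            options = [c for c in out_map.get(b, []) if (b, c) in unused]
            c = max(options, key=lambda c: left_turn_key(din, (c[0] - b[0], c[1] - b[1])))
            unused.remove((b, c))
            a, b = b, c
        loops.append(loop)

    def area(loop):
        s = 0.0
        for (x0, y0), (x1, y1) in zip(loop, loop[1:] + loop[:1]):
            s += x0 * y1 - x1 * y0
        return abs(s) / 2.0

    outline = max(loops, key=area)
    arr = np.array(outline)
    return arr[:, 0], arr[:, 1]


def export_imagej_rois(rois, path) -> None:
    """Export ROIs to an ImageJ/FIJI ``.zip`` archive of ``.roi`` records.

    The ImageJ format is 2D-per-record, so a 3D ROI becomes one freehand
    outline per occupied z-plane; records of one ROI share a name prefix
    ``roi{index:04d}`` with a ``-z{plane:04d}`` suffix. An empty ROI set
    produces an empty archive; a ROI with no voxels is an error.
    """
    from scipy import ndimage

    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for i, roi in enumerate(rois):
            voxels = np.asarray(roi.voxels)
            if voxels.size == 0:
                raise ValueError(f"ROI {i} has no voxels")
            planes = np.unique(voxels[:, 0])
            for z in planes:
                in_plane = voxels[voxels[:, 0] == z]
                ymax = in_plane[:, 1].max() + 1
                xmax = in_plane[:, 2].max() + 1
                mask = np.zeros((ymax + 1, xmax + 1), dtype=bool)
                mask[in_plane[:, 1], in_plane[:, 2]] = True
                # a 26-connected 3D ROI may fall apart in-plane; outline
                # each 4-connected part as its own record
                labels, n_parts = ndimage.label(mask)
                for part in range(1, n_parts + 1):
                    xs, ys = _plane_outline(labels == part)
                    name = f"roi{i:04d}-z{int(z):04d}"
                    if n_parts > 1:
                        name += f"-p{part:02d}"
                    zf.writestr(name + ".roi",
                                _encode_imagej_roi(name, xs, ys, int(z)))


# --------------------------------------------------------------------------
# rescaling
# --------------------------------------------------------------------------

def rescale_stack(stack: ImageStack, target_xy_um: float) -> ImageStack:
    """Resample every plane to a new xy pixel pitch (bilinear); z untouched.

    The physical extent ``n_px · µm/px`` is preserved to within one voxel.
    A target equal to the current pitch returns an identical copy.
    """
    if target_xy_um <= 0:
        raise ValueError("target pixel size must be positive")
    sx, sy, sz = stack.voxel_size
    nz, ny, nx = stack.voxels.shape
    new_nx = max(1, int(round(nx * sx / target_xy_um)))
    new_ny = max(1, int(round(ny * sy / target_xy_um)))
    if (new_nx, new_ny) == (nx, ny):
        return ImageStack(stack.voxels.copy(), (target_xy_um, target_xy_um, sz))
    out = np.empty((nz, new_ny, new_nx), dtype=np.float64)
    for k in range(nz):
        out[k] = resize(
            stack.voxels[k].astype(np.float64), (new_ny, new_nx),
            order=1, mode="edge", anti_aliasing=False, preserve_range=True,
        )
    if np.issubdtype(stack.voxels.dtype, np.integer):
        info = np.iinfo(stack.voxels.dtype)
        out = np.clip(np.round(out), info.min, info.max).astype(stack.voxels.dtype)
    else:
        out = out.astype(stack.voxels.dtype)
    return ImageStack(out, (target_xy_um, target_xy_um, sz))
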