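"""ROI-based fluorescence quantification.

Three downstream measurements operate on spine ROIs:

* per-frame mean-intensity traces from a time series of frames,
* ΔF/F₀(t) = (F(t) − F₀)/F₀ with F₀ the mean over user-chosen baseline
  frames (conventionally 20 frames free of spontaneous calcium events),
* the ratiometric spine-to-dendrite ratio
  RSDR = (Maturity_spine/Structure_spine) /
  (Maturity_dendrite/Structure_dendrite), where the spine terms are mean
  intensities over one spine ROI in a maturity-marker channel (e.g. a
  tagged PSD-95 nanobody) and a structural channel, and the dendrite
  terms are means over all dendrite-labeled voxels of the field of view.
  RSDR > 1 means the marker is enriched in the spine over the dendrite.

Trace agreement between two ROI sources uses the Pearson correlation,
optionally after a centered moving average (width 9 by default, with
truncated windows at the trace edges).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .roi_builder import RoiSet


@dataclass
class TraceMatrix:
    """Mean-fluorescence traces: one row per ROI, one column per frame."""

    values: np.ndarray
    roi_ids: list[int]
    frame_rate_hz: Optional[float] = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("traces must be finite")
        if len(self.roi_ids) != self.values.shape[0]:
            raise ValueError("one roi id per trace row required")


@dataclass
class RsdrInput:
    maturity_spine: float
    structure_spine: float
    maturity_dendrite: float
    structure_dendrite: float

    def __post_init__(self):
        vals = (self.maturity_spine, self.structure_spine,
                self.maturity_dendrite, self.structure_dendrite)
        if any(v <= 0 for v in vals):
            raise ValueError("RSDR requires strictly positive mean intensities")


def extract_traces(movie: Sequence[np.ndarray], rois: RoiSet,
                   frame_rate_hz: Optional[float] = None) -> TraceMatrix:
    """Mean intensity over each ROI's voxels for every frame.

    Frames may be 3D volumes (matching ROI voxel indices) or single 2D
    planes (then ROI z-indices are ignored and must be in-plane).
    """
    if not len(rois):
        raise ValueError("empty ROI set")
    traces = np.empty((len(rois), len(movie)), dtype=np.float64)
    for i, roi in enumerate(rois):
        if roi.size == 0:
            raise ValueError(f"ROI {i} is empty")
        idx = tuple(roi.voxels.T)
        for t, frame in enumerate(movie):
            frame = np.asarray(frame, dtype=np.float64)
            if frame.ndim == 2:
                frame = frame[None]
            traces[i, t] = frame[idx].mean()
    return TraceMatrix(traces, roi_ids=list(range(len(rois))),
                       frame_rate_hz=frame_rate_hz)


def delta_f_over_f(trace: np.ndarray, baseline_frames: Sequence[int]) -> np.ndarray:
    """ΔF/F₀ against the mean of the baseline frames.

    F₀ must be positive: a zero or negative baseline makes the ratio
    meaningless and is flagged as an error.
    """
    trace = np.asarray(trace, dtype=np.float64)
    baseline_frames = np.asarray(list(baseline_frames), dtype=int)
    if baseline_frames.size == 0:
        raise ValueError("baseline_frames must be non-empty")
    f0 = float(trace[baseline_frames].mean())
    if f0 <= 0:
        raise ValueError(f"baseline mean F0 = {f0} must be positive")
    return (trace - f0) / f0


def lowest_window_baseline(trace: np.ndarray, width: int = 20) -> np.ndarray:
    """Automatic baseline: the contiguous window with the lowest mean.

    A convenience rule for when no manual event-free window is supplied.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if len(trace) < width:
        raise ValueError("trace shorter than baseline window")
    means = np.convolve(trace, np.ones(width) / width, mode="valid")
    start = int(np.argmin(means))
    return np.arange(start, start + width)


def rsdr(inputs: RsdrInput) -> float:
    """Ratiometric spine-to-dendrite ratio; > 1 indicates spine enrichment."""
    return (inputs.maturity_spine / inputs.structure_spine) / (
        inputs.maturity_dendrite / inputs.structure_dendrite)


def rsdr_per_roi(maturity: np.ndarray, structure: np.ndarray, rois: RoiSet,
                 dendrite_mask: np.ndarray) -> np.ndarray:
    """RSDR for every ROI against the whole dendritic arbor in the volume."""
    maturity = np.asarray(maturity, dtype=np.float64)
    structure = np.asarray(structure, dtype=np.float64)
    dmask = np.asarray(dendrite_mask, dtype=bool)
    if not dmask.any():
        raise ValueError("dendrite mask is empty")
    md = float(maturity[dmask].mean())
    sd = float(structure[dmask].mean())
    out = np.empty(len(rois))
    for i, roi in enumerate(rois):
        idx = tuple(roi.voxels.T)
        out[i] = rsdr(RsdrInput(
            maturity_spine=float(maturity[idx].mean()),
            structure_spine=float(structure[idx].mean()),
            maturity_dendrite=md,
            structure_dendrite=sd,
        ))
    return out


def moving_average(trace: np.ndarray, width: int = 9) -> np.ndarray:
    """Centered moving average with truncated windows at the edges."""
    trace = np.asarray(trace, dtype=np.float64)
    kernel = np.ones(width)
    summed = np.convolve(trace, kernel, mode="same")
    counts = np.convolve(np.ones_like(trace), kernel, mode="same")
    return summed / counts


def trace_correlation(a: np.ndarray, b: np.ndarray,
                      smoothing: Optional[int] = None) -> float:
    """Pearson r between two traces, optionally after moving-average
    smoothing of the given width (9-point is the conventional choice)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) <= 2:
        raise ValueError("traces must be equal-length 1D with length > 2")
    if smoothing is not None:
        a = moving_average(a, smoothing)
        b = moving_average(b, smoothing)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance trace: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
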