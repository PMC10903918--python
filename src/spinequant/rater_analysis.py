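"""Matching spine annotations across raters and reliability statistics.

Point annotations from several raters (a spine-detection algorithm's ROI
centroids can enter as one more rater) are pooled and grouped so that
each group ideally holds all annotations of one physical spine. Grouping
starts with density clustering (DBSCAN) on anisotropically scaled
coordinates — the xy radius (0.85 µm) and z radius (2.5 µm) become one
common radius — followed by three adjustment passes: (i) eject points
too distant from their cluster centroid, (ii) split clusters holding
more annotations than there are raters by 2-means, (iii) greedily merge
cluster pairs whose centroids are within the radii, provided the merged
size stays within the cap.

From the matched clusters, pairwise recall (the fraction of one rater's
spines also found by another), inter-rater reliability (mean ± sd of the
off-diagonal recall matrix), intra-rater reliability across two
annotation rounds, and the cluster-size histogram are computed.
Pixel-wise agreement between segmentation masks uses the Jaccard
intersection-over-union score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .stack_io import PointAnnotationSet


@dataclass
class ClusterParams:
    r_xy_um: float = 0.85
    r_z_um: float = 2.5
    max_cluster_size: int = 7
    seed: int = 0


@dataclass
class Cluster:
    """One matched spine: member annotations and their centroid."""

    members: pd.DataFrame        # rows of the annotation table
    centroid_um: tuple[float, float, float]

    @property
    def size(self) -> int:
        return len(self.members)

    def raters(self) -> set[tuple[str, int]]:
        """Distinct (rater, round) identities present in the cluster."""
        return set(zip(self.members["rater"], self.members["round"]))


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    params: ClusterParams

    def __len__(self) -> int:
        return len(self.clusters)

    def n_points(self) -> int:
        return sum(c.size for c in self.clusters)

    def size_histogram(self, by_rater: bool = True) -> dict[int, int]:
        """Counts of clusters by size (distinct raters by default)."""
        hist: dict[int, int] = {}
        for c in self.clusters:
            k = len({r for r, _ in c.raters()}) if by_rater else c.size
            hist[k] = hist.get(k, 0) + 1
        return dict(sorted(hist.items()))


def _centroid(df: pd.DataFrame) -> tuple[float, float, float]:
    return (float(df["x_um"].mean()), float(df["y_um"].mean()),
            float(df["z_um"].mean()))


def _within_radii(df: pd.DataFrame, centroid, params: ClusterParams) -> np.ndarray:
    dx = (df["x_um"] - centroid[0]).abs().to_numpy()
    dy = (df["y_um"] - centroid[1]).abs().to_numpy()
    dz = (df["z_um"] - centroid[2]).abs().to_numpy()
    return (dx <= params.r_xy_um) & (dy <= params.r_xy_um) & (dz <= params.r_z_um)


def _split_two_means(df: pd.DataFrame, rng: np.random.Generator,
                     params: ClusterParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic 2-means split, seeded at the two most distant members."""
    pts = df[["x_um", "y_um", "z_um"]].to_numpy(float)
    scaled = pts / np.array([params.r_xy_um, params.r_xy_um, params.r_z_um])
    d2 = ((scaled[:, None, :] - scaled[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    if i == j:  # all points coincide: split by index
        half = len(df) // 2
        return df.iloc[:half], df.iloc[half:]
    centers = scaled[[i, j]]
    for _ in range(50):
        assign = np.argmin(((scaled[:, None, :] - centers[None]) ** 2).sum(-1), axis=1)
        if assign.all() or not assign.any():  # degenerate: keep seeds apart
            assign[i], assign[j] = 0, 1
        new = np.stack([scaled[assign == k].mean(axis=0) for k in (0, 1)])
        if np.allclose(new, centers):
            break
        centers = new
    return df[assign == 0], df[assign == 1]


def cluster_annotations(points: PointAnnotationSet,
                        params: Optional[ClusterParams] = None) -> ClusterSet:
    """Group pooled annotations into per-spine clusters.

    Deterministic given the params seed. Every input point ends up in
    exactly one cluster (ejected points become singletons); after the
    adjustment passes no cluster exceeds ``max_cluster_size`` members
    and every member lies within the per-axis radii of its centroid.
    """
    params = params or ClusterParams()
    df = points.points.copy().reset_index(drop=True)
    if df.empty:
        return ClusterSet([], params)
    rng = np.random.default_rng(params.seed)

    scaled = df[["x_um", "y_um", "z_um"]].to_numpy(float) / np.array(
        [params.r_xy_um, params.r_xy_um, params.r_z_um])
    labels = DBSCAN(eps=1.0, min_samples=1).fit_predict(scaled)
    groups: list[pd.DataFrame] = [df[labels == lab] for lab in np.unique(labels)]

    # pass (i): eject members too far from their cluster centroid
    adjusted: list[pd.DataFrame] = []
    for g in groups:
        while True:
            keep = _within_radii(g, _centroid(g), params)
            if keep.all():
                break
            worst = np.argmax(~keep)  # eject one at a time, centroid moves
            adjusted.append(g.iloc[[worst]])
            g = g.drop(g.index[worst])
        adjusted.append(g)
    groups = [g for g in adjusted if len(g)]

    # pass (ii): split oversize clusters with 2-means until none exceeds the cap
    queue = groups
    groups = []
    while queue:
        g = queue.pop()
        if len(g) <= params.max_cluster_size:
            groups.append(g)
        else:
            a, b = _split_two_means(g, rng, params)
            queue.extend([a, b])

    # pass (iii): greedy merge of close cluster pairs, ascending distance
    merged = True
    while merged:
        merged = False
        cents = np.array([_centroid(g) for g in groups])
        n = len(groups)
        pairs = []
        for a in range(n):
            for b in range(a + 1, n):
                dxy = np.abs(cents[a, :2] - cents[b, :2])
                dz = abs(cents[a, 2] - cents[b, 2])
                if (dxy < params.r_xy_um).all() and dz < params.r_z_um \
                        and len(groups[a]) + len(groups[b]) <= params.max_cluster_size:
                    d = np.linalg.norm(
                        (cents[a] - cents[b]) /
                        [params.r_xy_um, params.r_xy_um, params.r_z_um])
                    pairs.append((d, a, b))
        if pairs:
            _, a, b = min(pairs)
            g = pd.concat([groups[a], groups[b]])
            groups = [groups[k] for k in range(n) if k not in (a, b)] + [g]
            merged = True

    # final radii enforcement: merging moves centroids, so re-eject violators
    stable = False
    while not stable:
        stable = True
        out: list[pd.DataFrame] = []
        for g in groups:
            keep = _within_radii(g, _centroid(g), params)
            if keep.all() or len(g) == 1:
                out.append(g)
            else:
                worst = np.argmax(~keep)
                out.append(g.iloc[[worst]])
                out.append(g.drop(g.index[worst]))
                stable = False
        groups = [g for g in out if len(g)]

    clusters = [Cluster(g.reset_index(drop=True), _centroid(g)) for g in groups]
    clusters.sort(key=lambda c: c.centroid_um)
    return ClusterSet(clusters, params)


# --------------------------------------------------------------------------
# reliability statistics
# --------------------------------------------------------------------------

def pairwise_recall_matrix(clusters: ClusterSet,
                           raters: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Recall matrix over raters: entry (A, B) = TP/(TP+FN) of B against A.

    A cluster counts once per rater regardless of duplicate same-rater
    members. Rows of raters with zero annotations are NaN (undefined).
    """
    present = [{r for r, _ in c.raters()} for c in clusters.clusters]
    if raters is None:
        raters = sorted(set().union(*present)) if present else []
    mat = pd.DataFrame(np.nan, index=list(raters), columns=list(raters))
    for a in raters:
        n_a = sum(a in s for s in present)
        if n_a == 0:
            continue
        for b in raters:
            both = sum((a in s) and (b in s) for s in present)
            mat.loc[a, b] = both / n_a
    return mat


def intra_rater_reliability(points: PointAnnotationSet,
                            params: Optional[ClusterParams] = None) -> float:
    """Mean recall (%) between a rater's two annotation rounds.

    Each rater's own two rounds are clustered separately (so the member
    cap — sized for the number of raters — is never hit by pooling
    rounds), and recall is counted in both directions, averaged over all
    raters that annotated twice.
    """
    params = params or ClusterParams()
    df = points.points
    rounds = sorted(df["round"].unique())
    if len(rounds) < 2:
        raise ValueError("need two annotation rounds for intra-rater reliability")
    r1, r2 = rounds[:2]
    recalls = []
    for rater, g in df.groupby("rater"):
        sub = g[g["round"].isin([r1, r2])]
        n1 = int((sub["round"] == r1).sum())
        n2 = int((sub["round"] == r2).sum())
        if n1 == 0 or n2 == 0:
            continue
        clusters = cluster_annotations(
            PointAnnotationSet(sub.reset_index(drop=True)), params)
        present = [c.raters() for c in clusters.clusters]
        both = sum(((rater, r1) in s) and ((rater, r2) in s) for s in present)
        recalls.extend([both / n1, both / n2])
    if not recalls:
        raise ValueError("no rater annotated in both rounds")
    return 100.0 * float(np.mean(recalls))


def fraction_found_by_all(clusters: ClusterSet, n_raters: int) -> float:
    """Fraction of clusters (spines) containing all ``n_raters`` raters."""
    if not len(clusters):
        return float("nan")
    hist = clusters.size_histogram(by_rater=True)
    return hist.get(n_raters, 0) / len(clusters)


@dataclass
class ReliabilitySummary:
    irr_mean_pct: float
    irr_sd_pct: float
    n_raters: int
    cluster_size_histogram: dict[int, int]
    intra_rater_pct: Optional[float] = None


def reliability_summary(clusters: ClusterSet) -> ReliabilitySummary:
    """Inter-rater (and, with two rounds, intra-rater) reliability.

    IRR is the mean ± sd of the off-diagonal recall-matrix entries, in
    percent, computed on round-1 annotations. If any rater annotated in
    two rounds, intra-rater reliability is the mean recall between a
    rater's two rounds (both directions), averaged over such raters.
    """
    rounds = sorted({rnd for c in clusters.clusters for _, rnd in c.raters()})
    present = [c.raters() for c in clusters.clusters]

    first_round = rounds[0] if rounds else 1
    raters_r1 = sorted({r for s in present for r, rnd in s if rnd == first_round})
    if len(raters_r1) < 2:
        raise ValueError("need at least two raters for inter-rater reliability")
    sets_r1 = [{r for r, rnd in s if rnd == first_round} for s in present]
    mat = np.full((len(raters_r1), len(raters_r1)), np.nan)
    for ia, a in enumerate(raters_r1):
        n_a = sum(a in s for s in sets_r1)
        for ib, b in enumerate(raters_r1):
            if n_a:
                mat[ia, ib] = sum((a in s) and (b in s) for s in sets_r1) / n_a
    off = mat[~np.eye(len(raters_r1), dtype=bool)]
    off = off[np.isfinite(off)]

    intra = None
    if len(rounds) >= 2:
        r2 = rounds[1]
        recalls = []
        for r in raters_r1:
            n1 = sum((r, first_round) in s for s in present)
            n2 = sum((r, r2) in s for s in present)
            if n1 == 0 or n2 == 0:
                continue
            both = sum(((r, first_round) in s) and ((r, r2) in s) for s in present)
            recalls.extend([both / n1, both / n2])
        if recalls:
            intra = 100.0 * float(np.mean(recalls))

    return ReliabilitySummary(
        irr_mean_pct=100.0 * float(off.mean()),
        irr_sd_pct=100.0 * float(off.std()),
        n_raters=len(raters_r1),
        cluster_size_histogram=clusters.size_histogram(by_rater=True),
        intra_rater_pct=intra,
    )


# --------------------------------------------------------------------------
# mask agreement
# --------------------------------------------------------------------------

def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union |A∩B|/|A∪B|; 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def combine_rater_masks(masks: Sequence[np.ndarray], mode: str) -> np.ndarray:
    """Voxelwise AND (``intersection``) or OR (``union``) of rater masks."""
    if mode not in ("intersection", "union"):
        raise ValueError("mode must be 'intersection' or 'union'")
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks:
        raise ValueError("need at least one mask")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    op = np.logical_and if mode == "intersection" else np.logical_or
    out = masks[0]
    for m in masks[1:]:
        out = op(out, m)
    return out
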