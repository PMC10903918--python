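"""Annotation clustering, reliability statistics and mask agreement."""

import numpy as np
import pandas as pd
import pytest

import spinequant as sq
from spinequant.rater_analysis import (Cluster, ClusterParams, ClusterSet,
                                       cluster_annotations,
                                       fraction_found_by_all, mask_iou,
                                       pairwise_recall_matrix,
                                       reliability_summary)


def _ann(records):
    return sq.PointAnnotationSet.from_records(records)


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def test_two_nearby_points_form_one_cluster():
    # Δx = 0.3 µm, Δz = 1 µm: inside the 0.85/2.5 µm radii
    ann = _ann([(1.0, 1.0, 1.0, "A", 1), (1.3, 1.0, 2.0, "B", 1)])
    clusters = cluster_annotations(ann)
    assert len(clusters) == 1
    assert clusters.clusters[0].size == 2


def test_oversize_cluster_split_by_two_means():
    # 9 annotations within a tight ball: must split into two clusters ≤ 7
    rng = np.random.default_rng(0)
    pts = rng.normal(0, 0.1, (9, 2))
    ann = _ann([(5 + x, 5 + y, 2.0, f"r{i}", 1)
                for i, (x, y) in enumerate(pts)])
    clusters = cluster_annotations(ann)
    sizes = sorted(c.size for c in clusters.clusters)
    assert sum(sizes) == 9
    assert all(s <= 7 for s in sizes)
    assert len(sizes) >= 2


def test_distant_z_point_is_not_a_member():
    ann = _ann([(1.0, 1.0, 1.0, "A", 1), (1.1, 1.0, 1.2, "B", 1),
                (1.0, 1.1, 1.1, "C", 1), (1.0, 1.0, 6.0, "D", 1)])
    clusters = cluster_annotations(ann)
    big = max(clusters.clusters, key=lambda c: c.size)
    assert big.size == 3
    assert "D" not in {r for r, _ in big.raters()}
    # the far point still exists as its own cluster
    assert clusters.n_points() == 4


def test_close_clusters_merge():
    # two raters 0.4 µm apart in x: DBSCAN may or may not join, but the
    # final clustering must contain them in one cluster of 2
    ann = _ann([(2.0, 2.0, 1.0, "A", 1), (2.4, 2.0, 1.0, "B", 1)])
    clusters = cluster_annotations(ann)
    assert len(clusters) == 1 and clusters.clusters[0].size == 2


def test_empty_input():
    ann = sq.PointAnnotationSet(
        pd.DataFrame(columns=list(sq.PointAnnotationSet.REQUIRED)))
    assert len(cluster_annotations(ann)) == 0


@pytest.mark.parametrize("seed", range(6))
def test_clustering_postconditions_fuzz(seed):
    """Point conservation, size cap and per-axis membership radii hold on
    random clouds mixing tight clumps and scattered points."""
    rng = np.random.default_rng(seed)
    records = []
    for c in range(rng.integers(2, 6)):
        center = rng.uniform(2, 18, 3) * np.array([1, 1, 0.3])
        for i in range(rng.integers(1, 10)):
            x, y = center[:2] + rng.normal(0, 0.25, 2)
            z = center[2] + rng.normal(0, 0.4)
            records.append((x, y, z, f"r{i % 7}", 1))
    for _ in range(rng.integers(0, 5)):
        x, y, z = rng.uniform(0, 20, 3)
        records.append((x, y, z, "s", 1))
    params = ClusterParams()
    clusters = cluster_annotations(_ann(records), params)
    assert clusters.n_points() == len(records)
    for c in clusters.clusters:
        assert c.size <= params.max_cluster_size
        coords = c.members[["x_um", "y_um", "z_um"]].to_numpy()
        centroid = coords.mean(axis=0)
        dev = np.abs(coords - centroid)
        assert (dev[:, 0] <= params.r_xy_um + 1e-9).all()
        assert (dev[:, 1] <= params.r_xy_um + 1e-9).all()
        assert (dev[:, 2] <= params.r_z_um + 1e-9).all()


def test_clustering_deterministic():
    rng = np.random.default_rng(1)
    records = [(x, y, z, f"r{i % 5}", 1)
               for i, (x, y, z) in enumerate(rng.uniform(0, 10, (40, 3)))]
    a = cluster_annotations(_ann(records))
    b = cluster_annotations(_ann(records))
    assert [c.centroid_um for c in a.clusters] == [c.centroid_um for c in b.clusters]


# --------------------------------------------------------------------------
# recall matrix
# --------------------------------------------------------------------------

def test_recall_identical_raters():
    pts = [(float(i), 1.0, 1.0) for i in range(0, 20, 4)]
    ann = _ann([(x, y, z, r, 1) for r in ("A", "B") for x, y, z in pts])
    mat = pairwise_recall_matrix(cluster_annotations(ann))
    assert mat.loc["A", "B"] == 1.0
    assert mat.loc["B", "A"] == 1.0
    assert mat.loc["A", "A"] == 1.0


def test_recall_half_overlap_asymmetric():
    pts = [(float(4 * i), 1.0, 1.0) for i in range(10)]
    records = [(x, y, z, "A", 1) for x, y, z in pts]
    records += [(x, y, z, "B", 1) for x, y, z in pts[:5]]
    mat = pairwise_recall_matrix(cluster_annotations(_ann(records)))
    assert mat.loc["A", "B"] == pytest.approx(0.5)
    assert mat.loc["B", "A"] == pytest.approx(1.0)


def test_recall_invariant_under_translation():
    rng = np.random.default_rng(2)
    pts = rng.uniform(0, 30, (15, 3))
    records = [(x, y, z, f"r{i % 3}", 1) for i, (x, y, z) in enumerate(pts)]
    shifted = [(x + 100, y - 40, z + 7, r, rnd) for x, y, z, r, rnd in records]
    a = pairwise_recall_matrix(cluster_annotations(_ann(records)))
    b = pairwise_recall_matrix(cluster_annotations(_ann(shifted)))
    pd.testing.assert_frame_equal(a, b)


def test_recall_missing_rater_row_is_nan():
    ann = _ann([(1.0, 1.0, 1.0, "A", 1)])
    mat = pairwise_recall_matrix(cluster_annotations(ann), raters=["A", "B"])
    assert mat.loc["A", "A"] == 1.0
    assert np.isnan(mat.loc["B", "A"])


# --------------------------------------------------------------------------
# reliability summary
# --------------------------------------------------------------------------

def _manual_cluster(raters_rounds, centroid=(0.0, 0.0, 0.0)):
    df = pd.DataFrame([
        {"x_um": centroid[0], "y_um": centroid[1], "z_um": centroid[2],
         "rater": r, "round": rnd} for r, rnd in raters_rounds])
    return Cluster(df, centroid)


def test_summary_uniform_recall():
    # A and B each have 10 clusters, 8 shared: every off-diagonal is 0.8
    clusters = [
        *(_manual_cluster([("A", 1), ("B", 1)]) for _ in range(8)),
        *(_manual_cluster([("A", 1)]) for _ in range(2)),
        *(_manual_cluster([("B", 1)]) for _ in range(2)),
    ]
    summary = reliability_summary(ClusterSet(clusters, ClusterParams()))
    assert summary.irr_mean_pct == pytest.approx(80.0)
    assert summary.irr_sd_pct == pytest.approx(0.0)
    assert summary.cluster_size_histogram == {1: 4, 2: 8}


def test_summary_identical_rounds_give_full_intra_rater():
    clusters = [_manual_cluster([("A", 1), ("A", 2), ("B", 1), ("B", 2)])
                for _ in range(6)]
    summary = reliability_summary(ClusterSet(clusters, ClusterParams()))
    assert summary.intra_rater_pct == pytest.approx(100.0)


def test_intra_rater_reliability_identical_rounds():
    pts = [(float(4 * i), 1.0, 1.0) for i in range(6)]
    records = [(x, y, z, "K", rnd) for rnd in (1, 2) for x, y, z in pts]
    assert sq.intra_rater_reliability(_ann(records)) == pytest.approx(100.0)


def test_intra_rater_reliability_tracks_detection_probability(small_scene):
    """Two independent annotation rounds at detection probability p give
    intra-rater recall ≈ p (25 Monte-Carlo seeds)."""
    _, gt = small_scene
    p = 0.85
    vals = []
    for seed in range(25):
        model = sq.RaterModel(n_raters=7, detection_prob=p,
                              jitter_sd_um=(0.1, 0.1),
                              false_positive_rate=0.0, seed=seed)
        rounds = pd.concat(
            [sq.simulate_raters(gt, model, annotation_round=r).points
             for r in (1, 2)], ignore_index=True)
        vals.append(sq.intra_rater_reliability(sq.PointAnnotationSet(rounds)))
    assert np.mean(vals) == pytest.approx(100 * p, abs=4.0)


def test_intra_rater_reliability_needs_two_rounds():
    with pytest.raises(ValueError, match="round"):
        sq.intra_rater_reliability(_ann([(1.0, 1.0, 1.0, "A", 1)]))


def test_summary_needs_two_raters():
    clusters = [_manual_cluster([("A", 1)])]
    with pytest.raises(ValueError):
        reliability_summary(ClusterSet(clusters, ClusterParams()))


def test_fraction_found_by_all():
    clusters = ClusterSet([
        _manual_cluster([("A", 1), ("B", 1), ("C", 1)]),
        _manual_cluster([("A", 1), ("B", 1)]),
        _manual_cluster([("A", 1)]),
        _manual_cluster([("A", 1), ("B", 1), ("C", 1)]),
    ], ClusterParams())
    assert fraction_found_by_all(clusters, 3) == pytest.approx(0.5)


# --------------------------------------------------------------------------
# simulation-based recovery
# --------------------------------------------------------------------------

def test_simulated_recall_tracks_detection_probability(small_scene):
    """Seven raters with detection probability p and small jitter: the
    mean off-diagonal recall approaches p (50 Monte-Carlo seeds)."""
    _, gt = small_scene
    p = 0.85
    vals = []
    for seed in range(50):
        model = sq.RaterModel(n_raters=7, detection_prob=p,
                              jitter_sd_um=(0.1, 0.1),
                              false_positive_rate=0.0, seed=seed)
        clusters = cluster_annotations(sq.simulate_raters(gt, model))
        mat = pairwise_recall_matrix(clusters).to_numpy()
        off = mat[~np.eye(len(mat), dtype=bool)]
        vals.append(np.nanmean(off))
    assert np.mean(vals) == pytest.approx(p, abs=0.03)


@pytest.mark.parametrize("jitter", [0.1, 0.2, 0.25])
def test_cluster_count_recovers_spine_count(jitter):
    """Total cluster count over 20 seeds within ±5% of the true total."""
    total_true = total_clusters = 0
    for seed in range(20):
        spec = sq.SceneSpec(seed=200 + seed)
        gt = sq.generate_scene(spec)
        model = sq.RaterModel(n_raters=7, detection_prob=0.85,
                              jitter_sd_um=(jitter, jitter),
                              false_positive_rate=0.0, seed=seed)
        clusters = cluster_annotations(sq.simulate_raters(gt, model))
        total_true += len(gt.spine_centers)
        total_clusters += len(clusters)
    assert abs(total_clusters - total_true) / total_true <= 0.05


def test_algorithm_enters_as_extra_rater(small_scene):
    """ROI centroids can be pooled with human annotations as one more
    rater; perfect centroids give recall 1.0 against every rater."""
    _, gt = small_scene
    human = sq.simulate_raters(gt, sq.RaterModel(
        n_raters=2, detection_prob=1.0, jitter_sd_um=(0.05, 0.1),
        false_positive_rate=0.0, seed=4))
    algo = pd.DataFrame([
        {"x_um": x, "y_um": y, "z_um": z, "rater": "model", "round": 1}
        for x, y, z in gt.spine_centers])
    pooled = sq.PointAnnotationSet(pd.concat([human.points, algo],
                                             ignore_index=True))
    mat = pairwise_recall_matrix(cluster_annotations(pooled))
    assert mat.loc["rater1", "model"] == 1.0
    assert mat.loc["model", "rater1"] == 1.0


# --------------------------------------------------------------------------
# mask agreement
# --------------------------------------------------------------------------

def test_iou_basic_values():
    a = np.zeros((3, 3), dtype=bool)
    a[0, :2] = True
    assert mask_iou(a, a) == 1.0
    b = np.zeros((3, 3), dtype=bool)
    b[2, :] = True
    assert mask_iou(a, b) == 0.0
    c = np.zeros((3, 3), dtype=bool)
    c[0, :2] = True
    c[1, :2] = True
    d = np.zeros((3, 3), dtype=bool)
    d[0, :2] = True
    d[2, :2] = True   # |c∩d| = 2, |c∪d| = 6
    assert mask_iou(c, d) == pytest.approx(2 / 6)


def test_iou_both_empty_is_one():
    assert mask_iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0


def test_iou_symmetry_random():
    rng = np.random.default_rng(3)
    for _ in range(10):
        a = rng.random((5, 6, 7)) > 0.5
        b = rng.random((5, 6, 7)) > 0.5
        assert mask_iou(a, b) == mask_iou(b, a)


def test_iou_shape_mismatch():
    with pytest.raises(ValueError):
        mask_iou(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


def test_combine_masks_modes():
    rng = np.random.default_rng(5)
    masks = [rng.random((4, 8, 8)) > 0.5 for _ in range(3)]
    inter = sq.combine_rater_masks(masks, "intersection")
    union = sq.combine_rater_masks(masks, "union")
    for m in masks:
        assert (inter <= m).all()
        assert (m <= union).all()
    single = sq.combine_rater_masks([masks[0]], "union")
    np.testing.assert_array_equal(single, masks[0])
    disjoint = [np.zeros((2, 2), bool) for _ in range(3)]
    for i, m in enumerate(disjoint):
        m.flat[i] = True
    assert not sq.combine_rater_masks(disjoint, "intersection").any()
    assert sq.combine_rater_masks(disjoint, "union").sum() == 3


def test_combine_masks_errors():
    with pytest.raises(ValueError):
        sq.combine_rater_masks([np.zeros((2, 2), bool)], "xor")
    with pytest.raises(ValueError):
        sq.combine_rater_masks([np.zeros((2, 2), bool),
                                np.zeros((3, 3), bool)], "union")
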