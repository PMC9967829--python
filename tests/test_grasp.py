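"""Grasp point, straight-segment filter, classifier, ratio, heat map."""

import numpy as np
import pytest

from stairwatch import (
    GraspSample,
    classify_frames,
    cv_accuracy_from_confusion,
    grasp_point,
    grasp_ratio,
    heatmap,
    straight_segment_filter,
    train_grasp_classifier,
)
from stairwatch.grasp import GraspClassifier, grasp_density
from stairwatch.recording import SkeletonFrame
from stairwatch.scene import make_labeled_grasp_dataset
from stairwatch.stairframe import StairFrame


def _frame(hand, handtip, thumb, t=0.0, side="right"):
    suffix = side.upper()
    return SkeletonFrame(
        timestamp=t,
        joints={
            f"HAND_{suffix}": np.asarray(hand, float),
            f"HANDTIP_{suffix}": np.asarray(handtip, float),
            f"THUMB_{suffix}": np.asarray(thumb, float),
        },
    )


def _sample(x, y=0.0, z=0.0, label="unlabeled"):
    return GraspSample(timestamp=0.0, pgp=np.array([x, y, z]), label=label)


# --- grasp point

def test_grasp_point_degenerate_centroid():
    s = grasp_point(_frame([100, 200, 300], [100, 200, 300], [100, 200, 300]), "right")
    np.testing.assert_allclose(s.pgp, [100, 200, 300])


def test_grasp_point_hand_arithmetic():
    s = grasp_point(_frame([0, 0, 0], [3, 0, 0], [0, 3, 0]), "right")
    np.testing.assert_allclose(s.pgp, [1, 1, 0])


def test_grasp_point_incomplete_triplet_skips():
    f = SkeletonFrame(timestamp=0.0, joints={"HAND_RIGHT": np.zeros(3)})
    assert grasp_point(f, "right") is None


# --- straight segment filter

def test_filter_boundary_semantics():
    xs = [-5, 0, 1, 500, 999, 1000, 1500]
    kept = straight_segment_filter([_sample(x) for x in xs])
    assert [s.pgp[0] for s in kept] == [1, 500, 999]


def test_filter_empty_and_idempotent():
    assert straight_segment_filter([]) == []
    samples = [_sample(x) for x in range(-100, 1200, 37)]
    once = straight_segment_filter(samples)
    assert straight_segment_filter(once) == once


# --- confusion accuracy

@pytest.mark.parametrize(
    "matrix,expected",
    [
        ([[117, 22], [14, 122]], 0.869),
        ([[29, 12], [5, 69]], 0.852),
        ([[10, 0], [0, 10]], 1.0),
    ],
)
def test_cv_accuracy_from_confusion(matrix, expected):
    assert cv_accuracy_from_confusion(matrix) == pytest.approx(expected, abs=5e-4)


def test_cv_accuracy_zero_total_rejected():
    with pytest.raises(ValueError):
        cv_accuracy_from_confusion([[0, 0], [0, 0]])


# --- training

def test_separable_clusters_reach_perfect_cv():
    samples = make_labeled_grasp_dataset(100, 100, separation=300.0, cluster_sd=10.0, seed=0)
    model = train_grasp_classifier(samples, seed=0)
    assert model.cv_accuracy == 1.0
    assert model.confusion.sum() == 200


def test_shuffled_labels_stay_near_chance():
    samples = make_labeled_grasp_dataset(500, 500, separation=0.0, seed=1)
    model = train_grasp_classifier(samples, seed=1)
    assert 0.45 <= model.cv_accuracy <= 0.55


def test_single_class_rejected():
    samples = [_sample(500, label="grasped") for _ in range(20)]
    with pytest.raises(ValueError):
        train_grasp_classifier(samples)


def test_too_few_per_class_rejected():
    samples = [_sample(500, 0, 0, "grasped")] * 3 + [_sample(500, 300, 300, "not_grasped")] * 20
    with pytest.raises(ValueError, match="at least 5"):
        train_grasp_classifier(samples)


def test_model_json_round_trip(tmp_path):
    samples = make_labeled_grasp_dataset(60, 60, separation=250.0, seed=3)
    model = train_grasp_classifier(samples, seed=3)
    model.save(tmp_path / "model.json")
    loaded = GraspClassifier.load(tmp_path / "model.json")
    X = np.array([[s.pgp[1], s.pgp[2]] for s in samples])
    np.testing.assert_array_equal(loaded.predict(X), model.predict(X))
    assert loaded.cv_accuracy == model.cv_accuracy


# --- classification and ratio

def test_classify_cluster_centroid_is_grasped():
    samples = make_labeled_grasp_dataset(100, 100, separation=300.0, seed=0)
    model = train_grasp_classifier(samples, seed=0)
    out = classify_frames([_sample(500, 0.0, 0.0)], model)
    assert out[0].label == "grasped"
    assert classify_frames([], model) == []


def test_grasp_ratio_counts():
    labeled = [_sample(500, label="grasped")] * 5 + [_sample(500, label="not_grasped")] * 5
    r = grasp_ratio(labeled)
    assert r.ratio == 0.5 and r.n == 10
    assert grasp_ratio([_sample(1, label="not_grasped")] * 7).ratio == 0.0


def test_grasp_ratio_concatenation_is_weighted_mean():
    a = [_sample(1, label="grasped")] * 3 + [_sample(1, label="not_grasped")] * 1
    b = [_sample(1, label="grasped")] * 1 + [_sample(1, label="not_grasped")] * 5
    ra, rb, rc = grasp_ratio(a), grasp_ratio(b), grasp_ratio(a + b)
    assert rc.ratio == pytest.approx((ra.ratio * ra.n + rb.ratio * rb.n) / (ra.n + rb.n))


def test_grasp_ratio_requires_labels():
    with pytest.raises(ValueError):
        grasp_ratio([_sample(5)])
    with pytest.raises(ValueError):
        grasp_ratio([])


# --- heat map

def test_heatmap_single_point_peak(intr, true_frame):
    from stairwatch.camera import project

    sample = GraspSample(timestamp=0.0, pgp=np.array([500.0, 0.0, 0.0]), label="grasped")
    density, skipped = grasp_density([sample], true_frame, intr, bandwidth_px=5.0)
    assert skipped == 0
    cam = true_frame.invert(sample.pgp)
    uv = project(cam, intr)
    peak = np.unravel_index(np.argmax(density), density.shape)
    assert abs(peak[1] - uv[0]) <= 1 and abs(peak[0] - uv[1]) <= 1


def test_heatmap_no_grasps_returns_background(intr, true_frame):
    bg = np.full((intr.height, intr.width, 3), 50, dtype=np.uint8)
    out = heatmap([_sample(500, label="not_grasped")], true_frame, intr, background=bg)
    np.testing.assert_array_equal(out, bg)


def test_heatmap_mass_ratio_9_to_1(intr, true_frame):
    rng = np.random.default_rng(4)
    big = [GraspSample(timestamp=0, pgp=np.array([200.0, 0, 0]) + rng.normal(0, 3, 3),
                       label="grasped") for _ in range(90)]
    small = [GraspSample(timestamp=0, pgp=np.array([900.0, 0, 0]) + rng.normal(0, 3, 3),
                         label="grasped") for _ in range(10)]
    density, _ = grasp_density(big + small, true_frame, intr, bandwidth_px=4.0)
    from stairwatch.camera import project

    u_big = project(true_frame.invert(np.array([200.0, 0, 0])), intr)[0]
    u_small = project(true_frame.invert(np.array([900.0, 0, 0])), intr)[0]
    u_mid = (u_big + u_small) / 2.0
    lo, hi = sorted([u_big, u_small])
    side_big = density[:, : int(u_mid)] if u_big < u_mid else density[:, int(u_mid):]
    side_small = density[:, int(u_mid):] if u_big < u_mid else density[:, : int(u_mid)]
    ratio = side_big.sum() / side_small.sum()
    assert ratio == pytest.approx(9.0, rel=0.10)


def test_heatmap_behind_camera_skipped(intr):
    # a frame whose inverse transform throws the point behind the camera
    frame = StairFrame(origin=np.array([0.0, 0.0, 5000.0]), R=np.eye(3))
    s = GraspSample(timestamp=0.0, pgp=np.array([0.0, 0.0, -6000.0]), label="grasped")
    density, skipped = grasp_density([s], frame, intr)
    assert skipped == 1 and density.sum() == 0
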