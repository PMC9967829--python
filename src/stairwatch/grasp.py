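"""Handrail-grasp analysis: grasp point, classifier, ratio, heat map.

The *grasp point* of one hand is the centroid of its HAND, HANDTIP and THUMB
joints, ``Pgp = (Phand + Phandtip + Pthumb) / 3``, taken as a proxy for
where the handrail is held.  Analysis is restricted to the handrail's
straight part, the open stair-x interval 0 < Pgp_x < 1000 mm.  Within it, a
binary decision tree over the lateral/vertical coordinates (Pgp_y, Pgp_z)
classifies each frame as grasped or not grasped; the tree is evaluated with
stratified 5-fold cross-validation and its held-out confusion matrix and
accuracy are recorded.  The grasping ratio (grasped frames / all filtered
frames) summarizes handrail dependence per participant and direction, and a
heat map visualizes where along the rail grasps concentrate by mapping
grasped-frame points back to camera space and projecting them onto the
image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .camera import project
from .recording import HAND_TRIPLETS, CameraIntrinsics, Session, SkeletonFrame
from .stairframe import StairFrame

DEFAULT_SEGMENT_MM = (0.0, 1000.0)
#: tree hyper-parameters: small trees, matching the shallow published models
TREE_PARAMS = {"criterion": "gini", "max_depth": 4, "min_samples_leaf": 5}
CLASSES = ("not_grasped", "grasped")


@dataclass(frozen=True)
class GraspSample:
    """One frame's grasp point in stair coordinates (mm) with optional label."""

    timestamp: float
    pgp: np.ndarray
    label: str = "unlabeled"
    side: str = "right"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pgp", np.asarray(self.pgp, dtype=float).reshape(3))
        if not np.all(np.isfinite(self.pgp)):
            raise ValueError("grasp point must be finite")
        if self.label not in ("grasped", "not_grasped", "unlabeled"):
            raise ValueError(f"unknown grasp label {self.label!r}")


def grasp_point(frame: SkeletonFrame, side: str) -> GraspSample | None:
    """Centroid of the side's HAND/HANDTIP/THUMB joints, or None if incomplete.

    None is the skip-frame signal: a frame whose hand triplet is not fully
    tracked contributes no grasp sample.
    """
    triplet = HAND_TRIPLETS[side]
    if not frame.has_hand(side):
        return None
    pgp = sum(frame.joint(j) for j in triplet) / 3.0
    return GraspSample(timestamp=frame.timestamp, pgp=pgp, label=frame.grasp_label, side=side)


def choose_hand_side(session: Session) -> str:
    """Pick the hand nearer the handrail plane (smaller mean |stair-y| of Pgp)."""
    if session.space != "stair":
        raise ValueError("hand-side choice needs stair coordinates")
    best_side, best_dist = None, np.inf
    for side in ("left", "right"):
        ys = [
            abs(grasp_point(f, side).pgp[1])
            for f in session.frames
            if f.has_hand(side)
        ]
        if ys and float(np.mean(ys)) < best_dist:
            best_side, best_dist = side, float(np.mean(ys))
    if best_side is None:
        raise ValueError("no complete hand triplet in session")
    return best_side


def grasp_points(session: Session, side: str = "auto") -> list[GraspSample]:
    """All grasp samples of a stair-space session for one hand side."""
    if session.space != "stair":
        raise ValueError("grasp points are computed in stair coordinates")
    if side == "auto":
        side = choose_hand_side(session)
    out = []
    for f in session.frames:
        s = grasp_point(f, side)
        if s is not None:
            out.append(s)
    return out


def straight_segment_filter(
    samples, segment: tuple[float, float] = DEFAULT_SEGMENT_MM
) -> list[GraspSample]:
    """Keep samples on the handrail's straight part: lo < Pgp_x < hi (strict)."""
    lo, hi = segment
    return [s for s in samples if lo < s.pgp[0] < hi]


def cv_accuracy_from_confusion(matrix) -> float:
    """Classification accuracy of a 2x2 confusion matrix: trace / total."""
    m = np.asarray(matrix, dtype=float).reshape(2, 2)
    if np.any(m < 0):
        raise ValueError("confusion counts must be non-negative")
    total = m.sum()
    if total <= 0:
        raise ValueError("confusion matrix has zero total")
    return float(np.trace(m) / total)


@dataclass
class GraspClassifier:
    """A fitted grasp/no-grasp decision tree with its cross-validation record.

    The tree is stored as plain node arrays (feature, threshold, children,
    leaf votes) so a saved model round-trips through JSON without pickling;
    prediction traverses these arrays directly.  Predictors are Pgp_y and
    Pgp_z (mm, stair space).  ``confusion`` rows are true (not_grasped,
    grasped), columns predicted, accumulated over held-out folds.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class: np.ndarray
    confusion: np.ndarray
    cv_accuracy: float
    folds: int
    seed: int
    fold_assignment: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (0.0 <= self.cv_accuracy <= 1.0):
            raise ValueError("cv accuracy must lie in [0, 1]")

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Predict class indices (0=not_grasped, 1=grasped) for (N, 2) features."""
        X = np.asarray(features, dtype=float).reshape(-1, 2)
        out = np.empty(len(X), dtype=int)
        for i, x in enumerate(X):
            node = 0
            while self.children_left[node] != -1:
                f, thr = self.feature[node], self.threshold[node]
                node = self.children_left[node] if x[f] <= thr else self.children_right[node]
            out[i] = self.leaf_class[node]
        return out

    def to_dict(self) -> dict:
        return {
            "predictors": ["pgp_y", "pgp_z"],
            "classes": list(CLASSES),
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "leaf_class": self.leaf_class.tolist(),
            "confusion": self.confusion.tolist(),
            "cv_accuracy": self.cv_accuracy,
            "folds": self.folds,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GraspClassifier":
        return cls(
            children_left=np.array(d["children_left"], dtype=int),
            children_right=np.array(d["children_right"], dtype=int),
            feature=np.array(d["feature"], dtype=int),
            threshold=np.array(d["threshold"], dtype=float),
            leaf_class=np.array(d["leaf_class"], dtype=int),
            confusion=np.array(d["confusion"], dtype=int),
            cv_accuracy=float(d["cv_accuracy"]),
            folds=int(d["folds"]),
            seed=int(d["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GraspClassifier":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _features_labels(samples) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[s.pgp[1], s.pgp[2]] for s in samples])
    y = np.array([CLASSES.index(s.label) for s in samples])
    return X, y


def _from_sklearn_tree(tree: DecisionTreeClassifier) -> dict:
    t = tree.tree_
    votes = t.value.reshape(t.node_count, -1)
    return {
        "children_left": t.children_left.copy(),
        "children_right": t.children_right.copy(),
        "feature": t.feature.copy(),
        "threshold": t.threshold.copy(),
        "leaf_class": np.asarray(tree.classes_)[np.argmax(votes, axis=1)].astype(int),
    }


def train_grasp_classifier(samples, folds: int = 5, seed: int = 0, **tree_params) -> GraspClassifier:
    """Fit the grasp decision tree with stratified k-fold cross-validation.

    The confusion matrix and accuracy are accumulated over the held-out
    folds (fold shuffling controlled by ``seed``); the returned tree is then
    refit on all labeled samples.  Requires labeled samples of both classes,
    at least ``folds`` per class.
    """
    samples = [s for s in samples if s.label != "unlabeled"]
    X, y = _features_labels(samples)
    counts = np.bincount(y, minlength=2)
    if np.any(counts == 0):
        raise ValueError("training needs both grasped and not_grasped samples")
    if np.any(counts < folds):
        raise ValueError(f"need at least {folds} samples per class, got {counts.tolist()}")

    params = {**TREE_PARAMS, **tree_params}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    confusion = np.zeros((2, 2), dtype=int)
    fold_assignment = np.empty(len(y), dtype=int)
    for k, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        fold_assignment[test_idx] = k
        fold_tree = DecisionTreeClassifier(random_state=seed, **params)
        fold_tree.fit(X[train_idx], y[train_idx])
        pred = fold_tree.predict(X[test_idx])
        for yt, yp in zip(y[test_idx], pred):
            confusion[yt, yp] += 1

    final = DecisionTreeClassifier(random_state=seed, **params)
    final.fit(X, y)
    return GraspClassifier(
        **_from_sklearn_tree(final),
        confusion=confusion,
        cv_accuracy=cv_accuracy_from_confusion(confusion),
        folds=folds,
        seed=seed,
        fold_assignment=fold_assignment,
    )


def classify_frames(samples, model: GraspClassifier) -> list[GraspSample]:
    """Label every sample grasped/not_grasped with the fitted tree."""
    samples = list(samples)
    if not samples:
        return []
    X, _ = _features_labels_unlabeled(samples)
    pred = model.predict(X)
    return [replace(s, label=CLASSES[p]) for s, p in zip(samples, pred)]


def _features_labels_unlabeled(samples) -> tuple[np.ndarray, None]:
    X = np.array([[s.pgp[1], s.pgp[2]] for s in samples])
    return X, None


@dataclass(frozen=True)
class GraspRatio:
    """Grasped-frame fraction over the straight-segment frames."""

    ratio: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ratio <= 1.0):
            raise ValueError("grasp ratio must lie in [0, 1]")


def grasp_ratio(labeled) -> GraspRatio:
    """Fraction of frames labeled grasped among all (filtered) frames."""
    labeled = list(labeled)
    if not labeled:
        raise ValueError("cannot compute a grasp ratio of zero frames")
    if any(s.label == "unlabeled" for s in labeled):
        raise ValueError("all samples must be classified before computing the ratio")
    n_grasp = sum(s.label == "grasped" for s in labeled)
    return GraspRatio(ratio=n_grasp / len(labeled), n=len(labeled))


# ---------------------------------------------------------------------------
# Heat map

def grasp_density(
    labeled,
    frame: StairFrame,
    intr: CameraIntrinsics,
    bandwidth_px: float = 15.0,
) -> tuple[np.ndarray, int]:
    """Image-plane density of grasped-frame grasp points.

    Grasped samples are inverse-transformed to camera space, perspective-
    projected, binned onto the image grid, and smoothed with a Gaussian
    kernel (sigma = ``bandwidth_px``).  Returns the (height, width) density
    (sum preserved up to boundary truncation) and the count of points
    skipped for being behind the camera or outside the image.
    """
    grid = np.zeros((intr.height, intr.width))
    skipped = 0
    pts = [s.pgp for s in labeled if s.label == "grasped"]
    if not pts:
        return grid, 0
    cam = frame.invert(np.vstack(pts))
    in_front = cam[:, 2] > 0
    skipped += int((~in_front).sum())
    if in_front.any():
        uv = project(cam[in_front], intr)
        ui = np.round(uv[:, 0]).astype(int)
        vi = np.round(uv[:, 1]).astype(int)
        ok = (ui >= 0) & (ui < intr.width) & (vi >= 0) & (vi < intr.height)
        skipped += int((~ok).sum())
        np.add.at(grid, (vi[ok], ui[ok]), 1.0)
    return gaussian_filter(grid, sigma=bandwidth_px), skipped


def heatmap(
    labeled,
    frame: StairFrame,
    intr: CameraIntrinsics,
    background: np.ndarray | None = None,
    bandwidth_px: float = 15.0,
    alpha: float = 0.7,
    colormap: str = "jet",
) -> np.ndarray:
    """Render the grasp-point density as a colored overlay on an RGB image.

    Overlay intensity is proportional to local grasp frequency (red = most
    frequent with the default colormap); with no grasped frames the
    background is returned unchanged.  ``background`` defaults to a neutral
    gray canvas at the camera resolution.
    """
    from matplotlib import colormaps

    if background is None:
        background = np.full((intr.height, intr.width, 3), 96, dtype=np.uint8)
    bg = np.asarray(background)
    if bg.shape[:2] != (intr.height, intr.width):
        raise ValueError("background size must match the camera resolution")

    density, skipped = grasp_density(labeled, frame, intr, bandwidth_px)
    if skipped:
        warnings.warn(f"heatmap skipped {skipped} point(s) outside the view", stacklevel=2)
    if density.max() <= 0:
        return bg.copy()
    norm = density / density.max()
    colors = (np.asarray(colormaps[colormap](norm))[..., :3] * 255).astype(float)
    weight = (alpha * norm)[..., None]
    out = (1.0 - weight) * bg.astype(float) + weight * colors
    return np.clip(out, 0, 255).astype(np.uint8)
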