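"""End-to-end orchestration: cohort simulation, full analysis, reports.

``run_full_analysis`` strings the stages together for a directory of
recorded (or simulated) sessions: load and label-filter, calibrate the
stair frame, transform, measure speeds, train the grasp classifier on the
labeled sample sessions, classify everything else, and write the speed
table, grasp-ratio tables, confusion report, and per-participant heat maps.
Every number in a report comes from one upstream operation; the report
layer only formats.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import grasp as grasp_mod
from . import kinematics as kin
from .grasp import (
    GraspClassifier,
    classify_frames,
    cv_accuracy_from_confusion,
    grasp_points,
    grasp_ratio,
    heatmap,
    straight_segment_filter,
    train_grasp_classifier,
)
from .recording import DepthMap, Session, filter_sessions, load_session, save_session
from .scene import (
    SceneSpec,
    TraversalSpec,
    make_depth_map,
    segment_coverage_episode,
    simulate_traversal,
)
from .stairframe import StairFrame, build_stair_frame, load_calibration, to_stair_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and analysis parameters for a full run.

    Parameter defaults follow the published protocol: speed window and
    straight segment 0–1000 mm on stair x, 5 cross-validation folds,
    15 Hz nominal sampling.
    """

    sessions_dir: Path
    calibration_file: Path | None = None
    output_dir: Path = Path("stairwatch_out")
    model_file: Path | None = None
    window: tuple[float, float] = (0.0, 1000.0)
    segment: tuple[float, float] = (0.0, 1000.0)
    folds: int = 5
    seed: int = 0
    hand_side: str = "auto"
    speed_definition: str = "path"
    kernel_bandwidth: float = 15.0

    def __post_init__(self) -> None:
        self.sessions_dir = Path(self.sessions_dir)
        self.output_dir = Path(self.output_dir)
        if self.calibration_file is not None:
            self.calibration_file = Path(self.calibration_file)
        if self.model_file is not None:
            self.model_file = Path(self.model_file)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key-value JSON config; keyword overrides win."""
        raw = json.loads(Path(path).read_text())
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        if "segment" in raw:
            raw["segment"] = tuple(raw["segment"])
        return cls(**raw)


def report_confusion(model_or_matrix) -> str:
    """Format a 2x2 grasp confusion matrix with row totals and accuracy.

    Accepts a trained :class:`GraspClassifier` or a raw 2x2 count matrix
    (rows true non-grip/grip, columns predicted).
    """
    if isinstance(model_or_matrix, GraspClassifier):
        m = np.asarray(model_or_matrix.confusion)
    else:
        m = np.asarray(model_or_matrix)
    m = m.reshape(2, 2).astype(int)
    acc = cv_accuracy_from_confusion(m)
    lines = [
        f"{'':22s}{'Predicted non-grip':>20s}{'Predicted grip':>16s}",
        f"{'Non-grip (n = ' + str(m[0].sum()) + ')':22s}{m[0, 0]:>20d}{m[0, 1]:>16d}",
        f"{'Grip (n = ' + str(m[1].sum()) + ')':22s}{m[1, 0]:>20d}{m[1, 1]:>16d}",
        f"Accuracy: {100 * acc:.1f}%",
    ]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Synthetic cohort (study-condition defaults)

#: per-participant mean traversal speeds, m/s (ascent, descent)
COHORT_SPEEDS = {
    "p1": (0.54, 0.60), "p2": (0.52, 0.58), "p3": (0.50, 0.68),
    "p4": (0.55, 0.67), "p5": (0.24, 0.39), "p6": (0.37, 0.24),
}
#: per-participant handrail grasp fractions (ascent, descent)
COHORT_GRASP_FRACTIONS = {
    "p1": (0.046, 0.038), "p2": (0.25, 0.51), "p3": (0.025, 0.087),
    "p4": (0.19, 0.093), "p5": (0.816, 0.482), "p6": (0.763, 0.833),
}
COHORT_SPEED_SD = 0.04  # m/s between-traversal spread
COHORT_JOINT_NOISE_SD = 10.0  # mm


def simulate_cohort(
    out_dir: str | Path,
    seed: int = 0,
    traversals_per_direction: int = 3,
    n_labeled: int = 2,
    participants: dict | None = None,
    grasp_fractions: dict | None = None,
    joint_noise_sd: float = COHORT_JOINT_NOISE_SD,
    scene: SceneSpec | None = None,
) -> Path:
    """Write a synthetic cohort of session directories plus calibration.

    Emulates the two-house study layout: six participants with the
    configured per-direction mean speeds and grasp fractions, a shared
    staircase scene (``depth.png`` + ``calibration.json`` at the cohort
    root), and ``n_labeled`` grasp-labeled sample sessions used to train
    the classifier.  Each session directory carries a ``truth.json``
    sidecar with its generator ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scene = scene or SceneSpec()
    rng = np.random.default_rng(seed)

    depth, landmarks = make_depth_map(scene, seed=int(rng.integers(2**31)))
    depth.save(out_dir / "depth.png")
    calib = landmarks.calibration()
    (out_dir / "calibration.json").write_text(json.dumps(calib, indent=2))
    (out_dir / "intrinsics.json").write_text(json.dumps(scene.intrinsics.to_dict(), indent=2))

    speeds = participants or COHORT_SPEEDS
    fractions = grasp_fractions or COHORT_GRASP_FRACTIONS
    for pid, (v_up, v_down) in speeds.items():
        f_up, f_down = fractions.get(pid, (0.0, 0.0))
        for direction, v_mean, f in (("up", v_up, f_up), ("down", v_down, f_down)):
            for k in range(traversals_per_direction):
                v = max(0.05, float(rng.normal(v_mean, COHORT_SPEED_SD)))
                spec = TraversalSpec(
                    direction=direction,
                    speed=v,
                    joint_noise_sd=joint_noise_sd,
                    seed=int(rng.integers(2**31)),
                )
                episodes = (
                    _random_episode(spec, f, rng) if f > 0 else ()
                )
                spec = TraversalSpec(
                    **{**spec.__dict__, "grasp_episodes": episodes}
                )
                session, truth = simulate_traversal(scene, spec, participant=pid)
                sdir = out_dir / f"{pid}_{direction}_{k:02d}"
                save_session(session, sdir)
                (sdir / "truth.json").write_text(json.dumps({
                    "direction": truth.direction,
                    "speed": truth.speed,
                    "frame_grasp": truth.frame_grasp.astype(int).tolist(),
                }, indent=2))

    # labeled sample sessions (both classes present) for classifier training
    for k in range(n_labeled):
        spec = TraversalSpec(
            direction="up",
            speed=0.4,
            joint_noise_sd=joint_noise_sd,
            seed=int(rng.integers(2**31)),
        )
        episodes = segment_coverage_episode(spec, 0.5)
        spec = TraversalSpec(**{**spec.__dict__, "grasp_episodes": episodes})
        session, _ = simulate_traversal(scene, spec, label_grasps=True, participant="sample")
        save_session(session, out_dir / f"sample_labeled_{k:02d}")
    return out_dir


def _random_episode(spec: TraversalSpec, fraction: float, rng) -> tuple[tuple[float, float], ...]:
    """One grasp episode with in-segment coverage ``fraction``, random phase."""
    span = spec.x_end - spec.x_start
    s0 = (0.0 - spec.x_start) / span
    s1 = (1000.0 - spec.x_start) / span
    if spec.direction == "down":
        s0, s1 = 1.0 - s1, 1.0 - s0
    length = fraction * (s1 - s0)
    start = float(rng.uniform(s0, s1 - length)) if s1 - length > s0 else s0
    return ((start, start + length),)


# ---------------------------------------------------------------------------
# Full analysis

def discover_sessions(sessions_dir: str | Path) -> list[Session]:
    """Load every session directory under ``sessions_dir`` (sorted by name)."""
    sessions = []
    for p in sorted(Path(sessions_dir).iterdir()):
        if p.is_dir() and (p / "meta.json").is_file():
            sessions.append(load_session(p))
    return sessions


def _stair_frame_for(config: PipelineConfig, sessions: list[Session]) -> StairFrame:
    if config.calibration_file is None:
        raise ValueError("a calibration file is required")
    calib = load_calibration(config.calibration_file)
    depth_map = None
    depth_path = config.calibration_file.parent / "depth.png"
    if depth_path.is_file() and sessions:
        depth_map = DepthMap.load(depth_path, sessions[0].intrinsics)
    frame, _ = build_stair_frame(calib, depth_map)
    return frame


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run the whole pipeline and write the report bundle.

    Outputs under ``config.output_dir``: ``speed_table.csv`` (per-participant
    ascent/descent n, mean, SD and up-vs-down p), ``grasp_ratio_up.csv`` and
    ``grasp_ratio_down.csv`` (per-participant n and ratio), ``model.json``,
    ``confusion.txt``, ``stair_frame.json``, per-participant heat maps, and
    ``run_log.txt``.  Deterministic for a fixed seed and inputs.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    sessions = discover_sessions(config.sessions_dir)
    if not sessions:
        raise ValueError(f"no sessions found under {config.sessions_dir}")
    analyzed = filter_sessions(sessions, carried="none")
    log_lines.append(f"sessions: {len(sessions)} loaded, {len(analyzed)} with carried=none")

    frame = _stair_frame_for(config, analyzed)
    frame.save(out / "stair_frame.json")
    stair_sessions = [to_stair_frame(s, frame) for s in analyzed]

    # --- speeds (unlabeled activity sessions only; labeled samples are fixtures)
    activity: list[Session] = []
    training: list[Session] = []
    for s in stair_sessions:
        has_labels = any(f.grasp_label != "unlabeled" for f in s.frames)
        (training if has_labels else activity).append(s)
    measurements = []
    for s in activity:
        try:
            measurements.append(
                kin.compute_speed(s, window=config.window, definition=config.speed_definition)
            )
        except kin.IncompleteTraversalError as exc:
            log_lines.append(f"speed skipped for {s.participant}/{s.direction}: {exc}")
    speed_table = kin.summarize_participant(measurements) if measurements else pd.DataFrame()
    speed_table.to_csv(out / "speed_table.csv", index=False, float_format="%.4f")
    log_lines.append(f"speed: {len(measurements)} traversals measured")

    # --- grasp classifier
    if config.model_file is not None:
        model = GraspClassifier.load(config.model_file)
        log_lines.append(f"model: loaded from {config.model_file}")
    else:
        train_samples = []
        for s in training:
            train_samples.extend(
                straight_segment_filter(grasp_points(s, side=config.hand_side), config.segment)
            )
        if not train_samples:
            raise ValueError("no labeled sessions to train the grasp classifier")
        model = train_grasp_classifier(train_samples, folds=config.folds, seed=config.seed)
        log_lines.append(
            f"model: trained on {len(train_samples)} samples, "
            f"cv accuracy {100 * model.cv_accuracy:.1f}%"
        )
    model.save(out / "model.json")
    (out / "confusion.txt").write_text(report_confusion(model) + "\n")

    # --- grasp ratios + heat maps
    ratio_rows: dict[str, list[dict]] = {"up": [], "down": []}
    heat_samples: dict[str, list] = {}
    by_pd: dict[tuple[str, str], list] = {}
    for s in activity:
        samples = straight_segment_filter(grasp_points(s, side=config.hand_side), config.segment)
        if not samples:
            continue
        labeled = classify_frames(samples, model)
        direction = s.direction if s.direction in ("up", "down") else kin.infer_direction(s)
        by_pd.setdefault((s.participant, direction), []).extend(labeled)
        heat_samples.setdefault(s.participant, []).extend(labeled)
    for (pid, direction), labeled in sorted(by_pd.items()):
        r = grasp_ratio(labeled)
        ratio_rows[direction].append(
            {"participant": pid, "n": r.n, "grasp_ratio_pct": round(100 * r.ratio, 1)}
        )
    for direction in ("up", "down"):
        pd.DataFrame(ratio_rows[direction]).to_csv(
            out / f"grasp_ratio_{direction}.csv", index=False
        )
    intr = analyzed[0].intrinsics
    for pid, labeled in sorted(heat_samples.items()):
        img = heatmap(labeled, frame, intr, bandwidth_px=config.kernel_bandwidth)
        iio.imwrite(out / f"heatmap_{pid}.png", img, extension=".png")
    log_lines.append(f"grasp: ratios for {len(by_pd)} participant/direction groups")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return {
        "speed_table": speed_table,
        "measurements": measurements,
        "model": model,
        "ratios": {d: pd.DataFrame(ratio_rows[d]) for d in ("up", "down")},
        "stair_frame": frame,
        "output_dir": out,
        "log": log_lines,
    }
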