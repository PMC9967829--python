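"""Traversal speed over the stair-x window and between-group comparisons.

A participant's ascent/descent speed is the average pelvis speed across the
stair-x window 0–1000 mm: the 3-D path length of the pelvis between its
first entry into and last exit from the window, divided by the elapsed time,
with window-boundary crossings linearly interpolated between adjacent
frames.  Because per-frame skeleton noise inflates raw step lengths at
15 Hz, the pelvis trajectory is low-pass smoothed (centered moving average,
default 7 frames ~ 0.47 s) before the path is summed; the filter is exact on
constant-velocity motion.  A displacement/time variant ("chord speed") is
available via ``definition='displacement'``.

Group comparisons use Welch's two-sample t-test (two-sided), appropriate for
the very unequal group sizes and variances seen between participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .recording import Session

DEFAULT_WINDOW_MM = (0.0, 1000.0)
DEFAULT_SMOOTH_WINDOW = 7
_MIN_NET_DISPLACEMENT_MM = 100.0


class IncompleteTraversalError(ValueError):
    """The pelvis never fully crosses the measurement window."""


class IndeterminateDirectionError(ValueError):
    """Net pelvis displacement too small to call a direction."""


@dataclass(frozen=True)
class SpeedMeasurement:
    """One traversal's speed over the stair-x window."""

    participant: str
    direction: str
    speed: float  # m/s
    n_frames_in_window: int
    window: tuple[float, float] = DEFAULT_WINDOW_MM

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise ValueError("speed must be positive")
        if self.n_frames_in_window < 2:
            raise ValueError("need at least 2 frames inside the window")


@dataclass(frozen=True)
class SpeedComparison:
    """Welch t-test summary between two groups of speed measurements."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


def _pelvis_trajectory(session: Session) -> tuple[np.ndarray, np.ndarray]:
    t, p = session.joint_trajectory("PELVIS")
    if len(t) < 2:
        raise IncompleteTraversalError("fewer than 2 pelvis frames")
    return t, p


def infer_direction(session: Session, use_label: bool = True) -> str:
    """Infer ascent/descent from net pelvis stair-x displacement.

    A manual ``up``/``down`` metadata label, when present, overrides the
    geometric inference (set ``use_label=False`` to force it).  Requires the
    session to be in stair coordinates.
    """
    if use_label and session.direction in ("up", "down"):
        return session.direction
    if session.space != "stair":
        raise ValueError("direction inference needs stair-space coordinates")
    _, p = _pelvis_trajectory(session)
    net = p[-1, 0] - p[0, 0]
    if abs(net) < _MIN_NET_DISPLACEMENT_MM:
        raise IndeterminateDirectionError(
            f"net pelvis displacement {net:.0f} mm < {_MIN_NET_DISPLACEMENT_MM:.0f} mm"
        )
    return "up" if net > 0 else "down"


def _smooth(t: np.ndarray, p: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average ('valid' mode: edge frames are dropped)."""
    if window <= 1 or len(t) < window + 2:
        return t, p
    kern = np.ones(window) / window
    half = window // 2
    smoothed = np.column_stack(
        [np.convolve(p[:, i], kern, mode="valid") for i in range(3)]
    )
    return t[half : len(t) - half], smoothed


def _window_path(
    t: np.ndarray, p: np.ndarray, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Clip a piecewise-linear trajectory to the stair-x window.

    Returns the in-window times and positions, with the entry and exit
    points linearly interpolated onto the window boundary, plus the count of
    original frames inside the window.
    """
    lo, hi = window
    x = p[:, 0]
    if not (np.min(x) < lo and np.max(x) > hi):
        raise IncompleteTraversalError(
            f"pelvis x spans [{np.min(x):.0f}, {np.max(x):.0f}] mm; "
            f"must cross both {lo:.0f} and {hi:.0f}"
        )
    inside = (x >= lo) & (x <= hi)
    if int(inside.sum()) < 2:
        raise IncompleteTraversalError("fewer than 2 frames inside the window")
    idx = np.nonzero(inside)[0]
    i, j = int(idx[0]), int(idx[-1])

    times = [t[i:j + 1]]
    points = [p[i:j + 1]]
    if i > 0:
        boundary = lo if x[i - 1] < lo else hi
        s = (boundary - x[i - 1]) / (x[i] - x[i - 1])
        times.insert(0, np.array([t[i - 1] + s * (t[i] - t[i - 1])]))
        points.insert(0, (p[i - 1] + s * (p[i] - p[i - 1]))[None, :])
    if j < len(x) - 1:
        boundary = lo if x[j + 1] < lo else hi
        s = (boundary - x[j]) / (x[j + 1] - x[j])
        times.append(np.array([t[j] + s * (t[j + 1] - t[j])]))
        points.append((p[j] + s * (p[j + 1] - p[j]))[None, :])
    return np.concatenate(times), np.vstack(points), int(inside.sum())


def compute_speed(
    session: Session,
    window: tuple[float, float] = DEFAULT_WINDOW_MM,
    definition: str = "path",
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> SpeedMeasurement:
    """Average pelvis speed across the stair-x window, in m/s.

    Parameters
    ----------
    window
        Stair-x bounds in millimetres (default 0–1000).
    definition
        ``'path'``: 3-D path length / elapsed time (default);
        ``'displacement'``: straight-line entry-to-exit distance / time.
    smooth_window
        Moving-average length in frames applied to the pelvis trajectory
        before the path is summed (1 disables; ignored for very short
        recordings).
    """
    if definition not in ("path", "displacement"):
        raise ValueError(f"unknown speed definition {definition!r}")
    if session.space != "stair":
        raise ValueError("speed is computed in stair coordinates")
    t, p = _pelvis_trajectory(session)
    if definition == "path":
        t, p = _smooth(t, p, smooth_window)
    times, points, n_in = _window_path(t, p, window)
    elapsed = times[-1] - times[0]
    if elapsed <= 0:
        raise IncompleteTraversalError("non-positive elapsed time in window")
    if definition == "path":
        dist_mm = float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))
    else:
        dist_mm = float(np.linalg.norm(points[-1] - points[0]))
    return SpeedMeasurement(
        participant=session.participant,
        direction=session.direction if session.direction != "unknown" else infer_direction(session),
        speed=dist_mm / elapsed / 1000.0,
        n_frames_in_window=n_in,
        window=tuple(window),
    )


def _speeds(values) -> np.ndarray:
    return np.array([v.speed if isinstance(v, SpeedMeasurement) else float(v) for v in values])


def compare_speeds(a, b, label_a: str = "A", label_b: str = "B") -> SpeedComparison:
    """Welch two-sample t-test (two-sided) between two speed groups.

    Accepts sequences of :class:`SpeedMeasurement` or raw m/s floats.  Two
    zero-variance samples with equal means are degenerate: they yield t=0,
    p=1 with a warning rather than an error, since perfectly repeated
    measurements carry no evidence of a difference.
    """
    xa, xb = _speeds(a), _speeds(b)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each group needs at least 2 measurements")
    var_a, var_b = float(np.var(xa, ddof=1)), float(np.var(xb, ddof=1))
    if var_a == 0.0 and var_b == 0.0:
        if np.isclose(xa.mean(), xb.mean()):
            warnings.warn("both groups have zero variance and equal means; p set to 1", stacklevel=2)
            t_stat, p_val = 0.0, 1.0
        else:
            warnings.warn("both groups have zero variance; difference is exact", stacklevel=2)
            t_stat = float(np.inf if xa.mean() > xb.mean() else -np.inf)
            p_val = 0.0
    else:
        res = stats.ttest_ind(xa, xb, equal_var=False)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return SpeedComparison(
        label_a=label_a, label_b=label_b,
        n_a=len(xa), n_b=len(xb),
        mean_a=float(xa.mean()), mean_b=float(xb.mean()),
        sd_a=float(np.std(xa, ddof=1)), sd_b=float(np.std(xb, ddof=1)),
        t_statistic=t_stat, p_value=p_val,
    )


def summarize_participant(measurements) -> pd.DataFrame:
    """Per-participant speed summary table (ascent vs descent).

    One row per participant: n/mean/SD for each direction plus the Welch
    p-value of the within-participant up-vs-down comparison.  A direction
    with a single measurement reports SD 0 and is flagged in ``notes``;
    the comparison p is NaN unless both directions have n >= 2.
    """
    ms = list(measurements)
    if not ms:
        raise ValueError("no measurements to summarize")
    rows = []
    participants = sorted({m.participant for m in ms})
    for pid in participants:
        row: dict[str, object] = {"participant": pid}
        notes = []
        groups = {}
        for direction in ("up", "down"):
            vals = _speeds([m for m in ms if m.participant == pid and m.direction == direction])
            groups[direction] = vals
            n = len(vals)
            row[f"{direction}_n"] = n
            row[f"{direction}_mean"] = float(vals.mean()) if n else np.nan
            if n >= 2:
                row[f"{direction}_sd"] = float(np.std(vals, ddof=1))
            else:
                row[f"{direction}_sd"] = 0.0
                notes.append(f"{direction}_sd_undefined")
        if len(groups["up"]) >= 2 and len(groups["down"]) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["p_up_vs_down"] = compare_speeds(groups["up"], groups["down"]).p_value
        else:
            row["p_up_vs_down"] = np.nan
        row["notes"] = ";".join(notes)
        rows.append(row)
    return pd.DataFrame(rows)
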