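"""Trajectory assembly, key-frame identification and mm-per-px calibration.

Detection runs frame by frame with the previous frame's marker pair as a
prior; isolated single-frame detection failures are filled by linear
interpolation and flagged, longer runs are reported as gaps.  Calibration
uses the known 5-mm sticker diameter by default; the acquisition device's
border inner edges serve as an alternative reference when their physical
separation is known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import DetectionParams, MarkerObservation, MarkerPair, detect_markers, select_pair
from .errors import CalibrationError, DetectionError, KeyframeError, TrackingError

__all__ = [
    "Trajectory",
    "Calibration",
    "KeyFrames",
    "GapReport",
    "track",
    "calibrate_from_markers",
    "calibrate_from_border",
    "find_border_edges",
    "find_keyframes",
    "read_trajectory_csv",
    "write_trajectory_csv",
]


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed A/B marker positions across a frame sequence.

    Positions are (x, y) with x = column and y = row for pixel-space
    trajectories; the synthetic generator also uses this container for
    exact millimetre trajectories (``source_id`` records which).
    """

    a_px: np.ndarray                  # (n, 2)
    b_px: np.ndarray                  # (n, 2)
    fps: float = 30.0
    source_id: str = ""
    frame_index: np.ndarray = None    # strictly increasing ints
    interpolated: np.ndarray = None   # bool flags per frame

    def __post_init__(self):
        a = np.asarray(self.a_px, dtype=float)
        b = np.asarray(self.b_px, dtype=float)
        if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
            raise TrackingError("a_px and b_px must both have shape (n, 2)")
        object.__setattr__(self, "a_px", a)
        object.__setattr__(self, "b_px", b)
        n = len(a)
        idx = (np.arange(n) if self.frame_index is None
               else np.asarray(self.frame_index, dtype=int))
        if len(idx) != n or (np.diff(idx) <= 0).any():
            raise TrackingError("frame_index must be strictly increasing, one per frame")
        object.__setattr__(self, "frame_index", idx)
        interp = (np.zeros(n, dtype=bool) if self.interpolated is None
                  else np.asarray(self.interpolated, dtype=bool))
        object.__setattr__(self, "interpolated", interp)

    def __len__(self) -> int:
        return len(self.a_px)

    @property
    def time_s(self) -> np.ndarray:
        return self.frame_index / self.fps

    @property
    def has_gaps(self) -> bool:
        return bool(np.isnan(self.a_px).any() or np.isnan(self.b_px).any())


@dataclass(frozen=True)
class GapReport:
    """Which frames were interpolated and which remain unresolved."""

    interpolated: list[int] = field(default_factory=list)
    unresolved: list[int] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale plus the left/right orientation convention.

    ``mirror_x = True`` means image-left corresponds to the subject's right
    (the usual case for unmirrored recorded video); all signed lateral
    quantities downstream are expressed in the subject's frame using this
    flag, so direction labels remain anatomically auditable.
    """

    mm_per_px: float
    method: str                       # "marker_diameter" | "border_width" | "manual"
    reference_length_mm: float
    reference_length_px: float
    mirror_x: bool = True

    def __post_init__(self):
        if self.mm_per_px <= 0 or self.reference_length_px <= 0:
            raise CalibrationError("calibration lengths must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mm_per_px": self.mm_per_px, "method": self.method,
            "reference_length_mm": self.reference_length_mm,
            "reference_length_px": self.reference_length_px,
            "mirror_x": self.mirror_x,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Calibration":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class KeyFrames:
    """Rest (closed), maximum-opening and re-closed frame indices."""

    rest_index: int
    max_open_index: int
    closed_again_index: int | None = None
    rest_a_px: tuple[float, float] | None = None   # median rest positions
    rest_b_px: tuple[float, float] | None = None

    def __post_init__(self):
        if self.rest_index >= self.max_open_index:
            raise KeyframeError("rest frame must precede maximum opening")
        if self.closed_again_index is not None and self.closed_again_index <= self.max_open_index:
            raise KeyframeError("re-closure must follow maximum opening")

    def shifted(self, k: int) -> "KeyFrames":
        return replace(
            self, rest_index=self.rest_index + k,
            max_open_index=self.max_open_index + k,
            closed_again_index=None if self.closed_again_index is None
            else self.closed_again_index + k,
        )


def track(frames: np.ndarray, params: DetectionParams | None = None,
          fps: float = 30.0, source_id: str = "",
          gating_radius_px: float | None = None,
          max_missing_fraction: float = 0.2) -> tuple[Trajectory, GapReport]:
    """Detect and associate both markers across a frame stack.

    The first frame must yield both markers (it seeds the prior); later
    frames are matched to the previous pair by gated nearest-neighbour
    assignment.  Single missing frames are linearly interpolated and
    flagged; runs of two or more are left as gaps and reported.  More than
    ``max_missing_fraction`` missing frames aborts tracking.
    """
    frames = np.asarray(frames)
    n = len(frames)
    if n < 3:
        raise TrackingError("need at least 3 frames to track a cycle")
    params = params or DetectionParams()

    a = np.full((n, 2), np.nan)
    b = np.full((n, 2), np.nan)
    messages: list[str] = []
    missing: list[int] = []

    obs0 = detect_markers(frames[0], params, frame_index=0)
    try:
        prior = select_pair(obs0)
    except DetectionError as exc:
        raise TrackingError(f"first frame undetectable: {exc}") from exc
    a[0], b[0] = prior.a.centroid, prior.b.centroid

    for k in range(1, n):
        obs = detect_markers(frames[k], params, frame_index=k)
        try:
            pair = select_pair(obs, prior=prior, gating_radius_px=gating_radius_px)
        except DetectionError as exc:
            missing.append(k)
            messages.append(str(exc))
            continue
        a[k], b[k] = pair.a.centroid, pair.b.centroid
        prior = pair

    if len(missing) > max_missing_fraction * n:
        raise TrackingError(
            f"{len(missing)}/{n} frames undetectable (> {max_missing_fraction:.0%}); "
            f"first failures: {messages[:3]}"
        )

    interpolated, unresolved = [], []
    for k in missing:
        prev_ok = k - 1 not in missing and k - 1 >= 0
        next_ok = k + 1 not in missing and k + 1 < n
        if prev_ok and next_ok:
            a[k] = 0.5 * (a[k - 1] + a[k + 1])
            b[k] = 0.5 * (b[k - 1] + b[k + 1])
            interpolated.append(k)
        else:
            unresolved.append(k)

    traj = Trajectory(
        a_px=a, b_px=b, fps=fps, source_id=source_id,
        interpolated=np.isin(np.arange(n), interpolated),
    )
    return traj, GapReport(interpolated=interpolated, unresolved=unresolved, messages=messages)


def calibrate_from_markers(observations: list[MarkerObservation],
                           sticker_diameter_mm: float = 5.0,
                           mirror_x: bool = True) -> Calibration:
    """Scale from the known sticker diameter and the observed blob areas.

    Uses the mean equivalent-circle diameter ``2*sqrt(area/pi)`` over the
    supplied (ideally rest-frame) observations.
    """
    if not observations:
        raise CalibrationError("need at least one marker observation to calibrate")
    areas = np.array([m.area for m in observations], dtype=float)
    if (areas <= 0).any():
        raise CalibrationError("marker observation with non-positive area")
    diam_px = float(np.mean(2.0 * np.sqrt(areas / np.pi)))
    return Calibration(
        mm_per_px=sticker_diameter_mm / diam_px,
        method="marker_diameter",
        reference_length_mm=sticker_diameter_mm,
        reference_length_px=diam_px,
        mirror_x=mirror_x,
    )


def find_border_edges(frame: np.ndarray, level: float = 0.5) -> tuple[float, float]:
    """Locate the inner edges of the bright device border flanking the scene.

    Scans the column-median intensity profile inward from each side and
    returns the (left_inner, right_inner) column indices where the bright
    border ends, refined to sub-pixel by linear interpolation of the
    crossing of ``level``.
    """
    img = np.asarray(frame, dtype=float)
    profile = np.median(img, axis=0)
    w = len(profile)
    if profile[0] <= level or profile[-1] <= level:
        raise CalibrationError("no bright border found at the frame edges")
    li = 0
    while li + 1 < w and profile[li + 1] > level:
        li += 1
    ri = w - 1
    while ri - 1 > li and profile[ri - 1] > level:
        ri -= 1
    if ri - li < 2:
        raise CalibrationError("border edges not separated; frame looks fully bright")

    def cross(i0, i1):  # sub-pixel crossing of `level` between adjacent columns
        y0, y1 = profile[i0], profile[i1]
        return i0 + (level - y0) / (y1 - y0) * (i1 - i0) if y1 != y0 else float(i0)

    return cross(li, li + 1), cross(ri, ri - 1)


def calibrate_from_border(frame: np.ndarray, border_width_mm: float,
                          mirror_x: bool = True, level: float = 0.5) -> Calibration:
    """Scale from the physical distance between the device border's inner edges."""
    left, right = find_border_edges(frame, level=level)
    sep = right - left
    return Calibration(
        mm_per_px=border_width_mm / sep,
        method="border_width",
        reference_length_mm=border_width_mm,
        reference_length_px=sep,
        mirror_x=mirror_x,
    )


def find_keyframes(traj: Trajectory, threshold_px: float) -> KeyFrames:
    """Identify the rest (closed) frame, maximum opening and re-closure.

    The initial quasi-static run is the maximal prefix whose B positions
    stay within ``threshold_px`` of the first frame.  The rest position is
    the per-axis median over that run (noise suppression); the rest index
    is the run's last frame — the frame immediately "before mouth opening",
    which also makes the result shift by exactly k when k static frames are
    prepended.  Maximum opening is the frame of largest vertical B
    displacement from rest; re-closure is the last frame after it whose B
    position returns within the threshold of rest.
    """
    if traj.has_gaps:
        raise KeyframeError("trajectory has unresolved gaps; interpolate or trim first")
    b = traj.b_px
    a = traj.a_px
    n = len(b)
    d0 = np.hypot(b[:, 0] - b[0, 0], b[:, 1] - b[0, 1])
    moving = np.flatnonzero(d0 >= threshold_px)
    if moving.size == 0:
        raise KeyframeError("no opening event: B never moves beyond the motion threshold")
    run_end = int(moving[0])           # first moving frame; run is [0, run_end)
    if run_end == 0:
        run_end = 1                    # motion from the very start: rest = frame 0
    rest_b = np.median(b[:run_end], axis=0)
    rest_a = np.median(a[:run_end], axis=0)
    rest_index = run_end - 1

    vertical = np.abs(b[:, 1] - rest_b[1])
    max_open_index = int(np.argmax(vertical))
    if max_open_index <= rest_index or vertical[max_open_index] < threshold_px:
        raise KeyframeError("no opening event: no vertical excursion beyond threshold")

    dist_rest = np.hypot(b[:, 0] - rest_b[0], b[:, 1] - rest_b[1])
    post = np.flatnonzero((np.arange(n) > max_open_index) & (dist_rest < threshold_px))
    return KeyFrames(
        rest_index=rest_index,
        max_open_index=max_open_index,
        closed_again_index=int(post[-1]) if post.size else None,
        rest_a_px=(float(rest_a[0]), float(rest_a[1])),
        rest_b_px=(float(rest_b[0]), float(rest_b[1])),
    )


TRAJECTORY_COLUMNS = ["frame", "time_s", "ax_px", "ay_px", "bx_px", "by_px", "interpolated"]


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({
        "frame": traj.frame_index,
        "time_s": traj.time_s,
        "ax_px": traj.a_px[:, 0], "ay_px": traj.a_px[:, 1],
        "bx_px": traj.b_px[:, 0], "by_px": traj.b_px[:, 1],
        "interpolated": traj.interpolated.astype(int),
    }).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path, fps: float | None = None) -> Trajectory:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns and c != "interpolated"]
    if missing:
        raise TrackingError(f"trajectory CSV missing columns: {missing}")
    idx = df["frame"].to_numpy(dtype=int)
    if fps is None:
        dt = np.diff(df["time_s"].to_numpy())
        didx = np.diff(idx)
        fps = float(np.median(didx / dt)) if len(dt) and (dt > 0).all() else 30.0
    return Trajectory(
        a_px=df[["ax_px", "ay_px"]].to_numpy(),
        b_px=df[["bx_px", "by_px"]].to_numpy(),
        fps=fps,
        source_id=str(path),
        frame_index=idx,
        interpolated=df.get("interpolated", pd.Series(np.zeros(len(df)))).to_numpy().astype(bool),
    )
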