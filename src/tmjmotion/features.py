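"""Kinematic indices of the mouth-opening cycle.

With rest landmarks A, B (closed mouth) and their positions A', B' at
maximum opening, all in millimetres in the subject's anatomical frame
(x = subject's right, y = down):

* maximum mouth-opening distance = |y(B') - y(B)| — vertical displacement
  of the lower-lip landmark;
* offset distance = x(B') - x(B), signed, + = subject's right; its unsigned
  per-frame maximum over the cycle is the maximum offset distance;
* offset angle = signed angle between the rest segment AB and the current
  segment A''B'' (+ = path deviates to the subject's right);
* offset direction = side of the signed offset at the frame achieving the
  maximum offset magnitude, with a dead zone below which no call is made.

Per-frame offset-distance and offset-angle series over the open-close cycle
form the fluctuation diagrams; the RMS of their first differences is the
movement-stability summary (smoother series = more stable joint motion).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FeatureError
from .tracking import Calibration, KeyFrames, Trajectory

__all__ = [
    "KinematicFeatures",
    "FluctuationSeries",
    "compute_features",
    "fluctuation",
    "classify_direction",
    "signed_angle_deg",
    "trajectory_to_mm",
]

DIRECTION_THRESHOLD_MM = 0.5
MIN_AB_SEPARATION_MM = 5.0


def signed_angle_deg(v0, v1) -> np.ndarray:
    """Signed angle (degrees) from segment direction ``v0`` to ``v1``.

    In the subject frame (x right, y down), positive means ``v1`` is tilted
    toward the subject's right relative to ``v0``.
    """
    v0 = np.asarray(v0, dtype=float)
    v1 = np.atleast_2d(np.asarray(v1, dtype=float))
    num = v0[1] * v1[:, 0] - v0[0] * v1[:, 1]
    den = v0[0] * v1[:, 0] + v0[1] * v1[:, 1]
    out = np.degrees(np.arctan2(num, den))
    return out if out.size > 1 else out.reshape(-1)


def classify_direction(signed_offset_mm: float,
                       threshold_mm: float = DIRECTION_THRESHOLD_MM) -> str:
    """Side of lateral deviation: ``right`` / ``left`` / ``none``.

    Offsets within ``threshold_mm`` of zero are below calibration precision
    and yield ``none``.
    """
    if not np.isfinite(signed_offset_mm):
        raise FeatureError("offset must be finite to classify a direction")
    if signed_offset_mm > threshold_mm:
        return "right"
    if signed_offset_mm < -threshold_mm:
        return "left"
    return "none"


@dataclass(frozen=True)
class KinematicFeatures:
    """The five indices of one opening cycle (mm / degrees, subject frame)."""

    max_opening_mm: float
    max_offset_mm: float              # unsigned per-frame maximum
    offset_at_max_open_mm: float      # signed, at the maximum-opening frame
    max_offset_angle_deg: float       # unsigned per-frame maximum
    angle_at_max_open_deg: float      # signed
    offset_direction: str             # "left" | "right" | "none"
    key_frames: KeyFrames | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.key_frames is not None:
            d["key_frames"] = {
                "rest_index": self.key_frames.rest_index,
                "max_open_index": self.key_frames.max_open_index,
                "closed_again_index": self.key_frames.closed_again_index,
            }
        return d

    def to_json(self, path: str | Path, provenance: dict | None = None) -> None:
        payload = self.to_dict()
        if provenance:
            payload["provenance"] = provenance
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass(frozen=True)
class FluctuationSeries:
    """Per-frame offset/angle/opening series over the cycle plus stability RMS."""

    time_s: np.ndarray
    opening_mm: np.ndarray
    offset_distance_mm: np.ndarray    # signed
    offset_angle_deg: np.ndarray      # signed
    stability_rms_distance: float     # RMS of first differences, mm
    stability_rms_angle: float        # RMS of first differences, deg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s,
            "opening_mm": self.opening_mm,
            "offset_mm": self.offset_distance_mm,
            "angle_deg": self.offset_angle_deg,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def trajectory_to_mm(traj: Trajectory, calib: Calibration) -> tuple[np.ndarray, np.ndarray]:
    """Convert a pixel trajectory to anatomical millimetres.

    Applies the scale and, if the calibration records a mirrored image
    (image-left = subject-right), flips the x axis so that +x is the
    subject's right.
    """
    sx = -1.0 if calib.mirror_x else 1.0
    a = traj.a_px * calib.mm_per_px
    b = traj.b_px * calib.mm_per_px
    a[:, 0] *= sx
    b[:, 0] *= sx
    return a, b


def _cycle_slice(traj: Trajectory, keys: KeyFrames) -> slice:
    stop = len(traj) if keys.closed_again_index is None else keys.closed_again_index + 1
    return slice(keys.rest_index, stop)


def _rest_points(a_mm, b_mm, calib: Calibration, keys: KeyFrames):
    if keys.rest_a_px is not None and keys.rest_b_px is not None:
        sx = -1.0 if calib.mirror_x else 1.0
        ra = np.array(keys.rest_a_px) * calib.mm_per_px
        rb = np.array(keys.rest_b_px) * calib.mm_per_px
        ra[0] *= sx
        rb[0] *= sx
        return ra, rb
    return a_mm[keys.rest_index], b_mm[keys.rest_index]


def _series(traj: Trajectory, calib: Calibration, keys: KeyFrames):
    if traj.has_gaps:
        raise FeatureError("trajectory has unresolved gaps")
    a_mm, b_mm = trajectory_to_mm(traj, calib)
    rest_a, rest_b = _rest_points(a_mm, b_mm, calib, keys)
    if np.hypot(*(rest_b - rest_a)) < MIN_AB_SEPARATION_MM:
        raise FeatureError(
            f"markers A and B are closer than {MIN_AB_SEPARATION_MM} mm at rest; "
            "implausible landmark geometry"
        )
    win = _cycle_slice(traj, keys)
    opening = b_mm[win, 1] - rest_b[1]
    offset = b_mm[win, 0] - rest_b[0]
    angle = signed_angle_deg(rest_b - rest_a, b_mm[win] - a_mm[win])
    return win, opening, offset, angle


def compute_features(traj: Trajectory, calib: Calibration, keys: KeyFrames,
                     direction_threshold_mm: float = DIRECTION_THRESHOLD_MM) -> KinematicFeatures:
    """Extract the opening/offset indices from a calibrated trajectory.

    Maxima of the offset distance and angle are taken over the whole cycle's
    per-frame series (deviation can peak during closing), while the values
    at the maximum-opening frame are reported alongside.
    """
    win, opening, offset, angle = _series(traj, calib, keys)
    i_open = keys.max_open_index - win.start
    if not 0 <= i_open < len(opening):
        raise FeatureError("max_open_index outside the cycle window")
    k_off = int(np.argmax(np.abs(offset)))
    return KinematicFeatures(
        max_opening_mm=float(abs(opening[i_open])),
        max_offset_mm=float(abs(offset[k_off])),
        offset_at_max_open_mm=float(offset[i_open]),
        max_offset_angle_deg=float(np.max(np.abs(angle))),
        angle_at_max_open_deg=float(angle[i_open]),
        offset_direction=classify_direction(float(offset[k_off]), direction_threshold_mm),
        key_frames=keys,
    )


def fluctuation(traj: Trajectory, calib: Calibration, keys: KeyFrames) -> FluctuationSeries:
    """Per-frame fluctuation series over the cycle and stability metrics.

    The stability metric is the RMS of the first differences of each series:
    zero for perfectly smooth constant motion, growing with frame-to-frame
    jitter, matching the visual reading of the fluctuation diagrams.
    """
    win, opening, offset, angle = _series(traj, calib, keys)

    def rms_diff(x):
        return float(np.sqrt(np.mean(np.diff(x) ** 2))) if len(x) > 1 else 0.0

    return FluctuationSeries(
        time_s=traj.time_s[win],
        opening_mm=opening,
        offset_distance_mm=offset,
        offset_angle_deg=angle,
        stability_rms_distance=rms_diff(offset),
        stability_rms_angle=rms_diff(angle),
    )
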