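"""End-to-end analysis: frame stack -> trajectory -> calibration -> indices."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import detection, features, tracking
from .detection import DetectionParams
from .errors import PipelineError

__all__ = ["AnalysisResult", "analyze_stack", "analyze_trajectory", "load_frame_dir"]


@dataclass(frozen=True)
class AnalysisResult:
    trajectory: tracking.Trajectory
    gap_report: tracking.GapReport | None
    calibration: tracking.Calibration
    key_frames: tracking.KeyFrames
    features: features.KinematicFeatures
    fluctuation: features.FluctuationSeries

    def provenance(self) -> dict:
        return {
            "calibration_method": self.calibration.method,
            "mm_per_px": self.calibration.mm_per_px,
            "mirror_x": self.calibration.mirror_x,
            "source": self.trajectory.source_id,
            "n_frames": len(self.trajectory),
            "interpolated_frames": int(self.trajectory.interpolated.sum()),
        }


def load_frame_dir(path: str | Path) -> tuple[np.ndarray, list[Path]]:
    """Load a directory of numbered raster frames as a float [0,1] stack."""
    import imageio.v3 as iio

    files = sorted(p for p in Path(path).iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"))
    if len(files) < 3:
        raise PipelineError(f"frame directory {path} holds {len(files)} frames; need >= 3")
    stack = np.stack([detection.to_luminance(iio.imread(f)) for f in files])
    return stack, files


def analyze_stack(frames: np.ndarray, fps: float = 30.0,
                  params: DetectionParams | None = None,
                  sticker_diameter_mm: float = 5.0,
                  mirror_x: bool = True,
                  motion_threshold_mm: float = 0.5,
                  direction_threshold_mm: float = features.DIRECTION_THRESHOLD_MM,
                  source_id: str = "") -> AnalysisResult:
    """Track both markers, self-calibrate from the sticker size, and extract
    the opening/offset indices and fluctuation series."""
    params = params or DetectionParams()
    traj, gaps = tracking.track(frames, params, fps=fps, source_id=source_id)
    rest_obs = detection.detect_markers(frames[0], params, frame_index=0)[:2]
    calib = tracking.calibrate_from_markers(rest_obs, sticker_diameter_mm,
                                            mirror_x=mirror_x)
    return _finish(traj, gaps, calib, motion_threshold_mm, direction_threshold_mm)


def analyze_trajectory(traj: tracking.Trajectory, calib: tracking.Calibration,
                       motion_threshold_mm: float = 0.5,
                       direction_threshold_mm: float = features.DIRECTION_THRESHOLD_MM
                       ) -> AnalysisResult:
    """Run key-frame identification and feature extraction on an existing
    (e.g. CSV-loaded) pixel trajectory with a known calibration."""
    return _finish(traj, None, calib, motion_threshold_mm, direction_threshold_mm)


def _finish(traj, gaps, calib, motion_threshold_mm, direction_threshold_mm):
    keys = tracking.find_keyframes(traj, threshold_px=motion_threshold_mm / calib.mm_per_px)
    feats = features.compute_features(traj, calib, keys,
                                      direction_threshold_mm=direction_threshold_mm)
    fluct = features.fluctuation(traj, calib, keys)
    return AnalysisResult(trajectory=traj, gap_report=gaps, calibration=calib,
                          key_frames=keys, features=feats, fluctuation=fluct)
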