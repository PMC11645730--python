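"""Detection of the two white sticker fiducials in a single frame.

The markers are, by experimental design, the brightest near-circular objects
in the scene (5-mm white stickers on a plain dark background), so detection
is a global threshold (Otsu by default), 8-connected component labelling, an
area + circularity filter, and a background-subtracted intensity-weighted
centroid that resolves sub-pixel position from the anti-aliased disc edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import DetectionError

__all__ = [
    "DetectionParams",
    "MarkerObservation",
    "MarkerPair",
    "detect_markers",
    "select_pair",
    "to_luminance",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def to_luminance(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB(A) frame to single-channel luminance in [0, 1].

    White stickers are hue-neutral, so standard Rec. 709 luma weights keep
    full marker contrast.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    if img.max() > 1.0:
        img = img / 255.0
    return img


@dataclass(frozen=True)
class DetectionParams:
    """Thresholding and blob-filter settings.

    ``min_area_px``/``max_area_px`` default to a generous bracket
    (speck-sized noise excluded, anything beyond 1% of the frame excluded);
    when a calibration is available the caller should tighten them to the
    expected sticker area +/- 60%.
    """

    threshold_mode: str = "otsu"          # "otsu" | "fixed"
    fixed_threshold: float = 0.5
    min_area_px: int = 20
    max_area_px: int | None = None        # None -> 1% of frame area
    min_circularity: float = 0.6
    expected_markers: int = 2

    def __post_init__(self):
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.max_area_px is not None and self.min_area_px >= self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if not 0.0 <= self.min_circularity <= 1.0:
            raise ValueError("min_circularity must lie in [0, 1]")

    def area_bounds(self, frame_shape) -> tuple[int, float]:
        hi = self.max_area_px
        if hi is None:
            hi = 0.01 * frame_shape[0] * frame_shape[1]
        return self.min_area_px, hi

    @classmethod
    def for_marker_radius(cls, radius_px: float, **kwargs) -> "DetectionParams":
        """Area gates set to the expected disc area +/- 60%."""
        area = np.pi * radius_px**2
        return cls(min_area_px=max(1, int(0.4 * area)),
                   max_area_px=int(np.ceil(1.6 * area)), **kwargs)


@dataclass(frozen=True)
class MarkerObservation:
    """One detected sticker: sub-pixel centroid plus shape descriptors."""

    frame_index: int
    centroid: tuple[float, float]     # (x=col, y=row), sub-pixel
    area: float                       # px^2
    circularity: float                # 4*pi*area / perimeter^2, clamped to 1
    mean_intensity: float


@dataclass(frozen=True)
class MarkerPair:
    """Markers A (upper lip) and B (lower lip) for one frame; A above B."""

    a: MarkerObservation
    b: MarkerObservation

    def __post_init__(self):
        if self.a.centroid[1] >= self.b.centroid[1]:
            raise DetectionError(
                f"marker A must be above marker B in frame {self.a.frame_index}"
            )


def detect_markers(frame: np.ndarray, params: DetectionParams | None = None,
                   frame_index: int = 0) -> list[MarkerObservation]:
    """Detect bright circular blobs in a single-channel [0, 1] frame.

    Returns observations sorted by area, largest first; an empty list is a
    valid result (no markers in view).
    """
    params = params or DetectionParams()
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise DetectionError("detect_markers expects a single-channel frame")

    if params.threshold_mode == "fixed":
        thr = params.fixed_threshold
    else:
        if img.max() - img.min() < 1e-12:
            return []  # uniform frame: nothing to segment
        thr = threshold_otsu(img)
    mask = img > thr
    if not mask.any():
        return []

    labels = measure.label(mask, connectivity=2)
    lo, hi = params.area_bounds(img.shape)
    out: list[MarkerObservation] = []
    for prop in measure.regionprops(labels):
        if not lo <= prop.area <= hi:
            continue
        perim = prop.perimeter
        circ = 1.0 if perim == 0 else min(4.0 * np.pi * prop.area / perim**2, 1.0)
        if circ < params.min_circularity:
            continue
        rows, cols = prop.coords[:, 0], prop.coords[:, 1]
        # weights above threshold: the anti-aliased rim carries the sub-pixel
        # information, the constant plateau does not bias the centroid
        w = img[rows, cols] - thr
        wsum = w.sum()
        if wsum <= 0:
            continue
        cx = float((w * cols).sum() / wsum)
        cy = float((w * rows).sum() / wsum)
        out.append(MarkerObservation(
            frame_index=frame_index,
            centroid=(cx, cy),
            area=float(prop.area),
            circularity=float(circ),
            mean_intensity=float(img[rows, cols].mean()),
        ))
    out.sort(key=lambda m: m.area, reverse=True)
    return out


def _nearest(obs: list[MarkerObservation], point: tuple[float, float],
             gate: float) -> MarkerObservation | None:
    best, best_d = None, gate
    for m in obs:
        d = float(np.hypot(m.centroid[0] - point[0], m.centroid[1] - point[1]))
        if d < best_d:
            best, best_d = m, d
    return best


def select_pair(observations: list[MarkerObservation],
                prior: MarkerPair | None = None,
                gating_radius_px: float | None = None) -> MarkerPair:
    """Assign observations to markers A (upper) and B (lower).

    Without a prior, the two largest observations are taken and ordered by
    vertical position (A above B) — this is the initial-frame assignment.
    With a prior, each of A and B is matched to the nearest observation
    within ``gating_radius_px`` (default: 3x the prior marker diameter,
    generous for inter-frame motion at video rates yet far below the A–B
    separation).
    """
    if prior is None:
        if len(observations) < 2:
            k = observations[0].frame_index if observations else "?"
            raise DetectionError(
                f"frame {k}: need 2 markers for initial assignment, "
                f"found {len(observations)}"
            )
        big = sorted(observations, key=lambda m: m.area, reverse=True)[:2]
        if abs(big[0].centroid[1] - big[1].centroid[1]) < 1e-9:
            raise DetectionError(
                f"frame {big[0].frame_index}: candidates at equal height, "
                "cannot tell A from B"
            )
        a, b = sorted(big, key=lambda m: m.centroid[1])
        return MarkerPair(a=a, b=b)

    if not observations:
        k = prior.a.frame_index
        raise DetectionError(f"no observations to match against prior (after frame {k})")
    if gating_radius_px is None:
        diam = 2.0 * np.sqrt(max(prior.a.area, prior.b.area) / np.pi)
        gating_radius_px = 3.0 * diam
    a = _nearest(observations, prior.a.centroid, gating_radius_px)
    b = _nearest(observations, prior.b.centroid, gating_radius_px)
    if a is None or b is None or a is b:
        missing = "A" if a is None else ("B" if b is None else "A/B (collided)")
        k = observations[0].frame_index
        raise DetectionError(f"frame {k}: marker {missing} not found within gate")
    return MarkerPair(a=a, b=b)
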