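"""Synthetic jaw-motion generator: parametric kinematics plus frame rendering.

The mandible is modelled as a rigid body rotating about the condylar axis
during mouth opening.  Two circular facial fiducials are simulated: marker A
at the nasolabial-groove midpoint (upper lip, nearly stationary) and marker B
at the chin–labial-groove depression (lower lip, carried by the mandible).
The opening rotation happens in the sagittal plane; a frontal camera sees its
vertical component.  Lateral deviation of the opening path — the clinically
interesting asymmetry — is imposed directly on B's horizontal coordinate via
a configurable deviation profile.

Coordinate conventions
----------------------
Anatomical (subject) frame, millimetres: x increases to the subject's RIGHT,
y increases DOWNWARD (image convention).  The renderer can mirror x to
emulate an unmirrored camera, in which case image-left = subject-right; the
flag is recorded so downstream direction labels stay anatomically correct.

Ground truth is exact: the per-frame marker positions are evaluated in
closed form and the kinematic indices are obtained by exhaustively scanning
those frames, which is the reference any analytic shortcut must agree with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import RenderError, SimulationError
from .features import KinematicFeatures, classify_direction, signed_angle_deg
from .tracking import KeyFrames, Trajectory

__all__ = [
    "JawModel",
    "RenderParams",
    "GroundTruth",
    "raised_cosine_opening",
    "deviation_bump",
    "zero_profile",
    "opening_angle_for_distance",
    "simulate_trajectory",
    "analytic_features",
    "render_frames",
    "render_disc_frame",
    "write_frame_stack",
    "GROUND_TRUTH_COLUMNS",
]

Profile = Callable[[np.ndarray], np.ndarray]

GROUND_TRUTH_COLUMNS = [
    "frame", "t", "ax_mm", "ay_mm", "bx_mm", "by_mm",
    "ax_px", "ay_px", "bx_px", "by_px",
]


def zero_profile(t):
    """Profile that is identically zero (no opening / no deviation)."""
    return np.zeros_like(np.asarray(t, dtype=float))


def raised_cosine_opening(peak_deg: float) -> Profile:
    """Smooth open–close cycle: 0 at t=0 and t=1, ``peak_deg`` at t=0.5.

    theta(t) = peak * (1 - cos(2*pi*t)) / 2
    """
    if peak_deg < 0:
        raise SimulationError("peak opening angle must be >= 0")

    def profile(t):
        t = np.asarray(t, dtype=float)
        return peak_deg * 0.5 * (1.0 - np.cos(2.0 * np.pi * t))

    return profile


def deviation_bump(peak_mm: float, center: float = 0.5, width: float = 0.35) -> Profile:
    """Compactly supported lateral-deviation bump.

    A raised-cosine-squared bump of half-width ``width`` peaking at
    ``t = center`` with value ``peak_mm`` (signed; + = subject's right).
    Placing ``center`` late in the cycle (> 0.5) reproduces deviation that
    intensifies during closing.
    """
    if not 0.0 < width <= 1.0:
        raise SimulationError("bump width must lie in (0, 1]")

    def profile(t):
        t = np.asarray(t, dtype=float)
        u = (t - center) / width
        out = np.where(np.abs(u) < 1.0, np.cos(0.5 * np.pi * u) ** 2, 0.0)
        return peak_mm * out

    return profile


@dataclass(frozen=True)
class JawModel:
    """Parametric model of mandibular motion seen by a frontal camera.

    Parameters
    ----------
    condyle_center : (float, float)
        Condylar rotation centre, mm.  Only the vertical (second)
        coordinate enters the frontal projection; the first is kept for
        completeness of the sagittal geometry.
    jaw_length : float
        Distance condyle -> marker B at rest, mm.  Must exceed the vertical
        separation between condyle and B for the sagittal geometry to close.
    opening_profile : callable
        t in [0,1] -> opening angle, degrees, >= 0, zero at both endpoints.
    deviation_profile : callable
        t -> lateral displacement of B, mm, signed (+ = subject's right).
    marker_a_rest, marker_b_rest : (float, float)
        Rest positions of markers A (upper lip) and B (lower lip), mm in
        the anatomical frame; A must be above B (smaller y).
    marker_a_coupling : float
        Fraction in [0, 0.2] of B's displacement that bleeds into A,
        modelling soft-tissue drag.
    """

    condyle_center: tuple[float, float] = (0.0, -40.0)
    jaw_length: float = 80.0
    opening_profile: Profile = field(default_factory=lambda: raised_cosine_opening(18.0))
    deviation_profile: Profile = field(default_factory=lambda: zero_profile)
    marker_a_rest: tuple[float, float] = (0.0, -12.0)
    marker_b_rest: tuple[float, float] = (0.0, 8.0)
    marker_a_coupling: float = 0.05

    def __post_init__(self):
        if not 0.0 <= self.marker_a_coupling <= 0.2:
            raise SimulationError("marker_a_coupling must lie in [0, 0.2]")
        if self.marker_a_rest[1] >= self.marker_b_rest[1]:
            raise SimulationError("marker A must sit above marker B (smaller y)")
        dy = self.marker_b_rest[1] - self.condyle_center[1]
        if self.jaw_length <= abs(dy):
            raise SimulationError(
                "jaw_length must exceed the vertical condyle–B separation "
                f"({self.jaw_length} <= {abs(dy)})"
            )
        for name in ("opening_profile", "deviation_profile"):
            prof = getattr(self, name)
            ends = np.asarray(prof(np.array([0.0, 1.0])), dtype=float)
            if name == "opening_profile" and not np.allclose(ends, 0.0, atol=1e-9):
                raise SimulationError("opening_profile must vanish at t=0 and t=1")

    # -- closed-form kinematics -------------------------------------------

    @property
    def _rest_elevation_rad(self) -> float:
        """Rest angle of the condyle→B vector below the horizontal (sagittal)."""
        dy = self.marker_b_rest[1] - self.condyle_center[1]
        return math.asin(dy / self.jaw_length)

    def positions(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Marker positions at normalized times ``t`` (anatomical mm).

        Returns ``(a, b)`` arrays of shape (len(t), 2).
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        theta = np.asarray(self.opening_profile(t), dtype=float)
        dev = np.asarray(self.deviation_profile(t), dtype=float)
        bad = ~(np.isfinite(theta) & np.isfinite(dev))
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            raise SimulationError(f"profile returned a non-finite value at frame {k}")
        alpha0 = self._rest_elevation_rad
        by = self.condyle_center[1] + self.jaw_length * np.sin(alpha0 + np.radians(theta))
        bx = self.marker_b_rest[0] + dev
        b = np.column_stack([bx, by])
        b_rest = np.asarray(self.marker_b_rest, dtype=float)
        a = np.asarray(self.marker_a_rest, dtype=float) + self.marker_a_coupling * (b - b_rest)
        return a, b

    def opening_displacement(self, t) -> np.ndarray:
        """Vertical displacement of B from rest at times ``t``, mm."""
        _, b = self.positions(t)
        return b[:, 1] - self.marker_b_rest[1]


def opening_angle_for_distance(model: JawModel, opening_mm: float) -> float:
    """Opening angle (degrees) that displaces B vertically by ``opening_mm``."""
    alpha0 = model._rest_elevation_rad
    s = math.sin(alpha0) + opening_mm / model.jaw_length
    if not -1.0 <= s <= 1.0:
        raise SimulationError(f"opening of {opening_mm} mm is unreachable for this jaw")
    return math.degrees(math.asin(s) - alpha0)


@dataclass(frozen=True)
class RenderParams:
    """Rendering configuration for synthetic frame stacks."""

    image_size: tuple[int, int] = (1280, 720)   # (width, height) px
    mm_per_px: float = 0.25
    marker_radius_mm: float = 2.5               # 5-mm sticker
    background_level: float = 0.10
    marker_level: float = 0.90
    noise_sd: float = 0.0
    border_columns: tuple[int, int] | None = None  # inner edges of device frame
    mirror_x: bool = True                       # image-left = subject-right
    seed: int = 0

    def __post_init__(self):
        if self.mm_per_px <= 0:
            raise RenderError("mm_per_px must be positive")
        if self.marker_level <= self.background_level + 3.0 * self.noise_sd:
            raise RenderError(
                "markers undetectable: need marker_level > background_level + 3*noise_sd"
            )

    def mm_to_px(self, xy_mm: np.ndarray) -> np.ndarray:
        """Map anatomical mm coordinates to (col, row) pixel coordinates."""
        xy_mm = np.asarray(xy_mm, dtype=float)
        w, h = self.image_size
        sx = -1.0 if self.mirror_x else 1.0
        px = np.empty_like(xy_mm)
        px[..., 0] = (w - 1) / 2.0 + sx * xy_mm[..., 0] / self.mm_per_px
        px[..., 1] = (h - 1) / 2.0 + xy_mm[..., 1] / self.mm_per_px
        return px


@dataclass(frozen=True)
class GroundTruth:
    """Exact trajectory plus analytically derived kinematic indices."""

    trajectory: Trajectory           # positions in anatomical mm (exact)
    features: KinematicFeatures
    model: JawModel
    a_mm: np.ndarray                 # (n, 2) marker A positions
    b_mm: np.ndarray                 # (n, 2) marker B positions
    times: np.ndarray                # normalized t per frame


def _scan_features(model: JawModel, a: np.ndarray, b: np.ndarray,
                   direction_threshold_mm: float = 0.5) -> KinematicFeatures:
    """Exhaustive per-frame scan of the model output: the feature oracle."""
    a0, b0 = a[0], b[0]
    opening = b[:, 1] - b0[1]
    offset = b[:, 0] - b0[0]
    v0 = b0 - a0
    angles = signed_angle_deg(v0, b - a)
    max_open_index = int(np.argmax(opening))
    k_off = int(np.argmax(np.abs(offset)))
    k_ang = int(np.argmax(np.abs(angles)))
    if opening[max_open_index] < 1e-12:
        keys = None          # degenerate cycle: the mouth never opens
        max_open_index = 0
    else:
        # closed again: last frame after max opening that returns near rest
        post = np.flatnonzero(
            (np.arange(len(b)) > max_open_index)
            & (np.hypot(b[:, 0] - b0[0], b[:, 1] - b0[1]) < direction_threshold_mm)
        )
        keys = KeyFrames(
            rest_index=0,
            max_open_index=max_open_index,
            closed_again_index=int(post[-1]) if post.size else None,
        )
    max_offset = float(np.abs(offset[k_off]))
    return KinematicFeatures(
        max_opening_mm=float(opening[max_open_index]),
        max_offset_mm=max_offset,
        offset_at_max_open_mm=float(offset[max_open_index]),
        max_offset_angle_deg=float(np.abs(angles[k_ang])),
        angle_at_max_open_deg=float(angles[max_open_index]),
        offset_direction=classify_direction(
            float(offset[k_off]), threshold_mm=direction_threshold_mm
        ),
        key_frames=keys,
    )


def simulate_trajectory(model: JawModel, n_frames: int, fps: float = 30.0) -> GroundTruth:
    """Evaluate the jaw model on ``n_frames`` equally spaced times in [0, 1].

    The returned features come from an exhaustive scan of the evaluated
    frames, so they are exact for the sampled cycle by construction.
    """
    if n_frames < 3:
        raise SimulationError("need at least 3 frames to describe a cycle")
    t = np.linspace(0.0, 1.0, n_frames)
    a, b = model.positions(t)
    traj = Trajectory(
        a_px=a.copy(), b_px=b.copy(), fps=fps,
        source_id="synthetic:mm", frame_index=np.arange(n_frames),
    )
    feats = _scan_features(model, a, b)
    return GroundTruth(trajectory=traj, features=feats, model=model, a_mm=a, b_mm=b, times=t)


def analytic_features(model: JawModel, n_frames: int,
                      opening_peak_t: float = 0.5,
                      deviation_peak_t: float | None = 0.5) -> dict:
    """Closed-form extreme values for unimodal default profiles.

    Evaluates the model at the known peak phases of a raised-cosine opening
    and a deviation bump, snapped to the nearest sampled frame so that the
    result is comparable with the exhaustive frame scan of
    :func:`simulate_trajectory` to machine precision.
    """
    grid = np.linspace(0.0, 1.0, n_frames)

    def snap(t):
        return grid[int(round(t * (n_frames - 1)))]

    t_open = snap(opening_peak_t)
    opening = float(model.opening_displacement([t_open])[0])
    out = {"max_opening_mm": opening, "max_open_t": t_open}
    if deviation_peak_t is not None:
        t_dev = snap(deviation_peak_t)
        dev = float(np.asarray(model.deviation_profile(np.array([t_dev])))[0])
        out["max_offset_mm"] = abs(dev)
        out["offset_sign"] = float(np.sign(dev))
    return out


def _draw_disc(img: np.ndarray, center_px: Sequence[float], radius_px: float,
               level: float, background: float, supersample: int = 4) -> None:
    """Additively draw an anti-aliased disc via subpixel-coverage sampling."""
    cx, cy = float(center_px[0]), float(center_px[1])
    h, w = img.shape
    r0 = max(int(math.floor(cy - radius_px)) - 1, 0)
    r1 = min(int(math.ceil(cy + radius_px)) + 2, h)
    c0 = max(int(math.floor(cx - radius_px)) - 1, 0)
    c1 = min(int(math.ceil(cx + radius_px)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5
    rows = (np.arange(r0, r1)[:, None] + off[None, :]).ravel()
    cols = (np.arange(c0, c1)[:, None] + off[None, :]).ravel()
    inside = ((cols[None, :] - cx) ** 2 + (rows[:, None] - cy) ** 2) <= radius_px ** 2
    cov = inside.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))
    img[r0:r1, c0:c1] += (level - background) * cov


def render_disc_frame(centers_px: Sequence[Sequence[float]], radius_px: float,
                      image_size: tuple[int, int] = (160, 160),
                      background_level: float = 0.1, marker_level: float = 0.9,
                      noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Render one frame with anti-aliased discs at given (col, row) centres.

    Convenience for detector benchmarking: the exact sub-pixel centres are
    the caller's ground truth.
    """
    w, h = image_size
    img = np.full((h, w), background_level, dtype=np.float64)
    for c in centers_px:
        _draw_disc(img, c, radius_px, marker_level, background_level)
    if noise_sd > 0:
        img += np.random.default_rng(seed).normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def render_frames(truth: GroundTruth, params: RenderParams) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the ground-truth trajectory into a noisy frame stack.

    Returns
    -------
    stack : float32 array, shape (n_frames, height, width), values in [0, 1]
    table : DataFrame with the exact sub-pixel ground truth per frame
        (columns ``frame, t, ax_mm, ..., by_px``).

    Rendering is bit-reproducible for a fixed ``params.seed``.
    """
    w, h = params.image_size
    radius_px = params.marker_radius_mm / params.mm_per_px
    a_px = params.mm_to_px(truth.a_mm)
    b_px = params.mm_to_px(truth.b_mm)
    n = len(truth.times)

    for k in range(n):
        for name, p in (("A", a_px[k]), ("B", b_px[k])):
            if not (radius_px <= p[0] <= w - 1 - radius_px
                    and radius_px <= p[1] <= h - 1 - radius_px):
                raise RenderError(f"marker {name} out of bounds in frame {k}: {tuple(p)}")
        if np.hypot(*(a_px[k] - b_px[k])) < 2.0 * radius_px:
            raise RenderError(f"markers overlap in frame {k}")

    rng = np.random.default_rng(params.seed)
    stack = np.empty((n, h, w), dtype=np.float32)
    base = np.full((h, w), params.background_level, dtype=np.float64)
    if params.border_columns is not None:
        left, right = params.border_columns
        if not 0 <= left < right <= w - 1:
            raise RenderError("border_columns must satisfy 0 <= left < right < width")
        base[:, : left + 1] = params.marker_level
        base[:, right:] = params.marker_level
    for k in range(n):
        frame = base.copy()
        _draw_disc(frame, a_px[k], radius_px, params.marker_level, params.background_level)
        _draw_disc(frame, b_px[k], radius_px, params.marker_level, params.background_level)
        if params.noise_sd > 0:
            frame += rng.normal(0.0, params.noise_sd, size=frame.shape)
        stack[k] = np.clip(frame, 0.0, 1.0)

    table = pd.DataFrame({
        "frame": np.arange(n),
        "t": truth.times,
        "ax_mm": truth.a_mm[:, 0], "ay_mm": truth.a_mm[:, 1],
        "bx_mm": truth.b_mm[:, 0], "by_mm": truth.b_mm[:, 1],
        "ax_px": a_px[:, 0], "ay_px": a_px[:, 1],
        "bx_px": b_px[:, 0], "by_px": b_px[:, 1],
    })
    return stack, table


def write_frame_stack(stack: np.ndarray, table: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write frames as zero-padded PNGs plus ``ground_truth.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(stack) - 1)))
    for k, frame in enumerate(stack):
        img8 = np.clip(np.round(frame * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(out / f"frame_{k:0{width}d}.png", img8)
    table.to_csv(out / "ground_truth.csv", index=False)
    return out


def mirrored(model: JawModel) -> JawModel:
    """Model with the deviation profile negated (left/right swapped)."""
    prof = model.deviation_profile
    return replace(model, deviation_profile=lambda t: -np.asarray(prof(t)))
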