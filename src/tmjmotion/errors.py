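"""Exception hierarchy for the analysis pipeline.

Every stage raises a subclass of :class:`PipelineError` so the CLI can
report the failing stage by name and exit non-zero.
"""


class PipelineError(Exception):
    """Base class for all pipeline failures."""


class SimulationError(PipelineError):
    """Invalid jaw model or profile output during trajectory simulation."""


class RenderError(PipelineError):
    """A marker cannot be rendered (out of bounds, overlapping discs)."""


class DetectionError(PipelineError):
    """Marker detection or pairing failed for a frame."""


class TrackingError(PipelineError):
    """Trajectory assembly failed (undetectable first frame, too many gaps)."""


class CalibrationError(PipelineError):
    """Pixel-to-millimetre calibration could not be established."""


class KeyframeError(PipelineError):
    """Rest / maximum-opening frames could not be identified."""


class FeatureError(PipelineError):
    """Kinematic feature extraction failed (implausible geometry)."""


class StatsError(PipelineError):
    """Group statistics could not be computed."""
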