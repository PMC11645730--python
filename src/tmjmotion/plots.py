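"""Fluctuation-diagram plotting (offset angle and offset distance panels)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .features import FluctuationSeries

__all__ = ["fluctuation_figure", "save_fluctuation_plots"]


def fluctuation_figure(fs: FluctuationSeries):
    """Two-panel fluctuation diagram: offset angle (a) and distance (b).

    Larger oscillation in either panel indicates poorer movement stability.
    """
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 3.5), constrained_layout=True)
    ax1.plot(fs.time_s, fs.offset_angle_deg, lw=1.2)
    ax1.axhline(0.0, color="0.7", lw=0.8)
    ax1.set_xlabel("time (s)")
    ax1.set_ylabel("offset angle (deg)")
    ax1.set_title(f"(a) offset angle  RMSΔ={fs.stability_rms_angle:.3f}°")
    ax2.plot(fs.time_s, fs.offset_distance_mm, lw=1.2, color="tab:orange")
    ax2.axhline(0.0, color="0.7", lw=0.8)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("offset distance (mm)")
    ax2.set_title(f"(b) offset distance  RMSΔ={fs.stability_rms_distance:.3f} mm")
    return fig


def save_fluctuation_plots(fs: FluctuationSeries, out_path: str | Path) -> Path:
    fig = fluctuation_figure(fs)
    out = Path(out_path)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
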