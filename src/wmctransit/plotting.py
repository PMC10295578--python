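"""Basic trace plots with landmark overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .segmentation import LANDMARKS, Segmentation
from .trace_io import WmcRecording

_LANDMARK_STYLE = {
    "t_ingest": ("ingestion", "tab:green"),
    "t_empty": ("gastric emptying", "tab:orange"),
    "t_ileocecal": ("colon arrival", "tab:red"),
    "t_exit": ("body exit", "tab:purple"),
}


def plot_trace(rec: WmcRecording, seg: Segmentation | None = None, path=None):
    """Three stacked panels (pH, pressure, temperature) with landmark lines."""
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(10, 7))
    hours = rec.t / 3600.0
    axes[0].plot(hours, rec.ph, lw=0.6, color="tab:blue")
    axes[0].set_ylabel("pH")
    axes[1].plot(hours, rec.pressure, lw=0.4, color="tab:gray")
    axes[1].set_ylabel("pressure (mmHg)")
    axes[2].plot(hours, rec.temperature, lw=0.6, color="tab:brown")
    axes[2].set_ylabel("temperature (°C)")
    axes[2].set_xlabel("time (h)")
    if seg is not None:
        for key in LANDMARKS:
            val = getattr(seg, key)
            if val is None:
                continue
            label, color = _LANDMARK_STYLE[key]
            for ax in axes:
                ax.axvline(val / 3600.0, color=color, ls="--", lw=0.8)
            axes[0].text(
                val / 3600.0, axes[0].get_ylim()[1], label, rotation=90, va="top", fontsize=7, color=color
            )
    fig.suptitle(f"{rec.subject_id} / {rec.session}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=110)
        plt.close(fig)
        return None
    return fig
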