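"""Band-versus-phase plots with the zero (grand mean) reference line."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bootstrap import ConfidenceBand

__all__ = ["plot_bands"]


def plot_bands(gsbb: ConfidenceBand, vbpbb: ConfidenceBand, path, title: str = "") -> None:
    """Overlay GSBB (red) and VBPBB (blue) bands across the phase grid."""
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for band, color, name in ((gsbb, "tab:red", "GSBB"), (vbpbb, "tab:blue", "VBPBB")):
        x = np.arange(band.period)
        ax.fill_between(x, band.lower, band.upper, alpha=0.3, color=color, label=name)
        ax.plot(x, band.center, color=color, lw=1.0)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("phase (samples into period)")
    ax.set_ylabel("deviation from grand mean")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
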