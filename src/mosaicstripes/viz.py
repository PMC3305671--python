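"""Diagnostic overlays: the sampling circle and detected stripe boundaries
drawn on the analysed image, for eyeballing circle placement and run
extraction on real or synthetic whole-mounts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .circular import MosaicImage, RunSegment, SamplingCircle

__all__ = ["plot_overlay"]


def plot_overlay(
    image: MosaicImage,
    circle: SamplingCircle,
    runs: Sequence[RunSegment] | None = None,
    out: str | Path | None = None,
):
    """Draw the sampling circle (and stripe boundaries, if given) on the image.

    Returns the matplotlib figure; also saves it as PNG when ``out`` is set.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if image.is_rgb:
        ax.imshow(image.pixels)
    else:
        ax.imshow(image.pixels, cmap="gray", interpolation="nearest")

    cr, cc = circle.center
    theta = np.linspace(0, 2 * np.pi, 721)
    ax.plot(cc + circle.radius * np.cos(theta),
            cr - circle.radius * np.sin(theta), "r-", lw=1.2,
            label="sampling circle")
    if runs is not None:
        for run in runs:
            a = run.start_angle
            ax.plot([cc + 0.9 * circle.radius * np.cos(a),
                     cc + 1.1 * circle.radius * np.cos(a)],
                    [cr - 0.9 * circle.radius * np.sin(a),
                     cr - 1.1 * circle.radius * np.sin(a)],
                    color="yellow", lw=1.0)
    ax.set_axis_off()
    ax.legend(loc="lower right", fontsize=8)
    if out is not None:
        fig.savefig(out, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
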