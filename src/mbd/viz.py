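"""Regional-PD heatmap rendering.

The color semantics follow the study's convention: yellow for zero or
minimal density, orange around 25% PD, red at 50% PD and above.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

__all__ = ["density_colormap", "render_heatmap"]


def density_colormap() -> LinearSegmentedColormap:
    """Yellow (0%) -> orange (25%) -> red (>=50%) over a 0-100 PD scale."""
    return LinearSegmentedColormap.from_list(
        "regional_pd",
        [(0.0, "#ffe94d"), (0.25, "#ff9a1f"), (0.5, "#d7191c"), (1.0, "#a50026")],
    )


def render_heatmap(
    pd_matrix: np.ndarray,
    path: str | Path | None = None,
    title: str | None = None,
    annotate: bool = True,
):
    """Render one regional-PD matrix; saves PNG when a path is given."""
    pd_matrix = np.asarray(pd_matrix, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 5))
    ax.imshow(pd_matrix, cmap=density_colormap(), vmin=0, vmax=100)
    if annotate:
        for (i, j), v in np.ndenumerate(pd_matrix):
            ax.text(j, i, f"{v:.0f}", ha="center", va="center", fontsize=8)
    ax.set_xticks(range(pd_matrix.shape[1]))
    ax.set_yticks(range(pd_matrix.shape[0]))
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig, ax
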