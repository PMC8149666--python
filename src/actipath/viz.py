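"""Optional rendering: 2D occupancy heatmaps with a planned path overlaid.

Requires matplotlib (the ``plot`` extra); imported lazily so the core
package works without it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .dataset import Dataset
from .pathplan import PlanResult


def plot_path_heatmap(
    result: PlanResult,
    data: Dataset,
    var_x: str,
    var_y: str,
    out: str | Path,
    bins: int = 30,
) -> None:
    """2D histogram of the data over two variables, planned path overlaid.

    ``data`` should be on the same (standardized) scale the planner used.
    The start node is drawn as a circle, the destination as a star.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = data.values[var_x].dropna().to_numpy(float)
    ys = data.values[var_y].dropna().to_numpy(float)
    fig, ax = plt.subplots(figsize=(5, 4))
    h, xe, ye, im = ax.hist2d(xs, ys, bins=bins, cmap="viridis")
    fig.colorbar(im, ax=ax, label="count")

    px = [float(n.x[var_x]) for n in result.path.nodes]
    py = [float(n.x[var_y]) for n in result.path.nodes]
    ax.plot(px, py, "w.-", lw=2)
    ax.plot(px[0], py[0], "wo", ms=9, mfc="none")
    ax.plot(px[-1], py[-1], "w*", ms=13)
    ax.set_xlabel(var_x)
    ax.set_ylabel(var_y)
    ax.set_title("planned path over data occupancy")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
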