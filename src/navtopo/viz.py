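"""Map plots of street networks colored by a per-segment quantity."""

from __future__ import annotations

import pandas as pd

from .network import PrimalNetwork

__all__ = ["plot_network"]


def plot_network(net: PrimalNetwork, values: pd.Series | None = None,
                 ax=None, cmap: str = "viridis", linewidth: float = 2.5):
    """Draw the primal network using junction coordinates; segments are
    colored by *values* (e.g. a centrality-table column) when given.

    Junctions without coordinates cannot be drawn and raise a ValueError.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib import colormaps
    from matplotlib.colors import Normalize

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    coords = {}
    for j in net.junctions.values():
        if j.x is None or j.y is None:
            raise ValueError(f"junction {j.id!r} has no coordinates; cannot plot")
        coords[j.id] = (j.x, j.y)
    if values is not None:
        norm = Normalize(vmin=float(values.min()), vmax=float(values.max()))
        colormap = colormaps[cmap]
    for seg in net.segments.values():
        (x1, y1), (x2, y2) = (coords[j] for j in seg.endpoint_junctions)
        if values is not None and seg.id in values.index:
            color = colormap(norm(float(values[seg.id])))
        else:
            color = "0.6"
        ax.plot([x1, x2], [y1, y2], color=color, linewidth=linewidth,
                solid_capstyle="round")
    ax.set_aspect("equal")
    ax.set_axis_off()
    return ax
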