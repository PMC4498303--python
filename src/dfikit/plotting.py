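"""Static figures: ternary composition scatter and promiscuity scatter."""

from __future__ import annotations

import math
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .classify import ternary_coordinates
from .core import CLASS_COLORS, DFBSProfile

_SQRT3_2 = math.sqrt(3.0) / 2.0


def ternary_scatter(profiles: Sequence[DFBSProfile], surface: bool = False, ax=None):
    """Scatter of site (or surface) compositions on the ternary simplex,
    coloured by SSE class (red/orange/green/cyan/blue for classes 1-5)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5.5))
    # triangle frame: alpha bottom-left, beta bottom-right, gamma top
    ax.plot([0, 1, 0.5, 0], [0, 0, _SQRT3_2, 0], color="black", lw=1)
    for p in profiles:
        triple = p.surface_propensity if surface else p.site_propensity
        cls = p.surface_class if surface else p.sse_class
        if triple is None or cls is None:
            continue
        x, y = ternary_coordinates(triple)
        ax.plot(x, y, ".", color=CLASS_COLORS[cls], markersize=3)
    ax.text(-0.03, -0.04, "alpha", ha="center")
    ax.text(1.03, -0.04, "beta", ha="center")
    ax.text(0.5, _SQRT3_2 + 0.02, "gamma", ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def promiscuity_scatter_plot(scatter_frame, ax=None):
    """Total partners (x) vs max partners per binding site (y) per domain."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(
        scatter_frame["total_partners"],
        scatter_frame["max_partners_per_dfbs"],
        "o",
        alpha=0.4,
        markersize=4,
    )
    ax.set_xlabel("distinct partner families per domain")
    ax.set_ylabel("max partners of a single binding site")
    return ax
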