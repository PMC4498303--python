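"""Five-class ternary classification of SSE propensity triples.

The (alpha, beta, gamma) simplex is partitioned by the contour lines
P(alpha) = 30%/70% and P(gamma) = 30%/70% into five classes:

1. alpha-rich        P(a) >= 0.70
2. gamma-rich        P(g) >= 0.70                     (and P(a) < 0.70)
3. alpha+gamma       0.30 <= P(g) < 0.70 and 0.30 <= P(a) < 0.70
4. beta+gamma        0.30 <= P(g) < 0.70 and P(a) < 0.30
5. alpha+beta+gamma  P(g) < 0.30 and P(a) < 0.70

There is deliberately no beta-rich class: compositions with very high beta
content are too rare to form one, so the all-beta vertex falls in class 5.
Every simplex point receives exactly one class.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import CLASS_LABELS, DFBSProfile, InputError, PropensityTriple, SSEClass

_SQRT3_2 = math.sqrt(3.0) / 2.0

#: Extreme composition categories: vertex ("all") and edge ("no") memberships.
EXTREME_LABELS = ("all_alpha", "all_beta", "all_gamma", "no_alpha", "no_beta", "no_gamma")


def classify_sse(p: PropensityTriple) -> SSEClass:
    """Assign a normalized propensity triple to one of the five SSE classes.

    Boundary inclusivity follows the printed class definitions exactly
    (>= on the upper contours, half-open elsewhere); classification uses the
    unrounded fractions.
    """
    a, g = p.p_alpha, p.p_gamma
    if a >= 0.70:
        return SSEClass.alpha_rich
    if g >= 0.70:
        return SSEClass.gamma_rich
    if 0.30 <= g < 0.70:
        return SSEClass.alpha_gamma if a >= 0.30 else SSEClass.beta_gamma
    # g < 0.30 and a < 0.70
    return SSEClass.alpha_beta_gamma


def extreme_categories(p: PropensityTriple, atol: float = 1e-12) -> Set[str]:
    """Labels for vertex/edge compositions: ``all_X`` iff P(X)=1, ``no_X`` iff P(X)=0.

    Comparisons use a 1e-12 tolerance, which is exact for fractions formed
    from integer residue counts and absorbs float round-off in multi-member
    averages.  A vertex point carries one "all" label and two "no" labels.
    """
    labels: Set[str] = set()
    for name, value in (("alpha", p.p_alpha), ("beta", p.p_beta), ("gamma", p.p_gamma)):
        if abs(value - 1.0) <= atol:
            labels.add(f"all_{name}")
        if abs(value) <= atol:
            labels.add(f"no_{name}")
    return labels


def ternary_coordinates(p: PropensityTriple) -> Tuple[float, float]:
    """Planar embedding of the simplex in an equilateral triangle.

    Vertices: all-alpha at (0, 0), all-beta at (1, 0), all-gamma at
    (1/2, sqrt(3)/2).  The map is invertible (see
    :func:`triple_from_ternary_coordinates`).
    """
    x = p.p_beta + p.p_gamma / 2.0
    y = p.p_gamma * _SQRT3_2
    return (x, y)


def triple_from_ternary_coordinates(x: float, y: float) -> PropensityTriple:
    """Algebraic inverse of :func:`ternary_coordinates`."""
    p_gamma = y / _SQRT3_2
    p_beta = x - p_gamma / 2.0
    p_alpha = 1.0 - p_beta - p_gamma
    return PropensityTriple(p_alpha, p_beta, p_gamma)


def _frame_records(frame: pd.DataFrame) -> List[Dict]:
    """JSON-safe records: flatten any MultiIndex columns to dotted names."""
    flat = frame.copy()
    if isinstance(flat.columns, pd.MultiIndex):
        flat.columns = [".".join(str(part) for part in col) for col in flat.columns]
    flat = flat.reset_index()
    flat.columns = [str(c) for c in flat.columns]
    return flat.to_dict(orient="records")


@dataclass
class ClassSummary:
    """Per-class composition statistics and the site-by-surface conditional table.

    ``class_counts``/``surface_class_counts``: DFBS counts per class.
    ``site_stats``/``surface_stats``: mean and SD (percent) of each propensity
    per class.  ``conditional`` has one row per surface class giving the
    percent distribution of site classes, plus an ``All domains`` marginal
    row; each row sums to 100 up to rounding.  ``extreme_counts`` counts the
    "all"/"none" categories for sites and surfaces.
    """

    n_profiles: int
    class_counts: pd.Series
    surface_class_counts: pd.Series
    site_stats: pd.DataFrame
    surface_stats: pd.DataFrame
    conditional: pd.DataFrame
    extreme_counts: pd.DataFrame

    def to_dict(self) -> Dict:
        return {
            "n_profiles": self.n_profiles,
            "class_counts": {str(k): int(v) for k, v in self.class_counts.items()},
            "surface_class_counts": {
                str(k): int(v) for k, v in self.surface_class_counts.items()
            },
            "site_stats": _frame_records(self.site_stats),
            "surface_stats": _frame_records(self.surface_stats),
            "conditional": _frame_records(self.conditional),
            "extreme_counts": _frame_records(self.extreme_counts),
        }


def _stats_frame(rows: List[Tuple[SSEClass, PropensityTriple]]) -> pd.DataFrame:
    data = pd.DataFrame(
        {
            "sse_class": [c for c, _ in rows],
            "alpha": [100.0 * t.p_alpha for _, t in rows],
            "beta": [100.0 * t.p_beta for _, t in rows],
            "gamma": [100.0 * t.p_gamma for _, t in rows],
        }
    )
    grouped = data.groupby("sse_class")[["alpha", "beta", "gamma"]]
    stats = pd.concat({"mean": grouped.mean(), "sd": grouped.std(ddof=1)}, axis=1)
    return stats.reindex(list(SSEClass))


def summarize_classes(profiles: Sequence[DFBSProfile]) -> ClassSummary:
    """Class counts, per-class propensity statistics (percent), and the
    conditional site-class-given-surface-class table for a set of profiles.

    Profiles must already carry ``sse_class``; the surface rows are computed
    from the subset that also carries ``surface_class``.
    """
    if not profiles:
        raise InputError("cannot summarise an empty profile set")
    for prof in profiles:
        if prof.sse_class is None:
            raise InputError(f"profile {prof.dfbs_id} has no assigned SSE class")

    classes = list(SSEClass)
    class_counts = pd.Series(
        {c: sum(1 for p in profiles if p.sse_class == c) for c in classes}, name="n_dfbs"
    )
    with_surface = [p for p in profiles if p.surface_class is not None]
    surface_class_counts = pd.Series(
        {c: sum(1 for p in with_surface if p.surface_class == c) for c in classes},
        name="n_surfaces",
    )

    site_stats = _stats_frame([(p.sse_class, p.site_propensity) for p in profiles])
    surface_stats = (
        _stats_frame([(p.surface_class, p.surface_propensity) for p in with_surface])
        if with_surface
        else pd.DataFrame()
    )

    # conditional percent table: P(site class | surface class), Table-3 shape
    rows: Dict[str, List[float]] = {}
    for surf_class in classes:
        subset = [p for p in with_surface if p.surface_class == surf_class]
        if subset:
            row = [
                100.0 * sum(1 for p in subset if p.sse_class == c) / len(subset)
                for c in classes
            ]
        else:
            row = [float("nan")] * len(classes)
        rows[CLASS_LABELS[surf_class]] = row
    rows["All domains"] = [100.0 * class_counts[c] / len(profiles) for c in classes]
    conditional = pd.DataFrame.from_dict(
        rows, orient="index", columns=[CLASS_LABELS[c] for c in classes]
    )

    site_extreme: Counter = Counter()
    for p in profiles:
        site_extreme.update(p.extreme_labels or extreme_categories(p.site_propensity))
    surface_extreme: Counter = Counter()
    for p in with_surface:
        surface_extreme.update(extreme_categories(p.surface_propensity))
    extreme = pd.DataFrame(
        {
            "site": [site_extreme.get(lbl, 0) for lbl in EXTREME_LABELS],
            "surface": [surface_extreme.get(lbl, 0) for lbl in EXTREME_LABELS],
        },
        index=list(EXTREME_LABELS),
    )

    return ClassSummary(
        n_profiles=len(profiles),
        class_counts=class_counts,
        surface_class_counts=surface_class_counts,
        site_stats=site_stats,
        surface_stats=surface_stats,
        conditional=conditional,
        extreme_counts=extreme,
    )
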