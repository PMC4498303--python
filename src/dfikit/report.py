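"""Rendering of analysis results as text tables.

Percent cells are printed with one decimal using round-half-away-from-zero;
expected counts appear in parentheses after observed counts, rounded to the
nearest integer.  Statistics are always computed on unrounded values —
rounding happens here and only here.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Sequence

import pandas as pd

from .core import CLASS_LABELS, SSEClass


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention of printed tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def format_percent(fraction: float, ndigits: int = 1) -> str:
    """Format a fraction (0.044 -> '4.4%')."""
    return f"{round_half_up(100.0 * fraction, ndigits):.{ndigits}f}%"


def format_observed_expected(observed: int, expected: float) -> str:
    """'251 (191)' style cell: observed count, expected count in parentheses."""
    return f"{observed} ({round_half_up(expected, 0):.0f})"


def render_pairing_table(pair_table: pd.DataFrame) -> str:
    """Upper-triangle class-pair matrix with observed (expected) and percent rows."""
    labels = [CLASS_LABELS[c] for c in SSEClass]
    cells: Dict[tuple, str] = {}
    pcts: Dict[tuple, str] = {}
    for row in pair_table.itertuples(index=False):
        key = (row.class_i, row.class_j)
        mark = {"enriched": "+", "depleted": "-", "ns": " "}.get(row.flag, " ")
        cells[key] = format_observed_expected(int(row.observed), row.expected_count) + mark
        pcts[key] = format_percent(row.observed_pct / 100.0)
    width = 14
    header = " " * 18 + "".join(lbl.rjust(width + 2) for lbl in labels)
    lines = [header]
    for i, li in enumerate(labels):
        obs_line = li.ljust(18)
        pct_line = " " * 18
        for j, lj in enumerate(labels):
            if j < i:
                obs_line += " " * (width + 2)
                pct_line += " " * (width + 2)
            else:
                key = (li, lj)
                obs_line += cells.get(key, "").rjust(width + 2)
                pct_line += pcts.get(key, "").rjust(width + 2)
        lines.append(obs_line)
        lines.append(pct_line)
    lines.append("")
    lines.append("(+ enriched, - depleted vs random pairing)")
    return "\n".join(lines)


def render_class_distribution(class_counts: Dict[str, int], total: int) -> str:
    lines = ["SSE class distribution:"]
    for cls in SSEClass:
        count = class_counts.get(str(cls), class_counts.get(cls, 0))
        lines.append(
            f"  {CLASS_LABELS[cls]:<18} {count:>6}  {format_percent(count / total):>7}"
        )
    return "\n".join(lines)


def render_tables(summary: Dict) -> str:
    """Render a pipeline summary dict (see ReportBundle.summary_dict) as text."""
    parts: List[str] = []
    counts = summary.get("counts", {})
    parts.append(
        "Dataset: {ddis_in} DDIs in, {ddis_nonredundant} non-redundant, "
        "{dfbs} DFBSs on {domains} domains, {dfis} DFIs".format(**counts)
    )
    cs = summary.get("class_summary")
    if cs:
        parts.append(render_class_distribution(cs["class_counts"], counts["dfbs"]))
    pairing = summary.get("pairing")
    if pairing:
        parts.append(
            f"Random-pairing test: chi2 = {pairing['chi2']:.1f} (df {pairing['df']}), "
            f"p = {pairing['p']:.3g}"
        )
        parts.append(render_pairing_table(pd.DataFrame(pairing["table"])))
    mono = summary.get("monogamy")
    if mono:
        parts.append(
            "Domains with one binding site: "
            f"{format_percent(mono['pct_single_site_domains'] / 100.0)} "
            f"({mono['n_single_site_domains']}/{mono['n_domains']}); of these, "
            f"{format_percent(mono['pct_single_partner_among_single_site'] / 100.0)} "
            "are single-partner"
        )
    return "\n\n".join(parts)
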