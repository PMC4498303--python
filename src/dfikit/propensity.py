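"""SSE propensities of binding sites and whole domain surfaces.

A binding site's propensity triple is the unweighted mean, over the member
DDIs of the site, of each member's per-residue SSE fractions — explicitly a
mean of fractions, not a pooled count ratio, so every member contributes
equally regardless of its interface size.  The same average over whole-domain
surface residues gives the surface propensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Sequence

from .core import InputError, PropensityTriple

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MemberCounts:
    """Residue counts of one member DDI, per SSE class."""

    n_alpha: int
    n_beta: int
    n_gamma: int

    def __post_init__(self) -> None:
        if min(self.n_alpha, self.n_beta, self.n_gamma) < 0:
            raise InputError("SSE counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_alpha + self.n_beta + self.n_gamma


def member_fractions(counts: MemberCounts) -> PropensityTriple:
    """Per-member SSE fractions: each class count over the member's total."""
    total = counts.total
    if total == 0:
        raise InputError("member has no residues of any SSE class")
    return PropensityTriple(counts.n_alpha / total, counts.n_beta / total, counts.n_gamma / total)


def _mean_of_fractions(members: Sequence[MemberCounts], what: str) -> PropensityTriple:
    usable = [m for m in members if m.total > 0]
    if len(usable) < len(members):
        logger.warning(
            "%d member(s) with zero %s residues excluded from the average",
            len(members) - len(usable), what,
        )
    if not usable:
        raise InputError(f"no members with {what} residues to average")
    n = len(usable)
    a = sum(m.n_alpha / m.total for m in usable) / n
    b = sum(m.n_beta / m.total for m in usable) / n
    g = sum(m.n_gamma / m.total for m in usable) / n
    # renormalise away float round-off so downstream sees an exact simplex point
    total = a + b + g
    return PropensityTriple(a / total, b / total, g / total)


def dfbs_propensity(members: Sequence[MemberCounts]) -> PropensityTriple:
    """Binding-site propensity: mean of the members' interface-residue fractions.

    Members with zero interface residues are excluded with a warning rather
    than failing the whole site.
    """
    return _mean_of_fractions(members, "interface")


def surface_propensity(members: Sequence[MemberCounts]) -> PropensityTriple:
    """Domain-surface propensity: mean of the members' surface-residue fractions."""
    return _mean_of_fractions(members, "surface")
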