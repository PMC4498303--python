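"""Shared domain types and identity/aggregation rules for the pipeline.

Terminology
-----------
DDI
    A domain-domain interaction: one physical contact between two protein
    domain instances from distinct PDB chains.
DFBS
    A domain family binding site, named ``"<family_id>:<index>"`` with a
    1-based site index so sites sort naturally within a family.
DFI
    A domain family interaction: an unordered pair of DFBSs abstracting all
    DDIs that use that pair of sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple


class InputError(ValueError):
    """Invalid user-facing input (bad IDs, malformed tables, broken invariants)."""


class SSE3(Enum):
    """Three-state secondary structure element class.

    ALPHA groups helices (DSSP H/G/I), BETA groups strands and bridges
    (DSSP E/B), GAMMA groups everything irregular (DSSP T/S and blank/loop).
    """

    ALPHA = "a"
    BETA = "b"
    GAMMA = "g"

    @classmethod
    def from_code(cls, code: str) -> "SSE3":
        try:
            return cls(code.lower())
        except ValueError:
            raise InputError(f"unknown 3-state SSE code {code!r}; expected one of a, b, g")


class SSEClass(IntEnum):
    """The five SSE composition classes of the ternary-simplex partition."""

    alpha_rich = 1
    gamma_rich = 2
    alpha_gamma = 3
    beta_gamma = 4
    alpha_beta_gamma = 5


#: Human-readable class labels, in class order 1..5.
CLASS_LABELS: Dict[SSEClass, str] = {
    SSEClass.alpha_rich: "alpha-rich",
    SSEClass.gamma_rich: "gamma-rich",
    SSEClass.alpha_gamma: "alpha+gamma",
    SSEClass.beta_gamma: "beta+gamma",
    SSEClass.alpha_beta_gamma: "alpha+beta+gamma",
}

#: Conventional plotting colours for the five classes on ternary diagrams.
CLASS_COLORS: Dict[SSEClass, str] = {
    SSEClass.alpha_rich: "red",
    SSEClass.gamma_rich: "orange",
    SSEClass.alpha_gamma: "green",
    SSEClass.beta_gamma: "cyan",
    SSEClass.alpha_beta_gamma: "blue",
}

_NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class PropensityTriple:
    """A point on the (alpha, beta, gamma) composition simplex.

    The three fractions must be in [0, 1] and sum to 1 within 1e-9; this is
    the coordinate every binding site and domain surface is mapped to.
    """

    p_alpha: float
    p_beta: float
    p_gamma: float

    def __post_init__(self) -> None:
        for name, value in (
            ("p_alpha", self.p_alpha),
            ("p_beta", self.p_beta),
            ("p_gamma", self.p_gamma),
        ):
            if not (-_NORMALIZATION_TOL <= value <= 1.0 + _NORMALIZATION_TOL):
                raise InputError(f"{name}={value} outside [0, 1]")
        total = self.p_alpha + self.p_beta + self.p_gamma
        if not math.isclose(total, 1.0, abs_tol=_NORMALIZATION_TOL):
            raise InputError(f"propensity triple sums to {total}, not 1 within 1e-9")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.p_alpha, self.p_beta, self.p_gamma)

    def __getitem__(self, sse: SSE3) -> float:
        return {SSE3.ALPHA: self.p_alpha, SSE3.BETA: self.p_beta, SSE3.GAMMA: self.p_gamma}[sse]


@dataclass(frozen=True)
class ResidueAnnotation:
    """One residue of one domain-instance side.

    ``residue_index`` is 1-based within the domain instance; ``rsa`` is the
    relative solvent accessibility as a fraction of the residue's maximum
    accessible surface area.
    """

    residue_index: int
    sse: SSE3
    in_interface: bool
    rsa: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rsa <= 1.0):
            raise InputError(f"rsa={self.rsa} outside [0, 1]")


@dataclass
class DDISide:
    """One side of a domain-domain interaction."""

    family_id: str
    dfbs_id: str
    residues: List[ResidueAnnotation] = field(default_factory=list)
    sequence: str = ""
    sas_unbound: float = 0.0
    chain: str = ""

    def validate(self, ddi_id: str = "?") -> None:
        if self.residues:
            indices = [r.residue_index for r in self.residues]
            if len(set(indices)) != len(indices):
                raise InputError(f"duplicate residue indices on one side of DDI {ddi_id}")


@dataclass
class DDIRecord:
    """One non-redundant hetero domain-domain interaction.

    Two sides from distinct PDB chains; ``sas_complex`` is the solvent
    accessible surface of the bound complex, shared by the pair.
    """

    ddi_id: str
    side_a: DDISide
    side_b: DDISide
    sas_complex: float = 0.0
    pdb_id: str = ""

    @property
    def concatenated_sequence(self) -> str:
        return self.side_a.sequence + self.side_b.sequence


@dataclass(frozen=True, order=True)
class DFI:
    """An unordered pair of DFBS IDs; the family-level abstraction of DDIs.

    Canonical form sorts the two IDs lexicographically, so ``(a, b)`` and
    ``(b, a)`` compare and hash identically.  Self-pairs are permitted
    (distinct chains of the same family can interact at the same site).
    """

    endpoint_a: str
    endpoint_b: str

    def endpoints(self) -> Tuple[str, str]:
        return (self.endpoint_a, self.endpoint_b)


def canonical_dfi(endpoint_a: str, endpoint_b: str) -> DFI:
    """Build the canonical (order-independent) DFI for two DFBS IDs.

    Raises :class:`InputError` if either ID is empty.  Idempotent: applying
    the canonicalization to an already-canonical pair changes nothing.
    """
    if not endpoint_a or not endpoint_b:
        raise InputError("DFBS IDs of a DFI must be non-empty")
    a, b = sorted((endpoint_a, endpoint_b))
    return DFI(a, b)


def aggregate_ddis_to_dfis(ddis: Sequence[DDIRecord]) -> Dict[DFI, List[str]]:
    """Group DDIs by their unordered DFBS pair.

    Returns a mapping DFI -> list of supporting ddi_ids (input order
    preserved).  The supporting counts sum to ``len(ddis)`` and the number of
    distinct DFIs never exceeds the number of DDIs.
    """
    out: Dict[DFI, List[str]] = {}
    for ddi in ddis:
        if not ddi.side_a.dfbs_id or not ddi.side_b.dfbs_id:
            raise InputError(f"DDI {ddi.ddi_id!r} has a side without an assigned dfbs_id")
        dfi = canonical_dfi(ddi.side_a.dfbs_id, ddi.side_b.dfbs_id)
        out.setdefault(dfi, []).append(ddi.ddi_id)
    return out


@dataclass
class DFBSProfile:
    """Everything the downstream analyses need to know about one family binding site."""

    dfbs_id: str
    family_id: str
    site_propensity: PropensityTriple
    surface_propensity: Optional[PropensityTriple] = None
    sse_class: Optional[SSEClass] = None
    surface_class: Optional[SSEClass] = None
    extreme_labels: Set[str] = field(default_factory=set)
    partner_families: Set[str] = field(default_factory=set)
    mean_site_sas: float = 0.0
    mean_site_residues: float = 0.0
    n_members: int = 1

    def __post_init__(self) -> None:
        if self.mean_site_sas < 0:
            raise InputError(f"mean_site_sas must be >= 0 for {self.dfbs_id}")


def make_dfbs_id(family_id: str, site_index: int) -> str:
    """Format a DFBS ID as ``family:index`` (1-based site index)."""
    if site_index < 1:
        raise InputError("site index is 1-based and must be >= 1")
    return f"{family_id}:{site_index}"


def family_of_dfbs(dfbs_id: str) -> str:
    """Extract the family accession from a ``family:index`` DFBS ID."""
    family, sep, index = dfbs_id.rpartition(":")
    if not sep or not family or not index:
        raise InputError(f"malformed dfbs_id {dfbs_id!r}; expected 'family:index'")
    return family
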