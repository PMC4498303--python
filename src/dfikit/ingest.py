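"""Structural ingestion: DSSP parsing, 8->3 SSE grouping, interface and
surface residue detection, and per-site buried solvent accessible surface.

The raw path starts from classic DSSP output (secondary structure + absolute
accessibility per residue) and PDB-format coordinates (for interface contact
detection).  Interface membership uses a heavy-atom distance cutoff, 5.0 A by
default; surface membership uses relative solvent accessibility (RSA)
normalised by the theoretical maximum accessible surface per amino acid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import SSE3, InputError

logger = logging.getLogger(__name__)


class DsspFormatError(InputError):
    """Raised when a DSSP stream is not classic column-formatted output."""


#: Theoretical maximum accessible surface area per residue (A^2),
#: Tien et al. 2013 "theoretical" values, used to normalise DSSP ACC to RSA.
MAX_ASA: Dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: DSSP 8-state codes grouped into the three SSE classes.  The blank DSSP
#: code is the loop/irregular state (often rendered "L" or "-").
_SSE8_TO_3: Dict[str, SSE3] = {
    "H": SSE3.ALPHA, "G": SSE3.ALPHA, "I": SSE3.ALPHA,
    "B": SSE3.BETA, "E": SSE3.BETA,
    "T": SSE3.GAMMA, "S": SSE3.GAMMA, " ": SSE3.GAMMA, "": SSE3.GAMMA,
    "L": SSE3.GAMMA, "-": SSE3.GAMMA,
}

#: Codes emitted by newer DSSP builds that postdate the classic 8-state set.
_MODERN_CODES = {"P"}  # polyproline-II helix


@dataclass(frozen=True)
class DsspResidueLine:
    """One residue record from a classic DSSP file."""

    chain: str
    residue_number: int
    insertion_code: str
    amino_acid: str
    sse8: str
    accessibility: float

    def __post_init__(self) -> None:
        if self.accessibility < 0:
            raise InputError("DSSP accessibility must be >= 0")


def map_sse8_to3(sse8: str, strict: bool = False) -> SSE3:
    """Collapse an 8-state DSSP code onto the three SSE classes.

    H/G/I (helices) -> ALPHA, B/E (bridge/strand) -> BETA, T/S/blank
    (turn/bend/irregular) -> GAMMA.  Codes from newer DSSP versions (e.g.
    'P') map to GAMMA with a warning unless ``strict`` is set, in which case
    they raise.
    """
    code = sse8.upper() if sse8 else " "
    if code in _SSE8_TO_3:
        return _SSE8_TO_3[code]
    if code in _MODERN_CODES and not strict:
        warnings.warn(f"modern DSSP code {code!r} mapped to GAMMA", stacklevel=2)
        return SSE3.GAMMA
    raise InputError(f"unknown DSSP SSE code {sse8!r}")


def parse_dssp(text: str) -> List[DsspResidueLine]:
    """Parse classic column-formatted DSSP output into residue records.

    Chain-break lines (amino acid ``!``) are skipped; residue order is
    preserved.  Raises :class:`DsspFormatError` if the header never reaches
    the ``#  RESIDUE`` banner, or on an unparsable residue line (the error
    message carries the 1-based line number).
    """
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise DsspFormatError("truncated DSSP header: '#  RESIDUE' banner not found")

    records: List[DsspResidueLine] = []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        if len(line) < 38:
            raise DsspFormatError(f"DSSP line {lineno} too short to hold the ACC column")
        amino_acid = line[13]
        if amino_acid == "!":  # chain break: carries no residue
            continue
        try:
            residue_number = int(line[5:10])
            insertion_code = line[10].strip()
            chain = line[11].strip()
            sse8 = line[16]
            accessibility = float(line[34:38])
        except ValueError as exc:
            raise DsspFormatError(f"unparsable DSSP residue line {lineno}: {exc}") from exc
        records.append(
            DsspResidueLine(
                chain=chain,
                residue_number=residue_number,
                insertion_code=insertion_code,
                amino_acid=amino_acid,
                sse8=sse8,
                accessibility=accessibility,
            )
        )
    return records


def relative_accessibility(
    line: DsspResidueLine,
    max_asa_table: Optional[Dict[str, float]] = None,
    skip_unknown: bool = True,
) -> Optional[float]:
    """Convert absolute DSSP accessibility to RSA in [0, 1] (capped at 1).

    Lower-case DSSP amino-acid codes denote SS-bonded cysteines.  Unknown
    amino acids return None with a warning when ``skip_unknown`` is set,
    otherwise raise.
    """
    table = max_asa_table if max_asa_table is not None else MAX_ASA
    # lower-case DSSP amino-acid codes are SS-bonded cysteines
    aa = "C" if line.amino_acid.islower() else line.amino_acid.upper()
    if aa not in table:
        if skip_unknown:
            warnings.warn(f"unknown amino acid {line.amino_acid!r}; residue skipped", stacklevel=2)
            return None
        raise InputError(f"unknown amino acid {line.amino_acid!r}")
    return min(1.0, line.accessibility / table[aa])


def surface_residues(
    lines: Sequence[DsspResidueLine],
    rsa_threshold: float = 0.05,
    max_asa_table: Optional[Dict[str, float]] = None,
    skip_unknown: bool = True,
) -> Set[Tuple[str, int, str]]:
    """Residues whose RSA meets the threshold, keyed (chain, number, icode).

    With ``rsa_threshold == 0`` every residue is a surface residue.
    """
    out: Set[Tuple[str, int, str]] = set()
    for line in lines:
        rsa = relative_accessibility(line, max_asa_table, skip_unknown)
        if rsa is None:
            continue
        if rsa >= rsa_threshold:
            out.add((line.chain, line.residue_number, line.insertion_code))
    return out


def _heavy_atoms(atoms: Iterable) -> Tuple[np.ndarray, List[Tuple[str, int, str]]]:
    """Coordinates and residue keys of non-hydrogen atoms.

    Accepts Bio.PDB atoms or (residue_key, element, xyz) triples.
    """
    coords: List[np.ndarray] = []
    keys: List[Tuple[str, int, str]] = []
    for atom in atoms:
        if hasattr(atom, "get_coord"):  # Bio.PDB.Atom
            element = (atom.element or "").strip().upper()
            if element == "H" or element == "D":
                continue
            residue = atom.get_parent()
            het, resseq, icode = residue.get_id()
            chain = residue.get_parent().get_id()
            coords.append(np.asarray(atom.get_coord(), dtype=float))
            keys.append((chain, resseq, icode.strip()))
        else:
            key, element, xyz = atom
            if str(element).strip().upper() in ("H", "D"):
                continue
            coords.append(np.asarray(xyz, dtype=float))
            keys.append(key)
    if not coords:
        return np.empty((0, 3)), []
    return np.vstack(coords), keys


def find_interface_residues(
    coords_a: Iterable,
    coords_b: Iterable,
    cutoff: float = 5.0,
) -> Tuple[Set[Tuple[str, int, str]], Set[Tuple[str, int, str]]]:
    """Residues of each side with any heavy-atom pair across sides within cutoff.

    Symmetric in its arguments: swapping the sides swaps the returned sets.
    Raises :class:`InputError` when a side has no heavy atoms or the cutoff is
    not positive; an empty interface yields a warning and two empty sets.
    """
    if cutoff <= 0:
        raise InputError("contact cutoff must be > 0")
    xyz_a, keys_a = _heavy_atoms(coords_a)
    xyz_b, keys_b = _heavy_atoms(coords_b)
    if len(keys_a) == 0 or len(keys_b) == 0:
        raise InputError("both coordinate sets must contain heavy atoms")
    tree_b = cKDTree(xyz_b)
    pairs = cKDTree(xyz_a).query_ball_tree(tree_b, r=cutoff)
    res_a: Set[Tuple[str, int, str]] = set()
    res_b: Set[Tuple[str, int, str]] = set()
    for ia, hits in enumerate(pairs):
        if hits:
            res_a.add(keys_a[ia])
            for ib in hits:
                res_b.add(keys_b[ib])
    if not res_a:
        warnings.warn("no interface residues found within cutoff", stacklevel=2)
    return res_a, res_b


def buried_site_sas(sas_a_unbound: float, sas_b_unbound: float, sas_complex: float) -> float:
    """Per-site buried solvent accessible surface for one DDI (A^2).

    Each binding site is taken to contribute equally to the buried surface,
    so the per-site value is ``(SAS_a + SAS_b - SAS_complex) / 2``.  The
    result is symmetric in the two sides and never negative.
    """
    for name, value in (
        ("sas_a_unbound", sas_a_unbound),
        ("sas_b_unbound", sas_b_unbound),
        ("sas_complex", sas_complex),
    ):
        if value < 0:
            raise InputError(f"{name} must be >= 0, got {value}")
    if sas_complex > sas_a_unbound + sas_b_unbound:
        raise InputError(
            "complex SAS exceeds the sum of the unbound surfaces: inconsistent input"
        )
    return (sas_a_unbound + sas_b_unbound - sas_complex) / 2.0
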