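"""Two-stage sequence-identity redundancy filtering of DDIs.

Stage 1 removes near-duplicate DDIs at 99% identity on the concatenation of
the two interacting domain sequences.  Stage 2 then filters the remaining
DDIs within each binding site's member group at 60% identity, so each DFBS
retains mostly distinct domain pairs.  Representative selection is a
deterministic greedy sweep (longest sequence first, ties broken by entry ID),
a simplified stand-in for full clustering of near-identical sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

from Bio import Align

from .core import DDIRecord, InputError

logger = logging.getLogger(__name__)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceEntry:
    """A sequence to deduplicate: the concatenated pair sequence of one DDI."""

    entry_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"entry {self.entry_id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - _AA_ALPHABET
        if bad:
            raise InputError(f"entry {self.entry_id!r} has non-amino-acid letters {sorted(bad)}")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Identity is the number of identical aligned positions divided by the
    alignment length (gap columns included), which makes the measure
    symmetric and conservative.
    """
    if not seq1 or not seq2:
        raise InputError("sequences must be non-empty")
    s1, s2 = seq1.upper(), seq2.upper()
    if s1 == s2:
        return 1.0
    alignment = _aligner().align(s1, s2)[0]
    identical = 0
    length = 0
    a, b = alignment[0], alignment[1]
    for x, y in zip(a, b):
        length += 1
        if x == y and x != "-":
            identical += 1
    return identical / length if length else 0.0


def filter_redundant(entries: Sequence[SequenceEntry], threshold: float) -> List[str]:
    """Greedy representative selection at a given identity threshold.

    Entries are visited longest-sequence first (ties by entry_id); an entry
    is kept iff its identity to every already-kept representative is below
    the threshold.  Hence no two kept entries reach the threshold, and every
    removed entry matches some kept representative at >= threshold.
    """
    if not (0.0 < threshold <= 1.0):
        raise InputError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(entries, key=lambda e: (-len(e.sequence), e.entry_id))
    kept: List[SequenceEntry] = []
    for entry in order:
        redundant = False
        for rep in kept:
            # identity can never exceed len(shorter)/len(longer): cheap prescreen
            lo, hi = sorted((len(entry.sequence), len(rep.sequence)))
            if lo / hi < threshold:
                continue
            if pairwise_identity(entry.sequence, rep.sequence) >= threshold:
                redundant = True
                break
        if not redundant:
            kept.append(entry)
    kept_ids = {e.entry_id for e in kept}
    return [e.entry_id for e in entries if e.entry_id in kept_ids]


def filter_redundant_report(
    entries: Sequence[SequenceEntry], threshold: float
) -> Tuple[List[str], Dict[str, str]]:
    """Like :func:`filter_redundant` but also map removed entry -> representative."""
    kept_ids = set(filter_redundant(entries, threshold))
    by_id = {e.entry_id: e for e in entries}
    removed: Dict[str, str] = {}
    kept_sorted = sorted(kept_ids)
    for entry in entries:
        if entry.entry_id in kept_ids:
            continue
        for rep_id in kept_sorted:
            if pairwise_identity(entry.sequence, by_id[rep_id].sequence) >= threshold:
                removed[entry.entry_id] = rep_id
                break
    return [e.entry_id for e in entries if e.entry_id in kept_ids], removed


def filter_ddis(
    ddis: Sequence[DDIRecord],
    stage1_threshold: float = 0.99,
    stage2_threshold: float = 0.60,
) -> List[DDIRecord]:
    """Apply the two-stage non-redundancy filter to a DDI set.

    Stage 1: greedy filtering of all DDIs on concatenated pair sequences at
    ``stage1_threshold``.  Stage 2: the survivors are grouped by each DFBS
    they involve and filtered per group at ``stage2_threshold``; a DDI is
    retained iff it is retained in every group it belongs to.
    """
    entries = [SequenceEntry(d.ddi_id, d.concatenated_sequence) for d in ddis]
    stage1_kept = set(filter_redundant(entries, stage1_threshold))
    stage1 = [d for d in ddis if d.ddi_id in stage1_kept]
    logger.info("redundancy stage 1 (%.0f%%): %d -> %d DDIs", stage1_threshold * 100, len(ddis), len(stage1))

    groups: Dict[str, List[DDIRecord]] = {}
    for d in stage1:
        groups.setdefault(d.side_a.dfbs_id, []).append(d)
        if d.side_b.dfbs_id != d.side_a.dfbs_id:
            groups.setdefault(d.side_b.dfbs_id, []).append(d)

    keep: Set[str] = {d.ddi_id for d in stage1}
    for dfbs_id, members in groups.items():
        group_entries = [SequenceEntry(d.ddi_id, d.concatenated_sequence) for d in members]
        kept_here = set(filter_redundant(group_entries, stage2_threshold))
        dropped = {d.ddi_id for d in members} - kept_here
        keep -= dropped
    result = [d for d in stage1 if d.ddi_id in keep]
    logger.info("redundancy stage 2 (%.0f%%): %d -> %d DDIs", stage2_threshold * 100, len(stage1), len(result))
    return result
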