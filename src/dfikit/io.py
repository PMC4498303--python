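"""Interchange table reading/writing.

Two tab-separated, UTF-8, headered tables move data between stages:

``ddi.tsv``
    one row per domain-domain interaction:
    ddi_id, pdb_id, chain_a, family_a, dfbs_a, chain_b, family_b, dfbs_b,
    seq_a, seq_b, sas_a_unbound, sas_b_unbound, sas_complex

``residues.tsv``
    one row per residue per DDI side (residue_index is 1-based within the
    domain instance):
    ddi_id, side (A|B), residue_index, sse3 (a|b|g), in_interface (0|1), rsa

See FORMATS.md at the repository root for the full column semantics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .core import (
    DDIRecord,
    DDISide,
    InputError,
    ResidueAnnotation,
    SSE3,
)

DDI_COLUMNS = [
    "ddi_id", "pdb_id", "chain_a", "family_a", "dfbs_a",
    "chain_b", "family_b", "dfbs_b", "seq_a", "seq_b",
    "sas_a_unbound", "sas_b_unbound", "sas_complex",
]

RESIDUE_COLUMNS = ["ddi_id", "side", "residue_index", "sse3", "in_interface", "rsa"]

PathLike = Union[str, Path]


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_ddi_table(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, DDI_COLUMNS, f"ddi table {path}")
    for col in ("sas_a_unbound", "sas_b_unbound", "sas_complex"):
        frame[col] = pd.to_numeric(frame[col], errors="raise")
    if frame["ddi_id"].duplicated().any():
        dupes = frame.loc[frame["ddi_id"].duplicated(), "ddi_id"].tolist()
        raise InputError(f"duplicate ddi_id values in {path}: {dupes[:5]}")
    return frame


def read_residue_table(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, RESIDUE_COLUMNS, f"residue table {path}")
    frame["residue_index"] = pd.to_numeric(frame["residue_index"], errors="raise").astype(int)
    frame["in_interface"] = pd.to_numeric(frame["in_interface"], errors="raise").astype(int)
    frame["rsa"] = pd.to_numeric(frame["rsa"], errors="raise").astype(float)
    bad_side = ~frame["side"].isin(["A", "B"])
    if bad_side.any():
        lineno = int(frame.index[bad_side][0]) + 2  # header + 1-based
        raise InputError(f"residue table {path}: invalid side at line {lineno}")
    bad_sse = ~frame["sse3"].isin(["a", "b", "g"])
    if bad_sse.any():
        lineno = int(frame.index[bad_sse][0]) + 2
        raise InputError(f"residue table {path}: invalid sse3 code at line {lineno}")
    return frame


def records_from_frames(
    ddi_frame: pd.DataFrame, residue_frame: Optional[pd.DataFrame] = None
) -> List[DDIRecord]:
    """Materialise DDIRecord objects (with residue annotations, if given)."""
    residues_by_key: Dict[tuple, List[ResidueAnnotation]] = {}
    if residue_frame is not None:
        for row in residue_frame.itertuples(index=False):
            residues_by_key.setdefault((row.ddi_id, row.side), []).append(
                ResidueAnnotation(
                    residue_index=int(row.residue_index),
                    sse=SSE3(row.sse3),
                    in_interface=bool(int(row.in_interface)),
                    rsa=float(row.rsa),
                )
            )
    records: List[DDIRecord] = []
    for row in ddi_frame.itertuples(index=False):
        side_a = DDISide(
            family_id=row.family_a,
            dfbs_id=row.dfbs_a,
            residues=residues_by_key.get((row.ddi_id, "A"), []),
            sequence=row.seq_a,
            sas_unbound=float(row.sas_a_unbound),
            chain=row.chain_a,
        )
        side_b = DDISide(
            family_id=row.family_b,
            dfbs_id=row.dfbs_b,
            residues=residues_by_key.get((row.ddi_id, "B"), []),
            sequence=row.seq_b,
            sas_unbound=float(row.sas_b_unbound),
            chain=row.chain_b,
        )
        side_a.validate(row.ddi_id)
        side_b.validate(row.ddi_id)
        records.append(
            DDIRecord(
                ddi_id=row.ddi_id,
                side_a=side_a,
                side_b=side_b,
                sas_complex=float(row.sas_complex),
                pdb_id=row.pdb_id,
            )
        )
    return records


def load_ddis(
    ddi_path: PathLike, residues_path: Optional[PathLike] = None
) -> List[DDIRecord]:
    ddi_frame = read_ddi_table(ddi_path)
    residue_frame = read_residue_table(residues_path) if residues_path else None
    return records_from_frames(ddi_frame, residue_frame)


def frames_from_records(records: Sequence[DDIRecord]) -> tuple:
    """Inverse of :func:`records_from_frames`: (ddi_frame, residue_frame)."""
    ddi_rows = []
    residue_rows = []
    for rec in records:
        ddi_rows.append(
            {
                "ddi_id": rec.ddi_id,
                "pdb_id": rec.pdb_id,
                "chain_a": rec.side_a.chain,
                "family_a": rec.side_a.family_id,
                "dfbs_a": rec.side_a.dfbs_id,
                "chain_b": rec.side_b.chain,
                "family_b": rec.side_b.family_id,
                "dfbs_b": rec.side_b.dfbs_id,
                "seq_a": rec.side_a.sequence,
                "seq_b": rec.side_b.sequence,
                "sas_a_unbound": rec.side_a.sas_unbound,
                "sas_b_unbound": rec.side_b.sas_unbound,
                "sas_complex": rec.sas_complex,
            }
        )
        for side_label, side in (("A", rec.side_a), ("B", rec.side_b)):
            for res in side.residues:
                residue_rows.append(
                    {
                        "ddi_id": rec.ddi_id,
                        "side": side_label,
                        "residue_index": res.residue_index,
                        "sse3": res.sse.value,
                        "in_interface": int(res.in_interface),
                        "rsa": res.rsa,
                    }
                )
    return (
        pd.DataFrame(ddi_rows, columns=DDI_COLUMNS),
        pd.DataFrame(residue_rows, columns=RESIDUE_COLUMNS),
    )


def write_tsv(frame: pd.DataFrame, path: PathLike, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)
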