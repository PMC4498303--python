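"""End-to-end pipeline: interchange tables -> profiles -> classification ->
pairing statistics -> promiscuity analyses -> report bundle.

The heavy lifting is done on pandas frames (one residue per row) so that
study-scale datasets (thousands of DDIs, ~10^6 residues) remain cheap.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as dio
from .classify import classify_sse, extreme_categories, summarize_classes, ternary_coordinates
from .core import (
    CLASS_LABELS,
    DFBSProfile,
    DFI,
    InputError,
    PropensityTriple,
    SSEClass,
    aggregate_ddis_to_dfis,
    canonical_dfi,
)
from .pairing import RandomPairingModel
from .promiscuity import (
    domain_dfbs_histogram,
    domain_promiscuity_summary,
    monogamy_fractions,
    partner_families_map,
    promiscuity_scatter,
    sas_by_partner_count,
    stratify_by_partners,
)
from .redundancy import filter_ddis

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline thresholds and options."""

    rsa_threshold: float = 0.05
    contact_cutoff_angstrom: float = 5.0
    stage1_identity: float = 0.99
    stage2_identity: float = 0.60
    alpha: float = 0.001
    apply_redundancy_filter: bool = True
    exclude_families: Set[str] = field(default_factory=set)
    top_n_domains: int = 9

    def __post_init__(self) -> None:
        for name in ("rsa_threshold", "stage1_identity", "stage2_identity", "alpha"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise InputError(f"{name}={value} outside [0, 1]")
        if not (0.0 < self.stage1_identity <= 1.0) or not (0.0 < self.stage2_identity <= 1.0):
            raise InputError("identity thresholds must be in (0, 1]")


def _member_fraction_table(
    residue_frame: pd.DataFrame, mask: pd.Series
) -> pd.DataFrame:
    """Per-(ddi_id, side) SSE fractions and residue totals over masked residues."""
    sub = residue_frame.loc[mask, ["ddi_id", "side", "sse3"]]
    counts = (
        sub.groupby(["ddi_id", "side", "sse3"], sort=False)
        .size()
        .unstack("sse3", fill_value=0)
        .reindex(columns=["a", "b", "g"], fill_value=0)
    )
    total = counts.sum(axis=1)
    fractions = counts.div(total, axis=0)
    fractions.columns = ["f_alpha", "f_beta", "f_gamma"]
    fractions["n_residues"] = total
    return fractions.reset_index()


def dfis_from_frame(ddi_frame: pd.DataFrame) -> Tuple[List[DFI], Dict[DFI, List[str]]]:
    """Distinct DFIs and their supporting DDI ids from a ddi table."""
    support: Dict[DFI, List[str]] = {}
    for row in ddi_frame.itertuples(index=False):
        if not row.dfbs_a or not row.dfbs_b:
            raise InputError(f"DDI {row.ddi_id!r} has a side without an assigned dfbs_id")
        dfi = canonical_dfi(row.dfbs_a, row.dfbs_b)
        support.setdefault(dfi, []).append(row.ddi_id)
    return list(support.keys()), support


def build_profiles(
    ddi_frame: pd.DataFrame,
    residue_frame: pd.DataFrame,
    rsa_threshold: float = 0.05,
) -> List[DFBSProfile]:
    """Compute one :class:`DFBSProfile` per binding site from interchange frames.

    Site propensities average each member's interface-residue SSE fractions;
    surface propensities average each member's fractions over residues with
    RSA >= ``rsa_threshold``.  Buried site surface is the equal-split buried
    SAS of each member DDI, averaged per site.
    """
    # member -> dfbs mapping from the long form of the ddi table
    side_map = pd.concat(
        [
            ddi_frame[["ddi_id", "dfbs_a", "family_a"]].rename(
                columns={"dfbs_a": "dfbs_id", "family_a": "family_id"}
            ).assign(side="A"),
            ddi_frame[["ddi_id", "dfbs_b", "family_b"]].rename(
                columns={"dfbs_b": "dfbs_id", "family_b": "family_id"}
            ).assign(side="B"),
        ],
        ignore_index=True,
    )

    buried = (
        ddi_frame["sas_a_unbound"] + ddi_frame["sas_b_unbound"] - ddi_frame["sas_complex"]
    ) / 2.0
    if (buried < -1e-9).any():
        bad = ddi_frame.loc[buried < -1e-9, "ddi_id"].iloc[0]
        raise InputError(f"DDI {bad!r}: complex SAS exceeds the sum of unbound surfaces")
    sas_map = dict(zip(ddi_frame["ddi_id"], buried.clip(lower=0.0)))

    iface = _member_fraction_table(residue_frame, residue_frame["in_interface"] == 1)
    surface = _member_fraction_table(residue_frame, residue_frame["rsa"] >= rsa_threshold)

    iface = iface.merge(side_map, on=["ddi_id", "side"], how="left", validate="one_to_one")
    if iface["dfbs_id"].isna().any():
        orphan = iface.loc[iface["dfbs_id"].isna(), "ddi_id"].iloc[0]
        raise InputError(f"residue rows reference DDI {orphan!r} absent from the ddi table")
    surface = surface.merge(side_map, on=["ddi_id", "side"], how="left", validate="one_to_one")

    iface["buried_sas"] = iface["ddi_id"].map(sas_map)

    grouped = iface.groupby("dfbs_id", sort=False)
    site_means = grouped[["f_alpha", "f_beta", "f_gamma"]].mean()
    site_extras = grouped.agg(
        n_members=("ddi_id", "size"),
        mean_site_residues=("n_residues", "mean"),
        mean_site_sas=("buried_sas", "mean"),
        family_id=("family_id", "first"),
    )
    surf_means = surface.groupby("dfbs_id", sort=False)[["f_alpha", "f_beta", "f_gamma"]].mean()

    merged = site_means.join(site_extras).join(
        surf_means.rename(columns=lambda c: "s_" + c), how="left"
    )
    profiles: List[DFBSProfile] = []
    for row in merged.itertuples():
        dfbs_id = row.Index
        total = row.f_alpha + row.f_beta + row.f_gamma
        triple = PropensityTriple(row.f_alpha / total, row.f_beta / total, row.f_gamma / total)
        if pd.notna(row.s_f_alpha):
            stotal = row.s_f_alpha + row.s_f_beta + row.s_f_gamma
            surface_triple = PropensityTriple(
                row.s_f_alpha / stotal, row.s_f_beta / stotal, row.s_f_gamma / stotal
            )
            surface_class = classify_sse(surface_triple)
        else:
            surface_triple, surface_class = None, None
        profiles.append(
            DFBSProfile(
                dfbs_id=dfbs_id,
                family_id=row.family_id,
                site_propensity=triple,
                surface_propensity=surface_triple,
                sse_class=classify_sse(triple),
                surface_class=surface_class,
                extreme_labels=extreme_categories(triple),
                mean_site_sas=float(row.mean_site_sas),
                mean_site_residues=float(row.mean_site_residues),
                n_members=int(row.n_members),
            )
        )
    return profiles


def attach_partners(profiles: Sequence[DFBSProfile], dfis: Sequence[DFI]) -> None:
    """Fill ``partner_families`` on each profile from the DFI set (in place)."""
    family_of = {p.dfbs_id: p.family_id for p in profiles}
    partners = partner_families_map(dfis, family_of=family_of)
    for p in profiles:
        p.partner_families = partners.get(p.dfbs_id, set())


@dataclass
class ReportBundle:
    """All per-stage outputs of one pipeline run."""

    n_ddis_in: int
    n_ddis_nonredundant: int
    profiles: List[DFBSProfile]
    dfis: List[DFI]
    dfi_support: Dict[DFI, List[str]]
    class_summary: object
    pairing: object
    strata: object
    sas_table: pd.DataFrame
    domain_histogram: pd.DataFrame
    monogamy: Dict[str, float]
    domain_ranking: list

    def summary_dict(self) -> Dict:
        from .report import round_half_up

        pairing = self.pairing
        return {
            "counts": {
                "ddis_in": self.n_ddis_in,
                "ddis_nonredundant": self.n_ddis_nonredundant,
                "dfbs": len(self.profiles),
                "dfis": len(self.dfis),
                "domains": len({p.family_id for p in self.profiles}),
            },
            "class_summary": self.class_summary.to_dict(),
            "pairing": {
                "chi2": pairing.chi2,
                "df": pairing.df,
                "p": pairing.pvalue,
                "table": pairing.pair_table.to_dict(orient="records"),
            },
            "strata": self.strata.table.reset_index().to_dict(orient="records"),
            "sas_by_partners": self.sas_table.reset_index().to_dict(orient="records"),
            "domain_histogram": self.domain_histogram.reset_index().to_dict(orient="records"),
            "monogamy": self.monogamy,
            "domain_ranking": [
                {
                    "family_id": d.family_id,
                    "n_dfbs": d.n_dfbs,
                    "per_site_partners": list(d.per_site_partners),
                    "total_partners": d.total_partners,
                    "max_partners": d.max_partners,
                }
                for d in self.domain_ranking
            ],
        }


def run_pipeline(
    ddi_frame: pd.DataFrame,
    residue_frame: pd.DataFrame,
    config: Optional[RunConfig] = None,
) -> ReportBundle:
    """Execute redundancy -> propensity -> classify -> pairing -> promiscuity."""
    config = config or RunConfig()
    n_in = len(ddi_frame)

    if config.apply_redundancy_filter and n_in > 0:
        records = dio.records_from_frames(ddi_frame)
        kept = filter_ddis(records, config.stage1_identity, config.stage2_identity)
        kept_ids = {r.ddi_id for r in kept}
        ddi_frame = ddi_frame[ddi_frame["ddi_id"].isin(kept_ids)].reset_index(drop=True)
        residue_frame = residue_frame[residue_frame["ddi_id"].isin(kept_ids)].reset_index(
            drop=True
        )
        logger.info("redundancy filter: %d -> %d DDIs", n_in, len(ddi_frame))

    if len(ddi_frame) == 0:
        return ReportBundle(
            n_ddis_in=n_in, n_ddis_nonredundant=0, profiles=[], dfis=[], dfi_support={},
            class_summary=None, pairing=None, strata=None,
            sas_table=pd.DataFrame(), domain_histogram=pd.DataFrame(),
            monogamy={}, domain_ranking=[],
        )

    profiles = build_profiles(ddi_frame, residue_frame, config.rsa_threshold)
    dfis, support = dfis_from_frame(ddi_frame)
    attach_partners(profiles, dfis)
    logger.info("profiles: %d DFBSs, %d DFIs", len(profiles), len(dfis))

    class_summary = summarize_classes(profiles)
    pairing = RandomPairingModel.from_profiles(dfis, profiles).fit(alpha=config.alpha)
    analysed = (
        [p for p in profiles if p.family_id not in config.exclude_families]
        if config.exclude_families
        else profiles
    )
    strata = stratify_by_partners(analysed, alpha=config.alpha)
    sas_table = sas_by_partner_count(analysed)
    histogram = domain_dfbs_histogram(profiles)
    monogamy = monogamy_fractions(profiles)
    ranking = domain_promiscuity_summary(
        profiles, exclude=config.exclude_families, top_n=config.top_n_domains
    )

    return ReportBundle(
        n_ddis_in=n_in,
        n_ddis_nonredundant=len(ddi_frame),
        profiles=profiles,
        dfis=dfis,
        dfi_support=support,
        class_summary=class_summary,
        pairing=pairing,
        strata=strata,
        sas_table=sas_table,
        domain_histogram=histogram,
        monogamy=monogamy,
        domain_ranking=ranking,
    )


def profiles_frame(profiles: Sequence[DFBSProfile]) -> pd.DataFrame:
    """Flat per-DFBS table (classes.tsv / promiscuity.tsv source)."""
    rows = []
    for p in profiles:
        x, y = ternary_coordinates(p.site_propensity)
        rows.append(
            {
                "dfbs_id": p.dfbs_id,
                "family_id": p.family_id,
                "n_members": p.n_members,
                "p_alpha": p.site_propensity.p_alpha,
                "p_beta": p.site_propensity.p_beta,
                "p_gamma": p.site_propensity.p_gamma,
                "q_alpha": p.surface_propensity.p_alpha if p.surface_propensity else np.nan,
                "q_beta": p.surface_propensity.p_beta if p.surface_propensity else np.nan,
                "q_gamma": p.surface_propensity.p_gamma if p.surface_propensity else np.nan,
                "sse_class": int(p.sse_class) if p.sse_class else np.nan,
                "surface_class": int(p.surface_class) if p.surface_class else np.nan,
                "extreme_labels": ",".join(sorted(p.extreme_labels)),
                "ternary_x": x,
                "ternary_y": y,
                "n_partners": len(p.partner_families),
                "mean_site_sas": p.mean_site_sas,
                "mean_site_residues": p.mean_site_residues,
            }
        )
    return pd.DataFrame(rows)


def write_report(bundle: ReportBundle, out_dir: Path) -> None:
    """Write all stage TSVs plus summary.json under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if bundle.profiles:
        frame = profiles_frame(bundle.profiles)
        dio.write_tsv(frame, out_dir / "classes.tsv")
        dio.write_tsv(
            frame[
                ["dfbs_id", "n_members", "p_alpha", "p_beta", "p_gamma",
                 "q_alpha", "q_beta", "q_gamma"]
            ],
            out_dir / "propensities.tsv",
        )
        dio.write_tsv(
            frame[["dfbs_id", "family_id", "n_partners", "mean_site_sas", "mean_site_residues"]],
            out_dir / "promiscuity.tsv",
        )
        dio.write_tsv(bundle.pairing.pair_table, out_dir / "pairing.tsv")
        dio.write_tsv(bundle.sas_table, out_dir / "sas_by_partners.tsv", index=True)
        dio.write_tsv(bundle.domain_histogram, out_dir / "domain_histogram.tsv", index=True)
        dio.write_tsv(
            promiscuity_scatter(domain_promiscuity_summary(bundle.profiles)),
            out_dir / "promiscuity_scatter.tsv",
        )
        domains = pd.DataFrame(
            [
                {
                    "family_id": d.family_id,
                    "n_dfbs": d.n_dfbs,
                    "per_site_partners": ",".join(map(str, d.per_site_partners)),
                    "total_partners": d.total_partners,
                    "max_partners": d.max_partners,
                }
                for d in domain_promiscuity_summary(bundle.profiles)
            ]
        )
        dio.write_tsv(domains, out_dir / "domains.tsv")
        summary = bundle.summary_dict()
    else:
        summary = {
            "counts": {
                "ddis_in": bundle.n_ddis_in,
                "ddis_nonredundant": 0,
                "dfbs": 0,
                "dfis": 0,
                "domains": 0,
            }
        }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
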