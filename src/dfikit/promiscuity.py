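"""Partner-multiplicity (promiscuity) analyses at binding-site and domain level.

A binding site's promiscuity is its number of distinct partner domain
families across all its DFIs; a domain's promiscuity combines the number of
binding sites it harbours with each site's partner count.  Sites are
stratified by partner count into {1, 2, 3, >3} for the class-distribution and
buried-surface comparisons.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import CLASS_LABELS, DFBSProfile, DFI, InputError, SSEClass, family_of_dfbs

logger = logging.getLogger(__name__)

#: Stratum labels over the number of distinct Pfam partners.
STRATA = ("1", "2", "3", ">3")


def stratum_of(n_partners: int) -> str:
    if n_partners < 1:
        raise InputError("every binding site in the dataset has at least one partner")
    return str(n_partners) if n_partners <= 3 else ">3"


def partner_families_map(
    dfis: Iterable[DFI], family_of: Optional[Mapping[str, str]] = None
) -> Dict[str, Set[str]]:
    """Distinct partner families of every DFBS appearing in the DFIs.

    ``family_of`` maps DFBS IDs to family accessions; by default the family
    is parsed from the ``family:index`` ID itself.  A family partnering the
    same site through several of its own sites counts once.
    """

    def fam(dfbs_id: str) -> str:
        if family_of is not None:
            try:
                return family_of[dfbs_id]
            except KeyError as exc:
                raise InputError(f"dangling dfbs_id {dfbs_id!r} with no family") from exc
        return family_of_dfbs(dfbs_id)

    partners: Dict[str, Set[str]] = {}
    for dfi in dfis:
        a, b = dfi.endpoint_a, dfi.endpoint_b
        partners.setdefault(a, set()).add(fam(b))
        partners.setdefault(b, set()).add(fam(a))
    return partners


def partner_counts(
    dfis: Iterable[DFI], family_of: Optional[Mapping[str, str]] = None
) -> Dict[str, int]:
    """Number of distinct partner families per DFBS."""
    return {k: len(v) for k, v in partner_families_map(dfis, family_of).items()}


@dataclass
class StratifiedClassResults:
    """Class distribution per partner-count stratum with tests vs the global one.

    ``table``: per-stratum class percentages (rows sum to 100).
    ``tests``: per-stratum global chi-square and per-class z-tests against the
    all-DFBS distribution.
    """

    table: pd.DataFrame
    tests: pd.DataFrame
    global_fractions: pd.Series


def stratify_by_partners(
    profiles: Sequence[DFBSProfile], alpha: float = 0.001
) -> StratifiedClassResults:
    """Distribution of DFBSs over the five SSE classes per partner stratum.

    Each stratum's class distribution is compared with the global DFBS
    distribution by a chi-square test (df = 4) followed by per-class
    one-proportion z-tests.  Empty strata are omitted with a warning.
    """
    for p in profiles:
        if p.sse_class is None:
            raise InputError(f"profile {p.dfbs_id} is not classified")
        if not p.partner_families:
            raise InputError(f"profile {p.dfbs_id} has no partner count")
    classes = list(SSEClass)
    n_total = len(profiles)
    global_counts = np.array(
        [sum(1 for p in profiles if p.sse_class == c) for c in classes], dtype=float
    )
    global_fractions = global_counts / n_total

    rows = []
    test_rows = []
    for stratum in STRATA:
        subset = [p for p in profiles if stratum_of(len(p.partner_families)) == stratum]
        if not subset:
            warnings.warn(f"partner stratum {stratum!r} is empty; row omitted")
            continue
        n = len(subset)
        counts = np.array(
            [sum(1 for p in subset if p.sse_class == c) for c in classes], dtype=float
        )
        rows.append(
            {"stratum": stratum, "n_dfbs": n}
            | {CLASS_LABELS[c]: 100.0 * counts[i] / n for i, c in enumerate(classes)}
        )
        expected = n * global_fractions
        if np.all(expected > 0):
            chi2 = float(np.sum((counts - expected) ** 2 / expected))
            p_chi2 = float(stats.chi2.sf(chi2, len(classes) - 1))
        else:
            chi2, p_chi2 = float("nan"), float("nan")
        for i, c in enumerate(classes):
            p0 = global_fractions[i]
            se = math.sqrt(n * p0 * (1 - p0))
            z = (counts[i] - n * p0) / se if se > 0 else float("nan")
            pval = 2.0 * float(stats.norm.sf(abs(z))) if math.isfinite(z) else float("nan")
            flag = "ns"
            if math.isfinite(pval) and pval < alpha:
                flag = "higher" if z > 0 else "lower"
            test_rows.append(
                {
                    "stratum": stratum,
                    "sse_class": CLASS_LABELS[c],
                    "chi2": chi2,
                    "chi2_p": p_chi2,
                    "z": z,
                    "p": pval,
                    "flag": flag,
                }
            )

    # global row, mirroring the "Any" row of the stratified table
    rows.append(
        {"stratum": "any", "n_dfbs": n_total}
        | {CLASS_LABELS[c]: 100.0 * global_fractions[i] for i, c in enumerate(classes)}
    )
    return StratifiedClassResults(
        table=pd.DataFrame(rows).set_index("stratum"),
        tests=pd.DataFrame(test_rows),
        global_fractions=pd.Series(global_fractions, index=[CLASS_LABELS[c] for c in classes]),
    )


def _two_sample_z(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> Tuple[float, float]:
    """Unequal-variance two-sample z-test on means."""
    se = math.sqrt(sd1 ** 2 / n1 + sd2 ** 2 / n2)
    if se == 0:
        return float("nan"), float("nan")
    z = (mean1 - mean2) / se
    return z, 2.0 * float(stats.norm.sf(abs(z)))


def sas_by_partner_count(profiles: Sequence[DFBSProfile]) -> pd.DataFrame:
    """Mean +/- SD of buried site surface (A^2) and interface residue count
    per partner stratum, with two-sample z-tests against the single-partner
    stratum.

    Strata of size < 2 report missing SDs and tests.
    """
    groups: Dict[str, List[DFBSProfile]] = {s: [] for s in STRATA}
    for p in profiles:
        if not p.partner_families:
            raise InputError(f"profile {p.dfbs_id} has no partner count")
        groups[stratum_of(len(p.partner_families))].append(p)

    ref = groups["1"]
    ref_sas = np.array([p.mean_site_sas for p in ref], dtype=float)
    ref_res = np.array([p.mean_site_residues for p in ref], dtype=float)

    rows = []
    for stratum in STRATA:
        subset = groups[stratum]
        if not subset:
            warnings.warn(f"partner stratum {stratum!r} is empty; row omitted")
            continue
        sas = np.array([p.mean_site_sas for p in subset], dtype=float)
        res = np.array([p.mean_site_residues for p in subset], dtype=float)
        n = len(subset)
        row = {
            "stratum": stratum,
            "n_dfbs": n,
            "mean_sas": float(sas.mean()),
            "sd_sas": float(sas.std(ddof=1)) if n > 1 else float("nan"),
            "mean_residues": float(res.mean()),
            "sd_residues": float(res.std(ddof=1)) if n > 1 else float("nan"),
        }
        if stratum != "1" and n > 1 and len(ref) > 1:
            z_sas, p_sas = _two_sample_z(
                row["mean_sas"], row["sd_sas"], n,
                float(ref_sas.mean()), float(ref_sas.std(ddof=1)), len(ref),
            )
            z_res, p_res = _two_sample_z(
                row["mean_residues"], row["sd_residues"], n,
                float(ref_res.mean()), float(ref_res.std(ddof=1)), len(ref),
            )
            row |= {"z_sas": z_sas, "p_sas": p_sas, "z_residues": z_res, "p_residues": p_res}
        else:
            row |= {
                "z_sas": float("nan"), "p_sas": float("nan"),
                "z_residues": float("nan"), "p_residues": float("nan"),
            }
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


def domain_dfbs_histogram(profiles: Sequence[DFBSProfile]) -> pd.DataFrame:
    """Distribution of domains over their number of binding sites.

    Also reports the fraction of one-site domains and, among those, the
    fraction whose single site is single-partner ("monogamous" domains).
    """
    by_family: Dict[str, List[DFBSProfile]] = {}
    for p in profiles:
        by_family.setdefault(p.family_id, []).append(p)
    n_sites = pd.Series({fam: len(v) for fam, v in by_family.items()})
    hist = n_sites.value_counts().sort_index()
    frame = pd.DataFrame({"n_domains": hist})
    frame.index.name = "n_dfbs"
    frame["pct_domains"] = 100.0 * frame["n_domains"] / len(by_family)
    return frame


def monogamy_fractions(profiles: Sequence[DFBSProfile]) -> Dict[str, float]:
    """Fractions describing single-site domains.

    Returns the percent of domains with exactly one binding site and, among
    those, the percent whose site has a single partner family.
    """
    by_family: Dict[str, List[DFBSProfile]] = {}
    for p in profiles:
        by_family.setdefault(p.family_id, []).append(p)
    single_site = [v[0] for v in by_family.values() if len(v) == 1]
    n_domains = len(by_family)
    pct_single_site = 100.0 * len(single_site) / n_domains if n_domains else float("nan")
    if single_site:
        single_partner = sum(1 for p in single_site if len(p.partner_families) == 1)
        pct_single_partner = 100.0 * single_partner / len(single_site)
    else:
        pct_single_partner = float("nan")
    return {
        "n_domains": n_domains,
        "n_single_site_domains": len(single_site),
        "pct_single_site_domains": pct_single_site,
        "pct_single_partner_among_single_site": pct_single_partner,
    }


@dataclass
class DomainPromiscuity:
    """Partner multiplicities of one domain family."""

    family_id: str
    n_dfbs: int
    per_site_partners: Tuple[int, ...]  # descending
    total_partners: int
    max_partners: int

    def __post_init__(self) -> None:
        if self.n_dfbs < 1:
            raise InputError("a domain must harbour at least one binding site")
        if not (self.max_partners <= self.total_partners <= sum(self.per_site_partners)):
            raise InputError(
                f"partner invariant violated for {self.family_id}: "
                f"max {self.max_partners} <= total {self.total_partners} "
                f"<= sum {sum(self.per_site_partners)}"
            )


def domain_promiscuity_summary(
    profiles: Sequence[DFBSProfile],
    exclude: Optional[Set[str]] = None,
    top_n: Optional[int] = None,
) -> List[DomainPromiscuity]:
    """Per-domain promiscuity ranking (most binding sites first).

    ``exclude`` omits outlier families from the ranking; ``top_n`` truncates
    it.  Ties in site count are broken by total partner count, then family
    ID.  For every domain, max per-site partners <= total distinct partners
    <= sum of per-site partner counts.
    """
    exclude = exclude or set()
    by_family: Dict[str, List[DFBSProfile]] = {}
    for p in profiles:
        if p.family_id in exclude:
            continue
        by_family.setdefault(p.family_id, []).append(p)

    out: List[DomainPromiscuity] = []
    for family, sites in by_family.items():
        per_site = tuple(sorted((len(p.partner_families) for p in sites), reverse=True))
        all_partners: Set[str] = set()
        for p in sites:
            all_partners |= p.partner_families
        out.append(
            DomainPromiscuity(
                family_id=family,
                n_dfbs=len(sites),
                per_site_partners=per_site,
                total_partners=len(all_partners),
                max_partners=max(per_site),
            )
        )
    out.sort(key=lambda d: (-d.n_dfbs, -d.total_partners, d.family_id))
    return out[:top_n] if top_n is not None else out


def promiscuity_scatter(summary: Sequence[DomainPromiscuity]) -> pd.DataFrame:
    """Scatter data: total partners (x) vs max per-site partners (y) per domain."""
    return pd.DataFrame(
        {
            "family_id": [d.family_id for d in summary],
            "total_partners": [d.total_partners for d in summary],
            "max_partners_per_dfbs": [d.max_partners for d in summary],
        }
    )
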