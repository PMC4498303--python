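"""Synthetic dataset generator with the statistical structure the analyses assume.

The generator emits interchange frames (``ddi.tsv`` / ``residues.tsv``) plus a
ground-truth record, emulating the study conditions: a Table-1-like class
mixture of ~4000 binding sites on ~2150 families, within-class compositional
spread around each class's mean triple, random (or enriched) class pairing of
~3000 DFIs, a skewed partner-multiplicity distribution (~81% single-partner
sites), and Table-6-like per-stratum buried surfaces and interface sizes.

Two constructions make the generated data exact rather than approximate
ground truth:

* DFI class pairs are drawn iid from the random-pairing product distribution
  computed from the *realized* roster class fractions (optionally multiplied
  by an enrichment matrix and renormalised), and every roster site is covered
  by at least one DFI.  The pipeline's expectation model therefore uses
  exactly the fractions the pairs were sampled from, so with enrichment = 1
  the global chi-square test is exactly calibrated.
* Site compositions are rejection-sampled until the *integer residue counts*
  realised for the site's members still classify to the intended archetype,
  so generated class labels are exact, not approximate, truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as dio
from .core import InputError, PropensityTriple, SSEClass, make_dfbs_id
from .classify import classify_sse

#: Table-like class mixture: DFBS counts 835/996/1117/784/269 over 4001.
DEFAULT_CLASS_MIXTURE = (835 / 4001, 996 / 4001, 1117 / 4001, 784 / 4001, 269 / 4001)

#: Mean site composition per class (normalised percent means).
SITE_ARCHETYPES = (
    (0.866, 0.005, 0.129),
    (0.073, 0.055, 0.872),
    (0.485, 0.039, 0.476),
    (0.093, 0.391, 0.517),
    (0.293, 0.531, 0.176),
)

#: Mean whole-surface composition per class (normalised).
SURFACE_ARCHETYPES = (
    (0.797, 0.002, 0.201),
    (0.096, 0.009, 0.824),
    (0.467, 0.097, 0.436),
    (0.147, 0.330, 0.523),
    (0.531, 0.210, 0.260),
)

#: Sites-per-family distribution: ~53% one site, ~9.5% four or more.
DEFAULT_SITES_PER_FAMILY = {
    1: 0.532, 2: 0.250, 3: 0.123, 4: 0.050, 5: 0.020,
    6: 0.012, 7: 0.008, 8: 0.003, 9: 0.002,
}

#: Partner-count distribution of binding sites (fraction of sites with k
#: distinct partner families); ">3" sites draw 4 + geometric extras.
DEFAULT_PARTNER_MULTIPLICITY = {1: 0.811, 2: 0.125, 3: 0.030, 4: 0.034}

#: Per-stratum (mean, SD) of buried site surface (A^2) and residue counts.
DEFAULT_SITE_SAS = {"1": (678.0, 496.0), "2": (579.0, 429.0), "3": (554.0, 482.0), ">3": (578.0, 334.0)}
DEFAULT_SITE_RESIDUES = {"1": (12.0, 9.0), "2": (10.0, 8.0), "3": (10.0, 9.0), ">3": (11.0, 7.0)}

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _normalized(v: Sequence[float]) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    return arr / arr.sum()


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic generator; defaults mirror the study scale."""

    seed: int = 0
    n_families: int = 2153
    n_dfis: int = 3084
    sites_per_family: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SITES_PER_FAMILY)
    )
    class_mixture: Tuple[float, ...] = DEFAULT_CLASS_MIXTURE
    composition_concentration: float = 15.0
    pairing_enrichment: Optional[Sequence[Sequence[float]]] = None  # 5x5 symmetric
    partner_multiplicity: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PARTNER_MULTIPLICITY)
    )
    multiplicity_class_boost: Dict[int, float] = field(default_factory=dict)
    site_residue_count: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SITE_RESIDUES)
    )
    site_sas: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SITE_SAS)
    )
    sas_offset: Tuple[float, float] = (800.0, 2000.0)  # unbound = latent + U(range)
    surface_extra_residues: Tuple[float, float] = (60.0, 20.0)
    surface_match_prob: float = 0.6
    buried_residues_per_side: int = 6
    multi_member_prob: float = 0.149  # fraction of DFIs with >1 supporting DDI
    multi_member_extra_mean: float = 2.5  # extras ~ 1 + Poisson(mean) for those
    sequence_length: int = 50
    rejection_budget: int = 3000
    rsa_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.class_mixture), 1.0, abs_tol=1e-9):
            raise InputError("class_mixture must sum to 1")
        if not math.isclose(sum(self.sites_per_family.values()), 1.0, abs_tol=1e-9):
            raise InputError("sites_per_family must sum to 1")
        if self.pairing_enrichment is not None:
            mat = np.asarray(self.pairing_enrichment, dtype=float)
            if mat.shape != (5, 5) or np.any(mat < 0) or not np.allclose(mat, mat.T):
                raise InputError("pairing_enrichment must be a symmetric non-negative 5x5 matrix")

    def to_dict(self) -> Dict:
        d = asdict(self)
        if self.pairing_enrichment is not None:
            d["pairing_enrichment"] = np.asarray(self.pairing_enrichment).tolist()
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        kwargs = dict(data)
        for key in ("sites_per_family", "partner_multiplicity", "multiplicity_class_boost"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = {int(k): float(v) for k, v in kwargs[key].items()}
        for key in ("site_residue_count", "site_sas"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = {str(k): tuple(map(float, v)) for k, v in kwargs[key].items()}
        if "class_mixture" in kwargs and kwargs["class_mixture"] is not None:
            kwargs["class_mixture"] = tuple(kwargs["class_mixture"])
        for key in ("sas_offset", "surface_extra_residues"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class SyntheticDataset:
    """Generator output: interchange frames plus the ground-truth record."""

    ddi_frame: pd.DataFrame
    residue_frame: pd.DataFrame
    truth: Dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dio.write_tsv(self.ddi_frame, out / "ddi.tsv")
        dio.write_tsv(self.residue_frame, out / "residues.tsv")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, default=float))


# ---------------------------------------------------------------------------
# composition sampling


def _classify_arrays(p_alpha: np.ndarray, p_gamma: np.ndarray) -> np.ndarray:
    """Vectorised five-class assignment from alpha/gamma fractions."""
    cls = np.full(p_alpha.shape, 5, dtype=int)
    cls[(p_gamma >= 0.30) & (p_gamma < 0.70) & (p_alpha < 0.30)] = 4
    cls[(p_gamma >= 0.30) & (p_gamma < 0.70) & (p_alpha >= 0.30) & (p_alpha < 0.70)] = 3
    cls[(p_gamma >= 0.70) & (p_alpha < 0.70)] = 2
    cls[p_alpha >= 0.70] = 1
    return cls


def _largest_remainder(targets: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Round rows of fractional targets (M,3) to integers summing to totals (M,)."""
    raw = targets * totals[:, None]
    base = np.floor(raw).astype(int)
    need = totals - base.sum(axis=1)
    order = np.argsort(-(raw - base), axis=1, kind="stable")
    rows = np.arange(len(totals))
    for k in range(3):
        mask = need > k
        if not mask.any():
            break
        base[rows[mask], order[mask, k]] += 1
    return base


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray, size: int) -> np.ndarray:
    """Batch Dirichlet draws, guarding against all-zero gamma underflow."""
    draws = rng.gamma(np.broadcast_to(alpha, (size, 3)))
    total = draws.sum(axis=1, keepdims=True)
    bad = (total == 0).ravel()
    while bad.any():
        redraw = rng.gamma(np.broadcast_to(alpha, (int(bad.sum()), 3)))
        draws[bad] = redraw
        total = draws.sum(axis=1, keepdims=True)
        bad = (total == 0).ravel()
    return draws / total


def sample_composition(
    archetype: SSEClass,
    concentration: float,
    rng: np.random.Generator,
    budget: int = 1000,
) -> PropensityTriple:
    """One simplex point near the class archetype that classifies to it.

    Draws from a Dirichlet centred on the class mean composition and rejects
    draws that fall outside the class region.  Raises when the rejection
    budget is exhausted (a larger ``concentration`` tightens the draw around
    the archetype and raises the acceptance rate).
    """
    if concentration <= 0:
        raise InputError("concentration must be > 0")
    alpha = concentration * _normalized(SITE_ARCHETYPES[int(archetype) - 1])
    alpha = np.maximum(alpha, 1e-3)
    for _ in range(budget):
        draw = _dirichlet(rng, alpha, 1)[0]
        triple = PropensityTriple(*(draw / draw.sum()))
        if classify_sse(triple) == archetype:
            return triple
    raise InputError(
        f"rejection budget exhausted sampling class {archetype}; "
        "increase composition_concentration"
    )


def _realize_site_compositions(
    rng: np.random.Generator,
    site_classes: np.ndarray,
    member_sizes: List[np.ndarray],
    concentration: float,
    budget: int,
) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Per-site composition triples and per-member integer SSE counts.

    For each site, a candidate triple is drawn around its class archetype and
    the member interface counts are realised by largest-remainder rounding;
    the candidate is accepted only if the site propensity recomputed from
    those integer counts (mean of member fractions) still classifies to the
    intended class.  This makes the emitted class labels exact ground truth.
    """
    n_sites = len(site_classes)
    triples = np.zeros((n_sites, 3))
    member_counts: List[Optional[np.ndarray]] = [None] * n_sites

    for cls in range(1, 6):
        idx = np.flatnonzero(site_classes == cls)
        if idx.size == 0:
            continue
        alpha = np.maximum(concentration * _normalized(SITE_ARCHETYPES[cls - 1]), 1e-3)
        pending = idx.copy()
        for _ in range(budget):
            if pending.size == 0:
                break
            draws = _dirichlet(rng, alpha, pending.size)
            sizes = [member_sizes[i] for i in pending]
            n_members = np.array([len(s) for s in sizes])
            flat_sizes = np.concatenate(sizes)
            flat_triples = np.repeat(draws, n_members, axis=0)
            counts = _largest_remainder(flat_triples, flat_sizes)
            fractions = counts / flat_sizes[:, None]
            offsets = np.concatenate(([0], np.cumsum(n_members)[:-1]))
            means = np.add.reduceat(fractions, offsets, axis=0) / n_members[:, None]
            realized = _classify_arrays(means[:, 0], means[:, 2])
            accept = realized == cls
            for j, site in enumerate(pending):
                lo = offsets[j]
                hi = lo + n_members[j]
                if accept[j]:
                    triples[site] = draws[j]
                    member_counts[site] = counts[lo:hi]
            pending = pending[~accept]
        if pending.size:
            raise InputError(
                f"rejection budget exhausted for class {cls}; "
                "increase composition_concentration"
            )
    return triples, [np.asarray(c) for c in member_counts]


# ---------------------------------------------------------------------------
# pairing realisation


def _draw_class_pairs(
    rng: np.random.Generator,
    fractions: np.ndarray,
    enrichment: Optional[np.ndarray],
    n_dfis: int,
) -> np.ndarray:
    """(n_dfis, 2) class labels (1..5) drawn iid from the pair distribution."""
    pairs = [(i, j) for i in range(5) for j in range(i, 5)]
    probs = np.array(
        [
            (fractions[i] ** 2 if i == j else 2.0 * fractions[i] * fractions[j])
            * (enrichment[i, j] if enrichment is not None else 1.0)
            for i, j in pairs
        ]
    )
    probs = probs / probs.sum()
    choice = rng.choice(len(pairs), size=n_dfis, p=probs)
    out = np.array([pairs[c] for c in choice], dtype=int) + 1
    # randomise which endpoint is "a" for off-diagonal pairs
    swap = rng.random(n_dfis) < 0.5
    out[swap] = out[swap][:, ::-1]
    return out


def _assign_sites_to_slots(
    rng: np.random.Generator,
    class_pairs: np.ndarray,
    site_classes: np.ndarray,
    site_weights: np.ndarray,
) -> np.ndarray:
    """Fill the (n_dfis, 2) endpoint slots with site indices.

    Within each class every site takes one slot (coverage), and the remaining
    slots are assigned with probability proportional to the site weights (the
    multiplicity skew).  Raises when a class has fewer slots than sites.
    """
    endpoints = np.zeros_like(class_pairs)
    flat_classes = class_pairs.ravel()
    for cls in range(1, 6):
        slot_pos = np.flatnonzero(flat_classes == cls)
        sites = np.flatnonzero(site_classes == cls)
        if slot_pos.size < sites.size:
            raise InputError(
                f"class {cls}: {slot_pos.size} DFI endpoints cannot cover "
                f"{sites.size} sites; increase n_dfis"
            )
        extra = slot_pos.size - sites.size
        if extra:
            w = site_weights[sites].astype(float)
            p = w / w.sum() if w.sum() > 0 else None
            extras = rng.choice(sites, size=extra, p=p, replace=True)
            labels = np.concatenate([sites, extras])
        else:
            labels = sites.copy()
        rng.shuffle(labels)
        endpoints.ravel()[slot_pos] = labels
    return endpoints


def _repair_duplicate_pairs(
    rng: np.random.Generator,
    endpoints: np.ndarray,
    site_classes: np.ndarray,
    max_attempts: int = 200,
) -> np.ndarray:
    """Swap same-class endpoints between DFIs to remove duplicate site pairs.

    Swapping endpoints of the same class preserves both DFIs' class pairs and
    the per-site degree multiset.  Residual duplicates (rare) are left in and
    merge into multi-DDI DFIs downstream.
    """
    def canon(row):
        return (min(row), max(row))

    used: Dict[Tuple[int, int], int] = {}
    dupes: List[int] = []
    for k in range(len(endpoints)):
        key = canon(endpoints[k])
        if key in used:
            dupes.append(k)
        else:
            used[key] = k

    n = len(endpoints)
    for k in dupes:
        fixed = False
        for _ in range(max_attempts):
            other = int(rng.integers(n))
            if other == k:
                continue
            old_o = canon(endpoints[other])
            # only swap with a row registered under its own key: duplicate
            # rows share their key with the first occurrence, and swapping
            # with one would corrupt the bookkeeping
            if used.get(old_o) != other:
                continue
            for col_k in (0, 1):
                for col_o in (0, 1):
                    if site_classes[endpoints[k, col_k]] != site_classes[endpoints[other, col_o]]:
                        continue
                    new_k = endpoints[k].copy()
                    new_o = endpoints[other].copy()
                    new_k[col_k], new_o[col_o] = endpoints[other, col_o], endpoints[k, col_k]
                    key_k, key_o = canon(new_k), canon(new_o)
                    if key_k == key_o:
                        continue
                    taken = set(used) - {old_o}
                    if key_k in taken or key_o in taken:
                        continue
                    del used[old_o]
                    endpoints[k] = new_k
                    endpoints[other] = new_o
                    used[key_k] = k
                    used[key_o] = other
                    fixed = True
                    break
                if fixed:
                    break
            if fixed:
                break
    return endpoints


# ---------------------------------------------------------------------------
# full dataset generation


def _stratum_key(n_partners: int) -> str:
    return str(n_partners) if n_partners <= 3 else ">3"


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> List[str]:
    letters = rng.integers(0, len(_AA), size=(n, length))
    return ["".join(_AA[row]) for row in letters]


def _segment_rows(
    ddi_ids: np.ndarray,
    sides: np.ndarray,
    counts3: np.ndarray,
    offsets: np.ndarray,
    in_interface: int,
    rsa: np.ndarray,
) -> pd.DataFrame:
    """Expand per-member SSE count rows into one residue per row."""
    n = counts3.sum(axis=1)
    total = int(n.sum())
    if total == 0:
        return pd.DataFrame(columns=dio.RESIDUE_COLUMNS)
    ddi_col = np.repeat(ddi_ids, n)
    side_col = np.repeat(sides, n)
    sse_col = np.repeat(np.tile(np.array(["a", "b", "g"]), len(n)), counts3.ravel())
    starts = np.cumsum(n) - n
    index_col = np.arange(total) - np.repeat(starts, n) + np.repeat(offsets, n) + 1
    return pd.DataFrame(
        {
            "ddi_id": ddi_col,
            "side": side_col,
            "residue_index": index_col.astype(int),
            "sse3": sse_col,
            "in_interface": in_interface,
            "rsa": rsa,
        }
    )


def generate_dataset(
    config: Optional[GeneratorConfig] = None, seed: Optional[int] = None
) -> SyntheticDataset:
    """Generate a full synthetic dataset plus ground truth, reproducible by seed."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    if config.n_families <= 0 or config.n_dfis <= 0:
        empty_ddi = pd.DataFrame(columns=dio.DDI_COLUMNS)
        empty_res = pd.DataFrame(columns=dio.RESIDUE_COLUMNS)
        return SyntheticDataset(empty_ddi, empty_res, {"n_sites": 0, "n_dfis": 0, "sites": {}})

    # --- roster -----------------------------------------------------------
    spf_keys = np.array(sorted(config.sites_per_family))
    spf_probs = _normalized([config.sites_per_family[k] for k in spf_keys])
    sites_per_family = rng.choice(spf_keys, size=config.n_families, p=spf_probs)
    family_ids = [f"SF{i + 1:05d}" for i in range(config.n_families)]
    site_family: List[int] = []
    dfbs_ids: List[str] = []
    for fam_idx, n_sites in enumerate(sites_per_family):
        for s in range(int(n_sites)):
            site_family.append(fam_idx)
            dfbs_ids.append(make_dfbs_id(family_ids[fam_idx], s + 1))
    site_family_arr = np.array(site_family)
    n_sites = len(dfbs_ids)

    mixture = np.asarray(config.class_mixture, dtype=float)
    site_classes = rng.choice(np.arange(1, 6), size=n_sites, p=mixture)
    realized_fractions = np.bincount(site_classes, minlength=6)[1:] / n_sites

    # --- DFI realisation ---------------------------------------------------
    enrichment = (
        np.asarray(config.pairing_enrichment, dtype=float)
        if config.pairing_enrichment is not None
        else None
    )
    class_pairs = None
    for _ in range(50):
        candidate = _draw_class_pairs(rng, realized_fractions, enrichment, config.n_dfis)
        counts = np.bincount(candidate.ravel(), minlength=6)[1:]
        roster = np.bincount(site_classes, minlength=6)[1:]
        if np.all(counts >= roster):
            class_pairs = candidate
            break
    if class_pairs is None:
        raise InputError(
            "could not cover every site with a DFI endpoint; "
            "n_dfis is too small for the roster size"
        )

    # multiplicity weights: target partner count per site, boosted per class
    mult_keys = np.array(sorted(config.partner_multiplicity))
    mult_probs = _normalized([config.partner_multiplicity[k] for k in mult_keys])
    target_k = np.zeros(n_sites, dtype=int)
    for i in range(n_sites):
        probs = mult_probs.copy()
        boost = config.multiplicity_class_boost.get(int(site_classes[i]))
        if boost:
            hi = mult_keys > 3
            probs[hi] = probs[hi] * boost
            probs = probs / probs.sum()
        k = int(rng.choice(mult_keys, p=probs))
        if k >= 4:  # heavy tail for highly promiscuous sites
            k = 3 + int(rng.geometric(0.35))
        target_k[i] = k
    site_weights = np.maximum(target_k - 1, 0).astype(float)

    endpoints = _assign_sites_to_slots(rng, class_pairs, site_classes, site_weights)
    endpoints = _repair_duplicate_pairs(rng, endpoints, site_classes)

    # realized distinct DFIs (duplicates merge)
    seen: Dict[Tuple[int, int], int] = {}
    dfi_pairs: List[Tuple[int, int]] = []
    for row in endpoints:
        key = (int(min(row)), int(max(row)))
        if key not in seen:
            seen[key] = 1
            dfi_pairs.append(key)

    # --- DDIs (members per DFI) -------------------------------------------
    ddi_site_a: List[int] = []
    ddi_site_b: List[int] = []
    for a, b in dfi_pairs:
        n_members = 1
        if config.multi_member_prob > 0 and rng.random() < config.multi_member_prob:
            n_members = 2 + int(rng.poisson(config.multi_member_extra_mean))
        for _ in range(n_members):
            ddi_site_a.append(a)
            ddi_site_b.append(b)
    n_ddis = len(ddi_site_a)
    ddi_ids = np.array([f"D{i + 1:06d}" for i in range(n_ddis)])
    site_a_arr = np.array(ddi_site_a)
    site_b_arr = np.array(ddi_site_b)

    # --- per-site bookkeeping ----------------------------------------------
    partner_sets: Dict[int, set] = {i: set() for i in range(n_sites)}
    for a, b in dfi_pairs:
        partner_sets[a].add(site_family[b])
        partner_sets[b].add(site_family[a])
    n_partners = np.array([len(partner_sets[i]) for i in range(n_sites)])

    # member occurrences: (ddi index, side) per site
    occurrences: List[List[Tuple[int, int]]] = [[] for _ in range(n_sites)]
    for d in range(n_ddis):
        occurrences[site_a_arr[d]].append((d, 0))
        occurrences[site_b_arr[d]].append((d, 1))

    member_sizes: List[np.ndarray] = []
    for i in range(n_sites):
        mean, sd = config.site_residue_count[_stratum_key(int(n_partners[i]))]
        sizes = np.clip(np.rint(rng.normal(mean, sd, size=len(occurrences[i]))), 3, 80)
        member_sizes.append(sizes.astype(int))

    triples, member_counts = _realize_site_compositions(
        rng, site_classes, member_sizes,
        config.composition_concentration, config.rejection_budget,
    )

    # latent buried surface per site, by partner stratum
    latent_sas = np.zeros(n_sites)
    for i in range(n_sites):
        mean, sd = config.site_sas[_stratum_key(int(n_partners[i]))]
        latent_sas[i] = max(50.0, rng.normal(mean, sd))

    # --- surface compositions ----------------------------------------------
    surf_mean, surf_sd = config.surface_extra_residues
    surface_triples = np.zeros((n_sites, 3))
    surface_classes = np.zeros(n_sites, dtype=int)
    extra_counts_per_site: List[np.ndarray] = []
    extra_sizes_per_site: List[np.ndarray] = []
    for i in range(n_sites):
        arch_cls = int(site_classes[i])
        if rng.random() >= config.surface_match_prob:
            arch_cls = int(rng.choice(np.arange(1, 6), p=mixture))
        alpha = np.maximum(
            config.composition_concentration * _normalized(SURFACE_ARCHETYPES[arch_cls - 1]),
            1e-3,
        )
        striple = _dirichlet(rng, alpha, 1)[0]
        sizes = np.clip(
            np.rint(rng.normal(surf_mean, surf_sd, size=len(occurrences[i]))), 5, 400
        ).astype(int)
        extras = _largest_remainder(np.tile(striple, (len(sizes), 1)), sizes)
        combined = member_counts[i] + extras
        fractions = combined / combined.sum(axis=1, keepdims=True)
        mean_frac = fractions.mean(axis=0)
        surface_triples[i] = mean_frac
        surface_classes[i] = _classify_arrays(
            np.array([mean_frac[0]]), np.array([mean_frac[2]])
        )[0]
        extra_counts_per_site.append(extras)
        extra_sizes_per_site.append(sizes)

    # --- assemble ddi frame --------------------------------------------------
    u_lo, u_hi = config.sas_offset
    sas_a_unbound = latent_sas[site_a_arr] + rng.uniform(u_lo, u_hi, size=n_ddis)
    sas_b_unbound = latent_sas[site_b_arr] + rng.uniform(u_lo, u_hi, size=n_ddis)
    sas_complex = sas_a_unbound + sas_b_unbound - (latent_sas[site_a_arr] + latent_sas[site_b_arr])
    seqs = _random_sequences(rng, 2 * n_ddis, config.sequence_length)

    ddi_frame = pd.DataFrame(
        {
            "ddi_id": ddi_ids,
            "pdb_id": [f"S{(i % 9999) + 1:04d}" for i in range(n_ddis)],
            "chain_a": "A",
            "family_a": [family_ids[site_family[s]] for s in site_a_arr],
            "dfbs_a": [dfbs_ids[s] for s in site_a_arr],
            "chain_b": "B",
            "family_b": [family_ids[site_family[s]] for s in site_b_arr],
            "dfbs_b": [dfbs_ids[s] for s in site_b_arr],
            "seq_a": seqs[:n_ddis],
            "seq_b": seqs[n_ddis:],
            "sas_a_unbound": np.round(sas_a_unbound, 1),
            "sas_b_unbound": np.round(sas_b_unbound, 1),
            "sas_complex": np.round(sas_complex, 1),
        }
    )

    # --- assemble residue frame ---------------------------------------------
    occ_ddi: List[str] = []
    occ_side: List[str] = []
    occ_iface: List[np.ndarray] = []
    occ_extra: List[np.ndarray] = []
    for i in range(n_sites):
        for j, (d, side) in enumerate(occurrences[i]):
            occ_ddi.append(ddi_ids[d])
            occ_side.append("A" if side == 0 else "B")
            occ_iface.append(member_counts[i][j])
            occ_extra.append(extra_counts_per_site[i][j])
    occ_ddi_arr = np.array(occ_ddi)
    occ_side_arr = np.array(occ_side)
    iface_counts = np.vstack(occ_iface)
    extra_counts = np.vstack(occ_extra)

    n_iface = iface_counts.sum(axis=1)
    n_extra = extra_counts.sum(axis=1)
    frames = [
        _segment_rows(
            occ_ddi_arr, occ_side_arr, iface_counts,
            np.zeros(len(n_iface), dtype=int), 1,
            rng.uniform(0.25, 0.95, size=int(n_iface.sum())),
        ),
        _segment_rows(
            occ_ddi_arr, occ_side_arr, extra_counts, n_iface, 0,
            rng.uniform(config.rsa_threshold, 0.95, size=int(n_extra.sum())),
        ),
    ]
    if config.buried_residues_per_side > 0:
        nb = config.buried_residues_per_side
        buried = np.zeros((len(occ_ddi_arr), 3), dtype=int)
        buried[:, 2] = nb  # irregular labels; excluded by the RSA filter anyway
        frames.append(
            _segment_rows(
                occ_ddi_arr, occ_side_arr, buried, n_iface + n_extra, 0,
                rng.uniform(0.0, max(config.rsa_threshold - 0.001, 0.0), size=nb * len(occ_ddi_arr)),
            )
        )
    residue_frame = pd.concat(frames, ignore_index=True)

    # --- truth ---------------------------------------------------------------
    pair_counts: Dict[str, int] = {}
    for a, b in dfi_pairs:
        ci, cj = sorted((int(site_classes[a]), int(site_classes[b])))
        key = f"{ci}-{cj}"
        pair_counts[key] = pair_counts.get(key, 0) + 1
    strata_counts: Dict[str, int] = {}
    for i in range(n_sites):
        key = _stratum_key(int(n_partners[i]))
        strata_counts[key] = strata_counts.get(key, 0) + 1
    truth = {
        "seed": int(config.seed if seed is None else seed),
        "n_families": config.n_families,
        "n_sites": n_sites,
        "n_dfis_requested": config.n_dfis,
        "n_dfis_realized": len(dfi_pairs),
        "n_ddis": n_ddis,
        "class_mixture": list(config.class_mixture),
        "realized_class_counts": np.bincount(site_classes, minlength=6)[1:].tolist(),
        "pair_counts": pair_counts,
        "partner_multiplicity": strata_counts,
        "sites": {
            dfbs_ids[i]: {
                "family": family_ids[site_family[i]],
                "sse_class": int(site_classes[i]),
                "surface_class": int(surface_classes[i]),
                "n_partners": int(n_partners[i]),
                "latent_sas": float(latent_sas[i]),
            }
            for i in range(n_sites)
        },
    }
    return SyntheticDataset(ddi_frame, residue_frame, truth)


# ---------------------------------------------------------------------------
# worked fixtures


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice(_AA))
    return "".join(out)


def make_worked_fixtures() -> Dict:
    """Deterministic toy datasets for the worked examples and edge tests.

    * ``kunitz``: the trypsin-inhibitor scenario — 11 DDIs of a Kunitz-type
      inhibitor family (PF00197) over 4 binding sites, with 6 near-duplicate
      members, reducing at 60% identity to 5 non-redundant DDIs = 5 DFIs with
      per-site partner counts (2, 1, 1, 1).
    * ``boundary_triples``: compositions on the class contours with their
      expected classes.
    """
    rng = np.random.default_rng(20150409)
    kun = "".join(rng.choice(_AA, size=50))
    try1 = "".join(rng.choice(_AA, size=150))
    try2 = "".join(rng.choice(_AA, size=150))
    pep = "".join(rng.choice(_AA, size=150))
    amy = "".join(rng.choice(_AA, size=150))
    thi = "".join(rng.choice(_AA, size=150))

    def near(seq: str) -> str:
        return _mutate(rng, seq, 0.10)

    def far_kun() -> str:
        return _mutate(rng, kun, 0.10)

    kun5 = far_kun()
    # (ddi_id, kunitz site, partner family, partner dfbs, kun seq, partner seq)
    rows = [
        ("k01", 1, "PF00089", "PF00089:1", kun, try1),
        ("k02", 1, "PF00089", "PF00089:1", kun, near(try1)),
        ("k03", 1, "PF00089", "PF00089:1", kun, near(try1)),
        ("k04", 1, "PF00082", "PF00082:1", far_kun(), pep),
        ("k05", 2, "PF00089", "PF00089:2", kun5, try2),
        ("k06", 2, "PF00089", "PF00089:2", kun5, near(try2)),
        ("k07", 2, "PF00089", "PF00089:2", kun5, near(try2)),
        ("k08", 3, "PF00128", "PF00128:1", (kun8 := far_kun()), amy),
        ("k09", 3, "PF00128", "PF00128:1", kun8, near(amy)),
        ("k10", 4, "PF00085", "PF00085:1", (kun10 := far_kun()), thi),
        ("k11", 4, "PF00085", "PF00085:1", kun10, near(thi)),
    ]

    # per-side interface compositions (alpha, beta, gamma counts): the Kunitz
    # sites are beta/gamma flavoured, partners vary
    kun_iface = {1: (0, 3, 5), 2: (0, 4, 4), 3: (1, 3, 4), 4: (0, 2, 6)}
    partner_iface = {
        "PF00089": (1, 4, 5), "PF00082": (2, 3, 5), "PF00128": (3, 2, 5), "PF00085": (4, 1, 5),
    }
    surface_counts = (10, 10, 10)

    ddi_rows = []
    residue_rows = []
    for ddi_id, site, fam_b, dfbs_b, seq_a, seq_b in rows:
        ddi_rows.append(
            {
                "ddi_id": ddi_id,
                "pdb_id": "1TOY",
                "chain_a": "A",
                "family_a": "PF00197",
                "dfbs_a": f"PF00197:{site}",
                "chain_b": "B",
                "family_b": fam_b,
                "dfbs_b": dfbs_b,
                "seq_a": seq_a,
                "seq_b": seq_b,
                "sas_a_unbound": 2000.0,
                "sas_b_unbound": 2400.0,
                "sas_complex": 3200.0,  # buried per site: 600
            }
        )
        for side, counts in (("A", kun_iface[site]), ("B", partner_iface[fam_b])):
            index = 1
            for sse, n in zip("abg", counts):
                for _ in range(n):
                    residue_rows.append(
                        {
                            "ddi_id": ddi_id, "side": side, "residue_index": index,
                            "sse3": sse, "in_interface": 1, "rsa": 0.5,
                        }
                    )
                    index += 1
            for sse, n in zip("abg", surface_counts):
                for _ in range(n):
                    residue_rows.append(
                        {
                            "ddi_id": ddi_id, "side": side, "residue_index": index,
                            "sse3": sse, "in_interface": 0, "rsa": 0.3,
                        }
                    )
                    index += 1

    boundary_triples = [
        ((0.70, 0.00, 0.30), SSEClass.alpha_rich),
        ((0.30, 0.00, 0.70), SSEClass.gamma_rich),
        ((0.30, 0.40, 0.30), SSEClass.alpha_gamma),
        ((0.2999, 0.4001, 0.30), SSEClass.beta_gamma),
        ((0.30, 0.4001, 0.2999), SSEClass.alpha_beta_gamma),
        ((0.00, 1.00, 0.00), SSEClass.alpha_beta_gamma),
    ]

    return {
        "kunitz": {
            "ddi_frame": pd.DataFrame(ddi_rows, columns=dio.DDI_COLUMNS),
            "residue_frame": pd.DataFrame(residue_rows, columns=dio.RESIDUE_COLUMNS),
            "expected": {
                "n_dfbs": 4,
                "n_nonredundant_ddis": 5,
                "n_dfis": 5,
                "partner_counts": (2, 1, 1, 1),
                "total_partners": 4,
            },
        },
        "boundary_triples": boundary_triples,
    }
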