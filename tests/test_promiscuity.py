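"""Tests for partner-multiplicity analyses at site and domain level."""

import numpy as np
import pytest

from dfikit.core import (
    DFBSProfile,
    InputError,
    PropensityTriple,
    canonical_dfi,
)
from dfikit.classify import classify_sse
from dfikit.promiscuity import (
    STRATA,
    DomainPromiscuity,
    domain_dfbs_histogram,
    domain_promiscuity_summary,
    monogamy_fractions,
    partner_counts,
    partner_families_map,
    promiscuity_scatter,
    sas_by_partner_count,
    stratify_by_partners,
    stratum_of,
)


class TestStratumOf:
    def test_strata(self):
        assert [stratum_of(k) for k in (1, 2, 3, 4, 10)] == ["1", "2", "3", ">3", ">3"]
        assert STRATA == ("1", "2", "3", ">3")

    def test_zero_rejected(self):
        with pytest.raises(InputError):
            stratum_of(0)


class TestPartnerFamilies:
    def test_brute_force_oracle(self, rng):
        """Partner sets match an independent per-endpoint scan of the DFI list."""
        sites = [f"PF{f:02d}:{s}" for f in range(8) for s in (1, 2)]
        dfis = list(
            {
                canonical_dfi(*rng.choice(sites, size=2, replace=True))
                for _ in range(60)
            }
        )
        got = partner_families_map(dfis)

        want = {}
        for dfi in dfis:
            a, b = dfi.endpoints()
            want.setdefault(a, set()).add(b.split(":")[0])
            want.setdefault(b, set()).add(a.split(":")[0])
        assert got == want
        assert partner_counts(dfis) == {k: len(v) for k, v in want.items()}

    def test_same_family_through_two_sites_counts_once(self):
        dfis = [canonical_dfi("PF1:1", "PF2:1"), canonical_dfi("PF1:1", "PF2:2")]
        assert partner_counts(dfis)["PF1:1"] == 1

    def test_self_interaction_counts_own_family(self):
        dfis = [canonical_dfi("PF1:1", "PF1:1")]
        assert partner_families_map(dfis)["PF1:1"] == {"PF1"}

    def test_explicit_family_map(self):
        dfis = [canonical_dfi("siteA", "siteB")]
        families = {"siteA": "F1", "siteB": "F2"}
        assert partner_families_map(dfis, family_of=families)["siteA"] == {"F2"}

    def test_dangling_id_rejected(self):
        dfis = [canonical_dfi("siteA", "siteB")]
        with pytest.raises(InputError):
            partner_families_map(dfis, family_of={"siteA": "F1"})


def _profile(dfbs_id, triple, partners, sas=500.0, residues=10.0):
    return DFBSProfile(
        dfbs_id=dfbs_id,
        family_id=dfbs_id.split(":")[0],
        site_propensity=triple,
        sse_class=classify_sse(triple),
        partner_families=set(partners),
        mean_site_sas=sas,
        mean_site_residues=residues,
    )


ALPHA = PropensityTriple(0.8, 0.1, 0.1)
GAMMA = PropensityTriple(0.1, 0.1, 0.8)


def _roster(rng, n=60):
    profiles = []
    for i in range(n):
        k = int(rng.integers(1, 6))
        triple = ALPHA if i % 2 else GAMMA
        partners = {f"X{j}" for j in range(k)}
        profiles.append(_profile(f"PF{i:03d}:1", triple, partners))
    return profiles


class TestStratifyByPartners:
    def test_rows_sum_to_100(self, rng):
        result = stratify_by_partners(_roster(rng))
        class_cols = result.table.columns.drop("n_dfbs")
        for _, row in result.table.iterrows():
            assert row[class_cols].sum() == pytest.approx(100.0)

    def test_any_row_is_global(self, rng):
        profiles = _roster(rng)
        result = stratify_by_partners(profiles)
        assert result.table.loc["any", "n_dfbs"] == len(profiles)

    def test_stratum_sizes_partition_roster(self, rng):
        profiles = _roster(rng)
        result = stratify_by_partners(profiles)
        strata_n = result.table.drop(index="any")["n_dfbs"]
        assert int(strata_n.sum()) == len(profiles)

    def test_unclassified_rejected(self, rng):
        p = _profile("PF1:1", ALPHA, {"X"})
        p.sse_class = None
        with pytest.raises(InputError):
            stratify_by_partners([p])

    def test_missing_partners_rejected(self):
        p = _profile("PF1:1", ALPHA, set())
        with pytest.raises(InputError):
            stratify_by_partners([p])

    def test_empty_stratum_warns(self):
        profiles = [_profile(f"PF{i}:1", ALPHA, {"X"}) for i in range(5)]
        with pytest.warns(UserWarning, match="empty"):
            result = stratify_by_partners(profiles)
        assert "2" not in result.table.index


class TestSasByPartnerCount:
    def test_brute_force_means(self, rng):
        profiles = []
        for i in range(30):
            k = int(rng.integers(1, 6))
            profiles.append(
                _profile(
                    f"PF{i:03d}:1", ALPHA, {f"X{j}" for j in range(k)},
                    sas=float(rng.uniform(200, 900)),
                    residues=float(rng.integers(4, 25)),
                )
            )
        table = sas_by_partner_count(profiles)
        for stratum in table.index:
            subset = [p for p in profiles if stratum_of(len(p.partner_families)) == stratum]
            sas = np.array([p.mean_site_sas for p in subset])
            assert table.loc[stratum, "n_dfbs"] == len(subset)
            assert table.loc[stratum, "mean_sas"] == pytest.approx(sas.mean())
            assert table.loc[stratum, "sd_sas"] == pytest.approx(sas.std(ddof=1))

    def test_detects_simulated_sas_gap(self, rng):
        """Multi-partner sites drawn with smaller surfaces must test smaller."""
        profiles = []
        for i in range(200):
            profiles.append(
                _profile(f"PFA{i:03d}:1", ALPHA, {"X"}, sas=float(rng.normal(680, 60)))
            )
        for i in range(200):
            profiles.append(
                _profile(
                    f"PFB{i:03d}:1", ALPHA, {"X", "Y"}, sas=float(rng.normal(560, 60))
                )
            )
        table = sas_by_partner_count(profiles)
        assert table.loc["2", "mean_sas"] < table.loc["1", "mean_sas"]
        assert table.loc["2", "z_sas"] < 0
        assert table.loc["2", "p_sas"] < 0.01

    def test_singleton_stratum_has_nan_sd(self):
        profiles = [
            _profile("PF1:1", ALPHA, {"X"}, sas=100.0),
            _profile("PF2:1", ALPHA, {"X"}, sas=200.0),
            _profile("PF3:1", ALPHA, {"X", "Y"}, sas=150.0),
        ]
        table = sas_by_partner_count(profiles)
        assert np.isnan(table.loc["2", "sd_sas"])


class TestDomainHistogramAndMonogamy:
    def _profiles(self):
        return [
            _profile("PF1:1", ALPHA, {"A"}),
            _profile("PF2:1", ALPHA, {"A", "B"}),
            _profile("PF3:1", ALPHA, {"A"}),
            _profile("PF3:2", ALPHA, {"B"}),
            _profile("PF3:3", ALPHA, {"C"}),
        ]

    def test_histogram(self):
        hist = domain_dfbs_histogram(self._profiles())
        assert hist.loc[1, "n_domains"] == 2
        assert hist.loc[3, "n_domains"] == 1
        assert hist["n_domains"].sum() == 3
        assert hist["pct_domains"].sum() == pytest.approx(100.0)

    def test_monogamy_fractions(self):
        mono = monogamy_fractions(self._profiles())
        assert mono["n_domains"] == 3
        assert mono["n_single_site_domains"] == 2
        assert mono["pct_single_site_domains"] == pytest.approx(200 / 3)
        # of the two single-site domains, PF1 has one partner, PF2 has two
        assert mono["pct_single_partner_among_single_site"] == pytest.approx(50.0)


class TestDomainPromiscuity:
    def test_invariant_enforced(self):
        with pytest.raises(InputError, match="invariant"):
            DomainPromiscuity(
                family_id="PF1", n_dfbs=2, per_site_partners=(2, 1),
                total_partners=5, max_partners=2,
            )

    def test_summary_kunitz_partner_counts(self, kunitz):
        """The worked 4-site domain binds (2,1,1,1) partners, 4 in total."""
        from dfikit.io import records_from_frames
        from dfikit.pipeline import attach_partners, build_profiles, dfis_from_frame
        from dfikit.redundancy import filter_ddis
        from dfikit.io import frames_from_records

        records = records_from_frames(kunitz["ddi_frame"])
        kept = filter_ddis(records, 0.99, 0.60)
        ddi_frame, _ = frames_from_records(kept)
        residue_frame = kunitz["residue_frame"]
        residue_frame = residue_frame[
            residue_frame["ddi_id"].isin(ddi_frame["ddi_id"])
        ]
        profiles = build_profiles(ddi_frame, residue_frame)
        dfis, _ = dfis_from_frame(ddi_frame)
        attach_partners(profiles, dfis)
        summary = domain_promiscuity_summary(profiles)
        domain = next(d for d in summary if d.family_id == "PF00197")
        expected = kunitz["expected"]
        assert domain.n_dfbs == expected["n_dfbs"]
        assert domain.per_site_partners == tuple(
            sorted(expected["partner_counts"], reverse=True)
        )
        assert domain.total_partners == expected["total_partners"]

    def test_exclude_and_top_n(self, rng):
        profiles = _roster(rng, 20)
        full = domain_promiscuity_summary(profiles)
        excluded = domain_promiscuity_summary(profiles, exclude={full[0].family_id})
        assert full[0].family_id not in {d.family_id for d in excluded}
        assert len(domain_promiscuity_summary(profiles, top_n=5)) == 5

    def test_sorted_most_sites_first(self, rng):
        profiles = _roster(rng, 30) + [
            _profile("PFBIG:1", ALPHA, {"A"}),
            _profile("PFBIG:2", ALPHA, {"B"}),
            _profile("PFBIG:3", ALPHA, {"C"}),
            _profile("PFBIG:4", ALPHA, {"D"}),
        ]
        summary = domain_promiscuity_summary(profiles)
        assert summary[0].family_id == "PFBIG"
        sites = [d.n_dfbs for d in summary]
        assert sites == sorted(sites, reverse=True)

    def test_scatter_frame(self, rng):
        summary = domain_promiscuity_summary(_roster(rng, 10))
        frame = promiscuity_scatter(summary)
        assert list(frame.columns) == ["family_id", "total_partners", "max_partners_per_dfbs"]
        assert (frame["max_partners_per_dfbs"] <= frame["total_partners"]).all()
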