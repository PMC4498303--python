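"""Tests for the random-pairing expectation model.

The reference scenario uses the published five-class census of 4001 binding
sites (835, 996, 1117, 784, 269) and 3084 family-family interactions; the
printed expectation arithmetic (probabilities such as 4.4% and 10.4%, counts
such as 191 and 240) must come out of the model exactly.
"""

import math

import numpy as np
import pytest
from scipy import stats

from dfikit.core import InputError, SSEClass
from dfikit.pairing import (
    RandomPairingModel,
    chi_square_global,
    count_class_pairs,
    expected_pair_counts,
    expected_pair_probabilities,
    pair_z_tests,
    unordered_class_pairs,
)
from dfikit.core import canonical_dfi
from dfikit.report import round_half_up

C1, C2, C3, C4, C5 = list(SSEClass)

REFERENCE_CLASS_COUNTS = {C1: 835, C2: 996, C3: 1117, C4: 784, C5: 269}
REFERENCE_N_SITES = 4001
REFERENCE_N_DFI = 3084


def reference_fractions():
    return [REFERENCE_CLASS_COUNTS[c] / REFERENCE_N_SITES for c in SSEClass]


class TestUnorderedClassPairs:
    def test_fifteen_cells(self):
        pairs = unordered_class_pairs()
        assert len(pairs) == 15
        assert len(set(pairs)) == 15
        assert all(i <= j for i, j in pairs)


class TestExpectedPairProbabilities:
    def test_sum_to_one_reference(self):
        probs = expected_pair_probabilities(reference_fractions())
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_sum_to_one_random(self, rng):
        for _ in range(20):
            f = rng.dirichlet(np.ones(5))
            probs = expected_pair_probabilities(list(f))
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_diagonal_and_off_diagonal_formulas(self):
        f = [0.1, 0.2, 0.3, 0.25, 0.15]
        probs = expected_pair_probabilities(f)
        assert probs[(C1, C1)] == pytest.approx(0.01)
        assert probs[(C1, C2)] == pytest.approx(2 * 0.1 * 0.2)

    def test_printed_percentages(self):
        """20.9% alpha-rich sites -> 4.4% alpha/alpha pairs; with 24.9%
        gamma-rich sites -> 10.4% alpha/gamma pairs (one-decimal rendering)."""
        probs = expected_pair_probabilities(reference_fractions())
        assert round_half_up(100 * probs[(C1, C1)]) == 4.4
        assert round_half_up(100 * probs[(C1, C2)]) == 10.4

    def test_unnormalized_rejected(self):
        with pytest.raises(InputError):
            expected_pair_probabilities([0.3, 0.3, 0.3, 0.3, 0.3])

    def test_wrong_length_rejected(self):
        with pytest.raises(InputError):
            expected_pair_probabilities([0.5, 0.5])


class TestExpectedPairCounts:
    def test_printed_expected_counts(self):
        probs = expected_pair_probabilities(reference_fractions())
        expected = expected_pair_counts(probs, REFERENCE_N_DFI)
        # every published cell where the printed value matches the
        # exact-fraction recipe (all but the alpha-rich diagonal, whose
        # printed 124 disagrees with the formula's 134)
        printed = {
            (C1, C2): 320, (C1, C3): 359, (C1, C4): 252, (C1, C5): 87,
            (C2, C2): 191, (C2, C3): 429, (C2, C4): 301, (C2, C5): 103,
            (C3, C3): 240, (C3, C4): 337, (C3, C5): 116,
            (C4, C4): 118, (C4, C5): 81,
            (C5, C5): 14,
        }
        for pair, want in printed.items():
            assert round_half_up(expected[pair], 0) == want, pair

    def test_counts_scale_with_n(self):
        probs = expected_pair_probabilities(reference_fractions())
        e1 = expected_pair_counts(probs, 100)
        e2 = expected_pair_counts(probs, 200)
        for pair in e1:
            assert e2[pair] == pytest.approx(2 * e1[pair])

    def test_nonpositive_n_rejected(self):
        probs = expected_pair_probabilities(reference_fractions())
        with pytest.raises(InputError):
            expected_pair_counts(probs, 0)


class TestCountClassPairs:
    def test_brute_force_tally(self, rng):
        """Counting matches an independent dict-of-sorted-tuples tally."""
        classes = {f"PF{i}:1": SSEClass(int(rng.integers(1, 6))) for i in range(40)}
        ids = list(classes)
        dfis = []
        for _ in range(300):
            a, b = rng.choice(ids, size=2, replace=True)
            dfis.append(canonical_dfi(a, b))
        got = count_class_pairs(dfis, classes)

        want = {}
        for dfi in dfis:
            key = tuple(sorted((classes[dfi.endpoint_a], classes[dfi.endpoint_b])))
            want[key] = want.get(key, 0) + 1
        for pair, count in got.items():
            assert count == want.get(pair, 0)
        assert sum(got.values()) == len(dfis)

    def test_unclassified_endpoint_names_dfi(self):
        dfis = [canonical_dfi("PF1:1", "PF2:1")]
        with pytest.raises(InputError, match="PF2:1"):
            count_class_pairs(dfis, {"PF1:1": C1})


class TestChiSquare:
    def test_zero_when_observed_equals_expected(self):
        probs = expected_pair_probabilities(reference_fractions())
        expected = expected_pair_counts(probs, REFERENCE_N_DFI)
        observed = {pair: expected[pair] for pair in expected}
        chi2, df, p = chi_square_global(observed, expected)
        assert chi2 == 0.0
        assert df == 14
        assert p == pytest.approx(1.0)

    def test_matches_scipy_oracle(self, rng):
        probs = expected_pair_probabilities(reference_fractions())
        expected = expected_pair_counts(probs, REFERENCE_N_DFI)
        observed = {
            pair: max(0, int(round(e + rng.normal(0, math.sqrt(e)))))
            for pair, e in expected.items()
        }
        # renormalise to same total so scipy's chisquare applies directly
        obs = np.array([observed[p] for p in unordered_class_pairs()], dtype=float)
        exp = np.array([expected[p] for p in unordered_class_pairs()], dtype=float)
        exp = exp * obs.sum() / exp.sum()
        want_chi2, want_p = stats.chisquare(obs, exp)
        scaled_expected = dict(zip(unordered_class_pairs(), exp))
        chi2, df, p = chi_square_global(observed, scaled_expected)
        assert chi2 == pytest.approx(float(want_chi2))
        assert p == pytest.approx(float(want_p))

    def test_zero_expected_with_observations_rejected(self):
        pairs = unordered_class_pairs()
        expected = {pair: 0.0 for pair in pairs}
        expected[pairs[0]] = 10.0
        observed = {pair: 1 for pair in pairs}
        with pytest.raises(InputError):
            chi_square_global(observed, expected)

    def test_zero_expected_empty_cells_dropped(self):
        pairs = unordered_class_pairs()
        expected = {pair: 0.0 for pair in pairs}
        observed = {pair: 0 for pair in pairs}
        expected[pairs[0]] = 10.0
        expected[pairs[1]] = 10.0
        observed[pairs[0]] = 12
        observed[pairs[1]] = 8
        chi2, df, p = chi_square_global(observed, expected)
        assert df == 1
        assert chi2 == pytest.approx((2 ** 2) / 10 + (2 ** 2) / 10)


class TestPairZTests:
    def test_zero_z_at_expectation(self):
        probs = expected_pair_probabilities(reference_fractions())
        observed = {pair: probs[pair] * REFERENCE_N_DFI for pair in probs}
        results = pair_z_tests(observed, probs, REFERENCE_N_DFI)
        for z, pval, flag in results.values():
            assert z == pytest.approx(0.0, abs=1e-12)
            assert pval == pytest.approx(1.0)
            assert flag == "ns"

    def test_exact_binomial_oracle_agreement(self, rng):
        """z-test decisions agree with the exact binomial for clear cases."""
        probs = expected_pair_probabilities(reference_fractions())
        n = REFERENCE_N_DFI
        observed = {pair: int(round(probs[pair] * n)) for pair in probs}
        # push one cell far above expectation
        bumped = (C1, C1)
        observed[bumped] = int(round(probs[bumped] * n * 2))
        results = pair_z_tests(observed, probs, n, alpha=0.001)
        z, pval, flag = results[bumped]
        assert flag == "enriched"
        p_exact = stats.binomtest(observed[bumped], n, probs[bumped]).pvalue
        assert p_exact < 0.001
        # z and exact binomial p agree in order of magnitude for moderate cells
        assert pval < 0.001

    def test_z_formula_oracle(self):
        probs = expected_pair_probabilities(reference_fractions())
        n = REFERENCE_N_DFI
        pairs = unordered_class_pairs()
        observed = {pair: 10 for pair in pairs}
        results = pair_z_tests(observed, probs, n)
        for pair in pairs:
            p_k = probs[pair]
            want = (10 - n * p_k) / math.sqrt(n * p_k * (1 - p_k))
            assert results[pair][0] == pytest.approx(want)


class TestRandomPairingModel:
    def test_published_scenario_flags(self):
        """Observed counts from the reference census: alpha/alpha is observed
        at 227 (7.4%) vs expected 134 (4.4%) and must flag as enriched."""
        class_of = {}
        idx = 0
        for cls, count in REFERENCE_CLASS_COUNTS.items():
            for _ in range(count):
                class_of[f"PF{idx}:1"] = cls
                idx += 1
        observed_counts = {
            (C1, C1): 227, (C1, C2): 177, (C1, C3): 334, (C1, C4): 137, (C1, C5): 40,
            (C2, C2): 251, (C2, C3): 327, (C2, C4): 356, (C2, C5): 84,
            (C3, C3): 333, (C3, C4): 72, (C3, C5): 307,
            (C4, C4): 312, (C4, C5): 97,
            (C5, C5): 30,
        }
        # build synthetic DFIs realising those counts using sites of each class
        by_class = {}
        for dfbs_id, cls in class_of.items():
            by_class.setdefault(cls, []).append(dfbs_id)
        dfis = []
        used = {cls: 0 for cls in SSEClass}
        for (ci, cj), count in observed_counts.items():
            for _ in range(count):
                a = by_class[ci][used[ci] % len(by_class[ci])]
                used[ci] += 1
                b = by_class[cj][used[cj] % len(by_class[cj])]
                used[cj] += 1
                if a == b:
                    b = by_class[cj][(used[cj] + 1) % len(by_class[cj])]
                dfis.append(canonical_dfi(a, b))

        model = RandomPairingModel(dfis, class_of)
        results = model.fit(alpha=0.001)
        table = results.pair_table.set_index(["class_i", "class_j"])
        cell = table.loc[("alpha-rich", "alpha-rich")]
        assert round_half_up(cell["observed_pct"]) == 7.4
        assert round_half_up(100 * cell["expected_prob"]) == 4.4
        assert cell["flag"] == "enriched"
        # all five diagonal cells are enriched; alpha+gamma x beta+gamma
        # (72 observed vs 337 expected) is the most depleted cell
        for label in ("gamma-rich", "alpha+gamma", "beta+gamma", "alpha+beta+gamma"):
            assert table.loc[(label, label), "flag"] == "enriched"
        assert table.loc[("alpha+gamma", "beta+gamma"), "flag"] == "depleted"
        # exactly three published pairs show no significant preference
        ns_cells = set(
            results.pair_table.loc[results.pair_table["flag"] == "ns",
                                   ["class_i", "class_j"]].itertuples(index=False, name=None)
        )
        assert ns_cells == {
            ("alpha-rich", "alpha+gamma"),
            ("gamma-rich", "alpha+beta+gamma"),
            ("beta+gamma", "alpha+beta+gamma"),
        }
        assert results.chi2 > stats.chi2.isf(0.001, 14)

    def test_empty_dfis_rejected(self):
        with pytest.raises(InputError):
            RandomPairingModel([], {"PF1:1": C1})

    def test_explicit_fractions_override(self):
        dfis = [canonical_dfi("PF1:1", "PF2:1")]
        class_of = {"PF1:1": C1, "PF2:1": C2}
        model = RandomPairingModel(dfis, class_of, class_fractions=reference_fractions())
        assert model.class_fractions == pytest.approx(reference_fractions())

    def test_summary_contains_layout(self, small_dataset):
        from dfikit.pipeline import build_profiles, dfis_from_frame

        profiles = build_profiles(small_dataset.ddi_frame, small_dataset.residue_frame)
        dfis, _ = dfis_from_frame(small_dataset.ddi_frame)
        results = RandomPairingModel.from_profiles(dfis, profiles).fit()
        text = results.summary()
        assert "chi2" in text
        assert "(" in text  # observed (expected) cells
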