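"""Random-pairing expectation model for SSE class pairs of DFIs.

Under the null hypothesis that binding sites pair independently of their SSE
class, the probability of an unordered class pair (i, j) is f_i^2 on the
diagonal and 2 f_i f_j off it, where f are the DFBS class fractions.  The
model compares observed DFI counts over the 15 unordered pairs with those
expectations via a global chi-square goodness-of-fit test (df = 14) and
per-pair one-proportion z-tests with enrichment/depletion flags.

The API follows the fitted-model idiom: build a :class:`RandomPairingModel`
from data, call :meth:`~RandomPairingModel.fit`, and read the estimates,
tests and :meth:`~PairingResults.summary` table off the results object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import CLASS_LABELS, DFBSProfile, DFI, InputError, SSEClass

PairKey = Tuple[SSEClass, SSEClass]

_CLASSES = list(SSEClass)


def unordered_class_pairs() -> List[PairKey]:
    """The 15 unordered pairs (i, j) with i <= j over the five classes."""
    return [(ci, cj) for idx, ci in enumerate(_CLASSES) for cj in _CLASSES[idx:]]


def _canonical_pair(ci: SSEClass, cj: SSEClass) -> PairKey:
    return (ci, cj) if ci <= cj else (cj, ci)


def count_class_pairs(
    dfis: Iterable[DFI], class_of: Mapping[str, SSEClass]
) -> Dict[PairKey, int]:
    """Tally DFIs into the 15 unordered class-pair cells.

    Each DFI increments exactly one cell, so the cell counts sum to the
    number of DFIs.  An endpoint missing from ``class_of`` raises an
    :class:`InputError` naming the offending DFI.
    """
    counts: Dict[PairKey, int] = {pair: 0 for pair in unordered_class_pairs()}
    for dfi in dfis:
        try:
            ca = class_of[dfi.endpoint_a]
            cb = class_of[dfi.endpoint_b]
        except KeyError as exc:
            raise InputError(
                f"DFI ({dfi.endpoint_a}, {dfi.endpoint_b}) has an unclassified endpoint {exc}"
            ) from exc
        counts[_canonical_pair(ca, cb)] += 1
    return counts


def expected_pair_probabilities(class_fractions: Sequence[float]) -> Dict[PairKey, float]:
    """Random-pairing probability of each unordered class pair.

    Diagonal pairs get f_i^2; off-diagonal pairs get 2 f_i f_j (the product
    doubles because either endpoint order realises the same unordered pair).
    The 15 probabilities sum to 1 exactly when the fractions do.
    """
    if len(class_fractions) != len(_CLASSES):
        raise InputError(f"expected {len(_CLASSES)} class fractions")
    total = float(sum(class_fractions))
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise InputError(f"class fractions sum to {total}, not 1 within 1e-9")
    f = {c: float(class_fractions[i]) for i, c in enumerate(_CLASSES)}
    probs: Dict[PairKey, float] = {}
    for ci, cj in unordered_class_pairs():
        probs[(ci, cj)] = f[ci] ** 2 if ci == cj else 2.0 * f[ci] * f[cj]
    return probs


def expected_pair_counts(
    probabilities: Mapping[PairKey, float], n_dfi: int
) -> Dict[PairKey, float]:
    """Expected DFI count per pair under random pairing (unrounded)."""
    if n_dfi <= 0:
        raise InputError("n_dfi must be > 0")
    return {pair: p * n_dfi for pair, p in probabilities.items()}


def chi_square_global(
    observed: Mapping[PairKey, int], expected: Mapping[PairKey, float]
) -> Tuple[float, int, float]:
    """Global goodness-of-fit test over the 15 class-pair cells.

    chi2 = sum (O - E)^2 / E with df = 14 when all 15 cells carry positive
    expectation; the p-value comes from the chi-square distribution.  Cells
    with expected count 0 are dropped when their observed count is also 0
    (they carry no information and arise when a class is absent from the
    roster) and reduce the degrees of freedom; an observed count in a
    zero-expectation cell is an error.  Cells with expected < 5 trigger a
    warning (the approximation weakens there).
    """
    pairs = unordered_class_pairs()
    exp = np.array([expected[p] for p in pairs], dtype=float)
    obs = np.array([observed[p] for p in pairs], dtype=float)
    if np.any((exp <= 0) & (obs > 0)):
        raise InputError("observed count in a cell with zero expected count")
    keep = exp > 0
    if not np.any(keep):
        raise InputError("all expected counts are zero")
    exp, obs = exp[keep], obs[keep]
    if np.any(exp < 5):
        warnings.warn("some expected counts are below 5; chi-square approximation is weak")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = max(int(keep.sum()) - 1, 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def pair_z_tests(
    observed: Mapping[PairKey, int],
    probabilities: Mapping[PairKey, float],
    n_dfi: int,
    alpha: float = 0.001,
) -> Dict[PairKey, Tuple[float, float, str]]:
    """One-proportion z-test per class pair against the random expectation.

    z = (O - n p) / sqrt(n p (1 - p)), two-sided p-value; the flag is
    ``enriched``/``depleted`` when significant at ``alpha`` and ``ns``
    otherwise.  Cells with degenerate probability (0 or 1) have zero variance:
    when the observed count matches the deterministic expectation exactly the
    cell is reported as ``ns`` with NaN z and p; otherwise an
    :class:`InputError` is raised.  Cells where n p or n (1 - p) fall below 5
    produce a warning.
    """
    results: Dict[PairKey, Tuple[float, float, str]] = {}
    for pair in unordered_class_pairs():
        p_k = probabilities[pair]
        if p_k <= 0.0 or p_k >= 1.0:
            if observed[pair] != round(n_dfi * p_k):
                raise InputError(
                    f"observed count {observed[pair]} inconsistent with "
                    f"degenerate pair probability {p_k} for {pair}"
                )
            results[pair] = (float("nan"), float("nan"), "ns")
            continue
        if n_dfi * p_k < 5 or n_dfi * (1 - p_k) < 5:
            warnings.warn(f"normal approximation weak for pair {pair} (n p < 5)")
        se = math.sqrt(n_dfi * p_k * (1.0 - p_k))
        z = (observed[pair] - n_dfi * p_k) / se
        pval = 2.0 * float(stats.norm.sf(abs(z)))
        if pval < alpha:
            flag = "enriched" if z > 0 else "depleted"
        else:
            flag = "ns"
        results[pair] = (z, pval, flag)
    return results


class RandomPairingModel:
    """Random-pairing null model for the class-pair composition of a DFI set.

    Parameters
    ----------
    dfis:
        The DFIs to analyse.
    class_of:
        Mapping from every DFBS ID in the roster to its SSE class.  The
        expectation model uses the class fractions of this roster (all
        classified binding sites), not the DFI-endpoint fractions.
    class_fractions:
        Optional explicit class fractions (5 values summing to 1) overriding
        the roster-derived ones — useful for worked examples with published
        class counts.
    """

    def __init__(
        self,
        dfis: Sequence[DFI],
        class_of: Mapping[str, SSEClass],
        class_fractions: Optional[Sequence[float]] = None,
    ) -> None:
        if not dfis:
            raise InputError("cannot model an empty DFI set")
        self.dfis = list(dfis)
        self.class_of = dict(class_of)
        if class_fractions is None:
            n = len(self.class_of)
            if n == 0:
                raise InputError("class_of mapping is empty")
            counts = {c: 0 for c in _CLASSES}
            for cls in self.class_of.values():
                counts[cls] += 1
            class_fractions = [counts[c] / n for c in _CLASSES]
        self.class_fractions = [float(x) for x in class_fractions]

    @classmethod
    def from_profiles(
        cls, dfis: Sequence[DFI], profiles: Sequence[DFBSProfile]
    ) -> "RandomPairingModel":
        return cls(dfis, {p.dfbs_id: p.sse_class for p in profiles if p.sse_class is not None})

    def fit(self, alpha: float = 0.001) -> "PairingResults":
        """Count the observed pairs, compute expectations and run the tests."""
        observed = count_class_pairs(self.dfis, self.class_of)
        n_dfi = len(self.dfis)
        probs = expected_pair_probabilities(self.class_fractions)
        expected = expected_pair_counts(probs, n_dfi)
        chi2, df, p_global = chi_square_global(observed, expected)
        ztests = pair_z_tests(observed, probs, n_dfi, alpha=alpha)

        rows = []
        for ci, cj in unordered_class_pairs():
            pair = (ci, cj)
            z, pval, flag = ztests[pair]
            rows.append(
                {
                    "class_i": CLASS_LABELS[ci],
                    "class_j": CLASS_LABELS[cj],
                    "observed": observed[pair],
                    "observed_pct": 100.0 * observed[pair] / n_dfi,
                    "expected_prob": probs[pair],
                    "expected_count": expected[pair],
                    "z": z,
                    "p": pval,
                    "flag": flag,
                }
            )
        table = pd.DataFrame(rows)
        return PairingResults(
            model=self,
            n_dfi=n_dfi,
            pair_table=table,
            chi2=chi2,
            df=df,
            pvalue=p_global,
            alpha=alpha,
        )


@dataclass
class PairingResults:
    """Fitted random-pairing comparison: per-pair table plus the global test."""

    model: RandomPairingModel
    n_dfi: int
    pair_table: pd.DataFrame
    chi2: float
    df: int
    pvalue: float
    alpha: float

    @property
    def observed(self) -> Dict[PairKey, int]:
        return count_class_pairs(self.model.dfis, self.model.class_of)

    def summary(self) -> str:
        """Human-readable report mirroring the observed-(expected) table layout."""
        from .report import render_pairing_table

        lines = [
            "Random-pairing expectation model",
            f"  DFIs: {self.n_dfi}    class-pair cells: {len(self.pair_table)}",
            f"  global chi2 = {self.chi2:.1f}  (df = {self.df}),  p = {self.pvalue:.3g}",
            f"  per-pair z-tests at alpha = {self.alpha}",
            "",
            render_pairing_table(self.pair_table),
        ]
        return "\n".join(lines)
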