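# Methods

This note documents the statistical model, the parameter defaults and their
rationale, the synthetic generator's scope, and known limitations.

## Secondary-structure alphabet

DSSP's 8 states are collapsed to 3: α = {H, G, I}, β = {E, B}, γ = {T, S,
blank}. The modern DSSP code `P` (polyproline II helix) post-dates the
8-state convention; it is mapped to γ with a warning by default (strict mode
raises), since κ-helices are neither α-helical nor strand-like.

Relative solvent accessibility (RSA) is the DSSP absolute accessibility
divided by the residue's theoretical maximum ASA (Tien et al. 2013,
"theoretical" column), capped at 1. Lower-case DSSP amino-acid codes
(SS-bonded cysteines) are treated as Cys. Residues with RSA ≥ 0.05 count as
surface residues; the threshold is configurable because no universal
criterion exists, and 0.05 is a common "not fully buried" convention.

Interface residues are detected by a heavy-atom distance cutoff between
chains (hydrogens/deuteriums excluded). Interface residues always count
toward the site propensity regardless of RSA.

## Propensities (site and surface)

For one binding site with *m* member DDIs, the site propensity is the
**unweighted mean of the per-member residue fractions**:

p_x = (1/m) Σ_k n_x,k / n_k,  x ∈ {α, β, γ}

and analogously for the whole domain surface. Averaging fractions (rather
than pooling counts) weights each member interaction equally, so one large
member cannot dominate the site's profile. The three components sum to 1 to
within 1e-9 by construction.

## Five-class ternary partition

Each propensity triple is a point on the 2-simplex and falls in exactly one
class:

1. **α-rich**: p_α ≥ 0.70
2. **γ-rich**: else p_γ ≥ 0.70
3. **α+γ**: else 0.30 ≤ p_γ < 0.70 and p_α ≥ 0.30
4. **β+γ**: else 0.30 ≤ p_γ < 0.70 (and p_α < 0.30)
5. **α+β+γ**: everything else (includes pure-β compositions)

The rules are evaluated in order, so the partition is complete and disjoint;
the test suite verifies this on the full 1%-step simplex grid (5151 points).
Boundary membership: the 70% contours belong to classes 1–2, the γ ∈ [30%,
70%) band to classes 3–4.

## Random-pairing expectation model

Let f_i be the fraction of classified binding sites in class i (over the
whole roster, not over DFI endpoints). Under random pairing, an unordered
class pair (i, j) has probability f_i² on the diagonal and 2 f_i f_j off the
diagonal; these 15 probabilities sum to 1. Expected counts are n·p for n
DFIs.

The global test is Pearson's χ² over the 15 cells with df = 14. Cells with
zero expected **and** zero observed count are dropped (df reduced
accordingly, minimum 1); a zero-expected cell with observations is an input
error. Per-cell tests use the normal approximation to the binomial,
z = (O − np) / √(np(1−p)), two-sided, flagged enriched/depleted at
α = 0.001 by default (matching the convention of reporting only very strong
cells); a warning is emitted when np < 5. Degenerate cells with p ∈ {0, 1}
are reported as `ns` with NaN statistics when the observation matches the
deterministic expectation.

## Redundancy filtering

Sequence identity is computed by Needleman–Wunsch global alignment
(match 2, mismatch −1, gap open −2, gap extend −0.5) as identical columns
over alignment length, with a length-ratio prescreen. Selection is greedy
longest-first (ties broken by entry ID), so the kept set is deterministic
and every removed entry is within the threshold of some kept entry.

Two stages: (1) near-duplicate removal at 99% identity over the concatenated
pair sequence of each DDI; (2) 60% identity within each binding site's
member group, a DDI being retained only if retained in every group it
belongs to. The published protocol does not state which sequence the
per-site filter compares; using the concatenated pair sequence keeps both
stages on the same footing.

## Promiscuity

A site's promiscuity is its number of distinct partner families (a family
partnering through several of its own sites counts once). Strata are 1, 2,
3 and >3 partners. Per-stratum class composition is compared with the global
composition (χ², df 4, plus per-class z-tests); buried interface area
(SAS_A + SAS_B − SAS_complex)/2 and interface residue counts are compared
across strata by two-sample z-tests against the single-partner stratum.

## Synthetic generator

The generator produces desk-scale datasets with known ground truth:

- a roster of families with a configurable sites-per-family distribution and
  class mixture (defaults mirror the study scale: 2153 families, ≈4000
  sites, 53.2% single-site domains);
- per-site SSE compositions drawn from class-archetype Dirichlet
  distributions, rejection-sampled until the realized integer residue counts
  still classify to the intended class — generated labels are therefore
  exact ground truth;
- DFI class pairs drawn iid from the random-pairing product distribution
  (optionally multiplied by a symmetric 5×5 enrichment matrix and
  renormalized), then mapped to concrete sites within class. Duplicate site
  pairs are repaired by class-preserving endpoint swaps; residual duplicates
  merge into multi-DDI DFIs downstream;
- latent site SAS and residue counts per partner stratum, plus optional
  multi-member DDIs per DFI.

Because the null construction uses the same product-form expectation as the
analysis, the 5% calibration of the global χ² test on null data is a
property of the construction, not a tuned outcome.

**Scope and limits.** Generated sequences are random strings (non-redundant
by construction), so the redundancy filter is pointless on generator output
and the pipeline can be told to skip it. The equal-split buried-SAS rule
means a site's measured SAS is the mean of its own latent size and its
partners', so between-stratum SAS differences configured in the generator
appear roughly halved in pipeline output.

## Numerical and reporting conventions

- Percentages in rendered tables are rounded half-away-from-zero (the
  convention of printed tables); expected counts are shown rounded to
  integers next to observed counts as `obs (exp)`.
- Propensity normalization is checked to 1e-9; ternary coordinates
  round-trip to 1e-12.
- All generator and analysis randomness flows through
  `numpy.random.default_rng` seeds; derived seeds are below 2³¹.

## Limitations

- The interface-residue criterion of the original resource pipeline is not
  fully published; absolute residue counts depend on it and are therefore
  configurable rather than fixed.
- The per-cell z-tests use a normal approximation; for small expected counts
  (np < 5) a warning is raised and exact binomial tests would be preferable.
- The χ² cells are treated as independent binomials for flagging purposes;
  the multinomial constraint makes the per-cell tests slightly conservative
  in aggregate.
- Surface propensities require surface residue annotations for every member;
  sites lacking them get site-only profiles.
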