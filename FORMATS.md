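# File formats

All interchange files are tab-separated, UTF-8, with a header row. Floating
point values are written in full precision; missing values are not permitted
unless noted.

## Input tables

### `ddi.tsv` — one row per domain–domain interaction (DDI)

| column | type | meaning |
|---|---|---|
| `ddi_id` | str | unique identifier of this DDI (e.g. a PDB-derived tag); duplicates are rejected |
| `pdb_id` | str | source structure identifier (free-form provenance) |
| `chain_a` | str | chain of the first domain instance |
| `family_a` | str | domain family accession of side A (e.g. a Pfam accession) |
| `dfbs_a` | str | binding-site ID of side A, formatted `family:index` with a 1-based index |
| `chain_b` | str | chain of the second domain instance |
| `family_b` | str | family accession of side B |
| `dfbs_b` | str | binding-site ID of side B |
| `seq_a` | str | amino-acid sequence of the side-A domain instance (one-letter codes) |
| `seq_b` | str | sequence of the side-B domain instance |
| `sas_a_unbound` | float | solvent accessible surface (Å²) of side A alone |
| `sas_b_unbound` | float | solvent accessible surface (Å²) of side B alone |
| `sas_complex` | float | solvent accessible surface (Å²) of the complex |

The buried SAS of the interface is `(sas_a_unbound + sas_b_unbound −
sas_complex) / 2` per side; a negative value is rejected as inconsistent.

### `residues.tsv` — one row per residue per DDI side

| column | type | meaning |
|---|---|---|
| `ddi_id` | str | the DDI this residue belongs to; must exist in `ddi.tsv` |
| `side` | `A` or `B` | which domain instance of the DDI |
| `residue_index` | int | 1-based position within the domain instance |
| `sse3` | `a`, `b` or `g` | 3-state secondary structure: α (helix H/G/I), β (strand/bridge E/B), γ (everything else: T/S/blank) |
| `in_interface` | `0` or `1` | whether the residue is part of the binding-site interface |
| `rsa` | float in [0, 1] | relative solvent accessibility (absolute accessibility over the residue's maximum ASA, capped at 1) |

Residues with `rsa` at or above the surface threshold (default 0.05) count as
surface residues; interface residues always count toward the site propensity
regardless of `rsa`.

## Output files (written by `dfikit run-all` / `write_report`)

- `classes.tsv` — one row per DFBS: propensities (`p_alpha`, `p_beta`,
  `p_gamma`), surface propensities (`q_*`), `sse_class` and `surface_class`
  (1–5), extreme labels, ternary plot coordinates, partner count, mean site
  SAS and residue count.
- `propensities.tsv` — the propensity columns of `classes.tsv`.
- `pairing.tsv` — one row per unordered class pair: observed count and
  percentage, expected probability and count under random pairing, z, p and
  enrichment flag (`enriched` / `depleted` / `ns`).
- `pairing_global.json` — global χ² statistic, degrees of freedom and p-value
  (written by the `pairing` subcommand).
- `promiscuity.tsv`, `strata.tsv` — DFBS class distribution per
  partner-count stratum (1, 2, 3, >3) with per-stratum tests.
- `sas_by_partners.tsv` — mean/SD of buried SAS and interface residue count
  per stratum, with two-sample z-tests against the single-partner stratum.
- `domain_histogram.tsv` — number of domain families per binding-site count.
- `promiscuity_scatter.tsv` — per-family site count vs distinct partner count.
- `domains.tsv` — per-family promiscuity summary.
- `summary.json` — machine-readable run summary (counts, class summary,
  pairing results, promiscuity fractions); input to `dfikit report`.

## Synthetic datasets (`dfikit simulate`)

`simulate` writes `ddi.tsv` and `residues.tsv` in the formats above plus
`truth.json`, the generator's ground-truth record: the configuration, the
realized class counts, per-site latent values and the true pair counts.

## DSSP input (`dfikit ingest`)

`ingest` reads classic column-formatted DSSP output (the residue table
following the `#  RESIDUE` banner). The 8-state DSSP codes are collapsed to
the 3-state alphabet above; the modern `P` (polyproline II) code maps to γ
with a warning. Relative accessibility uses the Tien et al. (2013)
theoretical maximum ASA table.
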