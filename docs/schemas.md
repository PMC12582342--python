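# Table schemas

All tables are UTF-8 tab-separated text with a header row. Days are
numeric relative to Day 0 (start of the controlled phase); periods use
the closed labels `FL` (free living, days −5..0), `EB` (energy balance,
0..5), `ED` (energy deficit, 5..10). Sample identifiers are
`<subject>_D<day>`, e.g. `S03_D5`. `proteoturn validate <bundle>` checks
every table below.

## isotopomers.tsv
| column | meaning |
|---|---|
| peptide_id | unique peptide identifier |
| accession | parent protein accession |
| subject | subject id |
| period | FL / EB / ED |
| boundary | `start` or `end` of the period's labelling window |
| i_m0, i_m1 | monoisotopic and first heavy isotopomer intensities (≥ 0, sum > 0) |

One row per (peptide, subject, period, boundary); duplicates are a
validation error.

## lfq_peptides.tsv
`accession`, `peptide_id`, `conflict` (boolean; conflicting peptides are
excluded from protein quantification), then one intensity column per
sample. Must include the spiked standard rows (`accession = ADH1_STD`,
≥ 3 peptides).

## gcms_standards.tsv
`enrichment_pct` (known D₂O %, 0.0–5.0 in 0.5 steps), `rep`, `i58`,
`i59` (ion intensities at m/z 58 and 59, > 0).

## gcms_samples.tsv
`subject`, `period`, `day`, `rep`, `i58`, `i59`.

## prm.tsv
`target` (e.g. PLIN2), `peptide`, `sample`, `fragment`, `light_i`,
`heavy_i` (fragment intensities, ≥ 0).

## physiology.tsv
`subject`, `period`, `energy_intake_kcal`, `eee_kcal`, `ffm_kg`,
`vo2_rest`, `vco2_rest`, `vo2_ex`, `vco2_ex` (gas exchange in L/min).

## annotation.tsv
`accession`, `compartment` (mitochondrial / myofibrillar /
sarcoplasmic), `mw_kda`. Proteins absent from the annotation fall into
the sarcoplasmic catch-all with a warning count.

## peptides.tsv
`peptide_id`, `accession`, `sequence`, `n_exch` (deuterium-accessible
C–H count), `ria_natural` (theoretical unlabelled RIA, used only for QC
cross-checks and by the simulator).

## proteins.fasta
Protein sequences (FASTA); used for molecular weights when the
annotation lacks them and by the simulator.

## Configuration tables (shipped in `src/proteoturn/data/`)
- `exchangeable_h.tsv`: residue → deuterium-accessible C–H count.
- `isotope_abundances.tsv`: element, nominal mass shift, abundance.
- `oxidation_coefficients.tsv`: context, a1, a2, b1, b2 for the
  substrate-oxidation equations.

All three are two-column-plus key/value text files; user-substituted
tables propagate to every downstream number.
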