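# Supplementary ratio tables (not distributed)

The cross-dataset tests in `tests/test_acceptance.py` consume TSV
exports of the published supplementary result tables for the
heterocyst/filament ICAT study. Those tables are distributed by the
journal as XLSX and are not shipped with this package; to run the
corresponding tests, export them here with the following schemas
(tab-separated, header row, one protein per line):

- `additional_file1_ratios.tsv` — all 511 quantified proteins:
  `locus_tag`, `log2_ratio` (log2 Het/Fil).
- `additional_file4_young.tsv` / `additional_file4_steady.tsv` — the
  newly formed and steady-state datasets restricted to their 180-protein
  overlap: `locus_tag`, `log2_ratio`.
- `additional_file5_proteins.tsv` — protein ratios for loci with
  transcript data: `locus_tag`, `log2_ratio`.
- `additional_file5_transcripts.tsv` — matching transcript data:
  `locus_tag`, `log2_fc`, `differential` (boolean, the source study's
  own call), `cluster` (integer or empty).

Without these files the supplementary recomputation tests fail with a
missing-file error; all other tests are self-contained.
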