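# icatq

Two-channel ICAT (isotope-coded affinity tag) Cys-proteomics for
cell-type-specific quantification in heterocyst-forming cyanobacteria.

## The problem

Filamentous cyanobacteria such as *Nostoc punctiforme* differentiate a
small fraction of their cells into heterocysts — terminally specialized
N₂-fixing cells occurring at a frequency *f* of roughly 7.5% along the
filament. Shotgun proteomics cannot measure single cells, so the
accessible comparison is an enriched heterocyst fraction against the
whole N₂-fixing filament, labeled with the light (+227.127 Da/Cys) and
heavy (+236.157 Da/Cys) cleavable ICAT reagents respectively. After
tryptic digestion and avidin enrichment of the Cys-labeled peptides,
light/heavy precursor pairs of the same charge state (Δm = n_Cys ×
9.030 Da, matched at 10 ppm) yield peptide ratios, which roll up to a
per-protein log₂ heterocyst/filament ratio across biological
replicates.

Two quantitative models anchor the analysis:

* **Empirical null threshold.** In a 1:1 self-mixture every true ratio
  is 1, so the 5th percentile of the observed protein-ratio
  distribution bounds the false-positive rate: a value of 0.657
  corresponds to a 1.52-fold down-regulation at P = 0.05, motivating a
  1.6-fold cutoff applied symmetrically (log₂ ± 0.678).
* **Dilution ceiling.** The whole-filament fraction of a protein with
  per-cell abundances H (heterocyst) and V (vegetative) is
  F = f·H + (1 − f)·V, so the observable Het/Fil ratio of a
  heterocyst-exclusive protein (V = 0) is capped at 1/f ≈ 13.3-fold at
  f = 0.075. The same algebra inverts to the vegetative abundance,
  V = (F − f·H)/(1 − f).

`icatq` implements the full pipeline — in-silico digestion, Cys
enrichment, tag-mass pair matching, protein rollup, known-mixture
calibration (1:5, 1:1, 5:1), three-way cell-type classification,
functional category summaries, and cross-dataset / transcript
concordance — together with a synthetic-data generator that emulates
the two-cell-fraction design end-to-end, so every stage is testable
without any external download.

## Worked example

```sh
icatq demo --seed 1 --out-dir demo_out
```

simulates 300 proteins (two replicates, lognormal area noise
σ = 0.11), quantifies them, calibrates on the three known mixtures, and
classifies every protein:

```
                                 1to5     1to1   5to1
Expected                          0.2        1      5
Average                         0.201        1   5.04
Median                            0.2        1   5.04
Stdev                          0.0153   0.0697  0.387
95th percentile                 0.227     1.13   5.63
5th percentile                  0.176    0.903   4.33
Variance                     0.000234  0.00486   0.15
Variance %                      0.116    0.484   2.98
Number of proteins analyzed       284      284    284

null 5th percentile: 0.903 (implied fold 1.11); chosen cutoff 1.6-fold = log2 0.678
dilution ceiling at f=0.075: 13.3-fold
265 proteins quantified: 73 higher in heterocysts, 81 higher in filaments
```

Reading the output: each mixture column recovers its designed ratio
(medians 0.2, 1.0, 5.04) with the spread growing at the extreme 5:1
ratio; the 1:1 null implies that anything beyond a 1.11-fold change
already clears this synthetic noise floor, so the conventional 1.6-fold
cutoff is comfortably conservative; and no protein can exceed the
13.3-fold ceiling imposed by the 7.5% heterocyst frequency. The output
directory holds every stage's TSV plus a `MANIFEST` of SHA-256 hashes —
rerunning with the same seed reproduces it byte-for-byte.

The same stages are available as composable subcommands
(`simulate`, `quantify`, `calibrate`, `classify`, `compare`,
`compare-transcripts`, `run-all`) and as a plain Python API
(`icatq.simulate`, `icatq.quantify`, `icatq.calibration`,
`icatq.classify_report`, `icatq.comparative`, `icatq.pipeline`).

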