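# Methods

## Quantification model

ICAT labels cysteine thiols with a cleavable biotinylated tag in two
isotopic forms: light, +227.127 Da per Cys, and heavy (nine ¹³C),
+236.157 Da per Cys. A peptide with n cysteines therefore appears as a
precursor pair separated by n × 9.030 Da at the same charge state. The
pipeline pairs light and heavy peaks within a protein's identified
peptides when replicate, sample and charge agree and the observed mass
difference is within a 10 ppm tolerance of n × 9.030 Da; each peak is
used at most once, the nearest-mass candidate wins, and residual ties
go to the larger summed area, making the matching deterministic. The
peptide ratio is the light/heavy precursor area quotient.

Rollup to proteins is: per replicate, the **median** of the protein's
peptide-pair ratios (robust to a single outlier pair when three or
more pairs exist); across replicates, the **arithmetic mean of the
log₂ ratios**, i.e. the geometric mean of the fold changes, which
treats up- and down-regulation symmetrically. Proteins not quantified
in every required replicate (default two) are dropped and counted, not
imputed; a pair missing one channel is likewise dropped. Replicate
variability is reported on the linear scale as 100·|r₁ − r₂|/mean for
two replicates and as the percent sample CV for more; the two
definitions differ by √2 at n = 2, and the first is what the
per-protein "variability %" column contains.

## Empirical null threshold

A self-mixture in which both channels derive from the same sample has
true ratio 1 for every protein, so its protein-ratio distribution is a
direct empirical null. The α-quantile (default α = 0.05, linear
interpolation / type-7 — the convention matters at small n and is
fixed and documented here) of the 1:1 ratios gives the fold change
below which only a fraction α of unchanged proteins falls; its
reciprocal is the implied minimal detectable down-regulation. The
analyst cutoff (default 1.6-fold, log₂ 0.678) is an explicit parameter
recorded next to the implied fold — never silently substituted — and is
applied symmetrically: calls are HET_HIGHER above +cutoff, FIL_HIGHER
below −cutoff, EQUAL otherwise, with boundary values assigned EQUAL.
No multiple-testing correction is applied; the analysis uses the single
empirical fold threshold throughout, and reports say so.

Calibration mixtures at 1:5, 1:1 and 5:1 are summarized by expected,
average, median, stdev, sample variance, 5th/95th percentiles,
variance % (defined as 100·variance/average) and protein count, one
column per mixture.

## Two-cell-type dilution model

With heterocysts at frequency f along the filament and per-cell
abundances H (heterocyst) and V (vegetative), the whole-filament
concentration is F = f·H + (1 − f)·V. Consequences used throughout:

* the observable Het/Fil ratio H/F of a heterocyst-exclusive protein
  (V = 0) equals 1/f — 13.3-fold at the observed f = 0.075 — and no
  noise-free measurement can exceed it;
* the vegetative abundance deconvolves as V = (F − f·H)/(1 − f);
  negative algebraic solutions indicate measurement inconsistency with
  the model and are clipped to zero with a flag.

f is a parameter (default 0.075) validated to lie strictly in (0, 1).

## Synthetic-data generator

The generator emulates the two-cell-fraction design, not the mass
spectrometer. Proteomes are i.i.d. residue strings with a controlled
cysteine probability (default 1.38%, a typical low bacterial Cys
content; the other 19 residues follow a fixed Swiss-Prot-like
composition), lengths uniform in 80–450 residues. Ground truth assigns
each protein to one of five classes — heterocyst-exclusive, enriched,
equal, filament-enriched, vegetative-exclusive — with fold changes
drawn log-uniformly (default 2–8) and base abundances log-uniform over
two decades.

Peak tables contain one row per Cys-bearing tryptic peptide (fully
cleaved, duplicates within a protein collapsed — indistinguishable
precursors), per channel, per replicate: light follows H, heavy
follows F; calibration mixtures use F in both channels with the light
channel scaled by the designed ratio. Each peptide gets a log-uniform
ionization factor shared between channels and replicates (it cancels
in ratios, as in the real measurement, but spreads areas realistically)
and each peak independent multiplicative lognormal noise; areas below a
hard detection limit are censored, which is the mechanism that inflates
ratio spread at extreme mixing ratios. Charge states are assigned
deterministically from basic-residue content (2+ or 3+). Defaults: two
biological replicates; σ = 0.11 on the natural-log scale, giving a
peptide-pair ratio CV of about 16% (σ√2); after median rollup over
peptides and averaging of two replicates the protein-level CV is ~7%.
Channel convention, fixed repo-wide: light = heterocyst = numerator,
heavy = filament = denominator.

What the generator does **not** model: isotope envelopes, retention
time, co-elution and chromatographic (SCX) fractionation, MS/MS
identification error, ratio compression from co-isolated background,
shared peptides between proteins (locus tags are unique by
construction), or systematic channel bias (real 1:1 data sits at a
median near 0.90, not 1.0). Passing tests therefore demonstrate the
correctness of the arithmetic and the statistical behavior of the
estimators under the stated noise law — not instrument-level realism.

## Protein metadata

Molecular weights use embedded standard average and monoisotopic
residue-mass tables plus one water. Isoelectric points solve for zero
net Henderson–Hasselbalch charge (N-terminus 7.5, C-terminus 3.55,
side chains D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0 — a
fixed Bjellqvist-style set chosen for determinism; values are
internally consistent rather than guaranteed to match any external
tool digit-for-digit) by bisection on (0, 14) to 1e-4, valid because
the terminal groups guarantee a monotone charge curve with a zero
crossing. FASTA entries with ambiguous `X` residues are excluded with
a warning rather than assigned guessed masses; other non-amino-acid
characters are errors with a position. Cys-coverage summaries bin by
exact cysteine count and report sparsely populated high-Cys bins
as-is.

## Comparative analyses

Concordance between two datasets' three-way calls uses the ordered
scale FIL < EQUAL < HET: agreeing extremes map to both-higher /
both-lower classes; the (EQUAL, EQUAL) cell is reported separately as
OTHER rather than forced into a directional class; every remaining
combination — including moves spanning FIL to HET — is assigned to the
dataset standing strictly higher on the scale. The mapping is total
and deterministic over the 3×3 grid. Transcript comparison joins on
locus tag, takes each transcript's differential flag from its source
dataset (thresholds are not re-derived), applies the protein cutoff to
the protein side, and reports per-cluster fractions of
heterocyst-enriched protein calls.

## Numerical and design choices

* Percentile convention: type-7 linear interpolation everywhere.
* Percentage rounding in category summaries: half-away-from-zero to
  integers; counts are authoritative and always conserve, and rounded
  percentages may not sum to 100.
* Pair matching groups within the protein identification carried by
  the peak table; the mass-window test then applies within that group.
  This mirrors identification-driven quantification and avoids
  cross-protein pairing of identical short tryptic peptides.
* Pipeline runs are deterministic per seed; every stage writes TSV and
  the run directory carries a SHA-256 MANIFEST.
* Default problem sizes (300 proteins in the pipeline demo, 80–150 in
  simulation studies, 20-seed Monte-Carlo repeats) keep a full run in
  seconds while leaving >100 quantified proteins per experiment, ample
  for stable medians and 5th percentiles.

## Known limitations

* The rollup statistic inside commercial software is not public;
  median-per-replicate is a documented choice, and datasets rolled up
  with a weighted average will differ slightly.
* The empirical threshold machinery assumes the 1:1 mixture shares its
  noise structure with the biological samples; instrument drift
  between runs violates this silently.
* The "variance %" of a calibration table admits several plausible
  definitions; ours (100·variance/average) is self-consistent across
  columns but not the only convention in use.
* Deconvolution of vegetative abundance amplifies noise for proteins
  near the ceiling, where F − f·H is a small difference of large
  numbers.
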