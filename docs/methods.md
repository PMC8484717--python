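# Methods

This note documents the models, conventions and numerical choices behind
pepsieve, and what its synthetic fixtures do and do not emulate.

## Database construction

Sequences from three sources — a reference proteome, repository predictions
(altProt/isoform style) and ribosome-profiling sORF predictions — are
combined under the rules used for enzyme-free proteogenomic searching.

* **Coordinates.** Genomic loci use 0-based half-open intervals (BED
  convention). The stop position of an ORF is its strand-aware 3′-most
  coding coordinate: last block end − 1 on `+`, first block start on `-`.
* **Longest-per-stop.** Predictions sharing (chromosome, strand, stop) are
  reduced to the longest sequence; ties break to the lexicographically
  smallest sequence, then smallest id, so output is deterministic.
* **Single-exon filter.** A prediction is dropped iff it has exactly one
  block and that block overlaps (≥1 nt, same chromosome and strand) any
  annotated coding exon. Spliced (multi-block) predictions always survive.
  The alternative reading — "fully contained within one exon" — was
  considered and rejected as the weaker filter; any overlap of an unspliced
  prediction with a coding exon makes reference-derived MS evidence
  plausible, which is what the filter guards against.
* **Reference-overlap exclusion.** "Identical" means exact full-sequence
  equality. Removing predicted sequences merely *contained* in a reference
  protein would discard potentially distinct proteoforms, so containment
  removal is available only behind `BuildConfig.remove_contained`.
* **Deduplication.** Survivor precedence is
  reference > openprot > sorfs_org > contaminant, then smallest id;
  absorbed ids are appended to the survivor's description. The operation is
  idempotent.
* **Decoys.** One whole-sequence reversal per target (id prefixed
  `DECOY_`). No K/R anchoring is used because the searches the database
  feeds are enzyme-free. Palindromic decoys are admitted and logged.
* **Composition.** Distinct sequences are partitioned into the 7 Venn cells
  of (reference, openprot, sorfs_org); percentages are rounded half-up to
  one decimal. Sequences containing X or U are admitted to the database but
  refused by the fragmentation code.

## Masses and fragmentation

Residue monoisotopic masses are fixed in code (standard amino-acid residue
table, 5-decimal precision); proton = 1.007276 Da, water = 18.010565 Da.
Modification deltas: amidation −0.98402, Met oxidation +15.99491, pyro-Glu
−17.02655 from Q and −18.01056 from E. Only b/y ions are generated (HCD-type
fragmentation); amidation shifts the y series only, pyro-Glu the b series
only. Fragment charges 1 and 2 are considered for precursors of charge ≥2,
charge 1 otherwise. No neutral losses or isotope envelopes are modeled.

Peak matching takes, for each theoretical m/z, the nearest observed peak
within a symmetric ±0.02 Da window (distance ties go to the higher
intensity); matching is non-exclusive, i.e. one observed peak may serve
several theoretical ions. This is simpler than greedy exclusive assignment
and fully deterministic.

## Rescoring

**Features.** Observed fragment intensities are TIC-normalized and
transformed log₂(10⁴·x + 1); the 10⁴ constant rescales TIC-normalized
intensities (which live around 10⁻²–10⁻⁴) so real peaks land well above 1
while absent peaks stay at exactly 0. Features are the Pearson correlation
between predicted and observed vectors (overall and per ion series, with
zero-variance vectors assigned PCC 0 by convention), the spectral angle,
matched fraction/count, and absolute/signed/relative retention-time errors.
Missing values are median-imputed per column with an indicator mask
appended.

**q-values.** At every score threshold FDR = (D + [plus-one]) / max(T, 1),
monotonized from the permissive end and clipped to [0, 1]. Decoys rank
above targets at ties (conservative). The decoy count is not incremented by
default; the Percolator-style `plus_one` numerator is a flag, and both
variants are tested against an exhaustive threshold-enumeration oracle.

**Semi-supervised loop.** PSMs are assigned to `folds` (default 3)
cross-validation folds by a seeded SHA-256 hash of the spectrum id, so all
candidates for one spectrum share a fold and results are reproducible
across platforms. Per fold: positives are initialized as training-split
targets at base-score q ≤ 0.01, an L2 logistic classifier (regularization
strength chosen from {0.01, 0.1, 1} by inner 2-fold selection maximizing
accepted targets) is refit while re-selecting positives until the positive
set stabilizes (≤10 iterations), and the held-out fold is scored with
weights its PSMs never influenced. Degenerate training splits (no decoys,
no initial positives) fall back to the base score with a warning.

**Fold-score calibration.** Each fold's scores are z-scaled on the decoy
scores produced by that fold's model — computed over the *entire* decoy
collection, not just the held-out decoys. Because every fold normalizes
against the same reference sample, fold-to-fold scale noise cancels: if the
learned model is a monotone function of the base score alone, the merged
ranking reproduces the base-score ranking exactly, so adding no information
changes no identifications. Normalizing on per-fold decoy subsets (a third
of the decoys each) was measured to introduce ±3% noise in the accepted set
at the 1% FDR cut; anchoring at the q-threshold score was noisier still,
being a single order statistic.

**PEP.** The posterior error probability is the isotonic
(monotone-non-increasing in score) regression of the decoy indicator — a
smoothed local decoy-fraction estimate. In the uninformative limit (all
scores equal) every PSM receives D/(D+T). PEP is reported alongside, not
derived from, the q-values.

## Summarization and sORF selection

* The q filter for peptide grouping is strict (q < 0.01); a PSM exactly at
  the threshold is excluded.
* The peptide key includes modifications by default (`key_mods=False`
  collapses modified forms), since method comparisons count peptidoforms.
* Neuropeptide annotation matches a peptide to a reference entry iff either
  sequence contains the other; bidirectional containment captures both the
  truncation ladders produced by endogenous proteolysis and extended
  intermediates. Peptides inside a known precursor but matching no mature
  entry are flagged precursor-only.
* Non-coding filtering operates at the gene level: `protein_coding` genes
  are excluded; lncRNA, TEC and pseudogene biotypes are retained; genes on
  an explicit allowlist (predicted genes with limited annotation) are
  retained; genes missing from the biotype table are retained but flagged.
* The uniqueness scan is an ungapped windowed Hamming comparison of the
  peptide tag against every same-length window of the proteome, with a
  mismatch budget (default 1). It is a deliberate surrogate for a gapped
  short-tag homology search: adequate for tags of ~8–25 residues where a
  single substitution dominates near-matches. The mapping from an e-value
  cutoff to a mismatch bound is a heuristic, not an equivalence; tags
  shorter than 8 residues are refused as unreliable.
* Coverage is the unioned fraction of protein residues covered by all
  occurrences of all identified peptides, binned at <10%, 10–30%, >30%.
* Overview tables always carry a totals row asserted equal to the column
  sums. Annotation flags (conservation, prior MS evidence, translation
  efficiency, orthology, transmembrane helix, disorder) are consumed as
  input columns; computing them is out of scope.

## Synthetic fixtures: what they emulate, and what they do not

The generators are pure functions of a `SimConfig` (seed included) and emit
machine-readable ground truth.

* **Proteome sets** realize exact planted Venn-cell counts with distinct
  random sequences (default cells ≈ the published full database scaled by
  1000, lengths 20–60 aa). Feasibility versus the alphabet is checked.
* **sORF predictions** plant stop-sharing groups (known longest member) and
  single-exon coding-overlap decoys, with the expected survivor list
  emitted alongside.
* **Spectra** place b/y ions at exact theoretical m/z with intensities from
  a gamma (default) or dyadic-ladder model; observed intensities mix the
  predicted vector with independent noise *in transformed space* so the
  expected post-transform Pearson correlation equals `correlation_rho`
  (exact at ρ = 1; realized values scatter as sample correlations do).
  Noise peaks are placed away from theoretical positions. Peptide lengths
  span 8–50 aa, charges 1–6, and by default 80% of peptides end on a
  non-basic residue, the hallmark of enzyme-free peptidomics.
* **PSM mixtures** draw base scores from a two-Gaussian model: correct
  targets from N(3, 1), incorrect targets and all decoys from N(0, 1), with
  35% of targets correct — a low identification rate typical of endogenous
  peptidomics against an inflated search space. Three informative features
  are shifted by +1.5σ for correct PSMs only; five uninformative features
  are standard normal. These defaults give the base score real but
  incomplete separation, leaving the headroom that auxiliary features close
  (the rescorer roughly multiplies 1% FDR acceptances by ~1.6 under these
  conditions). Two-Gaussian tails are chosen for analytic tractability.

What passing tests on these fixtures shows: the bookkeeping (Venn cells,
filtering, grouping, tables) is exact; q-value estimation matches exhaustive
enumeration; the semi-supervised loop is calibrated (mean true FDP at
q ≤ 0.01 within [0, 0.03] over 20 replicates, with informative or with
signal-free features) and gains identifications when auxiliary signal
exists. What it does not show: performance on real timsTOF spectra, whose
fragment-intensity structure, co-elution interference, ion-mobility physics
and retention-time error structure the fixtures deliberately do not model.

## Problem sizes

Replicate suites use 20 seeded replicates of 4,000 PSMs (2,000 targets,
2,000 decoys); complementarity identities are checked on 1,000 random
peptidoforms; oracle-equivalence suites use ≤50-PSM q-value instances and
~10–15-protein proteomes. The full test suite runs in well under a minute;
the acceptance script in a few seconds.

## Known limitations

* The decoy model is whole-sequence reversal only; no shuffling option.
* The rescorer's classifier is linear; non-linear interactions between
  features are not exploited.
* Gapped homology search, PTM localization, quantification and
  transcript-level biotype logic are out of scope.
* mzIdentML ingestion is not implemented; PSMs arrive via the documented
  TSV dialect, spectra via MGF.
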