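# pepsieve

A toolkit for the computational core of enzyme-free (endogenous) peptidomics
with a proteogenomic search space: building a custom target–decoy FASTA
database that combines a reference proteome with predicted small open reading
frames (sORFs), rescoring peptide-to-spectrum matches (PSMs) with
predicted-spectrum and retention-time features under target–decoy false
discovery rate (FDR) control, and selecting/validating neuropeptide and
sORF-encoded peptide identifications.

It is aimed at peptidomics and proteogenomics analysts who search
non-digested peptide data (e.g. neuropeptide extracts) against very large
custom databases, where the enlarged search space and the absence of tryptic
termini make post-processing rescoring and careful candidate validation
essential.

## What it computes

**Database construction** (`pepsieve.fasta_db`). From a reference proteome
*R*, repository predictions *O* (OpenProt-style altProts) and
ribosome-profiling predictions *S* (sORFs.org-style), the builder keeps only
the longest predicted sORF per genomic stop position, drops single-exon
predictions overlapping annotated coding exons, deduplicates within and
across sources, removes predicted sequences identical to a reference
protein, concatenates contaminants, and appends one reversed-sequence decoy
per target. Composition is reported as the seven disjoint Venn cells over
distinct sequences of (R, O, S) with derived percentages.

**Fragmentation and matching** (`pepsieve.spectra`). Monoisotopic masses and
singly/doubly protonated b/y ions for peptidoforms carrying the variable
modifications of mature bioactive peptides (C-terminal amidation, Met
oxidation, N-terminal pyro-Glu from Q/E), MGF I/O, and nearest-peak matching
within a ±0.02 Da tolerance.

**Rescoring** (`pepsieve.rescore`). PSM features are expanded with the
Pearson correlation (PCC) between predicted and observed fragment
intensities (TIC-normalized, log₂(10⁴·x+1)-transformed), spectral angle and
retention-time errors. Target–decoy q-values use

    FDR(t) = (#decoys ≥ t) / max(#targets ≥ t, 1),   q = running minimum,

with decoys ranked above targets at score ties. The semi-supervised
rescorer splits PSMs spectrum-wise into folds, iteratively refits an
L2-regularized linear classifier on confident targets (q ≤ 0.01) versus
decoys, scores each held-out fold with weights it never influenced, and
calibrates fold scores on the common decoy set. Posterior error
probabilities come from an isotonic (monotone-decreasing) fit of the decoy
fraction against score.

**Summarization and sORF selection** (`pepsieve.summarize`,
`pepsieve.sorf_select`). Passing PSMs (q strictly below 0.01) collapse to
unique peptidoforms, are annotated against a neuropeptide reference by
bidirectional sequence containment, and compared across search strategies by
exact set arithmetic. Small proteins (≤100 aa) are categorized by database
provenance, filtered to non-coding gene biotypes at the gene level (lncRNA,
TEC, pseudogene, plus an allowlist), checked for sequence-tag uniqueness
with a windowed Hamming scan, and aggregated into per-category overview
tables.

**Synthetic fixtures** (`pepsieve.fixtures`). Seed-deterministic generators
for Venn-structured proteomes, sORF predictions with planted filtering
structure, spectra with tunable predicted–observed correlation, and
two-Gaussian target/decoy PSM score mixtures with per-PSM correctness
labels.

## Worked example

```python
from pepsieve import fixtures, fasta_db, rescore

cfg = fixtures.SimConfig(seed=1)

# 1. build a database from a simulated three-source proteome
sim = fixtures.simulate_proteome(cfg)
records, comp = fasta_db.build_database(
    sim["reference"], sim["openprot"], sim["sorfs_org"], contaminants=[])
print(comp.total, comp.pct_proteogenomics_only)

# 2. rescore a simulated PSM mixture
psms = fixtures.simulate_psm_scores(cfg)
res = rescore.semi_supervised_rescore(
    psms, rescore.default_feature_matrix(psms),
    rescore.RescoreConfig(seed=1))
accepted = (res["q_value"] <= 0.01) & ~res["is_decoy"]
print(int(accepted.sum()))
```

prints

```
530 83.4
624
```

Here 530 is the number of distinct target sequences in the simulated
database and 83.4% of them come from a predicted (proteogenomic) source;
624 target PSMs pass the 1% FDR threshold after rescoring — substantially
more than the 355 that pass on the search-engine score alone, because the
simulation plants auxiliary features that separate correct from incorrect
matches, the situation the rescorer is designed to exploit.

The same steps are available from the shell: `pepsieve simulate`,
`pepsieve build-db`, `pepsieve rescore`, `pepsieve summarize`,
`pepsieve sorf-select` (see `pepsieve --help`).

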