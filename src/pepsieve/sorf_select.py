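"""Selection and validation of sORF-encoded peptide identifications.

Small proteins (<=100 aa) identified in the proteogenomic search are
categorized by database provenance, filtered to presumed non-coding gene
biotypes at the gene level, checked for sequence-tag uniqueness against the
reference proteome with a windowed Hamming scan, and aggregated into
per-category overview tables with MS-evidence and annotation-flag columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fasta_db import SeqRecord, Source

__all__ = [
    "Category",
    "SorfCandidate",
    "filter_small",
    "assign_category",
    "noncoding_filter",
    "uniqueness_scan",
    "coverage",
    "coverage_bin",
    "cross_reference_psm_ids",
    "summary_tables",
    "read_biotype_table",
    "read_allowlist",
]

# Non-coding biotypes retained by default (Ensembl vocabulary).
NONCODING_BIOTYPES = frozenset({"lncRNA", "TEC", "pseudogene"})


class Category(str, Enum):
    SWISS = "SWISS"
    TREMBL = "TrEMBL"
    OPENPROT_PREDICTED = "OpenProt predicted"
    SORFS_ORG_PREDICTED = "sORFs.org predicted"


@dataclass
class SorfCandidate:
    """One <=100-aa protein with its MS evidence and validation flags."""

    protein_id: str
    category: Category
    length: int
    gene_id: str | None = None
    gene_biotype: str | None = None
    peptides: list[tuple[str, int]] = field(default_factory=list)  # (seq, psms)
    coverage_pct: float = 0.0
    non_coding: bool = False
    unique_tag: bool = True
    in_reference_search: bool = False
    one_hit: bool = False
    conservation_hit: bool = False  # homology-search hit in other species
    ms_evidence: bool = False       # prior MS evidence reported externally
    te_evidence: bool = False       # translation-efficiency evidence
    orthology: bool = False
    tmh: bool = False               # predicted transmembrane helix
    disorder: bool = False          # predicted short disordered region
    biotype_missing: bool = False

    def __post_init__(self) -> None:
        if self.length > 100:
            raise ValueError(
                f"{self.protein_id}: length {self.length} exceeds 100 aa")
        if not 0.0 <= self.coverage_pct <= 100.0:
            raise ValueError("coverage_pct outside [0, 100]")

    @property
    def total_psms(self) -> int:
        return sum(n for _, n in self.peptides)

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)


def filter_small(proteins: Sequence, max_len: int = 100) -> list:
    """Keep proteins with length <= max_len (boundary inclusive).

    Accepts sequence records, candidates carrying a ``length`` attribute, or
    plain strings.
    """
    out = []
    for p in proteins:
        if hasattr(p, "sequence"):
            length = len(p.sequence)
        elif hasattr(p, "length"):
            length = p.length
        else:
            length = len(p)
        if length <= max_len:
            out.append(p)
    return out


def assign_category(record: SeqRecord) -> Category:
    """Map a database record to its identification category.

    UniProt headers carry an 'sp|' (Swiss-Prot) or 'tr|' (TrEMBL) prefix;
    predicted entries map by their source tag.
    """
    if record.source == Source.REFERENCE:
        if record.id.startswith("sp|"):
            return Category.SWISS
        if record.id.startswith("tr|"):
            return Category.TREMBL
        raise ValueError(
            f"cannot categorize reference header {record.id!r} "
            "(expected sp|/tr| prefix)")
    if record.source == Source.OPENPROT:
        return Category.OPENPROT_PREDICTED
    if record.source == Source.SORFS_ORG:
        return Category.SORFS_ORG_PREDICTED
    raise ValueError(f"cannot categorize source {record.source!r}")


def noncoding_filter(
    candidates: Sequence[SorfCandidate],
    biotype_table: Mapping[str, str],
    allowlist: Iterable[str] = (),
) -> list[SorfCandidate]:
    """Keep candidates on non-protein-coding genes, at the gene level.

    Protein-coding genes are excluded; recognized non-coding biotypes
    (lncRNA, TEC, pseudogene) are kept, as are explicitly allowlisted genes
    (predicted genes with limited annotation). Genes without a biotype entry
    are retained but flagged ``biotype_missing``.
    """
    allow = set(allowlist)
    kept: list[SorfCandidate] = []
    for cand in candidates:
        gene = cand.gene_id
        biotype = cand.gene_biotype
        if biotype is None and gene is not None:
            biotype = biotype_table.get(gene)
        if gene is not None and gene in allow:
            cand.non_coding = True
            kept.append(cand)
            continue
        if biotype is None:
            cand.biotype_missing = True
            cand.non_coding = True
            kept.append(cand)
            continue
        if biotype == "protein_coding":
            continue
        cand.gene_biotype = biotype
        cand.non_coding = True
        kept.append(cand)
    return kept


def uniqueness_scan(
    tag: str,
    proteome: Sequence[SeqRecord],
    max_mismatches: int = 1,
    own_protein_ids: Iterable[str] = (),
) -> list[tuple[str, int, int]]:
    """Windowed Hamming scan of a peptide tag against a proteome.

    Returns (protein_id, position, mismatches) for every window of length
    len(tag) with at most ``max_mismatches`` substitutions — an ungapped
    stand-in for a short-tag homology search. A tag is unique iff no hit
    falls outside its own source protein(s).
    """
    if len(tag) < 8:
        raise ValueError("tags shorter than 8 residues are unreliable")
    own = set(own_protein_ids)
    k = len(tag)
    hits: list[tuple[str, int, int]] = []
    tag_b = tag.encode()
    for rec in proteome:
        seq = rec.sequence.encode()
        n = len(seq)
        for pos in range(n - k + 1):
            mm = 0
            window = seq[pos:pos + k]
            for a, b in zip(window, tag_b):
                if a != b:
                    mm += 1
                    if mm > max_mismatches:
                        break
            else:
                hits.append((rec.id, pos, mm))
    return [h for h in hits if h[0] not in own] if own else hits


def is_unique(tag: str, proteome: Sequence[SeqRecord],
              own_protein_ids: Iterable[str], max_mismatches: int = 1) -> bool:
    return not uniqueness_scan(tag, proteome, max_mismatches, own_protein_ids)


def coverage(protein_seq: str, peptides: Iterable[str]) -> float:
    """Percent of protein residues covered by the identified peptides.

    Every occurrence of every peptide contributes; covered positions are
    unioned before dividing by the protein length.
    """
    covered: set[int] = set()
    for pep in peptides:
        start = protein_seq.find(pep)
        if start < 0:
            raise ValueError(f"peptide {pep!r} not found in protein")
        while start >= 0:
            covered.update(range(start, start + len(pep)))
            start = protein_seq.find(pep, start + 1)
    return 100.0 * len(covered) / len(protein_seq)


def coverage_bin(pct: float) -> str:
    if pct > 30.0:
        return ">30%"
    if pct >= 10.0:
        return "10-30%"
    return "<10%"


def cross_reference_psm_ids(
    candidate_psm_ids: Iterable[str], reference_search_psm_ids: Iterable[str]
) -> set[str]:
    """PSM ids shared with the reference-proteome search (empty = validated)."""
    return set(candidate_psm_ids) & set(reference_search_psm_ids)


# ---------------------------------------------------------------------------
# Aggregation tables
# ---------------------------------------------------------------------------

_CATEGORY_ORDER = [
    Category.SWISS, Category.TREMBL,
    Category.OPENPROT_PREDICTED, Category.SORFS_ORG_PREDICTED,
]


def summary_tables(
    candidates: Sequence[SorfCandidate],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category overview and annotation-flag tables with totals rows.

    The first table counts sORFs, PSMs and peptides per category, overall and
    within the non-coding subset. The second counts validation/annotation
    flags (conservation, prior MS evidence, translation-efficiency evidence,
    orthology, transmembrane helix, disorder, one-hit wonders) among the
    non-coding subset. Totals rows are asserted to equal the column sums.
    """
    rows1, rows2 = [], []
    for cat in _CATEGORY_ORDER:
        sub = [c for c in candidates if c.category == cat]
        nc = [c for c in sub if c.non_coding]
        rows1.append({
            "category": cat.value,
            "sorfs": len(sub),
            "total_psms": sum(c.total_psms for c in sub),
            "total_peptides": sum(c.n_peptides for c in sub),
            "non_coding": len(nc),
            "non_coding_psms": sum(c.total_psms for c in nc),
            "non_coding_peptides": sum(c.n_peptides for c in nc),
        })
        rows2.append({
            "category": cat.value,
            "non_coding_sorfs": len(nc),
            "conservation": sum(1 for c in nc if c.conservation_hit),
            "ms_evidence": sum(1 for c in nc if c.ms_evidence),
            "te_evidence": sum(1 for c in nc if c.te_evidence),
            "orthology": sum(1 for c in nc if c.orthology),
            "tmh": sum(1 for c in nc if c.tmh),
            "disorder": sum(1 for c in nc if c.disorder),
            "one_hit": sum(1 for c in nc if c.one_hit),
        })

    t1 = pd.DataFrame(rows1)
    t2 = pd.DataFrame(rows2)
    for t, label in ((t1, "Total sORFs"), (t2, "Total")):
        totals = {c: int(t[c].sum()) for c in t.columns if c != "category"}
        totals["category"] = label
        t.loc[len(t)] = totals
        num_cols = [c for c in t.columns if c != "category"]
        assert (t[num_cols].iloc[-1] == t[num_cols].iloc[:-1].sum()).all()
    return t1, t2


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_biotype_table(path: str) -> dict[str, str]:
    """Read gene_id -> biotype from a TSV (gene_id, gene_name, biotype)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "biotype" not in df.columns:
        raise ValueError(f"{path}: expected gene_id and biotype columns")
    return dict(zip(df["gene_id"], df["biotype"]))


def read_allowlist(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
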