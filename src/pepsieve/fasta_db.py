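"""Proteogenomic search-database construction.

Combines a reference proteome, two predicted-sORF/altProt sets (ribosome
profiling and repository predictions) and a contaminant set into a single
concatenated target-decoy FASTA, applying the filtering rules used for
enzyme-free peptidomics searches:

* per stop position, keep only the longest predicted sORF;
* drop single-exon sORF predictions overlapping coding exons;
* deduplicate identical sequences within and across sources;
* remove predicted sequences identical to a reference protein;
* append contaminants and reversed-sequence decoys.

Composition of the pre-decoy, pre-contaminant database is reported as the
seven disjoint Venn cells over the three sequence sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "Source",
    "Locus",
    "ExonInterval",
    "SeqRecord",
    "CompositionReport",
    "BuildConfig",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "select_longest_per_stop",
    "drop_single_exon_coding_overlaps",
    "dedupe_identical",
    "exclude_reference_identical",
    "generate_decoys",
    "compute_composition",
    "build_database",
]


class Source(str, Enum):
    """Provenance of a database entry."""

    REFERENCE = "reference"
    OPENPROT = "openprot"
    SORFS_ORG = "sorfs_org"
    CONTAMINANT = "contaminant"
    DECOY = "decoy"


# Dedup survivor precedence: annotated entries outrank predictions.
_SOURCE_PRECEDENCE = {
    Source.REFERENCE: 0,
    Source.OPENPROT: 1,
    Source.SORFS_ORG: 2,
    Source.CONTAMINANT: 3,
    Source.DECOY: 4,
}

_ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXU")


@dataclass(frozen=True)
class Locus:
    """Genomic location of a predicted ORF as 0-based half-open blocks."""

    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.blocks:
            raise ValueError("locus requires at least one block")
        blocks = tuple((int(s), int(e)) for s, e in self.blocks)
        object.__setattr__(self, "blocks", blocks)
        prev_end = None
        for s, e in blocks:
            if s >= e:
                raise ValueError(f"empty or inverted block [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError("blocks must be sorted and non-overlapping")
            prev_end = e

    @property
    def stop_coord(self) -> int:
        """Strand-aware 3'-most coding coordinate (the stop position)."""
        if self.strand == "+":
            return self.blocks[-1][1] - 1
        return self.blocks[0][0]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class ExonInterval:
    """One stranded coding-exon interval (BED6 line)."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."


@dataclass
class SeqRecord:
    """One database entry."""

    id: str
    description: str
    sequence: str
    source: Source
    locus: Locus | None = None
    gene_id: str | None = None
    gene_biotype: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CompositionReport:
    """Disjoint Venn-cell counts over distinct sequences of three sources.

    R = reference proteome, O = repository predictions, S = ribosome-profiling
    predictions. ``pct_small`` is the percentage of distinct sequences shorter
    than 100 aa.
    """

    r_only: int
    o_only: int
    s_only: int
    ro: int
    rs: int
    os_: int
    ros: int
    total: int
    pct_proteogenomics_only: float | None
    pct_reference_only: float | None
    pct_reference_overlap: float | None
    pct_small: float | None

    def cells(self) -> dict[str, int]:
        return {
            "R_only": self.r_only,
            "O_only": self.o_only,
            "S_only": self.s_only,
            "RO": self.ro,
            "RS": self.rs,
            "OS": self.os_,
            "ROS": self.ros,
        }

    def to_dict(self) -> dict:
        d: dict = dict(self.cells())
        d["total"] = self.total
        d["pct_proteogenomics_only"] = self.pct_proteogenomics_only
        d["pct_reference_only"] = self.pct_reference_only
        d["pct_reference_overlap"] = self.pct_reference_overlap
        d["pct_small"] = self.pct_small
        return d


@dataclass(frozen=True)
class BuildConfig:
    """Options for build_database."""

    decoy_prefix: str = "DECOY_"
    remove_contained: bool = False  # also drop predicted substrings of reference


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(
        Decimal("0." + "0" * ndigits), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str, source: Source | str) -> list[SeqRecord]:
    """Read a FASTA file; the header token before the first space is the id."""
    source = Source(source)
    records: list[SeqRecord] = []
    try:
        parsed = list(SeqIO.parse(path, "fasta"))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTA: {exc}") from exc
    for rec in parsed:
        seq = str(rec.seq).upper().replace(" ", "").replace("-", "")
        if not seq:
            raise ValueError(
                f"{path}: entry {rec.id!r} has an empty sequence"
            )
        records.append(
            SeqRecord(
                id=rec.id,
                description=rec.description,
                sequence=seq,
                source=source,
            )
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str, width: int = 60) -> None:
    """Write records with '>{source}|{id}|{gene_id}|{biotype} description'."""
    with open(path, "w") as fh:
        for rec in records:
            gene = rec.gene_id or ""
            biotype = rec.gene_biotype or ""
            header = f">{rec.source.value}|{rec.id}|{gene}|{biotype}"
            if rec.description and rec.description != rec.id:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_bed(path: str) -> list[ExonInterval]:
    """Read a stranded 6-column BED file of coding exons."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        ExonInterval(chrom=row.chrom, start=int(row.start), end=int(row.end),
                     strand=row.strand, name=row.name)
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Filtering stages
# ---------------------------------------------------------------------------

def select_longest_per_stop(records: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Keep only the longest sequence per (chrom, strand, stop) group.

    Ties on length break to the lexicographically smallest sequence, then the
    smallest id, so the survivor is deterministic.
    """
    missing = [r.id for r in records if r.locus is None]
    if missing:
        raise ValueError(f"records without locus: {missing}")
    groups: dict[tuple[str, str, int], SeqRecord] = {}
    for rec in records:
        key = (rec.locus.chrom, rec.locus.strand, rec.locus.stop_coord)
        cur = groups.get(key)
        if cur is None or _stop_rank(rec) < _stop_rank(cur):
            groups[key] = rec
    survivors = set(id(r) for r in groups.values())
    return [r for r in records if id(r) in survivors]


def _stop_rank(rec: SeqRecord) -> tuple[int, str, str]:
    return (-len(rec.sequence), rec.sequence, rec.id)


def _blocks_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def drop_single_exon_coding_overlaps(
    sorfs: Sequence[SeqRecord], coding_exons: Sequence[ExonInterval]
) -> list[SeqRecord]:
    """Drop single-block sORFs overlapping a same-strand coding exon.

    Multi-block (spliced) predictions are always retained; overlap is >=1 nt
    on the same chromosome and strand.
    """
    by_key: dict[tuple[str, str], list[ExonInterval]] = {}
    for ex in coding_exons:
        by_key.setdefault((ex.chrom, ex.strand), []).append(ex)

    kept: list[SeqRecord] = []
    for rec in sorfs:
        loc = rec.locus
        if loc is None or loc.n_blocks != 1:
            kept.append(rec)
            continue
        s, e = loc.blocks[0]
        exons = by_key.get((loc.chrom, loc.strand), [])
        if any(_blocks_overlap(s, e, ex.start, ex.end) for ex in exons):
            continue
        kept.append(rec)
    return kept


def dedupe_identical(
    records: Sequence[SeqRecord],
) -> tuple[list[SeqRecord], dict[str, list[str]]]:
    """Collapse identical sequences to one survivor per distinct sequence.

    Survivor precedence: reference > openprot > sorfs_org > contaminant,
    then smallest id. Absorbed ids are appended to the survivor description
    and returned in the merge map. Idempotent.
    """
    by_seq: dict[str, list[SeqRecord]] = {}
    for rec in records:
        by_seq.setdefault(rec.sequence, []).append(rec)

    out: list[SeqRecord] = []
    merge_map: dict[str, list[str]] = {}
    chosen: dict[str, SeqRecord] = {}
    for seq, group in by_seq.items():
        survivor = min(group, key=lambda r: (_SOURCE_PRECEDENCE[r.source], r.id))
        absorbed = sorted(r.id for r in group if r is not survivor)
        if absorbed:
            desc = survivor.description or survivor.id
            survivor = replace(
                survivor, description=f"{desc} merged={','.join(absorbed)}"
            )
            merge_map[survivor.id] = absorbed
        chosen[seq] = survivor
    # preserve input order of survivors
    seen: set[str] = set()
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(chosen[rec.sequence])
    return out, merge_map


def exclude_reference_identical(
    predicted: Sequence[SeqRecord],
    reference: Sequence[SeqRecord],
    remove_contained: bool = False,
) -> list[SeqRecord]:
    """Drop predicted records whose sequence equals a reference sequence.

    With ``remove_contained`` also drops predicted sequences that are proper
    substrings of a reference protein (the aggressive reading; off by
    default to keep potentially distinct proteoforms).
    """
    ref_seqs = {r.sequence for r in reference}
    kept: list[SeqRecord] = []
    removed = 0
    for rec in predicted:
        if rec.sequence in ref_seqs:
            removed += 1
            continue
        if remove_contained and any(rec.sequence in rs for rs in ref_seqs):
            removed += 1
            continue
        kept.append(rec)
    if removed:
        logger.info("exclude_reference_identical removed %d records", removed)
    return kept


def generate_decoys(
    records: Sequence[SeqRecord], prefix: str = "DECOY_"
) -> list[SeqRecord]:
    """One reversed-sequence decoy per target; id = prefix + target id."""
    clashing = [r.id for r in records if r.id.startswith(prefix)]
    if clashing:
        raise ValueError(
            f"input already contains ids with decoy prefix {prefix!r}: "
            f"{clashing[:5]}"
        )
    decoys: list[SeqRecord] = []
    for rec in records:
        rev = rec.sequence[::-1]
        if rev == rec.sequence:
            logger.info("palindromic decoy for %s", rec.id)
        decoys.append(
            SeqRecord(
                id=prefix + rec.id,
                description=f"decoy of {rec.id}",
                sequence=rev,
                source=Source.DECOY,
            )
        )
    return decoys


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def _as_seq_set(seqs: Iterable) -> set[str]:
    out = set()
    for s in seqs:
        out.add(s.sequence if isinstance(s, SeqRecord) else str(s))
    return out


def compute_composition(
    ref_seqs: Iterable, openprot_seqs: Iterable, sorfs_seqs: Iterable
) -> CompositionReport:
    """Classify every distinct sequence into one of 7 disjoint Venn cells.

    Percentages: proteogenomics-only = cells outside the reference circle;
    reference-only = R alone; reference-overlap = R intersected with either
    predicted source. Rounded half-up to one decimal.
    """
    R = _as_seq_set(ref_seqs)
    O = _as_seq_set(openprot_seqs)
    S = _as_seq_set(sorfs_seqs)
    all_seqs = R | O | S

    cells = {k: 0 for k in ("R_only", "O_only", "S_only", "RO", "RS", "OS", "ROS")}
    small = 0
    for seq in all_seqs:
        in_r, in_o, in_s = seq in R, seq in O, seq in S
        if in_r and in_o and in_s:
            cells["ROS"] += 1
        elif in_r and in_o:
            cells["RO"] += 1
        elif in_r and in_s:
            cells["RS"] += 1
        elif in_o and in_s:
            cells["OS"] += 1
        elif in_r:
            cells["R_only"] += 1
        elif in_o:
            cells["O_only"] += 1
        else:
            cells["S_only"] += 1
        if len(seq) < 100:
            small += 1

    total = len(all_seqs)
    assert total == sum(cells.values())
    if total == 0:
        pg = ref_only = ref_ov = pct_small = None
    else:
        pg = _round_half_up(
            100.0 * (cells["O_only"] + cells["S_only"] + cells["OS"]) / total)
        ref_only = _round_half_up(100.0 * cells["R_only"] / total)
        ref_ov = _round_half_up(
            100.0 * (cells["RO"] + cells["RS"] + cells["ROS"]) / total)
        pct_small = _round_half_up(100.0 * small / total)
    return CompositionReport(
        r_only=cells["R_only"], o_only=cells["O_only"], s_only=cells["S_only"],
        ro=cells["RO"], rs=cells["RS"], os_=cells["OS"], ros=cells["ROS"],
        total=total,
        pct_proteogenomics_only=pg,
        pct_reference_only=ref_only,
        pct_reference_overlap=ref_ov,
        pct_small=pct_small,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def build_database(
    reference: Sequence[SeqRecord],
    openprot: Sequence[SeqRecord],
    sorfs_org: Sequence[SeqRecord],
    contaminants: Sequence[SeqRecord],
    coding_exons: Sequence[ExonInterval] = (),
    config: BuildConfig | None = None,
) -> tuple[list[SeqRecord], CompositionReport]:
    """Run the full database-construction pipeline.

    Stages, in order: per-source dedup; longest-per-stop and single-exon
    filters on the ribosome-profiling predictions (when loci are present);
    cross-source dedup of the two predicted sets; removal of predicted
    sequences identical to reference; concatenation with contaminants;
    decoy generation. Composition is computed on the pre-decoy,
    pre-contaminant source sets.
    """
    cfg = config or BuildConfig()

    reference, _ = dedupe_identical(reference)
    openprot, _ = dedupe_identical(openprot)
    sorfs_org, _ = dedupe_identical(sorfs_org)
    contaminants, _ = dedupe_identical(contaminants)

    with_loci = [r for r in sorfs_org if r.locus is not None]
    if with_loci:
        without_loci = [r for r in sorfs_org if r.locus is None]
        filtered = select_longest_per_stop(with_loci)
        filtered = drop_single_exon_coding_overlaps(filtered, coding_exons)
        sorfs_org = without_loci + filtered

    report = compute_composition(reference, openprot, sorfs_org)

    predicted, _ = dedupe_identical(list(openprot) + list(sorfs_org))
    predicted = exclude_reference_identical(
        predicted, reference, remove_contained=cfg.remove_contained
    )

    targets = list(reference) + list(predicted) + list(contaminants)
    decoys = generate_decoys(targets, prefix=cfg.decoy_prefix)
    return targets + decoys, report
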