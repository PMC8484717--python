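"""Peptide-level summaries, neuropeptide annotation and method comparison.

Rescored PSM tables are collapsed to unique peptidoforms (sequence plus
modifications by default), filtered at a strict q-value threshold, annotated
against a neuropeptide reference table by bidirectional sequence containment
(which captures the truncation ladders produced by endogenous proteolytic
processing), and compared across identification methods by exact set
arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PeptideGroup",
    "NeuropepEntry",
    "MethodComparison",
    "group_peptides",
    "annotate_neuropeptides",
    "compare_methods",
    "precursor_totals",
    "read_neuropep_table",
    "write_peptide_summary",
]


@dataclass
class PeptideGroup:
    """A unique peptidoform aggregated over its supporting PSMs."""

    sequence: str
    mods: str
    psm_ids: list[str]
    samples: set[str]
    replicates: set[str]
    best_q: float
    protein_ids: set[str]
    neuropeptide_names: set[str] = field(default_factory=set)
    families: set[str] = field(default_factory=set)
    precursor_only: bool = False

    @property
    def psm_count(self) -> int:
        return len(self.psm_ids)

    @property
    def key(self) -> tuple[str, str]:
        return (self.sequence, self.mods)


@dataclass(frozen=True)
class NeuropepEntry:
    """One mature-neuropeptide row of the reference table."""

    precursor_name: str
    precursor_accession: str
    neuropeptide_name: str
    family: str
    mature_sequence: str

    def __post_init__(self) -> None:
        if not self.mature_sequence:
            raise ValueError(
                f"empty mature sequence for {self.neuropeptide_name!r}")


def group_peptides(
    psms: pd.DataFrame,
    q_threshold: float = 0.01,
    key_mods: bool = True,
) -> list[PeptideGroup]:
    """Group passing target PSMs into unique peptidoforms.

    Decoys are excluded and the q filter is strict (q < threshold). With
    ``key_mods`` the grouping key is (sequence, mods); without it, sequence
    alone (modified forms collapse).
    """
    passing = psms[(~psms["is_decoy"]) & (psms["q_value"] < q_threshold)]
    groups: dict[tuple[str, str], PeptideGroup] = {}
    for row in passing.itertuples(index=False):
        mods = str(getattr(row, "mods", "") or "")
        key = (row.sequence, mods if key_mods else "")
        g = groups.get(key)
        if g is None:
            g = PeptideGroup(
                sequence=row.sequence, mods=key[1], psm_ids=[],
                samples=set(), replicates=set(), best_q=float("inf"),
                protein_ids=set(),
            )
            groups[key] = g
        g.psm_ids.append(str(row.psm_id))
        g.samples.add(str(row.sample_id))
        g.replicates.add(str(row.replicate_id))
        g.best_q = min(g.best_q, float(row.q_value))
        prots = str(getattr(row, "protein_ids", "") or "")
        g.protein_ids.update(p for p in prots.split(",") if p)
    return list(groups.values())


def annotate_neuropeptides(
    groups: Sequence[PeptideGroup],
    reference: Sequence[NeuropepEntry],
    precursor_seqs: Mapping[str, str] | None = None,
) -> dict:
    """Annotate peptide groups against a neuropeptide reference.

    A group matches an entry iff either sequence contains the other
    (truncated mature forms and extended intermediates both count). Groups
    that match no mature entry but lie within a known precursor protein are
    flagged precursor-only. Returns summary counts; groups are annotated in
    place.
    """
    precursor_seqs = precursor_seqs or {}
    matched_names: set[str] = set()
    families: set[str] = set()
    n_precursor_only = 0
    for g in groups:
        g.neuropeptide_names = set()
        g.families = set()
        g.precursor_only = False
        for entry in reference:
            if g.sequence in entry.mature_sequence or \
                    entry.mature_sequence in g.sequence:
                g.neuropeptide_names.add(entry.neuropeptide_name)
                g.families.add(entry.family)
        if g.neuropeptide_names:
            matched_names.update(g.neuropeptide_names)
            families.update(g.families)
        elif any(g.sequence in seq for seq in precursor_seqs.values()):
            g.precursor_only = True
            n_precursor_only += 1
    return {
        "n_neuropeptides": len(matched_names),
        "n_families": len(families),
        "n_precursor_only": n_precursor_only,
        "n_matched_groups": sum(1 for g in groups if g.neuropeptide_names),
    }


@dataclass(frozen=True)
class MethodComparison:
    """Exact set arithmetic between two identification sets."""

    both: frozenset
    only_a: frozenset
    only_b: frozenset

    @property
    def union(self) -> frozenset:
        return self.both | self.only_a | self.only_b

    def counts(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "only_a": len(self.only_a),
            "only_b": len(self.only_b),
            "union": len(self.union),
        }


def compare_methods(
    set_a: Iterable[Hashable], set_b: Iterable[Hashable]
) -> MethodComparison:
    a, b = set(set_a), set(set_b)
    return MethodComparison(
        both=frozenset(a & b),
        only_a=frozenset(a - b),
        only_b=frozenset(b - a),
    )


def precursor_totals(
    matched_count: int, additional_counts: Mapping[str, int] | None = None
) -> dict:
    """Total precursor-linked peptides with the per-source breakdown kept."""
    additional_counts = dict(additional_counts or {})
    if matched_count < 0 or any(v < 0 for v in additional_counts.values()):
        raise ValueError("counts must be non-negative")
    return {
        "matched": matched_count,
        "additional": additional_counts,
        "total": matched_count + sum(additional_counts.values()),
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_neuropep_table(path: str) -> list[NeuropepEntry]:
    """Read a neuropeptide reference TSV.

    Columns: precursor_name, accession, neuropeptide_name, family, sequence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        NeuropepEntry(
            precursor_name=row.precursor_name,
            precursor_accession=row.accession,
            neuropeptide_name=row.neuropeptide_name,
            family=row.family,
            mature_sequence=row.sequence,
        )
        for row in df.itertuples(index=False)
    ]


def write_peptide_summary(
    groups: Sequence[PeptideGroup], tsv_path: str,
    summary: dict | None = None, json_path: str | None = None,
) -> pd.DataFrame:
    """Write one row per peptide group plus an optional JSON summary."""
    samples = sorted({s for g in groups for s in g.samples})
    rows = []
    for g in sorted(groups, key=lambda g: g.key):
        row = {
            "sequence": g.sequence,
            "mods": g.mods,
            "psm_count": g.psm_count,
            "n_replicates": len(g.replicates),
            "best_q": g.best_q,
            "protein_ids": ",".join(sorted(g.protein_ids)),
            "neuropeptides": ",".join(sorted(g.neuropeptide_names)),
            "families": ",".join(sorted(g.families)),
            "precursor_only": int(g.precursor_only),
        }
        for s in samples:
            row[f"in_{s}"] = int(s in g.samples)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {"n_peptides": len(groups)}
        payload.update(summary or {})
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
    return df
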