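"""Database-construction stages against brute-force oracles."""

import itertools

import numpy as np
import pytest

from pepsieve import fasta_db, fixtures
from pepsieve.fasta_db import (
    BuildConfig,
    CompositionReport,
    ExonInterval,
    Locus,
    SeqRecord,
    Source,
    build_database,
    compute_composition,
    dedupe_identical,
    drop_single_exon_coding_overlaps,
    exclude_reference_identical,
    generate_decoys,
    read_fasta,
    select_longest_per_stop,
    write_fasta,
)

from conftest import make_locus, make_record, random_sequence


class TestReadFasta:
    def test_single_entry(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">sp|P1|X some description\nMKV\n")
        recs = read_fasta(str(p), Source.REFERENCE)
        assert len(recs) == 1
        assert recs[0].id == "sp|P1|X"
        assert recs[0].sequence == "MKV"
        assert "some description" in recs[0].description

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        assert read_fasta(str(p), Source.REFERENCE) == []

    def test_lowercase_normalized(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\nmkv\n")
        assert read_fasta(str(p), Source.OPENPROT)[0].sequence == "MKV"

    def test_empty_sequence_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\n>y\nMK\n")
        with pytest.raises(ValueError, match="empty sequence"):
            read_fasta(str(p), Source.REFERENCE)

    def test_multiline_sequence_joined(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\nMKV\nLEG\n")
        assert read_fasta(str(p), Source.REFERENCE)[0].sequence == "MKVLEG"


class TestLocus:
    def test_stop_coord_plus_strand(self):
        loc = Locus("chr1", "+", ((10, 40), (60, 100)))
        assert loc.stop_coord == 99

    def test_stop_coord_minus_strand(self):
        loc = Locus("chr1", "-", ((10, 40), (60, 100)))
        assert loc.stop_coord == 10

    @pytest.mark.parametrize("blocks", [((40, 10),), ((10, 40), (30, 60)), ()])
    def test_invalid_blocks_rejected(self, blocks):
        with pytest.raises(ValueError):
            Locus("chr1", "+", blocks)


class TestSelectLongestPerStop:
    def test_longest_wins(self):
        short = make_record("a", "A" * 30, locus=make_locus("chr1", "+", ((910, 1000),)))
        long_ = make_record("b", "A" * 45, locus=make_locus("chr1", "+", ((865, 1000),)))
        out = select_longest_per_stop([short, long_])
        assert [r.id for r in out] == ["b"]

    def test_distinct_stops_all_retained(self):
        recs = [
            make_record(f"r{i}", "M" * (10 + i),
                        locus=make_locus(blocks=((i * 100, i * 100 + 33),)))
            for i in range(4)
        ]
        assert select_longest_per_stop(recs) == recs

    def test_missing_locus_reported(self):
        rec = make_record("nolocus", "MKV")
        with pytest.raises(ValueError, match="nolocus"):
            select_longest_per_stop([rec])

    def test_matches_brute_force_groupby(self, rng):
        stops = [int(s) for s in rng.integers(0, 10, size=50)]
        recs = []
        for i, stop in enumerate(stops):
            length = int(rng.integers(10, 40))
            start = stop * 1000
            recs.append(make_record(
                f"r{i:02d}", random_sequence(rng, length),
                locus=make_locus("chrX", "+", ((start, start + 99),))))
        got = {r.id for r in select_longest_per_stop(recs)}

        expected = set()
        keyfn = lambda r: (r.locus.chrom, r.locus.strand, r.locus.stop_coord)
        for _, group in itertools.groupby(sorted(recs, key=keyfn), key=keyfn):
            group = list(group)
            best = min(group, key=lambda r: (-len(r.sequence), r.sequence, r.id))
            expected.add(best.id)
        assert got == expected

    def test_survivor_is_group_maximum(self, rng):
        recs = [
            make_record(f"r{i}", random_sequence(rng, int(rng.integers(8, 30))),
                        locus=make_locus(blocks=((int(s) * 50, int(s) * 50 + 40),)))
            for i, s in enumerate(rng.integers(0, 5, size=30))
        ]
        out = select_longest_per_stop(recs)
        keys = [(r.locus.chrom, r.locus.strand, r.locus.stop_coord) for r in out]
        assert len(keys) == len(set(keys))
        by_key = {}
        for r in recs:
            k = (r.locus.chrom, r.locus.strand, r.locus.stop_coord)
            by_key.setdefault(k, []).append(len(r.sequence))
        for r in out:
            k = (r.locus.chrom, r.locus.strand, r.locus.stop_coord)
            assert len(r.sequence) == max(by_key[k])


class TestDropSingleExonOverlaps:
    exon = ExonInterval("chr1", 100, 200, "+")

    def test_single_block_inside_exon_removed(self):
        rec = make_record("s", "M" * 10,
                          locus=make_locus("chr1", "+", ((120, 180),)))
        assert drop_single_exon_coding_overlaps([rec], [self.exon]) == []

    def test_two_block_overlap_retained(self):
        rec = make_record("s", "M" * 10,
                          locus=make_locus("chr1", "+", ((120, 180), (300, 350))))
        assert drop_single_exon_coding_overlaps([rec], [self.exon]) == [rec]

    def test_opposite_strand_retained(self):
        rec = make_record("s", "M" * 10,
                          locus=make_locus("chr1", "-", ((120, 180),)))
        assert drop_single_exon_coding_overlaps([rec], [self.exon]) == [rec]

    def test_empty_exons_no_removals(self):
        rec = make_record("s", "M" * 10,
                          locus=make_locus("chr1", "+", ((120, 180),)))
        assert drop_single_exon_coding_overlaps([rec], []) == [rec]

    def test_matches_interval_scan_oracle(self, rng):
        exons = [
            ExonInterval("chr1", int(s), int(s) + int(rng.integers(50, 300)),
                         "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(0, 20_000, size=20)
        ]
        sorfs = []
        for i in range(100):
            start = int(rng.integers(0, 20_000))
            n_blocks = 1 if rng.random() < 0.6 else 2
            blocks = [(start, start + int(rng.integers(30, 400)))]
            if n_blocks == 2:
                b2 = blocks[0][1] + 50
                blocks.append((b2, b2 + 100))
            sorfs.append(make_record(
                f"s{i}", "M" * 10,
                locus=make_locus("chr1", "+" if rng.random() < 0.5 else "-",
                                 tuple(blocks))))
        got = {r.id for r in drop_single_exon_coding_overlaps(sorfs, exons)}

        expected = set()
        for r in sorfs:
            if r.locus.n_blocks != 1:
                expected.add(r.id)
                continue
            s, e = r.locus.blocks[0]
            hit = any(
                ex.chrom == r.locus.chrom and ex.strand == r.locus.strand
                and s < ex.end and ex.start < e
                for ex in exons)
            if not hit:
                expected.add(r.id)
        assert got == expected


class TestDedupeIdentical:
    def test_source_precedence(self):
        a = make_record("op1", "MKVLE", source=Source.OPENPROT)
        b = make_record("so1", "MKVLE", source=Source.SORFS_ORG)
        out, merge_map = dedupe_identical([b, a])
        assert [r.id for r in out] == ["op1"]
        assert merge_map == {"op1": ["so1"]}
        assert "so1" in out[0].description

    def test_distinct_input_unchanged(self):
        recs = [make_record(f"r{i}", "M" * (5 + i)) for i in range(4)]
        out, merge_map = dedupe_identical(recs)
        assert out == recs
        assert merge_map == {}

    def test_planted_duplicates_match_set_cardinality(self, rng):
        base = [random_sequence(rng, 12) for _ in range(30)]
        seqs = base + [base[i] for i in rng.integers(0, 30, size=15)]
        recs = [make_record(f"r{i:02d}", s) for i, s in enumerate(seqs)]
        out, _ = dedupe_identical(recs)
        assert len(out) == len(set(seqs))

    def test_idempotent(self, rng):
        seqs = [random_sequence(rng, 10) for _ in range(10)] * 2
        recs = [make_record(f"r{i}", s) for i, s in enumerate(seqs)]
        once, _ = dedupe_identical(recs)
        twice, merge_map = dedupe_identical(once)
        assert twice == once
        assert merge_map == {}


class TestExcludeReferenceIdentical:
    def test_exact_match_removed(self):
        pred = [make_record("p", "MKVLE", source=Source.OPENPROT)]
        ref = [make_record("r", "MKVLE", source=Source.REFERENCE)]
        assert exclude_reference_identical(pred, ref) == []

    def test_substring_retained_by_default(self):
        pred = [make_record("p", "KVL", source=Source.OPENPROT)]
        ref = [make_record("r", "MKVLE", source=Source.REFERENCE)]
        assert exclude_reference_identical(pred, ref) == pred
        assert exclude_reference_identical(pred, ref, remove_contained=True) == []

    def test_set_difference_oracle(self, rng):
        ref_seqs = {random_sequence(rng, 10) for _ in range(20)}
        pred_seqs = {random_sequence(rng, 10) for _ in range(20)} | set(
            list(ref_seqs)[:5])
        pred = [make_record(f"p{i}", s, source=Source.OPENPROT)
                for i, s in enumerate(sorted(pred_seqs))]
        ref = [make_record(f"r{i}", s, source=Source.REFERENCE)
               for i, s in enumerate(sorted(ref_seqs))]
        out = exclude_reference_identical(pred, ref)
        assert {r.sequence for r in out} == pred_seqs - ref_seqs


class TestGenerateDecoys:
    def test_reversal(self):
        rec = make_record("t", "MKVLE")
        (decoy,) = generate_decoys([rec])
        assert decoy.sequence == "ELVKM"
        assert decoy.id == "DECOY_t"
        assert decoy.source == Source.DECOY

    def test_palindromic_single_residue(self):
        (decoy,) = generate_decoys([make_record("t", "M")])
        assert decoy.sequence == "M"

    def test_involution(self, rng):
        recs = [make_record(f"t{i}", random_sequence(rng, 12))
                for i in range(20)]
        decoys = generate_decoys(recs)
        re_reversed = [d.sequence[::-1] for d in decoys]
        assert re_reversed == [r.sequence for r in recs]

    def test_existing_prefix_rejected(self):
        with pytest.raises(ValueError, match="DECOY_"):
            generate_decoys([make_record("DECOY_x", "MK")])


class TestComputeComposition:
    def test_figure_scale_cells(self):
        """Database composition at the published full-database scale."""
        cells = {"O_only": 309463, "OS": 32106, "S_only": 113446,
                 "R_only": 51995, "RO": 16430, "RS": 11744, "ROS": 11346}
        r, o, s = _sets_from_cells(cells)
        rep = compute_composition(r, o, s)
        assert rep.total == 546530
        assert rep.cells() == cells
        assert rep.pct_proteogenomics_only == 83.3
        assert rep.pct_reference_only == 9.5
        assert rep.pct_reference_overlap == 7.2

    def test_identical_sets_all_ros(self, rng):
        seqs = [random_sequence(rng, 10) for _ in range(7)]
        rep = compute_composition(seqs, seqs, seqs)
        assert rep.ros == 7
        assert rep.total == 7
        assert sum(rep.cells().values()) == 7

    def test_empty_input(self):
        rep = compute_composition([], [], [])
        assert rep.total == 0
        assert rep.pct_proteogenomics_only is None

    def test_membership_oracle(self, rng):
        pool = [random_sequence(rng, 8) for _ in range(40)]
        r = {pool[i] for i in rng.integers(0, 40, size=20)}
        o = {pool[i] for i in rng.integers(0, 40, size=20)}
        s = {pool[i] for i in rng.integers(0, 40, size=20)}
        rep = compute_composition(r, o, s)
        oracle = {"R_only": 0, "O_only": 0, "S_only": 0, "RO": 0, "RS": 0,
                  "OS": 0, "ROS": 0}
        for seq in r | o | s:
            key = "".join(c for c, inside in
                          (("R", seq in r), ("O", seq in o), ("S", seq in s))
                          if inside)
            oracle[{"R": "R_only", "O": "O_only", "S": "S_only"}.get(key, key)] += 1
        assert rep.cells() == oracle
        assert rep.total == sum(oracle.values())

    def test_percentages_sum_to_100(self, rng):
        pool = [random_sequence(rng, 8) for _ in range(60)]
        rep = compute_composition(pool[:30], pool[20:50], pool[40:])
        total_pct = (rep.pct_proteogenomics_only + rep.pct_reference_only
                     + rep.pct_reference_overlap)
        assert abs(total_pct - 100.0) <= 0.2


def _sets_from_cells(cells):
    """Materialize token sequence sets realizing exact Venn-cell counts."""
    r, o, s = [], [], []
    i = 0
    membership = {"R_only": "R", "O_only": "O", "S_only": "S",
                  "RO": "RO", "RS": "RS", "OS": "OS", "ROS": "ROS"}
    for cell, parts in membership.items():
        for _ in range(cells[cell]):
            token = f"SEQTOKEN{i}"
            if "R" in parts:
                r.append(token)
            if "O" in parts:
                o.append(token)
            if "S" in parts:
                s.append(token)
            i += 1
    return r, o, s


class TestBuildDatabase:
    def test_fixture_bookkeeping(self, sim_config):
        sim = fixtures.simulate_proteome(sim_config)
        sorfs = fixtures.simulate_sorf_predictions(sim_config)
        contaminants = [make_record("crap1", "KKKKKKHHHH",
                                    source=Source.CONTAMINANT)]
        records, rep = build_database(
            sim["reference"], sim["openprot"],
            sim["sorfs_org"] + sorfs["records"],
            contaminants, sorfs["coding_exons"])
        targets = [r for r in records if r.source != Source.DECOY]
        decoys = [r for r in records if r.source == Source.DECOY]
        assert len(decoys) == len(targets)
        target_seqs = {r.sequence for r in targets}
        assert len(target_seqs) == len(targets)  # fully deduplicated

    def test_empty_predicted_sets(self):
        ref = [make_record("sp|P1|X", "MKVLE", source=Source.REFERENCE)]
        crap = [make_record("c1", "HHHH", source=Source.CONTAMINANT)]
        records, rep = build_database(ref, [], [], crap)
        assert [r.id for r in records] == ["sp|P1|X", "c1", "DECOY_sp|P1|X",
                                           "DECOY_c1"]
        assert rep.total == 1

    def test_rebuild_is_fixed_point(self, sim_config):
        sim = fixtures.simulate_proteome(sim_config)
        records, _ = build_database(
            sim["reference"], sim["openprot"], sim["sorfs_org"], [])
        targets = [r for r in records if r.source != Source.DECOY]
        ref2 = [r for r in targets if r.source == Source.REFERENCE]
        op2 = [r for r in targets if r.source == Source.OPENPROT]
        so2 = [r for r in targets if r.source == Source.SORFS_ORG]
        records2, _ = build_database(ref2, op2, so2, [])
        assert sorted(r.sequence for r in records2) == \
            sorted(r.sequence for r in records)


class TestFastaRoundTrip:
    def test_write_read_lossless(self, tmp_path, rng):
        recs = [
            make_record(f"id{i}", random_sequence(rng, int(rng.integers(5, 200))),
                        source=Source.OPENPROT)
            for i in range(10)
        ]
        path = tmp_path / "db.fa"
        write_fasta(recs, str(path))
        back = read_fasta(str(path), Source.OPENPROT)
        assert [r.sequence for r in back] == [r.sequence for r in recs]
        assert [r.id.split("|")[1] for r in back] == [r.id for r in recs]

    def test_wrap_width(self, tmp_path):
        write_fasta([make_record("x", "A" * 130)], str(tmp_path / "w.fa"))
        lines = (tmp_path / "w.fa").read_text().splitlines()
        assert [len(l) for l in lines[1:]] == [60, 60, 10]
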