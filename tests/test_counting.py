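"""Strand-specific junction/site counting over SAM input."""

from __future__ import annotations

import random

import pytest

from intronpsi import (
    AlignmentBlocks,
    AnnotationIndex,
    CountingConfig,
    CountsTable,
    Junction,
    classify_and_increment,
    count_file,
)
from intronpsi.counting import ANNOTATED, OPPOSITE, STATUS_NOVEL

from conftest import FIXTURE_PROTOCOL, TWELVE_READ_SAM
import _oracle

CFG = CountingConfig(protocol=FIXTURE_PROTOCOL)


def count_text(tmp_path, text, index, config=CFG):
    path = tmp_path / "reads.sam"
    path.write_text(text)
    return count_file(path, index, config)


def sam(records, chrom="chr1", ln=1000):
    body = "\n".join(
        f"{name}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*{tags}"
        for name, flag, pos, mapq, cigar, tags in records
    )
    header = f"@HD\tVN:1.6\n@SQ\tSN:{chrom}\tLN:{ln}"
    return header + ("\n" + body if body else "") + "\n"


class TestTwelveReadFixture:
    """The hand-ledgered fixture: five integers and their strand split."""

    def test_exact_counts(self, tmp_path, shared_donor_index):
        table = count_text(tmp_path, TWELVE_READ_SAM, shared_donor_index)
        assert table.junction_counts[("chr1", 201, 300, "+")] == [3, 2]
        assert table.junction_counts[("chr1", 201, 500, "+")] == [1, 0]
        assert table.site_counts[("chr1", 201, "+", "donor")] == [4, 0]
        assert table.read_totals["junction_spanning"] == 6
        assert table.read_totals["genomic"] == 6
        assert table.read_totals["mapped"] == 12
        assert table.junction_status[("chr1", 201, 300, "+")] == "annotated"

    def test_matches_naive_recount(self, tmp_path, shared_donor_index):
        table = count_text(tmp_path, TWELVE_READ_SAM, shared_donor_index)
        introns = {(j.chrom, j.left, j.right, j.strand) for j in shared_donor_index.introns}
        sites = [
            (s.chrom, s.pos, s.strand, s.kind) for s in shared_donor_index.all_sites()
        ]
        junctions, site_counts, totals = _oracle.naive_count(
            TWELVE_READ_SAM, introns, sites, FIXTURE_PROTOCOL
        )
        assert junctions == table._nonzero_junctions()
        assert site_counts == table._nonzero_sites()
        for k, v in totals.items():
            assert table.read_totals[k] == v

    def test_overhang_filter_reclassifies_read_as_genomic(self, tmp_path, shared_donor_index):
        """Read j4 has a 5-base left anchor; raising min_overhang above it
        discards its gap, and the read is recounted as genomic (its blocks
        straddle no boundary, so no site counter moves)."""
        strict = CountingConfig(protocol=FIXTURE_PROTOCOL, min_overhang=6)
        table = count_text(tmp_path, TWELVE_READ_SAM, shared_donor_index, strict)
        assert ("chr1", 201, 500, "+") not in table.junction_counts
        assert table.junction_counts[("chr1", 201, 300, "+")] == [3, 2]
        assert table.read_totals["junction_spanning"] == 5
        assert table.read_totals["genomic"] == 7
        assert table.site_counts[("chr1", 201, "+", "donor")] == [4, 0]


class TestCountFile:
    def test_empty_sam(self, tmp_path, shared_donor_index):
        table = count_text(tmp_path, sam([]), shared_donor_index)
        assert not table.junction_counts and not table.site_counts
        assert all(v == 0 for v in table.read_totals.values())

    def test_record_order_invariance(self, tmp_path, shared_donor_index):
        lines = TWELVE_READ_SAM.strip().split("\n")
        header, body = lines[:2], lines[2:]
        random.Random(11).shuffle(body)
        shuffled = "\n".join(header + body) + "\n"
        a = count_text(tmp_path, TWELVE_READ_SAM, shared_donor_index)
        b = count_text(tmp_path, shuffled, shared_donor_index)
        assert a == b

    def test_strand_swap_exactly_swaps_categories(self, tmp_path, shared_donor_index):
        fwd = count_text(
            tmp_path, TWELVE_READ_SAM, shared_donor_index,
            CountingConfig(protocol="fr-secondstrand"),
        )
        rev = count_text(
            tmp_path, TWELVE_READ_SAM, shared_donor_index,
            CountingConfig(protocol="fr-firststrand"),
        )
        for key, (ann, opp) in fwd.junction_counts.items():
            assert rev.junction_counts[key] == [opp, ann]
        for key, (ann, opp) in fwd.site_counts.items():
            assert rev.site_counts[key] == [opp, ann]

    def test_multi_junction_read_increments_each_counter_once(self, tmp_path):
        # two 100-base introns separated by a 10-base exon
        index = AnnotationIndex(
            [Junction("chr1", 111, 210, "+"), Junction("chr1", 221, 320, "+")]
        )
        text = sam([("m1", 0, 101, 50, "10M100N10M100N10M", "\tNH:i:1")])
        table = count_text(tmp_path, text, index)
        assert table.junction_counts[("chr1", 111, 210, "+")] == [1, 0]
        assert table.junction_counts[("chr1", 221, 320, "+")] == [1, 0]
        assert table.read_totals["junction_spanning"] == 1
        assert table.total() == 2  # one read, two incidences

    def test_conservation_of_incidences(self, tmp_path, shared_donor_index):
        table = count_text(tmp_path, TWELVE_READ_SAM, shared_donor_index)
        # 6 junction reads x 1 surviving gap each
        assert table.total() == 6

    @pytest.mark.parametrize(
        "flag", [4, 256, 2048, 512, 1024]  # unmapped/secondary/suppl/qcfail/dup
    )
    def test_flag_filters(self, tmp_path, shared_donor_index, flag):
        text = sam([("r1", flag, 181, 50, "20M100N20M", "\tNH:i:1")])
        table = count_text(tmp_path, text, shared_donor_index)
        assert table.read_totals["filtered"] == 1
        assert not table.junction_counts

    def test_multimapper_filters(self, tmp_path, shared_donor_index):
        text = sam(
            [
                ("nh2", 0, 181, 50, "20M100N20M", "\tNH:i:2"),
                ("mapq0", 0, 181, 0, "20M100N20M", ""),
                ("ok", 0, 181, 50, "20M100N20M", ""),  # MAPQ passes, no NH
            ]
        )
        table = count_text(tmp_path, text, shared_donor_index)
        assert table.read_totals["filtered"] == 2
        assert table.junction_counts[("chr1", 201, 300, "+")] == [1, 0]

    def test_novel_junction_is_counted_with_status(self, tmp_path, shared_donor_index):
        # gap [201,450] shares the annotated donor at 201 but lands at an
        # unannotated acceptor: counted, flagged novel, strand inferred
        # from the annotated donor
        text = sam([("nv", 16, 181, 50, "20M250N20M", "\tNH:i:1")])
        table = count_text(tmp_path, text, shared_donor_index)
        key = ("chr1", 201, 450, "+")
        assert table.junction_counts[key] == [0, 1]  # read is '-' vs site '+'
        assert table.junction_status[key] == STATUS_NOVEL

    def test_gap_on_unannotated_chrom_counts_no_sites(self, tmp_path, shared_donor_index):
        text = (
            "@HD\tVN:1.6\n@SQ\tSN:chrU\tLN:1000\n"
            "u1\t0\tchrU\t181\t50\t20M100N20M\t*\t0\t0\t*\t*\tNH:i:1\n"
            "u2\t0\tchrU\t100\t50\t50M\t*\t0\t0\t*\t*\tNH:i:1\n"
        )
        table = count_text(tmp_path, text, shared_donor_index)
        assert table.junction_counts[("chrU", 201, 300, "+")] == [1, 0]
        assert table.junction_status[("chrU", 201, 300, "+")] == STATUS_NOVEL
        assert not table.site_counts

    def test_malformed_cigar_counted_not_fatal(self, tmp_path, shared_donor_index):
        text = sam(
            [
                ("bad", 0, 181, 50, "20M100N", "\tNH:i:1"),
                ("ok", 0, 181, 50, "20M100N20M", "\tNH:i:1"),
            ]
        )
        table = count_text(tmp_path, text, shared_donor_index)
        assert table.read_totals["malformed"] == 1
        assert table.junction_counts[("chr1", 201, 300, "+")] == [1, 0]

    def test_unsorted_input_rejected_when_required(self, tmp_path, shared_donor_index):
        text = sam(
            [
                ("r1", 0, 191, 50, "20M", "\tNH:i:1"),
                ("r2", 0, 100, 50, "20M", "\tNH:i:1"),
            ]
        )
        path = tmp_path / "unsorted.sam"
        path.write_text(text)
        cfg = CountingConfig(protocol=FIXTURE_PROTOCOL, require_sorted=True)
        with pytest.raises(ValueError, match="not coordinate-sorted"):
            count_file(path, shared_donor_index, cfg)


class TestClassifyAndIncrement:
    def test_genomic_block_straddling_donor_opposite_strand(self, shared_donor_index):
        table = CountsTable()
        aln = AlignmentBlocks("r", "chr1", [(180, 220)], [], "-")
        classify_and_increment(aln, shared_donor_index, table)
        assert table.site_counts[("chr1", 201, "+", "donor")] == [0, 1]

    @pytest.mark.parametrize(
        "block,hit",
        [
            ((180, 200), False),  # ends on the last exonic base: no straddle
            ((201, 240), False),  # starts on the first intronic base
            ((180, 201), True),
            ((200, 240), True),
        ],
    )
    def test_straddle_requires_both_boundary_bases(self, shared_donor_index, block, hit):
        table = CountsTable()
        aln = AlignmentBlocks("r", "chr1", [block], [], "+")
        classify_and_increment(aln, shared_donor_index, table)
        assert (("chr1", 201, "+", "donor") in table.site_counts) == hit

    def test_min_flank_widens_required_overlap(self, shared_donor_index):
        cfg = CountingConfig(protocol=FIXTURE_PROTOCOL, min_flank=5)
        table = CountsTable()
        # covers 4 exonic bases only: fails at min_flank=5
        classify_and_increment(
            AlignmentBlocks("r", "chr1", [(197, 230)], [], "+"),
            shared_donor_index, table, cfg,
        )
        assert ("chr1", 201, "+", "donor") not in table.site_counts
        classify_and_increment(
            AlignmentBlocks("r2", "chr1", [(196, 230)], [], "+"),
            shared_donor_index, table, cfg,
        )
        assert table.site_counts[("chr1", 201, "+", "donor")] == [1, 0]

    def test_one_read_counts_each_site_once(self, shared_donor_index):
        # block spans the whole first intron: straddles donor 201 and
        # acceptor 300, each once
        table = CountsTable()
        aln = AlignmentBlocks("r", "chr1", [(190, 310)], [], "+")
        classify_and_increment(aln, shared_donor_index, table)
        assert table.site_counts[("chr1", 201, "+", "donor")] == [1, 0]
        assert table.site_counts[("chr1", 300, "+", "acceptor")] == [1, 0]
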