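"""Strand-specific splice-junction and splice-site read counting.

A single pass over a BAM/SAM file accumulates, per intron (D, A) and per
splice site, the five integers the indices are built from:

* ``n(D, A)`` — reads whose alignment skips exactly the intron [D, A]
  via a CIGAR ``N`` operation (the ``xMyNzM`` pattern);
* the donor margin ``sum_A n(D, A)`` and acceptor margin ``sum_D n(D, A)``
  (derived, not stored);
* the genomic counts at D and at A — reads with no counted gap whose
  alignment block straddles the exon-intron boundary, i.e. evidence of
  unspliced molecules.

Every count is kept separately for reads whose protocol-corrected
orientation matches the annotated strand ("annotated") and for reads on
the opposite strand ("opposite").
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import pandas as pd

from .annotation import ACCEPTOR, DONOR, AnnotationIndex, Junction, SpliceSite

log = logging.getLogger(__name__)

ANNOTATED = "annotated"
OPPOSITE = "opposite"
CATEGORIES = (ANNOTATED, OPPOSITE)

STATUS_ANNOTATED = "annotated"
STATUS_NOVEL = "novel"

#: protocol spellings -> canonical value
_PROTOCOLS = {
    "unstranded": "unstranded",
    "fr-firststrand": "fr-firststrand",
    "reverse-first": "fr-firststrand",
    "fr-secondstrand": "fr-secondstrand",
    "forward-first": "fr-secondstrand",
}

_CIGAR_FULL_RE = re.compile(r"^(?:\d+[MIDNSHP=X])+$")
_CIGAR_OP_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# pysam cigartuples op integer -> op character (B is unsupported)
_PYSAM_OPS = "MIDNSHP=XB"


class MalformedCigar(ValueError):
    """CIGAR that cannot be interpreted for junction counting."""


def _walk(ops: Iterable[tuple[str, int]], pos: int):
    """Walk reference-consuming CIGAR ops from 1-based ``pos``.

    Returns (blocks, gaps): closed 1-based reference intervals.  M/=/X and
    D advance within the current block; N closes it and opens a gap;
    I/S/H/P consume no reference.  A gap with an empty block on either
    side (CIGAR starting/ending with N, or NN) is malformed.
    """
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    block_start = pos
    ref = pos
    for op, length in ops:
        if length <= 0:
            raise MalformedCigar(f"non-positive CIGAR length {length}{op}")
        if op in "M=XD":
            ref += length
        elif op == "N":
            if ref == block_start:
                raise MalformedCigar("N operation not flanked by aligned bases")
            blocks.append((block_start, ref - 1))
            gaps.append((ref, ref + length - 1))
            ref += length
            block_start = ref
        elif op in "ISHP":
            pass
        else:
            raise MalformedCigar(f"unsupported CIGAR operation {op!r}")
    if ref == block_start:
        raise MalformedCigar("CIGAR ends with N or consumes no reference")
    blocks.append((block_start, ref - 1))
    return blocks, gaps


def parse_cigar(cigar: str, pos: int) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Parse a CIGAR string into alignment blocks and N gaps.

    >>> parse_cigar("20M100N30M", 1)
    ([(1, 20), (121, 150)], [(21, 120)])
    """
    if pos < 1:
        raise ValueError(f"pos must be >= 1, got {pos}")
    if not _CIGAR_FULL_RE.match(cigar):
        raise MalformedCigar(f"cannot parse CIGAR {cigar!r}")
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_OP_RE.finditer(cigar)]
    return _walk(ops, pos)


def read_strand(sam_flags: int, protocol: str) -> str:
    """Protocol-corrected transcript strand of an alignment: '+', '-' or '.'.

    Under fr-secondstrand (forward-first) a forward single-end read comes
    from a + transcript; fr-firststrand (reverse-first, e.g. dUTP) inverts
    that.  For paired-end data the first-in-pair mate defines the
    orientation and the second is flipped.  Unstranded returns '.'.
    """
    proto = _PROTOCOLS.get(protocol)
    if proto is None:
        raise ValueError(f"unknown protocol {protocol!r}")
    if proto == "unstranded":
        return "."
    reverse = bool(sam_flags & 0x10)
    if (sam_flags & 0x1) and (sam_flags & 0x80):  # second in pair
        reverse = not reverse
    if proto == "fr-firststrand":
        reverse = not reverse
    return "-" if reverse else "+"


@dataclass(frozen=True)
class CountingConfig:
    """Filters and protocol for one counting run.

    min_overhang: minimum reference-aligned length on each side of an N
    gap for the gap to be counted (the x, z of xMyNzM); gaps failing it
    are discarded individually, and a read whose every gap is discarded
    is recounted as genomic.

    min_flank: a genomic read overlaps a splice site only if one block
    covers at least this many bases on both sides of the exon-intron
    boundary.

    min_mapq: MAPQ threshold applied when the mapper emits no NH tag;
    with NH present, NH == 1 is required instead.
    """

    protocol: str = "fr-firststrand"
    min_overhang: int = 1
    min_flank: int = 1
    min_mapq: int = 1
    require_sorted: bool = False

    def __post_init__(self) -> None:
        if self.protocol not in _PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.min_overhang < 1 or self.min_flank < 1:
            raise ValueError("min_overhang and min_flank must be >= 1")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


@dataclass
class AlignmentBlocks:
    """One alignment reduced to what counting needs."""

    read_id: str
    chrom: str
    blocks: list[tuple[int, int]]
    gaps: list[tuple[int, int]]  # gaps surviving the overhang filter
    read_strand: str  # '+', '-' or '.' (unknown)
    mapping_ok: bool = True


JunctionKey = tuple[str, int, int, str]  # chrom, left, right, strand
SiteKey = tuple[str, int, str, str]  # chrom, pos, strand, kind

SSJ_COLUMNS = [
    "chrom",
    "donor_pos",
    "acceptor_pos",
    "strand",
    "status",
    "count_annotated_strand",
    "count_opposite_strand",
]
SSC_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "kind",
    "genomic_count_annotated",
    "genomic_count_opposite",
]


class CountsTable:
    """Per-junction and per-site counters, split by strand category."""

    def __init__(self) -> None:
        # key -> [annotated, opposite]
        self.junction_counts: dict[JunctionKey, list[int]] = {}
        self.junction_status: dict[JunctionKey, str] = {}
        self.site_counts: dict[SiteKey, list[int]] = {}
        self.read_totals: dict[str, int] = {
            "records": 0,
            "filtered": 0,
            "mapped": 0,
            "malformed": 0,
            "junction_spanning": 0,
            "genomic": 0,
        }

    # -- increment API -------------------------------------------------
    def add_junction(
        self, key: JunctionKey, category: str, status: str, times: int = 1
    ) -> None:
        counts = self.junction_counts.setdefault(key, [0, 0])
        counts[CATEGORIES.index(category)] += times
        prev = self.junction_status.get(key)
        # annotated status wins if the same key is ever seen as annotated
        if prev is None or (prev == STATUS_NOVEL and status == STATUS_ANNOTATED):
            self.junction_status[key] = status

    def add_site(self, key: SiteKey, category: str, times: int = 1) -> None:
        counts = self.site_counts.setdefault(key, [0, 0])
        counts[CATEGORIES.index(category)] += times

    # -- margins -------------------------------------------------------
    def donor_margin(self, chrom: str, donor_pos: int, strand: str, category: str,
                     include_novel: bool = True) -> int:
        """sum over acceptors A of n(D, A) for the given donor."""
        return self._margin(chrom, donor_pos, strand, category, include_novel, donor=True)

    def acceptor_margin(self, chrom: str, acceptor_pos: int, strand: str, category: str,
                        include_novel: bool = True) -> int:
        """sum over donors D of n(D, A) for the given acceptor."""
        return self._margin(chrom, acceptor_pos, strand, category, include_novel, donor=False)

    def _margin(self, chrom, pos, strand, category, include_novel, donor):
        ci = CATEGORIES.index(category)
        total = 0
        for (c, left, right, s), counts in self.junction_counts.items():
            if c != chrom or s != strand:
                continue
            if not include_novel and self.junction_status[(c, left, right, s)] != STATUS_ANNOTATED:
                continue
            end = (left if s == "+" else right) if donor else (right if s == "+" else left)
            if end == pos:
                total += counts[ci]
        return total

    def site_count(self, key: SiteKey, category: str) -> int:
        counts = self.site_counts.get(key)
        return 0 if counts is None else counts[CATEGORIES.index(category)]

    def junction_count(self, key: JunctionKey, category: str) -> int:
        counts = self.junction_counts.get(key)
        return 0 if counts is None else counts[CATEGORIES.index(category)]

    # -- serialization -------------------------------------------------
    def to_ssj_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.junction_counts):
            chrom, left, right, strand = key
            ann, opp = self.junction_counts[key]
            j = Junction(chrom, left, right, strand)
            rows.append(
                (chrom, j.donor_pos, j.acceptor_pos, strand,
                 self.junction_status[key], ann, opp)
            )
        return pd.DataFrame(rows, columns=SSJ_COLUMNS)

    def to_ssc_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.site_counts):
            chrom, pos, strand, kind = key
            ann, opp = self.site_counts[key]
            rows.append((chrom, pos, strand, kind, ann, opp))
        return pd.DataFrame(rows, columns=SSC_COLUMNS)

    @classmethod
    def from_frames(cls, ssj: pd.DataFrame, ssc: pd.DataFrame) -> "CountsTable":
        for col in SSJ_COLUMNS:
            if col not in ssj.columns:
                raise ValueError(f"SSJ table missing column {col!r}")
        for col in SSC_COLUMNS:
            if col not in ssc.columns:
                raise ValueError(f"SSC table missing column {col!r}")
        table = cls()
        for row in ssj.itertuples(index=False):
            left, right = sorted((int(row.donor_pos), int(row.acceptor_pos)))
            key = (row.chrom, left, right, row.strand)
            table.add_junction(key, ANNOTATED, row.status, int(row.count_annotated_strand))
            table.add_junction(key, OPPOSITE, row.status, int(row.count_opposite_strand))
        for row in ssc.itertuples(index=False):
            key = (row.chrom, int(row.pos), row.strand, row.kind)
            table.add_site(key, ANNOTATED, int(row.genomic_count_annotated))
            table.add_site(key, OPPOSITE, int(row.genomic_count_opposite))
        return table

    # -- comparison ----------------------------------------------------
    def _nonzero_junctions(self):
        return {k: tuple(v) for k, v in self.junction_counts.items() if any(v)}

    def _nonzero_sites(self):
        return {k: tuple(v) for k, v in self.site_counts.items() if any(v)}

    def same_counts(self, other: "CountsTable") -> bool:
        """Field-for-field equality of all nonzero counters."""
        return (
            self._nonzero_junctions() == other._nonzero_junctions()
            and self._nonzero_sites() == other._nonzero_sites()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountsTable):
            return NotImplemented
        return self.same_counts(other) and all(
            self.read_totals[k] == other.read_totals[k]
            for k in ("junction_spanning", "genomic")
        )

    def total(self, category: Optional[str] = None) -> int:
        """Total junction incidences, optionally for one strand category."""
        if category is None:
            return sum(sum(v) for v in self.junction_counts.values())
        ci = CATEGORIES.index(category)
        return sum(v[ci] for v in self.junction_counts.values())


def _category(read_strand: str, annotated_strand: str) -> str:
    # unknown read strand (unstranded protocol) counts as annotated by
    # convention; use merge_strands downstream for unstranded libraries.
    if read_strand == ".":
        return ANNOTATED
    return ANNOTATED if read_strand == annotated_strand else OPPOSITE


def classify_and_increment(
    aln: AlignmentBlocks,
    index: AnnotationIndex,
    table: CountsTable,
    config: CountingConfig = CountingConfig(),
    times: int = 1,
) -> CountsTable:
    """Count one alignment into ``table``.

    Junction-spanning reads (>= 1 surviving gap) increment one junction
    counter per gap — a read spanning k introns increments k counters.
    Reads with no surviving gap are genomic and increment the genomic
    counter of every annotated splice site whose exon-intron boundary one
    of their blocks straddles.
    """
    if not aln.mapping_ok:
        raise ValueError("classify_and_increment requires a filtered-in alignment")
    if aln.gaps:
        table.read_totals["junction_spanning"] += times
        for left, right in aln.gaps:
            strands = index.intron_strands(aln.chrom, left, right)
            if strands:
                if len(strands) == 1:
                    ann_strand = strands[0]
                else:  # annotated on both strands: prefer the read's
                    ann_strand = aln.read_strand if aln.read_strand in strands else strands[0]
                status = STATUS_ANNOTATED
            else:
                ann_strand = _infer_novel_strand(aln, index, left, right)
                status = STATUS_NOVEL
            key = (aln.chrom, left, right, ann_strand)
            table.add_junction(key, _category(aln.read_strand, ann_strand), status, times)
    else:
        table.read_totals["genomic"] += times
        seen: set[SiteKey] = set()
        flank = config.min_flank
        for bstart, bend in aln.blocks:
            for site in index.sites_in_interval(aln.chrom, bstart - flank, bend + flank):
                exonic, intronic = site.boundary_bases()
                lo = min(exonic, intronic) - (flank - 1)
                hi = max(exonic, intronic) + (flank - 1)
                if bstart <= lo and hi <= bend:
                    key = (site.chrom, site.pos, site.strand, site.kind)
                    if key not in seen:
                        seen.add(key)
                        table.add_site(key, _category(aln.read_strand, site.strand), times)
    return table


def _infer_novel_strand(aln: AlignmentBlocks, index: AnnotationIndex,
                        left: int, right: int) -> str:
    """Strand for an unannotated gap: borrow it from an annotated site at
    either gap end if one exists, else fall back to the read strand."""
    candidates = []
    for strand in ("+", "-"):
        j = Junction(aln.chrom, left, right, strand)
        if index.has_site(j.donor_site()) or index.has_site(j.acceptor_site()):
            candidates.append(strand)
    if len(candidates) == 1:
        return candidates[0]
    if len(candidates) == 2 and aln.read_strand in candidates:
        return aln.read_strand
    if candidates:
        return candidates[0]
    return aln.read_strand if aln.read_strand in ("+", "-") else "+"


def _filter_gaps(blocks, gaps, min_overhang):
    """Drop gaps whose flanking blocks are shorter than min_overhang."""
    if not gaps or min_overhang <= 1:
        # blocks flanking a gap are >= 1 by construction
        return gaps
    kept = []
    for i, gap in enumerate(gaps):
        lb = blocks[i]
        rb = blocks[i + 1]
        if (lb[1] - lb[0] + 1) >= min_overhang and (rb[1] - rb[0] + 1) >= min_overhang:
            kept.append(gap)
    return kept


AlignmentSource = Union[str, os.PathLike, "pysam.AlignmentFile", Iterable]


def count_file(
    source: AlignmentSource,
    index: AnnotationIndex,
    config: CountingConfig = CountingConfig(),
) -> CountsTable:
    """Stream a BAM/SAM file once and return the populated CountsTable.

    Records are filtered out if unmapped, secondary, supplementary,
    QC-fail or duplicate, or if they fail the uniqueness rule (NH tag
    present and != 1, or NH absent and MAPQ < min_mapq).  Memory is
    proportional to the annotation plus distinct observed junctions,
    never to the number of reads.
    """
    import pysam

    if isinstance(source, (str, os.PathLike)):
        with pysam.AlignmentFile(str(source), check_sq=False) as fh:
            return _count_records(fh.fetch(until_eof=True), index, config)
    if isinstance(source, pysam.AlignmentFile):
        return _count_records(source.fetch(until_eof=True), index, config)
    return _count_records(source, index, config)


def _count_records(records, index: AnnotationIndex, config: CountingConfig) -> CountsTable:
    table = CountsTable()
    totals = table.read_totals
    last_seen: Optional[tuple[int, int]] = None
    for rec in records:
        totals["records"] += 1
        if (
            rec.is_unmapped
            or rec.is_secondary
            or rec.is_supplementary
            or rec.is_qcfail
            or rec.is_duplicate
        ):
            totals["filtered"] += 1
            continue
        try:
            nh = rec.get_tag("NH")
        except KeyError:
            nh = None
        if nh is not None:
            if nh != 1:
                totals["filtered"] += 1
                continue
        elif rec.mapping_quality < config.min_mapq:
            totals["filtered"] += 1
            continue
        if config.require_sorted:
            here = (rec.reference_id, rec.reference_start)
            if last_seen is not None and here < last_seen:
                raise ValueError(
                    f"input is not coordinate-sorted at {rec.reference_name}:"
                    f"{rec.reference_start + 1} (record {totals['records']})"
                )
            last_seen = here
        totals["mapped"] += 1
        pos = rec.reference_start + 1  # pysam is 0-based
        try:
            ops = [(_PYSAM_OPS[op], length) for op, length in rec.cigartuples or ()]
            blocks, gaps = _walk(ops, pos)
        except (MalformedCigar, IndexError):
            totals["malformed"] += 1
            continue
        gaps = _filter_gaps(blocks, gaps, config.min_overhang)
        aln = AlignmentBlocks(
            read_id=rec.query_name,
            chrom=rec.reference_name,
            blocks=blocks,
            gaps=gaps,
            read_strand=read_strand(rec.flag, config.protocol),
        )
        classify_and_increment(aln, index, table, config)
    return table
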