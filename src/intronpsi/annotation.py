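"""Splice-site and intron annotation derived from GTF exon records.

An intron is identified by its two ends: the donor (5' splice site, the
first intronic base downstream of the upstream exon) and the acceptor
(3' splice site, the last intronic base upstream of the downstream exon).
Both are 1-based genomic coordinates.  On the + strand the donor is
``exon_end + 1`` and the acceptor is ``next_exon_start - 1``; on the -
strand the roles of the two intron ends swap (the donor sits at the
genomic-right end of the intron).

The :class:`AnnotationIndex` holds the deduplicated sets of donors,
acceptors and introns over all transcripts, plus a per-chromosome sorted
position index so that "which splice sites fall in this interval" is a
binary search, not a scan.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Union

log = logging.getLogger(__name__)

DONOR = "donor"
ACCEPTOR = "acceptor"

_STRANDS = ("+", "-")
_KINDS = (DONOR, ACCEPTOR)


@dataclass(frozen=True, order=True)
class SpliceSite:
    """A strand-aware splice site.

    ``pos`` is the first intronic base for a donor and the last intronic
    base for an acceptor, so the exon-intron boundary always lies between
    ``pos`` and one of its genomic neighbours (which one depends on kind
    and strand; see :meth:`boundary_bases`).
    """

    chrom: str
    pos: int
    strand: str
    kind: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"splice site position must be >= 1, got {self.pos}")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be donor or acceptor, got {self.kind!r}")

    def boundary_bases(self) -> tuple[int, int]:
        """The (exonic, intronic) base pair flanking this site's boundary.

        The intronic base is always ``pos``.  A genomic read carries
        evidence of unspliced molecules at this site only if one of its
        alignment blocks covers both bases.
        """
        if (self.kind == DONOR) == (self.strand == "+"):
            return self.pos - 1, self.pos  # exon | intron reading left to right
        return self.pos + 1, self.pos


@dataclass(frozen=True, order=True)
class Junction:
    """An intron stored by its genomic-left/right intronic bases plus strand.

    One canonical key serves both strands: the donor/acceptor roles are
    derived from the strand on demand.
    """

    chrom: str
    left: int
    right: int
    strand: str

    def __post_init__(self) -> None:
        if self.left < 1 or self.right < self.left:
            raise ValueError(
                f"invalid intron span [{self.left},{self.right}] (need 1 <= left <= right)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.right - self.left + 1

    @property
    def donor_pos(self) -> int:
        return self.left if self.strand == "+" else self.right

    @property
    def acceptor_pos(self) -> int:
        return self.right if self.strand == "+" else self.left

    def donor_site(self) -> SpliceSite:
        return SpliceSite(self.chrom, self.donor_pos, self.strand, DONOR)

    def acceptor_site(self) -> SpliceSite:
        return SpliceSite(self.chrom, self.acceptor_pos, self.strand, ACCEPTOR)


class AnnotationIndex:
    """Deduplicated donor/acceptor/intron sets with interval lookup."""

    def __init__(self, introns: Iterable[Junction] = ()) -> None:
        self.introns: set[Junction] = set()
        self.donors: set[SpliceSite] = set()
        self.acceptors: set[SpliceSite] = set()
        self._by_chrom: dict[str, list[SpliceSite]] = {}
        self._positions: dict[str, list[int]] = {}
        self._dirty = False
        self._unknown_chroms_logged: set[str] = set()
        for intron in introns:
            self.add_intron(intron)

    def add_intron(self, intron: Junction) -> None:
        if intron not in self.introns:
            self.introns.add(intron)
            self.donors.add(intron.donor_site())
            self.acceptors.add(intron.acceptor_site())
            self._dirty = True

    def _refresh(self) -> None:
        if not self._dirty:
            return
        by_chrom: dict[str, list[SpliceSite]] = {}
        for site in self.all_sites():
            by_chrom.setdefault(site.chrom, []).append(site)
        for sites in by_chrom.values():
            sites.sort(key=lambda s: (s.pos, s.kind, s.strand))
        self._by_chrom = by_chrom
        self._positions = {c: [s.pos for s in sites] for c, sites in by_chrom.items()}
        self._dirty = False

    def all_sites(self) -> Iterator[SpliceSite]:
        yield from self.donors
        yield from self.acceptors

    def has_intron(self, chrom: str, left: int, right: int, strand: str) -> bool:
        return Junction(chrom, left, right, strand) in self.introns

    def intron_strands(self, chrom: str, left: int, right: int) -> list[str]:
        """Strands on which the intron [left,right] is annotated (0, 1 or 2)."""
        return [s for s in _STRANDS if Junction(chrom, left, right, s) in self.introns]

    def has_site(self, site: SpliceSite) -> bool:
        return site in (self.donors if site.kind == DONOR else self.acceptors)

    def sites_in_interval(
        self,
        chrom: str,
        start: int,
        end: int,
        strand: Optional[str] = None,
    ) -> list[SpliceSite]:
        """All annotated sites with pos in the closed interval [start, end].

        Returned sorted by (pos, kind); unknown chromosomes yield an empty
        list (logged once per chromosome).
        """
        if start > end:
            raise ValueError(f"interval start {start} > end {end}")
        self._refresh()
        if chrom not in self._by_chrom:
            if chrom not in self._unknown_chroms_logged:
                log.debug("chromosome %s absent from annotation", chrom)
                self._unknown_chroms_logged.add(chrom)
            return []
        positions = self._positions[chrom]
        lo = bisect_left(positions, start)
        hi = bisect_right(positions, end)
        sites = self._by_chrom[chrom][lo:hi]
        if strand is not None:
            sites = [s for s in sites if s.strand == strand]
        return sites

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationIndex):
            return NotImplemented
        return self.introns == other.introns

    def __len__(self) -> int:
        return len(self.introns)


_ATTR_RE = re.compile(r'transcript_id\s+"?([^";]+)"?')

GtfSource = Union[str, os.PathLike, io.IOBase, Iterable[str]]


def _open_lines(source: GtfSource) -> Iterator[str]:
    if isinstance(source, (str, os.PathLike)):
        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rt") as fh:  # type: ignore[operator]
            yield from fh
    else:
        for line in source:
            yield line.decode() if isinstance(line, bytes) else line


def parse_gtf(
    source: GtfSource,
    on_error: str = "skip",
    min_intron_length: int = 1,
) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from GTF exon records.

    Exons are grouped by their ``transcript_id`` attribute and ordered by
    coordinate (file order and sortedness are irrelevant); each pair of
    consecutive exons within a transcript defines one intron.  Non-exon
    features are ignored; single-exon transcripts contribute nothing.

    Parameters
    ----------
    source
        Path (plain or ``.gz``), open text stream, or iterable of lines.
    on_error
        ``"skip"`` logs malformed lines with their line number and moves
        on; ``"raise"`` fails fast on the first one.
    min_intron_length
        Exon pairs closer than this produce no intron (abutting exons are
        an annotation artefact, not splicing).
    """
    if on_error not in ("skip", "raise"):
        raise ValueError("on_error must be 'skip' or 'raise'")
    # transcript_id -> (chrom, strand, [(start, end), ...])
    transcripts: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}

    def problem(lineno: int, msg: str) -> None:
        full = f"GTF line {lineno}: {msg}"
        if on_error == "raise":
            raise ValueError(full)
        log.warning("%s (skipped)", full)

    for lineno, raw in enumerate(_open_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            problem(lineno, f"expected 9 tab-separated columns, got {len(fields)}")
            continue
        if fields[2] != "exon":
            continue
        chrom, start_s, end_s, strand, attrs = (
            fields[0],
            fields[3],
            fields[4],
            fields[6],
            fields[8],
        )
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            problem(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
            continue
        if start < 1 or start > end:
            problem(lineno, f"invalid exon span [{start},{end}]")
            continue
        if strand not in _STRANDS:
            log.warning(
                "GTF line %d: strand %r is not +/-; record skipped "
                "(strand is required to assign donor/acceptor roles)",
                lineno,
                strand,
            )
            continue
        m = _ATTR_RE.search(attrs)
        if m is None:
            problem(lineno, "attribute field lacks transcript_id")
            continue
        tid = m.group(1)
        if tid in transcripts:
            t_chrom, t_strand, exons = transcripts[tid]
            if (t_chrom, t_strand) != (chrom, strand):
                problem(
                    lineno,
                    f"transcript {tid} spans multiple chromosomes/strands",
                )
                continue
            exons.append((start, end))
        else:
            transcripts[tid] = (chrom, strand, [(start, end)])

    index = AnnotationIndex()
    for tid, (chrom, strand, exons) in transcripts.items():
        exons.sort()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                log.warning(
                    "transcript %s: exons [%d,%d] and [%d,%d] overlap; pair skipped",
                    tid,
                    s1,
                    e1,
                    s2,
                    e2,
                )
                continue
            left, right = e1 + 1, s2 - 1
            if right - left + 1 < min_intron_length:
                log.warning(
                    "transcript %s: intron [%d,%d] shorter than %d; skipped",
                    tid,
                    left,
                    right,
                    min_intron_length,
                )
                continue
            index.add_intron(Junction(chrom, left, right, strand))
    return index


def sites_in_interval(
    index: AnnotationIndex,
    chrom: str,
    start: int,
    end: int,
    strand: Optional[str] = None,
) -> list[SpliceSite]:
    """Functional alias for :meth:`AnnotationIndex.sites_in_interval`."""
    return index.sites_in_interval(chrom, start, end, strand)


def sites_to_frame(index: AnnotationIndex):
    """Annotated sites as a tidy DataFrame (chrom, pos, strand, kind)."""
    import pandas as pd

    rows = sorted(index.all_sites(), key=lambda s: (s.chrom, s.pos, s.kind, s.strand))
    return pd.DataFrame(
        [(s.chrom, s.pos, s.strand, s.kind) for s in rows],
        columns=["chrom", "pos", "strand", "kind"],
    )


def introns_to_frame(index: AnnotationIndex):
    """Annotated introns as a tidy DataFrame (chrom, left, right, strand)."""
    import pandas as pd

    rows = sorted(index.introns, key=lambda j: (j.chrom, j.left, j.right, j.strand))
    return pd.DataFrame(
        [(j.chrom, j.left, j.right, j.strand) for j in rows],
        columns=["chrom", "left", "right", "strand"],
    )
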