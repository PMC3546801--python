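"""Independent brute-force oracles for counting.

Everything here re-derives results from first principles with no imports
from the package under test: a character-by-character CIGAR reference
walk and a naive per-read recount over SAM text with linear scans over
the annotation (no interval index, no streaming state).
"""

from __future__ import annotations


def walk_cigar(cigar: str, pos: int):
    """Reference walk over a CIGAR string, one character at a time.

    Returns (blocks, gaps) as 1-based closed intervals, or raises
    ValueError for CIGARs that junction counting must reject.
    """
    blocks = []
    gaps = []
    num = ""
    block_start = ref = pos
    saw_op = False
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        if not num:
            raise ValueError("CIGAR op without length")
        length = int(num)
        num = ""
        saw_op = True
        if length <= 0:
            raise ValueError("non-positive op length")
        if ch in "M=XD":
            ref += length
        elif ch == "N":
            if ref == block_start:
                raise ValueError("N not preceded by aligned bases")
            blocks.append((block_start, ref - 1))
            gaps.append((ref, ref + length - 1))
            ref += length
            block_start = ref
        elif ch in "ISHP":
            pass
        else:
            raise ValueError(f"bad op {ch!r}")
    if num or not saw_op:
        raise ValueError("trailing digits or empty CIGAR")
    if ref == block_start:
        raise ValueError("no trailing aligned bases")
    blocks.append((block_start, ref - 1))
    return blocks, gaps


def strand_of(flag: int, protocol: str) -> str:
    """Truth-table read-strand assignment (independent formulation)."""
    if protocol == "unstranded":
        return "."
    # physical orientation of this alignment
    physical = "-" if flag & 16 else "+"
    # mate role: second-in-pair reads report the opposite of the fragment
    if flag & 1 and flag & 128:
        physical = {"+": "-", "-": "+"}[physical]
    if protocol in ("fr-secondstrand", "forward-first"):
        return physical
    if protocol in ("fr-firststrand", "reverse-first"):
        return {"+": "-", "-": "+"}[physical]
    raise ValueError(protocol)


def boundary_pair(pos: int, strand: str, kind: str):
    """(exonic, intronic) bases flanking a splice-site boundary."""
    if (kind == "donor") == (strand == "+"):
        return pos - 1, pos
    return pos + 1, pos


def naive_count(
    sam_text: str,
    introns: set,
    sites: list,
    protocol: str,
    min_overhang: int = 1,
    min_flank: int = 1,
    min_mapq: int = 1,
):
    """Per-read recount of a SAM text.

    introns: set of (chrom, left, right, strand); sites: iterable of
    (chrom, pos, strand, kind).  Returns (junction_counts, site_counts,
    totals) with category tuples (annotated, opposite).
    """
    junctions: dict = {}
    site_counts: dict = {}
    totals = {"mapped": 0, "filtered": 0, "malformed": 0,
              "junction_spanning": 0, "genomic": 0}
    sites = list(sites)
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        flag, chrom, pos, mapq, cigar = int(f[1]), f[2], int(f[3]), int(f[4]), f[5]
        if flag & (0x4 | 0x100 | 0x800 | 0x200 | 0x400):
            totals["filtered"] += 1
            continue
        nh = None
        for tag in f[11:]:
            if tag.startswith("NH:i:"):
                nh = int(tag[5:])
        if nh is not None:
            if nh != 1:
                totals["filtered"] += 1
                continue
        elif mapq < min_mapq:
            totals["filtered"] += 1
            continue
        totals["mapped"] += 1
        try:
            blocks, gaps = walk_cigar(cigar, pos)
        except ValueError:
            totals["malformed"] += 1
            continue
        rstrand = strand_of(flag, protocol)
        kept = []
        for i, gap in enumerate(gaps):
            lb, rb = blocks[i], blocks[i + 1]
            if (lb[1] - lb[0] + 1) >= min_overhang and (rb[1] - rb[0] + 1) >= min_overhang:
                kept.append(gap)
        if kept:
            totals["junction_spanning"] += 1
            for left, right in kept:
                strands = [s for s in "+-" if (chrom, left, right, s) in introns]
                assert strands, "oracle expects annotated gaps only"
                jstrand = rstrand if rstrand in strands else strands[0]
                cat = 0 if rstrand in (".", jstrand) else 1
                key = (chrom, left, right, jstrand)
                junctions.setdefault(key, [0, 0])[cat] += 1
        else:
            totals["genomic"] += 1
            for schrom, spos, sstrand, skind in sites:
                if schrom != chrom:
                    continue
                ex, intr = boundary_pair(spos, sstrand, skind)
                lo = min(ex, intr) - (min_flank - 1)
                hi = max(ex, intr) + (min_flank - 1)
                if any(bs <= lo and hi <= be for bs, be in blocks):
                    cat = 0 if rstrand in (".", sstrand) else 1
                    site_counts.setdefault((schrom, spos, sstrand, skind), [0, 0])[cat] += 1
    junctions = {k: tuple(v) for k, v in junctions.items()}
    site_counts = {k: tuple(v) for k, v in site_counts.items()}
    return junctions, site_counts, totals
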