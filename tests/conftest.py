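"""Shared fixtures: the shared-donor gene model and the 12-read SAM
whose expected counts were ledgered by hand alongside it."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracle as _oracle

from intronpsi import parse_gtf

# Two + transcripts sharing exon [100,200], splicing to [301,400] and
# [501,600]: one donor (201), two acceptors (300, 500), two introns.
SHARED_DONOR_GTF = "".join(
    f'chr1\ttest\texon\t{s}\t{e}\t.\t+\t.\tgene_id "G1"; transcript_id "{t}";\n'
    for t, s, e in [
        ("T1", 100, 200),
        ("T1", 301, 400),
        ("T2", 100, 200),
        ("T2", 501, 600),
    ]
)

# Hand-written 12-read fixture over the shared-donor model, under the
# fr-secondstrand protocol (flag 0 -> + strand read).  Per-read ledger:
#   j1-j3  flag 0   20M100N20M @181  -> junction (201,300,+) annotated
#   j4     flag 0   5M300N20M  @196  -> junction (201,500,+) annotated
#                                       (left anchor only 5 bases)
#   j5-j6  flag 16  20M100N20M @181  -> junction (201,300,+) opposite
#   g1-g4  flag 0   20M        @191  -> genomic, straddles donor 201 (annotated)
#   g5-g6  flag 0   20M        @100  -> genomic, overlaps no site
# Expected: n(201,300) ann=3 opp=2; n(201,500) ann=1;
#           g(donor 201) ann=4; junction_spanning=6, genomic=6.
_READS = [
    ("g5", 0, 100, "20M"),
    ("g6", 0, 100, "20M"),
    ("j1", 0, 181, "20M100N20M"),
    ("j2", 0, 181, "20M100N20M"),
    ("j3", 0, 181, "20M100N20M"),
    ("j5", 16, 181, "20M100N20M"),
    ("j6", 16, 181, "20M100N20M"),
    ("j4", 0, 196, "5M300N20M"),
    ("g1", 0, 191, "20M"),
    ("g2", 0, 191, "20M"),
    ("g3", 0, 191, "20M"),
    ("g4", 0, 191, "20M"),
]

TWELVE_READ_SAM = "\n".join(
    ["@HD\tVN:1.6\tSO:coordinate", "@SQ\tSN:chr1\tLN:1000"]
    + [
        f"{name}\t{flag}\tchr1\t{pos}\t50\t{cigar}\t*\t0\t0\t*\t*\tNH:i:1"
        for name, flag, pos, cigar in sorted(_READS, key=lambda r: r[2])
    ]
) + "\n"

FIXTURE_PROTOCOL = "fr-secondstrand"


@pytest.fixture(scope="session")
def shared_donor_index():
    return parse_gtf(SHARED_DONOR_GTF.splitlines())


@pytest.fixture()
def twelve_read_sam_path(tmp_path):
    path = tmp_path / "twelve.sam"
    path.write_text(TWELVE_READ_SAM)
    return path


@pytest.fixture()
def shared_donor_gtf_path(tmp_path):
    path = tmp_path / "shared_donor.gtf"
    path.write_text(SHARED_DONOR_GTF)
    return path
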