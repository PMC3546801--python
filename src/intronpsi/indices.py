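"""Splicing indices computed from junction and site counts.

Intron-centric indices (per intron (D, A)):

* ``psi5(D, A) = n(D, A) / sum_A' n(D, A')`` — the frequency of splicing
  from D to A among all splicing events that use donor D;
* ``psi3(D, A) = n(D, A) / sum_D' n(D', A)`` — likewise for acceptor A.

Completeness-of-splicing indices (per site):

* ``theta5(D) = sum_A n(D, A) / (sum_A n(D, A) + g(D))`` where g(D) is
  the number of genomic reads straddling D's exon-intron boundary;
* ``theta3(A)`` is the mirror image.  Theta estimates the fraction of
  molecules already spliced at the site.

Exon-centric percent-spliced-in for a cassette exon:

* ``psi = inc / (inc + 2 * exc)`` where inc combines the two inclusion
  junctions and exc counts the exclusion junction; the factor of two
  corrects for inclusion having twice as many mappable junction
  positions.  Under reasonably uniform coverage psi equals the weighted
  average of psi5 (upstream intron) and psi3 (downstream intron), with
  weights a/(a+a') and a'/(a+a').

Every index is a ratio of non-negative integers; a zero denominator
yields an *undefined* value (``None``, serialized "NA"), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import pandas as pd

from .annotation import ACCEPTOR, DONOR, AnnotationIndex, Junction, SpliceSite
from .counting import ANNOTATED, CATEGORIES, OPPOSITE, CountsTable, JunctionKey

MERGED = "merged"

PSI5 = "psi5"
PSI3 = "psi3"
THETA5 = "theta5"
THETA3 = "theta3"

INDEX_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "kind",
    "metric",
    "strand_category",
    "numerator",
    "denominator",
    "value",
]


@dataclass(frozen=True)
class IndexRecord:
    """One index value with the integers it is a ratio of."""

    metric: str
    key: Union[Junction, SpliceSite]
    strand_category: str
    numerator: int
    denominator: int

    @property
    def value(self) -> Optional[float]:
        """numerator/denominator, or None (undefined) for 0/0."""
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def defined(self) -> bool:
        return self.denominator > 0


@dataclass(frozen=True)
class ExonSkippingTriple:
    """The three junction counts of a single cassette exon.

    a: upstream inclusion intron (D1, A1); a_prime: downstream inclusion
    intron (D2, A2); b: exclusion intron (D1, A2).
    """

    a: int
    a_prime: int
    b: int

    def __post_init__(self) -> None:
        if min(self.a, self.a_prime, self.b) < 0:
            raise ValueError("junction counts must be non-negative")


def _junction_key(junction: Union[Junction, JunctionKey]) -> Junction:
    if isinstance(junction, Junction):
        return junction
    chrom, left, right, strand = junction
    return Junction(chrom, left, right, strand)


def psi5(
    table: CountsTable,
    junction: Union[Junction, JunctionKey],
    strand_category: str = ANNOTATED,
    include_novel: bool = True,
) -> IndexRecord:
    """5'-splicing index of one intron: n(D,A) over the donor margin."""
    j = _junction_key(junction)
    num = table.junction_count((j.chrom, j.left, j.right, j.strand), strand_category)
    den = table.donor_margin(j.chrom, j.donor_pos, j.strand, strand_category, include_novel)
    return IndexRecord(PSI5, j, strand_category, num, den)


def psi3(
    table: CountsTable,
    junction: Union[Junction, JunctionKey],
    strand_category: str = ANNOTATED,
    include_novel: bool = True,
) -> IndexRecord:
    """3'-splicing index of one intron: n(D,A) over the acceptor margin."""
    j = _junction_key(junction)
    num = table.junction_count((j.chrom, j.left, j.right, j.strand), strand_category)
    den = table.acceptor_margin(j.chrom, j.acceptor_pos, j.strand, strand_category, include_novel)
    return IndexRecord(PSI3, j, strand_category, num, den)


def psi_exon(inclusion_reads: int, exclusion_reads: int) -> Optional[float]:
    """Exon-centric percent-spliced-in: inc / (inc + 2*exc).

    ``inclusion_reads`` combines both inclusion junctions; undefined
    (None) when no reads of either kind exist.
    """
    if inclusion_reads < 0 or exclusion_reads < 0:
        raise ValueError("read counts must be non-negative")
    if inclusion_reads + exclusion_reads == 0:
        return None
    return inclusion_reads / (inclusion_reads + 2 * exclusion_reads)


def psi_from_intron_indices(triple: ExonSkippingTriple) -> Optional[float]:
    """Cassette-exon psi as the weighted average of psi5 and psi3.

    psi = w*psi5(D1,A1) + w'*psi3(D2,A2) with w = a/(a+a'),
    w' = a'/(a+a'); undefined when a + a' = 0.  Terms with zero weight
    drop out even if the corresponding index is itself undefined.
    """
    a, ap, b = triple.a, triple.a_prime, triple.b
    if a + ap == 0:
        return None
    result = 0.0
    if a:
        result += (a / (a + ap)) * (a / (a + b))
    if ap:
        result += (ap / (a + ap)) * (ap / (ap + b))
    return result


def theta5(
    table: CountsTable,
    donor: SpliceSite,
    strand_category: str = ANNOTATED,
    include_novel: bool = True,
) -> IndexRecord:
    """Completeness of splicing at a donor site.

    Junction reads out of D versus genomic reads straddling D's
    boundary: the fraction of molecules spliced at D.
    """
    if donor.kind != DONOR:
        raise ValueError(f"theta5 requires a donor site, got {donor.kind}")
    spliced = table.donor_margin(donor.chrom, donor.pos, donor.strand, strand_category,
                                 include_novel)
    g = table.site_count((donor.chrom, donor.pos, donor.strand, donor.kind), strand_category)
    return IndexRecord(THETA5, donor, strand_category, spliced, spliced + g)


def theta3(
    table: CountsTable,
    acceptor: SpliceSite,
    strand_category: str = ANNOTATED,
    include_novel: bool = True,
) -> IndexRecord:
    """Completeness of splicing at an acceptor site (mirror of theta5)."""
    if acceptor.kind != ACCEPTOR:
        raise ValueError(f"theta3 requires an acceptor site, got {acceptor.kind}")
    spliced = table.acceptor_margin(acceptor.chrom, acceptor.pos, acceptor.strand,
                                    strand_category, include_novel)
    g = table.site_count((acceptor.chrom, acceptor.pos, acceptor.strand, acceptor.kind),
                         strand_category)
    return IndexRecord(THETA3, acceptor, strand_category, spliced, spliced + g)


def _merge_categories(table: CountsTable) -> CountsTable:
    merged = CountsTable()
    for key, (ann, opp) in table.junction_counts.items():
        merged.add_junction(key, ANNOTATED, table.junction_status[key], ann + opp)
    for key, (ann, opp) in table.site_counts.items():
        merged.add_site(key, ANNOTATED, ann + opp)
    return merged


def compute_all(
    table: CountsTable,
    annotation: Optional[AnnotationIndex] = None,
    include_novel: bool = True,
    merge_strands: bool = False,
    add_ci: bool = False,
    ci_alpha: float = 0.05,
) -> pd.DataFrame:
    """All indices for every junction and site with any evidence.

    One row per (junction x {psi5, psi3}) and (site x {theta5, theta3})
    per strand category, with numerator, denominator and value (NaN when
    undefined; serialized as "NA").  Junctions/sites come from the
    counts table plus, when given, the annotation (annotated sites with
    zero junction evidence still get theta rows — genomic evidence alone
    makes theta 0, which is informative).  ``merge_strands`` collapses
    the annotated/opposite categories for unstranded libraries.
    ``add_ci`` appends Wilson score interval bounds for defined values.
    """
    if merge_strands:
        table = _merge_categories(table)
        categories = (MERGED,)
        lookup_categories = (ANNOTATED,)
    else:
        categories = CATEGORIES
        lookup_categories = CATEGORIES

    junctions: set[Junction] = set()
    for chrom, left, right, strand in table.junction_counts:
        junctions.add(Junction(chrom, left, right, strand))
    if not include_novel:
        junctions = {
            j for j in junctions
            if table.junction_status[(j.chrom, j.left, j.right, j.strand)] == "annotated"
        }

    sites: set[SpliceSite] = set()
    for chrom, pos, strand, kind in table.site_counts:
        sites.add(SpliceSite(chrom, pos, strand, kind))
    for j in junctions:
        sites.add(j.donor_site())
        sites.add(j.acceptor_site())
    if annotation is not None:
        sites.update(annotation.all_sites())

    rows = []

    def emit(rec: IndexRecord, label: str, start: int, end: int, kind: str) -> None:
        rows.append(
            (
                rec.key.chrom,
                start,
                end,
                rec.key.strand,
                kind,
                rec.metric,
                label,
                rec.numerator,
                rec.denominator,
                float("nan") if rec.value is None else rec.value,
            )
        )

    for j in sorted(junctions):
        for cat, label in zip(lookup_categories, categories):
            emit(psi5(table, j, cat, include_novel), label, j.left, j.right, "junction")
            emit(psi3(table, j, cat, include_novel), label, j.left, j.right, "junction")
    for s in sorted(sites):
        fn = theta5 if s.kind == DONOR else theta3
        for cat, label in zip(lookup_categories, categories):
            emit(fn(table, s, cat, include_novel), label, s.pos, s.pos, s.kind)

    frame = pd.DataFrame(rows, columns=INDEX_COLUMNS)
    frame = frame.sort_values(
        ["chrom", "start", "end", "kind", "metric", "strand_category"],
        kind="mergesort",
    ).reset_index(drop=True)
    if add_ci:
        frame = _append_wilson_ci(frame, ci_alpha)
    return frame


def _append_wilson_ci(frame: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Wilson score interval columns — an extension beyond the point
    estimators; meaningful only where the count is binomial-like."""
    from statsmodels.stats.proportion import proportion_confint

    lows, highs = [], []
    for num, den in zip(frame["numerator"], frame["denominator"]):
        if den == 0:
            lows.append(float("nan"))
            highs.append(float("nan"))
        else:
            lo, hi = proportion_confint(num, den, alpha=alpha, method="wilson")
            lows.append(float(lo))
            highs.append(float(hi))
    out = frame.copy()
    out["ci_low"] = lows
    out["ci_high"] = highs
    return out


def write_index_tsv(frame: pd.DataFrame, path) -> None:
    """Write the index table with undefined values serialized as NA."""
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")
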