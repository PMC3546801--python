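"""Synthetic gene models, spliced-read simulation and exact ground truth.

The generator emulates the two inputs of the counting pipeline — a GTF
gene model and a coordinate-sorted SAM of uniquely aligned reads — under
fully controlled conditions:

* multi-transcript gene models with shared and distinct donors/acceptors
  (the cassette-exon model is the canonical case: an inclusion isoform
  with two introns and an exclusion isoform with one, with the
  inclusion fraction f as the ground-truth percent-spliced-in);
* reads sampled position-uniformly along each molecule (or with a
  linear coverage gradient), so that a transcript's read yield is
  proportional to abundance x mappable length — the uniform-coverage
  regime under which the indices are unbiased;
* an ``unspliced_fraction`` of reads drawn from the unspliced pre-mRNA,
  which produces the boundary-straddling genomic reads that the
  completeness indices (theta) contrast against junction reads;
* an ``antisense_fraction`` of reads on the opposite strand, exercising
  the strand-category split.

Because every read is constructed from a known (isoform, start) class,
the simulator can tally the exact expected :class:`CountsTable` — the
TruthLedger — without ever parsing a CIGAR, which makes it an
independent oracle for the counting pipeline.  ``expected_counts``
computes the per-read expectation in exact rational arithmetic by
enumerating all classes, and ``sample_counts`` draws the class
multinomial directly, which is distribution-identical to read-level
simulation but fast enough for replicated estimator studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Optional

import numpy as np

from .annotation import ACCEPTOR, DONOR, AnnotationIndex, Junction, SpliceSite
from .counting import (
    ANNOTATED,
    OPPOSITE,
    STATUS_ANNOTATED,
    CountingConfig,
    CountsTable,
)

__all__ = [
    "GeneModel",
    "ReadSimConfig",
    "SimResult",
    "make_cassette_model",
    "simulate_reads",
    "expected_counts",
    "sample_counts",
    "ExpectedCounts",
]


@dataclass(frozen=True)
class GeneModel:
    """Transcript structures plus ground-truth isoform abundances.

    ``transcripts`` holds per-isoform exon lists as 1-based closed
    genomic intervals, ordered left to right; ``isoform_weights`` are
    relative molar abundances (normalized on construction).
    """

    chrom: str
    strand: str
    transcripts: tuple[tuple[tuple[int, int], ...], ...]
    isoform_weights: tuple[float, ...]
    gene_id: str = "SYNGENE"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.transcripts) != len(self.isoform_weights):
            raise ValueError("one weight per transcript required")
        if not self.transcripts:
            raise ValueError("at least one transcript required")
        if any(w < 0 for w in self.isoform_weights):
            raise ValueError("isoform weights must be non-negative")
        total = sum(self.isoform_weights)
        if total <= 0:
            raise ValueError("isoform weights must not all be zero")
        object.__setattr__(
            self,
            "isoform_weights",
            tuple(w / total for w in self.isoform_weights),
        )
        norm = []
        for exons in self.transcripts:
            exons = tuple(sorted((int(s), int(e)) for s, e in exons))
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping exons [{s1},{e1}] and [{s2},{e2}]")
            if any(s < 1 or e < s for s, e in exons):
                raise ValueError("invalid exon interval")
            norm.append(exons)
        object.__setattr__(self, "transcripts", tuple(norm))

    # -- structure -----------------------------------------------------
    def transcript_length(self, i: int) -> int:
        return sum(e - s + 1 for s, e in self.transcripts[i])

    def transcript_introns(self, i: int) -> list[Junction]:
        exons = self.transcripts[i]
        return [
            Junction(self.chrom, e1 + 1, s2 - 1, self.strand)
            for (_, e1), (s2, _) in zip(exons, exons[1:])
        ]

    def introns(self) -> list[Junction]:
        """Distinct introns over all transcripts, sorted."""
        out = set()
        for i in range(len(self.transcripts)):
            out.update(self.transcript_introns(i))
        return sorted(out)

    def splice_sites(self) -> list[SpliceSite]:
        sites = set()
        for j in self.introns():
            sites.add(j.donor_site())
            sites.add(j.acceptor_site())
        return sorted(sites, key=lambda s: (s.pos, s.kind))

    def annotation_index(self) -> AnnotationIndex:
        return AnnotationIndex(self.introns())

    def genomic_span(self) -> tuple[int, int]:
        starts = [e[0][0] for e in self.transcripts]
        ends = [e[-1][1] for e in self.transcripts]
        return min(starts), max(ends)

    # -- serialization -------------------------------------------------
    def to_gtf(self) -> str:
        lines = []
        for i, exons in enumerate(self.transcripts, start=1):
            tid = f"{self.gene_id}.T{i}"
            for s, e in exons:
                attrs = f'gene_id "{self.gene_id}"; transcript_id "{tid}";'
                lines.append(
                    "\t".join(
                        (self.chrom, "sim", "exon", str(s), str(e), ".",
                         self.strand, ".", attrs)
                    )
                )
        return "\n".join(lines) + "\n"


def make_cassette_model(
    inclusion_fraction: float,
    exon_lengths: tuple[int, int, int] = (200, 120, 200),
    intron_lengths: tuple[int, int] = (300, 300),
    chrom: str = "chrS",
    strand: str = "+",
    offset: int = 1001,
    gene_id: str = "CASSETTE",
) -> GeneModel:
    """Two-isoform cassette-exon gene: include (f) vs skip (1 - f).

    The true percent-spliced-in of the middle exon equals
    ``inclusion_fraction`` under uniform read sampling.
    """
    if not 0.0 <= inclusion_fraction <= 1.0:
        raise ValueError("inclusion_fraction must be in [0, 1]")
    e1, e2, e3 = exon_lengths
    i1, i2 = intron_lengths
    a = (offset, offset + e1 - 1)
    b = (a[1] + i1 + 1, a[1] + i1 + e2)
    c = (b[1] + i2 + 1, b[1] + i2 + e3)
    return GeneModel(
        chrom=chrom,
        strand=strand,
        transcripts=((a, b, c), (a, c)),
        isoform_weights=(inclusion_fraction, 1.0 - inclusion_fraction),
        gene_id=gene_id,
    )


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-sampling scheme; a fixed seed gives byte-identical output."""

    read_length: int = 50
    n_reads: int = 2000
    coverage_profile: str = "uniform"  # or "linear-gradient"
    gradient: float = 1.0  # end-to-start coverage excess for linear-gradient
    unspliced_fraction: float = 0.0  # pre-mRNA contamination
    antisense_fraction: float = 0.0
    protocol: str = "fr-firststrand"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 2:
            raise ValueError("read_length must be >= 2")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.coverage_profile not in ("uniform", "linear-gradient"):
            raise ValueError(f"unknown coverage_profile {self.coverage_profile!r}")
        if not 0.0 <= self.unspliced_fraction <= 1.0:
            raise ValueError("unspliced_fraction must be in [0, 1]")
        if not 0.0 <= self.antisense_fraction <= 1.0:
            raise ValueError("antisense_fraction must be in [0, 1]")
        if self.gradient < 0:
            raise ValueError("gradient must be >= 0")


PRE_MRNA = -1  # pseudo-isoform index of the unspliced molecule


@dataclass(frozen=True)
class _SimClass:
    """One (isoform, transcript start) sampling class."""

    isoform: int
    tstart: int
    blocks: tuple[tuple[int, int], ...]
    gaps: tuple[tuple[int, int], ...]


def _window_blocks(exons, tstart: int, read_length: int):
    """Genomic blocks/gaps covered by transcript window [tstart, tstart+rl-1].

    Transcript coordinates run along the concatenated exons in genomic
    left-to-right order (direction is irrelevant to which bases a read
    covers).
    """
    tend = tstart + read_length - 1
    blocks: list[tuple[int, int]] = []
    offset = 1  # transcript coordinate of current exon start
    for s, e in exons:
        exon_len = e - s + 1
        lo = max(tstart, offset)
        hi = min(tend, offset + exon_len - 1)
        if lo <= hi:
            blocks.append((s + (lo - offset), s + (hi - offset)))
        offset += exon_len
    if sum(e - s + 1 for s, e in blocks) != read_length:
        raise ValueError("read window exceeds transcript end")
    gaps = [(b1[1] + 1, b2[0] - 1) for b1, b2 in zip(blocks, blocks[1:])]
    return tuple(blocks), tuple(gaps)


def _enumerate_classes(
    model: GeneModel, cfg: ReadSimConfig
) -> tuple[list[_SimClass], list[Fraction]]:
    """All (isoform, start) classes with exact unnormalized weights."""
    u = Fraction(cfg.unspliced_fraction)
    rl = cfg.read_length
    molecules: list[tuple[int, tuple[tuple[int, int], ...], Fraction]] = []
    for i, exons in enumerate(model.transcripts):
        w = Fraction(model.isoform_weights[i]) * (1 - u)
        if w > 0:
            molecules.append((i, exons, w))
    if u > 0:
        span = model.genomic_span()
        molecules.append((PRE_MRNA, (span,), u))

    classes: list[_SimClass] = []
    weights: list[Fraction] = []
    for iso, exons, w in molecules:
        length = sum(e - s + 1 for s, e in exons)
        n_pos = length - rl + 1
        if n_pos < 1:
            raise ValueError(
                f"read_length {rl} exceeds molecule length {length} (isoform {iso})"
            )
        for t in range(1, n_pos + 1):
            if cfg.coverage_profile == "uniform":
                profile = Fraction(1)
            else:
                frac = Fraction(t - 1, n_pos - 1) if n_pos > 1 else Fraction(0)
                profile = 1 + Fraction(cfg.gradient) * frac
            blocks, gaps = _window_blocks(exons, t, rl)
            classes.append(_SimClass(iso, t, blocks, gaps))
            weights.append(w * profile)
    total = sum(weights)
    return classes, [w / total for w in weights]


# -- ground-truth tallying (no CIGAR parsing involved) ------------------

def _classify_blocks(
    model: GeneModel,
    blocks,
    gaps,
    counting_cfg: CountingConfig,
    sites: Optional[list[SpliceSite]] = None,
) -> tuple[str, list]:
    """Truth classification of a read from its constructed geometry.

    Mirrors the counting rules from first principles: overhang-filtered
    gaps are junctions; gap-free reads straddling a model splice-site
    boundary (min_flank bases each side) are genomic site evidence.
    ``sites`` lets callers in a loop amortize the site enumeration.
    """
    kept = []
    for i, gap in enumerate(gaps):
        lb, rb = blocks[i], blocks[i + 1]
        if (
            lb[1] - lb[0] + 1 >= counting_cfg.min_overhang
            and rb[1] - rb[0] + 1 >= counting_cfg.min_overhang
        ):
            kept.append(gap)
    if kept:
        return "junction", [
            (model.chrom, left, right, model.strand) for left, right in kept
        ]
    flank = counting_cfg.min_flank
    hits = []
    if sites is None:
        sites = model.splice_sites()
    for site in sites:
        exonic, intronic = site.boundary_bases()
        lo = min(exonic, intronic) - (flank - 1)
        hi = max(exonic, intronic) + (flank - 1)
        for bs, be in blocks:
            if bs <= lo and hi <= be:
                hits.append((site.chrom, site.pos, site.strand, site.kind))
                break
    return "genomic", hits


def _category(sense: bool, protocol: str) -> str:
    if protocol == "unstranded":
        return ANNOTATED  # unknown read strand falls in the annotated bin
    return ANNOTATED if sense else OPPOSITE


def _tally(
    table: CountsTable,
    model: GeneModel,
    blocks,
    gaps,
    sense: bool,
    counting_cfg: CountingConfig,
    times: int = 1,
    sites: Optional[list] = None,
) -> None:
    kind, keys = _classify_blocks(model, blocks, gaps, counting_cfg, sites)
    cat = _category(sense, counting_cfg.protocol)
    if kind == "junction":
        table.read_totals["junction_spanning"] += times
        for key in keys:
            table.add_junction(key, cat, STATUS_ANNOTATED, times)
    else:
        table.read_totals["genomic"] += times
        for key in keys:
            table.add_site(key, cat, times)
    table.read_totals["records"] += times
    table.read_totals["mapped"] += times


# -- exact expectations --------------------------------------------------

@dataclass
class ExpectedCounts:
    """Per-read expectations in exact rational arithmetic."""

    junctions: dict  # (chrom,left,right,strand) -> {category: Fraction}
    sites: dict  # (chrom,pos,strand,kind) -> {category: Fraction}
    p_junction_spanning: Fraction
    p_genomic: Fraction

    def expected_psi5(self, junction: Junction, category: str = ANNOTATED) -> Fraction:
        num = self.junctions.get(
            (junction.chrom, junction.left, junction.right, junction.strand), {}
        ).get(category, Fraction(0))
        den = Fraction(0)
        for (c, l, r, s), cats in self.junctions.items():
            j = Junction(c, l, r, s)
            if c == junction.chrom and s == junction.strand and j.donor_pos == junction.donor_pos:
                den += cats.get(category, Fraction(0))
        if den == 0:
            raise ZeroDivisionError("donor has zero expected junction reads")
        return num / den

    def expected_theta5(self, donor: SpliceSite, category: str = ANNOTATED) -> Fraction:
        spliced = Fraction(0)
        for (c, l, r, s), cats in self.junctions.items():
            if c == donor.chrom and s == donor.strand and Junction(c, l, r, s).donor_pos == donor.pos:
                spliced += cats.get(category, Fraction(0))
        g = self.sites.get((donor.chrom, donor.pos, donor.strand, donor.kind), {}).get(
            category, Fraction(0)
        )
        if spliced + g == 0:
            raise ZeroDivisionError("site has zero expected evidence")
        return spliced / (spliced + g)

    def expected_theta3(self, acceptor: SpliceSite, category: str = ANNOTATED) -> Fraction:
        spliced = Fraction(0)
        for (c, l, r, s), cats in self.junctions.items():
            if (
                c == acceptor.chrom
                and s == acceptor.strand
                and Junction(c, l, r, s).acceptor_pos == acceptor.pos
            ):
                spliced += cats.get(category, Fraction(0))
        g = self.sites.get(
            (acceptor.chrom, acceptor.pos, acceptor.strand, acceptor.kind), {}
        ).get(category, Fraction(0))
        if spliced + g == 0:
            raise ZeroDivisionError("site has zero expected evidence")
        return spliced / (spliced + g)


def expected_counts(
    model: GeneModel,
    cfg: ReadSimConfig,
    counting_cfg: Optional[CountingConfig] = None,
) -> ExpectedCounts:
    """Exact per-read expected counts from mappable-position enumeration."""
    if counting_cfg is None:
        counting_cfg = CountingConfig(protocol=cfg.protocol)
    classes, probs = _enumerate_classes(model, cfg)
    af = Fraction(cfg.antisense_fraction)
    junctions: dict = {}
    sites: dict = {}
    p_junc = Fraction(0)
    p_geno = Fraction(0)
    model_sites = model.splice_sites()
    for cls, p in zip(classes, probs):
        kind, keys = _classify_blocks(model, cls.blocks, cls.gaps, counting_cfg, model_sites)
        for sense, share in ((True, 1 - af), (False, af)):
            if share == 0:
                continue
            cat = _category(sense, counting_cfg.protocol)
            mass = p * share
            target = junctions if kind == "junction" else sites
            for key in keys:
                target.setdefault(key, {}).setdefault(cat, Fraction(0))
                target[key][cat] += mass
        if kind == "junction":
            p_junc += p
        else:
            p_geno += p
    return ExpectedCounts(junctions, sites, p_junc, p_geno)


def sample_counts(
    model: GeneModel,
    cfg: ReadSimConfig,
    rng: Optional[np.random.Generator] = None,
    counting_cfg: Optional[CountingConfig] = None,
) -> CountsTable:
    """Draw a CountsTable directly from the class multinomial.

    Reads are iid over (isoform, start) classes, so sampling class
    counts and tallying each class once with multiplicity reproduces the
    distribution of read-level simulation followed by counting — at a
    fraction of the cost.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if counting_cfg is None:
        counting_cfg = CountingConfig(protocol=cfg.protocol)
    classes, probs = _enumerate_classes(model, cfg)
    p = np.array([float(x) for x in probs])
    p /= p.sum()
    counts = rng.multinomial(cfg.n_reads, p)
    table = CountsTable()
    af = cfg.antisense_fraction
    model_sites = model.splice_sites()
    for cls, c in zip(classes, counts):
        if c == 0:
            continue
        anti = int(rng.binomial(c, af)) if af > 0 else 0
        if c - anti:
            _tally(table, model, cls.blocks, cls.gaps, True, counting_cfg,
                   c - anti, model_sites)
        if anti:
            _tally(table, model, cls.blocks, cls.gaps, False, counting_cfg,
                   anti, model_sites)
    return table


# -- read-level simulation ----------------------------------------------

@dataclass(frozen=True)
class _SimRead:
    name: str
    sense: bool
    blocks: tuple[tuple[int, int], ...]
    gaps: tuple[tuple[int, int], ...]

    @property
    def pos(self) -> int:
        return self.blocks[0][0]

    def cigar(self) -> str:
        parts = []
        for i, (s, e) in enumerate(self.blocks):
            parts.append(f"{e - s + 1}M")
            if i < len(self.gaps):
                gs, ge = self.gaps[i]
                parts.append(f"{ge - gs + 1}N")
        return "".join(parts)


@dataclass
class SimResult:
    """Simulated reads plus the exact ledger of their expected counts."""

    model: GeneModel
    config: ReadSimConfig
    reads: list[_SimRead]

    def sam_text(self) -> str:
        span_end = self.model.genomic_span()[1]
        rl = self.config.read_length
        header = [
            "@HD\tVN:1.6\tSO:coordinate",
            f"@SQ\tSN:{self.model.chrom}\tLN:{span_end + 1000}",
            "@PG\tID:intronpsi-sim\tPN:intronpsi-sim",
        ]
        strand = self.model.strand
        proto = self.config.protocol
        lines = []
        for read in sorted(self.reads, key=lambda r: (r.pos, r.name)):
            if proto == "fr-firststrand":
                reverse = strand == "+"
            else:  # fr-secondstrand and unstranded
                reverse = strand == "-"
            if not read.sense:
                reverse = not reverse
            flag = 16 if reverse else 0
            lines.append(
                "\t".join(
                    (
                        read.name,
                        str(flag),
                        self.model.chrom,
                        str(read.pos),
                        "50",
                        read.cigar(),
                        "*",
                        "0",
                        "0",
                        "A" * rl,
                        "*",
                        "NH:i:1",
                    )
                )
            )
        return "\n".join(header + lines) + "\n"

    def ledger(self, counting_cfg: Optional[CountingConfig] = None) -> CountsTable:
        """The TruthLedger: exact counts under the given counting rules."""
        if counting_cfg is None:
            counting_cfg = CountingConfig(protocol=self.config.protocol)
        table = CountsTable()
        sites = self.model.splice_sites()
        for read in self.reads:
            _tally(table, self.model, read.blocks, read.gaps, read.sense,
                   counting_cfg, sites=sites)
        return table


def simulate_reads(model: GeneModel, cfg: ReadSimConfig) -> SimResult:
    """Sample reads per the config; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    classes, probs = _enumerate_classes(model, cfg)
    p = np.array([float(x) for x in probs])
    p /= p.sum()
    picks = rng.choice(len(classes), size=cfg.n_reads, p=p)
    if cfg.antisense_fraction > 0:
        anti = rng.random(cfg.n_reads) < cfg.antisense_fraction
    else:
        anti = np.zeros(cfg.n_reads, dtype=bool)
    width = max(6, len(str(max(cfg.n_reads - 1, 0))))
    reads = [
        _SimRead(
            name=f"sim{i:0{width}d}",
            sense=not bool(anti[i]),
            blocks=classes[k].blocks,
            gaps=classes[k].gaps,
        )
        for i, k in enumerate(picks)
    ]
    return SimResult(model=model, config=cfg, reads=reads)
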