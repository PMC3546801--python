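# Methods

## Coordinates and splice-site representation

All genomic coordinates are 1-based closed intervals, matching GTF and
SAM `POS`. A donor is stored at the first intronic base (on `+`:
`exon_end + 1`) and an acceptor at the last intronic base (on `+`:
`next_exon_start − 1`); on the `−` strand the two roles swap ends of
the intron. An intron's canonical key is `(chrom, genomic-left,
genomic-right, strand)` — one key serves both strands, and the
donor/acceptor roles are derived from the strand on demand. This makes
junction keys depend only on the gap an aligner reports, not on the
aligner.

Annotation is derived from GTF exon records only: exons are grouped by
`transcript_id` and sorted by coordinate, so file order and sortedness
are irrelevant (sorting input is an optimization, not a semantic
requirement, and accepting unsorted GTF removes a silent-failure mode).
Records on strand `.` are skipped with a warning — without a strand the
donor/acceptor role of an exon boundary is undefined. Malformed lines
are reported with their line number and either skipped or fatal,
per configuration. Abutting exon pairs (zero-length "introns") are
ignored; the minimum intron length is configurable and defaults to 1.

## Counting rules

A single pass over the BAM/SAM stream keeps memory proportional to the
annotation plus the distinct observed junctions, never to read count.
Reads are dropped if unmapped, secondary, supplementary, QC-fail or
duplicate; uniqueness then requires `NH == 1` when the tag is present,
else `MAPQ ≥ min_mapq` (default 1). This covers both NH-emitting and
MAPQ-encoding aligners.

The CIGAR reference walk treats `M`, `=`, `X` and `D` as advancing
within an alignment block and `N` as closing the block and opening a
gap; `I`, `S`, `H`, `P` consume no reference. Deletions deliberately do
not split blocks: SAM semantics distinguish intron skips (`N`) from
deletions (`D`). A CIGAR whose `N` is not flanked by aligned bases on
both sides is malformed; such reads are counted in the run totals and
otherwise ignored.

Tunable thresholds:

- `min_overhang` (default 1 reference base): minimum aligned length on
  each side of an `N` gap for the gap to count. The default is the most
  permissive reading of the `xMyNzM` pattern (x, z ≥ 1); gaps failing
  the filter are discarded individually, and a read whose every gap is
  discarded is reclassified as genomic, keeping the junction/genomic
  dichotomy exhaustive.
- `min_flank` (default 1): a genomic read supports a splice site only
  if one of its blocks covers at least this many bases on *both* sides
  of the exon–intron boundary. A read entirely inside the exon or
  entirely inside the intron carries no information about splicing at
  that boundary; straddling reads are the natural complement of
  junction reads in the θ denominators. A single block that straddles
  several boundaries increments each corresponding site once.

Strand categories: the read strand is corrected for the library
protocol (`fr-secondstrand`: a single/first read matches the transcript
strand; `fr-firststrand`, the common dUTP chemistry, inverts that;
second-in-pair mates are flipped). Counts fall in the `annotated`
category when the corrected read strand matches the annotated strand of
the junction or site, else `opposite`. Under `unstranded` the read
strand is unknown and counts fall in the `annotated` bin by convention;
for such libraries the `merge_strands` option in the index step
collapses the two categories. Strand categories are never merged
implicitly.

Junctions absent from the annotation are still counted, with status
`novel`; their strand is borrowed from an annotated donor/acceptor at
either gap end when one exists, else taken from the read. Novel
junctions enter Ψ denominators by default (junction evidence outside
the annotation is real splicing signal) and can be excluded with
`--annotated-only` to recover the strictly annotation-bounded reading.

## Indices

With `n(D, A)` the junction count and `g(s)` the genomic straddling
count at site `s`, all within one strand category:

- Ψ5(D,A) = n(D,A) / Σ_{A′} n(D,A′), Ψ3 mirrored over donors;
- exon-centric Ψ = inc/(inc + 2·exc) for a cassette exon;
- the weighted relation Ψ ≈ w·Ψ5 + w′·Ψ3 with w = a/(a+a′),
  w′ = a′/(a+a′), exact in expectation under uniform coverage;
- θ5(D) = Σ_A n(D,A) / (Σ_A n(D,A) + g(D)), θ3 mirrored. This form is
  fixed by the estimand — the proportion of molecules in which the site
  is used for splicing among all molecules containing the site — and is
  validated against the simulator: with a pre-mRNA fraction u and
  uniform coverage the closed-form expectation is 1 − u, and the
  estimator converges there as coverage grows.

Any index with a zero denominator is undefined and serialized as `NA` —
never 0, which would conflate "no evidence" with "never used". Wilson
score intervals are available as an optional extension column; the
indices themselves are point estimators.

## The simulator and what passing tests mean

The generator produces multi-isoform gene models (canonically the
two-isoform cassette exon with inclusion fraction f, 200/120/200 nt
exons and 300 nt introns), and samples reads iid over (molecule, start
position) classes with probability ∝ molar abundance × position weight.
Uniform position weights give each transcript a read yield proportional
to abundance × mappable length — the regime in which Ψ5, Ψ3, Ψ and θ
are unbiased for f and for the spliced fraction; a linear-gradient
profile is available to break that assumption deliberately. The default
read length is 50 nt, single-end, with a pre-mRNA `unspliced_fraction`
and an `antisense_fraction` as explicit contamination knobs (both 0 by
default; studies here use 0.2 and 0.1 where stated).

Because each read is constructed from a known class, the simulator
tallies its exact expected counts (the TruthLedger) from the read
geometry alone, without CIGAR parsing — an oracle that is independent
of the counting path it checks. `expected_counts` enumerates all
classes in exact rational arithmetic; `sample_counts` draws the class
multinomial directly, which is distribution-identical to read-level
simulation (reads are iid over classes) and is used for the replicated
estimator studies: 200 replicates for the Ψ-vs-(Ψ5+Ψ3)/2 agreement at
f ∈ {0.5, 0.7} and 300 replicates for 3-SE recovery of Ψ and θ5, each
replicate sized to ~10,000 expected junction reads. The read-level and
class-level paths are themselves tested for exact agreement on the
ledger.

What the simulator does **not** emulate: sequencing errors and quality
strings, indels, soft-clipping, multi-mapping, paired-end fragment
effects, GC or positional bias beyond the linear gradient, and multiple
genes per chromosome. Passing tests therefore demonstrate correctness
of the counting and index arithmetic and the statistical behavior of
the estimators under the stated sampling model — not robustness to
aligner artifacts in real data.

## Numerical and design choices

- Counts are integers throughout; indices are exact integer ratios
  evaluated in double precision, so the per-donor normalization
  Σ_A Ψ5(D,A) = 1 holds to < 1e-12.
- Expected values use `fractions.Fraction`; float model parameters are
  converted exactly, so symmetry statements (e.g. equal expected counts
  for the two inclusion junctions) are exact, not approximate.
- All iteration and output orders are deterministic (chromosome,
  coordinate, kind, metric), so runs diff cleanly.
- The delta-method SE for exon-centric Ψ uses Ψ = p/(2−p) of the
  inclusion-read proportion p, giving SE = 2/(2−p)² · √(p(1−p)/n);
  θ's SE is the plain binomial SE conditional on the site's total
  evidence.
- A junction annotated on both strands at the same coordinates resolves
  to the read's strand when it matches, else to `+` (deterministic
  tie-break; such annotations are pathological).
- Paired-end mates are counted as two independent alignments; fragment
  deduplication when both mates span one junction is out of scope.

## Known limitations

Region-restricted counting requires an indexed BAM; novel-junction
strand inference is heuristic when neither gap end is annotated; the
`unstranded` convention places all counts in the `annotated` category
rather than a separate one; and the Wilson intervals ignore the
dependence between junctions sharing a denominator.
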