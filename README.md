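# intronpsi

Intron-centric quantification of alternative splicing from RNA-seq
alignments: strand-specific counting of splice-junction reads and
splice-site-straddling genomic reads, and the splicing indices built
from those counts.

## The problem and the model

Exon-centric percent-spliced-in (PSI, Ψ) summarizes a cassette exon with
a single number, but most splicing events are more complex than
single-exon skipping. This package takes the intron-centric view: each
intron is identified by its 5′ splice site D (donor) and 3′ splice site
A (acceptor), and the evidence for its excision is n(D, A), the number
of reads whose alignment skips exactly that intron through a CIGAR `N`
gap (the `xMyNzM` pattern). From the junction counts and the counts of
genomic reads straddling each exon–intron boundary, five quantities are
computed per intron/site:

- **Ψ5(D, A)** = n(D, A) / Σ<sub>A′</sub> n(D, A′) — the frequency of
  D→A splicing among all splicing events that use donor D;
- **Ψ3(D, A)** = n(D, A) / Σ<sub>D′</sub> n(D′, A) — likewise for
  acceptor A;
- **Ψ** = inc / (inc + 2·exc) — the exon-centric PSI for a cassette
  exon, where inc combines the two inclusion junctions and exc counts
  the exclusion junction (the factor 2 corrects for inclusion having
  twice as many mappable junction positions). Under reasonably uniform
  coverage Ψ equals the weighted average of Ψ5 (upstream intron) and Ψ3
  (downstream intron) with weights a/(a+a′) and a′/(a+a′);
- **θ5(D)** = Σ<sub>A</sub> n(D, A) / (Σ<sub>A</sub> n(D, A) + g(D)) and
  its mirror **θ3(A)** — completeness-of-splicing indices, where g is
  the number of gap-free (genomic) reads straddling the boundary:
  the fraction of molecules already spliced at the site.

All counting is strand-specific: every counter is kept separately for
reads whose protocol-corrected orientation matches the annotated strand
and for reads on the opposite strand, which makes antisense
contamination directly visible. A zero denominator yields an undefined
value (`NA`), never 0.

The counting semantics: a read with k surviving `N` gaps increments k
junction counters (one per spanned intron); a read with no counted gap
is genomic and increments the counter of every splice site whose
boundary one of its alignment blocks covers on both sides. Junctions
observed in the data but absent from the annotation are counted and
flagged `novel`.

## Worked example

Simulate a cassette-exon gene (true inclusion fraction f = 0.7, 20% of
reads from unspliced pre-mRNA), count, and compute indices:

```sh
intronpsi simulate --out-prefix demo --seed 7 -f 0.7 --n-reads 5000 \
    --unspliced-fraction 0.2 --protocol fr-secondstrand
intronpsi count --bam demo.sam --gtf demo.gtf --out-prefix demo \
    --protocol fr-secondstrand
intronpsi index --ssj demo.ssj.tsv --ssc demo.ssc.tsv --out demo.index.tsv
```

The count step prints the run summary

```
records=5000 filtered=0 mapped=5000 malformed=0 junction_spanning=614 genomic=4386
junction_count_total=614 opposite_strand_fraction=0.0000
```

and `demo.ssj.tsv` holds the per-junction counts (here: the two
inclusion junctions with 244 and 271 reads, the exclusion junction with
99). The index table then gives, per junction and site:

```
chrom  start  end   strand kind     metric strand_category numerator denominator value
chrS   1201   1201  +      donor    theta5 annotated       343       428         0.8014
chrS   1201   1500  +      junction psi5   annotated       244       343         0.7114
chrS   1201   1920  +      junction psi5   annotated       99        343         0.2886
chrS   1621   1920  +      junction psi3   annotated       271       370         0.7324
```

Ψ5 of the upstream inclusion junction (0.711) and Ψ3 of the downstream
one (0.732) estimate the true inclusion fraction 0.7; θ5 at the first
donor (0.801) estimates the spliced fraction 1 − 0.2 = 0.8. Ψ5 and its
complement over the same donor sum to 1 by construction.

The same machinery is available as a library (`intronpsi.parse_gtf`,
`count_file`, `psi5`, `theta5`, `compute_all`,
`make_cassette_model`, `simulate_reads`, ...).

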