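# Methods

## The model

A RAD-PE fragment has a restriction cut site at one end and a random
shear point at the other. Read 1 starts at the cut site — after adapter
ligation it begins with the enzyme's residual sequence (`TGCAGG` for
SbfI cutting CCTGCA^GG, `CATG` for NlaIII, `GATC` for Sau3AI) — and
read 2 is the reverse complement of the sheared end. Because the cut
site is fixed and the shear point is random, the set of read-2
sequences sharing one tag tiles the region adjacent to the site, out to
the upper bound of the shear size-selection window. That tiling is what
the per-bin assembler reconstructs.

Three library designs are modelled:

* **Standard (SNP discovery).** Single complete digest with a rare
  cutter; 2×60 bp reads; 300–800 bp shear window. Contigs extend
  ~300–800 bp from each cut site.
* **Partial digest (whole-genome tiling).** A frequent cutter (or two)
  digested incompletely, so different molecule copies are cut at
  different site subsets, producing overlapping fragments several kb
  long; 1–5 kb fragments are gel-selected before shearing (200–1200 bp
  window, 40+80 bp reads). Adjacent cut sites then carry overlapping
  contigs and the union tiles the genome.
* **Long insert.** A rare cutter plus two circularization steps places
  sequence 1–6 kb from the cut site at the far end of a short (~600 bp)
  sequencable fragment. Each final fragment carries one ligation
  junction; with 40+80 bp reads on 600 bp fragments, the expected
  fraction of fragments whose junction lands inside a read span is
  (40+80)/600 = 20%, which is why the protocol keeps final fragments
  near 600 bp (bound: 25%).

## Binning and filters

The tag is the first 39 nt of (barcode-trimmed) read 1 — the length
used by the contig-naming dialect — and is configurable. Filters, with
defaults per mode:

| parameter | default | meaning |
| --- | --- | --- |
| `min_count` | 30 (SNP) / 25 (partial) / 1000 (long-insert) | bins below this lack calling depth |
| `max_count` | 1000 (SNP) / 500 (partial) / none (long-insert) | bins at/above this are repetitive |
| derivative removal | on | tags at Hamming distance 1 from a repetitive tag are its error shadows |
| `coverage_cap` | 30× | bins are truncated (prefix order, no RNG) once Σ len(read 2) / region estimate exceeds the cap |
| quality filter | > 25 bases at phred ≤ 11 | drops the whole pair ('K' decodes to 11 under the offset-64 encoding); an orphaned mate cannot be binned |

Counts are pooled across samples: contigs are deliberately built from
all individuals together so that per-sample genotypes are read off one
shared reference. The region-length estimate used for depth defaults to
the upper bound of the shear window (read 2 can land no farther out).

## Per-bin assembly

K-mers are stored canonically (lexicographic minimum of k-mer and
reverse complement; k odd so no k-mer is its own reverse complement);
k-mers containing N are skipped. Cleanup, applied to a fixpoint:

1. **Coverage cutoff** (`cov_cutoff`, default 2): k-mers with
   multiplicity below the cutoff are dropped. This is purely an
   error-removal device — for error-free input (several validation
   experiments) it is set to 1, because otherwise the single-coverage
   k-mers at the extreme ends of the read-covered span are always
   clipped and exact truth equality is impossible by construction.
2. **Tip clipping**: dead-end unbranched paths shorter than 2k.
3. **Bubble popping**: parallel unbranched paths sharing both junction
   k-mer sets, with ≥ 90% identity (edlib edit distance), are merged
   keeping the higher-coverage branch. A balanced heterozygous SNP
   therefore yields one contig carrying one allele; the site is
   re-discovered at the pileup stage, where both alleles pass the
   count rule.

Contigs are maximal unbranched paths, canonically oriented
(lexicographic minimum of sequence and reverse complement) and sorted
longest-first — this makes output byte-deterministic and exactly
strand-invariant. Contigs below `min_contig_length` (100 bp) are
dropped. Mean k-mer coverage is the mean node multiplicity along the
path, printed with six decimals in the FASTA header.

**Word-length choice.** Deep bins support long words, sparse bins need
short ones. The depth→k step map is: < 10× → 21, 10–30× → 25,
30–100× → 29, > 100× → 31 (monotone by construction). Each bin is
assembled at `k_low` = 21, the predicted k, and `k_high` = 31, and the
trial with the largest total assembled length is kept; ties go to the
larger N50, then the smaller k. The specific map and the tie-breaks are
this package's own calibration — the depth-adaptive *shape* is the
method's point; all values are configurable.

**Two-pass long-insert assembly.** Pass 1 runs at k=41 (long words
separate repeat copies that share shorter words). Pass 2 runs at the
coverage-predicted k with pass-1 contigs added to the input once; after
graph cleanup, pass-1 contigs are threaded through the unitig graph and
junctions whose observed (in, out) transitions form a one-to-one
matching are spliced (k−1 overlaps verified literally, junction unitigs
duplicated as needed, consecutive traversals composed into chains).
This resolves exact repeats with length between the pass-2 word length
and the pass-1 word length. Note an inherent limit: an exact repeat
longer than the read length cannot be resolved by any word length —
pass-1 contigs themselves break there — so the mechanism targets the
window between the two word lengths, and the repeat-bridging test uses
a 30 bp repeat (k₂ = 25 < 30 < k₁ = 41).

## Read-back alignment and calling

Reads are mapped to their own bin's contigs by seed-and-extend: exact
17-mer seeds anchor a diagonal on either strand; if the gapless
interpretation has ≤ 2 mismatches it is accepted directly, otherwise a
banded gapped alignment runs around the diagonal (match +1, mismatch
−2, gap open −4, gap extend −1, band 10). Alignments scoring below 0.6
× read length are rejected; reads scoring equally on two contigs are
ambiguous and dropped. The scoring values are this package's own (the
aligner they stand in for is proprietary); the gapless fast path is
exact whenever no indel is present, which at a 0.5% error rate is
> 99% of reads.

Pileups keep only bases with phred ≥ 20 ("high-quality nucleotides";
the threshold is our interpretation and is configurable). Insertions
are counted at the contig base preceding them, deletions at their first
deleted position; coordinates are 0-based half-open internally and
1-based in every report. Genotypes per sample: alleles with ≥ 4
observations pass; 0 passing → no-call (`-`), 1 → homozygote, 2 →
heterozygote (`[X/Y]`, reference allele first), ≥ 3 → flagged
multi-allelic no-call. Homozygotes must themselves reach the ≥ 4 count
— the published rule specifies the threshold only for a nucleotide
*change*; requiring it of the single allele too is the symmetric
reading. Indels are called under the same rule. A record is emitted
wherever any sample's call contains an allele differing from the contig
consensus; output is the two-line report dialect
(`212 C low-110 [C/A] high-141 C`) and minimal VCF 4.2 (validated by
parsing with pysam in the tests).

**Haplotype pairing.** A polymorphism inside the tag itself splits a
locus into two tags at Hamming distance 1, each assembling a
chromosome-specific contig. Tags with exactly one distance-1 partner,
both passing the count filters, with count ratio within [1/3, 3]
(alleles of one locus are expected near 1:1; the bound excludes
error-derived partners and is our choice) are paired, and the aligned
differences between their contigs are reported as phased variants.
Gap placement within ~15 columns of a contig end is ambiguous
(overhanging span, not variation) and excluded from the difference
list.

## The simulator

What it models: i.i.d. genomes at a chosen GC (linear or circular —
circular matters because a bacterial chromosome has no ends and edge
effects would distort coverage statistics); diploid variant planting
(SNPs and short indels, ≥ 10 bp apart); per-copy partial digestion
(every site cut independently with probability `partial_cut_prob`);
gel selection of digest fragments and of sheared pieces; per-base
substitution errors at quality 15 against quality 40 for correct bases
(so the phred ≥ 20 pileup filter is meaningful — this also means
simulated errors stress the assembler but not the caller, which is the
division of labour the quality model encodes); and long-insert
geometry with one junction per final fragment.

Defaults are the study conditions of the three designs.
`SimConfig()` is the standard library (2×60 bp, 300–800 bp window);
`SimConfig.partial_digest()` is the whole-genome design (40+80 bp,
1–5 kb digest window then 200–1200 bp shear window, 50 molecule
copies, ~40 pairs per tag, **cut probability 0.1** — a digestion level
whose fragment pool actually populates the 1–5 kb gel window: with two
4-cutters the combined site spacing is ~128 bp, so cutting at p = 0.1
gives mean inter-cut distances of ~1.3 kb and overlapping several-kb
fragments, which is what "partial digest" means for this protocol);
`SimConfig.long_insert()` samples inserts 1–6 kb from SbfI sites.
Shearing draws the retained cut-end piece's length uniformly from the
selection window (the net effect of shearing followed by gel
selection), and each fragment is sheared `2 × depth` times
independently to emulate the many identical molecule copies in a real
prep.

What it does **not** model: PCR and GC bias, quality-by-cycle decay,
adapter chimeras, indel sequencing errors, or re-ligation concatemers.
Passing tests therefore demonstrate the pipeline's correctness under
clean library geometry and uniform substitution noise, not robustness
to every real-data artifact.

## Validation experiments and problem sizes

All expectations are computed against simulator truth tables:

* **Junction Monte Carlo** — 100,000 final fragments, length normal
  (600, 60) truncated at 200 bp; measured junction-in-read fraction
  ~20%, below the 25% design bound.
* **Whole-genome tiling** — 100 kb circular genome, NlaIII + Sau3AI
  partial digest as above, error-free reads, bins 25–500, best-of-three
  k 21/25–31, contigs placed on the truth genome by exact/seeded
  alignment. Measured: ≥ 99.9% of bases under ≥ 1 placed contig, ≥ 91%
  under ≥ 5. The 100 kb size keeps the experiment at about a minute on
  one CPU while leaving ~780 cut sites, plenty for the coverage
  statistics to stabilise.
* **Exact reconstruction** — 200 error-free bins (300–800 bp regions,
  depth 20): the single contig must equal the read-covered truth
  substring exactly (up to reverse complement) in ≥ 95% of bins.
* **Variant recovery** — 200 diploid two-sample loci, 30× per sample,
  0.5% error rate, one planted heterozygous SNP each: sensitivity
  ≥ 0.90 with zero records at unplanted positions.
* **Determinism** — identical seeds reproduce contig FASTA output byte
  for byte; binning is order-independent at the bin level; assembly is
  strand-invariant.

## Known limitations

* The graph cleanup thresholds are analogues of, not clones of, any
  particular historical assembler build, so contig counts on real
  libraries will differ in detail even at identical inputs.
* Paired-end insert-size constraints are not used inside a bin: all of
  a bin's reads already share a locus, so pairing information adds
  little at these region sizes.
* Bins are assembled independently; no scaffolding or cross-bin merge
  of the tiled contigs is attempted.
* The haplotype pairing ratio bound and the alignment scoring are
  package calibrations, stated above, not measured properties of real
  instruments.
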