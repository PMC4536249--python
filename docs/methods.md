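# Methods

## Model and scope

indelscout detects InDel length polymorphisms without read alignment or
variant calling: it simulates PCR. A marker is a pair of 20-mer primers
whose product length differs between samples. The approach assumes inbred
(effectively homozygous) samples — one consensus product per sample and
locus — and scores alleles by product length in bp, not sequence: two
same-length products that differ only by substitutions are one allele,
exactly as they would be on a gel. Sequence-level breakpoint resolution and
heterozygote handling are out of scope.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; only table writers emit
1-based positions (marker ids follow the `chrom-start` convention with a
1-based forward-primer start). FASTA/FASTQ/GFF3 are the input formats;
FASTQ is fixed to Phred+33. FASTA parsing is a small line-tracking reader
so that malformed input is rejected with the offending line number;
FASTQ parsing uses Biopython, GFF3 uses gffutils, interval queries use
intervaltree.

## Tiling design

Forward primer, inter-primer gap and reverse primer are each 20 bp; the
window advances by 20 bp, so consecutive 60-bp reference products overlap
by 40 bp and every base that is at least 60 bp from the template end lies
in some product. Trailing windows shorter than 60 bp are discarded, giving
the exact closed form `⌊(L−60)/20⌋ + 1` for the pair count — the
interpretation validated by reproducing the printed genome-wide total from
the 12 chromosome lengths. Windows containing N are designed (the count
stays exact) but flagged unusable and excluded from matching.

## Primer matching and in-silico amplification

Matching is ungapped full-length Hamming comparison of the 20-mer against
the target, both strands; an N in the target never matches. This mirrors
end-to-end, -v-style short-read matching semantics: no indels inside a
primer footprint. Two implementations exist — a numpy-vectorized scan for
genome-scale targets and a pigeonhole seed index (a 20-mer within k
mismatches split into k+1 disjoint parts has at least one exact part) for
streaming millions of reads — and the test suite holds both equal to a
naive Python scan.

An amplicon requires a forward-primer site and a properly oriented
reverse-footprint site downstream on the same strand, non-overlapping
footprints (length ≥ 40 bp), and a genomic product length in [40, 400] bp
by default — wide enough to tolerate InDels between the two references.
Uniqueness is defined at the pair level (exactly one amplicon in each
reference genome), not at the single-primer level: demanding that each
20-mer be unique within 3 mismatches genome-wide would reject nearly
everything at genome scale, and the discriminating event for a marker is
the amplicon, not the primer. Read-level e-PCR requires the entire product
inside one read (both read orientations are searched; products are
reported in pair orientation). This biases against insertions longer than
read length − 40 bp; the simulator's truth table marks such loci
undetectable rather than pretending otherwise.

## Quality filtering

The read-retention rule for the Phred-20 cutoff is: keep a read when at
least 70 % of its bases reach Q20 — the standard whole-read retention
default for cutoff-based filters. Both the cutoff and the fraction are
configurable.

## Genotyping and statistics

The consensus product per (locus, sample) is the modal (length, sequence)
product; ties break to the smaller length, then the lexicographically
smaller sequence, making every report deterministic under input
permutation. A locus becomes a marker iff typed in ≥ 20 samples (the
pipeline's hard support rule, configurable) with ≥ 2 length alleles.
PIC = 1 − Σ p² is computed at full precision over typed samples only
(missing cells never enter a denominator) and rounded half-up to 2
decimals in tables, like every other reported ratio. Allele ranking
(major/second major) orders by count descending, then length ascending;
the major-allele difference is the absolute length difference of the top
two. Per-group major-allele frequencies use the *global* major allele
within each group's typed samples; groups with no typed samples are
omitted.

## Region annotation

Seven categories are built from GFF3: CDS, 5′-UTR, 3′-UTR, intron (gene
span minus exons), 0.5-kb TSS-upstream and TES-downstream flanks on the
coding strand (truncated at chromosome ends), and intergenic as the exact
complement of all gene-derived intervals. Exonic stretches with no
CDS/UTR annotation are kept gene-internal (counted with introns) so the
categories cover every base. Categories may overlap; a marker is assigned
one category by its product midpoint under the fixed precedence
CDS > 5′-UTR > 3′-UTR > intron > TSS-up > TES-down > intergenic, which
makes the per-category counts a disjoint partition. The precedence and the
midpoint rule are design choices: published region tables report disjoint
counts without stating an overlap rule, and this one is deterministic and
testable.

## Marker selection and validation primers

Two gel-resolution tiers share the PIC ≥ 0.5 cutoff and differ in the
minimum major-allele difference (3 bp for polyacrylamide, 8 bp for
agarose). Validation templates are the 20-bp variable window (the
inter-primer gap, centered on the reference product) plus symmetric
flanks: 40 bp (100-bp template, 60–100-bp products) for polyacrylamide.
For agarose-scale 150–300-bp products the same recipe is extended with
150-bp flanks (320-bp template) — an inferred extension, since only the
100-bp recipe is standard.

Candidate primers (20–28 nt, both flanks, product spanning the window) are
filtered to Tm ∈ [60, 65] °C, GC ∈ [30, 70] %, G/C 3′ terminus (an
optional 2-of-5 GC clamp is stricter), then scored by

    penalty = 1·|len−23| + 2·|Tm−63| + 0.5·|GC−50| + 2·|ΔTm between mates|

summed over both mates where applicable. Tm deviations carry the largest
weights because mates must anneal together; the minimal-penalty pair wins,
with ties to the leftmost forward primer, then the shortest product. Tm is
the nearest-neighbor duplex model (unified parameters, 50 mM monovalent
salt, 250 nM oligo) via Biopython. The optimizer is exhaustive over the
candidate space, so the test-suite oracle is an independent re-enumeration.

## Simulator

`simdata` emulates the study design, not rice biology: i.i.d. bases at a
set GC content (default 0.44), a diverged second reference with planted
InDels and background SNPs (default 10⁻³/bp), and uniform single-end reads
(default 87 bp at 2×, matching the target study's read scale; recovery
experiments use 30×). InDel lengths are geometric (p = 0.4, truncated to
[1, 50] bp) because small length differences dominate real data; each
locus sits at the center of one tiling window's inter-primer gap, spaced
≥ 100 bp apart, so it falls in exactly one designed product's variable
region and truth matching is unambiguous. Deletions longer than the 20-bp
gap and insertions pushing the product past the read length are marked
undetectable. Base errors are substitutions at a constant per-base rate
whose Phred score is carried on every base (Q40 for error-free runs). What
the simulator does not model — repeats and transposons, indel clustering,
coverage and quality heterogeneity, paired ends — limits what passing
tests prove about real genomes: recovery results show the machinery is
correct, not that real-data yield matches.

All randomness flows from a single integer seed (population and read
stages derive child streams from it), so every simulated dataset and every
stochastic test is reproducible; the pipeline manifest records the seed,
parameters, per-stage counts and output checksums, and a rerun with the
same config is bit-identical.

## Problem sizes

Test and demonstration runs use desk-scale genomes: the parameter-recovery
experiment runs 200 samples over a 10-kb genome at 30× error-free
coverage with 20 planted biallelic loci at frequency 0.5 (≈ 0.7 M reads),
recovering every detectable locus with its correct major-allele difference
and calling no false loci; unit fixtures use 2–5-kb genomes. These sizes
were chosen so the full suite runs in well under a minute of simulation
time while still exercising every stage at meaningful depth.

## Known limitations

* Absolute unique-pair proportions on real genomes depend on the matching
  tool's reporting mode and repeat content; they are not expected to match
  published real-data percentages.
* Single-read product spanning caps detectable insertion size at
  read length − 40 bp.
* Monomorphic and under-typed loci are reported with reasons but carry no
  confidence measure; depth, not statistics, drives typing completeness.
* The agarose-tier template recipe is an extension (see above), and gel
  scoring of validation panels is summarized, not simulated.
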