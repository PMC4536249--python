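"""Sequence and annotation I/O.

Readers and writers for FASTA, FASTQ (Phred+33) and GFF3, read quality
filtering, and the genomic region index used to classify markers.

Coordinate convention: everything in memory is 0-based, half-open.
User-facing tables print 1-based positions; the conversion happens only at
the table writers, never inside the data structures.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator
from intervaltree import IntervalTree

__all__ = [
    "SequenceRecord",
    "ReadRecord",
    "FeatureInterval",
    "RegionIndex",
    "FastaParseError",
    "FastqParseError",
    "Gff3Error",
    "REGION_CATEGORIES",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "quality_filter_reads",
    "build_region_index",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_DNA = frozenset("ACGTN")

#: The seven genomic categories, in the precedence order used when a single
#: category must be assigned to a position (coding first, intergenic last).
REGION_CATEGORIES = (
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "intron",
    "TSS_up_0.5kb",
    "TES_down_0.5kb",
    "intergenic",
)


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaParseError(ValueError):
    pass


class FastqParseError(ValueError):
    pass


class Gff3Error(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class SequenceRecord:
    """A named DNA sequence (a chromosome, contig or template)."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class ReadRecord:
    """A single sequencing read with per-base Phred qualities."""

    id: str
    seq: str
    quals: Tuple[int, ...]
    sample_id: str

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: {len(self.quals)} qualities for "
                f"{len(self.seq)} bases"
            )


def read_fasta(path: str | os.PathLike) -> List[SequenceRecord]:
    """Parse a FASTA file into records, in file order.

    Sequences are uppercased and restricted to the alphabet {A,C,G,T,N}.
    Malformed input (text before the first header, empty sequence, duplicate
    or empty ids, invalid characters) raises :class:`FastaParseError` naming
    the offending line.
    """
    records: List[SequenceRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    header_line = 0
    chunks: List[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FastaParseError(
                f"{path}: empty sequence for {header!r} (header at line {header_line})"
            )
        bad = set(seq) - _VALID_DNA
        if bad:
            raise FastaParseError(
                f"{path}: invalid characters {sorted(bad)} in record {header!r}"
            )
        if header in seen:
            raise FastaParseError(
                f"{path}: duplicate id {header!r} (line {header_line})"
            )
        seen.add(header)
        records.append(SequenceRecord(id=header, seq=seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike, sample_id: str) -> Iterator[ReadRecord]:
    """Lazily parse a Phred+33 FASTQ file into :class:`ReadRecord` objects."""
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield ReadRecord(
                    id=title.split()[0],
                    seq=seq.upper(),
                    quals=tuple(ord(c) - 33 for c in qual),
                    sample_id=sample_id,
                )
        except ValueError as exc:  # truncated record / length mismatch
            raise FastqParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def quality_filter_reads(
    reads: Iterable[ReadRecord], cutoff: int = 20, min_fraction: float = 0.70
) -> Iterator[ReadRecord]:
    """Keep reads in which >= ``min_fraction`` of bases have Phred >= ``cutoff``.

    This is the standard whole-read retention rule for a per-base quality
    cutoff: a read passes when at least 70 % of its bases (by default) meet
    the Q20 threshold. Idempotent; the output is always a subset of the input.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    for read in reads:
        n = len(read.quals)
        if n == 0:
            continue
        good = sum(1 for q in read.quals if q >= cutoff)
        if good / n >= min_fraction:
            yield read


# ---------------------------------------------------------------------------
# Genomic region index
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class FeatureInterval:
    chrom: str
    start: int
    end: int
    category: str
    gene_id: Optional[str] = None


@dataclass
class RegionIndex:
    """Interval map of the seven genomic categories.

    Categories other than ``intergenic`` may overlap one another (a CDS base
    also lies in its gene span's intron complement, UTRs touch exons, and
    the 0.5-kb flanks of adjacent genes can overlap gene bodies).
    ``intergenic`` is the exact complement of the union of all gene-derived
    intervals, so every base is covered by at least one category.
    """

    chrom_lengths: Dict[str, int]
    trees: Dict[str, Dict[str, IntervalTree]] = field(default_factory=dict)
    category_bp: Dict[str, int] = field(default_factory=dict)

    def add(self, iv: FeatureInterval) -> None:
        if iv.start >= iv.end:
            return
        per_chrom = self.trees.setdefault(iv.chrom, {})
        tree = per_chrom.setdefault(iv.category, IntervalTree())
        tree.addi(iv.start, iv.end, iv.gene_id)

    def categories_at(self, chrom: str, pos: int) -> Dict[str, Optional[str]]:
        """All categories covering ``pos``, mapped to a gene id (or None)."""
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chrom_lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        out: Dict[str, Optional[str]] = {}
        for category, tree in self.trees.get(chrom, {}).items():
            hits = tree[pos]
            if hits:
                gene = sorted((h.data for h in hits), key=lambda g: (g is None, g))[0]
                out[category] = gene
        return out

    def finalize(self) -> None:
        """Merge intervals, build the intergenic complement and bp totals."""
        for chrom, length in self.chrom_lengths.items():
            per_chrom = self.trees.setdefault(chrom, {})
            covered = IntervalTree()
            for category, tree in per_chrom.items():
                if category == "intergenic":
                    continue
                for iv in tree:
                    covered.addi(iv.begin, iv.end)
            covered.merge_overlaps()
            inter = IntervalTree()
            prev = 0
            for iv in sorted(covered):
                if iv.begin > prev:
                    inter.addi(prev, iv.begin)
                prev = max(prev, iv.end)
            if prev < length:
                inter.addi(prev, length)
            per_chrom["intergenic"] = inter
        totals = {cat: 0 for cat in REGION_CATEGORIES}
        for chrom, per_chrom in self.trees.items():
            for category, tree in per_chrom.items():
                merged = IntervalTree(tree)
                merged.merge_overlaps()
                totals[category] += sum(iv.end - iv.begin for iv in merged)
        self.category_bp = totals


def _to0(start_1based: int, end_1based: int) -> Tuple[int, int]:
    # GFF3 is 1-based inclusive; internal convention is 0-based half-open.
    return start_1based - 1, end_1based


def build_region_index(
    gff3_path: str | os.PathLike,
    chrom_lengths: Mapping[str, int],
    flank: int = 500,
) -> RegionIndex:
    """Build the seven-category region index from a GFF3 annotation.

    * TSS_up_0.5kb: ``flank`` bp upstream of the transcription start site on
      the coding strand; TES_down_0.5kb the mirror window downstream of the
      transcription end site. Flanks are truncated at chromosome ends.
    * introns: gene span minus the union of the gene's exons.
    * intergenic: complement of the union of all gene-derived intervals
      (gene spans plus their flanks).
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    index = RegionIndex(chrom_lengths=dict(chrom_lengths))

    for gene in db.features_of_type("gene"):
        chrom = gene.seqid
        if chrom not in chrom_lengths:
            raise Gff3Error(f"gene {gene.id}: unknown chromosome {chrom!r}")
        length = chrom_lengths[chrom]
        gstart, gend = _to0(gene.start, gene.end)
        if gend > length or gstart < 0:
            raise Gff3Error(
                f"gene {gene.id}: span [{gene.start},{gene.end}] exceeds "
                f"{chrom} length {length}"
            )
        if gene.strand not in {"+", "-"}:
            raise Gff3Error(f"gene {gene.id}: missing strand")

        exon_tree = IntervalTree()
        for ftype, category in (
            ("exon", None),
            ("CDS", "CDS"),
            ("five_prime_UTR", "five_prime_UTR"),
            ("three_prime_UTR", "three_prime_UTR"),
        ):
            for feat in db.children(gene, featuretype=ftype):
                fstart, fend = _to0(feat.start, feat.end)
                if fend > length:
                    raise Gff3Error(
                        f"feature {feat.id or ftype} of gene {gene.id} exceeds "
                        f"{chrom} length {length}"
                    )
                if ftype == "exon":
                    exon_tree.addi(fstart, fend)
                else:
                    index.add(FeatureInterval(chrom, fstart, fend, category, gene.id))

        # Introns: gene span minus exons (CDS+UTRs stand in when no exon rows).
        if not exon_tree:
            for category in ("CDS", "five_prime_UTR", "three_prime_UTR"):
                tree = index.trees.get(chrom, {}).get(category)
                if tree:
                    for iv in tree.overlap(gstart, gend):
                        if iv.data == gene.id:
                            exon_tree.addi(iv.begin, iv.end)
        exon_tree.merge_overlaps()
        prev = gstart
        for iv in sorted(exon_tree):
            if iv.begin > prev:
                index.add(FeatureInterval(chrom, prev, iv.begin, "intron", gene.id))
            prev = max(prev, iv.end)
        if prev < gend:
            index.add(FeatureInterval(chrom, prev, gend, "intron", gene.id))

        if gene.strand == "+":
            tss_up = (max(0, gstart - flank), gstart)
            tes_down = (gend, min(length, gend + flank))
        else:
            tss_up = (gend, min(length, gend + flank))
            tes_down = (max(0, gstart - flank), gstart)
        index.add(FeatureInterval(chrom, *tss_up, "TSS_up_0.5kb", gene.id))
        index.add(FeatureInterval(chrom, *tes_down, "TES_down_0.5kb", gene.id))

        # Exon stretches that carry no CDS/UTR annotation (non-coding exon
        # parts) would otherwise fall through every category; keep them
        # gene-internal by assigning them to the exon's gene as intron-like
        # coverage so the categories tile the whole gene span.
        annotated = IntervalTree()
        for category in ("CDS", "five_prime_UTR", "three_prime_UTR"):
            tree = index.trees.get(chrom, {}).get(category)
            if tree:
                for iv in tree.overlap(gstart, gend):
                    if iv.data == gene.id:
                        annotated.addi(iv.begin, iv.end)
        for iv in sorted(exon_tree):
            gaps = IntervalTree([iv])
            for c in annotated.overlap(iv.begin, iv.end):
                gaps.chop(c.begin, c.end)
            for gap in gaps:
                index.add(FeatureInterval(chrom, gap.begin, gap.end, "intron", gene.id))

    index.finalize()
    return index
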