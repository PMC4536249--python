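"""Mismatch-tolerant primer-site search and in-silico amplification.

Matching semantics are ungapped, full-length Hamming comparison of the
20-mer primer against the target (end-to-end, like Bowtie's -v mode): no
indels inside a primer footprint, and an N in the target never matches any
primer base. Two search paths exist:

* :func:`find_primer_sites` — a numpy-vectorized scan of one primer against
  one target, used for genome-level amplification and uniqueness filtering.
* :class:`ReadProductScanner` — a pigeonhole seed index over many primer
  pairs, used to stream millions of short reads through the unique pair set.

Both must (and, by the test suite's independent naive-scan oracle, do)
return exactly the same hits.
"""

from __future__ import annotations

import os
import csv
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np

from .primer_design import PrimerPair
from .seqio import ReadRecord, SequenceRecord, revcomp

__all__ = [
    "PrimerHit",
    "Amplicon",
    "UniquenessVerdict",
    "find_primer_sites",
    "epcr_template",
    "classify_unique_pairs",
    "epcr_reads",
    "ReadProductScanner",
    "write_product_table",
    "read_product_table",
]

PRIMER_LEN = 20

GenomeLike = Union[SequenceRecord, Sequence[SequenceRecord], Mapping[str, str]]


@dataclass(frozen=True, slots=True)
class PrimerHit:
    """One ungapped full-length primer match on a target sequence."""

    target_id: str
    pos: int
    strand: str  # '+' or '-'
    mismatches: int


@dataclass(frozen=True, slots=True)
class Amplicon:
    """One predicted PCR product: forward-primer start to reverse-footprint end."""

    source_id: str
    start: int
    end: int
    seq: str
    f_mm: int
    r_mm: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class UniquenessVerdict:
    pair_id: str
    n_products_genome_a: int
    n_products_genome_b: int

    @property
    def unique(self) -> bool:
        return self.n_products_genome_a == 1 and self.n_products_genome_b == 1


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_positions(target_arr: np.ndarray, primer: str, max_mm: int) -> np.ndarray:
    """Start positions (and mismatch counts) where primer matches the array."""
    n = target_arr.size
    if n < PRIMER_LEN:
        return np.empty((0, 2), dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(target_arr, PRIMER_LEN)
    mm = (windows != _encode(primer)).sum(axis=1)
    pos = np.nonzero(mm <= max_mm)[0]
    return np.column_stack([pos, mm[pos]])


def find_primer_sites(
    target: str, primer: str, max_mm: int, target_id: str = ""
) -> List[PrimerHit]:
    """All full-length matches of a 20-mer primer in a target, both strands.

    A minus-strand hit at position p means the reverse complement of the
    primer occupies ``target[p:p+20]``. Hits are sorted by position, plus
    strand first at ties.
    """
    if len(primer) != PRIMER_LEN:
        raise ValueError(f"primer must be {PRIMER_LEN} nt, got {len(primer)}")
    if "N" in primer:
        raise ValueError("primer must not contain N")
    if max_mm not in (0, 1, 2, 3):
        raise ValueError("max_mm must be in 0..3")
    arr = _encode(target.upper())
    hits = [
        PrimerHit(target_id, int(p), "+", int(m))
        for p, m in _scan_positions(arr, primer, max_mm)
    ]
    hits += [
        PrimerHit(target_id, int(p), "-", int(m))
        for p, m in _scan_positions(arr, revcomp(primer), max_mm)
    ]
    hits.sort(key=lambda h: (h.pos, h.strand))
    return hits


def _as_records(genome: GenomeLike) -> List[SequenceRecord]:
    if isinstance(genome, SequenceRecord):
        return [genome]
    if isinstance(genome, Mapping):
        return [SequenceRecord(id=k, seq=v) for k, v in genome.items()]
    return list(genome)


def _paired_products(
    seq: str,
    source_id: str,
    left_hits: np.ndarray,
    right_hits: np.ndarray,
    min_len: int,
    max_len: int,
    orient: str,
) -> List[Amplicon]:
    """Combine left-primer and right-footprint hit arrays into amplicons.

    ``orient='+'``: left is the forward primer, right the reverse footprint;
    the product is reported as-is. ``orient='-'``: the pair anneals to the
    opposite strand; the product interval is still reported in target
    coordinates but f_mm/r_mm follow the primers' roles.
    """
    out: List[Amplicon] = []
    for a, a_mm in left_hits:
        for b, b_mm in right_hits:
            if b < a + PRIMER_LEN:
                continue  # footprints may not overlap
            end = b + PRIMER_LEN
            length = end - a
            if length > max_len:
                break  # right hits are position-sorted; all further are longer
            if length < min_len:
                continue
            f_mm, r_mm = (a_mm, b_mm) if orient == "+" else (b_mm, a_mm)
            out.append(
                Amplicon(
                    source_id=source_id,
                    start=int(a),
                    end=int(end),
                    seq=seq[a:end],
                    f_mm=int(f_mm),
                    r_mm=int(r_mm),
                )
            )
    return out


def epcr_template(
    pair: PrimerPair,
    genome: GenomeLike,
    max_mm: int = 3,
    min_len: int = 40,
    max_len: int = 400,
) -> List[Amplicon]:
    """Predict all products of one primer pair against genome sequences.

    A product arises from a forward-primer site with a properly oriented
    reverse-primer footprint downstream (on either strand of the genome),
    with both footprints non-overlapping and the product length within
    ``[min_len, max_len]``.
    """
    if not pair.usable:
        raise ValueError(f"pair {pair.pair_id} contains N; not usable for e-PCR")
    products: List[Amplicon] = []
    seen: set = set()
    for rec in _as_records(genome):
        arr = _encode(rec.seq)
        f_plus = _scan_positions(arr, pair.f_seq, max_mm)
        r_fp = _scan_positions(arr, revcomp(pair.r_seq), max_mm)
        r_plus = _scan_positions(arr, pair.r_seq, max_mm)
        f_rc = _scan_positions(arr, revcomp(pair.f_seq), max_mm)
        for amp in _paired_products(
            rec.seq, rec.id, f_plus, r_fp, min_len, max_len, "+"
        ) + _paired_products(rec.seq, rec.id, r_plus, f_rc, min_len, max_len, "-"):
            key = (amp.source_id, amp.start, amp.end)
            if key not in seen:
                seen.add(key)
                products.append(amp)
    products.sort(key=lambda a: (a.source_id, a.start, a.end))
    return products


def classify_unique_pairs(
    pairs: Iterable[PrimerPair],
    genome_a: GenomeLike,
    genome_b: GenomeLike,
    max_mm: int = 3,
    min_len: int = 40,
    max_len: int = 400,
) -> List[UniquenessVerdict]:
    """Uniqueness verdict per pair: exactly one product in each genome."""
    recs_a = _as_records(genome_a)
    recs_b = _as_records(genome_b)
    verdicts = []
    for pair in pairs:
        if not pair.usable:
            verdicts.append(UniquenessVerdict(pair.pair_id, 0, 0))
            continue
        n_a = len(epcr_template(pair, recs_a, max_mm, min_len, max_len))
        n_b = len(epcr_template(pair, recs_b, max_mm, min_len, max_len))
        verdicts.append(UniquenessVerdict(pair.pair_id, n_a, n_b))
    return verdicts


# ---------------------------------------------------------------------------
# Read-level e-PCR
# ---------------------------------------------------------------------------

def _hamming_le(a: str, b: str, max_mm: int) -> int:
    """Hamming distance of equal-length strings, or -1 if it exceeds max_mm."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > max_mm:
                return -1
    return mm


class ReadProductScanner:
    """Batch in-silico PCR of many primer pairs against a read stream.

    Seeds use the pigeonhole principle: with at most ``max_mm`` mismatches
    over a 20-mer split into ``max_mm + 1`` disjoint parts, at least one part
    matches exactly, so an exact-seed dictionary lookup followed by a full
    Hamming verification finds every valid site in one pass per read.

    Each pair contributes four role sequences so that a single forward pass
    over the read covers both read orientations:

    * role 0/1 — forward primer, then reverse-primer footprint (read carries
      the product in pair orientation);
    * role 2/3 — reverse primer, then forward-primer footprint (read is the
      reverse complement of the product; the emitted sequence is flipped
      back into pair orientation).
    """

    def __init__(self, pairs: Iterable[PrimerPair], max_mm: int = 1):
        if max_mm not in (0, 1, 2, 3):
            raise ValueError("max_mm must be in 0..3")
        self.max_mm = max_mm
        self.pairs: List[PrimerPair] = [p for p in pairs if p.usable]
        part_len = PRIMER_LEN // (max_mm + 1)
        self._part_len = part_len
        self._offsets = [i * part_len for i in range(max_mm + 1)]
        self._roles: List[Tuple[str, str, str, str]] = []
        self._index: Dict[str, List[Tuple[int, int, int]]] = defaultdict(list)
        for idx, p in enumerate(self.pairs):
            roles = (p.f_seq, revcomp(p.r_seq), p.r_seq, revcomp(p.f_seq))
            self._roles.append(roles)
            for role, seq in enumerate(roles):
                for off in self._offsets:
                    self._index[seq[off : off + part_len]].append((idx, role, off))
        self._index = dict(self._index)

    def scan_read(self, read: ReadRecord) -> List[Tuple[str, int, str]]:
        """Products found in one read: (pair_id, product_length, product_seq)."""
        seq = read.seq
        n = len(seq)
        p = self._part_len
        index = self._index
        max_mm = self.max_mm
        hits: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
        seen: set = set()
        for i in range(n - p + 1):
            entries = index.get(seq[i : i + p])
            if not entries:
                continue
            for idx, role, off in entries:
                pos = i - off
                if pos < 0 or pos + PRIMER_LEN > n:
                    continue
                key = (idx, role, pos)
                if key in seen:
                    continue
                seen.add(key)
                mm = _hamming_le(seq[pos : pos + PRIMER_LEN], self._roles[idx][role], max_mm)
                if mm >= 0:
                    hits.setdefault((idx, role), []).append((pos, mm))
        products: List[Tuple[str, int, str]] = []
        emitted: set = set()
        for (idx, role), left in hits.items():
            if role not in (0, 2):
                continue
            right = hits.get((idx, role + 1))
            if not right:
                continue
            pid = self.pairs[idx].pair_id
            for a, _ in left:
                for b, _ in right:
                    if b < a + PRIMER_LEN:
                        continue
                    frag = seq[a : b + PRIMER_LEN]
                    if role == 2:
                        frag = revcomp(frag)
                    key = (pid, len(frag), frag)
                    if key not in emitted:
                        emitted.add(key)
                        products.append(key)
        return products

    def scan_reads(
        self, reads: Iterable[ReadRecord]
    ) -> List[Tuple[str, str, int, str]]:
        """Flat product records (pair_id, sample_id, length, seq) for a stream."""
        out: List[Tuple[str, str, int, str]] = []
        for read in reads:
            for pid, length, frag in self.scan_read(read):
                out.append((pid, read.sample_id, length, frag))
        return out


def epcr_reads(
    pair: PrimerPair,
    reads: Iterable[ReadRecord],
    max_mm: int = 1,
) -> List[Tuple[str, int, str]]:
    """Products of one pair across a read stream: (sample_id, length, seq).

    A product is emitted only when one read fully contains the forward
    primer and, downstream on the same strand, the reverse-primer footprint
    (each within ``max_mm`` mismatches); both read orientations are searched.
    """
    scanner = ReadProductScanner([pair], max_mm=max_mm)
    return [
        (sample_id, length, frag)
        for _, sample_id, length, frag in scanner.scan_reads(reads)
    ]


def write_product_table(
    products: Iterable[Tuple[str, str, int, str]], path: str | os.PathLike
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["pair_id", "sample_id", "product_length", "product_seq"])
        for row in products:
            writer.writerow(row)


def read_product_table(path: str | os.PathLike) -> List[Tuple[str, str, int, str]]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                (
                    row["pair_id"],
                    row["sample_id"],
                    int(row["product_length"]),
                    row["product_seq"],
                )
            )
    return out
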