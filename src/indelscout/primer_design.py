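"""Sliding-window e-PCR primer-pair design.

The tiling scheme extracts a 20-bp forward primer, skips a 20-bp gap, and
extracts a 20-bp reverse primer, then advances the window by one primer
length so that consecutive 60-bp reference products overlap by 40 bp and
every next forward primer sits immediately upstream of the previous reverse
primer's footprint. Trailing windows shorter than the full 60 bp are
discarded, which makes the pair count an exact closed form of the template
length.
"""

from __future__ import annotations

import csv
import os
import warnings
from dataclasses import dataclass
from typing import Iterable, List

from .seqio import SequenceRecord, revcomp

__all__ = [
    "PrimerPair",
    "design_sliding_window_primers",
    "expected_pair_count",
    "write_primer_table",
    "read_primer_table",
    "RICE_CHROM_LENGTHS",
]

#: Assembled lengths (bp) of the 12 rice chromosomes used as the reference
#: template scale for the genome-wide design.
RICE_CHROM_LENGTHS = {
    "chr01": 43_270_923,
    "chr02": 35_937_250,
    "chr03": 36_413_819,
    "chr04": 35_502_694,
    "chr05": 29_958_434,
    "chr06": 31_248_787,
    "chr07": 29_697_621,
    "chr08": 28_443_022,
    "chr09": 23_012_720,
    "chr10": 23_207_287,
    "chr11": 29_021_106,
    "chr12": 27_531_856,
}


@dataclass(frozen=True, slots=True)
class PrimerPair:
    """A forward/reverse tiling primer pair with template coordinates.

    ``f_seq`` is the template forward strand at ``[f_start, f_start+20)``;
    ``r_seq`` is the reverse complement of the template at
    ``[r_start, r_start+20)``, so the reference product is the interval
    ``[f_start, r_start+20)`` — 60 bp for the standard 20/20/20 layout.
    ``usable`` is False when either primer contains N (such pairs are kept in
    the design list so counts stay exact, but excluded from matching).
    """

    pair_id: str
    chrom: str
    f_start: int
    f_seq: str
    r_start: int
    r_seq: str
    usable: bool = True

    @property
    def product_start(self) -> int:
        return self.f_start

    @property
    def product_end(self) -> int:
        return self.r_start + len(self.r_seq)

    @property
    def ref_product_length(self) -> int:
        return self.product_end - self.product_start


def expected_pair_count(
    L: int, primer_len: int = 20, gap_len: int = 20, step: int = 20
) -> int:
    """Number of pairs the sliding-window design yields on a length-L template.

    ``floor((L - (2*primer_len + gap_len)) / step) + 1`` when the template
    fits at least one full window, else 0.
    """
    if L < 0:
        raise ValueError("length must be >= 0")
    window = 2 * primer_len + gap_len
    if L < window:
        return 0
    return (L - window) // step + 1


def design_sliding_window_primers(
    template: SequenceRecord,
    primer_len: int = 20,
    gap_len: int = 20,
    step: int = 20,
) -> List[PrimerPair]:
    """Design tiling primer pairs over a template sequence.

    Pair ids follow the ``chrom-fstart`` convention with a 1-based forward
    start, matching the marker naming used in reports.
    """
    window = 2 * primer_len + gap_len
    seq = template.seq
    L = len(seq)
    if L < window:
        warnings.warn(
            f"template {template.id!r} ({L} bp) shorter than one "
            f"{window}-bp window; no primers designed",
            stacklevel=2,
        )
        return []
    pairs: List[PrimerPair] = []
    for f_start in range(0, L - window + 1, step):
        r_start = f_start + primer_len + gap_len
        f_seq = seq[f_start : f_start + primer_len]
        r_fp = seq[r_start : r_start + primer_len]
        pairs.append(
            PrimerPair(
                pair_id=f"{template.id}-{f_start + 1}",
                chrom=template.id,
                f_start=f_start,
                f_seq=f_seq,
                r_start=r_start,
                r_seq=revcomp(r_fp),
                usable="N" not in f_seq and "N" not in r_fp,
            )
        )
    return pairs


_TABLE_COLUMNS = [
    "pair_id",
    "chrom",
    "f_start",
    "f_seq",
    "r_seq",
    "product_start",
    "product_end",
    "usable",
]


def write_primer_table(pairs: Iterable[PrimerPair], path: str | os.PathLike) -> None:
    """Write a primer TSV; positions are printed 1-based inclusive."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for p in pairs:
            writer.writerow(
                [
                    p.pair_id,
                    p.chrom,
                    p.f_start + 1,
                    p.f_seq,
                    p.r_seq,
                    p.product_start + 1,
                    p.product_end,
                    int(p.usable),
                ]
            )


def read_primer_table(path: str | os.PathLike) -> List[PrimerPair]:
    pairs: List[PrimerPair] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            f_start = int(row["f_start"]) - 1
            pairs.append(
                PrimerPair(
                    pair_id=row["pair_id"],
                    chrom=row["chrom"],
                    f_start=f_start,
                    f_seq=row["f_seq"],
                    r_start=int(row["product_end"]) - len(row["r_seq"]),
                    r_seq=row["r_seq"],
                    usable=bool(int(row.get("usable", 1))),
                )
            )
    return pairs
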