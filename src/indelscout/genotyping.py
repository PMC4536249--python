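"""Amplicon-length genotyping and InDel marker statistics.

A sample's genotype at a locus is the consensus (most frequent) in-silico
PCR product among its reads; the locus x sample matrix of consensus product
lengths is then screened for length polymorphisms. Allele identity is the
product length in bp — the markers are gel-scored length polymorphisms, so
same-length products that differ only by substitutions collapse to one
allele. Allelic diversity is summarized by the polymorphism information
content PIC = 1 - sum(p_j^2) over allele frequencies p_j among typed
samples (missing cells never enter a denominator).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "InDelMarker",
    "CallResult",
    "consensus_product",
    "build_matrix",
    "compute_pic",
    "call_indels",
    "major_allele_difference",
    "group_major_allele_freq",
    "write_marker_table",
]

MISSING = None

ProductRecord = Tuple[str, str, int, str]  # pair_id, sample_id, length, seq


def round2(x: float) -> float:
    """Round half-up to 2 decimals (table convention; floats round-half-even)."""
    from decimal import Decimal, ROUND_HALF_UP

    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def consensus_product(
    products: Iterable[Tuple[int, str]]
) -> Optional[Tuple[int, str]]:
    """Modal (length, seq) product, or ``MISSING`` for an empty collection.

    Count ties break toward the smaller length, then the lexicographically
    smaller sequence, so consensus calls are deterministic regardless of
    input order.
    """
    counts = Counter(products)
    if not counts:
        return MISSING
    return min(counts.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))[0]


@dataclass
class GenotypeMatrix:
    """Locus x sample table of consensus product lengths.

    ``lengths`` is a loci x samples DataFrame of floats with NaN for missing
    cells; ``seqs`` keeps the consensus sequence per non-missing cell for
    sequence-mode analyses.
    """

    lengths: pd.DataFrame
    seqs: Dict[Tuple[str, str], str] = field(default_factory=dict)

    @property
    def loci(self) -> List[str]:
        return list(self.lengths.index)

    @property
    def samples(self) -> List[str]:
        return list(self.lengths.columns)

    def typed_lengths(self, pair_id: str) -> Dict[str, int]:
        """Non-missing consensus lengths for one locus, keyed by sample."""
        row = self.lengths.loc[pair_id]
        return {s: int(v) for s, v in row.items() if not pd.isna(v)}


def build_matrix(
    sample_tables: Mapping[str, Sequence[Tuple[str, int, str]]]
    | Iterable[ProductRecord],
) -> GenotypeMatrix:
    """Assemble the genotype matrix from per-sample product tables.

    Accepts either a mapping ``sample_id -> [(pair_id, length, seq), ...]``
    or a flat iterable of (pair_id, sample_id, length, seq) records. Cells
    depend only on the per-cell multiset of products, so any input ordering
    yields an identical matrix.
    """
    explicit_samples: List[str] = []
    if isinstance(sample_tables, Mapping):
        flat: List[ProductRecord] = []
        seen_samples: set = set()
        for sample_id, rows in sample_tables.items():
            if sample_id in seen_samples:
                raise ValueError(f"duplicate product table for sample {sample_id!r}")
            seen_samples.add(sample_id)
            explicit_samples.append(sample_id)
            flat.extend((pid, sample_id, length, seq) for pid, length, seq in rows)
    else:
        flat = list(sample_tables)

    cells: Dict[Tuple[str, str], List[Tuple[int, str]]] = {}
    loci: Dict[str, None] = {}
    samples: Dict[str, None] = dict.fromkeys(explicit_samples)
    for pid, sample_id, length, seq in flat:
        cells.setdefault((pid, sample_id), []).append((int(length), seq))
        loci[pid] = None
        samples[sample_id] = None

    loci_order = sorted(loci)
    sample_order = sorted(samples)
    data = np.full((len(loci_order), len(sample_order)), np.nan)
    seqs: Dict[Tuple[str, str], str] = {}
    for i, pid in enumerate(loci_order):
        for j, sample_id in enumerate(sample_order):
            products = cells.get((pid, sample_id))
            if not products:
                continue
            call = consensus_product(products)
            data[i, j] = call[0]
            seqs[(pid, sample_id)] = call[1]
    lengths = pd.DataFrame(data, index=loci_order, columns=sample_order)
    return GenotypeMatrix(lengths=lengths, seqs=seqs)


def compute_pic(counts: Mapping[Hashable, int]) -> float:
    """Polymorphism information content: 1 - sum((count/total)^2).

    Full precision; report writers round to 2 decimals. Invariant under
    relabeling of the patterns; 0 exactly when monomorphic.
    """
    if not counts:
        raise ValueError("PIC of an empty pattern set is undefined")
    total = sum(counts.values())
    if total < 1:
        raise ValueError("pattern counts must sum to >= 1")
    return 1.0 - sum((c / total) ** 2 for c in counts.values())


def major_allele_difference(alleles: Mapping[int, int]) -> int:
    """|most frequent length - second most frequent length| in bp.

    Count ties rank toward the smaller length (the same deterministic order
    used everywhere in reports).
    """
    if len(alleles) < 2:
        raise ValueError("major allele difference needs >= 2 alleles")
    ranked = sorted(alleles.items(), key=lambda kv: (-kv[1], kv[0]))
    return abs(ranked[0][0] - ranked[1][0])


@dataclass
class InDelMarker:
    """A polymorphic locus: its allele-length spectrum and summary statistics."""

    pair_id: str
    chrom: str
    product_start: int  # 0-based, reference product interval
    product_end: int
    n_typed: int
    alleles: Dict[int, int]
    pic: float
    major_allele_diff: int
    per_group_major_freq: Dict[str, float] = field(default_factory=dict)
    region: Optional[str] = None
    gene_id: Optional[str] = None

    @property
    def allele_number(self) -> int:
        return len(self.alleles)

    @property
    def size_range(self) -> int:
        return max(self.alleles) - min(self.alleles)


@dataclass
class CallResult:
    markers: List[InDelMarker]
    excluded: List[Tuple[str, str]]  # (pair_id, reason)


def call_indels(
    matrix: GenotypeMatrix,
    min_samples: int = 20,
    pair_info: Optional[Mapping[str, Tuple[str, int, int]]] = None,
) -> CallResult:
    """Screen the genotype matrix for InDel markers.

    A locus becomes a marker iff it is typed in at least ``min_samples``
    samples and shows at least two product-length alleles (equivalently
    PIC > 0). Under-typed and monomorphic loci are reported with reasons.
    ``pair_info`` optionally maps pair_id to (chrom, product_start,
    product_end) for coordinates in the marker records.
    """
    markers: List[InDelMarker] = []
    excluded: List[Tuple[str, str]] = []
    arr = matrix.lengths.to_numpy()
    for i, pid in enumerate(matrix.loci):
        row = arr[i]
        typed = row[~np.isnan(row)].astype(int)
        n_typed = typed.size
        if n_typed < min_samples:
            excluded.append((pid, f"typed in {n_typed} < {min_samples} samples"))
            continue
        alleles = dict(sorted(Counter(typed.tolist()).items()))
        if len(alleles) < 2:
            excluded.append((pid, "monomorphic"))
            continue
        chrom, start, end = (pair_info or {}).get(pid, ("", -1, -1))
        markers.append(
            InDelMarker(
                pair_id=pid,
                chrom=chrom,
                product_start=start,
                product_end=end,
                n_typed=n_typed,
                alleles=alleles,
                pic=compute_pic(alleles),
                major_allele_diff=major_allele_difference(alleles),
            )
        )
    return CallResult(markers=markers, excluded=excluded)


def group_major_allele_freq(
    calls: Mapping[str, Optional[int]],
    sample_groups: Mapping[str, str],
) -> Dict[str, float]:
    """Per-group frequency of the globally most frequent allele.

    ``calls`` maps sample to consensus length (missing samples may be absent
    or None). Groups with no typed samples are absent from the result.
    """
    typed = {s: v for s, v in calls.items() if v is not None}
    if not typed:
        return {}
    counts = Counter(typed.values())
    major = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    out: Dict[str, float] = {}
    group_totals: Counter = Counter()
    group_major: Counter = Counter()
    for sample, length in typed.items():
        group = sample_groups.get(sample)
        if group is None:
            continue
        group_totals[group] += 1
        if length == major:
            group_major[group] += 1
    for group, total in group_totals.items():
        out[group] = group_major[group] / total
    return out


def annotate_group_frequencies(
    markers: Iterable[InDelMarker],
    matrix: GenotypeMatrix,
    sample_groups: Mapping[str, str],
) -> None:
    """Fill ``per_group_major_freq`` on each marker in place."""
    for marker in markers:
        calls = matrix.typed_lengths(marker.pair_id)
        marker.per_group_major_freq = group_major_allele_freq(calls, sample_groups)


def _fmt_alleles(alleles: Mapping[int, int]) -> str:
    ranked = sorted(alleles.items(), key=lambda kv: (-kv[1], kv[0]))
    return ",".join(f"{length}:{count}" for length, count in ranked)


def write_marker_table(markers: Sequence[InDelMarker], path, groups: Sequence[str] = ()):
    """Marker TSV (1-based positions); optional per-group frequency columns."""
    import csv

    group_cols = [f"major_freq_{g}" for g in groups]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "pair_id",
                "chrom",
                "pos_1based",
                "product_end",
                "alleles",
                "allele_number",
                "n_typed",
                "PIC",
                "major_allele_diff",
                "size_range",
                "region",
                "gene_id",
            ]
            + group_cols
        )
        for m in markers:
            row = [
                m.pair_id,
                m.chrom,
                m.product_start + 1,
                m.product_end,
                _fmt_alleles(m.alleles),
                m.allele_number,
                m.n_typed,
                f"{round2(m.pic):.2f}",
                m.major_allele_diff,
                m.size_range,
                m.region or "",
                m.gene_id or "",
            ]
            for g in groups:
                freq = m.per_group_major_freq.get(g)
                row.append("" if freq is None else f"{freq:.3f}")
            writer.writerow(row)


def read_marker_table(path) -> List[InDelMarker]:
    """Parse a marker TSV back into records (PIC recomputed at full precision)."""
    import csv

    markers: List[InDelMarker] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            alleles = {
                int(part.split(":")[0]): int(part.split(":")[1])
                for part in row["alleles"].split(",")
            }
            markers.append(
                InDelMarker(
                    pair_id=row["pair_id"],
                    chrom=row["chrom"],
                    product_start=int(row["pos_1based"]) - 1,
                    product_end=int(row["product_end"]),
                    n_typed=int(row["n_typed"]),
                    alleles=alleles,
                    pic=compute_pic(alleles),
                    major_allele_diff=int(row["major_allele_diff"]),
                    region=row.get("region") or None,
                    gene_id=row.get("gene_id") or None,
                )
            )
    return markers
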