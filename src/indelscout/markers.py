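"""Marker annotation, summaries, selection and validation-primer design.

Covers the reporting end of the pipeline: assigning each marker to one of
seven genomic categories, Table-style density/proportion summaries, the
two-tier gel-resolution marker selection (polyacrylamide vs agarose), PCR
validation-primer design under length/Tm/GC/3'-end constraints, and the
summary statistics of an experimental validation panel.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from .genotyping import InDelMarker, compute_pic, round2
from .seqio import REGION_CATEGORIES, RegionIndex, revcomp

__all__ = [
    "RegionAssignment",
    "ValidationPrimerPair",
    "PanelResult",
    "PanelStats",
    "MODE_PRODUCT_WINDOWS",
    "assign_region",
    "summarize_by_region",
    "summarize_by_chromosome",
    "density_per_kb",
    "proportion_pct",
    "average_spacing",
    "select_marker_sets",
    "extract_template",
    "melting_temperature",
    "gc_percent",
    "design_validation_primers",
    "panel_statistics",
]

#: Product-length windows (bp) resolvable on each gel system.
MODE_PRODUCT_WINDOWS = {"page": (60, 100), "agarose": (150, 300)}

#: Selection thresholds per gel mode: (min PIC, min major-allele difference).
MODE_THRESHOLDS = {"page": (0.5, 3), "agarose": (0.5, 8)}

#: Template flank (bp) around the 20-bp variable window per gel mode. The
#: polyacrylamide recipe uses 40-bp flanks (100-bp template); agarose needs
#: longer products, hence 150-bp flanks (320-bp template).
MODE_FLANKS = {"page": 40, "agarose": 150}


@dataclass(frozen=True, slots=True)
class RegionAssignment:
    pair_id: str
    category: str
    gene_id: Optional[str] = None


def assign_region(marker: InDelMarker, region_index: RegionIndex) -> RegionAssignment:
    """Single-category assignment of a marker by its product midpoint.

    Categories may overlap in the index; the assignment resolves overlaps by
    the fixed precedence CDS > 5'-UTR > 3'-UTR > intron > TSS_up_0.5kb >
    TES_down_0.5kb > intergenic, so every marker lands in exactly one
    category and Table-style counts are disjoint.
    """
    midpoint = (marker.product_start + marker.product_end) // 2
    cats = region_index.categories_at(marker.chrom, midpoint)
    for category in REGION_CATEGORIES:
        if category in cats:
            gene = cats[category] if category != "intergenic" else None
            return RegionAssignment(marker.pair_id, category, gene)
    # finalize() guarantees intergenic covers every uncovered base
    return RegionAssignment(marker.pair_id, "intergenic", None)


def density_per_kb(count: int, length_bp: int) -> Optional[float]:
    """Count per 1000 bp, rounded to 2 decimals; NA for a zero-length region."""
    if length_bp == 0:
        return None
    return round2(count / length_bp * 1000)


def proportion_pct(part: int, total: int) -> Optional[float]:
    """100 * part / total, rounded to 2 decimals; NA when total is 0."""
    if total == 0:
        return None
    return round2(100.0 * part / total)


def average_spacing(length_bp: int, count: int) -> Optional[float]:
    """Average bp between consecutive items (length / count), 2 decimals."""
    if count == 0:
        return None
    return round2(length_bp / count)


def summarize_by_region(
    assignments: Iterable[RegionAssignment],
    region_index: RegionIndex,
    reference_counts: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Per-category count, region length, density per kb and proportion.

    ``reference_counts`` selects the denominator of the proportion column
    (e.g. unique pairs per category when summarizing InDels); without it the
    proportion is of the summed total.
    """
    counts = {cat: 0 for cat in REGION_CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    total = sum(counts.values())
    rows = []
    for cat in REGION_CATEGORIES:
        length = region_index.category_bp.get(cat, 0)
        denom = reference_counts.get(cat, 0) if reference_counts else total
        rows.append(
            {
                "category": cat,
                "count": counts[cat],
                "region_bp": length,
                "density_per_kb": density_per_kb(counts[cat], length),
                "proportion_pct": proportion_pct(counts[cat], denom),
            }
        )
    ref_total = sum(reference_counts.values()) if reference_counts else total
    rows.append(
        {
            "category": "Total",
            "count": total,
            "region_bp": sum(region_index.category_bp.values()),
            "density_per_kb": density_per_kb(
                total, sum(region_index.chrom_lengths.values())
            ),
            "proportion_pct": proportion_pct(total, ref_total),
        }
    )
    return pd.DataFrame(rows).set_index("category")


def summarize_by_chromosome(
    counts: Mapping[str, int], chrom_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Per-chromosome count, length, density per kb and average spacing."""
    rows = []
    for chrom in chrom_lengths:
        n = counts.get(chrom, 0)
        length = chrom_lengths[chrom]
        rows.append(
            {
                "chromosome": chrom,
                "length_bp": length,
                "count": n,
                "density_per_kb": density_per_kb(n, length),
                "avg_spacing_bp": average_spacing(length, n),
            }
        )
    total_n = sum(counts.get(c, 0) for c in chrom_lengths)
    total_len = sum(chrom_lengths.values())
    rows.append(
        {
            "chromosome": "Total",
            "length_bp": total_len,
            "count": total_n,
            "density_per_kb": density_per_kb(total_n, total_len),
            "avg_spacing_bp": average_spacing(total_len, total_n),
        }
    )
    return pd.DataFrame(rows).set_index("chromosome")


def select_marker_sets(
    markers: Iterable[InDelMarker], mode: str
) -> List[InDelMarker]:
    """Gel-appropriate marker subset: PIC >= 0.5 and a mode-specific minimum
    major-allele difference (3 bp for polyacrylamide, 8 bp for agarose).

    The mode's product-length window is enforced downstream by
    :func:`design_validation_primers`, which controls the amplicon size.
    """
    if mode not in MODE_THRESHOLDS:
        raise ValueError(f"mode must be one of {sorted(MODE_THRESHOLDS)}")
    min_pic, min_diff = MODE_THRESHOLDS[mode]
    return [
        m
        for m in markers
        if m.pic >= min_pic and m.major_allele_diff >= min_diff
    ]


def extract_template(
    marker: InDelMarker,
    genome: Mapping[str, str],
    flank: int = 40,
    indel_window: int = 20,
) -> str:
    """Validation-primer template around the marker's variable region.

    The variable region is the ``indel_window``-bp window centered on the
    reference product's inter-primer gap; ``flank`` bp are added on each
    side (40 gives the standard 100-bp template, 150 the 320-bp agarose
    template). Windows clipped by a chromosome end are truncated with a
    warning.
    """
    seq = genome[marker.chrom]
    center = (marker.product_start + marker.product_end) // 2
    w_start = center - indel_window // 2
    w_end = w_start + indel_window
    start = w_start - flank
    end = w_end + flank
    if start < 0 or end > len(seq):
        warnings.warn(
            f"marker {marker.pair_id}: template truncated at chromosome edge",
            stacklevel=2,
        )
        start = max(0, start)
        end = min(len(seq), end)
    return seq[start:end]


def melting_temperature(seq: str) -> float:
    """Nearest-neighbor duplex melting temperature in deg C.

    Unified nearest-neighbor parameters at 50 mM monovalent salt and 250 nM
    oligo. Deterministic; ambiguous bases are rejected.
    """
    if len(seq) < 8:
        raise ValueError("sequence too short for a meaningful duplex Tm")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous base in {seq!r}")
    return float(_mt.Tm_NN(seq, Na=50, dnac1=250, dnac2=0))


def gc_percent(seq: str) -> float:
    return 100.0 * sum(1 for c in seq if c in "GC") / len(seq)


@dataclass(frozen=True, slots=True)
class ValidationPrimerPair:
    """An optimized validation PCR primer pair on a marker template."""

    marker_id: str
    f_seq: str
    r_seq: str
    f_start: int  # 0-based on the template
    r_footprint_start: int
    f_tm: float
    r_tm: float
    gc_f: float
    gc_r: float
    product_len: int
    penalty: float


#: Penalty weights: length deviation from 23 nt, Tm deviation from 63 deg C,
#: GC deviation from 50 %, Tm difference between mates. Tm terms dominate,
#: favoring mates with matched Tm near the optimum.
PENALTY_WEIGHTS = (1.0, 2.0, 0.5, 2.0)

_PRIMER_LEN_RANGE = (20, 28)
_OPT_LEN = 23
_TM_RANGE = (60.0, 65.0)
_OPT_TM = 63.0
_GC_RANGE = (30.0, 70.0)
_OPT_GC = 50.0


def _candidate_primers(
    template: str, span: Tuple[int, int], is_forward: bool, gc_clamp: bool
) -> List[Tuple[int, int, str, float, float]]:
    """Feasible primers on one flank: (start, length, seq, tm, gc)."""
    lo, hi = span
    out = []
    for length in range(_PRIMER_LEN_RANGE[0], _PRIMER_LEN_RANGE[1] + 1):
        for start in range(lo, hi - length + 1):
            window = template[start : start + length]
            if set(window) - set("ACGT"):
                continue
            seq = window if is_forward else revcomp(window)
            if seq[-1] not in "GC":
                continue
            if gc_clamp and sum(1 for c in seq[-5:] if c in "GC") < 2:
                continue
            gc = gc_percent(seq)
            if not _GC_RANGE[0] <= gc <= _GC_RANGE[1]:
                continue
            tm = melting_temperature(seq)
            if not _TM_RANGE[0] <= tm <= _TM_RANGE[1]:
                continue
            out.append((start, length, seq, tm, gc))
    return out


def design_validation_primers(
    template: str,
    mode: str = "page",
    indel_window: Optional[Tuple[int, int]] = None,
    marker_id: str = "",
    weights: Tuple[float, float, float, float] = PENALTY_WEIGHTS,
    gc_clamp: bool = False,
) -> Optional[ValidationPrimerPair]:
    """Best validation primer pair on a template, or None if none is feasible.

    Candidates of length 20-28 nt are enumerated on both flanks of the
    variable window (primers must flank it so the product spans the InDel),
    filtered to Tm in [60, 65] deg C, GC in [30, 70] %, a G/C 3' terminus
    (optionally a 2-of-5 GC clamp), and a product length inside the gel
    mode's window. The surviving pair minimizing

        w1*(|len-23| summed) + w2*(|Tm-63| summed) + w3*(|GC-50| summed)
        + w4*|Tm_f - Tm_r|

    is returned; ties break to the leftmost forward primer, then the
    shortest product, then the shortest forward primer.
    """
    if mode not in MODE_PRODUCT_WINDOWS:
        raise ValueError(f"mode must be one of {sorted(MODE_PRODUCT_WINDOWS)}")
    min_prod, max_prod = MODE_PRODUCT_WINDOWS[mode]
    L = len(template)
    if indel_window is None:
        w_start = (L - 20) // 2
        indel_window = (w_start, w_start + 20)
    win_start, win_end = indel_window
    w1, w2, w3, w4 = weights

    fwd = _candidate_primers(template, (0, win_start), True, gc_clamp)
    rev = _candidate_primers(template, (win_end, L), False, gc_clamp)
    if not fwd or not rev:
        return None

    best = None
    best_key = None
    for f_start, f_len, f_seq, f_tm, f_gc in fwd:
        for r_start, r_len, r_seq, r_tm, r_gc in rev:
            product_len = (r_start + r_len) - f_start
            if not min_prod <= product_len <= max_prod:
                continue
            penalty = (
                w1 * (abs(f_len - _OPT_LEN) + abs(r_len - _OPT_LEN))
                + w2 * (abs(f_tm - _OPT_TM) + abs(r_tm - _OPT_TM))
                + w3 * (abs(f_gc - _OPT_GC) + abs(r_gc - _OPT_GC))
                + w4 * abs(f_tm - r_tm)
            )
            key = (penalty, f_start, product_len, f_len, r_start)
            if best_key is None or key < best_key:
                best_key = key
                best = ValidationPrimerPair(
                    marker_id=marker_id,
                    f_seq=f_seq,
                    r_seq=r_seq,
                    f_start=f_start,
                    r_footprint_start=r_start,
                    f_tm=f_tm,
                    r_tm=r_tm,
                    gc_f=f_gc,
                    gc_r=r_gc,
                    product_len=product_len,
                    penalty=penalty,
                )
    return best


@dataclass
class PanelResult:
    """Raw outcome of a wet-lab validation panel."""

    n_tested: int
    n_amplified_both_parents: int
    n_polymorphic: int
    gel_patterns: List[Mapping[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (
            0 <= self.n_polymorphic
            <= self.n_amplified_both_parents
            <= self.n_tested
        ):
            raise ValueError(
                "panel counts must satisfy polymorphic <= amplified <= tested"
            )


@dataclass
class PanelStats:
    success_pct: float
    accuracy_pct: Optional[float]
    marker_pics: List[float]
    mean_allele_number: Optional[float]


def panel_statistics(panel: PanelResult) -> PanelStats:
    """Validation-panel summary.

    Success rate is the share of tested markers amplifying in both parents;
    accuracy is the share of amplifying markers that are polymorphic (NA
    when nothing amplified). Gel PIC per marker is computed from the scored
    band patterns; allele number is the pattern count per marker.
    """
    success = proportion_pct(panel.n_amplified_both_parents, panel.n_tested)
    if panel.n_amplified_both_parents == 0:
        accuracy = None
    else:
        accuracy = proportion_pct(
            panel.n_polymorphic, panel.n_amplified_both_parents
        )
    pics = [round2(compute_pic(p)) for p in panel.gel_patterns]
    if panel.gel_patterns:
        mean_alleles = round2(
            sum(len(p) for p in panel.gel_patterns) / len(panel.gel_patterns)
        )
    else:
        mean_alleles = None
    return PanelStats(
        success_pct=success,
        accuracy_pct=accuracy,
        marker_pics=pics,
        mean_allele_number=mean_alleles,
    )
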