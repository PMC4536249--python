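"""Synthetic data: reference genomes, diverged populations, reads.

The generator emulates the pipeline's study design at desk scale: a random
reference genome (A), a diverged second reference (B) carrying planted
InDels and background SNPs, a population of inbred samples drawing the
planted alleles at known frequencies, and uniform-coverage single-end reads
with optional base errors. A truth table records every planted locus, the
tiling pair whose inter-primer gap contains it, and the expected product
length per allele, so every pipeline stage can be checked against ground
truth.

Planted InDels sit at the center of a tiling window's 20-bp inter-primer
gap and are spaced >= 100 bp apart, so each polymorphism falls inside
exactly one designed product's variable region (it disrupts a primer
footprint of the two overlapping neighbor windows, which therefore simply
fail to amplify the alternate allele).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

from .seqio import ReadRecord, SequenceRecord, revcomp, write_fasta, write_fastq

__all__ = [
    "SimConfig",
    "TruthLocus",
    "TruthTable",
    "simulate_references",
    "simulate_population",
    "simulate_reads",
    "write_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulation.

    Defaults mirror the target study's read scale: ~87-bp reads at ~2x
    depth; the InDel length distribution is geometric (small differences
    dominate real data) truncated to ``[indel_min, indel_max]``.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_len: int = 10_000
    gc: float = 0.44
    n_loci: int = 20
    indel_geom_p: float = 0.4
    indel_min: int = 1
    indel_max: int = 50
    allele_freq: Union[float, Sequence[float]] = 0.5
    snp_rate: float = 0.001
    n_samples: int = 200
    read_len: int = 87
    depth: float = 2.0
    base_error_rate: float = 0.005
    n_groups: int = 2
    min_locus_spacing: int = 100

    def __post_init__(self) -> None:
        if self.read_len < 60:
            raise ValueError("read_len must be >= 60 (one reference product)")
        for name in ("gc", "snp_rate", "base_error_rate", "indel_geom_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def freq_at(self, locus_index: int) -> float:
        if isinstance(self.allele_freq, (int, float)):
            return float(self.allele_freq)
        return float(self.allele_freq[locus_index])


@dataclass
class TruthLocus:
    """One planted polymorphism and everything needed to check its recovery."""

    locus_id: str
    chrom: str
    window_index: int  # tiling window whose gap holds the locus
    pair_id: str
    position: int  # gap center, 0-based on genome A
    kind: str  # 'ins' or 'del' (the alternate allele relative to A)
    indel_len: int
    alt_freq: float
    ins_seq: str = ""
    sample_alleles: Dict[str, int] = field(default_factory=dict)  # 0=ref, 1=alt

    @property
    def ref_product_len(self) -> int:
        return 60

    @property
    def alt_product_len(self) -> int:
        return 60 + self.indel_len if self.kind == "ins" else 60 - self.indel_len

    def detectable(self, read_len: int) -> bool:
        """Can the standard pipeline see this locus at all?

        A deletion longer than the 20-bp gap destroys a primer footprint;
        an insertion pushing the product past the read length can never lie
        fully inside one read.
        """
        if self.kind == "del":
            return self.indel_len <= 20
        return self.alt_product_len <= read_len

    @property
    def realized_alt_count(self) -> int:
        return sum(self.sample_alleles.values())


@dataclass
class TruthTable:
    loci: List[TruthLocus]

    def by_pair_id(self) -> Dict[str, TruthLocus]:
        return {locus.pair_id: locus for locus in self.loci}

    def write_tsv(self, path: str | os.PathLike) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(
                [
                    "locus_id",
                    "chrom",
                    "pair_id",
                    "pos_1based",
                    "kind",
                    "indel_len",
                    "alt_freq",
                    "ref_product_len",
                    "alt_product_len",
                    "realized_alt_count",
                ]
            )
            for t in self.loci:
                w.writerow(
                    [
                        t.locus_id,
                        t.chrom,
                        t.pair_id,
                        t.position + 1,
                        t.kind,
                        t.indel_len,
                        t.alt_freq,
                        t.ref_product_len,
                        t.alt_product_len,
                        t.realized_alt_count,
                    ]
                )


def _random_chromosome(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return _BASES[rng.choice(4, size=length, p=probs)]


def _draw_indel_len(rng: np.random.Generator, config: SimConfig) -> int:
    while True:
        d = int(rng.geometric(config.indel_geom_p))
        if config.indel_min <= d <= config.indel_max:
            return d


def _place_loci(
    rng: np.random.Generator, config: SimConfig, chrom_names: Sequence[str]
) -> List[Tuple[str, int]]:
    """Pick (chrom, window_index) slots with the minimum center spacing."""
    L = config.chrom_len
    spacing = config.min_locus_spacing
    per_chrom = [config.n_loci // config.n_chroms] * config.n_chroms
    for i in range(config.n_loci % config.n_chroms):
        per_chrom[i] += 1
    slots: List[Tuple[str, int]] = []
    n_windows = (L - 60) // 20 + 1 if L >= 60 else 0
    for chrom, want in zip(chrom_names, per_chrom):
        candidates = [
            i
            for i in range(n_windows)
            if spacing <= 20 * i + 30 <= L - spacing
        ]
        rng.shuffle(candidates)
        chosen: List[int] = []
        for i in candidates:
            if len(chosen) == want:
                break
            center = 20 * i + 30
            if all(abs(center - (20 * j + 30)) >= spacing for j in chosen):
                chosen.append(i)
        if len(chosen) < want:
            raise ValueError(
                f"cannot place {want} loci on {chrom} ({L} bp) with "
                f"{spacing}-bp spacing"
            )
        slots.extend((chrom, i) for i in sorted(chosen))
    return slots


def _apply_edits(
    seq_arr: np.ndarray,
    edits: Sequence[Tuple[int, str, int, str]],
) -> np.ndarray:
    """Apply (center, kind, length, ins_seq) edits; safe in one pass because
    edits are applied right-to-left."""
    parts = seq_arr
    for center, kind, d, ins_seq in sorted(edits, reverse=True):
        if kind == "del":
            a = center - d // 2
            parts = np.concatenate([parts[:a], parts[a + d :]])
        else:
            ins = np.frombuffer(ins_seq.encode("ascii"), dtype=np.uint8)
            parts = np.concatenate([parts[:center], ins, parts[center:]])
    return parts


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_references(
    config: SimConfig,
) -> Tuple[List[SequenceRecord], List[SequenceRecord], TruthTable]:
    """Generate genome A, the diverged genome B and the truth table.

    B equals A plus background SNPs (at ``snp_rate`` per bp, outside the
    planted gap windows) and the planted alternate allele at every truth
    locus. Byte-identical across runs with the same config.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    arrays: Dict[str, np.ndarray] = {
        c: _random_chromosome(rng, config.chrom_len, config.gc) for c in chrom_names
    }
    slots = _place_loci(rng, config, chrom_names)

    loci: List[TruthLocus] = []
    for k, (chrom, widx) in enumerate(slots):
        center = 20 * widx + 30
        kind = "del" if rng.random() < 0.5 else "ins"
        d = _draw_indel_len(rng, config)
        ins_seq = ""
        if kind == "ins":
            ins_seq = _to_str(_BASES[rng.integers(0, 4, size=d)])
        loci.append(
            TruthLocus(
                locus_id=f"L{k:03d}",
                chrom=chrom,
                window_index=widx,
                pair_id=f"{chrom}-{20 * widx + 1}",
                position=center,
                kind=kind,
                indel_len=d,
                alt_freq=config.freq_at(k),
                ins_seq=ins_seq,
            )
        )

    genome_a = [SequenceRecord(c, _to_str(arrays[c])) for c in chrom_names]

    protected: Dict[str, set] = {c: set() for c in chrom_names}
    for t in loci:
        protected[t.chrom].update(range(t.position - 30, t.position + 30))

    genome_b: List[SequenceRecord] = []
    for chrom in chrom_names:
        arr = arrays[chrom].copy()
        if config.snp_rate > 0:
            mask = rng.random(arr.size) < config.snp_rate
            for pos in np.nonzero(mask)[0]:
                if int(pos) in protected[chrom]:
                    continue
                cur = int(np.where(_BASES == arr[pos])[0][0])
                arr[pos] = _BASES[(cur + int(rng.integers(1, 4))) % 4]
        edits = [
            (t.position, t.kind, t.indel_len, t.ins_seq)
            for t in loci
            if t.chrom == chrom
        ]
        genome_b.append(SequenceRecord(chrom, _to_str(_apply_edits(arr, edits))))

    return genome_a, genome_b, TruthTable(loci=loci)


def simulate_population(
    config: SimConfig,
    truth: TruthTable,
    genome_a: Optional[Sequence[SequenceRecord]] = None,
) -> List[Tuple[str, Dict[str, str]]]:
    """Draw per-sample genomes from the planted allele frequencies.

    Each sample independently carries the alternate allele at each locus
    with that locus's frequency; realized alleles are recorded in the truth
    table. Returns (sample_id, {chrom: seq}) in sample order.
    """
    if genome_a is None:
        genome_a, _, _ = simulate_references(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    arrays = {rec.id: np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)
              for rec in genome_a}
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    draws = rng.random((config.n_samples, len(truth.loci)))
    population: List[Tuple[str, Dict[str, str]]] = []
    for s, sample_id in enumerate(sample_ids):
        edits_by_chrom: Dict[str, List[Tuple[int, str, int, str]]] = {}
        for k, t in enumerate(truth.loci):
            alt = int(draws[s, k] < t.alt_freq)
            t.sample_alleles[sample_id] = alt
            if alt:
                edits_by_chrom.setdefault(t.chrom, []).append(
                    (t.position, t.kind, t.indel_len, t.ins_seq)
                )
        genome = {
            chrom: _to_str(_apply_edits(arr, edits_by_chrom.get(chrom, [])))
            for chrom, arr in arrays.items()
        }
        population.append((sample_id, genome))
    return population


def sample_groups(config: SimConfig) -> Dict[str, str]:
    """Round-robin assignment of samples to ``n_groups`` named groups."""
    return {
        f"S{i:03d}": f"G{i % config.n_groups + 1}"
        for i in range(config.n_samples)
    }


def simulate_reads(
    sample_genome: Dict[str, str],
    config: SimConfig,
    sample_id: str = "S000",
    rng: Optional[np.random.Generator] = None,
) -> Iterator[ReadRecord]:
    """Uniform-coverage single-end reads from one sample genome.

    Read count per chromosome is ``round(depth * L / read_len)``; starts are
    uniform, strands equiprobable. Substitution errors occur independently
    per base at ``base_error_rate``; every base's quality is the Phred score
    of that error rate (Q40 when the rate is 0).
    """
    if config.depth <= 0:
        raise ValueError("depth must be > 0")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    e = config.base_error_rate
    qual = 40 if e == 0 else min(40, round(-10 * math.log10(e)))
    rl = config.read_len
    for chrom, seq in sample_genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        L = arr.size
        if L < rl:
            continue
        n_reads = round(config.depth * L / rl)
        starts = rng.integers(0, L - rl + 1, size=n_reads)
        strands = rng.random(n_reads) < 0.5
        quals = tuple([qual] * rl)
        for i in range(n_reads):
            fragment = arr[starts[i] : starts[i] + rl]
            if e > 0:
                fragment = fragment.copy()
                mask = rng.random(rl) < e
                if mask.any():
                    idx = np.nonzero(mask)[0]
                    for pos in idx:
                        cur = int(np.where(_BASES == fragment[pos])[0][0])
                        fragment[pos] = _BASES[(cur + int(rng.integers(1, 4))) % 4]
            read_seq = _to_str(fragment)
            if strands[i]:
                read_seq = revcomp(read_seq)
            yield ReadRecord(
                id=f"{sample_id}:{chrom}:{i}",
                seq=read_seq,
                quals=quals,
                sample_id=sample_id,
            )


def write_simulation(config: SimConfig, outdir: str | os.PathLike) -> None:
    """Materialize a full simulated study on disk.

    Writes ``ref_a.fa``, ``ref_b.fa``, ``samples/<id>.fq``, ``truth.tsv``
    and ``groups.tsv`` under ``outdir``.
    """
    outdir = os.fspath(outdir)
    os.makedirs(os.path.join(outdir, "samples"), exist_ok=True)
    genome_a, genome_b, truth = simulate_references(config)
    write_fasta(genome_a, os.path.join(outdir, "ref_a.fa"))
    write_fasta(genome_b, os.path.join(outdir, "ref_b.fa"))
    population = simulate_population(config, truth, genome_a)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    for sample_id, genome in population:
        reads = simulate_reads(genome, config, sample_id=sample_id, rng=rng)
        write_fastq(reads, os.path.join(outdir, "samples", f"{sample_id}.fq"))
    truth.write_tsv(os.path.join(outdir, "truth.tsv"))
    groups = sample_groups(config)
    with open(os.path.join(outdir, "groups.tsv"), "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample_id, group in groups.items():
            fh.write(f"{sample_id}\t{group}\n")
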