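import numpy as np
import pytest

from indelscout.genotyping import InDelMarker
from indelscout.markers import (
    MODE_PRODUCT_WINDOWS,
    PanelResult,
    assign_region,
    average_spacing,
    density_per_kb,
    design_validation_primers,
    extract_template,
    gc_percent,
    melting_temperature,
    panel_statistics,
    proportion_pct,
    select_marker_sets,
    summarize_by_chromosome,
    summarize_by_region,
)
from indelscout.seqio import revcomp

from oracles import brute_force_validation_pair


def _marker(pair_id="p", chrom="chr1", start=0, end=60, pic=0.6, diff=3,
            alleles=None):
    alleles = alleles or {60: 10, 60 - diff: 5}
    return InDelMarker(
        pair_id=pair_id, chrom=chrom, product_start=start, product_end=end,
        n_typed=sum(alleles.values()), alleles=alleles, pic=pic,
        major_allele_diff=diff,
    )


class TestAssignRegion:
    def test_cds_takes_precedence_over_gene_span(self, region_index):
        m = _marker(start=1170, end=1230)  # midpoint 1200 inside CDS of g1
        assert assign_region(m, region_index).category == "CDS"
        assert assign_region(m, region_index).gene_id == "g1"

    def test_upstream_window(self, region_index):
        m = _marker(start=770, end=830)  # midpoint 800, 200 bp upstream of TSS
        assert assign_region(m, region_index).category == "TSS_up_0.5kb"

    def test_gene_desert_is_intergenic(self, region_index):
        m = _marker(start=8970, end=9030)
        a = assign_region(m, region_index)
        assert (a.category, a.gene_id) == ("intergenic", None)

    def test_partition_every_marker_exactly_one_category(self, region_index):
        markers = [_marker(pair_id=f"p{s}", start=s, end=s + 60)
                   for s in range(0, 9940, 61)]
        assignments = [assign_region(m, region_index) for m in markers]
        assert len(assignments) == len(markers)
        table = summarize_by_region(assignments, region_index)
        counts = table.drop(index="Total")["count"]
        assert counts.sum() == len(markers)
        assert table.loc["Total", "count"] == len(markers)


class TestSummaries:
    def test_density_single_marker(self):
        assert density_per_kb(1, 1000) == 1.00

    def test_zero_length_region_is_na(self):
        assert density_per_kb(5, 0) is None

    def test_density_recovers_count_within_rounding(self):
        count, length = 1234, 5_678_901
        d = density_per_kb(count, length)
        assert abs(d * length / 1000 - count) <= 0.005 * length / 1000

    def test_chromosome_summary_totals(self):
        table = summarize_by_chromosome({"c1": 10, "c2": 5}, {"c1": 10_000, "c2": 10_000})
        assert table.loc["Total", "count"] == 15
        assert table.loc["c1", "density_per_kb"] == 1.00
        assert table.loc["c1", "avg_spacing_bp"] == 1000.00

    def test_proportion_rounding(self):
        assert proportion_pct(1, 3) == 33.33
        assert average_spacing(1000, 3) == 333.33


class TestSelection:
    def test_page_thresholds(self):
        assert select_marker_sets([_marker(pic=0.55, diff=3)], "page")

    def test_low_pic_in_neither_set(self):
        m = _marker(pic=0.49, diff=10)
        assert not select_marker_sets([m], "page")
        assert not select_marker_sets([m], "agarose")

    def test_large_difference_in_both_sets(self):
        m = _marker(pic=0.60, diff=8)
        assert select_marker_sets([m], "page") and select_marker_sets([m], "agarose")

    def test_agarose_subset_of_page(self):
        rng = np.random.default_rng(0)
        markers = [
            _marker(pair_id=f"p{i}", pic=float(rng.uniform(0, 0.9)),
                    diff=int(rng.integers(1, 15)))
            for i in range(200)
        ]
        page = {m.pair_id for m in select_marker_sets(markers, "page")}
        agarose = {m.pair_id for m in select_marker_sets(markers, "agarose")}
        assert agarose <= page

    def test_raising_pic_cutoff_never_grows_selection(self):
        markers = [_marker(pair_id=f"p{i}", pic=p, diff=5)
                   for i, p in enumerate(np.linspace(0, 0.9, 50))]
        page = select_marker_sets(markers, "page")
        assert all(m.pic >= 0.5 for m in page)
        stricter = [m for m in page if m.pic >= 0.7]
        assert len(stricter) <= len(page)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            select_marker_sets([], "gel")


class TestExtractTemplate:
    def _genome(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        return {"chr1": "".join(rng.choice(list("ACGT"), size=n))}

    def test_mid_chromosome_template_is_100bp(self):
        genome = self._genome()
        m = _marker(start=1000, end=1060)
        t = extract_template(m, genome, flank=40)
        assert len(t) == 100
        assert t == genome["chr1"][980:1080]

    def test_agarose_flank_gives_320bp(self):
        m = _marker(start=1000, end=1060)
        assert len(extract_template(m, self._genome(), flank=150)) == 320

    def test_truncated_near_chromosome_start(self):
        m = _marker(start=0, end=60)
        with pytest.warns(UserWarning, match="truncated"):
            t = extract_template(m, self._genome(), flank=40)
        assert len(t) < 100


class TestMeltingTemperature:
    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=23))
            assert melting_temperature(seq) == pytest.approx(
                melting_temperature(revcomp(seq)), abs=1e-6)

    def test_sanity_band_for_average_23mer(self):
        seq = "ACGTACGTACGTACGTACGTACG"  # ~50 % GC
        assert 50 <= melting_temperature(seq) <= 75

    def test_gc_substitution_never_decreases_tm(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=22))
            at_positions = [i for i, c in enumerate(seq) if c in "AT"]
            if not at_positions:
                continue
            i = int(rng.choice(at_positions))
            richer = seq[:i] + str(rng.choice(["G", "C"])) + seq[i + 1 :]
            assert melting_temperature(richer) >= melting_temperature(seq) - 1e-9

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTNACGTACG")


class TestValidationPrimers:
    def _template(self, seed, length=100, gc_bias=0.55):
        rng = np.random.default_rng(seed)
        p = [(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2]
        return "".join(rng.choice(list("ACGT"), size=length, p=p))

    def test_optimum_matches_exhaustive_enumeration(self):
        found = 0
        for seed in range(15):
            template = self._template(seed)
            got = design_validation_primers(template, mode="page")
            oracle = brute_force_validation_pair(template, 40, 60, 60, 100)
            if got is None:
                assert oracle is None
            else:
                found += 1
                key = (got.penalty, got.f_start, got.product_len,
                       len(got.f_seq), got.r_footprint_start)
                assert key == pytest.approx(oracle)
        assert found >= 3  # enough feasible templates for the check to bite

    def test_returned_pair_satisfies_all_constraints(self):
        for seed in range(25):
            got = design_validation_primers(self._template(seed + 100), mode="page")
            if got is None:
                continue
            for seq, tm, gc in ((got.f_seq, got.f_tm, got.gc_f),
                                (got.r_seq, got.r_tm, got.gc_r)):
                assert 20 <= len(seq) <= 28
                assert 60 <= tm <= 65
                assert 30 <= gc <= 70
                assert seq[-1] in "GC"
                assert gc == pytest.approx(gc_percent(seq))
            lo, hi = MODE_PRODUCT_WINDOWS["page"]
            assert lo <= got.product_len <= hi

    def test_infeasible_template_returns_none(self):
        # AT-only flanks: no candidate can end in G/C
        template = "AT" * 20 + "G" * 20 + "TA" * 20
        assert design_validation_primers(template, mode="page") is None

    def test_primers_flank_the_variable_window(self):
        for seed in range(10):
            got = design_validation_primers(self._template(seed + 200), mode="page")
            if got is None:
                continue
            assert got.f_start + len(got.f_seq) <= 40
            assert got.r_footprint_start >= 60
            assert got.product_len == got.r_footprint_start + len(got.r_seq) - got.f_start


class TestPanelStatistics:
    def test_validation_panel_percentages(self):
        stats = panel_statistics(PanelResult(100, 93, 89))
        assert stats.success_pct == 93.00
        assert stats.accuracy_pct == 95.70

    def test_fully_polymorphic_panel(self):
        assert panel_statistics(PanelResult(50, 50, 50)).accuracy_pct == 100.00

    def test_no_polymorphism(self):
        assert panel_statistics(PanelResult(10, 10, 0)).accuracy_pct == 0.00

    def test_nothing_amplified_accuracy_na(self):
        stats = panel_statistics(PanelResult(10, 0, 0))
        assert stats.accuracy_pct is None
        assert stats.success_pct == 0.00

    def test_gel_patterns_scored(self):
        panel = PanelResult(2, 2, 2, gel_patterns=[{"a": 5, "b": 5}, {"a": 2, "b": 2, "c": 1}])
        stats = panel_statistics(panel)
        assert stats.marker_pics[0] == pytest.approx(0.5)
        assert stats.mean_allele_number == 2.5

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            PanelResult(10, 5, 7)
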