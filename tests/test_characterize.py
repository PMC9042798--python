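import numpy as np
import pandas as pd
import pytest

from ecckit import (
    NullConfig,
    chromosome_density,
    element_enrichment,
    gc_profile,
    generate_insilico,
    genome_coverage_fraction,
    intragenic_stats,
    length_peaks,
    repeat_mapping_ratio,
)
from ecckit.genome import AnnotationSet, ReferenceGenome


def circles_df(triples):
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# GC profile
# ---------------------------------------------------------------------------


class TestGcProfile:
    def test_trivial_gc_values(self):
        g = ReferenceGenome({"c": "A" * 100 + "GCGCGC" + "A" * 100})
        table, _ = gc_profile(circles_df([("c", 100, 106)]), g)
        assert table["gc_circle"].iloc[0] == 1.0
        g2 = ReferenceGenome({"c": "A" * 100 + "ACGT" + "A" * 100})
        table2, _ = gc_profile(circles_df([("c", 100, 104)]), g2)
        assert table2["gc_circle"].iloc[0] == 0.5

    def test_planted_gc_contrast_recovered(self, rng):
        # 0.4-GC background with 0.8-GC blocks as the circles
        bg = rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=200_000)
        seq = "".join(bg)
        g = ReferenceGenome({"c": seq})
        triples = []
        for i in range(60):
            s = 1_000 + i * 3_000
            block = "".join(rng.choice(list("ACGT"), p=[0.1, 0.4, 0.4, 0.1], size=500))
            g.write("c", s, block)
            triples.append(("c", s, s + 500))
        table, peaks = gc_profile(circles_df(triples), g)
        flank_mean = np.nanmean(
            np.concatenate([table["gc_upstream_flank"], table["gc_downstream_flank"]])
        )
        assert table["gc_circle"].mean() - flank_mean == pytest.approx(0.4, abs=0.02)
        assert peaks["gc_circle"] > peaks["gc_upstream_flank"]

    def test_edge_circles_flagged(self):
        g = ReferenceGenome({"c": "ACGT" * 100})
        table, _ = gc_profile(circles_df([("c", 10, 60)]), g)  # flank would underrun
        assert bool(table["edge_flagged"].iloc[0])
        assert np.isnan(table["gc_upstream_flank"].iloc[0])

    def test_gc_in_unit_interval(self, small_study):
        genome, _, circles, _ = small_study
        table, _ = gc_profile(circles, genome)
        gc = table["gc_circle"].dropna()
        assert ((gc >= 0) & (gc <= 1)).all()


# ---------------------------------------------------------------------------
# length peaks
# ---------------------------------------------------------------------------


class TestLengthPeaks:
    def test_single_length_gives_single_peak(self):
        res = length_peaks(circles_df([("c", 0, 358)] * 150))
        assert len(res["peaks"]) == 1
        assert res["peaks"][0] == pytest.approx(358, abs=1)
        assert res["periodicity"] is None
        assert res["fraction_below_1kb"] == 1.0

    def test_two_peaks_periodicity(self):
        df = circles_df([("c", 0, 207)] * 100 + [("c", 0, 358)] * 100)
        res = length_peaks(df)
        assert len(res["peaks"]) == 2
        assert res["periodicity"] == pytest.approx(151, abs=2)

    def test_too_few_circles_histogram_only(self, caplog):
        with caplog.at_level("WARNING"):
            res = length_peaks(circles_df([("c", 0, 358)] * 50))
        assert res["peaks"] is None
        assert res["hist"].sum() == 50


# ---------------------------------------------------------------------------
# chromosome density
# ---------------------------------------------------------------------------


def _genome_with_genes(n_chroms, length, gene_counts, alu_counts=None):
    g = ReferenceGenome({f"chr{i + 1}": "ACGT" * (length // 4) for i in range(n_chroms)})
    rows = []
    for i, n in enumerate(gene_counts):
        for j in range(n):
            rows.append((f"chr{i + 1}", j * 100, j * 100 + 50, "+", "gene", f"g{i}_{j}"))
    for i, n in enumerate(alu_counts or [0] * n_chroms):
        for j in range(n):
            rows.append((f"chr{i + 1}", j * 80, j * 80 + 30, "+", "SINE", f"a{i}_{j}"))
    return g, AnnotationSet.from_records(rows)


class TestChromosomeDensity:
    def test_proportional_counts_give_r_1(self):
        gene_counts = [2, 4, 6, 8]
        g, ann = _genome_with_genes(4, 100_000, gene_counts, [1, 1, 1, 1])
        triples = []
        for i, n in enumerate(gene_counts):
            triples += [(f"chr{i + 1}", 10_000 + j, 10_300 + j) for j in range(5 * n)]
        rows, corr = chromosome_density(circles_df(triples), g, ann)
        assert corr["genes"][0] == pytest.approx(1.0)
        assert sum(r.percent_of_total for r in rows) == pytest.approx(100.0, abs=1e-9)

    def test_constant_circles_give_zero_correlation(self):
        g, ann = _genome_with_genes(4, 100_000, [2, 4, 6, 8], [1, 2, 3, 4])
        triples = [(f"chr{i + 1}", 10_000 + j, 10_300 + j) for i in range(4) for j in range(10)]
        _, corr = chromosome_density(circles_df(triples), g, ann)
        assert corr["genes"][0] == pytest.approx(0.0)

    def test_two_chromosomes_no_correlation(self):
        g, ann = _genome_with_genes(2, 100_000, [2, 4], [1, 1])
        _, corr = chromosome_density(circles_df([("chr1", 0, 100)]), g, ann)
        assert corr["genes"] is None

    def test_gene_density_weighted_placement_positive(self, rng):
        gene_counts = list(rng.integers(1, 30, size=10))
        g, ann = _genome_with_genes(10, 100_000, gene_counts,
                                    list(rng.integers(1, 10, size=10)))
        weights = np.array(gene_counts, dtype=float)
        picks = rng.choice(10, size=2_000, p=weights / weights.sum())
        triples = [(f"chr{i + 1}", 10_000, 10_300) for i in picks]
        _, corr = chromosome_density(circles_df(triples), g, ann)
        r, p = corr["genes"]
        assert r > 0
        assert p < 0.05


# ---------------------------------------------------------------------------
# element enrichment
# ---------------------------------------------------------------------------


class TestElementEnrichment:
    def test_whole_genome_class_ratio_exactly_one(self):
        g = ReferenceGenome({"c": "ACGT" * 25_000})
        ann = AnnotationSet.from_records([("c", 0, 100_000, "+", "all", "x")])
        (row,) = element_enrichment(circles_df([("c", 10, 400), ("c", 900, 1_300)]),
                                    ann, g, classes=["all"])
        assert row.ratio == 1.0

    def test_no_junction_in_class_ratio_zero(self):
        g = ReferenceGenome({"c": "ACGT" * 25_000})
        ann = AnnotationSet.from_records([("c", 50_000, 60_000, "+", "cls", "x")])
        (row,) = element_enrichment(circles_df([("c", 10, 400)]), ann, g, classes=["cls"])
        assert row.ratio == 0.0

    def test_uniform_null_calibrates_to_one(self):
        g = ReferenceGenome({"c": "A" * 1_000_000})
        # fragmented class: 100 intervals of 1 kb = 10% of the genome
        ann = AnnotationSet.from_records(
            [("c", i * 10_000, i * 10_000 + 1_000, "+", "cls", f"x{i}") for i in range(100)]
        )
        null = generate_insilico(NullConfig(n_per_dataset=[50_000], seed=1), g)[0]
        (row,) = element_enrichment(null, ann, g, classes=["cls"])
        assert row.expected_fraction == pytest.approx(0.10)
        assert row.ratio == pytest.approx(1.0, abs=0.05)

    def test_unknown_class_rejected(self, small_study):
        genome, ann, circles, _ = small_study
        with pytest.raises(ValueError, match="nonsense"):
            element_enrichment(circles, ann, genome, classes=["nonsense"])

    def test_circle_mode_exceeds_junction_mode_for_short_elements(self):
        g = ReferenceGenome({"c": "A" * 1_000_000})
        ann = AnnotationSet.from_records(
            [("c", i * 2_000, i * 2_000 + 200, "+", "cls", f"x{i}") for i in range(500)]
        )
        null = generate_insilico(NullConfig(n_per_dataset=[20_000], seed=2), g)[0]
        (junc,) = element_enrichment(null, ann, g, classes=["cls"], mode="junction")
        (circ,) = element_enrichment(null, ann, g, classes=["cls"], mode="circle")
        assert junc.ratio == pytest.approx(1.0, abs=0.05)
        assert circ.ratio > 1.5  # either-junction counting inflates short classes


# ---------------------------------------------------------------------------
# repeat mapping ratio
# ---------------------------------------------------------------------------


def _readset(genome, positions, read_len=150):
    import pysam
    from ecckit.simulate import ReadSet, _sam_header

    header = _sam_header(genome)
    recs = []
    for i, (chrom, pos) in enumerate(positions):
        a = pysam.AlignedSegment(header)
        a.query_name = f"r{i}"
        a.reference_name = chrom
        a.reference_start = pos
        a.cigarstring = f"{read_len}M"
        a.query_sequence = "A" * read_len
        a.mapping_quality = 60
        recs.append(a)
    recs.sort(key=lambda r: (r.reference_id, r.reference_start))
    return ReadSet(records=recs, header=header, mapped_read_count=len(recs))


class TestRepeatMappingRatio:
    def test_all_reads_in_half_genome_class(self):
        g = ReferenceGenome({"c": "A" * 100_000})
        ann = AnnotationSet.from_records([("c", 0, 50_000, "+", "SINE", "s")])
        rs = _readset(g, [("c", i * 100) for i in range(100)])  # all inside class
        ratios = repeat_mapping_ratio(rs, ann, g)
        assert ratios["SINE"] == pytest.approx(2.0)

    def test_no_overlap_ratio_zero(self):
        g = ReferenceGenome({"c": "A" * 100_000})
        ann = AnnotationSet.from_records([("c", 90_000, 100_000, "+", "LINE", "l")])
        rs = _readset(g, [("c", 0), ("c", 1_000)])
        assert repeat_mapping_ratio(rs, ann, g)["LINE"] == 0.0

    def test_uniform_reads_calibrate_to_one(self, rng):
        g = ReferenceGenome({"c": "A" * 1_000_000})
        # 10% of genome in 10-kb blocks, much longer than a read
        ann = AnnotationSet.from_records(
            [("c", i * 100_000, i * 100_000 + 10_000, "+", "SINE", f"s{i}") for i in range(10)]
        )
        pos = rng.integers(0, 1_000_000 - 150, size=50_000)
        rs = _readset(g, [("c", int(p)) for p in pos])
        assert repeat_mapping_ratio(rs, ann, g)["SINE"] == pytest.approx(1.0, abs=0.05)

    def test_zero_length_class_absent(self):
        g = ReferenceGenome({"c": "A" * 1_000})
        ann = AnnotationSet.from_records([("c", 0, 10, "+", "SINE", "s")])
        rs = _readset(g, [("c", 0)], read_len=100)
        assert repeat_mapping_ratio(rs, ann, g, classes=["LTR"])["LTR"] is None


# ---------------------------------------------------------------------------
# coverage fraction + intragenic
# ---------------------------------------------------------------------------


class TestGenomeCoverage:
    def test_overlapping_circles_merged(self):
        g = ReferenceGenome({"c": "A" * 1_000})
        frac, bases = genome_coverage_fraction(
            circles_df([("c", 0, 100), ("c", 50, 150)]), g
        )
        assert frac == 0.15
        assert bases == 150

    def test_disjoint_sum(self):
        g = ReferenceGenome({"c": "A" * 1_000})
        frac, _ = genome_coverage_fraction(circles_df([("c", 0, 100), ("c", 500, 600)]), g)
        assert frac == 0.20

    def test_empty(self):
        g = ReferenceGenome({"c": "A" * 1_000})
        assert genome_coverage_fraction(circles_df([]), g) == (0.0, 0)

    def test_union_bounded_by_total_length(self, small_study):
        genome, _, circles, _ = small_study
        frac, bases = genome_coverage_fraction(circles, genome)
        total = sum(c.end - c.start for c in circles)
        assert bases <= total
        assert frac <= total / genome.total_length


class TestIntragenic:
    def test_all_inside_one_gene(self):
        ann = AnnotationSet.from_records([("c", 0, 10_000, "+", "gene", "g1")])
        res = intragenic_stats(circles_df([("c", 100, 400), ("c", 500, 900)]), ann)
        assert res["intragenic_fraction"] == 1.0

    def test_uniform_circles_match_gene_fraction(self, rng):
        # genes cover 40% of a 1-Mb chromosome
        rows = [("c", i * 25_000, i * 25_000 + 10_000, "+", "gene", f"g{i}")
                for i in range(40)]
        ann = AnnotationSet.from_records(rows)
        starts = rng.integers(0, 1_000_000 - 500, size=20_000)
        df = circles_df([("c", int(s), int(s) + 400) for s in starts])
        res = intragenic_stats(df, ann)
        assert res["intragenic_fraction"] == pytest.approx(0.40, abs=0.03)

    def test_counts_proportional_to_gene_length(self, rng):
        rows = []
        triples = []
        pos = 0
        for i in range(200):
            L = int(rng.integers(1_000, 30_000))
            rows.append(("c", pos, pos + L, "+", "gene", f"g{i}"))
            n = rng.poisson(L / 500)
            for j in range(n):
                s = pos + int(rng.integers(0, max(1, L - 300)))
                triples.append(("c", s, s + 300))
            pos += L + 2_000
        ann = AnnotationSet.from_records(rows)
        res = intragenic_stats(circles_df(triples), ann)
        r, p = res["gene_length_correlation"]
        assert r >= 0.9

    def test_no_genes(self):
        ann = AnnotationSet.from_records([("c", 0, 100, "+", "SINE", "s")])
        res = intragenic_stats(circles_df([("c", 0, 50)]), ann)
        assert res["intragenic_fraction"] == 0.0
        assert res["gene_length_correlation"] is None
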