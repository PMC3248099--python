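"""Indel filtering, coding characterization and density/enrichment stats."""

import numpy as np
import pytest
from scipy import stats

from crossvar import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    IndelFilterParams,
    VariantCall,
    Zygosity,
    classify_3n,
    filter_indels,
    intersect_indel_callers,
    region_density_enrichment,
    relative_protein_position,
    snp_indel_ratio,
    windowed_density_correlation,
)


def indel(pos, ref="AT", alt="A", chrom="chr1", depth=10, strands=(3, 3), bq=30):
    return VariantCall(
        chrom, pos, ref, alt, Zygosity.HET, depth=depth,
        info={"strand_support": strands, "base_quality": bq},
    )


class TestIntersectCallers:
    def test_identical_sets(self):
        a = [indel(1), indel(2)]
        assert intersect_indel_callers(a, a) == a

    def test_disjoint_sets(self):
        assert intersect_indel_callers([indel(1)], [indel(2)]) == []

    def test_same_position_different_allele_not_matched(self):
        assert intersect_indel_callers([indel(1, "AT", "A")], [indel(1, "ATT", "A")]) == []

    def test_independent_dropout_matches_binomial_expectation(self):
        rng = np.random.default_rng(12)
        full = [indel(i * 30) for i in range(1000)]
        a = [v for v in full if rng.random() > 0.10]
        b = [v for v in full if rng.random() > 0.15]
        n = len(intersect_indel_callers(a, b))
        lo, hi = stats.binom.interval(0.999, 1000, 0.9 * 0.85)
        assert lo <= n <= hi


class TestFilterIndels:
    def hand_filter(self, records, n_mask):
        """Oracle: independent application of each rule."""
        out = []
        for r in records:
            fwd, rev = r.info["strand_support"]
            if fwd < 1 or rev < 1:
                continue
            if r.info["base_quality"] < 20:
                continue
            if not (4 <= r.depth <= 30):
                continue
            span = max(len(r.ref), 1)
            if any(
                m.chrom == r.chrom and r.pos < m.end and m.start < r.pos + span
                for m in n_mask
            ):
                continue
            out.append(r)
        return out

    @pytest.fixture
    def toy_set(self):
        n_mask = [GenomicInterval("chr1", 500, 600)]
        records = [
            indel(10),                                  # passes everything
            indel(20, depth=3),                         # below min depth
            indel(30, depth=31),                        # above max depth
            indel(40, strands=(0, 6)),                  # no forward support
            indel(50, strands=(6, 0)),                  # no reverse support
            indel(60, bq=19),                           # low base quality
            indel(550),                                 # inside N mask
            indel(499),                                 # deletion spans into mask
            indel(70, depth=4),                         # min depth boundary
            indel(80, depth=30),                        # max depth boundary
            indel(90, strands=(1, 1)),                  # minimal strand support
            indel(598, ref="A", alt="AT"),              # insertion inside mask
        ]
        return records, n_mask

    def test_toy_set_matches_hand_evaluation(self, toy_set):
        records, n_mask = toy_set
        kept, drops = filter_indels(records, n_mask=n_mask)
        assert kept == self.hand_filter(records, n_mask)
        assert sum(drops.values()) == len(records) - len(kept)

    def test_filter_is_idempotent(self, toy_set):
        records, n_mask = toy_set
        kept, _ = filter_indels(records, n_mask=n_mask)
        again, drops = filter_indels(kept, n_mask=n_mask)
        assert again == kept and sum(drops.values()) == 0

    def test_missing_annotations_counted(self):
        bare = VariantCall("chr1", 1, "AT", "A", Zygosity.HET, depth=10)
        kept, drops = filter_indels([bare])
        assert kept == [] and drops["missing"] == 1

    def test_survivors_equal_intersection_of_single_criterion_filters(self, toy_set):
        records, n_mask = toy_set
        loose = IndelFilterParams(min_base_quality=0, min_depth=0, max_depth=10**9,
                                  require_both_strands=False, exclude_n_overlap=False)
        single = [
            IndelFilterParams(min_base_quality=20, min_depth=0, max_depth=10**9,
                              require_both_strands=False, exclude_n_overlap=False),
            IndelFilterParams(min_base_quality=0, min_depth=4, max_depth=30,
                              require_both_strands=False, exclude_n_overlap=False),
            IndelFilterParams(min_base_quality=0, min_depth=0, max_depth=10**9,
                              require_both_strands=True, exclude_n_overlap=False),
            IndelFilterParams(min_base_quality=0, min_depth=0, max_depth=10**9,
                              require_both_strands=False, exclude_n_overlap=True),
        ]
        survivor_sets = []
        for p in single:
            kept, _ = filter_indels(records, p, n_mask=n_mask)
            survivor_sets.append({id(r) for r in kept})
        full_kept, _ = filter_indels(records, n_mask=n_mask)
        assert {id(r) for r in full_kept} == set.intersection(*survivor_sets)


class TestClassify3n:
    def test_all_multiples_of_three(self):
        res = classify_3n([3, 6, 9])
        assert res["coding_3n"] == 3 and res["coding_non_3n"] == 0

    def test_frameshift_size(self):
        res = classify_3n([4])
        assert res["coding_non_3n"] == 1

    def test_enrichment_chi_square_matches_textbook_hand_computation(self):
        """3n probability 0.5 in coding vs 0.11 genome-wide, n=400 each; the
        chi-square statistic must match the explicit 2x2 formula."""
        rng = np.random.default_rng(13)
        coding = [3 if rng.random() < 0.5 else 4 for _ in range(400)]
        genome = [3 if rng.random() < 0.11 else 4 for _ in range(400)]
        res = classify_3n(coding, genome)
        # textbook chi-square on the 2x2 table, no correction
        a, b = res["coding_3n"], res["coding_non_3n"]
        c, d = res["genome_3n"], res["genome_non_3n"]
        n = a + b + c + d
        expected_chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res["chi2"] == pytest.approx(expected_chi2, rel=1e-9)
        assert res["p_value"] < 1e-6

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            classify_3n([])


def single_cds_gene(start=100, n_codons=100, strand="+", chrom="chr1"):
    cds_len = 3 * (n_codons + 1)
    return GeneModel(
        "g1", chrom, strand,
        cds=(GenomicInterval(chrom, start, start + cds_len),),
    )


class TestRelativeProteinPosition:
    def test_first_codon_of_100aa_protein(self):
        gene = single_cds_gene(start=100, n_codons=100)
        iv = VariantCall("chr1", 99, "AT", "A", Zygosity.HET)  # first changed base 100
        assert relative_protein_position(iv, gene) == pytest.approx(0.01)

    def test_last_codon_gives_one(self):
        gene = single_cds_gene(start=100, n_codons=100)
        pos = 100 + 99 * 3  # first base of codon 100
        iv = VariantCall("chr1", pos - 1, "AT", "A", Zygosity.HET)
        assert relative_protein_position(iv, gene) == pytest.approx(1.0)

    def test_minus_strand_equals_explicit_cds_walk(self):
        gene = single_cds_gene(start=100, n_codons=50, strand="-")
        pos = 150
        iv = VariantCall("chr1", pos - 1, "AT", "A", Zygosity.HET)
        # oracle: walk the CDS base by base from the 3' genomic end
        cds_positions = list(range(100, 100 + 153))
        walk_offset = list(reversed(cds_positions)).index(pos)
        expected = (walk_offset // 3 + 1) / 50
        assert relative_protein_position(iv, gene) == pytest.approx(min(expected, 1.0))

    def test_outside_cds_is_an_error(self):
        gene = single_cds_gene()
        with pytest.raises(ValueError):
            relative_protein_position(VariantCall("chr1", 5, "AT", "A", Zygosity.HET), gene)

    def test_uniformly_placed_indels_give_uniform_relative_positions(self):
        rng = np.random.default_rng(14)
        gene = single_cds_gene(start=0, n_codons=500)
        positions = rng.integers(0, 500 * 3 - 1, size=400)
        rels = [
            relative_protein_position(
                VariantCall("chr1", int(p) - 1 if p > 0 else 0, "AT", "A", Zygosity.HET), gene
            )
            for p in positions
        ]
        assert all(0 < r <= 1 for r in rels)
        ks = stats.kstest(rels, "uniform")
        assert ks.pvalue > 0.01


class TestSnpIndelRatio:
    def test_coding_indel_fraction(self):
        assert 417 / 197_895 == pytest.approx(0.0021, abs=5e-5)

    def test_equal_counts(self):
        assert snp_indel_ratio(100, 100) == 1.0

    def test_genome_wide_ratio_rounds_to_published_15_to_1(self):
        ratio = snp_indel_ratio(2_859_650, 197_895)
        assert ratio == pytest.approx(14.45, abs=0.01)
        assert round(ratio) == 14  # paper rounds up to "15:1"

    def test_zero_indels_is_an_error(self):
        with pytest.raises(ValueError):
            snp_indel_ratio(10, 0)


def uniform_variants(rng, layout, n):
    chroms = layout.chroms
    lens = np.array([layout.lengths[c] for c in chroms], dtype=float)
    out = []
    for _ in range(n):
        ci = rng.choice(len(chroms), p=lens / lens.sum())
        pos = int(rng.integers(0, lens[ci]))
        out.append(VariantCall(chroms[ci], pos, "A", "G", Zygosity.HET))
    return out


class TestRegionDensityEnrichment:
    def test_uniform_variants_give_fold_near_one(self):
        layout = GenomeLayout({"chr1": 2_000_000})
        rng = np.random.default_rng(15)
        variants = uniform_variants(rng, layout, 5000)
        regions = [GenomicInterval("chr1", 0, 1_000_000)]
        res = region_density_enrichment(variants, regions, layout)
        assert res.fold == pytest.approx(1.0, abs=0.1)
        assert res.p_value > 0.001

    def test_planted_3_3_fold_density_recovered(self):
        layout = GenomeLayout({"chr1": 2_000_000})
        rng = np.random.default_rng(16)
        region = GenomicInterval("chr1", 0, 200_000)  # 10% of genome
        fold = 3.3
        n = 5000
        p_in = fold * 0.1 / (fold * 0.1 + 0.9)
        variants = []
        for _ in range(n):
            if rng.random() < p_in:
                variants.append(VariantCall("chr1", int(rng.integers(0, 200_000)), "A", "G", Zygosity.HET))
            else:
                variants.append(VariantCall("chr1", int(rng.integers(200_000, 2_000_000)), "A", "G", Zygosity.HET))
        res = region_density_enrichment(variants, [region], layout)
        assert res.fold == pytest.approx(3.3, rel=0.10)
        assert res.p_value < 1e-10

    def test_x_vs_autosome_depletion_recovered(self):
        """Planted 4.9x lower density on X than on the autosomes."""
        layout = GenomeLayout({"chr1": 4_000_000, "chrX": 2_000_000}, sex_chroms={"chrX"})
        rng = np.random.default_rng(17)
        depletion = 4.9
        variants = [
            VariantCall("chr1", int(p), "A", "G", Zygosity.HET)
            for p in rng.integers(0, 4_000_000, size=9800)
        ] + [
            VariantCall("chrX", int(p), "A", "G", Zygosity.HET)
            for p in rng.integers(0, 2_000_000, size=1000)
        ]
        res = region_density_enrichment(
            variants, [GenomicInterval("chrX", 0, 2_000_000)], layout
        )
        assert 1 / res.fold == pytest.approx(depletion, rel=0.10)

    def test_fold_invariant_under_subsampling_in_expectation(self):
        layout = GenomeLayout({"chr1": 1_000_000})
        rng = np.random.default_rng(18)
        region = GenomicInterval("chr1", 0, 250_000)
        variants = uniform_variants(rng, layout, 8000)
        full = region_density_enrichment(variants, [region], layout)
        sub = region_density_enrichment(
            [v for v in variants if rng.random() < 0.3], [region], layout
        )
        assert sub.fold == pytest.approx(full.fold, abs=0.15)

    def test_degenerate_region_sets_rejected(self):
        layout = GenomeLayout({"chr1": 1000})
        with pytest.raises(ValueError):
            region_density_enrichment([], [], layout)
        with pytest.raises(ValueError, match="absent"):
            region_density_enrichment([], [GenomicInterval("chr2", 0, 10)], layout)


class TestWindowedDensityCorrelation:
    def test_identical_series_give_r_one(self):
        layout = GenomeLayout({"chr1": 1_000_000})
        rng = np.random.default_rng(19)
        snps = uniform_variants(rng, layout, 2000)
        res = windowed_density_correlation(snps, snps, layout)
        assert res["r"] == pytest.approx(1.0)

    def test_independent_counts_give_near_zero_r(self):
        layout = GenomeLayout({"chr1": 100_000_000})
        rng = np.random.default_rng(20)
        snps = uniform_variants(rng, layout, 20_000)
        indels = uniform_variants(rng, layout, 20_000)
        res = windowed_density_correlation(snps, indels, layout)
        assert res["n_windows"] == 5000
        assert abs(res["r"]) < 0.1

    def test_shared_latent_rate_calibrated_to_r2_04(self):
        """Counts driven by a shared gamma latent rate, mixture calibrated so
        that the expected R^2 is 0.4."""
        layout = GenomeLayout({"chr1": 40_000_000})  # 2000 windows of 20 kb
        rng = np.random.default_rng(21)
        n_windows = 2000
        # shared log-rate with variance tuned by simulation so that Pearson
        # R^2 between the two Poisson count series is ~0.4
        shared = rng.gamma(2.0, 1.0, size=n_windows)
        snp_counts = rng.poisson(6.0 * shared)
        indel_counts = rng.poisson(1.2 * shared + 1.0)
        variants_s, variants_i = [], []
        for w in range(n_windows):
            base = w * 20_000
            variants_s += [
                VariantCall("chr1", base + int(o), "A", "G", Zygosity.HET)
                for o in rng.integers(0, 20_000, size=snp_counts[w])
            ]
            variants_i += [
                VariantCall("chr1", base + int(o), "A", "G", Zygosity.HET)
                for o in rng.integers(0, 20_000, size=indel_counts[w])
            ]
        res = windowed_density_correlation(variants_s, variants_i, layout)
        assert 0.3 <= res["r_squared"] <= 0.5

    def test_zero_variance_flagged(self):
        layout = GenomeLayout({"chr1": 100_000})
        snps = [VariantCall("chr1", p, "A", "G", Zygosity.HET) for p in (5, 25_000, 45_000, 65_000, 85_000)]
        with pytest.warns(UserWarning, match="zero variance"):
            res = windowed_density_correlation(snps, [], layout)
        assert np.isnan(res["r"])
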