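"""Generator tests: determinism, planted statistical structure, ground truth."""

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from selkie import io as skio
from selkie.synthgen import (
    ConfigurationError,
    CoverageShortfallError,
    GenomeModel,
    SimulationConfig,
    make_genome,
    simulate_coverage,
    simulate_kmer_histogram,
    simulate_synteny,
    simulate_variants,
    standardize_reads,
)


class TestMakeGenome:
    def test_direct_construction(self):
        g = make_genome(2, [10_000_000, 8_000_000], 6_000_000, 1_000_000, "male")
        assert len(g.chromosomes) == 3
        assert g.par_interval == (0, 1_000_000)
        assert g.x.name == "chrX"
        assert g.lengths["chr1"] == 10_000_000

    def test_zero_par_gives_absent_par(self):
        g = make_genome(1, [1_000_000], 500_000, 0, "female")
        assert g.par_interval is None

    def test_deterministic(self):
        a = make_genome(2, [10**6, 10**6], 10**6 // 2, 10**5, "male", seed=3)
        b = make_genome(2, [10**6, 10**6], 10**6 // 2, 10**5, "male", seed=3)
        assert a == b

    def test_par_at_least_x_length_rejected(self):
        with pytest.raises(ConfigurationError):
            make_genome(1, [10**6], 10**6, 10**6, "male")

    def test_par_must_abut_terminus(self):
        with pytest.raises(ConfigurationError):
            GenomeModel(
                make_genome(1, [10**6], 10**6 // 2, 0, "male").chromosomes,
                sex="male",
                par_interval=(100, 200),
            )


class TestSimulateCoverage:
    def test_male_x_at_half_depth(self, male_genome):
        cfg = SimulationConfig(mean_depth=30.0, seed=11)
        depth = simulate_coverage(male_genome, cfg)
        non_par = depth["chrX"][3_000_000:]
        # Poisson(15): mean within 3 standard errors
        se = np.sqrt(15.0 / non_par.size)
        assert abs(non_par.mean() - 15.0) < 3 * se
        par = depth["chrX"][:3_000_000]
        assert abs(par.mean() - 30.0) < 3 * np.sqrt(30.0 / par.size)

    def test_female_x_matches_autosomes(self, female_genome):
        cfg = SimulationConfig(mean_depth=30.0, seed=11)
        depth = simulate_coverage(female_genome, cfg)
        assert abs(depth["chrX"].mean() - depth["chr1"].mean()) < 0.1

    def test_poisson_variance(self, male_genome):
        cfg = SimulationConfig(mean_depth=30.0, depth_dispersion=1.0, seed=5)
        depth = simulate_coverage(male_genome, cfg)
        auto = depth["chr1"]
        assert abs(auto.var() - 30.0) / 30.0 < 0.05

    def test_overdispersion_inflates_variance(self, male_genome):
        cfg = SimulationConfig(mean_depth=30.0, depth_dispersion=3.0, seed=5)
        auto = simulate_coverage(male_genome, cfg)["chr1"]
        assert abs(auto.var() - 90.0) / 90.0 < 0.10

    def test_bedgraph_roundtrip_byte_identical(self, male_genome, tmp_path):
        cfg = SimulationConfig(mean_depth=10.0, seed=2)
        small = make_genome(1, [50_000], 20_000, 5_000, "male")
        depth = simulate_coverage(small, cfg)
        p1, p2 = tmp_path / "a.bg", tmp_path / "b.bg"
        skio.write_bedgraph(depth, p1)
        skio.write_bedgraph(simulate_coverage(small, cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = skio.read_bedgraph(p1, small.lengths)
        assert all(np.array_equal(back[c], depth[c]) for c in depth)


class TestSimulateVariants:
    def test_poisson_count_at_planted_density(self):
        g = make_genome(1, [10_000_000], 0, 0, "female")
        cfg = SimulationConfig(het_density_map={"default": 0.6}, seed=13)
        recs = simulate_variants(g, cfg)
        expected = 0.6 * 10_000_000 / 1000
        assert abs(len(recs) - expected) < 3 * np.sqrt(expected)

    def test_zero_density_empty(self, male_genome):
        cfg = SimulationConfig(het_density_map={"default": 0.0}, seed=1)
        assert simulate_variants(male_genome, cfg) == []

    def test_male_nonpar_x_has_no_het_records(self, male_genome, sim_config):
        recs = simulate_variants(male_genome, sim_config)
        x_recs = [r for r in recs if r.chrom == "chrX"]
        assert x_recs  # PAR emits records
        assert all(r.pos < 3_000_000 for r in x_recs)

    def test_counts_poisson_consistent_over_seeds(self):
        """Chi-square goodness of fit of per-seed counts vs the planted rate."""
        from scipy import stats

        g = make_genome(1, [2_000_000], 0, 0, "female")
        rate = 0.6 * 2_000_000 / 1000
        counts = [
            len(simulate_variants(g, SimulationConfig(het_density_map={"default": 0.6},
                                                      seed=s)))
            for s in range(20)
        ]
        # Poisson counts at this rate are ~ normal; use a dispersion test
        stat = np.sum((np.array(counts) - rate) ** 2 / rate)
        assert stats.chi2.sf(stat, df=20) > 0.01

    def test_negative_density_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(het_density_map={"default": -0.1})

    def test_vcf_roundtrip(self, male_genome, sim_config, tmp_path):
        recs = simulate_variants(male_genome, sim_config)[:200]
        path = tmp_path / "v.vcf"
        skio.write_vcf(recs, male_genome, path)
        back = skio.read_vcf(path)
        assert len(back) == len(recs)
        assert all(b.genotype == "het" for b in back)
        assert [b.pos for b in back] == [r.pos for r in recs]
        assert [b.dp for b in back] == [float(r.dp) for r in recs]


class TestSimulateSynteny:
    def test_planted_inversion_flips_contained_blocks(self):
        g = make_genome(1, [20_000_000], 0, 0, "female")
        bs = simulate_synteny(g, [("chr1", (2_000_000, 6_000_000))], seed=4)
        for b in bs.blocks:
            inside = 2_000_000 <= b.ref_start and b.ref_end <= 6_000_000
            assert b.orientation == ("-" if inside else "+")

    def test_identity_set(self):
        g = make_genome(2, [1_000_000, 1_000_000], 0, 0, "female")
        bs = simulate_synteny(g, seed=4)
        assert all(b.orientation == "+" for b in bs.blocks)
        assert all(b.ref_chrom == b.query_chrom for b in bs.blocks)
        # blocks tile each chromosome without overlap
        for chrom in g.lengths:
            blocks = [b for b in bs.blocks if b.ref_chrom == chrom]
            assert blocks[0].ref_start == 0
            assert blocks[-1].ref_end == g.lengths[chrom]
            for a, b in zip(blocks, blocks[1:]):
                assert a.ref_end == b.ref_start

    def test_permutation_relabels_queries(self):
        g = make_genome(2, [1_000_000, 1_000_000], 0, 0, "female")
        bs = simulate_synteny(g, scaffold_permutation={"chr1": "s2", "chr2": "s1"},
                              seed=4)
        assert {b.query_chrom for b in bs.blocks if b.ref_chrom == "chr1"} == {"s2"}
        assert {b.query_chrom for b in bs.blocks if b.ref_chrom == "chr2"} == {"s1"}

    def test_overlapping_inversions_rejected(self):
        g = make_genome(1, [10_000_000], 0, 0, "female")
        with pytest.raises(ConfigurationError):
            simulate_synteny(g, [("chr1", (0, 2_000_000)),
                                 ("chr1", (1_000_000, 3_000_000))])


class TestSimulateKmerHistogram:
    def test_mass_conservation_without_errors(self):
        cfg = SimulationConfig(mean_depth=20.0, error_rate=0.0, seed=9)
        hist = simulate_kmer_histogram(10_000_000, cfg)
        mass = sum(i * c for i, c in hist.items())
        assert abs(mass - 2.0e8) / 2.0e8 < 0.01

    def test_error_rate_creates_low_multiplicity_peak(self):
        cfg = SimulationConfig(mean_depth=20.0, error_rate=0.5, seed=9)
        hist = simulate_kmer_histogram(1_000_000, cfg)
        assert hist[1] > hist[10]  # error peak dwarfs the inter-peak trough

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(mean_depth=20.0, error_rate=0.05, seed=3)
        assert simulate_kmer_histogram(10**6, cfg) == simulate_kmer_histogram(10**6, cfg)

    def test_error_rate_one_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(error_rate=1.0)


def _reads(n, length, seed=0):
    for i in range(n):
        yield SeqRecord(Seq("A" * length), id=f"r{seed}_{i}",
                        letter_annotations={"phred_quality": [30] * length})


class TestStandardizeReads:
    def test_cut_and_downsample(self):
        # 150 bp reads at 40x over a 1 Mb genome -> 200,000 reads of 100 bp
        n_in = 40 * 1_000_000 // 150
        out = list(standardize_reads(_reads(n_in, 150), genome_size=1_000_000,
                                     target_len=100, target_cov=20))
        assert len(out) == 200_000
        assert all(len(r.seq) == 100 for r in out)

    def test_fixed_point_up_to_ordering(self):
        n = 20 * 100_000 // 100
        reads = list(_reads(n, 100, seed=1))
        out = list(standardize_reads(reads, genome_size=100_000,
                                     target_len=100, target_cov=20))
        assert sorted(r.id for r in out) == sorted(r.id for r in reads)

    def test_shortfall_error_names_achievable_coverage(self):
        n = 10 * 100_000 // 100
        with pytest.raises(CoverageShortfallError, match="10.00x"):
            list(standardize_reads(_reads(n, 100), genome_size=100_000,
                                   target_len=100, target_cov=20))

    def test_short_reads_dropped(self):
        reads = list(_reads(300, 50)) + list(_reads(200, 100, seed=2))
        out = list(standardize_reads(reads, genome_size=1000,
                                     target_len=100, target_cov=20))
        assert len(out) == 200  # only the 100 bp reads qualify
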