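import numpy as np
import pytest

from admixscan.drift import wright_fisher_variance
from admixscan.io import DimensionError, SnpMap
from admixscan.simulate import (
    AdmixtureConfig,
    GenomeModel,
    SimulatedSample,
    TractGenome,
    _recombine,
    default_chile_genome,
    meiosis,
    physical_to_genetic,
    project_tracts_to_snps,
    replicate_rng,
    simulate_population,
)

THREE_WAY = {"EUR": 0.521, "NAM": 0.442, "AFR": 0.037}


@pytest.fixture
def one_chrom() -> GenomeModel:
    return GenomeModel((("chr1", 2.0, 1_000_000),))


@pytest.fixture
def two_chroms() -> GenomeModel:
    return GenomeModel((("chr1", 0.5, 1_000_000), ("chr2", 0.3, 600_000)))


class TestMeiosis:
    def test_identical_single_ancestry_parents(self, one_chrom):
        rng = np.random.default_rng(0)
        a = TractGenome.uniform(0, one_chrom)
        gam = meiosis(a, a, one_chrom, rng)
        gam.validate()
        assert gam.breaks.size == 0
        assert gam.anc.tolist() == [0]

    def test_zero_crossovers_returns_one_parent_exactly(self, one_chrom):
        a = TractGenome(np.array([0.5]), np.array([0, 1], dtype=np.int8), one_chrom)
        b = TractGenome(np.array([1.2]), np.array([2, 0], dtype=np.int8), one_chrom)
        for phase, parent in ((0, a), (1, b)):
            bp, anc = _recombine(a.breaks, a.anc, b.breaks, b.anc,
                                 np.empty(0), phase)
            assert np.array_equal(bp, parent.breaks)
            assert np.array_equal(anc, parent.anc)

    def test_mean_crossover_count_is_poisson_mean(self, one_chrom):
        """On a 2 M chromosome with fully distinguishable parents, junctions
        in the gamete count crossovers: mean over meioses ~ 2.0."""
        rng = np.random.default_rng(1)
        a = TractGenome.uniform(0, one_chrom)
        b = TractGenome.uniform(1, one_chrom)
        counts = [meiosis(a, b, one_chrom, rng).n_junctions for _ in range(10_000)]
        assert np.mean(counts) == pytest.approx(2.0, abs=0.05)

    def test_mismatched_genomes_rejected(self, one_chrom, two_chroms):
        rng = np.random.default_rng(0)
        a = TractGenome.uniform(0, one_chrom)
        b = TractGenome.uniform(1, two_chroms)
        with pytest.raises(DimensionError):
            meiosis(a, b, one_chrom, rng)

    def test_gamete_is_canonical_and_tiles(self, two_chroms):
        rng = np.random.default_rng(2)
        a = TractGenome(np.array([0.1, 0.4, 0.6]),
                        np.array([0, 1, 0, 2], dtype=np.int8), two_chroms)
        b = TractGenome(np.array([0.3]), np.array([1, 2], dtype=np.int8), two_chroms)
        for _ in range(50):
            gam = meiosis(a, b, two_chroms, rng)
            gam.validate()
            for name, length, _ in two_chroms.chroms:
                tr = gam.tracts(name)
                assert tr[0][0] == 0.0
                assert tr[-1][1] == pytest.approx(length)
                for (s0, e0, _c0), (s1, _e1, _c1) in zip(tr, tr[1:]):
                    assert e0 == s1  # no gaps, no overlaps


class TestSimulatePopulation:
    def test_single_founder_pool_is_monomorphic(self, two_chroms):
        cfg = AdmixtureConfig(proportions={"EUR": 1.0, "NAM": 0.0, "AFR": 0.0},
                              T=3, Ne=20, n_sample=10)
        sim = simulate_population(cfg, two_chroms, seed=0)
        for hap in sim.haplotypes:
            assert hap.anc.tolist() == [0]

    def test_t_zero_gives_one_tract_per_chromosome(self, two_chroms):
        cfg = AdmixtureConfig(proportions=THREE_WAY, T=0, Ne=50, n_sample=25)
        sim = simulate_population(cfg, two_chroms, seed=1)
        for hap in sim.haplotypes:
            assert hap.breaks.size == 0
            assert len(hap.tracts("chr1")) == 1
            assert len(hap.tracts("chr2")) == 1

    def test_same_seed_is_bit_identical(self, two_chroms):
        cfg = AdmixtureConfig(proportions=THREE_WAY, T=4, Ne=40, n_sample=20)
        s1 = simulate_population(cfg, two_chroms, seed=7)
        s2 = simulate_population(cfg, two_chroms, seed=7)
        assert s1.founder_proportions == s2.founder_proportions
        for h1, h2 in zip(s1.haplotypes, s2.haplotypes):
            assert np.array_equal(h1.breaks, h2.breaks)
            assert np.array_equal(h1.anc, h2.anc)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_sample"):
            AdmixtureConfig(T=5, Ne=10, n_sample=11)
        with pytest.raises(ValueError, match="T must be"):
            AdmixtureConfig(T=-1, Ne=10, n_sample=5)

    def test_junction_density_matches_theory(self):
        """Mean ancestry junctions per haplotype ~ L * T * (1 - sum alpha^2)
        for T << Ne: 1 Morgan, two equal ancestries, T = 2 -> 1.0."""
        genome = GenomeModel((("chr1", 1.0, 1_000_000),))
        cfg = AdmixtureConfig(proportions={"EUR": 0.5, "NAM": 0.5},
                              T=2, Ne=10_000, n_sample=500)
        sim = simulate_population(cfg, genome, seed=3)
        mean_j = np.mean([h.n_junctions for h in sim.haplotypes])
        assert mean_j == pytest.approx(1.0, abs=0.15)

    def test_junctions_nondecreasing_in_time(self):
        genome = GenomeModel(tuple((f"c{i}", 0.5, 10**6) for i in range(6)))
        cfg = dict(proportions={"EUR": 0.5, "NAM": 0.5}, Ne=200, n_sample=100)
        means = []
        for t_gen in (1, 4, 10):
            sim = simulate_population(AdmixtureConfig(T=t_gen, **cfg), genome, seed=4)
            means.append(np.mean([h.n_junctions for h in sim.haplotypes]))
        assert means[0] < means[1] < means[2]

    def test_sampled_haplotypes_tile_and_are_canonical(self, two_chroms):
        cfg = AdmixtureConfig(proportions=THREE_WAY, T=6, Ne=60, n_sample=30)
        sim = simulate_population(cfg, two_chroms, seed=5)
        for hap in sim.haplotypes:
            hap.validate()

    def test_two_sex_mode_labels_sample(self, two_chroms):
        cfg = AdmixtureConfig(proportions=THREE_WAY, T=3, Ne=40, n_sample=20,
                              mating="two_sex")
        sim = simulate_population(cfg, two_chroms, seed=6)
        assert sim.sex is not None and len(sim.sex) == 20
        assert set(sim.sex) <= {"F", "M"}
        for hap in sim.haplotypes:
            hap.validate()

    def test_ancestry_proportion_conserved_across_replicates(self):
        """Sampled mean EUR fraction is an unbiased estimate of the founding
        proportion: replicate means bracket 0.521 within 3 standard errors."""
        genome = GenomeModel(tuple((f"c{i}", 0.5, 10**6) for i in range(4)))
        cfg = AdmixtureConfig(proportions=THREE_WAY, T=5, Ne=300, n_sample=150)
        snps = SnpMap([f"s{i}" for i in range(40)],
                      [f"c{i // 10}" for i in range(40)],
                      [j * 90_000 + 1 for _ in range(4) for j in range(10)])
        snps = physical_to_genetic(snps, genome)
        fracs = []
        for r in range(16):
            seed = int(replicate_rng(11, r).integers(0, 2**31 - 1))
            sim = simulate_population(cfg, genome, seed=seed)
            calls = project_tracts_to_snps(sim, snps)
            fracs.append(float(np.mean(calls.calls == 0)))
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.521) < 3 * se + 1e-3

    def test_marginal_snp_variance_matches_drift_model(self):
        """Across replicates, the variance of a SNP's sampled ancestry
        fraction follows the Wright-Fisher + binomial-sampling compound.

        Two refinements of the idealized Beta-binomial form apply to the
        simulator exactly: the i.i.d. founder draw adds one extra resampling
        event on top of the T breeding generations (discrete drift factor at
        T+1 steps), and diploids are sampled without replacement from the Ne
        final individuals, so the binomial sampling term carries the
        finite-population factor (1 - K / 2Ne).
        """
        ne, t_gen, k_hap, n_reps = 120, 6, 60, 150
        genome = GenomeModel(tuple((f"c{i}", 0.05, 10**6) for i in range(20)))
        snps = SnpMap([f"s{i}" for i in range(20)], [f"c{i}" for i in range(20)],
                      [500_000] * 20)
        snps = physical_to_genetic(snps, genome)
        cfg = AdmixtureConfig(proportions={"EUR": 0.521, "NAM": 0.479},
                              T=t_gen, Ne=ne, n_sample=k_hap // 2)
        p0 = 0.521
        sq_dev = []
        for r in range(n_reps):
            seed = int(replicate_rng(21, r).integers(0, 2**31 - 1))
            sim = simulate_population(cfg, genome, seed=seed)
            calls = project_tracts_to_snps(sim, snps)
            p_hat = (calls.calls == 0).mean(axis=0)
            sq_dev.extend(((p_hat - p0) ** 2).tolist())
        v_sim = float(np.mean(sq_dev))
        var_drift = wright_fisher_variance(p0, t_gen + 1, ne)
        fpc = 1.0 - k_hap / (2.0 * ne)
        v_model = var_drift + fpc * (p0 * (1 - p0) - var_drift) / k_hap
        assert v_sim == pytest.approx(v_model, rel=0.12)


class TestPhysicalToGenetic:
    def test_endpoint_and_midpoint(self, two_chroms):
        snps = SnpMap(["a", "b"], ["chr1", "chr1"], [500_000, 1_000_000])
        out = physical_to_genetic(snps, two_chroms)
        assert out.gpos_M[0] == pytest.approx(0.25)
        assert out.gpos_M[1] == pytest.approx(0.5)

    def test_same_relative_position_same_gpos_scaled(self, two_chroms):
        snps = SnpMap(["a", "b"], ["chr1", "chr2"], [500_000, 300_000])
        out = physical_to_genetic(snps, two_chroms)
        assert out.gpos_M[0] == pytest.approx(0.25)
        assert out.gpos_M[1] == pytest.approx(0.15)

    def test_position_beyond_chromosome_is_range_error(self, two_chroms):
        snps = SnpMap(["a"], ["chr1"], [1_000_001])
        with pytest.raises(ValueError, match="exceeds"):
            physical_to_genetic(snps, two_chroms)

    def test_unknown_chromosome(self, two_chroms):
        snps = SnpMap(["a"], ["chrX"], [10])
        with pytest.raises(KeyError):
            physical_to_genetic(snps, two_chroms)


class TestProjection:
    def _sample(self, genome, hap):
        cfg = AdmixtureConfig(proportions=THREE_WAY, T=1, Ne=2, n_sample=1)
        return SimulatedSample(config=cfg, genome=genome, haplotypes=[hap, hap],
                               founder_proportions=THREE_WAY,
                               sample_ids=["I1"])

    def test_half_open_tracts(self):
        genome = GenomeModel((("chr1", 0.5, 1_000_000),))
        hap = TractGenome(np.array([0.2]), np.array([0, 1], dtype=np.int8), genome)
        snps = SnpMap(["in_eur", "junction", "end"], ["chr1"] * 3,
                      [200_000, 400_000, 1_000_000],
                      [0.1, 0.2, 0.5])
        calls = project_tracts_to_snps(self._sample(genome, hap), snps)
        assert calls.calls[0].tolist() == [0, 1, 1]  # junction SNP takes next tract
        # the chromosome-end SNP stays on this chromosome's last tract
        assert calls.calls[0, 2] == 1

    def test_single_tract_haplotype_constant(self):
        genome = GenomeModel((("chr1", 0.5, 1_000_000),))
        hap = TractGenome.uniform(2, genome)
        snps = SnpMap([f"s{i}" for i in range(5)], ["chr1"] * 5,
                      [1, 10, 100, 1000, 10_000],
                      [0.0, 0.01, 0.02, 0.03, 0.04])
        calls = project_tracts_to_snps(self._sample(genome, hap), snps)
        assert np.all(calls.calls == 2)

    def test_missing_gpos_is_error(self):
        genome = GenomeModel((("chr1", 0.5, 1_000_000),))
        hap = TractGenome.uniform(0, genome)
        snps = SnpMap(["a"], ["chr1"], [10])
        with pytest.raises(ValueError, match="genetic positions"):
            project_tracts_to_snps(self._sample(genome, hap), snps)


class TestDefaultGenome:
    def test_default_dimensions(self):
        genome, snps = default_chile_genome(189, seed=0)
        assert genome.n_chroms == 189
        assert genome.total_length_M == pytest.approx(189 * 0.2)
        assert len(snps) == 189
        assert snps.has_gpos

    def test_snp_count_conserved(self):
        _, snps = default_chile_genome(5000, seed=1)
        assert len(snps) == 5000

    def test_deterministic_given_seed(self):
        _, a = default_chile_genome(100, seed=2)
        _, b = default_chile_genome(100, seed=2)
        assert a == b

    def test_literal_twenty_morgan_reading(self):
        genome, _ = default_chile_genome(10, seed=0, chrom_morgans=20.0)
        assert genome.total_length_M == pytest.approx(3780.0)
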