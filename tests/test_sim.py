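"""Simulator: meiosis, burn-in, gene drop, QTN placement, phenotypes, LD."""

import numpy as np
import pytest

from qtnprofile import (GenomeSpec, MatingDesign, TraitArchitecture,
                        assign_qtn, build_founders, empirical_r2, gene_drop,
                        minor_allele_frequencies, simulate_phenotypes)
from qtnprofile.sim import _gametes


class TestGenomeSpec:
    def test_counts_and_spacing(self):
        spec = GenomeSpec(n_chrom=10, chrom_length=1.0, snps_per_cm=50)
        assert spec.n_snp == 50_000
        assert spec.snps_per_chrom == 5_000
        assert spec.spacing == pytest.approx(1 / 5000)
        tab = spec.map_table()
        assert len(tab) == 50_000
        # positions strictly increasing within each chromosome
        for _, grp in tab.groupby("chrom"):
            assert (np.diff(grp["pos_cm"]) > 0).all()

    def test_validation(self):
        with pytest.raises(ValueError):
            GenomeSpec(n_chrom=0)
        with pytest.raises(ValueError):
            GenomeSpec(chrom_length=-1.0)


class TestMeiosis:
    def test_gamete_alleles_come_from_parent(self, micro_spec):
        rng = np.random.default_rng(0)
        h0 = rng.integers(0, 2, (40, micro_spec.n_snp)).astype(np.uint8)
        h1 = rng.integers(0, 2, (40, micro_spec.n_snp)).astype(np.uint8)
        gam = _gametes(h0, h1, micro_spec, rng)
        ok = (gam == h0) | (gam == h1)
        assert ok.all()

    def test_crossover_rate_matches_map_length(self):
        """Observed phase switches per meiosis ≈ chromosome length in
        Morgan (double crossovers between adjacent SNP are negligible at
        this density)."""
        spec = GenomeSpec(n_chrom=1, chrom_length=1.0, snps_per_cm=10)
        rng = np.random.default_rng(1)
        n = 12_000
        h0 = np.zeros((n, spec.n_snp), dtype=np.uint8)
        h1 = np.ones((n, spec.n_snp), dtype=np.uint8)
        gam = _gametes(h0, h1, spec, rng)
        switches = (np.diff(gam.astype(np.int8), axis=1) != 0).sum(axis=1)
        se = switches.std(ddof=1) / np.sqrt(n)
        assert abs(switches.mean() - spec.chrom_length) < 3 * se


class TestFounders:
    def test_deterministic_for_seed(self, micro_spec):
        a = build_founders(micro_spec, ne=20, burn_in=20, seed=5)
        b = build_founders(micro_spec, ne=20, burn_in=20, seed=5)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_zero_burn_in_is_linkage_equilibrium(self, micro_spec):
        """Without burn-in, inter-locus r² is pure sampling noise ≈ 1/n."""
        pool = build_founders(micro_spec, ne=100, burn_in=0, seed=6)
        edges = np.array([0.0, 0.5])
        tab = empirical_r2(pool.genotypes, micro_spec, edges)
        assert tab["mean_r2"].iloc[0] == pytest.approx(1 / 100, rel=0.35)

    def test_burn_in_default_and_errors(self, micro_spec):
        with pytest.raises(ValueError):
            build_founders(micro_spec, ne=20, burn_in=-1)
        with pytest.raises(ValueError):
            build_founders(micro_spec, ne=1)
        with pytest.raises(ValueError):
            build_founders(micro_spec, ne=20, ancestral_ne=10)

    def test_declining_history_keeps_more_diversity(self, micro_spec):
        """A decline from a large ancestral size preserves heterozygosity
        relative to the same total time at constant small size."""
        const = build_founders(micro_spec, ne=30, burn_in=120, seed=7)
        decl = build_founders(micro_spec, ne=30, burn_in=30, seed=7,
                              ancestral_ne=300, decline_generations=90)
        def het(pool):
            p = pool.genotypes.mean(axis=0) / 2
            return (2 * p * (1 - p)).mean()
        assert het(decl) > het(const)


class TestGeneDrop:
    def test_design_counts(self, micro_pop):
        design = micro_pop.design
        assert micro_pop.n == design.total_size == 150 + 5 * 100
        assert micro_pop.genotyped_idx.size == 3 * design.generation_size
        ped = micro_pop.pedigree
        base = ped["generation"] == 0
        assert (ped.loc[base, ["sire", "dam"]] == 0).all().all()
        assert (ped.loc[~base, ["sire", "dam"]] > 0).all().all()
        # parents precede offspring
        assert (ped.loc[~base, "sire"] < ped.loc[~base, "id"]).all()

    def test_reference_design_counts(self):
        """Reference designs: 24,000 recorded / 6,000 genotyped individuals
        (and 60,000 / 18,000 for the tripled variant)."""
        ne60 = MatingDesign(n_sires=15, n_dams=1000, base_size=6000)
        assert ne60.total_size == 24_000
        assert 3 * ne60.generation_size == 6_000
        assert ne60.implied_ne == pytest.approx(59.1, abs=0.05)
        ne60_3x = MatingDesign(n_sires=15, n_dams=3000, base_size=6000)
        assert ne60_3x.total_size == 60_000
        assert 3 * ne60_3x.generation_size == 18_000
        ne600 = MatingDesign(n_sires=175, n_dams=1000, base_size=6000)
        assert ne600.implied_ne == pytest.approx(595.7, abs=0.05)

    def test_mendelian_consistency_everywhere(self, micro_pop):
        """Each non-founder haplotype is a mosaic of its parent's two; in
        particular every child allele is carried by the parent."""
        hap = micro_pop.haplotypes
        ped = micro_pop.pedigree
        for i in ped.index[ped["generation"] > 0]:
            s = ped.at[i, "sire"] - 1
            d = ped.at[i, "dam"] - 1
            pat, mat = hap[2 * i], hap[2 * i + 1]
            assert ((pat == hap[2 * s]) | (pat == hap[2 * s + 1])).all()
            assert ((mat == hap[2 * d]) | (mat == hap[2 * d + 1])).all()

    def test_equal_sex_ratio_per_mating(self, micro_pop):
        ped = micro_pop.pedigree
        for g in range(1, 6):
            gen = ped[ped["generation"] == g]
            assert (gen["sex"].to_numpy() == 0).sum() == len(gen) // 2
            # each dam has exactly two progeny, one of each sex
            by_dam = gen.groupby("dam")["sex"].agg(["count", "sum"])
            assert (by_dam["count"] == 2).all()
            assert (by_dam["sum"] == 1).all()

    def test_design_validation(self):
        with pytest.raises(ValueError):
            MatingDesign(n_sires=0, n_dams=10, base_size=100)
        with pytest.raises(ValueError):
            MatingDesign(n_sires=60, n_dams=50, base_size=400)

    def test_inbreeding_rate_tracks_implied_ne(self, micro_pool):
        """Mean pedigree inbreeding accumulates at ≈ 1/(2·Ne_implied) per
        generation (checked within 15% over replicates)."""
        from qtnprofile import numerator_relationship
        design = MatingDesign(n_sires=10, n_dams=40, base_size=120,
                              n_generations=6)
        rates = []
        for seed in (21, 22, 23):
            pop = gene_drop(micro_pool, design, seed=seed)
            f = np.diag(numerator_relationship(pop.pedigree)) - 1.0
            gen = pop.generation
            mean_f = np.array([f[gen == g].mean() for g in range(7)])
            # regression of log(1-F) on generation
            slope = np.polyfit(np.arange(7), np.log(1 - mean_f), 1)[0]
            rates.append(1.0 / (2 * -slope))
        ne_est = np.mean(rates)
        assert ne_est == pytest.approx(design.implied_ne, rel=0.15)


class TestQtnPlacement:
    def test_equal_spacing_layout(self):
        spec = GenomeSpec(n_chrom=2, chrom_length=1.0, snps_per_cm=50)
        qtn = assign_qtn(spec, per_chrom=10, min_sep=500)
        assert qtn.size == 20
        within = qtn[:10]
        assert (np.diff(within) >= 500).all()
        # identical pattern on the second chromosome
        np.testing.assert_array_equal(qtn[10:] - spec.snps_per_chrom, within)

    def test_infeasible_spacing_raises(self):
        spec = GenomeSpec(n_chrom=1, chrom_length=0.02, snps_per_cm=50)  # 100 SNP
        with pytest.raises(ValueError):
            assign_qtn(spec, per_chrom=10, min_sep=500)

    def test_random_scheme_respects_separation(self):
        spec = GenomeSpec(n_chrom=1, chrom_length=1.0, snps_per_cm=20)
        for seed in range(100):
            qtn = assign_qtn(spec, per_chrom=8, min_sep=200, scheme="random",
                             seed=seed)
            assert (np.diff(qtn) >= 200).all()
            assert qtn.max() < spec.n_snp


class TestPhenotypes:
    def test_base_variance_is_rescaled_exactly(self, micro_pop):
        arch = TraitArchitecture(qtn_indices=assign_qtn(
            micro_pop.spec, per_chrom=5, min_sep=50))
        phen = simulate_phenotypes(micro_pop, arch, seed=1)
        base = micro_pop.generation == 0
        assert phen["tbv"].to_numpy()[base].var() == pytest.approx(1.0)
        assert arch.effect is not None and arch.effect > 0

    def test_full_heritability_means_no_residual(self, micro_pop):
        arch = TraitArchitecture(
            qtn_indices=assign_qtn(micro_pop.spec, per_chrom=5, min_sep=50),
            sigma2_e=0.0)
        assert arch.h2 == 1.0
        phen = simulate_phenotypes(micro_pop, arch, seed=1)
        np.testing.assert_array_equal(phen["phenotype"], phen["tbv"])

    def test_monomorphic_qtns_raise(self, micro_pop):
        mono = np.flatnonzero(micro_pop.genotypes.std(axis=0) == 0)
        if mono.size < 2:
            pytest.skip("no monomorphic SNP in this fixture")
        arch = TraitArchitecture(qtn_indices=mono[:2])
        with pytest.raises(RuntimeError):
            simulate_phenotypes(micro_pop, arch, seed=1)

    def test_realized_effect_magnitude_plausible(self, micro_pop):
        """With tens of segregating QTNs under a drifted spectrum the
        rescaled common effect lands in the few-tenths range."""
        arch = TraitArchitecture(qtn_indices=assign_qtn(
            micro_pop.spec, per_chrom=10, min_sep=40))
        simulate_phenotypes(micro_pop, arch, seed=1)
        assert 0.05 < arch.effect < 1.5


class TestLdSummaries:
    def test_duplicated_column_gives_r2_one(self, micro_spec):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, (80, micro_spec.n_snp)).astype(np.int8)
        g[:, 1] = g[:, 0]
        edges = np.array([0.0, 2 * micro_spec.spacing])
        tab = empirical_r2(g, micro_spec, edges)
        # adjacent-pair bin includes the duplicated pair; every other pair
        # is independent noise, so the mean is dominated by counts — check
        # the duplicated pair directly instead
        r = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        assert r**2 == pytest.approx(1.0)
        assert tab["n_pairs"].iloc[0] > 0

    def test_independent_loci_r2_near_one_over_n(self, micro_spec):
        n = 150
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.5, (n, micro_spec.n_snp)).astype(np.int8)
        tab = empirical_r2(g, micro_spec, np.array([0.0, 1.0]))
        assert tab["mean_r2"].iloc[0] == pytest.approx(1 / n, rel=0.3)

    def test_maf_properties(self):
        g = np.array([[1, 0, 2, 0], [1, 2, 2, 1], [1, 0, 2, 2]], dtype=np.int8)
        maf = minor_allele_frequencies(g)
        assert maf[0] == 0.5            # all heterozygous
        assert maf[2] == 0.0            # monomorphic
        np.testing.assert_allclose(minor_allele_frequencies(2 - g), maf)
        assert ((maf >= 0) & (maf <= 0.5)).all()
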