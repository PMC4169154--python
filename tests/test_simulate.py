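"""Breeding simulator, array observation models, phenotype generator."""

import numpy as np
import pytest
from scipy import stats

from mosaicqtl.simulate import (
    ArrayNoiseModel,
    BreedingConfig,
    IntensityClusterModel,
    PhenoSimConfig,
    breed_do,
    call_distributions,
    default_cluster_model,
    default_marker_map,
    diplotype_frequencies,
    generate_calls,
    generate_intensities,
    random_founder_alleles,
    simulate_phenotype,
)


class TestBreeding:
    def test_generation_one_is_all_heterozygous(self, small_map, panel, space):
        """F1 seeding (founding switch rate 0): distinct founder pairs."""
        pop = breed_do(BreedingConfig(20, 1, founding_switch_rate=0.0),
                       small_map, panel, rng=np.random.default_rng(0))
        states = pop.state_indices(space)
        assert not space.is_homozygous[states].any()
        assert pop.breakpoint_counts(autosomes_only=False).max() == 0

    def test_mosaics_tile_chromosomes(self, sim_population):
        for ind in sim_population.individuals[:20]:
            for chrom, (a, b) in ind.haplos.items():
                L = sim_population.chrom_lengths_cm[chrom]
                for h in (a, b):
                    assert h.breaks[-1] == pytest.approx(L)
                    assert (np.diff(h.breaks) > 0).all()

    def test_seed_reproducibility(self, small_map, panel, space):
        cfg = BreedingConfig(15, 4, n_final=30)
        p1 = breed_do(cfg, small_map, panel, rng=np.random.default_rng(42))
        p2 = breed_do(cfg, small_map, panel, rng=np.random.default_rng(42))
        assert (p1.state_indices(space) == p2.state_indices(space)).all()

    def test_founder_share_mean(self, panel, space):
        """Each founder's mean genome share approaches 1/8 at equilibrium."""
        map = default_marker_map(150)
        pop = breed_do(BreedingConfig(100, 6, n_final=300), map, panel,
                       rng=np.random.default_rng(1))
        shares = pop.founder_shares()
        assert shares.sum(axis=1) == pytest.approx(1.0)
        assert np.allclose(shares.mean(axis=0), 0.125, atol=0.02)

    def test_breakpoints_linear_in_generation(self, panel):
        """Mean autosomal breakpoint count grows ~linearly with generation."""
        map = default_marker_map(60, chromosomes=["1", "2", "3"])
        gens = [4, 6, 8, 10, 12]
        means = []
        for G in gens:
            pop = breed_do(BreedingConfig(60, G, n_final=120), map, panel,
                           rng=np.random.default_rng(G))
            means.append(pop.breakpoint_counts().mean())
        slope, _, r, *_ = stats.linregress(gens, means)
        assert slope > 0
        assert r**2 > 0.99

    def test_empty_map_rejected(self, panel):
        import pandas as pd

        from mosaicqtl.genome import MarkerMap

        empty = MarkerMap(pd.DataFrame(columns=["marker", "chr", "bp", "cM"]))
        with pytest.raises(ValueError, match="empty"):
            breed_do(BreedingConfig(5, 2), empty, panel)


class TestDiplotypeFrequencies:
    def test_equilibrium_frequencies(self, space, panel):
        """Het states near 1/32 and hom states near 1/64 in a mature cohort."""
        map = default_marker_map(200)
        pop = breed_do(BreedingConfig(150, 7, n_final=400), map, panel,
                       rng=np.random.default_rng(2))
        freqs = diplotype_frequencies(pop.state_indices(space), space)
        assert freqs.sum() == pytest.approx(1.0)
        assert freqs[space.is_homozygous].mean() == pytest.approx(1 / 64, rel=0.15)
        assert freqs[~space.is_homozygous].mean() == pytest.approx(1 / 32, rel=0.15)

    def test_matches_direct_count(self, sim_population, space):
        states = sim_population.state_indices(space)
        freqs = diplotype_frequencies(states, space)
        for s in (0, 8, 20, 35):
            assert freqs[s] == pytest.approx((states == s).mean())

    def test_single_state(self, space):
        states = np.zeros((1, 10), dtype=int)  # AA everywhere
        freqs = diplotype_frequencies(states, space)
        assert freqs[0] == 1.0
        assert freqs[1:].sum() == 0.0


class TestCalls:
    def test_zero_noise_reproduces_expected_genotype(self, small_map, space,
                                                     sim_population):
        from mosaicqtl.genome import expected_genotype

        rng = np.random.default_rng(5)
        alleles = random_founder_alleles(small_map, 8, rng)
        states = sim_population.state_indices(space)
        noise = ArrayNoiseModel(call_error=0.0, no_call_rate=0.0)
        calls = generate_calls(states, alleles, space, noise, rng)
        geno = expected_genotype(alleles, space)
        M = small_map.n_markers
        expect = geno[np.arange(M)[None, :], states]
        assert (calls.calls == expect).all()

    def test_state_dependent_no_call_rates(self, small_map, space):
        """FF homozygotes can be N 90% of the time while BB stays at 1%."""
        rng = np.random.default_rng(6)
        alleles = random_founder_alleles(small_map, 8, rng)
        noise = ArrayNoiseModel(call_error=0.0, no_call_rate=0.01,
                                state_no_call={"FF": 0.9})
        n, M = 400, small_map.n_markers
        states_ff = np.full((n, M), space.index("FF"))
        states_bb = np.full((n, M), space.index("BB"))
        frac_ff = (generate_calls(states_ff, alleles, space, noise, rng).calls == 3).mean()
        frac_bb = (generate_calls(states_bb, alleles, space, noise, rng).calls == 3).mean()
        se = 3 / np.sqrt(n * M)
        assert abs(frac_ff - 0.9) < se
        assert abs(frac_bb - 0.01) < se

    def test_call_frequencies_match_multinomial(self, small_map, space):
        """Observed call fractions agree with the configured distribution
        (chi-square goodness of fit at 10,000 draws)."""
        rng = np.random.default_rng(7)
        alleles = random_founder_alleles(small_map, 8, rng)
        noise = ArrayNoiseModel(call_error=0.02, no_call_rate=0.05)
        P = call_distributions(alleles, space, noise)
        s, j = 9, 4
        states = np.full((10000, 1), s)
        calls = generate_calls(states, alleles[[j]], space, noise, rng)
        observed = np.bincount(calls.calls.ravel(), minlength=4)
        chi2 = stats.chisquare(observed, P[j, s] * 10000)
        assert chi2.pvalue > 1e-3


class TestIntensities:
    def test_zero_variance_hits_cluster_centers(self, space):
        rng = np.random.default_rng(8)
        M = 5
        mu_t = rng.random((M, 36))
        mu_r = 1 + rng.random((M, 36))
        cm = IntensityClusterModel(mu_t, mu_r, np.zeros((M, 36)), np.zeros((M, 36)))
        states = rng.integers(0, 36, size=(20, M))
        data = generate_intensities(states, cm, rng)
        from mosaicqtl.hmm import polar_transform

        theta, rho = polar_transform(data.x, data.y)
        jj = np.arange(M)[None, :]
        assert np.allclose(theta, mu_t[jj, states], atol=1e-9)
        assert np.allclose(rho, mu_r[jj, states], atol=1e-9)

    def test_moment_recovery(self, space):
        """Sample moments per state recover configured parameters at n=1000."""
        rng = np.random.default_rng(9)
        cm = IntensityClusterModel(np.full((1, 36), 0.5), np.full((1, 36), 1.0),
                                   np.full((1, 36), 0.05), np.full((1, 36), 0.08))
        states = np.full((1000, 1), 10)
        data = generate_intensities(states, cm, rng)
        from mosaicqtl.hmm import polar_transform

        theta, rho = polar_transform(data.x, data.y)
        assert abs(theta.mean() - 0.5) < 3 * 0.05 / np.sqrt(1000)
        assert abs(rho.mean() - 1.0) < 3 * 0.08 / np.sqrt(1000)
        assert abs(theta.std() - 0.05) < 0.01
        assert abs(rho.std() - 0.08) < 0.015

    def test_nonconforming_markers_have_extra_clusters(self, small_map, space):
        """Markers with an off-target founder split beyond 3 cluster centers."""
        rng = np.random.default_rng(10)
        alleles = random_founder_alleles(small_map, 8, rng)
        noise = ArrayNoiseModel(nonconforming_fraction=1.0)
        cm = default_cluster_model(alleles, space, noise, rng)
        centers = {(round(t, 3), round(r, 3))
                   for t, r in zip(cm.mu_theta[0], cm.mu_rho[0])}
        assert len(centers) > 3
        conforming = default_cluster_model(
            alleles, space, ArrayNoiseModel(nonconforming_fraction=0.0), rng)
        centers3 = {(round(t, 3), round(r, 3))
                    for t, r in zip(conforming.mu_theta[0], conforming.mu_rho[0])}
        assert len(centers3) == 3

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            IntensityClusterModel(np.zeros((1, 36)), np.zeros((1, 36)),
                                  np.full((1, 36), -1.0), np.zeros((1, 36)))


class TestPhenotype:
    def test_null_variance_without_kinship(self, small_map, space, sim_population):
        """effect=0, K=I: phenotype is iid normal with variance ~2."""
        rng = np.random.default_rng(12)
        dos = sim_population.dosages(space)
        n = dos.shape[0]
        reps = [simulate_phenotype(dos, small_map,
                                   PhenoSimConfig(n=n, maf=2, effect=0.0),
                                   kinship=np.eye(n), rng=rng)[0]
                for _ in range(40)]
        y = np.concatenate(reps)
        assert y.var() == pytest.approx(2.0, rel=0.1)
        assert abs(y.mean()) < 3 * np.sqrt(2 / len(y))

    def test_qtl_variance_decomposition(self, space, panel):
        """Realized QTL variance ~ 2p(1-p) a^2 under random mating."""
        from mosaicqtl.simulate import breed_do, default_marker_map

        map = default_marker_map(50, chromosomes=["1", "2"])
        pop = breed_do(BreedingConfig(175, 7, n_final=2000), map, panel,
                       rng=np.random.default_rng(13))
        dos = pop.dosages(space)
        effect, maf = 1.0, 2
        _, truth = simulate_phenotype(
            dos, map, PhenoSimConfig(n=2000, maf=maf, effect=effect),
            rng=np.random.default_rng(14))
        p = maf / 8
        expected_var = 2 * p * (1 - p) * effect**2
        assert truth["qtl_term"].var() == pytest.approx(expected_var, rel=0.25)

    def test_qtl_signs(self, small_map, space, sim_population):
        dos = sim_population.dosages(space)
        y, truth = simulate_phenotype(
            dos, small_map, PhenoSimConfig(n=dos.shape[0], maf=1, effect=2.0),
            rng=np.random.default_rng(15))
        term = truth["qtl_term"]
        md = truth["minor_dose"]
        assert set(np.round(np.unique(term), 6)) <= {-2.0, 0.0, 2.0}
        assert (term[md >= 2 - 1e-9] == 2.0).all()
        assert (term[md <= 1e-9] == -2.0).all()

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            PhenoSimConfig(n=10, maf=5)
        with pytest.raises(ValueError):
            PhenoSimConfig(n=10, maf=2, effect=-1)
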