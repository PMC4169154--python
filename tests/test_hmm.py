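"""HMM reconstruction: preprocessing, transitions, forward-backward, EM,
phasing and recombination counting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mosaicqtl.genome import (
    DiplotypeStateSpace,
    FounderPanel,
    GenotypeCalls,
    IntensityData,
    MarkerMap,
)
from mosaicqtl.hmm import (
    build_transition,
    count_recombinations,
    diplotype_transition,
    em_fit,
    equilibrium_distribution,
    forward_backward,
    genotype_emission_loglik,
    haplotype_transition,
    init_clusters,
    init_genotype_emission,
    marginal_reconstruction,
    phase,
    polar_transform,
    quantile_normalize,
)


class TestPolarTransform:
    @pytest.mark.parametrize("x,y,theta,rho", [
        (1.0, 0.0, 0.0, 1.0),
        (0.0, 1.0, 1.0, 1.0),
        (1.0, 1.0, 0.5, np.sqrt(2)),
    ])
    def test_axis_and_diagonal(self, x, y, theta, rho):
        t, r = polar_transform(x, y)
        assert t == pytest.approx(theta)
        assert r == pytest.approx(rho)

    def test_origin_flagged_as_half(self):
        t, r = polar_transform(0.0, 0.0)
        assert t == 0.5
        assert r == 0.0


class TestQuantileNormalize:
    def test_matching_distributions_are_stable(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1, 0.2, size=(200, 3))
        ref = IntensityData([f"r{i}" for i in range(200)], x, x + 1)
        tgt = IntensityData([f"t{i}" for i in range(200)],
                            rng.normal(1, 0.2, size=(200, 3)),
                            rng.normal(2, 0.2, size=(200, 3)))
        out = quantile_normalize(ref, tgt)
        # ranks preserved, quantiles mapped onto the target's
        for j in range(3):
            assert (np.argsort(out.x[:, j]) == np.argsort(ref.x[:, j])).all()
            assert np.quantile(out.x[:, j], 0.5) == pytest.approx(
                np.quantile(tgt.x[:, j], 0.5), abs=0.05)

    def test_monotone_transform_undone(self):
        """A monotone distortion of the target distribution maps back onto
        the target's empirical quantiles at matching ranks."""
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, size=(500, 1))
        ref = IntensityData([f"r{i}" for i in range(500)],
                            np.exp(base), np.exp(base))  # distorted scale
        tgt = IntensityData([f"t{i}" for i in range(500)], base + 5, base + 5)
        out = quantile_normalize(ref, tgt)
        assert np.corrcoef(np.sort(out.x[:, 0]), np.sort(tgt.x[:, 0]))[0, 1] > 0.9999
        assert abs(np.sort(out.x[:, 0])[250] - np.sort(tgt.x[:, 0])[250]) < 0.05

    def test_shape_mismatch_rejected(self):
        a = IntensityData(["a", "b"], np.ones((2, 3)), np.ones((2, 3)))
        b = IntensityData(["c", "d"], np.ones((2, 4)), np.ones((2, 4)))
        with pytest.raises(ValueError):
            quantile_normalize(a, b)


class TestTransitionModel:
    def test_zero_distance_is_identity(self, space):
        T = diplotype_transition(space, haplotype_transition(8, 5.0, 0.0))
        assert np.allclose(T, np.eye(36))

    def test_rows_sum_to_one(self, space):
        T = diplotype_transition(space, haplotype_transition(8, 5.0, 0.123))
        assert np.allclose(T.sum(axis=1), 1.0)

    def test_long_distance_reaches_equilibrium(self, space):
        """Rows converge to 1/64 per homozygote, 1/32 per heterozygote."""
        T = diplotype_transition(space, haplotype_transition(8, 5.0, 100.0))
        pi = equilibrium_distribution(space)
        assert np.allclose(T, np.tile(pi, (36, 1)), atol=1e-10)
        assert pi[space.is_homozygous] == pytest.approx(1 / 64)
        assert pi[~space.is_homozygous] == pytest.approx(1 / 32)

    def test_two_marker_chain_matches_haplotype_convolution(self, space):
        """Diplotype transition equals brute-force convolution of two
        independent haplotype chains over ordered pairs."""
        Th = haplotype_transition(8, 3.0, 0.05)
        T = diplotype_transition(space, Th)
        for s_idx, (a, b) in enumerate(space.pairs):
            target = np.zeros(36)
            for c in range(8):
                for d in range(8):
                    t_idx = space.index(space.panel.labels[min(c, d)]
                                        + space.panel.labels[max(c, d)])
                    target[t_idx] += Th[a, c] * Th[b, d]
            assert np.allclose(T[s_idx], target, atol=1e-12)

    def test_build_transition_identity_at_duplicate_cm(self, space):
        t = pd.DataFrame({"marker": ["a", "b"], "chr": ["1", "1"],
                          "bp": [1, 2], "cM": [0.0, 0.5]})
        tm = build_transition(MarkerMap(t), 8, space)
        assert tm.chrom("1").shape == (1, 36, 36)
        assert tm.lam > 0


class TestEmission:
    def test_expected_call_logprob(self, space, small_map):
        from mosaicqtl.simulate import random_founder_alleles

        alleles = random_founder_alleles(small_map, 8, np.random.default_rng(2))
        em = init_genotype_emission(alleles, space, p_expected=0.97)
        # observing the expected call scores log(0.97)
        from mosaicqtl.genome import expected_genotype

        geno = expected_genotype(alleles, space)
        calls = geno[None, :, 0]  # observe state 0's expected genotype
        ll = genotype_emission_loglik(em, calls.astype(np.int8))
        assert ll[0, :, 0] == pytest.approx(np.log(0.97))

    def test_distributions_normalized(self, space, small_map):
        from mosaicqtl.simulate import random_founder_alleles

        alleles = random_founder_alleles(small_map, 8, np.random.default_rng(3))
        em = init_genotype_emission(alleles, space)
        assert np.allclose(em.probs.sum(axis=-1), 1.0)

    def test_intensity_mode_maximizes_likelihood(self):
        from mosaicqtl.hmm import IntensityEmission, intensity_emission_loglik

        em = IntensityEmission(np.array([[0.3]]), np.array([[0.01]]),
                               np.array([[1.2]]), np.array([[0.04]]))
        at_mode = intensity_emission_loglik(em, np.array([[0.3]]), np.array([[1.2]]))
        off = intensity_emission_loglik(em, np.array([[0.5]]), np.array([[1.2]]))
        assert at_mode[0, 0, 0] > off[0, 0, 0]


class TestForwardBackward:
    def test_single_marker_posterior_proportional_to_emission(self):
        rng = np.random.default_rng(4)
        le = np.log(rng.random((3, 1, 6)))
        prior = np.full(6, 1 / 6)
        post, ll = forward_backward(le, np.zeros((0, 6, 6)), prior)
        expect = np.exp(le[:, 0])
        expect /= expect.sum(axis=1, keepdims=True)
        assert np.allclose(post[:, 0], expect)

    def test_identity_transitions_pool_emissions(self):
        """With fully linked markers the posterior is the normalized product
        of all emissions at every marker."""
        rng = np.random.default_rng(5)
        le = np.log(rng.random((2, 3, 4)))
        T = np.tile(np.eye(4), (2, 1, 1))
        post, _ = forward_backward(le, T, np.full(4, 0.25))
        prod = np.exp(le.sum(axis=1))
        prod /= prod.sum(axis=1, keepdims=True)
        for j in range(3):
            assert np.allclose(post[:, j], prod, atol=1e-12)

    def test_matches_exhaustive_path_enumeration(self):
        """Posteriors equal brute-force enumeration over all state paths
        (6 states from a 3-founder panel, 3 markers, |diff| < 1e-10)."""
        panel = FounderPanel(("A", "B", "C"))
        sp = DiplotypeStateSpace(panel)
        S, M = sp.n_states, 3
        rng = np.random.default_rng(6)
        le = np.log(rng.random((1, M, S)))
        T = np.stack([diplotype_transition(sp, haplotype_transition(3, 2.0, d))
                      for d in (0.05, 0.2)])
        prior = equilibrium_distribution(sp)
        post, ll = forward_backward(le, T, prior)

        # oracle: enumerate all S^M paths
        brute = np.zeros((M, S))
        total = 0.0
        for path in itertools.product(range(S), repeat=M):
            p = prior[path[0]] * np.exp(le[0, 0, path[0]])
            for j in range(1, M):
                p *= T[j - 1][path[j - 1], path[j]] * np.exp(le[0, j, path[j]])
            total += p
            for j in range(M):
                brute[j, path[j]] += p
        brute /= total
        assert np.allclose(post[0], brute, atol=1e-10)
        assert ll[0] == pytest.approx(np.log(total), abs=1e-10)

    def test_vanishing_emissions_stay_normalized(self):
        """A marker where every state is astronomically unlikely must not
        produce NaNs; the posterior stays a probability distribution."""
        le = np.full((1, 2, 3), -1e30)
        le[:, 0] = 0.0
        post, ll = forward_backward(le, np.tile(np.eye(3), (1, 1, 1)),
                                    np.full(3, 1 / 3))
        assert np.isfinite(post).all()
        assert np.allclose(post.sum(axis=2), 1.0)


@pytest.fixture(scope="module")
def call_em_setup(small_map, panel, space, sim_population):
    from mosaicqtl.simulate import ArrayNoiseModel, generate_calls, random_founder_alleles

    rng = np.random.default_rng(21)
    alleles = random_founder_alleles(small_map, 8, rng)
    states = sim_population.state_indices(space)
    calls = generate_calls(states, alleles, space, ArrayNoiseModel(), rng)
    transition = build_transition(small_map, 6, space)
    emission = init_genotype_emission(alleles, space)
    return calls, transition, emission, states, alleles


class TestEM:
    def test_loglik_nondecreasing(self, call_em_setup, small_map):
        calls, transition, emission, *_ = call_em_setup
        state, probs = em_fit(calls, small_map, transition, emission)
        trace = np.array(state.loglik_trace)
        assert (np.diff(trace) >= -1e-6 * np.abs(trace[:-1])).all()
        assert np.allclose(probs.probs.sum(axis=2), 1.0, atol=1e-8)

    def test_fixed_point_at_true_parameters(self, small_map, space, panel):
        """Data generated exactly at the initial parameters converges almost
        immediately and leaves the emission distribution near its start."""
        from mosaicqtl.simulate import (ArrayNoiseModel, BreedingConfig, breed_do,
                                        generate_calls, random_founder_alleles)

        rng = np.random.default_rng(22)
        pop = breed_do(BreedingConfig(60, 5, n_final=250), small_map, panel, rng)
        states = pop.state_indices(space)
        alleles = random_founder_alleles(small_map, 8, rng)
        noise = ArrayNoiseModel(call_error=0.01, no_call_rate=0.01)
        calls = generate_calls(states, alleles, space, noise, rng)
        transition = build_transition(small_map, 5, space)
        emission = init_genotype_emission(alleles, space, p_expected=0.97)
        state, _ = em_fit(calls, small_map, transition, emission)
        assert state.converged
        assert state.n_iter <= 20  # only finite-sample noise left to absorb
        # the dominant-call probability stays near its generating value
        new_max = state.emission.probs.max(axis=-1)
        assert np.median(new_max) == pytest.approx(0.97, abs=0.03)

    def test_small_sample_warns(self, call_em_setup, small_map):
        calls, transition, emission, *_ = call_em_setup
        small = GenotypeCalls(calls.samples[:10], calls.calls[:10])
        with pytest.warns(UserWarning, match="unreliable"):
            em_fit(small, small_map, transition, emission, max_iter=1)


class TestMarginalAndPhasing:
    def test_one_hot_argmax(self, space):
        from mosaicqtl.genome import DiplotypeProbs

        p = np.zeros((1, 4, 36))
        seq = [3, 9, 9, 20]
        for j, s in enumerate(seq):
            p[0, j, s] = 1.0
        states, ties = marginal_reconstruction(DiplotypeProbs(["s"], p))
        assert states[0].tolist() == seq
        assert not ties.any()

    def test_tie_breaks_to_lowest_index_and_flags(self, space):
        from mosaicqtl.genome import DiplotypeProbs

        p = np.zeros((1, 1, 36))
        p[0, 0, 5] = 0.5
        p[0, 0, 17] = 0.5
        states, ties = marginal_reconstruction(DiplotypeProbs(["s"], p))
        assert states[0, 0] == 5
        assert ties[0, 0]

    def test_constant_het_phases_to_two_pure_strands(self, small_map, space):
        states = np.full((1, small_map.n_markers), space.index("AB"))
        recon = phase(states, small_map, space)
        assert (recon.hap1["1"] == recon.hap1["1"][0, 0]).all()
        assert (recon.hap2["1"] == recon.hap2["1"][0, 0]).all()
        assert count_recombinations(recon, small_map)[0] == 0

    def test_single_junction_keeps_shared_strand(self, small_map, space):
        """AB -> AC switches one strand; the A strand stays intact."""
        M = small_map.n_markers
        states = np.concatenate([
            np.full((1, M // 2), space.index("AB")),
            np.full((1, M - M // 2), space.index("AC")),
        ], axis=1)
        recon = phase(states, small_map, space)
        a_idx = 0
        on_h1 = (recon.hap1["1"][0] == a_idx).all()
        on_h2 = (recon.hap2["1"][0] == a_idx).all()
        assert on_h1 or on_h2
        # total autosomal events: exactly one per chromosome that contains
        # the junction (chromosome 1 here since split is inside chr 1 or 2)
        assert count_recombinations(recon, small_map)[0] == 1

    def test_phasing_matches_exhaustive_minimum(self, space):
        """DP switch count equals the brute-force minimum over all 2^M
        orientation choices on 10-marker instances."""
        rng = np.random.default_rng(30)
        pair_arr = np.array(space.pairs)
        t = pd.DataFrame({
            "marker": [f"m{k}" for k in range(10)], "chr": ["1"] * 10,
            "bp": np.arange(1, 11) * 1000, "cM": np.arange(10) * 1.0,
        })
        map1 = MarkerMap(t)
        for trial in range(5):
            states = rng.integers(0, 36, size=(1, 10))
            recon = phase(states, map1, space)
            dp_count = count_recombinations(recon, map1)[0]

            a = pair_arr[states[0], 0]
            b = pair_arr[states[0], 1]
            best = np.inf
            for orient in itertools.product((0, 1), repeat=10):
                s1 = [a[j] if o == 0 else b[j] for j, o in enumerate(orient)]
                s2 = [b[j] if o == 0 else a[j] for j, o in enumerate(orient)]
                c = sum(s1[j] != s1[j + 1] for j in range(9))
                c += sum(s2[j] != s2[j + 1] for j in range(9))
                best = min(best, c)
            assert dp_count == best

    def test_breakpoints_at_midpoints(self, space):
        t = pd.DataFrame({"marker": ["a", "b", "c"], "chr": ["1"] * 3,
                          "bp": [100, 300, 700], "cM": [0.0, 1.0, 2.0]})
        map1 = MarkerMap(t)
        states = np.array([[space.index("AA"), space.index("AA"),
                            space.index("AB")]])
        recon = phase(states, map1, space, samples=["s0"])
        assert recon.breakpoints_bp[("s0", "1")] == [500.0]

    def test_recombination_count_approaches_truth_with_density(self, panel, space):
        """Phased event counts from the true states increase toward the true
        breakpoint count as marker density grows."""
        from mosaicqtl.simulate import BreedingConfig, breed_do, default_marker_map

        counts = {}
        for m in (30, 120):
            map_m = default_marker_map(m, chromosomes=["1", "2", "3"])
            pop = breed_do(BreedingConfig(50, 8, n_final=60), map_m, panel,
                           rng=np.random.default_rng(31))
            states = pop.state_indices(space)
            recon = phase(states, map_m, space)
            counts[m] = count_recombinations(recon, map_m).mean()
            truth = pop.breakpoint_counts().mean()
            assert counts[m] <= truth + 1e-9
        assert counts[120] > counts[30]


class TestClusterInit:
    def test_three_cluster_marker_partitions_states(self, space):
        """References at three well-separated centers map the 36 states onto
        their genotype classes."""
        rng = np.random.default_rng(40)
        centers = {0: (0.1, 1.0), 1: (0.5, 1.0), 2: (0.9, 1.0)}
        alleles = np.array([0, 1, 0, 0, 1, 0, 1, 0])
        ref_states, rt, rr = [], [], []
        for s, (h, k) in enumerate(space.pairs):
            g = alleles[h] + alleles[k]
            for _ in range(3):
                ref_states.append(s)
                rt.append(centers[g][0] + rng.normal(0, 0.01))
                rr.append(centers[g][1] + rng.normal(0, 0.02))
        ct = rng.choice([0.1, 0.5, 0.9], 100) + rng.normal(0, 0.01, 100)
        cr = np.ones(100) + rng.normal(0, 0.02, 100)
        assignment, em = init_clusters(np.array(rt), np.array(rr),
                                       np.array(ref_states), ct, cr, space,
                                       rng=rng)
        geno = alleles[[p[0] for p in space.pairs]] + alleles[[p[1] for p in space.pairs]]
        for g in (0, 1, 2):
            assert len(set(assignment[geno == g])) == 1
        assert len(set(assignment)) == 3
        assert np.allclose(np.sort(np.unique(em.mu_theta[0])),
                           [0.1, 0.5, 0.9], atol=0.02)

    def test_bic_selects_generating_component_count(self, space):
        """BIC recovers the generating cluster count on most simulated
        well-separated mixtures."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(41)
        hits = 0
        trials = 20
        for _ in range(trials):
            k_true = rng.integers(2, 5)
            means = np.column_stack([np.linspace(0.1, 0.9, k_true),
                                     np.ones(k_true)])
            pts = np.concatenate([
                m + rng.normal(0, [0.02, 0.04], size=(60, 2)) for m in means])
            best_k, best_bic = 0, np.inf
            for k in range(1, 7):
                gm = GaussianMixture(k, covariance_type="diag", random_state=0,
                                     reg_covar=1e-4).fit(pts)
                if gm.bic(pts) < best_bic:
                    best_bic, best_k = gm.bic(pts), k
            hits += best_k == k_true
        assert hits >= 0.9 * trials
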