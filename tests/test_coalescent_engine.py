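"""Engine tests, including cross-checks against msprime as an independent
coalescent oracle."""

import numpy as np
import pytest

from pinepop.coalescent_engine import (
    DemographicModel,
    IMParams,
    sample_sfs,
    simulate_arg,
    simulate_im_locus,
    simulate_locus_patterns,
    wf_absorption_time,
)
from pinepop.popstats import harmonic

CONST = DemographicModel("constant")


class TestDemographicModel:
    def test_three_epoch_requires_ta_after_tb(self):
        with pytest.raises(ValueError, match="T_A > T_B"):
            DemographicModel("three_epoch", T_B=0.5, T_A=0.4, N_B_over_N0=0.1, N_A_over_N0=2)

    def test_epoch_layout(self):
        m = DemographicModel("three_epoch", T_B=0.1, T_A=0.3, N_B_over_N0=0.2, N_A_over_N0=4.0)
        assert m.epochs() == [(0.0, 1.0), (0.1, 0.2), (0.3, 4.0)]
        assert DemographicModel("constant").epochs() == [(0.0, 1.0)]


class TestSimulateArg:
    def test_constant_model_class_means(self, rng):
        # E[b_i] = 1/i under constant size
        reps = 4000
        b = np.array([simulate_arg(5, CONST, 0.0, 1, rng).b for _ in range(reps)])
        mean, se = b.mean(axis=0), b.std(axis=0, ddof=1) / np.sqrt(reps)
        expected = 1.0 / np.arange(1, 5)
        assert np.all(np.abs(mean - expected) < 3 * se + 1e-9)

    def test_total_length_matches_harmonic(self, rng):
        reps = 3000
        tot = np.array([simulate_arg(5, CONST, 0.0, 1, rng).b.sum() for _ in range(reps)])
        se = tot.std(ddof=1) / np.sqrt(reps)
        assert tot.mean() == pytest.approx(harmonic(4), abs=3 * se)

    def test_recombination_preserves_marginal_means(self, rng):
        reps = 1200
        b = np.array([simulate_arg(4, CONST, 0.02, 100, rng).b for _ in range(reps)])
        mean, se = b.mean(axis=0), b.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean - 1 / np.arange(1, 4)) < 3 * se + 1e-9)

    def test_degenerate_three_epoch_equals_constant(self, rng):
        from scipy.stats import ks_2samp

        degenerate = DemographicModel(
            "three_epoch", N_B_over_N0=1.0, N_A_over_N0=1.0, T_B=0.05, T_A=0.2
        )
        reps = 3000
        t1 = np.array([simulate_arg(6, CONST, 0.0, 1, rng).b.sum() for _ in range(reps)])
        t2 = np.array([simulate_arg(6, degenerate, 0.0, 1, rng).b.sum() for _ in range(reps)])
        assert ks_2samp(t1, t2).pvalue > 0.01

    def test_recent_bottleneck_reduces_total_length(self, rng):
        bottleneck = DemographicModel(
            "three_epoch", N_B_over_N0=0.1, N_A_over_N0=1.0, T_B=0.05, T_A=10.0
        )
        reps = 3000
        t_const = np.array([simulate_arg(8, CONST, 0.0, 1, rng).b.sum() for _ in range(reps)])
        t_bot = np.array([simulate_arg(8, bottleneck, 0.0, 1, rng).b.sum() for _ in range(reps)])
        se = np.hypot(t_const.std() / np.sqrt(reps), t_bot.std() / np.sqrt(reps))
        assert t_bot.mean() < t_const.mean() - 3 * se

    def test_identical_seed_identical_output(self):
        model = DemographicModel("two_epoch", T_A=0.3, N_A_over_N0=5.0)
        a = simulate_arg(6, model, 0.01, 50, np.random.default_rng(7)).b
        b = simulate_arg(6, model, 0.01, 50, np.random.default_rng(7)).b
        assert np.array_equal(a, b)

    def test_against_msprime_oracle_bottleneck(self, rng):
        """Mean per-class branch lengths under a bottleneck vs msprime."""
        import msprime

        n, reps = 6, 3000
        model = DemographicModel(
            "three_epoch", N_B_over_N0=0.15, N_A_over_N0=4.0, T_B=0.05, T_A=0.25
        )
        # ploidy 1 with size 2*N0 gives pair-coalescence rate 1/(2 N0) per
        # generation, matching the engine's diploid-N0 scaling
        N0 = 10_000
        dem = msprime.Demography()
        dem.add_population(name="p", initial_size=2 * N0)
        dem.add_population_parameters_change(time=0.05 * 2 * N0, initial_size=0.15 * 2 * N0)
        dem.add_population_parameters_change(time=0.25 * 2 * N0, initial_size=4.0 * 2 * N0)
        afs = np.zeros(n - 1)
        for ts in msprime.sim_ancestry(
            samples={"p": n}, demography=dem, ploidy=1, num_replicates=reps, random_seed=11
        ):
            afs += ts.allele_frequency_spectrum(
                mode="branch", polarised=True, span_normalise=True
            )[1:n]
        # branch-mode AFS counts generations; b_i uses 2N0 units and halves
        oracle = afs / reps / (2 * N0) / 2
        mine = np.array([simulate_arg(n, model, 0.0, 1, rng).b for _ in range(reps)])
        se = mine.std(axis=0, ddof=1) / np.sqrt(reps) * np.sqrt(2)
        assert np.all(np.abs(mine.mean(axis=0) - oracle) < 3.5 * se)


class TestSampleSfs:
    def test_zero_theta_gives_empty_spectrum(self, rng):
        arg = simulate_arg(5, CONST, 0.0, 1, rng)
        assert sample_sfs(arg, 0.0, rng).counts.sum() == 0

    def test_pair_sample_mean_matches_theta(self, rng):
        reps, theta = 4000, 2.0
        xs = np.array(
            [sample_sfs(simulate_arg(2, CONST, 0.0, 1, rng), theta, rng).counts[0] for _ in range(reps)]
        )
        se = xs.std(ddof=1) / np.sqrt(reps)
        assert xs.mean() == pytest.approx(theta, abs=3 * se)

    def test_deterministic_under_seed(self):
        def draw():
            rng = np.random.default_rng(3)
            return sample_sfs(simulate_arg(6, CONST, 0.0, 1, rng), 5.0, rng).counts

        assert np.array_equal(draw(), draw())


class TestMutationPlacement:
    def test_patterns_consistent_with_sample_size(self, rng):
        muts = simulate_locus_patterns(8, CONST, 0.01, 200, 0.02, rng)
        for site, mask in muts:
            assert 0 <= site < 200
            assert 1 <= int.bit_count(mask) <= 7  # visible polymorphism only

    def test_infinite_sites_no_recurrent_hits(self, rng):
        muts = simulate_locus_patterns(6, CONST, 0.0, 100, 0.05, rng)
        sites = [s for s, _ in muts]
        assert len(sites) == len(set(sites))


class TestIsolationSimulator:
    def test_panmixia_limit_no_fixed_differences(self, rng):
        p = IMParams(theta1=2.0, tau=0.0)
        sims = np.array(
            [simulate_im_locus(6, 2, p, 2.0, rng).as_array() for _ in range(3000)]
        )
        assert sims[:, 3].mean() < 0.05

    def test_deep_divergence_kills_shared_polymorphism(self, rng):
        p = IMParams(theta1=2.0, tau=20.0)
        sims = np.array(
            [simulate_im_locus(6, 2, p, 2.0, rng).as_array() for _ in range(3000)]
        )
        assert sims[:, 2].mean() < 0.01

    def test_fixed_differences_increase_with_tau(self, rng):
        means = []
        for tau in (0.5, 1.0, 2.0):
            p = IMParams(theta1=2.0, tau=tau)
            sims = np.array(
                [simulate_im_locus(6, 2, p, 2.0, rng).as_array() for _ in range(2500)]
            )
            means.append(sims[:, 3].mean())
        assert means[0] < means[1] < means[2]

    def test_against_msprime_oracle(self, rng):
        """Category means under the isolation model vs msprime."""
        import msprime

        n1, n2, reps = 6, 2, 4000
        theta1, r2, rA, tau = 1.5, 1.0, 4.0, 0.4
        N1 = 10_000
        dem = msprime.Demography()
        dem.add_population(name="p1", initial_size=2 * N1)
        dem.add_population(name="p2", initial_size=2 * N1 * r2)
        dem.add_population(name="anc", initial_size=2 * N1 * rA)
        dem.add_population_split(time=tau * 4 * N1, derived=["p1", "p2"], ancestral="anc")
        mu = theta1 / (4 * N1)
        counts = np.zeros(4)
        rs = np.random.default_rng(5)
        for ts in msprime.sim_ancestry(
            samples={"p1": n1, "p2": n2}, demography=dem, ploidy=1,
            num_replicates=reps, random_seed=17,
        ):
            mts = msprime.sim_mutations(
                ts, rate=mu, random_seed=int(rs.integers(1, 2**31)),
                model=msprime.BinaryMutationModel(), discrete_genome=False,
            )
            for var in mts.variants():
                g = var.genotypes
                d1, d2 = int(g[:n1].sum()), int(g[n1:].sum())
                if len(set(g)) == 1:
                    continue
                poly1, poly2 = 0 < d1 < n1, 0 < d2 < n2
                if poly1 and poly2:
                    counts[2] += 1
                elif poly1:
                    counts[0] += 1
                elif poly2:
                    counts[1] += 1
                elif (d1 == n1 and d2 == 0) or (d1 == 0 and d2 == n2):
                    counts[3] += 1
        oracle = counts / reps
        p = IMParams(theta1, r2, rA, tau)
        mine = np.array(
            [simulate_im_locus(n1, n2, p, theta1, rng).as_array() for _ in range(reps)]
        )
        se = mine.std(axis=0, ddof=1) / np.sqrt(reps) * np.sqrt(2)
        assert np.all(np.abs(mine.mean(axis=0) - oracle) < 3.5 * se + 0.01)


class TestWrightFisher:
    def test_started_fixed_absorbs_immediately(self, rng):
        mean, se = wf_absorption_time(1.0, 500, 1000, rng)
        assert mean == 0.0

    def test_low_frequency_diffusion_value(self, rng):
        # -4 (0.1 ln 0.1 + 0.9 ln 0.9) = 1.300
        mean, se = wf_absorption_time(0.1, 1000, 4000, rng)
        assert mean == pytest.approx(1.300, abs=3 * se)

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            wf_absorption_time(1.5, 1000, 2000, rng)
        with pytest.raises(ValueError):
            wf_absorption_time(0.5, 10, 2000, rng)
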