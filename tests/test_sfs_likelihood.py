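import math

import numpy as np
import pytest
from scipy.stats import poisson

from pinepop.coalescent_engine import ARGSample, DemographicModel, sample_sfs, simulate_arg
from pinepop.popstats import SFS
from pinepop.sfs_likelihood import (
    LikelihoodConfig,
    dataset_loglik,
    locus_loglik,
    theta_bias_factor,
)

CONST = DemographicModel("constant")


class TestLocusLoglik:
    def test_empty_spectrum_is_minus_theta_times_rate(self):
        # folded n=3 has one class with rate b1 + b2
        arg = ARGSample(n=3, b=np.array([1.2, 0.4]))
        sfs = SFS(n=3, folded=True, counts=[0])
        assert locus_loglik(sfs, [arg], 2.0) == pytest.approx(-2.0 * 1.6, rel=1e-12)

    def test_handcrafted_poisson_product(self):
        arg = ARGSample(n=3, b=np.array([1.0, 0.5]))
        sfs = SFS(n=3, folded=False, counts=[2, 1])
        expected = poisson.logpmf(2, 1.0) + poisson.logpmf(1, 0.5)
        assert locus_loglik(sfs, [arg], 1.0) == pytest.approx(expected, rel=1e-12)

    def test_folded_rates_use_sum_rule(self):
        arg = ARGSample(n=4, b=np.array([1.0, 0.5, 0.25]))
        sfs = SFS(n=4, folded=True, counts=[3, 1])
        expected = poisson.logpmf(3, 1.25) + poisson.logpmf(1, 0.5)
        assert locus_loglik(sfs, [arg], 1.0) == pytest.approx(expected, rel=1e-12)

    def test_duplicated_arg_leaves_value_unchanged(self):
        arg = ARGSample(n=3, b=np.array([0.8, 0.3]))
        sfs = SFS(n=3, folded=False, counts=[1, 2])
        single = locus_loglik(sfs, [arg], 1.5)
        assert locus_loglik(sfs, [arg] * 50, 1.5) == pytest.approx(single, rel=1e-12)

    def test_zero_rate_class_with_observation_drops_that_arg(self):
        dead = ARGSample(n=3, b=np.array([0.0, 1.0]))
        live = ARGSample(n=3, b=np.array([1.0, 1.0]))
        sfs = SFS(n=3, folded=False, counts=[1, 0])
        # averaging over {dead, live}: dead contributes likelihood 0
        ll = locus_loglik(sfs, [dead, live], 1.0)
        expected = math.log(0.5 * math.exp(poisson.logpmf(1, 1.0) + poisson.logpmf(0, 1.0)))
        assert ll == pytest.approx(expected, rel=1e-12)
        assert locus_loglik(sfs, [dead], 1.0) == -np.inf

    def test_mismatched_n_raises(self):
        arg = ARGSample(n=4, b=np.ones(3))
        with pytest.raises(ValueError, match="sample size"):
            locus_loglik(SFS(n=3, folded=False, counts=[0, 0]), [arg], 1.0)


class TestDatasetLoglik:
    def test_single_locus_equals_locus_loglik(self, rng):
        cfg = LikelihoodConfig(M=50, theta_by_class={"coding": 0.01}, rho_per_bp=0.0, seed=4)
        sfs = SFS(n=6, folded=True, counts=[2, 1, 0])
        cache = {}
        total = dataset_loglik([(sfs, "coding", 100)], CONST, cfg, arg_cache=cache)
        assert total == pytest.approx(locus_loglik(sfs, cache[(6, 100)], 1.0), rel=1e-12)

    def test_identical_loci_share_streams_and_double(self):
        cfg = LikelihoodConfig(M=40, theta_by_class={"coding": 0.01}, rho_per_bp=0.0, seed=4)
        sfs = SFS(n=6, folded=True, counts=[2, 1, 0])
        one = dataset_loglik([(sfs, "coding", 100)], CONST, cfg)
        two = dataset_loglik([(sfs, "coding", 100)] * 2, CONST, cfg)
        assert two == pytest.approx(2 * one, rel=1e-10)

    def test_likelihood_prefers_true_theta(self, rng):
        # data simulated at theta: loglik(theta) should usually beat 2*theta
        theta_site, L, n = 0.01, 200, 8
        wins = 0
        reps = 12
        for _ in range(reps):
            loci = []
            for _ in range(20):
                arg = simulate_arg(n, CONST, 0.0, L, rng)
                loci.append((sample_sfs(arg, theta_site * L, rng).fold(), "coding", L))
            cfg_true = LikelihoodConfig(M=150, theta_by_class={"coding": theta_site}, rho_per_bp=0.0, seed=9)
            cfg_double = LikelihoodConfig(M=150, theta_by_class={"coding": 2 * theta_site}, rho_per_bp=0.0, seed=9)
            shared_rng = np.random.default_rng(9)
            cache = {}
            ll_true = dataset_loglik(loci, CONST, cfg_true, rng=shared_rng, arg_cache=cache)
            ll_double = dataset_loglik(loci, CONST, cfg_double, arg_cache=cache)
            wins += ll_true >= ll_double
        assert wins >= 0.8 * reps


class TestBiasFactor:
    def test_constant_model_unbiased(self, rng):
        c, se = theta_bias_factor(CONST, 5.0, n=10, L=50, reps=1500, rng=rng, rho_per_bp=0.0)
        assert c == pytest.approx(1.0, abs=3 * se + 0.01)

    def test_invariant_to_theta(self, rng):
        model = DemographicModel("two_epoch", T_A=0.2, N_A_over_N0=5.0)
        c1, se1 = theta_bias_factor(model, 2.0, n=10, L=50, reps=1500, rng=rng, rho_per_bp=0.0)
        c2, se2 = theta_bias_factor(model, 8.0, n=10, L=50, reps=1500, rng=rng, rho_per_bp=0.0)
        assert c1 / c2 == pytest.approx(1.0, abs=3 * math.hypot(se1 / c2, se2 * c1 / c2**2) + 0.02)

    def test_two_runs_agree(self):
        model = DemographicModel("two_epoch", T_A=0.3, N_A_over_N0=0.2)
        c1, se1 = theta_bias_factor(model, 4.0, 8, 50, 1500, np.random.default_rng(1), 0.0)
        c2, se2 = theta_bias_factor(model, 4.0, 8, 50, 1500, np.random.default_rng(2), 0.0)
        assert abs(c1 - c2) < 3 * math.hypot(se1, se2) + 0.01


class TestClassThetaEstimates:
    def test_zero_variation_gives_zero(self, rng):
        from pinepop.popstats import LocusSummary
        from pinepop.sfs_likelihood import class_theta_estimates

        def ls(cls, i):
            return LocusSummary(
                locus_id=f"{cls}{i}", n=8, L=100, S=0, theta_w_locus=0.0,
                theta_w_site=0.0, pi=0.0, tajimas_d=None, fu_li_d=None,
                fu_li_variant="D*", diversity_class=cls,
            )

        loci = [ls("coding", 0), ls("coding", 1), ls("promoter", 0)]
        cfg = LikelihoodConfig(M=10, theta_by_class={}, rho_per_bp=0.0, seed=1)
        est = class_theta_estimates(loci, CONST, cfg, rng=rng, bias_reps=1000)
        assert est == {"coding": 0.0, "promoter": 0.0}

    def test_missing_class_raises(self, rng):
        from pinepop.popstats import LocusSummary
        from pinepop.sfs_likelihood import class_theta_estimates

        only_coding = [
            LocusSummary("a", 8, 100, 2, 1.0, 0.01, 1.0, None, None, "D*", "coding"),
            LocusSummary("b", 8, 100, 2, 1.0, 0.01, 1.0, None, None, "D*", "coding"),
        ]
        cfg = LikelihoodConfig(M=10, theta_by_class={}, rho_per_bp=0.0, seed=1)
        with pytest.raises(ValueError, match="promoter"):
            class_theta_estimates(only_coding, CONST, cfg, rng=rng, bias_reps=1000)
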