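import math

import numpy as np
import pytest

from pinepop.mkprf import (
    MKTable,
    PRFConfig,
    build_mk_table,
    fit_mkprf,
    gelman_rubin,
    mk_test,
    prf_expected_counts,
    prf_fixation_factor,
    prf_polymorphism_factor,
)
from pinepop.popstats import harmonic
from pinepop.synthetic_data import SyntheticConfig, generate_prf_tables

QUICK = dict(chains=3, burn_in=300, thin=2, samples_per_chain=300)


class TestPRFFactors:
    @pytest.mark.parametrize(
        "gamma,expected",
        [(0.0, 1.0), (1.0, 2.0 / (1 - math.exp(-2))), (-1.0, -2.0 / (1 - math.exp(2)))],
    )
    def test_fixation_factor_values(self, gamma, expected):
        assert prf_fixation_factor(gamma) == pytest.approx(expected, rel=1e-10)

    def test_fixation_factor_strictly_increasing_and_continuous_at_zero(self):
        gs = np.linspace(-8, 8, 81)
        vals = [prf_fixation_factor(g) for g in gs]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert prf_fixation_factor(1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_polymorphism_factor_neutral_limit_is_harmonic(self):
        assert prf_polymorphism_factor(0.0, 5) == pytest.approx(harmonic(4), abs=1e-10)
        assert prf_polymorphism_factor(0.0, 2) == pytest.approx(1.0, abs=1e-10)
        assert prf_polymorphism_factor(1e-7, 12) == pytest.approx(harmonic(11), abs=1e-6)

    def test_polymorphism_factor_decreasing_under_negative_selection(self):
        vals = [prf_polymorphism_factor(g, 10) for g in (0.0, -2.0, -5.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_expected_counts_layout(self):
        eps, epr, eds, edr = prf_expected_counts(2.0, 3.0, 0.0, 4.0, 6)
        assert eps == pytest.approx(2.0 * harmonic(5))
        assert epr == pytest.approx(3.0 * harmonic(5), rel=1e-8)
        assert eds == pytest.approx(8.0)
        assert edr == pytest.approx(12.0, rel=1e-8)


class TestMKTest:
    def test_balanced_table_is_null(self):
        odds, g, p = mk_test(MKTable("x", "g", 5, 5, 5, 5))
        assert odds == pytest.approx(1.0)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_g(self):
        t = MKTable("x", "g", 10, 2, 5, 15)
        obs = np.array([[10, 2], [5, 15]], dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        brute = 2 * sum(
            o * math.log(o / e) for o, e in zip(obs.ravel(), expected.ravel()) if o > 0
        )
        _, g, p = mk_test(t)
        assert g == pytest.approx(brute, rel=1e-12)
        assert 0 < p < 0.05

    def test_empty_polymorphism_margin_undefined(self):
        odds, g, p = mk_test(MKTable("x", "g", 0, 0, 5, 5))
        assert g is None and p is None

    def test_zero_cells_get_continuity_corrected_odds(self):
        odds, _, _ = mk_test(MKTable("x", "g", 3, 0, 4, 6))
        assert odds == pytest.approx((6.5 / 4.5) / (0.5 / 3.5))


class TestBuildMKTable:
    def _sites(self):
        from collections import Counter

        from pinepop.locus_io import Site, SiteTable

        def site(col, cls, c_t, c_y):
            return Site(col, {"t": Counter(c_t), "y": Counter(c_y)}, True, cls)

        sites = [
            site(0, "silent", {"A": 3, "G": 1}, {"A": 1}),  # silent polymorphism
            site(1, "silent", {"A": 4}, {"G": 1}),  # silent divergence
            site(2, "replacement", {"C": 2, "T": 2}, {"C": 1}),  # repl. polymorphism
            site(3, "replacement", {"C": 4}, {"T": 1}),  # repl. divergence
            site(4, "replacement", {"C": 1, "T": 3}, {"G": 1}),  # poly AND divergent
            site(5, "noncoding", {"A": 2, "T": 2}, {"A": 1}),  # ignored
        ]
        return SiteTable("toy", sites, {"t": 4, "y": 1})

    def test_partition_and_poly_over_divergence_rule(self):
        t = build_mk_table(self._sites(), "t", outgroup="y", group="g")
        assert (t.Ps, t.Pr, t.Ds, t.Dr) == (1, 2, 1, 1)

    def test_supplied_divergence_counts_override(self):
        t = build_mk_table(self._sites(), "t", divergence=(3, 4), group="g")
        assert (t.Ds, t.Dr) == (3, 4)
        assert (t.Ps, t.Pr) == (1, 2)

    def test_requires_some_divergence_source(self):
        with pytest.raises(ValueError):
            build_mk_table(self._sites(), "t")


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        x = np.linspace(0, 1, 50)
        assert gelman_rubin(np.stack([x, x, x])) == pytest.approx(1.0, abs=0.02)

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        b = rng.normal(100, 1, 200)
        assert gelman_rubin(np.stack([a, b])) > 10

    def test_matches_independent_reference(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(4, 500))
        m, n = chains.shape
        means = chains.mean(axis=1)
        W = sum(np.var(c, ddof=1) for c in chains) / m
        B = n * np.var(means, ddof=1)
        ref = math.sqrt(((n - 1) / n * W + B / n) / W)
        assert gelman_rubin(chains) == pytest.approx(ref, abs=1e-8)

    def test_needs_two_chains(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))


class TestFitMKPRF:
    def test_positive_selection_recovered(self, rng):
        cfg = SyntheticConfig(seed=21, prf_groups={"pos": (15, 2.0, 0.5)})
        tables, _ = generate_prf_tables(cfg, rng)
        res = fit_mkprf(tables, PRFConfig(seed=2, **QUICK))
        assert res.hyper_summary["pos"]["frac_positive"] > 0.95

    def test_conserved_pattern_gives_negative_group(self):
        # zero replacement divergence with plenty of silent divergence
        tables = [
            MKTable(f"c{i}", "conserved", Ps=6, Pr=4, Ds=12, Dr=0, n=32) for i in range(8)
        ]
        res = fit_mkprf(tables, PRFConfig(seed=3, **QUICK))
        assert res.hyper_summary["conserved"]["frac_positive"] < 0.05

    def test_locus_order_invariance(self, rng):
        cfg = SyntheticConfig(seed=9, prf_groups={"g": (10, 0.5, 0.5)})
        tables, _ = generate_prf_tables(cfg, rng)
        res1 = fit_mkprf(tables, PRFConfig(seed=5, **QUICK))
        res2 = fit_mkprf(tables[::-1], PRFConfig(seed=5, **QUICK))
        m1 = {l.locus_id: l.mean for l in res1.loci}
        m2 = {l.locus_id: l.mean for l in res2.loci}
        for k in m1:
            assert m1[k] == pytest.approx(m2[k], abs=0.35)

    def test_group_needs_two_loci(self):
        with pytest.raises(ValueError, match="2 loci"):
            fit_mkprf([MKTable("solo", "g", 1, 1, 1, 1)], PRFConfig(seed=1, **QUICK))

    def test_opposite_groups_separate(self, rng):
        cfg = SyntheticConfig(
            seed=30, prf_groups={"neg": (12, -2.0, 0.5), "pos": (12, 2.0, 0.5)}
        )
        tables, _ = generate_prf_tables(cfg, rng)
        res = fit_mkprf(tables, PRFConfig(seed=8, **QUICK))
        assert res.hyper_summary["neg"]["ci_high"] < res.hyper_summary["pos"]["ci_low"]
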