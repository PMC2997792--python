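import numpy as np
import pytest

from pinepop.coalescent_engine import IMParams, simulate_im_locus
from pinepop.datasets import pine_im_counts_objects, pine_im_significant_rows
from pinepop.isolation_model import (
    expected_category_rates,
    expected_counts,
    fit_wh,
    g_test_counts,
    im_gof_table,
    lineage_occupancy,
    wh_fit_quantile,
)
from pinepop.locus_io import IMCounts


class TestLineageOccupancy:
    def test_distribution_normalised_and_occupancy_sums_to_t(self):
        P, O = lineage_occupancy(10, 0.7)
        assert P.sum() == pytest.approx(1.0, abs=1e-10)
        assert O.sum() == pytest.approx(0.7, abs=1e-10)

    def test_pair_coalescence_closed_form(self):
        # two lineages: P(still 2 at t) = exp(-t)
        P, O = lineage_occupancy(2, 1.3)
        assert P[1] == pytest.approx(np.exp(-1.3), rel=1e-10)
        assert O[1] == pytest.approx(1 - np.exp(-1.3), rel=1e-10)


class TestExpectedRates:
    def test_matches_simulation(self, rng):
        params = IMParams(theta1=2.0, theta2_ratio=1.5, thetaA_ratio=3.0, tau=0.5)
        exact = expected_category_rates(params, 8, 2)
        reps = 6000
        sims = np.array(
            [simulate_im_locus(8, 2, params, 2.0, rng).as_array() for _ in range(reps)],
            dtype=float,
        )
        se = sims.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(sims.mean(axis=0) - exact) < 3.5 * se + 0.01)

    def test_single_outgroup_gamete_has_no_species2_classes(self):
        params = IMParams(theta1=2.0, tau=0.5)
        rates = expected_category_rates(params, 8, 1)
        assert rates[1] == 0.0 and rates[2] == 0.0
        assert rates[0] > 0 and rates[3] > 0

    def test_rates_proportional_to_theta1(self):
        p1 = IMParams(theta1=1.0, thetaA_ratio=4.0, tau=0.7)
        p2 = IMParams(theta1=3.0, thetaA_ratio=4.0, tau=0.7)
        r1 = expected_category_rates(p1, 6, 2)
        r2 = expected_category_rates(p2, 6, 2)
        assert np.allclose(r2, 3 * r1, rtol=1e-9)


class TestFitWH:
    def test_symmetric_data_gives_equal_sizes(self):
        counts = [IMCounts(f"l{i}", 8, 8, 1, 4) for i in range(10)]
        fit = fit_wh(counts, n1=6, n2=6)
        assert fit.params.theta2_ratio == pytest.approx(1.0, abs=0.02)
        assert fit.max_abs_log_residual < 1e-6

    def test_pine_counts_reproduce_published_estimates(self):
        counts, n1, n2 = pine_im_counts_objects()
        fit = fit_wh(counts, n1, n2)
        assert fit.params.tau == pytest.approx(0.86, rel=0.15)
        assert fit.params.thetaA_ratio == pytest.approx(6.72, rel=0.15)
        assert fit.params.theta2_ratio == pytest.approx(1.03, rel=0.15)

    def test_recovery_from_simulated_data(self):
        true = IMParams(theta1=5.0, theta2_ratio=1.0, thetaA_ratio=1.0, tau=1.0)
        hits = 0
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            counts = [
                simulate_im_locus(12, 6, true, 5.0, rng, locus_id=f"l{i}")
                for i in range(50)
            ]
            fit = fit_wh(counts, n1=12, n2=6)
            hits += abs(fit.params.tau - true.tau) / true.tau <= 0.25
        assert hits >= 4

    def test_degenerate_totals_rejected(self):
        counts = [IMCounts(f"l{i}", 0, 0, 0, 0) for i in range(6)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_wh(counts, n1=8, n2=2)

    def test_needs_enough_loci(self):
        with pytest.raises(ValueError, match="5 loci"):
            fit_wh([IMCounts("a", 1, 1, 1, 1)], n1=8, n2=2)


class TestGTest:
    def test_printed_rows_reproduced(self):
        for row in pine_im_significant_rows().itertuples():
            res = g_test_counts(row.observed, row.expected, row.locus, n_loci=27)
            assert res.g == pytest.approx(row.G, rel=0.005), row.locus
        assert res.df == 4

    def test_perfect_fit(self):
        res = g_test_counts([3, 2, 1, 4], [3, 2, 1, 4])
        assert res.g == 0.0 and res.p == 1.0

    def test_zero_observed_cells_contribute_nothing(self):
        res = g_test_counts([0, 0, 0, 4], [1, 1, 1, 4])
        assert res.g == pytest.approx(0.0, abs=1e-12)

    def test_category_order_invariance(self):
        a = g_test_counts([1, 2, 0, 13], [7.71, 2.25, 0.25, 5.65])
        b = g_test_counts([13, 0, 2, 1], [5.65, 0.25, 2.25, 7.71])
        assert a.g == pytest.approx(b.g, rel=1e-12)

    def test_observed_in_zero_expectation_cell_is_infinite(self):
        res = g_test_counts([1, 0, 0, 0], [0.0, 1, 1, 1])
        assert np.isinf(res.g) and res.p == 0.0

    def test_bonferroni_at_27_loci(self):
        res = g_test_counts([1, 2, 0, 13], [7.71, 2.25, 0.25, 5.65], n_loci=27)
        assert res.p_bonferroni == pytest.approx(min(1.0, res.p * 27))
        assert res.significant  # axr stays significant after correction


class TestExpectedCountsAndGof:
    def test_expected_total_matches_observed_total(self):
        params = IMParams(theta1=1.6, thetaA_ratio=7.0, tau=0.9)
        exp = expected_counts(params, total=24, n1=32, n2=2)
        assert exp.sum() == pytest.approx(24.0, rel=1e-9)

    def test_gof_table_calibrated_rejection_rate(self, rng):
        """Per-locus G-tests under study-like conditions: multi-hundred-bp
        recombining loci (rho = 0.023/bp), Bonferroni decision rule as used
        on the real data.

        The df = 4 chi-square tail on four cells is conservative for
        independent counts, but the four categories share one genealogical
        history per locus, which inflates raw rejections; intra-locus
        recombination shrinks that correlation and the Bonferroni rule
        (the study's significance criterion) stays conservative."""
        params = IMParams(theta1=1.6, theta2_ratio=1.0, thetaA_ratio=7.0, tau=0.9)
        counts = [
            simulate_im_locus(
                16, 2, params, 1.6, rng, locus_id=f"l{i}", rho_per_bp=0.023, L=700
            )
            for i in range(120)
        ]
        counts = [c for c in counts if c.total > 0]
        fit = fit_wh(counts, n1=16, n2=2)
        results = im_gof_table(counts, fit, 16, 2)
        assert np.mean([r.significant for r in results]) <= 0.05
        assert np.mean([r.p < 0.05 for r in results]) <= 0.30

    def test_doubling_locus_total_doubles_expectations(self):
        params = IMParams(theta1=1.6, thetaA_ratio=7.0, tau=0.9)
        e1 = expected_counts(params, total=10, n1=32, n2=2)
        e2 = expected_counts(params, total=20, n1=32, n2=2)
        assert np.allclose(e2, 2 * e1)


class TestFitQuantile:
    def test_reproducible_under_seed(self):
        counts, n1, n2 = pine_im_counts_objects()
        fit = fit_wh(counts, n1, n2)
        q1 = wh_fit_quantile(fit, counts, n1, n2, reps=60, rng=np.random.default_rng(9))
        q2 = wh_fit_quantile(fit, counts, n1, n2, reps=60, rng=np.random.default_rng(9))
        assert q1 == q2

    def test_gross_misfit_detected(self, rng):
        """A locus carrying 100 shared polymorphisms is flagged against a
        fitted isolation model (params fitted to clean data; refitting to
        data containing the aberration would let the four moment equations
        absorb it into an extreme ancestral size)."""
        params = IMParams(theta1=3.0, thetaA_ratio=2.0, tau=1.0)
        clean = [
            simulate_im_locus(10, 2, params, 3.0, rng, locus_id=f"l{i}")
            for i in range(20)
        ]
        fit = fit_wh(clean, n1=10, n2=2)
        corrupted = list(clean)
        corrupted[0] = IMCounts(
            "corrupt", clean[0].s_x1, clean[0].s_x2, 100, clean[0].s_fixed
        )
        q = wh_fit_quantile(fit, corrupted, 10, 2, reps=150, rng=rng)
        assert q < 0.05
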