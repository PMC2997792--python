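"""Two-species isolation-model fitting and per-locus goodness of fit.

The isolation (speciation) model: species 1 and 2 split from an ancestral
population at divergence time ``tau`` with no subsequent gene flow.
Parameters are the per-locus scaled mutation rate ``theta1 = 4 N_1 mu`` of
species 1 (the reference), the size ratios ``theta2/theta1`` and
``thetaA/theta1``, and ``tau`` in coalescent units of ``4 N_1`` generations.
Data are per-locus counts of the four polymorphism categories: exclusive to
species 1 (``S_x1``), exclusive to species 2 (``S_x2``), shared (``S_s``)
and fixed differences (``S_f``).

Fitting is by the method of moments: the four observed category totals
(summed over loci) are equated with their exact expectations under the
model.  Expectations are computed from coalescent theory without
approximation — the within-species phase through the lineage-count
distribution of the Kingman death chain (matrix exponential, with exact
time-integrated occupancies), the ancestral phase through exchangeable
subset-subtending branch lengths for the surviving lineages.  Per-locus
expected quadruplets multiply the model's category proportions by each
locus's observed total (loci differ in mutation rate and length; the
observed total is the natural relative-rate estimate), and deviations are
assessed with a G-test whose p-value uses df = 4, with Bonferroni
correction over loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

from .coalescent_engine import IMParams, simulate_im_locus
from .locus_io import IMCounts
from .stats_util import bonferroni, chisq_sf, g_statistic

__all__ = [
    "WHFit",
    "TestResult",
    "lineage_occupancy",
    "expected_category_rates",
    "fit_wh",
    "expected_counts",
    "g_test_counts",
    "im_gof_table",
    "wh_fit_quantile",
]


def lineage_occupancy(n: int, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Lineage-count distribution and time-integrated occupancies.

    For the Kingman death chain started from ``n`` lineages (pair
    coalescence rate 1 per unit time), returns ``(P, O)`` where ``P[k-1] =
    P(K(t) = k)`` and ``O[k-1] = int_0^t P(K(s) = k) ds``.  Computed with a
    block matrix exponential (the integral of the semigroup appears in the
    upper-right block), which is numerically stable for n up to the sample
    sizes used here.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if t <= 0:
        P = np.zeros(n)
        P[n - 1] = 1.0
        return P, np.zeros(n)
    Q = np.zeros((n, n))
    for k in range(2, n + 1):
        rate = k * (k - 1) / 2.0
        Q[k - 1, k - 1] = -rate
        Q[k - 1, k - 2] = rate
    A = np.zeros((2 * n, 2 * n))
    A[:n, :n] = Q
    A[:n, n:] = np.eye(n)
    E = expm(A * t)
    p0 = np.zeros(n)
    p0[n - 1] = 1.0
    return p0 @ E[:n, :n], p0 @ E[:n, n:]


def _ancestral_category_lengths(P1: np.ndarray, P2: np.ndarray, rA: float,
                                n1: int, n2: int) -> np.ndarray:
    """Expected scaled branch lengths (x1, x2, shared, fixed) contributed by
    the ancestral population, averaged over the numbers of surviving
    lineages of each species.

    With ``m = k1 + k2`` exchangeable lineages in a population of relative
    size ``rA``, the total expected branch length subtending exactly ``i``
    of them is ``2 rA / i`` (in 2 N_1-generation units), shared equally by
    the ``C(m, i)`` subsets; a subset containing ``j1`` species-1 and ``j2``
    species-2 lineages is polymorphic in species ``s`` iff ``0 < js < ks``.
    """
    out = np.zeros(4)
    for k1 in range(1, n1 + 1):
        p1 = P1[k1 - 1]
        if p1 < 1e-14:
            continue
        for k2 in range(1, n2 + 1):
            p2 = P2[k2 - 1]
            if p2 < 1e-14:
                continue
            m = k1 + k2
            w = p1 * p2
            for j1 in range(0, k1 + 1):
                for j2 in range(0, k2 + 1):
                    if (j1 == 0 and j2 == 0) or (j1 == k1 and j2 == k2):
                        continue
                    i = j1 + j2
                    length = (2.0 * rA / i) * comb(k1, j1) * comb(k2, j2) / comb(m, i)
                    poly1, poly2 = 0 < j1 < k1, 0 < j2 < k2
                    if poly1 and poly2:
                        out[2] += w * length
                    elif poly1:
                        out[0] += w * length
                    elif poly2:
                        out[1] += w * length
                    else:
                        out[3] += w * length
    return out


def expected_category_rates(params: IMParams, n1: int, n2: int) -> np.ndarray:
    """Exact per-locus expectations (E[S_x1], E[S_x2], E[S_s], E[S_f]).

    All four are proportional to ``theta1``; time is converted internally to
    2 N_1-generation units (the split is at ``2 * tau``).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least one sample per species")
    T = 2.0 * params.tau
    half = params.theta1 / 2.0
    r2, rA = params.theta2_ratio, params.thetaA_ratio
    P1, O1 = lineage_occupancy(n1, T)
    P2, O2chain = lineage_occupancy(n2, T / r2)
    O2 = O2chain * r2  # chain-time occupancy back to real time units
    k1 = np.arange(1, n1 + 1)
    k2 = np.arange(1, n2 + 1)
    e_x1 = half * float((k1[1:] * O1[1:]).sum())  # branches while >= 2 lineages
    e_x2 = half * float((k2[1:] * O2[1:]).sum()) if n2 >= 2 else 0.0
    e_fixed = half * (float(O1[0]) + float(O2[0]))  # fully-coalesced lineage time
    anc = half * _ancestral_category_lengths(P1, P2, rA, n1, n2)
    return np.array([e_x1, e_x2, 0.0, 0.0]) + np.array([0.0, 0.0, 0.0, e_fixed]) + anc


@dataclass
class WHFit:
    """Fitted isolation-model parameters and fit metadata."""

    params: IMParams
    n_loci: int
    observed_totals: np.ndarray
    expected_totals: np.ndarray
    max_abs_log_residual: float

    @property
    def tau(self) -> float:
        return self.params.tau

    @property
    def thetaA_ratio(self) -> float:
        return self.params.thetaA_ratio

    @property
    def theta2_ratio(self) -> float:
        return self.params.theta2_ratio


def fit_wh(
    counts: Sequence[IMCounts],
    n1: Sequence[int] | int,
    n2: Sequence[int] | int,
    x0: tuple[float, float, float, float] = (3.0, 1.0, 4.0, 0.8),
) -> WHFit:
    """Method-of-moments fit of the isolation model.

    Equates the four observed category totals with their exact expectations
    summed over loci (log-scale least squares; the solution drives the
    residuals to numerical zero when the totals are interior).  ``n1`` and
    ``n2`` may be scalars or per-locus sequences; loci with a single
    species-2 gamete contribute no expected shared or species-2-exclusive
    polymorphism, which matters whenever outgroup sampling is uneven.
    """
    if len(counts) < 5:
        raise ValueError("need >= 5 loci for a stable moment fit")
    n_loci = len(counts)
    n1v = np.full(n_loci, n1) if np.isscalar(n1) else np.asarray(n1)
    n2v = np.full(n_loci, n2) if np.isscalar(n2) else np.asarray(n2)
    if len(n1v) != n_loci or len(n2v) != n_loci:
        raise ValueError("per-locus sample sizes must match the number of loci")
    totals = np.sum([c.as_array() for c in counts], axis=0).astype(float)
    if np.count_nonzero(totals) < 2:
        raise ValueError("degenerate totals: not enough variation to fit")
    # categories that cannot occur under the design (e.g. no locus with
    # n2 >= 2 can show shared polymorphism) must be absent from the data too
    fit_mask = np.ones(4, dtype=bool)
    if not np.any(n2v >= 2):
        if totals[1] > 0 or totals[2] > 0:
            raise ValueError("species-2 polymorphism observed but all n2 < 2")
        fit_mask[[1, 2]] = False
    pair_counts: dict[tuple[int, int], int] = {}
    for a, b in zip(n1v, n2v):
        pair_counts[(int(a), int(b))] = pair_counts.get((int(a), int(b)), 0) + 1

    def expected_totals(params: IMParams) -> np.ndarray:
        E = np.zeros(4)
        for (a, b), k in pair_counts.items():
            E += k * expected_category_rates(params, a, b)
        return E

    # log residuals for observed categories; zero-total categories enter on
    # the linear scale (driving their expectation toward 0) so sparse data
    # (e.g. no shared polymorphisms observed) still fit
    def resid(x):
        th1, r2, rA, tau = np.exp(x)
        E = expected_totals(IMParams(th1, r2, rA, tau))
        out = np.zeros(fit_mask.sum())
        for i, c in enumerate(np.flatnonzero(fit_mask)):
            if totals[c] > 0:
                out[i] = np.log(max(E[c], 1e-300)) - np.log(totals[c])
            else:
                out[i] = E[c]
        return out

    sol = least_squares(
        resid, x0=np.log(x0), bounds=(-14.0, 14.0), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    th1, r2, rA, tau = np.exp(sol.x)
    params = IMParams(float(th1), float(r2), float(rA), float(tau))
    return WHFit(
        params=params,
        n_loci=n_loci,
        observed_totals=totals,
        expected_totals=expected_totals(params),
        max_abs_log_residual=float(np.abs(sol.fun).max()),
    )


def expected_counts(
    params: IMParams,
    total: float,
    n1: int,
    n2: int,
) -> np.ndarray:
    """Expected per-locus quadruplet given the locus's observed total.

    The model's category proportions for this locus's sample sizes are
    scaled by the observed total count — the locus total acts as the
    relative mutation-rate estimate, so expected and observed totals agree
    by construction and the G-test probes the partition, not the rate.
    """
    rates = expected_category_rates(params, n1, n2)
    return total * rates / rates.sum()


def simulated_expected_counts(
    params: IMParams,
    theta_locus: float,
    n1: int,
    n2: int,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo per-category means over ``reps`` simulated loci (the
    simulation route to the same expectations; used for validation and for
    variance estimates)."""
    if reps < 1000:
        raise ValueError("need reps >= 1000")
    p = IMParams(theta_locus, params.theta2_ratio, params.thetaA_ratio, params.tau)
    sims = np.array(
        [simulate_im_locus(n1, n2, p, theta_locus, rng).as_array() for _ in range(reps)],
        dtype=float,
    )
    return sims.mean(axis=0)


@dataclass
class TestResult:
    """Per-locus isolation-model goodness-of-fit."""

    locus_id: str
    observed: np.ndarray
    expected: np.ndarray
    g: float
    df: int
    p: float
    p_bonferroni: float
    significant: bool  # after Bonferroni at alpha = 0.05


def g_test_counts(
    observed: Sequence[float],
    expected: Sequence[float],
    locus_id: str = "",
    n_loci: int = 1,
    alpha: float = 0.05,
    df: int = 4,
) -> TestResult:
    """G-test of one observed quadruplet against its expectations.

    ``G = 2 sum_c O_c ln(O_c / E_c)`` with zero-observed cells contributing
    0; an observed count in a zero-expectation cell gives infinite G.  The
    p-value uses df = 4 (as in the source analyses, although 4 cells would
    conventionally give df = 3) and is Bonferroni-multiplied by ``n_loci``.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != (4,) or exp.shape != (4,):
        raise ValueError("observed and expected must be quadruplets")
    g = g_statistic(obs, exp)
    p = chisq_sf(g, df) if np.isfinite(g) else 0.0
    p_bonf = bonferroni(p, n_loci)
    return TestResult(
        locus_id=locus_id,
        observed=obs,
        expected=exp,
        g=g,
        df=df,
        p=p,
        p_bonferroni=p_bonf,
        significant=p_bonf < alpha,
    )


def im_gof_table(
    counts: Sequence[IMCounts],
    fit: WHFit,
    n1: Sequence[int] | int,
    n2: Sequence[int] | int,
) -> list[TestResult]:
    """Per-locus G-tests of all loci against the fitted model."""
    n_loci = len(counts)
    n1v = np.full(n_loci, n1) if np.isscalar(n1) else np.asarray(n1)
    n2v = np.full(n_loci, n2) if np.isscalar(n2) else np.asarray(n2)
    out = []
    for c, a, b in zip(counts, n1v, n2v):
        exp = expected_counts(fit.params, c.total, int(a), int(b))
        out.append(g_test_counts(c.as_array(), exp, c.locus_id, n_loci))
    return out


def wh_fit_quantile(
    fit: WHFit,
    counts: Sequence[IMCounts],
    n1: Sequence[int] | int,
    n2: Sequence[int] | int,
    reps: int,
    rng: np.random.Generator,
    locus_weights: Sequence[float] | None = None,
) -> float:
    """Parametric-bootstrap goodness-of-fit quantile for the global fit.

    The dispersion statistic has two Pearson-style parts: per locus, the
    category partition against the fitted category proportions conditioned
    on that locus's own total (``sum_lc (D_lc - T_l(D) p_lc)^2 / E_lc``),
    and globally, the four category totals against their unconditioned
    expectations under the fitted parameters.  The per-locus part flags
    variation concentrated in the wrong category at individual loci; the
    global part flags parameter vectors that cannot reproduce the overall
    totals (e.g. a fit pinned at its bounds by inconsistent data).

    Bootstrap datasets are simulated under the fitted model with per-locus
    rates ``theta1 * w_l``; by default ``w_l`` is the locus's observed total
    over the mean total (the relative-rate estimate), or pass
    ``locus_weights`` to fix the rates externally.  The returned value is
    the proportion of simulated statistics exceeding the observed one —
    small values indicate a poor fit.  No refitting is performed inside the
    bootstrap (plug-in usage, as in the original multi-locus test).
    """
    n_loci = len(counts)
    n1v = np.full(n_loci, n1) if np.isscalar(n1) else np.asarray(n1)
    n2v = np.full(n_loci, n2) if np.isscalar(n2) else np.asarray(n2)
    mean_total = np.mean([c.total for c in counts])
    if locus_weights is None:
        locus_weights = [
            c.total / mean_total if mean_total > 0 else 1.0 for c in counts
        ]
    props = np.empty((n_loci, 4))
    e_tot = np.zeros(4)
    for l, (a, b) in enumerate(zip(n1v, n2v)):
        rates = expected_category_rates(fit.params, int(a), int(b))
        props[l] = rates / rates.sum()
        e_tot += locus_weights[l] * rates
    sims = np.empty((reps, n_loci, 4))
    for r in range(reps):
        for l, (a, b) in enumerate(zip(n1v, n2v)):
            theta_l = max(fit.params.theta1 * locus_weights[l], 1e-6)
            p = IMParams(
                theta_l, fit.params.theta2_ratio, fit.params.thetaA_ratio, fit.params.tau
            )
            sims[r, l] = simulate_im_locus(int(a), int(b), p, theta_l, rng).as_array()

    def stat(data: np.ndarray) -> np.ndarray:
        totals = data.sum(axis=-1, keepdims=True)
        E = totals * props
        local = ((data - E) ** 2 / np.maximum(E, 0.5)).sum(axis=(-2, -1))
        tot_dev = data.sum(axis=-2) - e_tot
        global_part = (tot_dev**2 / np.maximum(e_tot, 0.5)).sum(axis=-1)
        return local + global_part

    obs = np.array([c.as_array() for c in counts], dtype=float)
    stat_obs = float(stat(obs))
    stat_sim = stat(sims)
    return float((stat_sim > stat_obs).mean())
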