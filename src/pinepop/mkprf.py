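"""McDonald-Kreitman tables, the classic MK test, and a hierarchical
Bayesian Poisson-random-field (PRF) model of selection on replacement sites.

The MK contrast compares silent and replacement site counts partitioned into
within-species polymorphism (Ps, Pr) and between-species divergence (Ds,
Dr).  Under the PRF model with scaled selection coefficient ``gamma = 2 N s``
acting on replacement mutations, expected counts are

    E[Ps] = theta_s * a_{n-1}            E[Ds] = theta_s * tau_div
    E[Pr] = theta_r * P(gamma, n)        E[Dr] = theta_r * tau_div * F(gamma)

where ``F(gamma) = 2 gamma / (1 - exp(-2 gamma))`` is the relative fixation
rate, ``P(gamma, n)`` the sojourn-density sampling integral (equal to the
harmonic number ``a_{n-1}`` at ``gamma = 0``), ``theta_s``/``theta_r`` the
per-locus silent/replacement mutation parameters and ``tau_div`` a
species-divergence parameter shared across loci.

The hierarchy places ``gamma_l ~ Normal(mu_g, sigma_g^2)`` within each locus
group, with diffuse priors on the group-level mean and variance; mutation
parameters and ``tau_div`` get diffuse Gamma priors (conjugate under the
Poisson likelihood).  Inference is Metropolis-within-Gibbs: conjugate Gibbs
draws for the rate parameters and hyper-parameters, a vectorised random-walk
Metropolis step for the ``gamma_l``.  Convergence across independent chains
is monitored with the Gelman-Rubin potential scale reduction factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline

from .popstats import harmonic
from .stats_util import chisq_sf, g_statistic

__all__ = [
    "MKTable",
    "PRFConfig",
    "SelectionPosterior",
    "build_mk_table",
    "mk_test",
    "prf_fixation_factor",
    "prf_polymorphism_factor",
    "prf_expected_counts",
    "fit_mkprf",
    "gelman_rubin",
]


@dataclass(frozen=True)
class MKTable:
    """Silent/replacement polymorphism and divergence counts for one locus."""

    locus_id: str
    group: str
    Ps: int
    Pr: int
    Ds: int
    Dr: int
    n: int = 32  # sample size used for polymorphism discovery

    def __post_init__(self) -> None:
        if min(self.Ps, self.Pr, self.Ds, self.Dr) < 0:
            raise ValueError("MK counts must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2")


def build_mk_table(
    sites,
    focal: str,
    outgroup: str | None = None,
    divergence: tuple[int, int] | None = None,
    group: str = "",
    n: int | None = None,
) -> MKTable:
    """Partition coding sites of a :class:`~pinepop.locus_io.SiteTable` into
    the 2x2 MK layout.

    Divergence counts (Ds, Dr) may be supplied directly (e.g. from EST
    orthologs) or counted as fixed differences against ``outgroup`` sequences
    present in the table.  A site that is both polymorphic in the focal
    species and divergent counts once, as polymorphism (standard MK
    convention).
    """
    if outgroup is None and divergence is None:
        raise ValueError("provide either an outgroup label or divergence counts")
    Ps = Pr = Ds = Dr = 0
    for site in sites.biallelic_sites():
        if site.site_class not in ("silent", "replacement"):
            continue
        c_f = site.counts.get(focal)
        if not c_f:
            continue
        is_poly = len(c_f) > 1
        if is_poly:
            if site.site_class == "silent":
                Ps += 1
            else:
                Pr += 1
        elif outgroup is not None:
            c_o = site.counts.get(outgroup)
            if c_o and len(c_o) == 1 and set(c_o) != set(c_f):
                if site.site_class == "silent":
                    Ds += 1
                else:
                    Dr += 1
    if divergence is not None:
        Ds, Dr = divergence
    return MKTable(
        sites.locus_id, group, Ps, Pr, Ds, Dr, n=n or sites.sample_sizes.get(focal, 32)
    )


def mk_test(table: MKTable) -> tuple[float | None, float | None, float | None]:
    """Classic MK 2x2 independence G-test.

    Returns (odds ratio, G, p) with ``df = 1``; the odds ratio ``(Dr/Ds) /
    (Pr/Ps)`` uses a 0.5 continuity correction when any cell is zero.  If a
    margin (all polymorphisms or all substitutions, or a site-type margin) is
    empty the test is undefined and ``(odds, None, None)`` or ``(None, None,
    None)`` is returned.
    """
    obs = np.array([[table.Ps, table.Pr], [table.Ds, table.Dr]], dtype=float)
    cells = obs.copy()
    if (cells == 0).any():
        cells += 0.5
    odds = (cells[1, 1] / cells[1, 0]) / (cells[0, 1] / cells[0, 0])
    if obs.sum(axis=1).min() == 0 or obs.sum(axis=0).min() == 0:
        return (float(odds) if obs.sum() > 0 else None), None, None
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    G = g_statistic(obs.ravel(), expected.ravel())
    return float(odds), G, chisq_sf(G, 1)


# --- PRF factors -----------------------------------------------------------


def prf_fixation_factor(gamma: float) -> float:
    """Relative fixation rate ``2 gamma / (1 - exp(-2 gamma))``; 1 at 0."""
    return math.exp(log_fixation_factor(gamma))


def log_fixation_factor(gamma: float | np.ndarray):
    """Numerically stable ``log`` of the fixation factor."""
    gamma = np.asarray(gamma, dtype=float)
    out = np.empty_like(gamma)
    small = np.abs(gamma) < 1e-8
    out[small] = gamma[small]  # log(2g/(1-e^{-2g})) ~ g for small g
    pos = (gamma >= 1e-8)
    out[pos] = np.log(2.0 * gamma[pos]) - np.log1p(-np.exp(-2.0 * gamma[pos]))
    neg = gamma <= -1e-8
    a = -gamma[neg]
    out[neg] = np.log(2.0 * a) - _log_expm1(2.0 * a)
    return out if out.ndim else float(out)


def _log_expm1(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    out = np.where(z > 30.0, z, np.log(np.expm1(np.minimum(z, 30.0))))
    return out


def _sojourn_ratio(gamma: float, x: np.ndarray) -> np.ndarray:
    """(1 - exp(-2 gamma (1-x))) / (1 - exp(-2 gamma)), -> (1-x) as gamma->0."""
    if abs(gamma) < 1e-8:
        return 1.0 - x
    if gamma > 0:
        return -np.expm1(-2.0 * gamma * (1.0 - x)) / -np.expm1(-2.0 * gamma)
    a = -gamma
    # exp(log expm1(2a(1-x)) - log expm1(2a)), stable for large a
    return np.exp(_log_expm1(2.0 * a * (1.0 - x)) - _log_expm1(np.asarray(2.0 * a)))


def prf_polymorphism_factor(gamma: float, n: int) -> float:
    """Expected relative polymorphism count under selection.

    ``int_0^1 [(1 - e^{-2g(1-x)}) / ((1 - e^{-2g}) x (1-x))] (1 - x^n -
    (1-x)^n) dx``; reduces to the harmonic number ``a_{n-1}`` at ``g = 0``.
    """
    if n < 2:
        raise ValueError("need n >= 2")

    def integrand(x):
        xa = np.asarray(x)
        return _sojourn_ratio(gamma, xa) * (1.0 - xa**n - (1.0 - xa) ** n) / (xa * (1.0 - xa))

    val, err = quad(integrand, 0.0, 1.0, epsrel=1e-10, epsabs=1e-12, limit=200)
    if not np.isfinite(val) or (val > 0 and err / max(val, 1e-300) > 1e-6):
        raise RuntimeError(f"sojourn quadrature failed for gamma={gamma}, n={n}")
    return float(val)


class _LogPolyFactor:
    """Cubic-spline interpolant of ``log P(gamma, n)`` on a gamma grid, per
    sample size (exact quadrature at the nodes)."""

    def __init__(self, lo: float = -30.0, hi: float = 30.0, step: float = 0.25):
        self.grid = np.arange(lo, hi + step / 2, step)
        self._splines: dict[int, CubicSpline] = {}
        self.lo, self.hi = lo, hi

    def spline(self, n: int) -> CubicSpline:
        if n not in self._splines:
            vals = np.log([prf_polymorphism_factor(g, n) for g in self.grid])
            self._splines[n] = CubicSpline(self.grid, vals)
        return self._splines[n]

    def __call__(self, gamma: np.ndarray, n_arr: np.ndarray) -> np.ndarray:
        gamma = np.clip(gamma, self.lo, self.hi)
        out = np.empty_like(gamma, dtype=float)
        for n in np.unique(n_arr):
            sel = n_arr == n
            out[sel] = self.spline(int(n))(gamma[sel])
        return out


def prf_expected_counts(
    theta_s: float, theta_r: float, gamma: float, tau_div: float, n: int
) -> tuple[float, float, float, float]:
    """(E[Ps], E[Pr], E[Ds], E[Dr]) under the PRF model."""
    a = harmonic(n - 1)
    return (
        theta_s * a,
        theta_r * prf_polymorphism_factor(gamma, n),
        theta_s * tau_div,
        theta_r * tau_div * prf_fixation_factor(gamma),
    )


# --- hierarchical model ----------------------------------------------------


@dataclass
class PRFConfig:
    """MCMC settings.  The published protocol ran 10 chains with a 10,000
    iteration burn-in, sampling every 10 iterations for 10,000 samples per
    chain; reduce for quick analyses."""

    chains: int = 10
    burn_in: int = 10_000
    thin: int = 10
    samples_per_chain: int = 10_000
    seed: int = 0
    # diffuse priors
    gamma_prior_sd: float = 10.0  # on the group hyper-mean
    rate_prior_shape: float = 0.01
    rate_prior_rate: float = 0.01
    sigma2_prior_shape: float = 2.0
    sigma2_prior_scale: float = 1.0
    proposal_sd: float = 0.8
    rhat_threshold: float = 1.2

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.thin < 1 or self.burn_in < 0 or self.samples_per_chain < 1:
            raise ValueError("bad MCMC settings")


@dataclass
class SelectionPosterior:
    """Posterior summary of one locus's selection coefficient."""

    locus_id: str
    group: str
    mean: float
    ci_low: float
    ci_high: float
    frac_positive: float
    rhat: float

    @property
    def significant_positive(self) -> bool:
        return self.frac_positive >= 0.95

    @property
    def significant_negative(self) -> bool:
        return self.frac_positive <= 0.05


@dataclass
class MKPRFResult:
    loci: list[SelectionPosterior]
    hyper_mean_samples: dict[str, np.ndarray]  # pooled across chains
    hyper_summary: dict[str, dict[str, float]]
    tau_div_mean: float
    max_rhat: float
    converged: bool
    gamma_samples: dict[str, np.ndarray] = field(default_factory=dict)


def _run_chain(
    tables: list[MKTable],
    groups: list[str],
    cfg: PRFConfig,
    logP: _LogPolyFactor,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    L = len(tables)
    Ps = np.array([t.Ps for t in tables], dtype=float)
    Pr = np.array([t.Pr for t in tables], dtype=float)
    Ds = np.array([t.Ds for t in tables], dtype=float)
    Dr = np.array([t.Dr for t in tables], dtype=float)
    n_arr = np.array([t.n for t in tables])
    a_n = np.array([harmonic(t.n - 1) for t in tables])
    glabels = sorted(set(groups))
    gidx = np.array([glabels.index(g) for g in groups])
    G = len(glabels)

    # overdispersed-ish random start
    th_s = rng.gamma(1.0, 1.0, size=L) + (Ps + Ds + 0.5) / (a_n + 1.0)
    th_r = rng.gamma(1.0, 1.0, size=L) + (Pr + Dr + 0.5) / (a_n + 1.0)
    tau = max(rng.gamma(2.0, 1.0), 0.1)
    gam = rng.normal(0.0, 1.0, size=L)
    mu_g = rng.normal(0.0, 1.0, size=G)
    sig2_g = np.full(G, 1.0)

    a0, b0 = cfg.rate_prior_shape, cfg.rate_prior_rate
    n_iter = cfg.burn_in + cfg.samples_per_chain * cfg.thin
    keep = cfg.samples_per_chain
    out_gam = np.empty((keep, L))
    out_mu = np.empty((keep, G))
    out_tau = np.empty(keep)
    k = 0

    def gamma_loglik(g: np.ndarray) -> np.ndarray:
        logF = log_fixation_factor(g)
        logPfac = logP(g, n_arr)
        return (
            Pr * logPfac
            + Dr * logF
            - th_r * (np.exp(logPfac) + tau * np.exp(logF))
        )

    ll_gam = gamma_loglik(gam)
    for it in range(n_iter):
        Pfac = np.exp(logP(gam, n_arr))
        Ffac = np.exp(log_fixation_factor(gam))
        th_s = rng.gamma(a0 + Ps + Ds, 1.0 / (b0 + a_n + tau))
        th_r = rng.gamma(a0 + Pr + Dr, 1.0 / (b0 + Pfac + tau * Ffac))
        tau = rng.gamma(
            a0 + Ds.sum() + Dr.sum(), 1.0 / (b0 + th_s.sum() + (th_r * Ffac).sum())
        )
        # vectorised random-walk Metropolis on the gammas
        ll_gam = gamma_loglik(gam)  # th_r, tau changed above
        prop = gam + rng.normal(0.0, cfg.proposal_sd, size=L)
        ll_prop = gamma_loglik(prop)
        prior_cur = -0.5 * (gam - mu_g[gidx]) ** 2 / sig2_g[gidx]
        prior_prop = -0.5 * (prop - mu_g[gidx]) ** 2 / sig2_g[gidx]
        accept = np.log(rng.random(L)) < (ll_prop + prior_prop) - (ll_gam + prior_cur)
        gam = np.where(accept, prop, gam)
        # conjugate hyper-parameter draws per group
        for g in range(G):
            sel = gidx == g
            kk = sel.sum()
            prec = kk / sig2_g[g] + 1.0 / cfg.gamma_prior_sd**2
            mean = (gam[sel].sum() / sig2_g[g]) / prec
            mu_g[g] = rng.normal(mean, 1.0 / math.sqrt(prec))
            ssq = ((gam[sel] - mu_g[g]) ** 2).sum()
            sig2_g[g] = 1.0 / rng.gamma(
                cfg.sigma2_prior_shape + kk / 2.0,
                1.0 / (cfg.sigma2_prior_scale + ssq / 2.0),
            )
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and k < keep:
            out_gam[k] = gam
            out_mu[k] = mu_g
            out_tau[k] = tau
            k += 1
    return {"gamma": out_gam, "mu": out_mu, "tau": out_tau, "group_labels": glabels}


def fit_mkprf(
    tables: list[MKTable],
    cfg: PRFConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MKPRFResult:
    """Fit the hierarchical PRF model by MCMC.

    Requires at least two loci per group.  Non-convergence (any parameter's
    Gelman-Rubin statistic above ``cfg.rhat_threshold``) is flagged on the
    result, never silent.
    """
    cfg = cfg or PRFConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    groups = [t.group for t in tables]
    for g in set(groups):
        if groups.count(g) < 2:
            raise ValueError(f"group {g!r} needs >= 2 loci")
    logP = _LogPolyFactor()
    chains = [
        _run_chain(tables, groups, cfg, logP, np.random.default_rng(rng.integers(2**31)))
        for _ in range(cfg.chains)
    ]
    glabels = chains[0]["group_labels"]
    gam_all = np.stack([c["gamma"] for c in chains])  # (chains, samples, loci)
    mu_all = np.stack([c["mu"] for c in chains])
    tau_all = np.stack([c["tau"] for c in chains])

    rhats = [gelman_rubin(gam_all[:, :, l]) for l in range(gam_all.shape[2])]
    rhats += [gelman_rubin(mu_all[:, :, g]) for g in range(mu_all.shape[2])]
    rhats.append(gelman_rubin(tau_all))
    max_rhat = float(max(rhats))

    loci = []
    for l, t in enumerate(tables):
        draw = gam_all[:, :, l].ravel()
        lo, hi = np.percentile(draw, [2.5, 97.5])
        loci.append(
            SelectionPosterior(
                locus_id=t.locus_id,
                group=t.group,
                mean=float(draw.mean()),
                ci_low=float(lo),
                ci_high=float(hi),
                frac_positive=float((draw > 0).mean()),
                rhat=float(rhats[l]),
            )
        )
    hyper_samples = {g: mu_all[:, :, i].ravel() for i, g in enumerate(glabels)}
    hyper_summary = {}
    for g, draw in hyper_samples.items():
        lo, hi = np.percentile(draw, [2.5, 97.5])
        hyper_summary[g] = {
            "mean": float(draw.mean()),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "frac_positive": float((draw > 0).mean()),
        }
    return MKPRFResult(
        loci=loci,
        hyper_mean_samples=hyper_samples,
        hyper_summary=hyper_summary,
        tau_div_mean=float(tau_all.mean()),
        max_rhat=max_rhat,
        converged=max_rhat <= cfg.rhat_threshold,
        gamma_samples={t.locus_id: gam_all[:, :, l].ravel() for l, t in enumerate(tables)},
    )


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is (m, n): m >= 2 chains of n >= 10 samples.  Computes
    ``sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain variance
    and B the between-chain variance of the means times n.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    if n < 10:
        raise ValueError("need >= 10 samples per chain")
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chains.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else float("inf")
    v_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(v_hat / W))
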