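"""Monte-Carlo likelihood of folded SFS data under a demographic model.

Given an ARG with per-frequency-class branch lengths ``b_i`` and a per-locus
scaled mutation rate ``Theta``, the probability of an observed spectrum is a
product of independent Poisson densities with rates ``b_i * Theta``.  The
likelihood under a demographic model integrates over ARGs, approximated by
averaging the Poisson products over ``M`` simulated ARGs; the average is
taken in log space with an overflow-safe reduction.  Folded spectra are
evaluated against folded rates ``b_i + b_{n-i}`` (``b_{n/2}`` unchanged for
even ``n``), the exact consequence of Poisson additivity.

Watterson's estimator is biased under non-equilibrium demography by a
model-dependent but Theta-independent constant factor; the factor is
estimated by simulating data with known Theta under the model and dividing
the mean estimate by the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .coalescent_engine import ARGSample, DemographicModel, sample_sfs, simulate_arg
from .popstats import SFS, harmonic, watterson_theta
from .stats_util import log_mean_exp

__all__ = [
    "LikelihoodConfig",
    "locus_loglik",
    "dataset_loglik",
    "theta_bias_factor",
    "class_theta_estimates",
]


@dataclass
class LikelihoodConfig:
    """Settings for Monte-Carlo likelihood evaluation."""

    M: int = 1000  # ARGs per (n, L) combination
    theta_by_class: dict[str, float] = field(default_factory=dict)  # per-site rates
    rho_per_bp: float = 0.023
    seed: int = 0
    n_reps: int = 1  # repeated evaluations for SE estimation

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        for k, v in self.theta_by_class.items():
            if v < 0:
                raise ValueError(f"theta for class {k!r} must be >= 0")


def locus_loglik(sfs: SFS, args: list[ARGSample], theta: float) -> float:
    """log of the ARG-averaged Poisson-product likelihood for one locus."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if not args:
        raise ValueError("need at least one ARG sample")
    for arg in args:
        if arg.n != sfs.n:
            raise ValueError(f"ARG sample size {arg.n} != SFS sample size {sfs.n}")
    B = np.stack([arg.folded_b() if sfs.folded else arg.b for arg in args])
    return _loglik_from_rates(sfs.counts, B * theta)


def _loglik_from_rates(x: np.ndarray, rates: np.ndarray) -> float:
    """log-mean over rows of prod_i Poisson(x_i; rates[m, i])."""
    x = np.asarray(x, dtype=float)
    zero = rates == 0.0
    bad = zero & (x > 0)  # that ARG gives the data probability zero
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(zero, 0.0, x * np.log(np.where(zero, 1.0, rates)))
    lls = (terms - rates).sum(axis=1) - gammaln(x + 1.0).sum()
    lls[bad.any(axis=1)] = -np.inf
    return log_mean_exp(lls)


def dataset_loglik(
    loci: list[tuple[SFS, str, int]],
    model: DemographicModel,
    cfg: LikelihoodConfig,
    rng: np.random.Generator | None = None,
    arg_cache: dict | None = None,
) -> float:
    """Sum of per-locus Monte-Carlo log-likelihoods.

    ``loci`` entries are (sfs, diversity_class, L); the per-locus rate is the
    per-site class rate times ``L``.  ARG streams are simulated once per
    distinct (n, L) pair and shared across the loci that need them (pass
    ``arg_cache`` to share streams across models of identical structure —
    e.g. repeated evaluations use fresh caches).
    """
    if not loci:
        raise ValueError("need at least one locus")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if arg_cache is None:
        arg_cache = {}
    total = 0.0
    for sfs, cls, L in loci:
        key = (sfs.n, L)
        if key not in arg_cache:
            arg_cache[key] = [
                simulate_arg(sfs.n, model, cfg.rho_per_bp, L, rng) for _ in range(cfg.M)
            ]
        theta = cfg.theta_by_class[cls] * L
        total += locus_loglik(sfs, arg_cache[key], theta)
    return total


def theta_bias_factor(
    model: DemographicModel,
    theta_true: float,
    n: int,
    L: int,
    reps: int,
    rng: np.random.Generator,
    rho_per_bp: float = 0.023,
) -> tuple[float, float]:
    """Bias factor ``c = mean(Theta_W) / Theta_true`` under the model.

    ``theta_true`` is the per-locus rate used in simulation.  Returns (c,
    standard error).  Under the constant model c = 1 (Watterson is unbiased
    at equilibrium); corrected estimates downstream are ``Theta_W / c``.
    """
    if reps < 1000:
        raise ValueError("need reps >= 1000 for a stable bias factor")
    est = np.empty(reps)
    for r in range(reps):
        arg = simulate_arg(n, model, rho_per_bp, L, rng)
        S = int(sample_sfs(arg, theta_true, rng).counts.sum())
        est[r] = watterson_theta(S, n)
    c = est.mean() / theta_true
    se = est.std(ddof=1) / np.sqrt(reps) / theta_true
    return float(c), float(se)


def class_theta_estimates(
    loci: list,
    model: DemographicModel,
    cfg: LikelihoodConfig,
    rng: np.random.Generator | None = None,
    bias_reps: int = 2000,
    required_classes: tuple[str, ...] = ("coding", "promoter"),
) -> dict[str, float]:
    """Bias-corrected per-site Theta averaged within each diversity class.

    ``loci`` are :class:`~pinepop.popstats.LocusSummary` objects.  The bias
    factor is estimated once (it does not depend on Theta or on the class)
    at a representative (n, L) and divides the within-class average of
    per-site Watterson estimates.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    by_class: dict[str, list] = {}
    for ls in loci:
        by_class.setdefault(ls.diversity_class, []).append(ls)
    for c in required_classes:
        if not by_class.get(c):
            raise ValueError(f"diversity class {c!r} has no loci")
    ref = loci[0]
    theta_ref = max(np.mean([ls.theta_w_locus for ls in loci]), 1.0)
    c_factor, _ = theta_bias_factor(
        model, theta_ref, ref.n, ref.L, bias_reps, rng, cfg.rho_per_bp
    )
    return {
        cls: float(np.mean([ls.theta_w_site for ls in group]) / c_factor)
        for cls, group in by_class.items()
    }
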