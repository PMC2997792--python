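"""Per-locus neutrality scan against simulation-based null distributions.

For each locus, summary statistics of the observed folded spectrum (number
of segregating sites, Tajima's D, Fu & Li's D*) are compared with their
empirical distributions under the best-fit demographic model: ARGs are
simulated under the model, mutations placed at the class-average corrected
per-site rate times locus length, and the statistics recomputed.  The
reported quantile is the proportion of simulated values strictly less than
the observed value; two-sided flags are raised at alpha = 0.05 (quantile
outside [0.025, 0.975]), alpha = 0.01, and a Bonferroni level that splits
alpha / n_loci between the tails.

Simulated replicates on which a statistic is undefined (no segregating
sites) are excluded from that statistic's null distribution and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coalescent_engine import DemographicModel, sample_sfs, simulate_arg
from .popstats import SFS, fu_li_d_star_from_sfs, tajimas_d_from_sfs

__all__ = ["NullDistribution", "ScanRow", "null_distribution", "quantile_of", "scan"]

_STATS = ("S", "tajimas_D", "fu_li_D")


def _stat_from_sfs(name: str, sfs: SFS) -> float | None:
    folded = sfs.counts if sfs.folded else sfs.fold().counts
    if name == "S":
        return float(folded.sum())
    if name == "tajimas_D":
        return tajimas_d_from_sfs(folded, sfs.n, folded_input=True)
    if name == "fu_li_D":
        return fu_li_d_star_from_sfs(folded, sfs.n)
    raise ValueError(f"unknown statistic {name!r}")


@dataclass
class NullDistribution:
    """Sorted empirical null for one statistic."""

    statistic: str
    model: DemographicModel
    n: int
    theta: float
    M: int
    values: np.ndarray  # sorted, defined replicates only
    n_undefined: int

    @property
    def n_defined(self) -> int:
        return self.values.size


def null_distribution(
    model: DemographicModel,
    theta: float,
    n: int,
    L: int,
    statistic: str,
    M: int,
    rng: np.random.Generator,
    rho_per_bp: float = 0.023,
) -> NullDistribution:
    """Empirical distribution of one statistic from ``M`` simulated loci.

    ``theta`` is the per-locus rate.  All three statistics are computed from
    the same stream when called via :func:`scan`; this entry point simulates
    a fresh stream for a single statistic.
    """
    if statistic not in _STATS:
        raise ValueError(f"statistic must be one of {_STATS}")
    values = []
    undefined = 0
    for _ in range(M):
        arg = simulate_arg(n, model, rho_per_bp, L, rng)
        sfs = sample_sfs(arg, theta, rng)
        v = _stat_from_sfs(statistic, sfs)
        if v is None:
            undefined += 1
        else:
            values.append(v)
    return NullDistribution(
        statistic, model, n, theta, M, np.sort(np.asarray(values, dtype=float)), undefined
    )


def quantile_of(observed: float | None, dist: NullDistribution) -> float | None:
    """Proportion of simulated values strictly less than the observed value
    (ties count as not-less); ``None`` for an undefined observation."""
    if observed is None:
        return None
    if dist.n_defined == 0:
        raise ValueError("empty null distribution")
    return float(np.searchsorted(dist.values, observed, side="left") / dist.n_defined)


@dataclass
class ScanRow:
    """Per-locus, per-statistic scan outcome."""

    locus_id: str
    statistic: str
    observed: float | None
    quantile: float | None
    sig_05: bool
    sig_01: bool
    sig_bonferroni: bool
    null_undefined_fraction: float


def _flags(q: float | None, n_loci: int) -> tuple[bool, bool, bool]:
    if q is None:
        return False, False, False
    bonf_tail = 0.05 / n_loci / 2.0
    return (
        q < 0.025 or q > 0.975,
        q < 0.005 or q > 0.995,
        q < bonf_tail or q > 1.0 - bonf_tail,
    )


def scan(
    loci: list[tuple[str, SFS, int, str]],
    model: DemographicModel,
    theta_by_class: dict[str, float],
    M: int,
    rng: np.random.Generator,
    rho_per_bp: float = 0.023,
) -> list[ScanRow]:
    """Scan loci against the model.

    ``loci`` entries are (locus_id, observed SFS, L, diversity_class); the
    null for each locus uses the class-average per-site rate times ``L`` (not
    the locus's own estimate, so diversity deviations remain detectable).
    Null streams are shared across loci with identical (n, L, class).
    """
    n_loci = len(loci)
    cache: dict[tuple, dict[str, NullDistribution]] = {}
    rows: list[ScanRow] = []
    for locus_id, sfs, L, cls in loci:
        theta = theta_by_class[cls] * L
        key = (sfs.n, L, cls)
        if key not in cache:
            per_stat: dict[str, list[float]] = {s: [] for s in _STATS}
            undef = {s: 0 for s in _STATS}
            for _ in range(M):
                arg = simulate_arg(sfs.n, model, rho_per_bp, L, rng)
                sim = sample_sfs(arg, theta, rng)
                for s in _STATS:
                    v = _stat_from_sfs(s, sim)
                    if v is None:
                        undef[s] += 1
                    else:
                        per_stat[s].append(v)
            cache[key] = {
                s: NullDistribution(
                    s, model, sfs.n, theta, M, np.sort(np.asarray(per_stat[s])), undef[s]
                )
                for s in _STATS
            }
        for s in _STATS:
            dist = cache[key][s]
            obs = _stat_from_sfs(s, sfs)
            q = quantile_of(obs, dist) if dist.n_defined else None
            f05, f01, fb = _flags(q, n_loci)
            rows.append(
                ScanRow(
                    locus_id=locus_id,
                    statistic=s,
                    observed=obs,
                    quantile=q,
                    sig_05=f05,
                    sig_01=f01,
                    sig_bonferroni=fb,
                    null_undefined_fraction=dist.n_undefined / M,
                )
            )
    return rows
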