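"""Coalescent simulation of ancestral recombination graphs and the
two-species isolation model, plus a forward Wright-Fisher simulator.

Unit conventions
----------------
Within-species demography: time is measured in units of ``2 N_0`` generations
(``N_0`` = current effective size); epoch sizes are ratios to ``N_0``.  The
per-frequency-class branch lengths ``b_i`` returned by :func:`simulate_arg`
are scaled so that the expected number of mutations in class ``i`` equals
``b_i * Theta`` with ``Theta = 4 N_0 mu L`` the per-locus scaled mutation
rate; under a constant-size history ``E[b_i] = 1/i``.  The scaled
recombination rate ``rho`` is ``4 N_0 r`` per base pair.

Isolation model: parameters follow the classical two-species isolation
parameterization — ``theta1 = 4 N_1 mu`` per locus for species 1 (the
reference), size ratios ``theta2/theta1`` and ``thetaA/theta1`` for species 2
and the ancestral population, and the divergence time ``tau`` in coalescent
units of ``4 N_1`` generations (the scaling used by ms-style simulators).

The ARG is built by the standard back-in-time coalescent with recombination
(Hudson's algorithm) over ``L`` discrete sites; each extant lineage stores,
per site, the set of sampled sequences it subtends as a 64-bit mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _arg_fast
from .locus_io import IMCounts

__all__ = [
    "DemographicModel",
    "ARGSample",
    "IMParams",
    "simulate_arg",
    "simulate_locus_patterns",
    "sample_sfs",
    "simulate_im_locus",
    "simulate_im_patterns",
    "wf_absorption_time",
]


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant single-population history (step changes only).

    ``model_class`` is one of ``constant``, ``two_epoch``, ``three_epoch``.
    Looking back in time the population has relative size 1 on ``[0, T_B)``,
    ``N_B/N_0`` on ``[T_B, T_A)`` and ``N_A/N_0`` on ``[T_A, inf)`` for the
    three-epoch (bottleneck) class; the two-epoch class changes once, at
    ``T_A``, to ``N_A/N_0``.  Times are in units of ``2 N_0`` generations.
    """

    model_class: str = "constant"
    N_B_over_N0: float = 1.0
    N_A_over_N0: float = 1.0
    T_B: float = 1.0
    T_A: float = 2.0

    def __post_init__(self) -> None:
        if self.model_class not in ("constant", "two_epoch", "three_epoch"):
            raise ValueError(f"unknown model class {self.model_class!r}")
        if self.model_class == "constant":
            return
        if self.N_A_over_N0 <= 0 or self.T_A <= 0:
            raise ValueError("size ratios and times must be > 0")
        if self.model_class == "three_epoch":
            if self.N_B_over_N0 <= 0 or self.T_B <= 0:
                raise ValueError("size ratios and times must be > 0")
            if self.T_A <= self.T_B:
                raise ValueError(
                    f"three-epoch model needs T_A > T_B, got T_A={self.T_A}, T_B={self.T_B}"
                )

    def epochs(self) -> list[tuple[float, float]]:
        """(start_time, relative_size) pairs, oldest epoch open-ended."""
        if self.model_class == "constant":
            return [(0.0, 1.0)]
        if self.model_class == "two_epoch":
            return [(0.0, 1.0), (self.T_A, self.N_A_over_N0)]
        return [(0.0, 1.0), (self.T_B, self.N_B_over_N0), (self.T_A, self.N_A_over_N0)]


@dataclass
class ARGSample:
    """Per-frequency-class branch lengths averaged over the sites of a locus.

    ``b[i-1]`` is scaled branch length subtending exactly ``i`` of the ``n``
    samples, such that mutation counts in class ``i`` are Poisson(``b_i *
    Theta``) for per-locus rate Theta.
    """

    n: int
    b: np.ndarray

    def folded_b(self) -> np.ndarray:
        k = self.n // 2
        out = np.empty(k)
        for i in range(1, k + 1):
            out[i - 1] = self.b[i - 1] if i == self.n - i else self.b[i - 1] + self.b[self.n - i - 1]
        return out


@dataclass(frozen=True)
class IMParams:
    """Isolation-model parameters (species 1 is the reference)."""

    theta1: float
    theta2_ratio: float = 1.0
    thetaA_ratio: float = 1.0
    tau: float = 1.0  # divergence time in units of 4*N_1 generations

    def __post_init__(self) -> None:
        if self.theta1 <= 0 or self.theta2_ratio <= 0 or self.thetaA_ratio <= 0:
            raise ValueError("theta parameters must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


class _Lineage:
    """One ancestral lineage: per-site subtended-sample masks and counts."""

    __slots__ = ("mask", "pop")

    def __init__(self, mask: np.ndarray, pop: np.ndarray):
        self.mask = mask  # uint64 bitmask of subtended samples, 0 = not carried
        self.pop = pop  # int16 popcount of mask

    @property
    def carried(self) -> np.ndarray:
        return np.nonzero(self.pop)[0]

    def span(self) -> tuple[int, int, int]:
        idx = self.carried
        return int(idx[0]), int(idx[-1]), idx.size

    def hist(self, n: int) -> np.ndarray:
        return np.bincount(self.pop, minlength=n + 1)


def _arg_core(
    n: int,
    model: DemographicModel,
    rho_per_bp: float,
    L: int,
    rng: np.random.Generator,
    theta_site: float | None = None,
):
    """Shared ARG machinery.

    Returns (b_acc, mutations) with ``b_acc[i]`` the time-integral of the
    number of (lineage, site) pairs subtending ``i`` samples, and
    ``mutations`` a list of (site, carrier bitmask) when ``theta_site`` is
    given.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if n > 64:
        raise ValueError("sample sizes above 64 are not supported")
    if L < 1 or rho_per_bp < 0:
        raise ValueError("need L >= 1 and rho >= 0")

    lineages = [
        _Lineage(np.full(L, np.uint64(1) << np.uint64(i)), np.ones(L, dtype=np.int16))
        for i in range(n)
    ]
    R = np.zeros(n + 1)
    R[1] = n * L
    b_acc = np.zeros(n + 1)
    mutations: list[tuple[int, int]] = []
    mutated_sites: set[int] = set()

    epochs = model.epochs()
    epoch_idx = 0
    t = 0.0

    def rec_rate(lin: _Lineage) -> float:
        if rho_per_bp == 0.0:
            return 0.0
        left, right, _ = lin.span()
        return rho_per_bp * (right - left) / 2.0

    rec_rates = [rec_rate(l) for l in lineages]

    while R[1:n].sum() > 0:
        k = len(lineages)
        size = epochs[epoch_idx][1]
        coal = k * (k - 1) / 2.0 / size
        rec_total = sum(rec_rates)
        total = coal + rec_total
        if total <= 0:  # single lineage, no recombination: finish instantly
            break
        dt = rng.exponential(1.0 / total)
        boundary = epochs[epoch_idx + 1][0] if epoch_idx + 1 < len(epochs) else np.inf
        if t + dt > boundary:
            step = boundary - t
            b_acc[1:n] += step * R[1:n]
            if theta_site is not None:
                _scatter_mutations(step, R, lineages, theta_site, rng, mutations, mutated_sites, n)
            t = boundary
            epoch_idx += 1
            continue
        b_acc[1:n] += dt * R[1:n]
        if theta_site is not None:
            _scatter_mutations(dt, R, lineages, theta_site, rng, mutations, mutated_sites, n)
        t += dt

        if rng.random() < coal / total:
            i, j = rng.choice(k, size=2, replace=False)
            a, b_lin = lineages[i], lineages[j]
            R -= a.hist(n) + b_lin.hist(n)
            R[0] = 0
            pop = a.pop + b_lin.pop
            mask = a.mask | b_lin.mask
            done = pop == n
            if done.any():
                pop[done] = 0
                mask[done] = 0
            merged = _Lineage(mask, pop)
            for idx in sorted((i, j), reverse=True):
                lineages.pop(idx)
                rec_rates.pop(idx)
            if pop.any():
                R += merged.hist(n)
                R[0] = 0
                lineages.append(merged)
                rec_rates.append(rec_rate(merged))
        else:
            w = np.asarray(rec_rates)
            i = int(rng.choice(len(lineages), p=w / w.sum()))
            lin = lineages[i]
            left, right, _ = lin.span()
            brk = int(rng.integers(left + 1, right + 1))  # left part: sites < brk
            lmask, lpop = lin.mask.copy(), lin.pop.copy()
            lmask[brk:] = 0
            lpop[brk:] = 0
            rmask, rpop = lin.mask.copy(), lin.pop.copy()
            rmask[:brk] = 0
            rpop[:brk] = 0
            lineages[i] = _Lineage(lmask, lpop)
            rec_rates[i] = rec_rate(lineages[i])
            new = _Lineage(rmask, rpop)
            lineages.append(new)
            rec_rates.append(rec_rate(new))
    return b_acc, mutations


def _scatter_mutations(dt, R, lineages, theta_site, rng, mutations, mutated_sites, n):
    active = R[1:n].sum()
    n_mut = rng.poisson(dt * theta_site / 2.0 * active)
    if n_mut == 0:
        return
    weights = np.array([np.count_nonzero(l.pop) for l in lineages], dtype=float)
    weights /= weights.sum()
    for _ in range(n_mut):
        lin = lineages[int(rng.choice(len(lineages), p=weights))]
        carried = lin.carried
        # infinite sites: recurrent hits at an already-mutated site are re-drawn
        for _attempt in range(100):
            site = int(carried[rng.integers(carried.size)])
            if site not in mutated_sites:
                mutated_sites.add(site)
                mutations.append((site, int(lin.mask[site])))
                break


def simulate_arg(
    n: int,
    model: DemographicModel,
    rho_per_bp: float,
    L: int,
    rng: np.random.Generator,
) -> ARGSample:
    """Draw one ARG; return per-frequency-class branch lengths.

    ``b_i`` is averaged over the ``L`` sites and scaled so that
    ``E[x_i] = b_i * Theta`` for per-locus ``Theta``; with ``rho == 0`` the
    ARG is a single tree.  Uses the JIT-compiled kernel when numba is
    available (same algorithm, independent random stream).
    """
    if _arg_fast.HAVE_NUMBA:
        if n < 2:
            raise ValueError("need n >= 2 samples")
        if n > 64:
            raise ValueError("sample sizes above 64 are not supported")
        if L < 1 or rho_per_bp < 0:
            raise ValueError("need L >= 1 and rho >= 0")
        epochs = model.epochs()
        starts = np.array([e[0] for e in epochs])
        sizes = np.array([e[1] for e in epochs])
        seed = int(rng.integers(1, 2**31))
        b_acc = _arg_fast.arg_branch_lengths(n, starts, sizes, rho_per_bp, L, seed)
        return ARGSample(n=n, b=b_acc[1:n] / (2.0 * L))
    b_acc, _ = _arg_core(n, model, rho_per_bp, L, rng)
    return ARGSample(n=n, b=b_acc[1:n] / (2.0 * L))


def simulate_locus_patterns(
    n: int,
    model: DemographicModel,
    rho_per_bp: float,
    L: int,
    theta_site: float,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Simulate a locus and place mutations on the ARG.

    Returns a list of (site index, carrier bitmask over the n samples); each
    site carries at most one mutation (infinite-sites; collisions re-drawn).
    """
    _, mutations = _arg_core(n, model, rho_per_bp, L, rng, theta_site=theta_site)
    return mutations


def sample_sfs(arg: ARGSample, theta: float, rng: np.random.Generator):
    """Unfolded SFS with ``x_i ~ Poisson(b_i * theta)`` independently."""
    from .popstats import SFS

    if theta < 0:
        raise ValueError("theta must be >= 0")
    counts = rng.poisson(arg.b * theta)
    return SFS(n=arg.n, folded=False, counts=counts)


# --- two-species isolation model ------------------------------------------


def _im_arg_mutations(
    n1: int,
    n2: int,
    params: IMParams,
    theta_site: float,
    rho_per_bp: float,
    L: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Isolation-model locus with intra-locus recombination.

    Two-population ancestral recombination graph: Hudson-style events within
    each species until the split (backward time ``2 * tau`` in 2 N_1 units),
    then a single ancestral population of relative size ``thetaA_ratio``.
    Returns (site, carrier bitmask) pairs; bits 0..n1-1 are species 1.
    """
    n = n1 + n2
    if n > 64:
        raise ValueError("sample sizes above 64 are not supported")
    T_split = 2.0 * params.tau
    sizes = [1.0, params.theta2_ratio]
    pools: list[list[_Lineage]] = [
        [_Lineage(np.full(L, np.uint64(1) << np.uint64(i)), np.ones(L, dtype=np.int16))
         for i in range(n1)],
        [_Lineage(np.full(L, np.uint64(1) << np.uint64(n1 + i)), np.ones(L, dtype=np.int16))
         for i in range(n2)],
    ]
    R = np.zeros(n + 1)
    R[1] = n * L
    mutations: list[tuple[int, int]] = []
    mutated: set[int] = set()

    def rec_rate(lin: _Lineage) -> float:
        if rho_per_bp == 0.0:
            return 0.0
        left, right, _ = lin.span()
        return rho_per_bp * (right - left) / 2.0

    def scatter(dt: float, lineages: list[_Lineage]) -> None:
        if theta_site > 0:
            _scatter_mutations(dt, R, lineages, theta_site, rng, mutations, mutated, n)

    def do_coalescence(pool: list[_Lineage]) -> None:
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b_lin = pool[i], pool[j]
        R[:] -= a.hist(n) + b_lin.hist(n)
        R[0] = 0
        pop = a.pop + b_lin.pop
        mask = a.mask | b_lin.mask
        done = pop == n
        if done.any():
            pop[done] = 0
            mask[done] = 0
        for idx in sorted((int(i), int(j)), reverse=True):
            pool.pop(idx)
        if pop.any():
            merged = _Lineage(mask, pop)
            R[:] += merged.hist(n)
            R[0] = 0
            pool.append(merged)

    def do_recombination(pool: list[_Lineage], i: int) -> None:
        lin = pool[i]
        left, right, _ = lin.span()
        brk = int(rng.integers(left + 1, right + 1))
        lmask, lpop = lin.mask.copy(), lin.pop.copy()
        lmask[brk:] = 0
        lpop[brk:] = 0
        rmask, rpop = lin.mask.copy(), lin.pop.copy()
        rmask[:brk] = 0
        rpop[:brk] = 0
        pool[i] = _Lineage(lmask, lpop)
        pool.append(_Lineage(rmask, rpop))

    t = 0.0
    while t < T_split and R[1:n].sum() > 0:
        k1, k2 = len(pools[0]), len(pools[1])
        coal = [k1 * (k1 - 1) / 2.0 / sizes[0], k2 * (k2 - 1) / 2.0 / sizes[1]]
        rr = [[rec_rate(l) for l in pools[0]], [rec_rate(l) for l in pools[1]]]
        rec_tot = sum(rr[0]) + sum(rr[1])
        total = coal[0] + coal[1] + rec_tot
        if total <= 0:
            scatter(T_split - t, pools[0] + pools[1])
            t = T_split
            break
        dt = rng.exponential(1.0 / total)
        step = min(dt, T_split - t)
        scatter(step, pools[0] + pools[1])
        t += step
        if t >= T_split:
            break
        u = rng.random() * total
        if u < coal[0]:
            do_coalescence(pools[0])
        elif u < coal[0] + coal[1]:
            do_coalescence(pools[1])
        else:
            u -= coal[0] + coal[1]
            for p in (0, 1):
                for i, w in enumerate(rr[p]):
                    u -= w
                    if u < 0:
                        do_recombination(pools[p], i)
                        break
                if u < 0:
                    break
    # ancestral phase
    pool = [l for l in pools[0] + pools[1] if l.pop.any()]
    size_a = params.thetaA_ratio
    while R[1:n].sum() > 0 and pool:
        k = len(pool)
        coal = k * (k - 1) / 2.0 / size_a
        rr = [rec_rate(l) for l in pool]
        total = coal + sum(rr)
        if total <= 0:
            break
        dt = rng.exponential(1.0 / total)
        scatter(dt, pool)
        if rng.random() < coal / total:
            do_coalescence(pool)
        else:
            u = rng.random() * sum(rr)
            for i, w in enumerate(rr):
                u -= w
                if u < 0:
                    do_recombination(pool, i)
                    break
        pool = [l for l in pool if l.pop.any()]
    return mutations


def _im_tree_mutations(
    n1: int,
    n2: int,
    params: IMParams,
    theta_locus: float,
    rng: np.random.Generator,
) -> list[int]:
    """Carrier bitmasks (bits 0..n1-1 species 1, bits n1.. species 2) of all
    mutations on one non-recombining isolation-model genealogy.

    Time unit: 2*N_1 generations; the split is at ``2 * tau`` in this unit.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least one sample per species")
    full = (1 << (n1 + n2)) - 1
    T_split = 2.0 * params.tau
    half_theta = theta_locus / 2.0
    muts: list[int] = []

    pops: list[list[int]] = [
        [1 << i for i in range(n1)],
        [1 << (n1 + i) for i in range(n2)],
    ]
    sizes = [1.0, params.theta2_ratio]
    t = 0.0
    # phase 1: two isolated populations until the split time
    while t < T_split:
        k1, k2 = len(pops[0]), len(pops[1])
        rates = [k1 * (k1 - 1) / 2.0 / sizes[0], k2 * (k2 - 1) / 2.0 / sizes[1]]
        total = rates[0] + rates[1]
        dt = rng.exponential(1.0 / total) if total > 0 else np.inf
        remaining = T_split - t
        step = min(dt, remaining)
        n_mut = rng.poisson(step * half_theta * (k1 + k2))
        if n_mut:
            lin = [*pops[0], *pops[1]]
            muts.extend(lin[i] for i in rng.integers(0, len(lin), size=n_mut))
        if dt >= remaining:  # no further event before the split
            t = T_split
            break
        t += dt
        which = 0 if rng.random() < rates[0] / total else 1
        pool = pops[which]
        i, j = rng.choice(len(pool), size=2, replace=False)
        merged = pool[i] | pool[j]
        for idx in sorted((i, j), reverse=True):
            pool.pop(idx)
        pool.append(merged)
    # phase 2: merged ancestral population
    pool = pops[0] + pops[1]
    size_a = params.thetaA_ratio
    while len(pool) > 1:
        k = len(pool)
        rate = k * (k - 1) / 2.0 / size_a
        dt = rng.exponential(1.0 / rate)
        targets = [m for m in pool if m != full]
        n_mut = rng.poisson(dt * half_theta * len(targets))
        if n_mut and targets:
            muts.extend(targets[i] for i in rng.integers(0, len(targets), size=n_mut))
        i, j = rng.choice(k, size=2, replace=False)
        merged = pool[i] | pool[j]
        for idx in sorted((i, j), reverse=True):
            pool.pop(idx)
        pool.append(merged)
    return muts


def classify_im_mask(mask: int, n1: int, n2: int) -> str | None:
    """Category of a mutation with the given carrier bitmask, or None if it
    produces no observable variation."""
    d1 = int.bit_count(mask & ((1 << n1) - 1))
    d2 = int.bit_count(mask >> n1)
    poly1, poly2 = 0 < d1 < n1, 0 < d2 < n2
    if poly1 and poly2:
        return "shared"
    if poly1:
        return "x1"
    if poly2:
        return "x2"
    if (d1 == n1 and d2 == 0) or (d1 == 0 and d2 == n2):
        return "fixed"
    return None


def simulate_im_patterns(
    n1: int,
    n2: int,
    params: IMParams,
    theta_locus: float,
    rng: np.random.Generator,
    locus_id: str = "sim",
    rho_per_bp: float = 0.0,
    L: int = 1,
) -> tuple[IMCounts, list[tuple[int, str]]]:
    """One isolation-model locus: category counts plus per-mutation carrier
    bitmasks and categories (for sequence generation).

    With ``rho_per_bp > 0`` the locus is a recombining ARG over ``L``
    discrete sites (category means are unchanged, but intra-locus
    recombination shrinks the genealogical variance of the counts, as in
    real multi-kb loci); the default is a single non-recombining genealogy.
    """
    if rho_per_bp > 0.0 and L > 1:
        muts_sites = _im_arg_mutations(
            n1, n2, params, theta_locus / L, rho_per_bp, L, rng
        )
        muts = [m for _, m in muts_sites]
    else:
        muts = _im_tree_mutations(n1, n2, params, theta_locus, rng)
    cats = {"x1": 0, "x2": 0, "shared": 0, "fixed": 0}
    kept: list[tuple[int, str]] = []
    for m in muts:
        c = classify_im_mask(m, n1, n2)
        if c is not None:
            cats[c] += 1
            kept.append((m, c))
    return IMCounts(locus_id, cats["x1"], cats["x2"], cats["shared"], cats["fixed"]), kept


def simulate_im_locus(
    n1: int,
    n2: int,
    params: IMParams,
    theta_locus: float,
    rng: np.random.Generator,
    locus_id: str = "sim",
    rho_per_bp: float = 0.0,
    L: int = 1,
) -> IMCounts:
    """Polymorphism-category counts for one simulated isolation-model locus."""
    if n1 < 2:
        raise ValueError("need n1 >= 2 to observe species-1 polymorphism")
    counts, _ = simulate_im_patterns(
        n1, n2, params, theta_locus, rng, locus_id, rho_per_bp=rho_per_bp, L=L
    )
    return counts


# --- forward Wright-Fisher -------------------------------------------------


def wf_absorption_time(
    p0: float,
    N: int,
    reps: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mean generations to loss or fixation of a neutral allele under
    discrete binomial resampling of ``N`` haploid gene copies, reported in
    units of the diploid-equivalent effective size ``N_e = N / 2``.

    Returns (mean, standard error).  On the ``N_e`` scale the diffusion
    prediction is ``-4 [p ln p + (1-p) ln(1-p)]`` (4 ln 2 = 2.77 at p0 =
    1/2); a population of ``N`` gene copies has drift variance ``p(1-p)/N``
    per generation, i.e. ``N = 2 N_e``.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if N < 100:
        raise ValueError("N must be >= 100 for the diffusion scaling to apply")
    if reps < 1000:
        raise ValueError("need reps >= 1000")
    counts = np.full(reps, int(round(p0 * N)), dtype=np.int64)
    gens = np.zeros(reps, dtype=np.int64)
    alive = (counts > 0) & (counts < N)
    g = 0
    while alive.any():
        g += 1
        counts[alive] = rng.binomial(N, counts[alive] / N)
        newly = alive & ((counts == 0) | (counts == N))
        gens[newly] = g
        alive &= ~newly
    scaled = gens / (N / 2.0)
    return float(scaled.mean()), float(scaled.std(ddof=1) / np.sqrt(reps))
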