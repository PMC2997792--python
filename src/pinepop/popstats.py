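"""Per-locus summary statistics and site-frequency spectra.

The site frequency spectrum (SFS) of a sample of ``n`` haploid sequences is
the vector ``x_i`` of counts of biallelic polymorphisms with ``i`` copies of
the derived allele (unfolded, ``i = 1..n-1``) or of the minor allele (folded,
``i = 1..floor(n/2)``).  Folding an unfolded spectrum adds symmetric classes:
``x_i + x_{n-i}`` for ``i < n/2``, with the ``n/2`` class unchanged for even
``n``.

Summary statistics (Watterson's theta, pairwise diversity pi, Tajima's D and
Fu & Li's D / D*) follow the standard normalisations.  All of them are
computable from the SFS alone, which is how the simulation-based null
distributions use them; the observed-data entry points accept a
:class:`~pinepop.locus_io.SiteTable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .locus_io import SiteTable

__all__ = [
    "SFS",
    "LocusSummary",
    "harmonic",
    "harmonic2",
    "build_sfs",
    "watterson_theta",
    "pairwise_pi",
    "tajimas_d",
    "fu_li_d",
    "tajimas_d_from_sfs",
    "fu_li_d_star_from_sfs",
    "fu_li_d_from_sfs",
    "write_sfs",
    "read_sfs",
]


def harmonic(m: int) -> float:
    """a_m = sum_{k=1}^{m} 1/k (a_0 = 0)."""
    return float(sum(1.0 / k for k in range(1, m + 1)))


def harmonic2(m: int) -> float:
    """b_m = sum_{k=1}^{m} 1/k^2."""
    return float(sum(1.0 / k**2 for k in range(1, m + 1)))


@dataclass
class SFS:
    """Frequency-class counts for a sample of ``n`` haploid sequences."""

    n: int
    folded: bool
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = self.n // 2 if self.folded else self.n - 1
        if self.counts.shape != (k,):
            raise ValueError(
                f"SFS for n={self.n} ({'folded' if self.folded else 'unfolded'}) "
                f"needs {k} classes, got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be non-negative")

    @property
    def segregating_sites(self) -> int:
        return int(self.counts.sum())

    def fold(self) -> "SFS":
        """Minor-allele-frequency spectrum; identity if already folded."""
        if self.folded:
            return SFS(self.n, True, self.counts.copy())
        return SFS(self.n, True, fold_counts(self.counts, self.n))


def fold_counts(unfolded: np.ndarray, n: int) -> np.ndarray:
    unfolded = np.asarray(unfolded)
    k = n // 2
    folded = np.zeros(k, dtype=unfolded.dtype)
    for i in range(1, k + 1):
        if i == n - i:
            folded[i - 1] = unfolded[i - 1]
        else:
            folded[i - 1] = unfolded[i - 1] + unfolded[n - i - 1]
    return folded


def build_sfs(sites: SiteTable, species: str, folded: bool = True, n: int | None = None) -> SFS:
    """SFS of one species' biallelic sites.

    Only sites at which the species has its full sample size ``n`` of
    non-missing alleles enter the spectrum, so frequency classes stay
    well-defined under missing data.  The unfolded spectrum requires an
    ancestral allele at every site.
    """
    if species not in sites.sample_sizes:
        raise KeyError(f"species {species!r} not in site table {sites.locus_id}")
    if n is None:
        n = sites.sample_sizes[species]
    k = n // 2 if folded else n - 1
    counts = np.zeros(k, dtype=np.int64)
    for site in sites.biallelic_sites():
        c = site.counts.get(species)
        if not c or sum(c.values()) != n or len(c) < 2:
            continue
        if folded:
            minor = min(c.values())
            if minor >= 1:
                counts[minor - 1] += 1
        else:
            if site.ancestral is None:
                raise ValueError(
                    f"{sites.locus_id} column {site.column}: unfolded SFS requires "
                    "an ancestral allele"
                )
            derived = n - c.get(site.ancestral, 0)
            if 1 <= derived <= n - 1:
                counts[derived - 1] += 1
    return SFS(n=n, folded=folded, counts=counts)


def watterson_theta(S: int, n: int, L: int | None = None) -> float:
    """Watterson's moment estimator ``theta_W = S / a_{n-1}``.

    Per locus; pass ``L`` to obtain the per-site value instead.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 sequences, got {n}")
    if S < 0:
        raise ValueError("S must be >= 0")
    theta = S / harmonic(n - 1)
    if L is not None:
        if L < 1:
            raise ValueError("L must be >= 1")
        theta /= L
    return theta


def _species_spectrum(sites: SiteTable, species: str) -> tuple[int, np.ndarray]:
    """(n, folded minor-allele spectrum) restricted to full-sample-size sites."""
    n = sites.sample_sizes[species]
    return n, build_sfs(sites, species, folded=True, n=n).counts


def pairwise_pi(sites: SiteTable, species: str, per_site_L: int | None = None) -> float:
    """Mean pairwise diversity from the folded spectrum."""
    n, folded = _species_spectrum(sites, species)
    pi = _pi_from_folded(folded, n)
    if per_site_L:
        pi /= per_site_L
    return pi


def _pi_from_folded(folded: np.ndarray, n: int) -> float:
    i = np.arange(1, len(folded) + 1)
    return float((folded * i * (n - i)).sum() / math.comb(n, 2))


def tajimas_d(sites: SiteTable, species: str) -> float | None:
    """Tajima's D; ``None`` when undefined (no segregating sites)."""
    n, folded = _species_spectrum(sites, species)
    return tajimas_d_from_sfs(folded, n, folded_input=True)


def fu_li_d(sites: SiteTable, species: str, use_outgroup: bool = False) -> float | None:
    """Fu & Li's D (ancestral states required) or D* (default, star-free).

    Which variant is computed is up to the caller; both use the standard
    normalisations with singleton counts (derived singletons for D, total
    singletons for D*).
    """
    if use_outgroup:
        n = sites.sample_sizes[species]
        unfolded = build_sfs(sites, species, folded=False, n=n).counts
        return fu_li_d_from_sfs(unfolded, n)
    n, folded = _species_spectrum(sites, species)
    return fu_li_d_star_from_sfs(folded, n)


# --- SFS-based statistic kernels (shared with the neutrality scan) ---------


def tajimas_d_from_sfs(counts: np.ndarray, n: int, folded_input: bool = True) -> float | None:
    """Tajima (1989) D from a spectrum (folded or unfolded both work: pi and
    S are invariant under folding)."""
    counts = np.asarray(counts, dtype=float)
    if not folded_input:
        counts = fold_counts(counts.astype(np.int64), n).astype(float)
    S = counts.sum()
    if S < 1 or n < 4:
        return None
    a1 = harmonic(n - 1)
    a2 = harmonic2(n - 1)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = _pi_from_folded(counts, n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return float((pi - S / a1) / math.sqrt(var))


def _fu_li_constants(n: int) -> tuple[float, float, float]:
    a_n = harmonic(n - 1)
    b_n = harmonic2(n - 1)
    c_n = 2.0 * (n * a_n - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    return a_n, b_n, c_n


def fu_li_d_from_sfs(unfolded: np.ndarray, n: int) -> float | None:
    """Fu & Li (1993) D from an unfolded spectrum (external mutations are the
    derived singletons ``x_1``)."""
    unfolded = np.asarray(unfolded, dtype=float)
    eta = unfolded.sum()
    if eta < 1 or n < 3:
        return None
    eta_e = unfolded[0]
    a_n, b_n, c_n = _fu_li_constants(n)
    v = 1.0 + a_n**2 / (b_n + a_n**2) * (c_n - (n + 1.0) / (n - 1.0))
    u = a_n - 1.0 - v
    var = u * eta + v * eta**2
    if var <= 0:
        return None
    return float((eta - a_n * eta_e) / math.sqrt(var))


def fu_li_d_star_from_sfs(folded: np.ndarray, n: int) -> float | None:
    """Fu & Li (1993) D* from a folded spectrum (singletons are the minor
    count-1 class); constants follow the corrected published form."""
    folded = np.asarray(folded, dtype=float)
    eta = folded.sum()
    if eta < 1 or n < 3:
        return None
    eta_s = folded[0]
    a_n, b_n, c_n = _fu_li_constants(n)
    a_n1 = a_n + 1.0 / n  # a_{n+1}
    d_n = (
        c_n
        + (n - 2.0) / (n - 1.0) ** 2
        + 2.0 / (n - 1.0) * (1.5 - (2.0 * a_n1 - 3.0) / (n - 2.0) - 1.0 / n)
    )
    v = ((n / (n - 1.0)) ** 2 * b_n + a_n**2 * d_n - 2.0 * n * a_n * (a_n + 1.0) / (n - 1.0) ** 2) / (
        a_n**2 + b_n
    )
    u = n / (n - 1.0) * (a_n - n / (n - 1.0)) - v
    var = u * eta + v * eta**2
    if var <= 0:
        return None
    return float((n / (n - 1.0) * eta - a_n * eta_s) / math.sqrt(var))


@dataclass
class LocusSummary:
    """Bundle of per-locus summary statistics."""

    locus_id: str
    n: int
    L: int
    S: int
    theta_w_locus: float
    theta_w_site: float
    pi: float
    tajimas_d: float | None
    fu_li_d: float | None
    fu_li_variant: str  # "D" or "D*"
    diversity_class: str = "coding"

    @classmethod
    def from_sites(
        cls,
        sites: SiteTable,
        species: str,
        L: int,
        diversity_class: str = "coding",
        use_outgroup: bool = False,
    ) -> "LocusSummary":
        n = sites.sample_sizes[species]
        S = int(_species_spectrum(sites, species)[1].sum())
        theta = watterson_theta(S, n)
        return cls(
            locus_id=sites.locus_id,
            n=n,
            L=L,
            S=S,
            theta_w_locus=theta,
            theta_w_site=theta / L,
            pi=pairwise_pi(sites, species),
            tajimas_d=tajimas_d(sites, species),
            fu_li_d=fu_li_d(sites, species, use_outgroup=use_outgroup),
            fu_li_variant="D" if use_outgroup else "D*",
            diversity_class=diversity_class,
        )


def write_sfs(sfs: SFS, path: str | Path) -> None:
    """TSV: header line ``n=<n>\tfolded=<0|1>`` then ``i<TAB>count`` rows."""
    lines = [f"n={sfs.n}\tfolded={int(sfs.folded)}"]
    lines += [f"{i + 1}\t{c}" for i, c in enumerate(sfs.counts)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sfs(path: str | Path) -> SFS:
    lines = Path(path).read_text().splitlines()
    head = dict(kv.split("=") for kv in lines[0].split("\t"))
    n, folded = int(head["n"]), bool(int(head["folded"]))
    k = n // 2 if folded else n - 1
    counts = np.zeros(k, dtype=np.int64)
    for line in lines[1:]:
        if not line.strip():
            continue
        i, c = line.split("\t")
        counts[int(i) - 1] = int(c)
    return SFS(n=n, folded=folded, counts=counts)
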