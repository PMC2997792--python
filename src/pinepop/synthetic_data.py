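"""Study-like synthetic datasets with known truth.

Generates per-locus haploid FASTA alignments (within-species and
two-species), MK-style count tables from the PRF model, and Mendelian
segregation tables, each with a truth manifest sufficient to recompute the
expected statistics.  Defaults emulate the study design: ~70 unlinked loci
of 500-2000 bp in two diversity classes with promoters about twice as
diverse as coding loci, scaled recombination rate 0.023/bp, a recent
bottleneck followed by partial recovery for the within-species history, and
a two-species isolation model sampled with 32 ingroup and 2 outgroup
gametes.

Sequences are built by dropping the simulated infinite-sites mutations onto
a random uniform-composition reference (recurrent hits are re-drawn by the
simulator); coding loci carry a single forward-strand ORF over a
configurable fraction of their length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalescent_engine import (
    DemographicModel,
    IMParams,
    simulate_im_patterns,
    simulate_locus_patterns,
)
from .locus_io import IMCounts, LocusAlignment
from .mkprf import MKTable, prf_fixation_factor, prf_polymorphism_factor
from .popstats import harmonic

__all__ = [
    "SyntheticConfig",
    "generate_locus_set",
    "generate_two_species",
    "generate_prf_tables",
    "generate_segregation",
    "write_locus_set",
]

_BASES = np.array(list("ACGT"))

# best-supported three-epoch bottleneck of the study system: ~85% size
# reduction 0.041 * 2N0 generations ago, ancestral size ~3.8x current
DEFAULT_BOTTLENECK = DemographicModel(
    "three_epoch", N_B_over_N0=0.155, N_A_over_N0=3.793, T_B=0.041, T_A=0.214
)
# isolation-model parameters near the fitted values for the species pair
DEFAULT_IM = IMParams(theta1=1.6, theta2_ratio=1.0, thetaA_ratio=6.7, tau=0.87)


@dataclass
class SyntheticConfig:
    """Knobs of the generators, with study-like defaults."""

    n_loci_per_class: dict[str, int] = field(
        default_factory=lambda: {"coding": 35, "promoter": 35}
    )
    length_range: tuple[int, int] = (500, 2000)
    n1: int = 32
    n2: int = 2
    demography: DemographicModel = field(default_factory=lambda: DEFAULT_BOTTLENECK)
    im_params: IMParams = field(default_factory=lambda: DEFAULT_IM)
    theta_site_by_class: dict[str, float] = field(
        default_factory=lambda: {"coding": 0.004, "promoter": 0.008}
    )
    rho_per_bp: float = 0.023
    coding_fraction: float = 0.8
    # PRF group settings: group -> (n_loci, hyper mean gamma, hyper sd gamma)
    prf_groups: dict[str, tuple[int, float, float]] = field(
        default_factory=lambda: {"disease": (20, 2.0, 1.0), "wood": (12, 0.0, 0.5)}
    )
    prf_theta_s: float = 3.0
    prf_theta_r: float = 3.0
    prf_tau_div: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.theta_site_by_class.values()):
            raise ValueError("theta must be >= 0")
        if not 0 < self.coding_fraction <= 1:
            raise ValueError("coding_fraction must be in (0, 1]")


@dataclass
class SyntheticLocus:
    alignment: LocusAlignment
    truth: dict


def _sequences_from_mutations(
    ref: np.ndarray, mutations: list[tuple[int, int]], n: int, rng: np.random.Generator
) -> list[str]:
    seqs = np.tile(ref, (n, 1))
    for site, mask in mutations:
        alt_choices = _BASES[_BASES != ref[site]]
        alt = alt_choices[rng.integers(3)]
        carriers = [i for i in range(n) if mask >> i & 1]
        seqs[carriers, site] = alt
    return ["".join(row) for row in seqs]


def generate_locus_set(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> list[SyntheticLocus]:
    """Within-species locus set under ``cfg.demography``.

    Coding loci carry a single in-frame forward-strand ORF covering
    ``coding_fraction`` of the aligned length (rounded to whole codons).
    The truth manifest records the model, class, per-site theta, length and
    every mutation's site and carrier mask.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out: list[SyntheticLocus] = []
    for cls, k in cfg.n_loci_per_class.items():
        theta_site = cfg.theta_site_by_class[cls]
        for j in range(k):
            L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            mutations = simulate_locus_patterns(
                cfg.n1, cfg.demography, cfg.rho_per_bp, L, theta_site, rng
            )
            ref = _BASES[rng.integers(4, size=L)]
            seqs = _sequences_from_mutations(ref, mutations, cfg.n1, rng)
            segments = []
            if cls == "coding":
                span = int(L * cfg.coding_fraction) // 3 * 3
                start = (L - span) // 2
                segments = [(start, start + span, 0, "+")]
            locus_id = f"{cls}_{j:03d}"
            aln = LocusAlignment(
                locus_id=locus_id,
                sequences=[(f"{locus_id}_s{i}", "taeda", s) for i, s in enumerate(seqs)],
                length=L,
                diversity_class=cls,
                coding_segments=segments,
            )
            out.append(
                SyntheticLocus(
                    alignment=aln,
                    truth={
                        "locus_id": locus_id,
                        "class": cls,
                        "L": L,
                        "theta_site": theta_site,
                        "n_mutations": len(mutations),
                        "mutations": [[s, m] for s, m in mutations],
                    },
                )
            )
    return out


def generate_two_species(
    cfg: SyntheticConfig, n_loci: int = 27, rng: np.random.Generator | None = None
) -> tuple[list[SyntheticLocus], list[IMCounts]]:
    """Two-species locus set under ``cfg.im_params``.

    Alignments contain ``n1`` ingroup and ``n2`` outgroup gametes; the truth
    manifest records the realised category of every variable site, and the
    returned :class:`IMCounts` are the exact truth quadruplets.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    loci: list[SyntheticLocus] = []
    truth_counts: list[IMCounts] = []
    n_tot = cfg.n1 + cfg.n2
    for j in range(n_loci):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        theta_locus = cfg.im_params.theta1  # per locus, species-1 scale
        locus_id = f"im_{j:03d}"
        counts, muts = simulate_im_patterns(
            cfg.n1, cfg.n2, cfg.im_params, theta_locus, rng, locus_id=locus_id
        )
        # place the mutations at distinct sites of a random reference
        sites = rng.choice(L, size=len(muts), replace=False) if muts else np.array([], int)
        placed = [(int(s), mask) for s, (mask, _cat) in zip(sites, muts)]
        ref = _BASES[rng.integers(4, size=L)]
        seqs = _sequences_from_mutations(ref, placed, n_tot, rng)
        names = [(f"{locus_id}_t{i}", "taeda", seqs[i]) for i in range(cfg.n1)] + [
            (f"{locus_id}_y{i}", "sylvestris", seqs[cfg.n1 + i]) for i in range(cfg.n2)
        ]
        aln = LocusAlignment(
            locus_id=locus_id, sequences=names, length=L, diversity_class="coding"
        )
        loci.append(
            SyntheticLocus(
                alignment=aln,
                truth={
                    "locus_id": locus_id,
                    "L": L,
                    "theta_locus": theta_locus,
                    "sites": [
                        {"site": int(s), "mask": mask, "category": cat}
                        for s, (mask, cat) in zip(sites, muts)
                    ],
                    "counts": counts.as_array().tolist(),
                },
            )
        )
        truth_counts.append(counts)
    return loci, truth_counts


def generate_prf_tables(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[list[MKTable], dict[str, np.ndarray]]:
    """MK tables drawn from the PRF Poisson model at known selection.

    Per group, locus selection coefficients are Normal(hyper mean, hyper
    sd^2); silent/replacement mutation parameters are jittered lognormally
    around the configured values.  Returns the tables and the true gamma per
    locus keyed by group.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tables: list[MKTable] = []
    truth: dict[str, np.ndarray] = {}
    n = cfg.n1
    a_n = harmonic(n - 1)
    for group, (k, mu, sd) in cfg.prf_groups.items():
        gammas = rng.normal(mu, sd, size=k)
        truth[group] = gammas
        for j, gamma in enumerate(gammas):
            th_s = cfg.prf_theta_s * rng.lognormal(0.0, 0.3)
            th_r = cfg.prf_theta_r * rng.lognormal(0.0, 0.3)
            e_ps = th_s * a_n
            e_pr = th_r * prf_polymorphism_factor(gamma, n)
            e_ds = th_s * cfg.prf_tau_div
            e_dr = th_r * cfg.prf_tau_div * prf_fixation_factor(gamma)
            tables.append(
                MKTable(
                    locus_id=f"{group}_{j:03d}",
                    group=group,
                    Ps=int(rng.poisson(e_ps)),
                    Pr=int(rng.poisson(e_pr)),
                    Ds=int(rng.poisson(e_ds)),
                    Dr=int(rng.poisson(e_dr)),
                    n=n,
                )
            )
    return tables, truth


def generate_segregation(
    families: int,
    expected_ratio,
    progeny_per_family: int,
    seed: int,
) -> np.ndarray:
    """Multinomial genotype-class counts per family (rows) for Mendelian
    segregation checks; ~16 progeny per family matches the study's
    family-based association population."""
    ratio = np.asarray(expected_ratio, dtype=float)
    if np.any(ratio < 0) or not np.isclose(ratio.sum(), 1.0):
        raise ValueError("expected_ratio must be a probability vector")
    rng = np.random.default_rng(seed)
    return rng.multinomial(progeny_per_family, ratio, size=families)


def write_locus_set(
    loci: list[SyntheticLocus],
    outdir: str | Path,
    species_map_name: str = "species_map.tsv",
) -> None:
    """Write FASTA per locus, a combined annotation TSV, a species map and
    the truth manifest (JSON) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann_lines = []
    sp_lines = []
    manifest = []
    for sl in loci:
        aln = sl.alignment
        fasta = []
        for sid, sp, seq in aln.sequences:
            fasta.append(f">{sid}\n{seq}")
            sp_lines.append(f"{sid}\t{sp}")
        (outdir / f"{aln.locus_id}.fasta").write_text("\n".join(fasta) + "\n")
        for start, end, frame, strand in aln.coding_segments:
            ann_lines.append(f"{aln.locus_id}\t{start}\t{end}\t{frame}\t{strand}")
        manifest.append(sl.truth)
    (outdir / "annotation.tsv").write_text("\n".join(ann_lines) + "\n")
    (outdir / species_map_name).write_text("\n".join(sp_lines) + "\n")
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=1))
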