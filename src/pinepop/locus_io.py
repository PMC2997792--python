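"""Reading and classifying per-locus haploid alignments.

Loci are aligned FASTA files of haploid gametes (conifer megagametophyte
sequences are phase-free haploids), optionally including one or two outgroup
gametes from a second species.  Variable columns are extracted into a
:class:`SiteTable`, classified as silent / replacement / noncoding against a
coding annotation, and biallelic sites are binned into the four polymorphism
categories of the two-species isolation analysis (exclusive to either
species, shared, or fixed).

Coordinates are 0-based half-open throughout.  Columns containing a gap or an
``N`` in any sequence are masked and never contribute to any count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "LocusAlignment",
    "Site",
    "SiteTable",
    "IMCounts",
    "read_fasta_alignment",
    "read_species_map",
    "read_annotation",
    "call_variants",
    "classify_site",
    "im_classify",
]

_NUCS = frozenset("ACGT")


@dataclass
class LocusAlignment:
    """A haploid multiple-sequence alignment for one locus."""

    locus_id: str
    sequences: list[tuple[str, str, str]]  # (sample_id, species, sequence)
    length: int
    diversity_class: str = "coding"  # {"coding", "promoter"}
    coding_segments: list[tuple[int, int, int, str]] = field(default_factory=list)
    column_mask: np.ndarray | None = None  # True = usable

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"{self.locus_id}: empty alignment")
        for sid, _, seq in self.sequences:
            if len(seq) != self.length:
                raise ValueError(
                    f"{self.locus_id}: sequence {sid} has length {len(seq)}, "
                    f"alignment length is {self.length}"
                )
        for start, end, frame, strand in self.coding_segments:
            if not (0 <= start < end <= self.length):
                raise ValueError(
                    f"{self.locus_id}: coding segment [{start}, {end}) outside "
                    f"[0, {self.length})"
                )
            if frame not in (0, 1, 2) or strand not in ("+", "-"):
                raise ValueError(f"{self.locus_id}: bad frame/strand {frame}/{strand}")
        segs = sorted(self.coding_segments)
        for (s1, e1, *_), (s2, _, *_) in zip(segs, segs[1:]):
            if s2 < e1:
                raise ValueError(f"{self.locus_id}: overlapping coding segments")
        if self.column_mask is None:
            self.column_mask = self._default_mask()
        self.column_mask = np.asarray(self.column_mask, dtype=bool)
        if self.column_mask.shape != (self.length,):
            raise ValueError(f"{self.locus_id}: column_mask has wrong length")

    def _default_mask(self) -> np.ndarray:
        mask = np.ones(self.length, dtype=bool)
        for _, _, seq in self.sequences:
            arr = np.frombuffer(seq.upper().encode(), dtype="S1")
            mask &= np.isin(arr, [b"A", b"C", b"G", b"T"])
        return mask

    @property
    def species_counts(self) -> Counter:
        return Counter(sp for _, sp, _ in self.sequences)

    def column(self, j: int) -> list[tuple[str, str]]:
        """(species, base) pairs at column ``j``."""
        return [(sp, seq[j].upper()) for _, sp, seq in self.sequences]

    def segment_at(self, j: int) -> tuple[int, int, int, str] | None:
        for seg in self.coding_segments:
            if seg[0] <= j < seg[1]:
                return seg
        return None


@dataclass
class Site:
    """One variable alignment column."""

    column: int
    counts: dict[str, Counter]  # species -> allele counter
    biallelic: bool
    site_class: str  # {"silent", "replacement", "noncoding", "unclassified"}
    ancestral: str | None = None

    @property
    def alleles(self) -> list[str]:
        pooled: Counter = Counter()
        for c in self.counts.values():
            pooled.update(c)
        return sorted(pooled)

    def pooled_counts(self) -> Counter:
        pooled: Counter = Counter()
        for c in self.counts.values():
            pooled.update(c)
        return pooled


@dataclass
class SiteTable:
    locus_id: str
    sites: list[Site]
    sample_sizes: dict[str, int]  # declared per-species sample size

    def biallelic_sites(self) -> list[Site]:
        return [s for s in self.sites if s.biallelic]

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class IMCounts:
    """Per-locus polymorphism-category counts for the two-species analysis."""

    locus_id: str
    s_x1: int
    s_x2: int
    s_shared: int
    s_fixed: int

    def __post_init__(self) -> None:
        if min(self.s_x1, self.s_x2, self.s_shared, self.s_fixed) < 0:
            raise ValueError("IM counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.s_x1, self.s_x2, self.s_shared, self.s_fixed])

    @property
    def total(self) -> int:
        return self.s_x1 + self.s_x2 + self.s_shared + self.s_fixed


def read_species_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sample_id <TAB> species."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sid, sp = line.split("\t")[:2]
        out[sid] = sp
    return out


def read_annotation(path: str | Path) -> dict[str, list[tuple[int, int, int, str]]]:
    """Coding-segment TSV: locus_id, start, end, frame, strand (0-based, half-open)."""
    out: dict[str, list[tuple[int, int, int, str]]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        locus, start, end, frame, strand = line.split("\t")[:5]
        out.setdefault(locus, []).append((int(start), int(end), int(frame), strand))
    return out


def read_fasta_alignment(
    path: str | Path,
    species_map: dict[str, str],
    annotation: list[tuple[int, int, int, str]] | None = None,
    locus_id: str | None = None,
    diversity_class: str = "coding",
) -> LocusAlignment:
    """Read one aligned FASTA into a :class:`LocusAlignment`.

    Every record id must appear in ``species_map``; unequal record lengths
    raise.  The column mask is set False wherever any sequence has a gap,
    ``N`` or other ambiguity code.
    """
    path = Path(path)
    aln = AlignIO.read(str(path), "fasta")
    lengths = {len(rec.seq) for rec in aln}
    if len(lengths) != 1:
        raise ValueError(f"{path}: unequal sequence lengths {sorted(lengths)}")
    seqs = []
    for rec in aln:
        if rec.id not in species_map:
            raise KeyError(f"{path}: sample {rec.id!r} missing from species map")
        seqs.append((rec.id, species_map[rec.id], str(rec.seq).upper()))
    return LocusAlignment(
        locus_id=locus_id or path.stem,
        sequences=seqs,
        length=lengths.pop(),
        diversity_class=diversity_class,
        coding_segments=annotation or [],
    )


def call_variants(aln: LocusAlignment) -> SiteTable:
    """Extract variable unmasked columns with per-species allele counts.

    Sites with more than two alleles are retained but flagged
    ``biallelic=False`` and excluded from SFS / isolation-model counting
    downstream (infinite-sites models assume biallelic sites).
    """
    sizes = dict(aln.species_counts)
    sites: list[Site] = []
    for j in range(aln.length):
        if not aln.column_mask[j]:
            continue
        col = aln.column(j)
        alleles = {b for _, b in col if b in _NUCS}
        if len(alleles) < 2:
            continue
        counts: dict[str, Counter] = {sp: Counter() for sp in sizes}
        for sp, b in col:
            if b in _NUCS:
                counts[sp][b] += 1
        biallelic = len(alleles) == 2
        site_class = classify_site(aln, j) if biallelic else "unclassified"
        sites.append(Site(column=j, counts=counts, biallelic=biallelic, site_class=site_class))
    return SiteTable(locus_id=aln.locus_id, sites=sites, sample_sizes=sizes)


def _consensus_base(aln: LocusAlignment, j: int) -> str:
    bases = Counter(b for _, b in aln.column(j) if b in _NUCS)
    if not bases:
        return "N"
    return bases.most_common(1)[0][0]


def classify_site(aln: LocusAlignment, column: int) -> str:
    """Silent/replacement/noncoding classification of a biallelic column.

    The two alleles are substituted into the codon containing the column
    (codon context taken from the alignment consensus; annotations carry a
    frame and strand, minus-strand codons are reverse-complemented before
    lookup in the standard genetic code).  The result is symmetric in the two
    alleles.  Returns ``"unclassified"`` when the codon is incomplete or
    contains masked columns.
    """
    seg = aln.segment_at(column)
    if seg is None:
        return "noncoding"
    start, end, frame, strand = seg
    if strand == "+":
        offset = (column - start - frame) % 3
        codon_cols = [column - offset, column - offset + 1, column - offset + 2]
    else:
        # frame counted from the segment's right edge on the minus strand
        offset = (end - 1 - column - frame) % 3
        first = column + offset  # 5'-most column of the codon on the minus strand
        codon_cols = [first, first - 1, first - 2]
    for c in codon_cols:
        if not (start <= c < end) or not aln.column_mask[c]:
            return "unclassified"
    alleles = sorted({b for _, b in aln.column(column) if b in _NUCS})
    if len(alleles) != 2:
        raise ValueError(f"{aln.locus_id} column {column}: classify_site needs a biallelic site")

    def translate(allele: str) -> str:
        bases = []
        for c in codon_cols:
            b = allele if c == column else _consensus_base(aln, c)
            if strand == "-":
                b = str(Seq(b).complement())
            bases.append(b)
        codon = "".join(bases)
        if codon in standard_dna_table.stop_codons:
            return "*"
        return standard_dna_table.forward_table.get(codon, "X")

    aa = {translate(a) for a in alleles}
    return "silent" if len(aa) == 1 else "replacement"


def im_classify(sites: SiteTable, sp1: str, sp2: str) -> IMCounts:
    """Bin biallelic sites into the four isolation-model categories.

    Each counted site goes to exactly one of: polymorphic only in ``sp1``,
    polymorphic only in ``sp2``, segregating in both (shared), or fixed for
    different alleles (fixed difference).  Sites where either species has no
    non-missing allele are excluded, as are sites monomorphic and identical
    in both species.
    """
    for sp in (sp1, sp2):
        if sp not in sites.sample_sizes:
            raise KeyError(f"species {sp!r} not present in site table {sites.locus_id}")
    x1 = x2 = shared = fixed = 0
    for site in sites.biallelic_sites():
        c1, c2 = site.counts.get(sp1, Counter()), site.counts.get(sp2, Counter())
        if not c1 or not c2:
            continue
        poly1, poly2 = len(c1) > 1, len(c2) > 1
        if poly1 and poly2:
            shared += 1
        elif poly1:
            x1 += 1
        elif poly2:
            x2 += 1
        elif set(c1) != set(c2):
            fixed += 1
    return IMCounts(sites.locus_id, x1, x2, shared, fixed)
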