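"""Diploid genotype calls from pooled allele counts (Popoolation2 sync files).

Isofemale-derived *Drosophila* strains are close to fully homozygous, so a
pool of ~30 flies can be collapsed to a two-allele genotype per site: the
allele frequencies observed in the pool are extrapolated to two diploid
allele copies after depth and minor-allele filtering. Sites where the two
parental strains are fixed for distinct alleles ("divergent sites") are the
diagnostic markers used downstream for ancestry painting.

Filtering rules: sites with fewer than 10 reads are excluded, alleles below
25% of the total nucleotide count are discarded, and sites where more than
two alleles survive the frequency filter are excluded as tri-allelic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable, Iterator

NUCLEOTIDES = ("A", "T", "C", "G")

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_ALLELE_FREQ = 0.25


class SyncFormatError(ValueError):
    """Raised on a malformed sync line."""


class CallStatus(Enum):
    CALLED = "CALLED"
    LOW_DEPTH = "LOW_DEPTH"
    TRIALLELIC = "TRIALLELIC"


@dataclass(frozen=True)
class SiteCounts:
    """Per-site nucleotide counts for every pool in a sync file.

    ``counts_per_pool[i]`` maps ``A/T/C/G`` to read counts for pool *i*.
    The sync format also carries N and deletion columns; they are parsed
    but never contribute to depth (indels and ambiguous bases are not
    callable alleles here).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    counts_per_pool: tuple[dict[str, int], ...]


@dataclass(frozen=True)
class DiploidCall:
    """A strain's two-allele genotype at one site.

    ``alleles``/``dosage`` are parallel: ``(("A",), (2,))`` homozygous,
    ``(("A", "T"), (1, 1))`` heterozygous. Both are empty unless
    ``status`` is CALLED.
    """

    chrom: str
    pos: int
    alleles: tuple[str, ...]
    dosage: tuple[int, ...]
    status: CallStatus

    @property
    def is_hom(self) -> bool:
        return self.status is CallStatus.CALLED and len(self.alleles) == 1

    @property
    def is_het(self) -> bool:
        return self.status is CallStatus.CALLED and len(self.alleles) == 2


@dataclass(frozen=True)
class DivergentSite:
    """A site where each parental strain is fixed for a different allele."""

    chrom: str
    pos: int
    allele_p1: str
    allele_p2: str


def read_sync(stream: IO[str] | Iterable[str]) -> Iterator[SiteCounts]:
    """Lazily parse a sync stream: chrom, pos, ref, then per-pool counts.

    Each pool column is colon-separated ``A:T:C:G:N:del``. The number of
    pool columns must be constant across lines.

    Raises
    ------
    SyncFormatError
        On missing pool columns, inconsistent pool counts, or
        non-integer counts — with the offending line number.
    """
    n_pools: int | None = None
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise SyncFormatError(
                f"line {lineno}: expected chrom, pos, ref and >=1 pool column"
            )
        if n_pools is None:
            n_pools = len(fields) - 3
        elif len(fields) - 3 != n_pools:
            raise SyncFormatError(
                f"line {lineno}: {len(fields) - 3} pool columns, expected {n_pools}"
            )
        try:
            pos = int(fields[1])
            pools = []
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise ValueError(f"pool column {col!r} lacks 6 fields")
                a, t, c, g, _n, _dele = (int(x) for x in parts)
                pools.append({"A": a, "T": t, "C": c, "G": g})
        except ValueError as exc:
            raise SyncFormatError(f"line {lineno}: {exc}") from exc
        yield SiteCounts(fields[0], pos, fields[2], tuple(pools))


def call_diploid(
    site: SiteCounts,
    pool_index: int,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_allele_freq: float = DEFAULT_MIN_ALLELE_FREQ,
) -> DiploidCall:
    """Collapse one pool's counts at one site to a diploid genotype.

    Depth is the sum of A/T/C/G counts. Sites with depth < ``min_depth``
    are LOW_DEPTH. Alleles with frequency < ``min_allele_freq`` of the
    depth are discarded; if more than two survive the site is TRIALLELIC,
    one survivor is a homozygote ``(2,0)``, two survivors a heterozygote
    ``(1,1)``. The surviving-allele ratio beyond the frequency cut does
    not matter: near-homozygous strains plus the 25% floor already absorb
    sequencing error, so no fractional dosage is modelled.
    """
    counts = site.counts_per_pool[pool_index]
    depth = sum(counts[n] for n in NUCLEOTIDES)
    if depth < min_depth:
        return DiploidCall(site.chrom, site.pos, (), (), CallStatus.LOW_DEPTH)
    surviving = [n for n in NUCLEOTIDES if counts[n] / depth >= min_allele_freq]
    # keep a deterministic order: by count desc, then nucleotide
    surviving.sort(key=lambda n: (-counts[n], n))
    if len(surviving) > 2:
        return DiploidCall(site.chrom, site.pos, (), (), CallStatus.TRIALLELIC)
    if len(surviving) == 1:
        return DiploidCall(
            site.chrom, site.pos, (surviving[0],), (2,), CallStatus.CALLED
        )
    return DiploidCall(
        site.chrom, site.pos, tuple(surviving), (1, 1), CallStatus.CALLED
    )


def ascertain_divergent_sites(
    parent1_calls: Iterable[DiploidCall],
    parent2_calls: Iterable[DiploidCall],
) -> list[DivergentSite]:
    """Find sites with distinct alleles fixed in each parental strain.

    Both inputs must be position-sorted within chromosomes and cover the
    same sites in the same order (calls made from the same sync stream
    satisfy this). A site is retained only when both parents are CALLED,
    both homozygous, and for different alleles; LOW_DEPTH, TRIALLELIC and
    heterozygous sites are dropped.

    Raises
    ------
    ValueError
        If the two call streams disagree on site order, or positions run
        backwards within a chromosome.
    """
    out: list[DivergentSite] = []
    last: dict[str, int] = {}
    for c1, c2 in zip(parent1_calls, parent2_calls, strict=True):
        if (c1.chrom, c1.pos) != (c2.chrom, c2.pos):
            raise ValueError(
                f"parental call streams out of register: "
                f"{c1.chrom}:{c1.pos} vs {c2.chrom}:{c2.pos}"
            )
        if c1.chrom in last and c1.pos <= last[c1.chrom]:
            raise ValueError(
                f"calls not position-sorted at {c1.chrom}:{c1.pos}"
            )
        last[c1.chrom] = c1.pos
        if c1.is_hom and c2.is_hom and c1.alleles[0] != c2.alleles[0]:
            out.append(DivergentSite(c1.chrom, c1.pos, c1.alleles[0], c2.alleles[0]))
    return out


def write_divergent_bed(sites: Iterable[DivergentSite], stream: IO[str]) -> None:
    """BED-like TSV export (0-based half-open): chrom, pos-1, pos, p1, p2."""
    for s in sites:
        stream.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.allele_p1}\t{s.allele_p2}\n")


def read_divergent_bed(stream: IO[str] | Iterable[str]) -> list[DivergentSite]:
    """Read the BED-like divergent-site TSV back to 1-based sites."""
    out = []
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        chrom, _start, end, p1, p2 = line.split("\t")[:5]
        out.append(DivergentSite(chrom, int(end), p1, p2))
    return out
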