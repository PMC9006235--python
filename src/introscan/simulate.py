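"""Forward simulator of a selective-backcross introgression experiment.

Emulates the breeding design that produced the introgressed strains: a
*D. yakuba* x *D. santomea* cross (fertile F1 females, sterile F1
males), a backcross of F1 females to recurrent *D. yakuba* males, then
mass culture with truncation selection in which each generation the ~50
lightest females seed the next bottle. Because females are assumed to
have mated before being scored — many with sterile males — selection on
the female phenotype is inefficient, which is the dynamic of interest.

Individuals carry ancestry-painted chromosomes: each haplotype is a set
of segments labelled *yak* (recipient) or *san* (donor). Female meiosis
recombines with Poisson crossover counts and uniform positions (Haldane,
no interference); male meiosis is achiasmate, as in *Drosophila*. Males
are hemizygous for the X.

The module emits every input the analysis modules consume — pooled sync
counts at divergent sites, pigmentation score tables, and mating-assay
counts under a preference matrix — so the whole pipeline is testable on
synthetic data with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

import numpy as np

RECIPIENT = 0  # D. yakuba (recurrent parent)
DONOR = 1  # D. santomea

SPECIES_CODE = {"yak": RECIPIENT, "san": DONOR}

#: Chromosome-arm lengths (bp) approximating the D. yakuba karyotype.
DEFAULT_CHROM_LENGTHS = {
    "X": 21_800_000,
    "2L": 23_500_000,
    "2R": 21_100_000,
    "3L": 24_200_000,
    "3R": 28_100_000,
}


class PopulationCrashed(RuntimeError):
    """Raised when a generation has no fertile males (or no breeding pairs)."""


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genome and haplotypes


@dataclass
class GenomeModel:
    """Chromosome structure and meiotic parameters.

    ``recomb_rate`` is the expected crossover count per chromosome per
    female meiosis (Poisson, no interference); ``divergent_density`` is
    diagnostic sites per kb when emitting pooled counts.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    recomb_rate: float = 1.0
    divergent_density: float = 0.5  # sites per kb

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.recomb_rate < 0 or self.divergent_density < 0:
            raise ValueError("rates must be non-negative")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())


class Haplotype:
    """One chromosome copy as ancestry segments.

    Segment *i* covers positions ``(ends[i-1], ends[i]]`` (1-based), with
    ``ends[-1]`` equal to the chromosome length; ``anc[i]`` is RECIPIENT
    or DONOR. Adjacent same-source segments are kept merged.
    """

    __slots__ = ("ends", "anc")

    def __init__(self, ends: np.ndarray, anc: np.ndarray):
        self.ends = ends
        self.anc = anc

    @classmethod
    def uniform(cls, length: int, source: int) -> "Haplotype":
        return cls(np.array([length], dtype=np.int64), np.array([source], dtype=np.uint8))

    def anc_at(self, pos: np.ndarray | int) -> np.ndarray | int:
        """Ancestry source at 1-based position(s)."""
        idx = np.searchsorted(self.ends, pos, side="left")
        return self.anc[idx]

    def donor_bp(self) -> int:
        starts = np.concatenate(([0], self.ends[:-1]))
        return int(((self.ends - starts) * (self.anc == DONOR)).sum())

    def tiles(self, length: int) -> bool:
        return (
            len(self.ends) == len(self.anc) > 0
            and int(self.ends[-1]) == length
            and bool(np.all(np.diff(self.ends) > 0))
        )

    def with_tract(self, start: int, end: int, source: int) -> "Haplotype":
        """Copy of this haplotype with [start, end] forced to ``source``."""
        length = int(self.ends[-1])
        pts = [start - 1, end] if start > 1 else [end]
        ends = np.unique(np.concatenate((self.ends, np.array(pts, dtype=np.int64))))
        ends = ends[(ends > 0) & (ends <= length)]
        anc = np.asarray(self.anc_at(ends), dtype=np.uint8).copy()
        anc[(ends >= start) & (ends <= end)] = source
        return _merged(ends, anc)


def _merged(ends: np.ndarray, anc: np.ndarray) -> Haplotype:
    """Merge adjacent segments sharing a source."""
    if len(ends) > 1:
        keep = np.concatenate((anc[:-1] != anc[1:], [True]))
        ends, anc = ends[keep], anc[keep]
    return Haplotype(ends, anc)


def _recombine(
    h1: Haplotype, h2: Haplotype, length: int, rate: float, rng: np.random.Generator
) -> Haplotype:
    """One recombinant gamete from two haplotypes (Haldane crossovers)."""
    n_xo = rng.poisson(rate)
    cur = int(rng.integers(2))
    if n_xo == 0:
        src = h1 if cur == 0 else h2
        return Haplotype(src.ends.copy(), src.anc.copy())
    cuts = np.unique(rng.integers(1, length, size=n_xo))
    haps = (h1, h2)
    ends_out: list[np.ndarray] = []
    anc_out: list[np.ndarray] = []
    prev = 0
    for cut in np.concatenate((cuts, [length])):
        h = haps[cur]
        i0 = int(np.searchsorted(h.ends, prev, side="right"))
        i1 = int(np.searchsorted(h.ends, cut, side="left"))
        seg_ends = np.concatenate((h.ends[i0:i1], [cut]))
        seg_anc = np.concatenate((h.anc[i0:i1], [h.anc[min(i1, len(h.anc) - 1)]]))
        ends_out.append(seg_ends)
        anc_out.append(seg_anc.astype(np.uint8))
        prev = int(cut)
        cur ^= 1
    return _merged(np.concatenate(ends_out), np.concatenate(anc_out))


# ---------------------------------------------------------------------------
# individuals


@dataclass
class Individual:
    """A diploid fly with ancestry-painted chromosomes.

    ``haplotypes[chrom]`` holds two copies for autosomes and female X,
    one copy for the male X (hemizygosity).
    """

    sex: str  # "F" or "M"
    haplotypes: dict[str, list[Haplotype]]
    fertile: bool = True

    def donor_fraction(self, genome: GenomeModel) -> float:
        """Genome-wide donor ancestry over this individual's allele copies."""
        donor = total = 0
        for chrom, haps in self.haplotypes.items():
            for h in haps:
                donor += h.donor_bp()
                total += genome.chrom_lengths[chrom]
        return donor / total

    def dosage(self, chrom: str, pos: int, x_compensation: bool = True) -> int:
        """Donor-allele dose at a locus, 0-2.

        A hemizygous male X counts as two doses when ``x_compensation``
        is on (dosage compensation makes one X copy act like two).
        """
        haps = self.haplotypes.get(chrom, [])
        # loci beyond a (scaled-down) chromosome contribute no donor dose
        d = sum(
            pos <= int(h.ends[-1]) and int(h.anc_at(pos)) == DONOR for h in haps
        )
        if chrom == "X" and self.sex == "M" and len(haps) == 1 and x_compensation:
            d *= 2
        return d


def make_pure(
    genome: GenomeModel, species: str, sex: str, fertile: bool = True
) -> Individual:
    """A pure-species individual (both parents same species)."""
    code = SPECIES_CODE[species]
    haps = {}
    for chrom, length in genome.chrom_lengths.items():
        n = 1 if (chrom == "X" and sex == "M") else 2
        haps[chrom] = [Haplotype.uniform(length, code) for _ in range(n)]
    return Individual(sex=sex, haplotypes=haps, fertile=fertile)


# ---------------------------------------------------------------------------
# sterility


@dataclass
class SterilityModel:
    """Hybrid male sterility via incompatibility loci.

    A male is sterile when any chromosome copy carries donor ancestry at
    any listed locus. The defaults are illustrative (the real number and
    strength of incompatibility loci is unknown): two X-linked loci —
    hybrid male sterility is disproportionately X-linked in *Drosophila*,
    and the X loci sit near the major pigmentation genes, reflecting the
    initial linkage between pigmentation and incompatibility factors
    whose breakdown by recombination is what eventually let selection
    advance — plus one autosomal locus, which guarantees that F1 males
    (heterozygous genome-wide) are sterile regardless of cross direction.
    """

    loci: list[tuple[str, int]] = field(
        default_factory=lambda: [("X", 1_400_000), ("X", 16_300_000), ("3R", 8_000_000)]
    )

    def is_sterile(self, ind: Individual) -> bool:
        if ind.sex != "M":
            return False
        for chrom, pos in self.loci:
            # loci beyond a (scaled-down) chromosome are inert
            for h in ind.haplotypes.get(chrom, []):
                if pos <= int(h.ends[-1]) and int(h.anc_at(pos)) == DONOR:
                    return True
        return False

    def apply(self, ind: Individual) -> Individual:
        ind.fertile = not self.is_sterile(ind)
        return ind


# ---------------------------------------------------------------------------
# trait architecture


@dataclass(frozen=True)
class TraitLocus:
    """One pigmentation locus: additive per-copy effects per segment.

    Negative effects lighten. ``sex_factor`` scales the effect in each
    sex (pigmentation loci act more strongly in females here, as female
    pigmentation was the more variable and the selected trait).
    """

    chrom: str
    pos: int
    effects: tuple[float, ...]  # one per analysis segment (6)
    sex_factor: dict[str, float] = field(
        default_factory=lambda: {"F": 1.0, "M": 0.5}
    )


def _default_loci() -> list[TraitLocus]:
    # Placements mirror the major pigmentation genes on the yakuba map:
    # y near the X tip, t mid-distal X, pdm3 on 2L.
    return [
        TraitLocus("X", 170_000, (0.0, 0.0, -0.5, -1.0, -1.5, -1.5)),
        TraitLocus("X", 17_680_000, (0.0, -0.5, -0.5, -1.0, -1.5, -2.0)),
        TraitLocus("2L", 17_300_000, (0.0, 0.0, -0.5, -0.5, -1.0, -0.5)),
    ]


@dataclass
class TraitArchitecture:
    """Additive genotype-to-phenotype map for the six analysis segments.

    ``baseline`` is the pure recipient (*D. yakuba*) expectation per
    segment and sex, in score classes 0-10; donor alleles subtract via
    the locus effects. Scores are Gaussian-noised, rounded and clipped
    to the 11 classes.
    """

    loci: list[TraitLocus] = field(default_factory=_default_loci)
    baseline: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "F": (3.0, 4.0, 5.0, 7.0, 9.0, 10.0),
            "M": (3.0, 4.0, 6.0, 8.0, 9.0, 10.0),
        }
    )
    noise_sd: float = 0.75
    x_dosage_compensation: bool = True

    def segment_means(self, ind: Individual) -> np.ndarray:
        """Expected (pre-noise, pre-rounding) segment scores."""
        mu = np.array(self.baseline[ind.sex], dtype=float)
        for locus in self.loci:
            d = ind.dosage(locus.chrom, locus.pos, self.x_dosage_compensation)
            if d:
                mu += d * locus.sex_factor[ind.sex] * np.array(locus.effects)
        return mu

    def scores(self, ind: Individual, rng: np.random.Generator) -> tuple[int, ...]:
        mu = self.segment_means(ind)
        noisy = mu + rng.normal(0.0, self.noise_sd, size=mu.shape)
        return tuple(int(s) for s in np.clip(np.rint(noisy), 0, 10))


# ---------------------------------------------------------------------------
# crosses


def _gamete(ind: Individual, chrom: str, genome: GenomeModel, rng) -> Haplotype:
    """One gamete haplotype: recombinant from females, whole-copy from males."""
    haps = ind.haplotypes[chrom]
    if ind.sex == "F":
        return _recombine(
            haps[0], haps[1], genome.chrom_lengths[chrom], genome.recomb_rate, rng
        )
    # achiasmate male meiosis: transmit an intact copy
    h = haps[int(rng.integers(len(haps)))]
    return Haplotype(h.ends.copy(), h.anc.copy())


def mate(
    mother: Individual,
    father: Individual,
    genome: GenomeModel,
    rng: np.random.Generator,
    sterility: SterilityModel | None = None,
) -> Individual:
    """One offspring; sex set by whether the father transmits his X."""
    sex = "F" if rng.integers(2) == 0 else "M"
    haps: dict[str, list[Haplotype]] = {}
    for chrom in genome.chroms:
        mat = _gamete(mother, chrom, genome, rng)
        if chrom == "X" and sex == "M":
            haps[chrom] = [mat]  # sons: maternal X only
        else:
            haps[chrom] = [mat, _gamete(father, chrom, genome, rng)]
    child = Individual(sex=sex, haplotypes=haps)
    if sterility is not None:
        sterility.apply(child)
    return child


def make_f1(
    genome: GenomeModel,
    maternal: str = "yak",
    n: int = 100,
    seed: int | np.random.Generator = 0,
    sterility: SterilityModel | None = None,
) -> list[Individual]:
    """F1s of a species cross (default: yakuba mothers x santomea males)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = _as_rng(seed)
    paternal = "san" if maternal == "yak" else "yak"
    mother = make_pure(genome, maternal, "F")
    father = make_pure(genome, paternal, "M")
    if sterility is None:
        sterility = SterilityModel()
    return [mate(mother, father, genome, rng, sterility) for _ in range(n)]


def backcross(
    f1_females: Sequence[Individual],
    recurrent_males: Sequence[Individual],
    genome: GenomeModel,
    seed: int | np.random.Generator = 0,
    n_offspring: int | None = None,
    sterility: SterilityModel | None = None,
) -> list[Individual]:
    """Backcross progeny: F1 females x recurrent-parent males."""
    rng = _as_rng(seed)
    if not all(f.sex == "F" for f in f1_females):
        raise ValueError("f1_females must all be female")
    if not all(m.sex == "M" for m in recurrent_males):
        raise ValueError("recurrent_males must all be male")
    if sterility is None:
        sterility = SterilityModel()
    n = n_offspring if n_offspring is not None else len(f1_females)
    out = []
    for _ in range(n):
        mother = f1_females[int(rng.integers(len(f1_females)))]
        father = recurrent_males[int(rng.integers(len(recurrent_males)))]
        out.append(mate(mother, father, genome, rng, sterility))
    return out


# ---------------------------------------------------------------------------
# mass culture with truncation selection


@dataclass
class SelectionScheme:
    """Truncation selection on female pigmentation.

    Each generation every female mates once with a uniformly drawn male
    (sterile males compete for matings but sire nothing — females are
    assumed mated before scoring), then the ``select_n`` most extreme
    females in ``direction`` ("light" or "dark", by total pigmentation
    score) are transferred; those among them with a fertile mate produce
    the next generation. ``select_n >= #females`` makes selection
    vacuous.
    """

    select_n: int = 50
    direction: str = "light"
    sterile_males_compete: bool = True
    mate_before_selection: bool = True


def evolve(
    population: list[Individual],
    generations: int,
    genome: GenomeModel,
    architecture: TraitArchitecture | None = None,
    sterility: SterilityModel | None = None,
    selection: SelectionScheme | None = None,
    census: int = 1000,
    seed: int | np.random.Generator = 0,
    trait_loci_to_track: Sequence[tuple[str, int]] | None = None,
) -> tuple[list[Individual], list[dict]]:
    """Run mass-culture generations; return (final population, summaries).

    Per-generation summaries record mean genome-wide donor fraction,
    donor allele frequency at each tracked locus (defaults to the
    architecture's loci), and the fraction of sterile males.

    Raises
    ------
    PopulationCrashed
        When no fertile male exists, or no selected female has a fertile
        mate.
    """
    rng = _as_rng(seed)
    arch = architecture if architecture is not None else TraitArchitecture()
    ster = sterility if sterility is not None else SterilityModel()
    sel = selection if selection is not None else SelectionScheme()
    track = (
        list(trait_loci_to_track)
        if trait_loci_to_track is not None
        else [(l.chrom, l.pos) for l in arch.loci]
    )
    # drop tracked loci outside a (scaled-down) genome
    track = [
        (c, p)
        for c, p in track
        if c in genome.chrom_lengths and p <= genome.chrom_lengths[c]
    ]

    pop = list(population)
    summaries = [_summarise(pop, genome, track, generation=0)]
    for gen in range(1, generations + 1):
        females = [i for i in pop if i.sex == "F"]
        males = [i for i in pop if i.sex == "M"]
        fertile_males = [m for m in males if m.fertile]
        if not females or not fertile_males:
            raise PopulationCrashed(
                f"generation {gen}: {len(females)} females, "
                f"{len(fertile_males)} fertile males"
            )
        mate_pool = males if sel.sterile_males_compete else fertile_males
        mates = [mate_pool[int(rng.integers(len(mate_pool)))] for _ in females]

        if sel.select_n < len(females):
            totals = np.array(
                [arch.scores(f, rng) for f in females], dtype=float
            ).sum(axis=1)
            order = np.argsort(totals, kind="stable")
            if sel.direction == "dark":
                order = order[::-1]
            chosen = order[: sel.select_n]
        else:
            chosen = np.arange(len(females))

        pairs = [(females[i], mates[i]) for i in chosen if mates[i].fertile]
        if not pairs:
            raise PopulationCrashed(
                f"generation {gen}: no selected female mated a fertile male"
            )
        pop = [
            mate(*pairs[int(rng.integers(len(pairs)))], genome, rng, ster)
            for _ in range(census)
        ]
        summaries.append(_summarise(pop, genome, track, generation=gen))
    return pop, summaries


def _summarise(
    pop: list[Individual],
    genome: GenomeModel,
    track: Sequence[tuple[str, int]],
    generation: int,
) -> dict:
    males = [i for i in pop if i.sex == "M"]
    autosomes = [c for c in genome.chroms if c != "X"]
    auto_donor = auto_total = 0
    for ind in pop:
        for chrom in autosomes:
            for h in ind.haplotypes[chrom]:
                auto_donor += h.donor_bp()
                auto_total += genome.chrom_lengths[chrom]
    summary = {
        "generation": generation,
        "n": len(pop),
        "mean_donor_fraction": float(
            np.mean([i.donor_fraction(genome) for i in pop])
        ),
        "mean_autosomal_donor_fraction": (
            auto_donor / auto_total if auto_total else float("nan")
        ),
        "fraction_sterile_males": (
            float(np.mean([not m.fertile for m in males])) if males else float("nan")
        ),
    }
    for chrom, pos in track:
        summary[f"donor_freq_{chrom}:{pos}"] = donor_allele_freq(pop, chrom, pos)
    return summary


def donor_allele_freq(pop: Sequence[Individual], chrom: str, pos: int) -> float:
    """Donor allele frequency at one position over all chromosome copies."""
    donor = total = 0
    for ind in pop:
        for h in ind.haplotypes[chrom]:
            donor += int(h.anc_at(pos)) == DONOR
            total += 1
    return donor / total


def plant_tract(
    pop: Iterable[Individual], chrom: str, start: int, end: int, source: int = DONOR
) -> list[Individual]:
    """Force an ancestry tract into every chromosome copy of a population.

    Used to create truth tracts with exactly known boundaries (e.g. a
    fixed donor tract around a pigmentation gene) for recovery tests.
    """
    out = []
    for ind in pop:
        haps = dict(ind.haplotypes)
        haps[chrom] = [h.with_tract(start, end, source) for h in haps[chrom]]
        out.append(replace(ind, haplotypes=haps))
    return out


def make_introgressed_strain(
    genome: GenomeModel,
    n: int,
    fixed_tracts: Sequence[tuple[str, int, int]] = (),
    intermediate_tracts: Sequence[tuple[str, int, int, float]] = (),
    residual_per_hap: float = 1.0,
    residual_len: int = 300_000,
    seed: int | np.random.Generator = 0,
) -> list[Individual]:
    """An introgressed strain with known-truth donor tracts.

    Emulates the composition of a long-established introgression line —
    a recipient-species background carrying a few donor tracts — with
    exactly known tract boundaries, the state reached only after many
    generations of selection plus recombinational sharpening (a freshly
    selected population instead carries broad hitchhiking halos around
    the selected loci). ``fixed_tracts`` (chrom, start, end) are planted
    in every chromosome copy; ``intermediate_tracts`` (chrom, start,
    end, freq) in each copy independently with probability ``freq``;
    per haplotype, Poisson(``residual_per_hap``) exponential-length
    private donor segments emulate residual segregating introgression.
    """
    rng = _as_rng(seed)
    pop = []
    for i in range(n):
        ind = make_pure(genome, "yak", "F" if i % 2 == 0 else "M")
        for chrom, haps in ind.haplotypes.items():
            length = genome.chrom_lengths[chrom]
            new = []
            for h in haps:
                for _ in range(rng.poisson(residual_per_hap)):
                    seg = max(1000, int(rng.exponential(residual_len)))
                    start = int(rng.integers(1, max(2, length - seg)))
                    h = h.with_tract(start, min(length, start + seg), DONOR)
                for c, s, e, freq in intermediate_tracts:
                    if c == chrom and rng.random() < freq:
                        h = h.with_tract(s, e, DONOR)
                for c, s, e in fixed_tracts:
                    if c == chrom:
                        h = h.with_tract(s, e, DONOR)
                new.append(h)
            ind.haplotypes[chrom] = new
        pop.append(ind)
    return pop


# ---------------------------------------------------------------------------
# emitters


def draw_divergent_positions(
    genome: GenomeModel, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Uniform-random divergent-site positions at the configured density."""
    sites = {}
    for chrom, length in genome.chrom_lengths.items():
        n = int(round(length / 1000 * genome.divergent_density))
        pos = np.unique(rng.integers(1, length + 1, size=n))
        sites[chrom] = pos
    return sites


def pool_donor_freq(
    pop: Sequence[Individual], chrom: str, positions: np.ndarray
) -> np.ndarray:
    """Donor allele frequency at many positions over a population's copies."""
    donor = np.zeros(len(positions), dtype=float)
    total = 0
    for ind in pop:
        for h in ind.haplotypes[chrom]:
            donor += np.asarray(h.anc_at(positions)) == DONOR
            total += 1
    return donor / total


def _read_counts(
    freq: np.ndarray,
    donor_base: np.ndarray,
    recip_base: np.ndarray,
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-site A/T/C/G counts: binomial sampling plus uniform read error."""
    n_sites = len(freq)
    counts = np.zeros((n_sites, 4), dtype=np.int64)
    donor_reads = rng.binomial(depth, freq)
    for true_base, n_reads in ((donor_base, donor_reads), (recip_base, depth - donor_reads)):
        errs = rng.binomial(n_reads, error_rate)
        np.add.at(counts, (np.arange(n_sites), true_base), n_reads - errs)
        for i in np.nonzero(errs)[0]:
            others = [b for b in range(4) if b != true_base[i]]
            wrong = rng.choice(others, size=errs[i])
            np.add.at(counts[i], wrong, 1)
    return counts


def emit_sync(
    populations: dict[str, Sequence[Individual]],
    genome: GenomeModel,
    depth: int = 50,
    error_rate: float = 0.001,
    seed: int | np.random.Generator = 0,
    positions: dict[str, np.ndarray] | None = None,
) -> tuple[list[str], list[str]]:
    """Pooled sync lines for the two parents plus admixed populations.

    Pool column order is: parent recipient (*yak*, fixed for the
    reference allele), parent donor (*san*, fixed for the alternative
    allele), then one column per entry of ``populations`` in order. At
    each divergent site the admixed pools' donor-allele counts are
    binomial draws at ``depth`` from the population allele frequency,
    with per-read error ``error_rate`` scattered uniformly over the
    other three nucleotides. Reproducible bit-for-bit given (config,
    seed).

    Returns (sync lines, pool names).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = _as_rng(seed)
    if positions is None:
        positions = draw_divergent_positions(genome, rng)
    bases = "ATCG"
    pool_names = ["yak", "san", *populations.keys()]
    lines: list[str] = []
    for chrom in genome.chroms:
        pos = positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        n_sites = len(pos)
        recip_base = rng.integers(0, 4, size=n_sites)
        shift = rng.integers(1, 4, size=n_sites)
        donor_base = (recip_base + shift) % 4  # distinct from recipient
        per_pool = [
            _read_counts(np.zeros(n_sites), donor_base, recip_base, depth, error_rate, rng),
            _read_counts(np.ones(n_sites), donor_base, recip_base, depth, error_rate, rng),
        ]
        for pop in populations.values():
            freq = pool_donor_freq(pop, chrom, pos)
            per_pool.append(
                _read_counts(freq, donor_base, recip_base, depth, error_rate, rng)
            )
        for i in range(n_sites):
            cols = "\t".join(
                ":".join(str(c) for c in counts[i]) + ":0:0" for counts in per_pool
            )
            lines.append(f"{chrom}\t{pos[i]}\t{bases[recip_base[i]]}\t{cols}")
    return lines, pool_names


def emit_phenotypes(
    population: Sequence[Individual],
    architecture: TraitArchitecture,
    seed: int | np.random.Generator = 0,
    strain: str = "sim",
    n_per_sex: int | None = None,
):
    """Pigmentation records for a sample of the population.

    With ``n_per_sex`` set, samples that many females and males (without
    replacement when possible), mirroring the 10-per-sex scoring design.
    """
    from .phenotype import PigmentationRecord

    rng = _as_rng(seed)
    inds = list(population)
    if n_per_sex is not None:
        chosen = []
        for sex in ("F", "M"):
            of_sex = [i for i in inds if i.sex == sex]
            k = min(n_per_sex, len(of_sex))
            idx = rng.choice(len(of_sex), size=k, replace=False)
            chosen.extend(of_sex[j] for j in idx)
        inds = chosen
    return [
        PigmentationRecord(
            individual=f"{strain}_{i}",
            strain=strain,
            sex=ind.sex,
            scores=architecture.scores(ind, rng),
        )
        for i, ind in enumerate(inds)
    ]


@dataclass
class PreferenceMatrix:
    """Relative acceptance probability per (female strain, male strain)."""

    accept: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for pair, p in self.accept.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"preference {pair} = {p} outside [0, 1]")

    def p(self, female: str, male: str) -> float:
        return self.accept[(female, male)]


def emit_nochoice_counts(
    preference: PreferenceMatrix,
    pairs: Sequence[tuple[str, str]],
    trials: int = 20,
    seed: int | np.random.Generator = 0,
) -> dict[tuple[str, str], tuple[int, int]]:
    """Successes per (female, male) strain pair: Binomial(trials, acceptance)."""
    rng = _as_rng(seed)
    return {
        (f, m): (int(rng.binomial(trials, preference.p(f, m))), trials)
        for f, m in pairs
    }


def emit_twochoice_counts(
    preference: PreferenceMatrix,
    focal_strain: str,
    own_strain: str,
    other_strain: str,
    n_trials: int,
    focal_sex: str = "F",
    seed: int | np.random.Generator = 0,
) -> tuple[int, int]:
    """(chose own, chose other) counts for one focal strain in a two-choice assay.

    Each trial copulates with probability equal to the mean of the two
    pairwise acceptance probabilities; given copulation, the mate is
    chosen proportionally to those probabilities. For a female focal the
    acceptance entries are (focal, candidate male); for a male focal,
    (candidate female, focal).
    """
    rng = _as_rng(seed)
    if focal_sex == "F":
        p_own = preference.p(focal_strain, own_strain)
        p_other = preference.p(focal_strain, other_strain)
    else:
        p_own = preference.p(own_strain, focal_strain)
        p_other = preference.p(other_strain, focal_strain)
    own = other = 0
    for _ in range(n_trials):
        if rng.random() >= (p_own + p_other) / 2.0:
            continue  # no copulation this trial
        tot = p_own + p_other
        if tot == 0:
            continue
        if rng.random() < p_own / tot:
            own += 1
        else:
            other += 1
    return own, other


def write_sync(lines: Iterable[str], stream: IO[str]) -> None:
    for line in lines:
        stream.write(line + "\n")
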