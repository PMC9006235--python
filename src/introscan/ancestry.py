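"""Windowed donor-ancestry along chromosomes and introgressed-locus calls.

An introgressed strain is genotyped at divergent sites (where the two
parental strains carry distinct fixed alleles). At each such site the
strain's two allele copies are matched against the parental alleles,
giving a donor-ancestry fraction of 0, 0.5 or 1. Fractions are averaged
in fixed 50-kb windows tiling each chromosome; windows are classified as
FIXED (mean donor ancestry >= 0.75), INTERMEDIATE (>= 0.40) or
BACKGROUND, and runs of classified windows are merged into introgressed
loci whose bounds are refined to the outermost informative sites. Loci
are finally annotated with overlapping genes and any members of a
watch-list of known pigmentation genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

from .poolgeno import DiploidCall, DivergentSite

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 50_000
DEFAULT_FIXED_THRESHOLD = 0.75
DEFAULT_INTERMEDIATE_THRESHOLD = 0.40

#: Pigmentation genes implicated in the D. yakuba / D. santomea difference.
DEFAULT_WATCHLIST = ("y", "t", "e", "pdm3", "Abd-B", "Gug")

FIXED = "FIXED"
INTERMEDIATE = "INTERMEDIATE"
BACKGROUND = "BACKGROUND"
MISSING = "MISSING"


@dataclass(frozen=True)
class SiteAncestry:
    """Donor-ancestry fraction of a strain's two allele copies at one site."""

    chrom: str
    pos: int  # 1-based
    donor_fraction: float  # 0, 0.5 or 1


@dataclass
class AncestryWindow:
    """One window of an ancestry track.

    ``mean_donor_fraction`` is None when the window holds fewer than the
    configured minimum number of informative sites; ``status`` is filled
    by :func:`classify_windows`.
    """

    chrom: str
    start: int  # 1-based
    end: int  # inclusive
    n_sites: int
    mean_donor_fraction: float | None
    status: str = MISSING


@dataclass
class IntrogressedLocus:
    """A merged run of classified windows, clipped to informative sites."""

    chrom: str
    start: int  # 1-based
    end: int  # inclusive
    status: str  # FIXED or INTERMEDIATE
    n_genes: int = 0
    candidates: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        """Locus length in bp, computed as end - start."""
        return self.end - self.start


def site_ancestry(
    admixed_call: DiploidCall, dsite: DivergentSite, donor: str = "p2"
) -> SiteAncestry | None:
    """Donor-allele dosage of the admixed strain at a divergent site.

    ``donor`` names which parent of the divergent-site pair is the donor
    species ("p2" by convention: parent 2 = *D. santomea*). Returns None
    (missing) when the admixed call is not CALLED or carries any allele
    matching neither parent.
    """
    if (admixed_call.chrom, admixed_call.pos) != (dsite.chrom, dsite.pos):
        raise ValueError(
            f"call at {admixed_call.chrom}:{admixed_call.pos} does not match "
            f"divergent site {dsite.chrom}:{dsite.pos}"
        )
    if not admixed_call.alleles:
        return None
    donor_allele = dsite.allele_p2 if donor == "p2" else dsite.allele_p1
    parental = {dsite.allele_p1, dsite.allele_p2}
    if any(a not in parental for a in admixed_call.alleles):
        return None
    copies = sum(
        d for a, d in zip(admixed_call.alleles, admixed_call.dosage) if a == donor_allele
    )
    return SiteAncestry(dsite.chrom, dsite.pos, copies / 2.0)


def window_ancestry(
    sites: Sequence[SiteAncestry],
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_sites: int = 1,
    chrom_lengths: dict[str, int] | None = None,
) -> list[AncestryWindow]:
    """Average donor fractions in fixed windows tiling each chromosome.

    Windows tile from position 1 in ``window_size`` steps ([1, 50000],
    [50001, 100000], ...). Sites must be position-sorted within each
    chromosome. When ``chrom_lengths`` is given, windows cover each
    chromosome to its stated length; otherwise they run to the window
    containing the last informative site. Windows with fewer than
    ``min_sites`` sites have no mean (MISSING).
    """
    by_chrom: dict[str, list[SiteAncestry]] = {}
    for s in sites:
        cs = by_chrom.setdefault(s.chrom, [])
        if cs and s.pos < cs[-1].pos:
            raise ValueError(f"sites not position-sorted at {s.chrom}:{s.pos}")
        cs.append(s)

    chroms = list(by_chrom)
    if chrom_lengths is not None:
        chroms = list(chrom_lengths)

    windows: list[AncestryWindow] = []
    for chrom in chroms:
        cs = by_chrom.get(chrom, [])
        if chrom_lengths is not None:
            span = chrom_lengths[chrom]
        elif cs:
            span = cs[-1].pos
        else:
            continue
        n_windows = (span + window_size - 1) // window_size
        sums = [0.0] * n_windows
        counts = [0] * n_windows
        for s in cs:
            idx = (s.pos - 1) // window_size
            sums[idx] += s.donor_fraction
            counts[idx] += 1
        for idx in range(n_windows):
            start = idx * window_size + 1
            mean = sums[idx] / counts[idx] if counts[idx] >= min_sites else None
            windows.append(
                AncestryWindow(chrom, start, start + window_size - 1, counts[idx], mean)
            )
    return windows


def classify_windows(
    windows: Iterable[AncestryWindow],
    fixed_threshold: float = DEFAULT_FIXED_THRESHOLD,
    intermediate_threshold: float = DEFAULT_INTERMEDIATE_THRESHOLD,
) -> list[AncestryWindow]:
    """Label windows FIXED / INTERMEDIATE / BACKGROUND by mean donor ancestry.

    Windows without a mean stay MISSING. Thresholds must satisfy
    0 < intermediate < fixed < 1.
    """
    if not (0.0 < intermediate_threshold < fixed_threshold < 1.0):
        raise ValueError(
            "thresholds must satisfy 0 < intermediate "
            f"({intermediate_threshold}) < fixed ({fixed_threshold}) < 1"
        )
    out = []
    for w in windows:
        if w.mean_donor_fraction is None:
            status = MISSING
        elif w.mean_donor_fraction >= fixed_threshold:
            status = FIXED
        elif w.mean_donor_fraction >= intermediate_threshold:
            status = INTERMEDIATE
        else:
            status = BACKGROUND
        out.append(replace(w, status=status))
    return out


def merge_loci(
    labeled: Sequence[AncestryWindow],
    sites: Sequence[SiteAncestry] | None = None,
    max_gap_windows: int = 1,
) -> list[IntrogressedLocus]:
    """Merge runs of classified windows into introgressed loci.

    A locus is a maximal run of FIXED/INTERMEDIATE windows on one
    chromosome, allowing up to ``max_gap_windows`` consecutive MISSING
    windows inside the run (divergent-site deserts should not split one
    biological tract); BACKGROUND always terminates a run. Locus status
    is FIXED when at least one window is FIXED and at least half of the
    labeled windows are FIXED, else INTERMEDIATE.

    Window-resolution bounds are clipped to the outermost informative
    sites when ``sites`` is provided, reproducing coordinate refinement
    below window resolution. Output is sorted and disjoint.
    """
    site_pos: dict[str, list[int]] = {}
    if sites is not None:
        for s in sites:
            site_pos.setdefault(s.chrom, []).append(s.pos)

    loci: list[IntrogressedLocus] = []
    run: list[AncestryWindow] = []
    pending_gap: list[AncestryWindow] = []

    def flush() -> None:
        if not run:
            return
        labeled_in_run = [w for w in run if w.status in (FIXED, INTERMEDIATE)]
        n_fixed = sum(1 for w in labeled_in_run if w.status == FIXED)
        status = (
            FIXED
            if n_fixed >= 1 and n_fixed * 2 >= len(labeled_in_run)
            else INTERMEDIATE
        )
        chrom = run[0].chrom
        start, end = run[0].start, run[-1].end
        inside = [p for p in site_pos.get(chrom, []) if start <= p <= end]
        if inside:
            start, end = min(inside), max(inside)
        loci.append(IntrogressedLocus(chrom, start, end, status))

    prev_chrom: str | None = None
    for w in labeled:
        if w.chrom != prev_chrom:
            flush()
            run, pending_gap = [], []
            prev_chrom = w.chrom
        if w.status in (FIXED, INTERMEDIATE):
            if run and pending_gap:
                run.extend(pending_gap)
            pending_gap = []
            run.append(w)
        elif w.status == MISSING and run and len(pending_gap) < max_gap_windows:
            pending_gap.append(w)
        else:  # BACKGROUND, or a too-long MISSING gap
            flush()
            run, pending_gap = [], []
    flush()
    return loci


def annotate_loci(
    loci: Iterable[IntrogressedLocus],
    genes: Sequence[tuple[str, int, int, str]],
    watchlist: Sequence[str] = DEFAULT_WATCHLIST,
) -> list[IntrogressedLocus]:
    """Count genes overlapping each locus and flag watch-list candidates.

    ``genes`` are (chrom, start, end, name) intervals, 1-based inclusive,
    on the same coordinate system as the loci. A locus on a chromosome
    absent from the annotation gets n_genes = 0 with a warning.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, name in genes:
        by_chrom.setdefault(chrom, []).append((start, end, name))
    watch = set(watchlist)

    out = []
    for locus in loci:
        if locus.chrom not in by_chrom and by_chrom:
            logger.warning(
                "locus chromosome %s absent from annotation", locus.chrom
            )
        hits = [
            name
            for (gs, ge, name) in by_chrom.get(locus.chrom, [])
            if gs <= locus.end and ge >= locus.start
        ]
        out.append(
            replace(
                locus,
                n_genes=len(hits),
                candidates=sorted(n for n in hits if n in watch),
            )
        )
    return out


def run_pool_pipeline(
    sync_lines: Iterable[str],
    p1_index: int,
    p2_index: int,
    admixed_index: int,
    min_depth: int | None = None,
    min_allele_freq: float | None = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_sites: int = 1,
    fixed_threshold: float = DEFAULT_FIXED_THRESHOLD,
    intermediate_threshold: float = DEFAULT_INTERMEDIATE_THRESHOLD,
    max_gap_windows: int = 1,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[AncestryWindow], list[IntrogressedLocus], list[SiteAncestry]]:
    """Full pooled-count pipeline: sync -> divergent sites -> windows -> loci.

    Calls diploid genotypes for both parents and the admixed strain from
    the given sync pool columns, ascertains divergent sites, paints the
    admixed strain's ancestry at those sites, windows and classifies it,
    and merges classified windows into loci clipped to informative sites.
    Returns (classified windows, loci, per-site ancestries).
    """
    from . import poolgeno as pg

    kw = {}
    if min_depth is not None:
        kw["min_depth"] = min_depth
    if min_allele_freq is not None:
        kw["min_allele_freq"] = min_allele_freq

    calls1, calls2, admixed_calls = [], [], {}
    for site in pg.read_sync(sync_lines):
        calls1.append(pg.call_diploid(site, p1_index, **kw))
        calls2.append(pg.call_diploid(site, p2_index, **kw))
        admixed_calls[(site.chrom, site.pos)] = pg.call_diploid(
            site, admixed_index, **kw
        )
    dsites = pg.ascertain_divergent_sites(calls1, calls2)
    site_fracs = []
    for d in dsites:
        sa = site_ancestry(admixed_calls[(d.chrom, d.pos)], d)
        if sa is not None:
            site_fracs.append(sa)
    windows = classify_windows(
        window_ancestry(
            site_fracs,
            window_size=window_size,
            min_sites=min_sites,
            chrom_lengths=chrom_lengths,
        ),
        fixed_threshold=fixed_threshold,
        intermediate_threshold=intermediate_threshold,
    )
    loci = merge_loci(windows, sites=site_fracs, max_gap_windows=max_gap_windows)
    return windows, loci, site_fracs


def read_genes_gff3(path: str, feature_type: str = "gene") -> list[tuple[str, int, int, str]]:
    """Extract (chrom, start, end, name) gene intervals from a GFF3 file.

    Uses the ``Name`` attribute when present, else ``ID``, else a
    positional label. Coordinates stay 1-based inclusive as in GFF3.
    """
    from gffutils.iterators import DataIterator

    genes = []
    for feat in DataIterator(path):
        if feat.featuretype != feature_type:
            continue
        name = (feat.attributes.get("Name") or feat.attributes.get("ID") or [None])[0]
        if name is None:
            name = f"{feat.seqid}:{feat.start}-{feat.end}"
        genes.append((feat.seqid, feat.start, feat.end, name))
    return genes


def write_track(windows: Iterable[AncestryWindow], stream: IO[str]) -> None:
    """Per-window TSV (chrom, start, end, n_sites, mean, status) for plotting."""
    stream.write("chrom\tstart\tend\tn_sites\tmean_donor_fraction\tstatus\n")
    for w in windows:
        mean = "NA" if w.mean_donor_fraction is None else f"{w.mean_donor_fraction:.4f}"
        stream.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_sites}\t{mean}\t{w.status}\n")


def write_loci(loci: Iterable[IntrogressedLocus], stream: IO[str]) -> None:
    """Locus table TSV: coordinates, status, length, gene content, candidates."""
    stream.write("chrom\tstart\tend\tstatus\tlength\tn_genes\tcandidates\n")
    for l in loci:
        stream.write(
            f"{l.chrom}\t{l.start}\t{l.end}\t{l.status}\t{l.length}\t"
            f"{l.n_genes}\t{','.join(l.candidates)}\n"
        )
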