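"""Assign assembly contigs to reference chromosome arms by homology.

When a chromosome-level reference is updated from a new (contig-level)
assembly of the same strain, each sufficiently long contig is attributed
to the reference arm with which it shares the most aligned sequence,
as measured from a whole-genome alignment in PAF format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

logger = logging.getLogger(__name__)

UNPLACED = "UNPLACED"

#: Minimum contig length (bp) for arm assignment.
DEFAULT_MIN_CONTIG_LEN = 100_000


class PafParseError(ValueError):
    """Raised when a PAF line cannot be parsed."""


@dataclass(frozen=True)
class PafRecord:
    """One alignment block from a PAF file (minimap2 ``-x asm5`` style).

    Coordinates are 0-based half-open on both query and target. Optional
    SAM-style tags beyond column 12 are ignored at parse time.
    """

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise PafParseError(
                f"invalid query interval {self.query_start}-{self.query_end} "
                f"for {self.query_name} (len {self.query_len})"
            )
        if self.strand not in "+-":
            raise PafParseError(f"invalid strand {self.strand!r}")
        if not (self.block_len >= self.matches >= 0):
            raise PafParseError(
                f"block_len {self.block_len} < matches {self.matches}"
            )


@dataclass
class ContigAssignment:
    """A contig's arm attribution with the per-arm homology breakdown."""

    contig: str
    arm: str
    contig_len: int
    homology_by_arm: dict[str, int] = field(default_factory=dict)


def read_paf(stream: IO[str] | Iterable[str]) -> list[PafRecord]:
    """Parse PAF lines into records.

    Parameters
    ----------
    stream
        An iterable of text lines (an open file works). Empty lines are
        skipped; anything else must carry >=12 tab-separated fields.

    Raises
    ------
    PafParseError
        If a line has fewer than 12 fields or non-integer coordinates,
        naming the offending line number.
    """
    records: list[PafRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise PafParseError(
                f"line {lineno}: expected >=12 tab-separated fields, got {len(fields)}"
            )
        try:
            rec = PafRecord(
                query_name=fields[0],
                query_len=int(fields[1]),
                query_start=int(fields[2]),
                query_end=int(fields[3]),
                strand=fields[4],
                target_name=fields[5],
                target_len=int(fields[6]),
                target_start=int(fields[7]),
                target_end=int(fields[8]),
                matches=int(fields[9]),
                block_len=int(fields[10]),
                mapq=int(fields[11]),
            )
        except (ValueError, PafParseError) as exc:
            raise PafParseError(f"line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def attribute_contigs(
    records: Iterable[PafRecord],
    min_contig_len: int = DEFAULT_MIN_CONTIG_LEN,
) -> list[ContigAssignment]:
    """Attribute each contig to the arm with the largest total homology.

    Homology per arm is the sum of query-side alignment block lengths
    (``query_end - query_start``) over all records pairing the contig with
    that arm; split alignments therefore accumulate. Overlapping query
    blocks on the same arm are not deduplicated — at the 100-kb assignment
    scale the effect is negligible.

    Contigs shorter than ``min_contig_len``, contigs with no alignments,
    and contigs whose two best arms tie exactly are left ``UNPLACED``
    (ties are logged rather than guessed).

    Returns assignments sorted by contig name.
    """
    by_contig: dict[str, ContigAssignment] = {}
    for rec in records:
        asg = by_contig.setdefault(
            rec.query_name,
            ContigAssignment(rec.query_name, UNPLACED, rec.query_len, {}),
        )
        span = rec.query_end - rec.query_start
        asg.homology_by_arm[rec.target_name] = (
            asg.homology_by_arm.get(rec.target_name, 0) + span
        )

    out: list[ContigAssignment] = []
    for name in sorted(by_contig):
        asg = by_contig[name]
        if asg.contig_len >= min_contig_len and asg.homology_by_arm:
            best = max(asg.homology_by_arm.values())
            winners = [a for a, v in asg.homology_by_arm.items() if v == best]
            if len(winners) == 1:
                asg.arm = winners[0]
            else:
                logger.warning(
                    "contig %s: exact homology tie between %s; left unplaced",
                    name,
                    winners,
                )
        out.append(asg)
    return out


def write_assignments(assignments: Iterable[ContigAssignment], stream: IO[str]) -> None:
    """Write a TSV: contig, assigned arm, contig length, per-arm homology bp."""
    stream.write("contig\tassigned_arm\tcontig_len\thomology_by_arm\n")
    for asg in assignments:
        detail = ",".join(
            f"{arm}:{bp}" for arm, bp in sorted(asg.homology_by_arm.items())
        )
        stream.write(f"{asg.contig}\t{asg.arm}\t{asg.contig_len}\t{detail}\n")
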