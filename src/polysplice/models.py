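"""Core data models shared across the pipeline.

Coordinates are 0-based half-open throughout the library; GTF input/output
converts to and from the 1-based inclusive convention at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

EVENT_TYPES = ("IR", "ES", "A5", "A3")

Interval = tuple[int, int]


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered chain of exons on one strand.

    Exons are ``(start, end)`` pairs in 0-based half-open genomic
    coordinates, sorted ascending and pairwise disjoint.  Introns are the
    gaps between consecutive exons.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-'"
            )
        if len(self.exons) < 1:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: empty exon ({start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping/unsorted exons"
                )
            prev_end = end
        object.__setattr__(self, "exons", tuple(map(tuple, self.exons)))

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Gaps between consecutive exons, ascending."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def structure(self) -> tuple[Interval, ...]:
        """Hashable exon-chain key used to collapse identical transcripts."""
        return self.exons


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcripts sharing chrom and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id}: no transcripts")
        for t in self.transcripts:
            if t.gene_id != self.gene_id or t.chrom != self.chrom or t.strand != self.strand:
                raise ValidationError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} disagrees "
                    "on gene_id/chrom/strand"
                )
        object.__setattr__(self, "transcripts", tuple(self.transcripts))

    @property
    def subgenome(self) -> str:
        """Subgenome label derived from the chromosome-name suffix (A or B)."""
        suffix = self.chrom[-1]
        if suffix not in ("A", "B"):
            raise ValidationError(
                f"gene {self.gene_id}: chromosome {self.chrom!r} lacks an A/B suffix"
            )
        return suffix


@dataclass(frozen=True)
class SpliceEvent:
    """A local alternative-splicing event.

    ``anchor`` is a type-specific 4-tuple of genomic coordinates:

    * ``ES``: (upstream-flank end, skipped-exon start, skipped-exon end,
      downstream-flank start)
    * ``IR``: (retained-exon start, intron start, intron end,
      retained-exon end)
    * ``A5``/``A3``: the two alternative introns sorted by (start, end)
      and flattened.

    Inclusion is the form with more exonic sequence: the exon-containing
    form for ES, the retaining form for IR, and the shorter intron for
    A5/A3.
    """

    event_id: str
    gene_id: str
    etype: str
    chrom: str
    strand: str
    anchor: tuple[int, int, int, int]
    inclusion_transcripts: frozenset[str]
    exclusion_transcripts: frozenset[str]

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.etype!r}")
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValidationError(f"event {self.event_id}: empty form set")
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValidationError(
                f"event {self.event_id}: inclusion/exclusion sets overlap"
            )


def format_event_id(
    gene_id: str, etype: str, chrom: str, anchor: tuple[int, int, int, int], strand: str
) -> str:
    """Canonical event identifier: ``gene;TYPE:chrom:n1-n2:n3-n4:strand``."""
    a, b, c, d = anchor
    return f"{gene_id};{etype}:{chrom}:{a}-{b}:{c}-{d}:{strand}"


@dataclass
class EventCatalog:
    """Deduplicated set of splice events with gene and type indexes."""

    events: list[SpliceEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for ev in self.events:
            if ev.event_id in seen:
                raise ValidationError(f"duplicate event id {ev.event_id}")
            seen.add(ev.event_id)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[SpliceEvent]:
        return iter(self.events)

    @property
    def event_ids(self) -> list[str]:
        return [ev.event_id for ev in self.events]

    def by_gene(self) -> dict[str, list[SpliceEvent]]:
        out: dict[str, list[SpliceEvent]] = {}
        for ev in self.events:
            out.setdefault(ev.gene_id, []).append(ev)
        return out

    def by_type(self) -> dict[str, list[SpliceEvent]]:
        out: dict[str, list[SpliceEvent]] = {t: [] for t in EVENT_TYPES}
        for ev in self.events:
            out[ev.etype].append(ev)
        return out

    def get(self, event_id: str) -> SpliceEvent:
        for ev in self.events:
            if ev.event_id == event_id:
                return ev
        raise KeyError(event_id)
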