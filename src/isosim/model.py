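"""Genomic data model shared by all simulation stages.

Coordinates are 1-based inclusive throughout the in-memory model (the GTF
convention). Introns ("junctions") are stored as 1-based inclusive
``[exon_end + 1, next_exon_start - 1]`` pairs so that junction-chain equality
is an exact integer comparison. Conversion to 0-based half-open happens only
at the BED writer boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


class TranscriptModel:
    """A transcript: ordered exons plus everything derived from them.

    Exons are stored genomic 5'->3' by coordinate (ascending), must share
    chrom/strand, and may not overlap. The junction chain, TSS/TTS and
    spliced length are derived once at construction.
    """

    __slots__ = (
        "transcript_id",
        "gene_id",
        "chrom",
        "strand",
        "exons",
        "junctions",
        "start",
        "end",
        "spliced_length",
        "attributes",
    )

    def __init__(
        self,
        transcript_id: str,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: Iterable[tuple[int, int]],
        attributes: Optional[dict[str, str]] = None,
    ) -> None:
        if strand not in STRANDS:
            raise ValueError(f"bad strand {strand!r} for {transcript_id}")
        exs = sorted((int(s), int(e)) for s, e in exons)
        if not exs:
            raise ValueError(f"transcript {transcript_id} has zero exons")
        for (s, e) in exs:
            if s > e:
                raise ValueError(f"exon {s}-{e} inverted in {transcript_id}")
        for (_, e1), (s2, _) in zip(exs, exs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping/abutting exons in {transcript_id}")
        self.transcript_id = transcript_id
        self.gene_id = gene_id
        self.chrom = chrom
        self.strand = strand
        self.exons: tuple[tuple[int, int], ...] = tuple(exs)
        # intron i spans [exon_i.end + 1, exon_{i+1}.start - 1], 1-based inclusive
        self.junctions: tuple[tuple[int, int], ...] = tuple(
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exs, exs[1:])
        )
        self.start = exs[0][0]
        self.end = exs[-1][1]
        self.spliced_length = sum(e - s + 1 for s, e in exs)
        self.attributes = dict(attributes) if attributes else {}

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        """Genomic position of the 5' end (max coordinate on '-')."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Genomic position of the 3' end."""
        return self.end if self.strand == "+" else self.start

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def is_mono_exon(self) -> bool:
        return len(self.exons) == 1

    def donors(self) -> frozenset[int]:
        """Intron-side donor coordinates (transcription order is irrelevant:
        donors/acceptors are keyed by genomic side consistently per strand)."""
        if self.strand == "+":
            return frozenset(j[0] for j in self.junctions)
        return frozenset(j[1] for j in self.junctions)

    def acceptors(self) -> frozenset[int]:
        if self.strand == "+":
            return frozenset(j[1] for j in self.junctions)
        return frozenset(j[0] for j in self.junctions)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"TranscriptModel({self.transcript_id}, {self.chrom}:{self.start}"
            f"-{self.end}{self.strand}, {self.exon_count} exons)"
        )


@dataclass
class AnnotationSet:
    """Transcripts + genes + an interval index for overlap queries."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    genes: dict[str, list[str]] = field(default_factory=dict)
    _index: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t
        self.genes.setdefault(t.gene_id, []).append(t.transcript_id)
        # interval tree is half-open; store [start, end+1)
        self._index.setdefault(t.chrom, IntervalTree()).addi(
            t.start, t.end + 1, t.transcript_id
        )

    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def overlapping(
        self,
        chrom: str,
        start: int,
        end: int,
        strand: Optional[str] = None,
        exclude: Optional[frozenset[str] | set[str]] = None,
    ) -> list[TranscriptModel]:
        """Transcripts whose span overlaps [start, end] (1-based inclusive)."""
        tree = self._index.get(chrom)
        if tree is None:
            return []
        hits = []
        for iv in tree.overlap(start, end + 1):
            tid = iv.data
            if exclude and tid in exclude:
                continue
            t = self.transcripts[tid]
            if strand is not None and t.strand != strand:
                continue
            hits.append(t)
        hits.sort(key=lambda t: t.transcript_id)
        return hits

    def gene_span(self, gene_id: str, exclude: Optional[set[str]] = None) -> Optional[GenomicInterval]:
        """Span of a gene's (non-excluded) transcripts; None if empty."""
        members = [
            self.transcripts[tid]
            for tid in self.genes.get(gene_id, [])
            if not (exclude and tid in exclude)
        ]
        if not members:
            return None
        return GenomicInterval(
            members[0].chrom,
            min(t.start for t in members),
            max(t.end for t in members),
            members[0].strand,
        )

    def subset(self, keep_ids: Iterable[str]) -> "AnnotationSet":
        """New AnnotationSet with the given transcripts; empty genes dropped."""
        out = AnnotationSet()
        for tid in keep_ids:
            out.add(self.transcripts[tid])
        return out

    def remove(self, drop_ids: Iterable[str]) -> "AnnotationSet":
        drop = set(drop_ids)
        return self.subset(tid for tid in self.transcripts if tid not in drop)
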