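"""Reading and writing of GTF, FASTA, BED and FASTQ.

GTF is parsed with :func:`pyranges.read_gtf` and materialized into
:class:`~isosim.model.TranscriptModel` objects; writing emits GENCODE-style
``key "value";`` attributes with gene/transcript/exon record hierarchy so a
round trip is lossless for ids, coordinates, strand and exon count.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .model import AnnotationSet, TranscriptModel

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_gtf(path: PathLike) -> AnnotationSet:
    """Parse a GTF file into an :class:`AnnotationSet`.

    Exon records are grouped by ``transcript_id``; gene/transcript feature
    rows are optional (exons alone define a transcript). Coordinates are kept
    1-based inclusive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        return AnnotationSet()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gr = __import__("pyranges").read_gtf(str(path))
    df = gr.df if hasattr(gr, "df") else pd.DataFrame(gr)
    if df.empty:
        return AnnotationSet()
    exons = df[df["Feature"] == "exon"]
    if "transcript_id" not in exons.columns or "gene_id" not in exons.columns:
        raise ValueError(f"{path}: GTF exon records lack gene_id/transcript_id")
    ann = AnnotationSet()
    for (tid, gid, chrom, strand), grp in exons.groupby(
        ["transcript_id", "gene_id", "Chromosome", "Strand"], observed=True, sort=False
    ):
        if pd.isna(tid) or tid == "":
            raise ValueError(f"{path}: exon record without transcript_id")
        # pyranges is 0-based half-open internally; back to 1-based inclusive
        ex = [(int(s) + 1, int(e)) for s, e in zip(grp["Start"], grp["End"])]
        ann.add(TranscriptModel(str(tid), str(gid), str(chrom), str(strand), ex))
    return ann


def _fmt_attrs(attrs: Mapping[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def write_gtf(annotation: AnnotationSet, path: PathLike, source: str = "isosim") -> None:
    """Write gene, transcript and exon records, GENCODE attribute dialect."""
    lines: list[str] = []
    for gene_id, tids in annotation.genes.items():
        span = annotation.gene_span(gene_id)
        if span is None:
            continue
        lines.append(
            "\t".join(
                [
                    span.chrom,
                    source,
                    "gene",
                    str(span.start),
                    str(span.end),
                    ".",
                    span.strand,
                    ".",
                    _fmt_attrs({"gene_id": gene_id}),
                ]
            )
        )
        for tid in tids:
            t = annotation.transcripts[tid]
            base = {"gene_id": gene_id, "transcript_id": tid}
            base.update(t.attributes)
            lines.append(
                "\t".join(
                    [
                        t.chrom,
                        source,
                        "transcript",
                        str(t.start),
                        str(t.end),
                        ".",
                        t.strand,
                        ".",
                        _fmt_attrs(base),
                    ]
                )
            )
            for i, (s, e) in enumerate(t.exons, start=1):
                ex_attrs = dict(base)
                ex_attrs["exon_number"] = str(i)
                lines.append(
                    "\t".join(
                        [t.chrom, source, "exon", str(s), str(e), ".", t.strand, ".", _fmt_attrs(ex_attrs)]
                    )
                )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


class GenomeStore:
    """Per-chromosome sequence store backed by a dict or an indexed FASTA."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = dict(sequences)

    @classmethod
    def from_fasta(cls, path: PathLike) -> "GenomeStore":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        return self._seqs[chrom]

    def chrom_length(self, chrom: str) -> int:
        return len(self[chrom])

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice."""
        seq = self[chrom]
        if start < 1 or end > len(seq):
            raise IndexError(
                f"{chrom}:{start}-{end} out of range (length {len(seq)})"
            )
        return seq[start - 1 : end]

    def write_fasta(self, path: PathLike, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def transcript_sequence(t: TranscriptModel, genome: GenomeStore) -> str:
    """Spliced transcript sequence, reverse-complemented on '-'."""
    parts = [genome.fetch(t.chrom, s, e) for s, e in t.exons]
    seq = "".join(parts)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq


def write_fastq(
    records: Iterable[tuple[str, str, str]], path: PathLike
) -> int:
    """Write (read_id, sequence, quality) triples; returns record count."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_fasta_reads(records: Iterable[tuple[str, str]], path: PathLike) -> int:
    n = 0
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
            n += 1
    return n


def write_bed(
    intervals: Iterable[tuple[str, int, int, str, float, str]], path: PathLike
) -> None:
    """Write BED6. Input intervals are 1-based inclusive; converted to
    0-based half-open here, at the writer boundary."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score:g}\t{strand}\n")


def read_bed(path: PathLike) -> pd.DataFrame:
    """Read BED into a DataFrame with 1-based inclusive start/end columns."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    df["start"] = df["start"] + 1  # back to 1-based inclusive
    return df
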