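"""Paired-end short-read simulation matched to the long-read design.

Fragments are sampled per transcript proportional to its long-read TPM;
mate 1 is the first ``read_length`` bases of the fragment (sense), mate 2
the reverse complement of its last ``read_length`` bases. Substitution
errors are uniform i.i.d. at ``error_rate`` (default 0.5%, reads 100 nt).

The truth table stores each fragment's transcript coordinates so coverage
and TSS features are computed by projecting through the exon structure,
without alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .annotation_io import (
    GenomeStore,
    reverse_complement,
    transcript_sequence,
    write_fasta_reads,
)
from .design import SimulationDesign
from .model import TranscriptModel

PathLike = Union[str, Path]

FRAGMENT_COLUMNS = ["fragment_id", "transcript_id", "frag_start", "frag_end"]


@dataclass
class ShortReadConfig:
    read_length: int = 100
    error_rate: float = 0.005
    short_count: int = 10_000  # total pairs
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.short_count <= 0:
            raise ValueError("short_count must be positive")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate == 0.0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = rng.random(len(arr)) < rate
    n = int(mask.sum())
    if n:
        idx = _BASE_INDEX[arr[mask]]
        arr[mask] = _BASES[(idx + rng.integers(1, 4, size=n)) % 4]
    return arr.tobytes().decode(), n


@dataclass
class ShortReadResult:
    truth: pd.DataFrame  # fragment transcript coordinates (1-based inclusive)
    mate1: list[tuple[str, str]]
    mate2: list[tuple[str, str]]
    n_substitutions: int
    n_bases: int


def simulate_short_reads(
    design: SimulationDesign,
    genome: GenomeStore,
    config: ShortReadConfig,
    seed: int = 0,
    out_prefix: Optional[PathLike] = None,
) -> ShortReadResult:
    """Simulate ``short_count`` read pairs; optionally writes
    ``<prefix>_1.fasta`` / ``<prefix>_2.fasta``."""
    if design.tpm is None:
        raise ValueError("expression must be assigned before simulating reads")
    rng = np.random.default_rng(seed)
    ids = [t for t in design.expressed_ids() if design.tpm.loc[t] > 0]
    if not ids:
        raise ValueError("no expressed transcripts with positive TPM")
    weights = np.array([design.tpm.loc[t] for t in ids], dtype=float)
    per_tx = rng.multinomial(config.short_count, weights / weights.sum())

    mate1: list[tuple[str, str]] = []
    mate2: list[tuple[str, str]] = []
    rows: list[tuple] = []
    n_sub = 0
    n_bases = 0
    rl = config.read_length
    serial = 0
    for tid, n_frags in zip(ids, per_tx):
        if n_frags == 0:
            continue
        t = design.annotation.transcripts[tid]
        tseq = transcript_sequence(t, genome)
        L = len(tseq)
        flens = rng.normal(config.fragment_mean, config.fragment_sd, size=n_frags)
        flens = np.clip(np.round(flens).astype(int), rl, L)
        starts = (rng.random(n_frags) * (L - flens + 1)).astype(int)
        for flen, start in zip(flens, starts):
            frag = tseq[start : start + flen]
            r1, s1 = _substitute(frag[:rl], config.error_rate, rng)
            r2, s2 = _substitute(
                reverse_complement(frag[-rl:]), config.error_rate, rng
            )
            fid = f"frag_{serial}"
            mate1.append((f"{fid}/1", r1))
            mate2.append((f"{fid}/2", r2))
            # 1-based inclusive transcript coordinates
            rows.append((fid, tid, start + 1, start + flen))
            n_sub += s1 + s2
            n_bases += 2 * rl
            serial += 1

    truth = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    if out_prefix is not None:
        write_fasta_reads(mate1, f"{out_prefix}_1.fasta")
        write_fasta_reads(mate2, f"{out_prefix}_2.fasta")
        truth.to_csv(f"{out_prefix}_fragments.tsv", sep="\t", index=False)
    return ShortReadResult(truth, mate1, mate2, n_sub, n_bases)


def project_to_genome(
    t: TranscriptModel, tstart: int, tend: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval (1-based inclusive, 5'->3' in
    transcript orientation) to genomic blocks (1-based inclusive, ascending).
    """
    if tstart < 1 or tend > t.spliced_length or tstart > tend:
        raise ValueError(
            f"transcript interval {tstart}-{tend} out of range for "
            f"{t.transcript_id} (length {t.spliced_length})"
        )
    if t.strand == "-":
        tstart, tend = (
            t.spliced_length - tend + 1,
            t.spliced_length - tstart + 1,
        )
    blocks: list[tuple[int, int]] = []
    offset = 0  # transcript bases before the current exon (plus-orientation)
    for es, ee in t.exons:
        elen = ee - es + 1
        lo = max(tstart, offset + 1)
        hi = min(tend, offset + elen)
        if lo <= hi:
            blocks.append((es + (lo - offset - 1), es + (hi - offset - 1)))
        offset += elen
    return blocks


def read_genomic_blocks(
    design: SimulationDesign, truth: pd.DataFrame, read_length: int
) -> list[tuple[str, str, list[tuple[int, int]]]]:
    """Genomic blocks covered by each mate of each fragment:
    (chrom, strand, blocks) per read."""
    out = []
    for tid, fs, fe in zip(
        truth["transcript_id"], truth["frag_start"], truth["frag_end"]
    ):
        t = design.annotation.transcripts[tid]
        m1 = project_to_genome(t, fs, min(fs + read_length - 1, fe))
        m2 = project_to_genome(t, max(fe - read_length + 1, fs), fe)
        out.append((t.chrom, t.strand, m1))
        out.append((t.chrom, t.strand, m2))
    return out


def genomic_coverage(
    design: SimulationDesign,
    truth: pd.DataFrame,
    read_length: int,
    chrom_lengths: dict[str, int],
) -> dict[str, np.ndarray]:
    """Per-base read depth (both mates), 0-based arrays per chromosome."""
    cov = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_lengths.items()}
    for chrom, _strand, blocks in read_genomic_blocks(design, truth, read_length):
        arr = cov[chrom]
        for s, e in blocks:
            arr[s - 1 : e] += 1
    return cov


def read_start_positions(
    design: SimulationDesign, truth: pd.DataFrame
) -> pd.DataFrame:
    """Genomic 5' start position of each fragment's sense mate (mate 1),
    used for the TSS-coverage-proportion feature."""
    rows = []
    for tid, fs in zip(truth["transcript_id"], truth["frag_start"]):
        t = design.annotation.transcripts[tid]
        blocks = project_to_genome(t, fs, fs)
        pos = blocks[0][0]
        rows.append((t.chrom, t.strand, pos))
    return pd.DataFrame(rows, columns=["chrom", "strand", "pos"])
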