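"""Long-read generation with platform-specific error and completeness
profiles.

Reads are drawn per transcript at exactly the designed counts. Each read is
a (possibly 5'/3'-truncated) copy of its transcript sequence corrupted by an
i.i.d. per-base error process: every template base is substituted with
probability ``mismatch_rate``, deleted with probability ``deletion_rate``,
and followed by a random inserted base with probability ``insertion_rate``.
The applied edit script is recorded per read in the truth table, so error
rates can be measured alignment-free.

Default profiles (per-base probabilities):

===========  =========  =========  ========  =====
platform     mismatch   insertion  deletion  total
===========  =========  =========  ========  =====
cDNA-ONT     0.028      0.019      0.035     0.082
dRNA-ONT     0.036      0.030      0.057     0.123
PacBio       0.01731    0.02204    0.01090   0.05025
===========  =========  =========  ========  =====

cDNA reads come from the sense or antisense strand with probability 1/2
each; dRNA (direct RNA) reads are sense-only, as in real protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .annotation_io import GenomeStore, reverse_complement, transcript_sequence, write_fastq
from .design import SimulationDesign

PathLike = Union[str, Path]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

TRUTH_COLUMNS = [
    "read_id",
    "transcript_id",
    "strand",
    "trunc5",
    "trunc3",
    "template_len",
    "n_mismatch",
    "n_insertion",
    "n_deletion",
]


@dataclass(frozen=True)
class ErrorProfile:
    platform: str
    mismatch_rate: float
    insertion_rate: float
    deletion_rate: float

    def __post_init__(self) -> None:
        for r in (self.mismatch_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")

    @property
    def total(self) -> float:
        return self.mismatch_rate + self.insertion_rate + self.deletion_rate

    @classmethod
    def cdna_ont(cls) -> "ErrorProfile":
        return cls("cDNA-ONT", 0.028, 0.019, 0.035)

    @classmethod
    def drna_ont(cls) -> "ErrorProfile":
        return cls("dRNA-ONT", 0.036, 0.030, 0.057)

    @classmethod
    def pacbio(cls) -> "ErrorProfile":
        return cls("PacBio", 0.01731, 0.02204, 0.01090)

    @classmethod
    def error_free(cls) -> "ErrorProfile":
        return cls("error-free", 0.0, 0.0, 0.0)

    @classmethod
    def by_name(cls, name: str) -> "ErrorProfile":
        table = {
            "cDNA-ONT": cls.cdna_ont,
            "dRNA-ONT": cls.drna_ont,
            "PacBio": cls.pacbio,
            "error-free": cls.error_free,
        }
        if name not in table:
            raise ValueError(f"unknown platform {name!r}; choose from {list(table)}")
        return table[name]()


@dataclass(frozen=True)
class CompletenessModel:
    """Geometric-tail truncation of read ends, in transcript coordinates.

    ``mean5``/``mean3`` are the mean number of bases lost from the 5'/3'
    end (0 disables truncation at that end). Truncations are clipped so at
    least ``min_read_length`` template bases remain.
    """

    mean5: float = 0.0
    mean3: float = 0.0
    min_read_length: int = 50

    @classmethod
    def none(cls) -> "CompletenessModel":
        return cls(0.0, 0.0)

    @classmethod
    def ont_default(cls) -> "CompletenessModel":
        return cls(mean5=100.0, mean3=0.0)

    def draw(self, rng: np.random.Generator, length: int) -> tuple[int, int]:
        def one(mean: float) -> int:
            if mean <= 0:
                return 0
            # geometric on {1,2,...} shifted to {0,1,...} with the given mean
            return int(rng.geometric(1.0 / (1.0 + mean)) - 1)

        t5, t3 = one(self.mean5), one(self.mean3)
        keep = length - t5 - t3
        if keep < self.min_read_length:
            # clip, removing excess truncation 5' first
            excess = self.min_read_length - max(keep, 0)
            take5 = min(t5, excess)
            t5 -= take5
            excess -= take5
            t3 = max(t3 - excess, 0)
            if length - t5 - t3 < 1:
                t5, t3 = 0, 0
        return t5, t3


def corrupt_sequence(
    seq: str, profile: ErrorProfile, rng: np.random.Generator
) -> tuple[str, int, int, int]:
    """Apply the i.i.d. error process; returns (read, n_mm, n_ins, n_del)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    L = len(arr)
    if L == 0 or profile.total == 0.0:
        return seq, 0, 0, 0
    u = rng.random(L)
    m, d = profile.mismatch_rate, profile.deletion_rate
    mm_mask = u < m
    del_mask = (u >= m) & (u < m + d)
    ins_mask = rng.random(L) < profile.insertion_rate

    n_mm = int(mm_mask.sum())
    if n_mm:
        idx = _BASE_INDEX[arr[mm_mask]]
        shift = rng.integers(1, 4, size=n_mm)
        arr[mm_mask] = _BASES[(idx + shift) % 4]

    n_ins = int(ins_mask.sum())
    n_del = int(del_mask.sum())
    if n_ins == 0 and n_del == 0:
        return arr.tobytes().decode(), n_mm, 0, 0

    ins_bases = _BASES[rng.integers(0, 4, size=n_ins)]
    pieces: list[np.ndarray] = []
    keep = ~del_mask
    ins_positions = np.flatnonzero(ins_mask)
    prev = 0
    for k, pos in enumerate(ins_positions):
        seg = arr[prev : pos + 1][keep[prev : pos + 1]]
        pieces.append(seg)
        pieces.append(ins_bases[k : k + 1])
        prev = pos + 1
    pieces.append(arr[prev:][keep[prev:]])
    read = np.concatenate(pieces) if pieces else arr[keep]
    return read.tobytes().decode(), n_mm, n_ins, n_del


@dataclass
class LongReadResult:
    """Truth table (one row per read) plus the reads themselves as
    (read_id, sequence, quality) triples."""

    truth: pd.DataFrame
    reads: list[tuple[str, str, str]]


def simulate_long_reads(
    design: SimulationDesign,
    genome: GenomeStore,
    profile: ErrorProfile,
    completeness: Optional[CompletenessModel] = None,
    seed: int = 0,
    fastq_path: Optional[PathLike] = None,
    truth_path: Optional[PathLike] = None,
) -> "LongReadResult":
    """Generate exactly ``requested_counts`` reads per expressed transcript.

    Returns a :class:`LongReadResult` with the truth table (one row per
    read, including the applied edit-script tallies) and the reads;
    optionally writes FASTQ and truth TSV.
    """
    if design.counts is None:
        raise ValueError("expression must be assigned before simulating reads")
    completeness = completeness or CompletenessModel.none()
    rng = np.random.default_rng(seed)
    qchar = _quality_char(profile)
    antisense_allowed = profile.platform != "dRNA-ONT"

    records: list[tuple[str, str, str]] = []
    rows: list[tuple] = []
    for tid in design.expressed_ids():
        n_reads = int(design.counts.loc[tid])
        if n_reads <= 0:
            continue
        t = design.annotation.transcripts[tid]
        tseq = transcript_sequence(t, genome)
        L = len(tseq)
        for serial in range(n_reads):
            t5, t3 = completeness.draw(rng, L)
            template = tseq[t5 : L - t3]
            strand = "+"
            if antisense_allowed and rng.random() < 0.5:
                template = reverse_complement(template)
                strand = "-"
            read, n_mm, n_ins, n_del = corrupt_sequence(template, profile, rng)
            rid = f"{tid}_{serial}"
            records.append((rid, read, qchar * len(read)))
            rows.append((rid, tid, strand, t5, t3, len(template), n_mm, n_ins, n_del))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if fastq_path is not None:
        write_fastq(records, fastq_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return LongReadResult(truth=truth, reads=records)


def _quality_char(profile: ErrorProfile) -> str:
    p = max(profile.total, 1e-4)
    q = min(int(round(-10.0 * math.log10(p))), 60)
    return chr(33 + q)


@dataclass(frozen=True)
class MeasuredErrorRates:
    mismatch: float
    insertion: float
    deletion: float

    @property
    def total(self) -> float:
        return self.mismatch + self.insertion + self.deletion


def empirical_error_rate(truth: pd.DataFrame) -> MeasuredErrorRates:
    """Class-wise error rates from the recorded per-read edit scripts:
    total edit operations of each class divided by total template bases."""
    bases = float(truth["template_len"].sum())
    if bases == 0:
        raise ValueError("truth table contains no template bases")
    return MeasuredErrorRates(
        mismatch=float(truth["n_mismatch"].sum()) / bases,
        insertion=float(truth["n_insertion"].sum()) / bases,
        deletion=float(truth["n_deletion"].sum()) / bases,
    )
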