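"""Deterministic synthetic genomes and annotations with a controlled number
of candidate transcripts per structural category.

Each requested candidate is built by a dedicated locus constructor:

* ISM — a gene with two full-length isoforms sharing one junction chain
  plus a truncated isoform whose chain is a contiguous sub-chain;
* NIC — an exon-skipping isoform recombining annotated donor/acceptor sites
  into a chain no reference uses;
* NNC — an isoform with one donor site shifted into unannotated sequence;
* fusion — a single transcript bridging the exons of two non-overlapping
  genes;
* antisense — a mono-exon transcript opposite an annotated gene;
* intergenic — an isolated single-transcript gene;
* genic — a mono-exon transcript inside another gene's intron.

Genome sequence is i.i.d. uniform nucleotides with canonical GT/AG (CT/AC
on the minus strand) dinucleotides planted at every annotated intron edge.
Generated candidates are verified with the classifier itself, not assumed
from construction; an infeasible spec raises :class:`FeasibilityError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation_io import GenomeStore, write_bed, write_gtf
from .classify import (
    ANTISENSE,
    FUSION,
    GENIC,
    INTERGENIC,
    ISM,
    NIC,
    NNC,
    NOVEL_CATEGORIES,
    classify_reference,
)
from .model import AnnotationSet, TranscriptModel


class FeasibilityError(ValueError):
    """The generated annotation does not contain the guaranteed candidates."""


@dataclass
class FixtureSpec:
    n_known_genes: int = 20
    novel_candidates: dict[str, int] = field(default_factory=dict)
    isoform_counts: tuple[int, ...] = (1, 2, 3)  # per known gene
    exon_length: tuple[int, int] = (120, 250)
    intron_length: tuple[int, int] = (300, 700)
    n_exons: tuple[int, int] = (3, 6)
    mono_exon_length: int = 250
    gap_length: tuple[int, int] = (400, 900)
    chrom_target_length: int = 1_500_000
    seed: int = 0

    def __post_init__(self) -> None:
        for cat, n in self.novel_candidates.items():
            if cat not in NOVEL_CATEGORIES:
                raise ValueError(f"unknown novel category {cat!r}")
            if n < 0:
                raise ValueError("candidate counts must be >= 0")
        if self.n_known_genes < 0:
            raise ValueError("n_known_genes must be >= 0")


@dataclass
class Fixture:
    genome: GenomeStore
    annotation: AnnotationSet
    count_table: np.ndarray  # long-tailed raw counts, for sample mode
    isoform_count_dist: np.ndarray  # per-gene expressed-isoform counts
    cage_peaks: pd.DataFrame  # synthetic observed peaks, for model training

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": str(outdir / "genome.fasta"),
            "annotation": str(outdir / "annotation.gtf"),
            "counts": str(outdir / "sample_counts.tsv"),
            "cage": str(outdir / "cage_peaks.bed"),
        }
        self.genome.write_fasta(paths["genome"])
        write_gtf(self.annotation, paths["annotation"])
        pd.DataFrame(
            {
                "transcript_id": [f"obs_{i}" for i in range(len(self.count_table))],
                "count": self.count_table.astype(int),
            }
        ).to_csv(paths["counts"], sep="\t", index=False)
        write_bed(
            (
                (r.chrom, int(r.start), int(r.end), f"peak_{i}", 1.0, r.strand)
                for i, r in enumerate(self.cage_peaks.itertuples())
            ),
            paths["cage"],
        )
        return paths


class _Builder:
    """Lays out gene loci left to right, one chromosome at a time."""

    def __init__(self, spec: FixtureSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.ann = AnnotationSet()
        self.chrom_no = 1
        self.pos = 1000
        self.chrom_junctions: dict[str, list[tuple[int, int, str]]] = {}
        self.n_gene = 0
        self.n_tx = 0

    @property
    def chrom(self) -> str:
        return f"chr{self.chrom_no}"

    def _advance(self, end: int) -> None:
        self.pos = end + int(self.rng.integers(*self.spec.gap_length))
        if self.pos > self.spec.chrom_target_length:
            self.chrom_no += 1
            self.pos = 1000

    def _ids(self) -> tuple[str, str]:
        self.n_gene += 1
        return f"gene_{self.n_gene:05d}", self.chrom

    def _tx_id(self) -> str:
        self.n_tx += 1
        return f"tx_{self.n_tx:06d}"

    def _exon_layout(
        self, n_exons: int, intron: Optional[tuple[int, int]] = None
    ) -> list[tuple[int, int]]:
        s = self.spec
        intron = intron or s.intron_length
        exons = []
        p = self.pos
        for _ in range(n_exons):
            el = int(self.rng.integers(*s.exon_length))
            exons.append((p, p + el - 1))
            p = p + el + int(self.rng.integers(*intron))
        return exons

    def _add(
        self, gene_id: str, strand: str, exons: list[tuple[int, int]], tid=None
    ) -> TranscriptModel:
        t = TranscriptModel(tid or self._tx_id(), gene_id, self.chrom, strand, exons)
        self.ann.add(t)
        for j in t.junctions:
            self.chrom_junctions.setdefault(self.chrom, []).append(
                (j[0], j[1], strand)
            )
        return t

    def _jitter_ends(
        self, exons: list[tuple[int, int]], max_shift: int = 30
    ) -> list[tuple[int, int]]:
        """Shrink the outer exon ends a little so isoforms sharing a chain
        still differ in TSS/TTS."""
        out = list(exons)
        d1 = int(self.rng.integers(0, max_shift))
        d2 = int(self.rng.integers(0, max_shift))
        s0, e0 = out[0]
        sn, en = out[-1]
        out[0] = (min(s0 + d1, e0 - 50), e0)
        out[-1] = (sn, max(en - d2, sn + 50))
        return out

    def _strand(self) -> str:
        return "+" if self.rng.random() < 0.5 else "-"

    # ---- locus constructors ------------------------------------------------

    def known_gene(self) -> None:
        gid, _ = self._ids()
        strand = self._strand()
        n_iso = int(
            self.spec.isoform_counts[
                self.rng.integers(len(self.spec.isoform_counts))
            ]
        )
        exons = self._exon_layout(int(self.rng.integers(*self.spec.n_exons)))
        base = self._add(gid, strand, exons)
        for _ in range(max(n_iso, 2) - 1):  # >=2 so every isoform is FSM
            self._add(gid, strand, self._jitter_ends(exons))
        self._advance(base.end)

    def _fsm_pair(self, gid: str, strand: str, exons) -> TranscriptModel:
        base = self._add(gid, strand, exons)
        self._add(gid, strand, self._jitter_ends(exons))
        return base

    def ism_locus(self) -> None:
        gid, _ = self._ids()
        strand = self._strand()
        exons = self._exon_layout(max(int(self.rng.integers(*self.spec.n_exons)), 4))
        base = self._fsm_pair(gid, strand, exons)
        # suffix (or prefix) contiguous sub-chain: drop one terminal exon
        sub = exons[1:] if self.rng.random() < 0.5 else exons[:-1]
        self._add(gid, strand, sub)
        self._advance(base.end)

    def nic_locus(self) -> None:
        gid, _ = self._ids()
        strand = self._strand()
        exons = self._exon_layout(4)
        base = self._fsm_pair(gid, strand, exons)
        self._add(gid, strand, [exons[0]] + exons[2:])  # skip exon 2
        self._advance(base.end)

    def nnc_locus(self) -> None:
        gid, _ = self._ids()
        strand = self._strand()
        exons = self._exon_layout(4)
        base = self._fsm_pair(gid, strand, exons)
        s0, e0 = exons[0]
        shifted = [(s0, e0 - 9)] + exons[1:]  # unannotated donor site
        self._add(gid, strand, shifted)
        self._advance(base.end)

    def fusion_locus(self) -> None:
        strand = self._strand()
        gid_a, _ = self._ids()
        exons_a = self._exon_layout(3)
        self._fsm_pair(gid_a, strand, exons_a)
        saved = self.pos
        self.pos = exons_a[-1][1] + int(self.rng.integers(400, 700))
        gid_b, _ = self._ids()
        exons_b = self._exon_layout(3)
        end_b = self._fsm_pair(gid_b, strand, exons_b).end
        gid_f, _ = self._ids()
        self._add(gid_f, strand, exons_a[:2] + exons_b[1:])
        self.pos = saved
        self._advance(end_b)

    def antisense_locus(self) -> None:
        gid, _ = self._ids()
        strand = self._strand()
        exons = self._exon_layout(3)
        base = self._fsm_pair(gid, strand, exons)
        gid_s, _ = self._ids()
        anti = "-" if strand == "+" else "+"
        mid = (base.start + base.end) // 2
        self._add(gid_s, anti, [(mid, mid + self.spec.mono_exon_length - 1)])
        self._advance(base.end)

    def intergenic_locus(self) -> None:
        gid, _ = self._ids()
        strand = self._strand()
        L = self.spec.mono_exon_length
        self._add(gid, strand, [(self.pos, self.pos + L - 1)])
        self._advance(self.pos + L - 1)

    def genic_locus(self) -> None:
        gid, _ = self._ids()
        strand = self._strand()
        # first intron wide enough to host a mono-exon transcript
        exons = self._exon_layout(3, intron=(600, 800))
        base = self._fsm_pair(gid, strand, exons)
        gid_g, _ = self._ids()
        istart = exons[0][1] + 1
        off = istart + 60
        self._add(gid_g, strand, [(off, off + self.spec.mono_exon_length - 1)])
        self._advance(base.end)


def generate_fixture(spec: FixtureSpec, verify: bool = True) -> Fixture:
    """Build genome + annotation per ``spec``; seeded and deterministic."""
    rng = np.random.default_rng(spec.seed)
    b = _Builder(spec, rng)
    builders = [(b.known_gene, spec.n_known_genes)]
    dispatch = {
        ISM: b.ism_locus,
        NIC: b.nic_locus,
        NNC: b.nnc_locus,
        FUSION: b.fusion_locus,
        ANTISENSE: b.antisense_locus,
        INTERGENIC: b.intergenic_locus,
        GENIC: b.genic_locus,
    }
    for cat, n in spec.novel_candidates.items():
        builders.append((dispatch[cat], n))
    tasks = [fn for fn, n in builders for _ in range(n)]
    rng.shuffle(tasks)
    for fn in tasks:
        fn()

    genome = _build_genome(b, rng)
    ann = b.ann

    if verify:
        index = classify_reference(ann)
        got = index.df["potential_category"].value_counts().to_dict()
        failing = [
            cat
            for cat, n in spec.novel_candidates.items()
            if got.get(cat, 0) < n
        ]
        if failing:
            raise FeasibilityError(
                f"guaranteed candidate counts not met for: {failing} "
                f"(achieved {[got.get(c, 0) for c in failing]})"
            )

    n_obs = max(2000, 2 * len(ann))
    count_table = np.round(rng.lognormal(mean=1.0, sigma=1.6, size=n_obs)) + 1
    iso_dist = rng.choice(
        np.arange(1, len(spec.isoform_counts) + 3),
        size=2000,
        p=_iso_probs(len(spec.isoform_counts) + 2),
    )
    cage = _synthetic_cage_peaks(ann, rng)
    return Fixture(genome, ann, count_table, iso_dist, cage)


def _iso_probs(k: int) -> np.ndarray:
    w = 1.0 / np.arange(1, k + 1)  # long-tailed: most genes express few isoforms
    return w / w.sum()


def _build_genome(b: _Builder, rng: np.random.Generator) -> GenomeStore:
    lengths: dict[str, int] = {}
    for t in b.ann:
        lengths[t.chrom] = max(lengths.get(t.chrom, 0), t.end + 1000)
    seqs: dict[str, str] = {}
    for chrom in sorted(lengths, key=lambda c: int(c[3:])):
        n = lengths[chrom]
        arr = rng.integers(0, 4, size=n).astype(np.uint8)
        arr = np.frombuffer(b"ACGT", dtype=np.uint8)[arr].copy()
        for js, je, strand in b.chrom_junctions.get(chrom, []):
            if strand == "+":
                arr[js - 1 : js + 1] = np.frombuffer(b"GT", dtype=np.uint8)
                arr[je - 2 : je] = np.frombuffer(b"AG", dtype=np.uint8)
            else:
                arr[js - 1 : js + 1] = np.frombuffer(b"CT", dtype=np.uint8)
                arr[je - 2 : je] = np.frombuffer(b"AC", dtype=np.uint8)
        seqs[chrom] = arr.tobytes().decode()
    return GenomeStore(seqs)


def _synthetic_cage_peaks(
    ann: AnnotationSet, rng: np.random.Generator, support_prob: float = 0.7
) -> pd.DataFrame:
    """Synthetic observed CAGE peaks for training: ~70% of TSSs get an
    overlapping peak, plus distal non-supporting peaks."""
    rows = []
    seen: set[tuple] = set()
    for t in ann:
        key = (t.chrom, t.tss, t.strand)
        if key in seen:
            continue
        seen.add(key)
        if rng.random() < support_prob:
            length = max(int(rng.lognormal(np.log(60), 0.4)), 10)
            center = t.tss + int(rng.normal(0, 8))
            start = center - length // 2
            end = start + length - 1
            if not (start <= t.tss <= end):
                start, end = t.tss - length // 2, t.tss + (length - length // 2) - 1
            rows.append((t.chrom, max(start, 1), end, t.strand))
        else:
            length = max(int(rng.lognormal(np.log(40), 0.5)), 10)
            off = int(rng.integers(300, 1200)) * (1 if rng.random() < 0.5 else -1)
            start = max(t.tss + off, 1)
            rows.append((t.chrom, start, start + length - 1, t.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
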