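"""Structural-category classification of transcripts against an annotation.

Implements the SQANTI3-style category scheme: FSM (full splice match), ISM
(incomplete splice match), NIC (novel in catalog), NNC (novel not in
catalog), fusion, antisense, intergenic and genic. A transcript is compared
against same-strand overlapping reference transcripts through a fixed
decision cascade; every query receives exactly one category.

Cascade (multi-exon query):
  1. junction chain equals a reference chain                  -> FSM
  2. chain is a contiguous sub-chain of a reference chain     -> ISM
  3. exonic overlap with >=2 distinct non-overlapping genes   -> fusion
  4. all donors/acceptors annotated, chain unmatched          -> NIC
  5. at least one unannotated donor or acceptor               -> NNC
  6. no same-strand overlap, opposite-strand gene overlap     -> antisense
  7. no gene overlap at all                                   -> intergenic
  (same-strand overlap with none of the above, e.g. a mono-exon
  transcript inside an intron, falls out as "genic")

Mono-exon queries: FSM against an overlapping mono-exon reference, ISM when
fully contained inside an exon of a multi-exon reference, otherwise
genic/antisense/intergenic by overlap.

Self-comparison is excluded when indexing a reference annotation: a
transcript compared against an annotation containing itself is trivially
FSM, so ``classify_reference`` classifies each transcript with itself
removed, yielding its *potential* category — the category it would receive
were it deleted from the annotation and rediscovered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .model import AnnotationSet, TranscriptModel

PathLike = Union[str, Path]

FSM = "FSM"
ISM = "ISM"
NIC = "NIC"
NNC = "NNC"
FUSION = "fusion"
ANTISENSE = "antisense"
INTERGENIC = "intergenic"
GENIC = "genic"

CATEGORIES = (FSM, ISM, NIC, NNC, FUSION, ANTISENSE, INTERGENIC, GENIC)
NOVEL_CATEGORIES = (ISM, NIC, NNC, FUSION, ANTISENSE, INTERGENIC, GENIC)

INDEX_COLUMNS = [
    "transcript_id",
    "gene_id",
    "chrom",
    "strand",
    "potential_category",
    "associated_transcript",
    "associated_gene",
    "spliced_length",
    "exon_count",
    "sim_type",
    "requested_counts",
    "requested_tpm",
]


@dataclass(frozen=True)
class StructuralCall:
    category: str
    associated_transcript: Optional[str] = None
    associated_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown structural category {self.category!r}")


def _is_contiguous_subchain(
    sub: Sequence[tuple[int, int]], chain: Sequence[tuple[int, int]]
) -> bool:
    n, m = len(sub), len(chain)
    if n == 0 or n > m:
        return False
    first = sub[0]
    for i in range(m - n + 1):
        if chain[i] == first and tuple(chain[i : i + n]) == tuple(sub):
            return True
    return False


def _shared_junctions(a: TranscriptModel, b: TranscriptModel) -> int:
    return len(set(a.junctions) & set(b.junctions))


def _pick_associated(
    query: TranscriptModel, candidates: Sequence[TranscriptModel]
) -> TranscriptModel:
    """Deterministic tie-break: most shared junctions, then longest spliced
    length, then lexicographically smallest id."""
    return min(
        candidates,
        key=lambda t: (-_shared_junctions(query, t), -t.spliced_length, t.transcript_id),
    )


def _exonic_overlap_len(query: TranscriptModel, ref: TranscriptModel) -> int:
    total = 0
    for qs, qe in query.exons:
        for rs, re_ in ref.exons:
            lo, hi = max(qs, rs), min(qe, re_)
            if lo <= hi:
                total += hi - lo + 1
    return total


def _gene_clusters(
    query: TranscriptModel, same_strand: Sequence[TranscriptModel]
) -> list[list[str]]:
    """Group same-strand overlapping genes into clusters of mutually
    overlapping gene spans (spans taken over the overlapping transcripts)."""
    spans: dict[str, list[int]] = {}
    for t in same_strand:
        sp = spans.setdefault(t.gene_id, [t.start, t.end])
        sp[0] = min(sp[0], t.start)
        sp[1] = max(sp[1], t.end)
    items = sorted(spans.items(), key=lambda kv: kv[1])
    clusters: list[list[str]] = []
    cur_end = -1
    for gid, (s, e) in items:
        if clusters and s <= cur_end:
            clusters[-1].append(gid)
            cur_end = max(cur_end, e)
        else:
            clusters.append([gid])
            cur_end = e
    return clusters


def classify_query(
    query: TranscriptModel,
    annotation: AnnotationSet,
    exclude_ids: frozenset[str] | set[str] = frozenset(),
) -> StructuralCall:
    """Assign the structural category of ``query`` relative to ``annotation``.

    ``exclude_ids`` removes reference transcripts from consideration (used
    for self-exclusion when indexing and for provisional-deletion audits).
    An empty annotation yields ``intergenic`` by definition.
    """
    if query.exon_count == 0:  # pragma: no cover - TranscriptModel forbids this
        raise ValueError("query transcript has zero exons")
    overlapping = annotation.overlapping(
        query.chrom, query.start, query.end, exclude=exclude_ids
    )
    same = [t for t in overlapping if t.strand == query.strand]
    opposite = [t for t in overlapping if t.strand != query.strand]

    if query.is_mono_exon:
        return _classify_mono_exon(query, same, opposite)

    chain = query.junctions
    multi_refs = [t for t in same if not t.is_mono_exon]

    fsm = [t for t in multi_refs if t.junctions == chain]
    if fsm:
        best = _pick_associated(query, fsm)
        return StructuralCall(FSM, best.transcript_id, best.gene_id)

    ism = [t for t in multi_refs if _is_contiguous_subchain(chain, t.junctions)]
    if ism:
        best = _pick_associated(query, ism)
        return StructuralCall(ISM, best.transcript_id, best.gene_id)

    if same:
        clusters = _gene_clusters(query, same)
        if len(clusters) >= 2:
            # exonic overlap with at least two non-overlapping gene clusters
            hit_clusters = []
            for cl in clusters:
                members = [t for t in same if t.gene_id in cl]
                if any(_exonic_overlap_len(query, t) > 0 for t in members):
                    hit_clusters.append(cl)
            if len(hit_clusters) >= 2:
                genes = sorted(g for cl in hit_clusters for g in cl)
                best = _pick_associated(
                    query,
                    [t for t in same if _exonic_overlap_len(query, t) > 0] or same,
                )
                return StructuralCall(FUSION, best.transcript_id, "_".join(genes))

        donors: set[int] = set()
        acceptors: set[int] = set()
        for t in multi_refs:
            donors.update(t.donors())
            acceptors.update(t.acceptors())
        q_donors, q_acceptors = query.donors(), query.acceptors()
        best = _pick_associated(query, same)
        if q_donors <= donors and q_acceptors <= acceptors:
            return StructuralCall(NIC, best.transcript_id, best.gene_id)
        return StructuralCall(NNC, best.transcript_id, best.gene_id)

    if opposite:
        best = _pick_associated(query, opposite)
        return StructuralCall(ANTISENSE, None, best.gene_id)
    return StructuralCall(INTERGENIC, None, None)


def _classify_mono_exon(
    query: TranscriptModel,
    same: Sequence[TranscriptModel],
    opposite: Sequence[TranscriptModel],
) -> StructuralCall:
    mono_refs = [t for t in same if t.is_mono_exon]
    if mono_refs:
        best = _pick_associated(query, mono_refs)
        return StructuralCall(FSM, best.transcript_id, best.gene_id)
    contained = [
        t
        for t in same
        if not t.is_mono_exon
        and any(s <= query.start and query.end <= e for s, e in t.exons)
    ]
    if contained:
        best = _pick_associated(query, contained)
        return StructuralCall(ISM, best.transcript_id, best.gene_id)
    if same:
        best = _pick_associated(query, same)
        return StructuralCall(GENIC, None, best.gene_id)
    if opposite:
        best = _pick_associated(query, opposite)
        return StructuralCall(ANTISENSE, None, best.gene_id)
    return StructuralCall(INTERGENIC, None, None)


class ClassificationIndex:
    """One row per annotated transcript: its potential structural category,
    associated reference transcript/gene, structural features, and (filled
    in later by the design stage) simulation status and requested reads."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in INDEX_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"index missing mandatory columns: {missing}")
        bad = set(df["potential_category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown category strings in index: {sorted(bad)}")
        self.df = df[INDEX_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def category_of(self, transcript_id: str) -> str:
        row = self.df.loc[self.df["transcript_id"] == transcript_id]
        if row.empty:
            raise KeyError(transcript_id)
        return row["potential_category"].iloc[0]

    def candidates(self, category: str, min_length: int = 0) -> list[str]:
        m = (self.df["potential_category"] == category) & (
            self.df["spliced_length"] >= min_length
        )
        return self.df.loc[m, "transcript_id"].tolist()

    def write(self, path: PathLike) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read(cls, path: PathLike) -> "ClassificationIndex":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"transcript_id": str, "gene_id": str, "chrom": str},
            na_values=["NA"],
            keep_default_na=False,
        )
        df["associated_transcript"] = df["associated_transcript"].where(
            df["associated_transcript"].notna(), None
        )
        df["associated_gene"] = df["associated_gene"].where(
            df["associated_gene"].notna(), None
        )
        return cls(df)


def classify_reference(annotation: AnnotationSet) -> ClassificationIndex:
    """Potential category for every annotated transcript, self excluded."""
    rows = []
    for t in annotation:
        call = classify_query(t, annotation, exclude_ids={t.transcript_id})
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "potential_category": call.category,
                "associated_transcript": call.associated_transcript,
                "associated_gene": call.associated_gene,
                "spliced_length": t.spliced_length,
                "exon_count": t.exon_count,
                "sim_type": "absent",
                "requested_counts": 0,
                "requested_tpm": 0.0,
            }
        )
    df = pd.DataFrame(rows, columns=INDEX_COLUMNS)
    df = df.sort_values("transcript_id", kind="mergesort").reset_index(drop=True)
    return ClassificationIndex(df)
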