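"""Scoring a reconstructed transcriptome against the simulation ground
truth.

A predicted multi-exon transcript is a true positive (TP) when its junction
chain equals that of a simulated expressed transcript and both its 5' and
3' ends lie within 50 nt of the simulated ends; a partial true positive
(PTP) matches all junctions but exceeds 50 nt at either end. Mono-exon
predictions match overlapping mono-exon simulated transcripts under the
same end rule. Anything detected but not simulated is a false positive
(FP); simulated expressed transcripts never recovered as TP are false
negatives (FN). Metrics per stratum:

    Pr  = TP / (TP + FP)            Sn  = TP / (TP + FN)
    F1  = TP / (TP + (FP + FN)/2)
    PDR = (TP + PTP) / (TP + FN)    FDR = FP / (TP + PTP + FP)

0/0 is reported as NA (NaN), never as 0.
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .classify import FSM, classify_query
from .design import SimulationDesign
from .model import AnnotationSet, TranscriptModel

PathLike = Union[str, Path]

END_TOLERANCE = 50  # nt, inclusive: offset <= 50 keeps a junction-match a TP

VERDICT_COLUMNS = [
    "transcript_id",
    "verdict",
    "matched_transcript",
    "category",
    "stratum",
    "offset5",
    "offset3",
    "duplicate",
]


@dataclass
class EvaluationCounts:
    tp: int = 0
    ptp: int = 0
    fp: int = 0
    fn: int = 0

    def add(self, verdict: str) -> None:
        if verdict == "TP":
            self.tp += 1
        elif verdict == "PTP":
            self.ptp += 1
        elif verdict == "FP":
            self.fp += 1
        elif verdict == "FN":
            self.fn += 1
        else:
            raise ValueError(f"unknown verdict {verdict!r}")


@dataclass
class MetricSet:
    sn: float
    pr: float
    f1: float
    pdr: float
    fdr: float
    counts: EvaluationCounts

    def as_dict(self) -> dict:
        def clean(x):
            return None if (isinstance(x, float) and math.isnan(x)) else x

        return {
            "Sn": clean(self.sn),
            "Pr": clean(self.pr),
            "F1": clean(self.f1),
            "PDR": clean(self.pdr),
            "FDR": clean(self.fdr),
            "TP": self.counts.tp,
            "PTP": self.counts.ptp,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
        }


def compute_metrics(counts: EvaluationCounts) -> MetricSet:
    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    tp, ptp, fp, fn = counts.tp, counts.ptp, counts.fp, counts.fn
    return MetricSet(
        sn=ratio(tp, tp + fn),
        pr=ratio(tp, tp + fp),
        f1=ratio(tp, tp + 0.5 * (fp + fn)),
        pdr=ratio(tp + ptp, tp + fn),
        fdr=ratio(fp, tp + ptp + fp),
        counts=counts,
    )


def _end_offsets(pred: TranscriptModel, sim: TranscriptModel) -> tuple[int, int]:
    return abs(pred.tss - sim.tss), abs(pred.tts - sim.tts)


def _sim_stratum(design: SimulationDesign, tid: str) -> tuple[str, str]:
    """(known/novel, category) of a simulated transcript."""
    if tid in design.novel:
        return "novel", design.novel[tid]
    return "known", FSM


def match_predictions(
    predicted: AnnotationSet, design: SimulationDesign
) -> tuple[pd.DataFrame, dict[str, EvaluationCounts]]:
    """Verdict per predicted transcript plus per-stratum tallies.

    Strata: ``overall``, ``known``, ``novel`` and each structural category.
    Simulated expressed transcripts can satisfy at most one TP; redundant
    junction-matching predictions are FP-duplicates. Unmatched predictions
    are structurally classified against the reduced annotation for
    per-category FP attribution.
    """
    sim_ids = design.expressed_ids()
    sims = {tid: design.annotation.transcripts[tid] for tid in sim_ids}
    by_chain: dict[tuple, list[str]] = defaultdict(list)
    mono_sims: dict[tuple[str, str], list[str]] = defaultdict(list)
    for tid, t in sims.items():
        if t.is_mono_exon:
            mono_sims[(t.chrom, t.strand)].append(tid)
        else:
            by_chain[(t.chrom, t.strand, t.junctions)].append(tid)

    # candidate (pred, sim) pairs with offsets
    pred_best: dict[str, tuple[str, int, int]] = {}
    for p in predicted:
        if p.is_mono_exon:
            cands = [
                tid
                for tid in mono_sims.get((p.chrom, p.strand), [])
                if sims[tid].start <= p.end and p.start <= sims[tid].end
            ]
        else:
            cands = by_chain.get((p.chrom, p.strand, p.junctions), [])
        if cands:
            best = min(
                cands,
                key=lambda tid: (max(_end_offsets(p, sims[tid])), tid),
            )
            o5, o3 = _end_offsets(p, sims[best])
            pred_best[p.transcript_id] = (best, o5, o3)

    # resolve TP claims: best (smallest max offset) prediction per sim wins
    claims: dict[str, list[str]] = defaultdict(list)
    for pid, (sid, o5, o3) in pred_best.items():
        if max(o5, o3) <= END_TOLERANCE:
            claims[sid].append(pid)
    tp_of_sim: dict[str, str] = {}
    for sid, pids in claims.items():
        pids.sort(key=lambda pid: (max(pred_best[pid][1], pred_best[pid][2]), pid))
        tp_of_sim[sid] = pids[0]

    rows = []
    counts: dict[str, EvaluationCounts] = defaultdict(EvaluationCounts)

    def tally(verdict: str, stratum: str, category: str) -> None:
        counts["overall"].add(verdict)
        counts[stratum].add(verdict)
        counts[category].add(verdict)

    matched_sims: set[str] = set()
    for p in predicted:
        pid = p.transcript_id
        if pid in pred_best:
            sid, o5, o3 = pred_best[pid]
            stratum, category = _sim_stratum(design, sid)
            if max(o5, o3) <= END_TOLERANCE:
                if tp_of_sim.get(sid) == pid:
                    verdict, dup = "TP", False
                    matched_sims.add(sid)
                else:
                    verdict, dup = "FP", True  # redundant match
            else:
                verdict, dup = "PTP", False
            tally(verdict, stratum, category)
            rows.append((pid, verdict, sid, category, stratum, o5, o3, dup))
        else:
            call = classify_query(p, design.reduced)
            stratum = "known" if call.category == FSM else "novel"
            tally("FP", stratum, call.category)
            rows.append(
                (pid, "FP", None, call.category, stratum, None, None, False)
            )

    for sid in sim_ids:
        if sid not in matched_sims:
            stratum, category = _sim_stratum(design, sid)
            tally("FN", stratum, category)
            rows.append((sid, "FN", None, category, stratum, None, None, False))

    verdicts = pd.DataFrame(rows, columns=VERDICT_COLUMNS)
    return verdicts, dict(counts)


def evaluate(
    predicted: AnnotationSet, design: SimulationDesign
) -> tuple[pd.DataFrame, dict[str, MetricSet]]:
    verdicts, counts = match_predictions(predicted, design)
    return verdicts, {k: compute_metrics(v) for k, v in counts.items()}


def gene_level_metrics(
    verdicts: pd.DataFrame, design: SimulationDesign, predicted: AnnotationSet
) -> MetricSet:
    """A simulated gene is detected when any of its simulated expressed
    transcripts is a TP or PTP; predicted genes mapping to no simulated
    gene are gene-level FPs."""
    sim_genes = {
        design.annotation.transcripts[tid].gene_id for tid in design.expressed_ids()
    }
    detected = set()
    for r in verdicts.itertuples():
        if r.verdict in ("TP", "PTP") and r.matched_transcript is not None:
            detected.add(design.annotation.transcripts[r.matched_transcript].gene_id)
    fp_pred_genes = set()
    hit = {
        r.transcript_id: r
        for r in verdicts.itertuples()
        if r.verdict in ("TP", "PTP")
    }
    for p in predicted:
        if p.transcript_id not in hit:
            fp_pred_genes.add(p.gene_id)
    counts = EvaluationCounts(
        tp=len(detected),
        fp=len(fp_pred_genes),
        fn=len(sim_genes - detected),
    )
    return compute_metrics(counts)


def support_summary(
    verdicts: pd.DataFrame,
    predicted: AnnotationSet,
    design: SimulationDesign,
    sr_truth: Optional[pd.DataFrame] = None,
    read_length: int = 100,
    cage_peaks: Optional[pd.DataFrame] = None,
    min_cov: int = 1,
) -> pd.DataFrame:
    """Per-prediction orthogonal support: minimum short-read coverage across
    junctions (from fragment truth coordinates) and CAGE-peak overlap at the
    TSS; cross-tabulated columns appended to the verdict rows."""
    junction_cov: Counter = Counter()
    if sr_truth is not None:
        from .shortread import read_genomic_blocks

        for chrom, strand, blocks in read_genomic_blocks(
            design, sr_truth, read_length
        ):
            for (s1, e1), (s2, _e2) in zip(blocks, blocks[1:]):
                junction_cov[(chrom, strand, e1 + 1, s2 - 1)] += 1

    rows = []
    for r in verdicts.itertuples():
        if r.transcript_id in predicted.transcripts:
            t = predicted.transcripts[r.transcript_id]
        elif r.transcript_id in design.annotation.transcripts:  # FN rows
            t = design.annotation.transcripts[r.transcript_id]
        else:  # pragma: no cover
            continue
        if sr_truth is not None and t.junctions:
            mc = min(
                junction_cov.get((t.chrom, t.strand, j[0], j[1]), 0)
                for j in t.junctions
            )
        elif sr_truth is not None:
            mc = None
        else:
            mc = None
        cage = None
        if cage_peaks is not None:
            sel = cage_peaks[
                (cage_peaks["chrom"] == t.chrom)
                & (cage_peaks["strand"] == t.strand)
            ]
            cage = bool(((sel["start"] <= t.tss) & (sel["end"] >= t.tss)).any())
        rows.append(
            (
                r.transcript_id,
                r.verdict,
                r.category,
                mc,
                (mc is not None and mc > min_cov),
                cage,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "verdict",
            "category",
            "min_junction_cov",
            "sj_supported",
            "cage_supported",
        ],
    )


def write_report(
    metrics: dict[str, MetricSet],
    verdicts: pd.DataFrame,
    json_path: PathLike,
    tsv_path: Optional[PathLike] = None,
    gene_metrics: Optional[MetricSet] = None,
) -> dict:
    payload = {"isoform": {k: m.as_dict() for k, m in metrics.items()}}
    if gene_metrics is not None:
        payload["gene"] = gene_metrics.as_dict()
    Path(json_path).write_text(json.dumps(payload, indent=2))
    if tsv_path is not None:
        verdicts.to_csv(tsv_path, sep="\t", index=False, na_rep="NA")
    return payload


def plot_descriptives(
    verdicts: pd.DataFrame, design: SimulationDesign, out_path: PathLike
) -> None:
    """Length / exon-count / expression distributions of TP vs FP vs FN."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    info = design.index.df.set_index("transcript_id")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    groups = {v: verdicts[verdicts["verdict"] == v] for v in ("TP", "FP", "FN")}
    for ax, (col, label) in zip(
        axes,
        [
            ("spliced_length", "spliced length (nt)"),
            ("exon_count", "exons"),
            ("requested_counts", "simulated reads"),
        ],
    ):
        for v, grp in groups.items():
            ids = [t for t in grp["transcript_id"] if t in info.index]
            if ids:
                vals = info.loc[ids, col].astype(float)
                ax.hist(np.log10(vals + 1), bins=30, alpha=0.5, label=v)
        ax.set_xlabel(f"log10 {label}")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
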