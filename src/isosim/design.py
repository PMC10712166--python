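"""Simulation design: pick transcripts to delete per novelty category,
build the reduced annotation, and assign expression.

The selection is greedy and seeded: per-category candidate lists are
shuffled, and a candidate is accepted only if it is long enough, its
associated reference transcript has not itself been selected for deletion,
and re-classification against the provisional reduced annotation still
yields the assigned category. Accepting a candidate locks its associated
transcript as "retained". A final audit pass re-classifies every selected
transcript against the final reduced annotation and swaps out violators
until the requested counts are met or candidates are exhausted — so the
ground-truth novelty of every deleted transcript is asserted with the same
classifier the evaluation stage uses, not assumed from construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .classify import (
    FSM,
    NOVEL_CATEGORIES,
    ClassificationIndex,
    classify_query,
)
from .model import AnnotationSet

log = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 200  # nt; avoids simulating small RNAs


@dataclass
class NoveltyRequest:
    """Requested novel-transcript counts per structural category plus the
    number of known (FSM) transcripts to simulate."""

    counts: dict[str, int] = field(default_factory=dict)
    n_known: int = 0
    min_length: int = DEFAULT_MIN_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        for cat, n in self.counts.items():
            if cat not in NOVEL_CATEGORIES:
                raise ValueError(f"{cat!r} is not a novel structural category")
            if n < 0:
                raise ValueError("requested counts must be >= 0")
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")


@dataclass
class ExpressionConfig:
    """How read counts are assigned to the selected transcripts.

    ``mode`` is one of ``equal`` (same value for every transcript),
    ``custom`` (two negative-binomial distributions, one for known and one
    for novel transcripts) or ``sample`` (inverse-transform sampling from
    the ECDF of an empirical raw-count table). ``diff_exp`` biases high
    expression values toward known transcripts: sampled values are assigned
    in weighted-order where a known transcript's odds of receiving the next
    largest value are exp(diff_exp) times a novel transcript's; 0 means
    exchangeable.
    """

    mode: str = "equal"
    long_count: int = 10_000
    nb_known: tuple[float, float] = (2.0, 100.0)  # (size, mean)
    nb_novel: tuple[float, float] = (2.0, 100.0)
    sample_counts: Optional[np.ndarray] = None
    diff_exp: float = 0.0
    iso_complex: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("equal", "custom", "sample"):
            raise ValueError(f"unknown expression mode {self.mode!r}")
        if self.diff_exp < 0:
            raise ValueError("diff_exp must be >= 0")
        for size, mu in (self.nb_known, self.nb_novel):
            if size <= 0 or mu < 0:
                raise ValueError("negative-binomial parameters must be positive")
        if self.mode == "sample":
            if self.sample_counts is None or len(self.sample_counts) == 0:
                raise ValueError("sample mode requires a non-empty count table")


@dataclass
class SimulationDesign:
    """The ground-truth partition every later stage consumes."""

    novel: dict[str, str]  # transcript id -> assigned category
    known: list[str]
    annotation: AnnotationSet  # full input annotation
    reduced: AnnotationSet  # input minus novel
    index: ClassificationIndex
    expressed: Optional[set[str]] = None  # subset receiving reads; None = all
    counts: Optional[pd.Series] = None  # per-transcript read counts
    tpm: Optional[pd.Series] = None

    @property
    def simulated_ids(self) -> list[str]:
        return list(self.novel) + list(self.known)

    def expressed_ids(self) -> list[str]:
        if self.expressed is None:
            return self.simulated_ids
        return [t for t in self.simulated_ids if t in self.expressed]


def select_novel_set(
    index: ClassificationIndex,
    annotation: AnnotationSet,
    request: NoveltyRequest,
    max_audit_rounds: int = 10,
) -> SimulationDesign:
    """Greedy seeded selection of the novel set with delete-and-reclassify
    auditing; see module docstring for the acceptance rules."""
    rng = np.random.default_rng(request.seed)
    selected: dict[str, str] = {}
    retained: set[str] = set()

    assoc_map = dict(
        zip(index.df["transcript_id"], index.df["associated_transcript"])
    )

    def try_accept(tid: str, category: str) -> bool:
        if tid in selected or tid in retained:
            return False
        assoc = assoc_map.get(tid)
        if isinstance(assoc, float) and math.isnan(assoc):
            assoc = None
        if assoc is not None and assoc in selected:
            return False
        t = annotation.transcripts[tid]
        call = classify_query(t, annotation, exclude_ids=set(selected) | {tid})
        if call.category != category:
            return False
        selected[tid] = category
        if assoc is not None:
            retained.add(assoc)
        return True

    pools: dict[str, list[str]] = {}
    for cat, n_req in request.counts.items():
        pool = index.candidates(cat, min_length=request.min_length)
        perm = rng.permutation(len(pool))
        pools[cat] = [pool[i] for i in perm]

    for cat, n_req in request.counts.items():
        got = 0
        pool_iter = iter(pools[cat])
        while got < n_req:
            tid = next(pool_iter, None)
            if tid is None:
                break
            if try_accept(tid, cat):
                got += 1
        if got < n_req:
            log.warning(
                "category %s: only %d of %d requested candidates selected",
                cat,
                got,
                n_req,
            )
        pools[cat] = list(pool_iter)  # unused remainder, for audit swaps

    # final audit: re-classify against the final reduced annotation; swap out
    # violators and refill from the unused pools until stable
    for _round in range(max_audit_rounds):
        violators = []
        excl = set(selected)
        for tid, cat in selected.items():
            t = annotation.transcripts[tid]
            if classify_query(t, annotation, exclude_ids=excl).category != cat:
                violators.append(tid)
        if not violators:
            break
        for tid in violators:
            cat = selected.pop(tid)
            pool_iter = iter(pools[cat])
            while True:
                repl = next(pool_iter, None)
                if repl is None or try_accept(repl, cat):
                    break
            pools[cat] = list(pool_iter)

    reduced = annotation.remove(selected)
    achieved: dict[str, int] = {}
    for cat in request.counts:
        achieved[cat] = sum(1 for c in selected.values() if c == cat)

    # known transcripts drawn from the retained (non-deleted) pool
    known_pool = [
        tid
        for tid in index.df.loc[
            index.df["spliced_length"] >= request.min_length, "transcript_id"
        ]
        if tid not in selected
    ]
    if request.n_known > len(known_pool):
        log.warning(
            "requested %d known transcripts but only %d available",
            request.n_known,
            len(known_pool),
        )
    n_known = min(request.n_known, len(known_pool))
    known = [known_pool[i] for i in rng.permutation(len(known_pool))[:n_known]]
    known.sort()

    df = index.df.copy()
    df["sim_type"] = "absent"
    df.loc[df["transcript_id"].isin(selected), "sim_type"] = "novel"
    df.loc[df["transcript_id"].isin(known), "sim_type"] = "known"
    new_index = ClassificationIndex(df)

    return SimulationDesign(
        novel=dict(selected),
        known=known,
        annotation=annotation,
        reduced=reduced,
        index=new_index,
    )


def design_from_index(
    annotation: AnnotationSet, index: ClassificationIndex
) -> SimulationDesign:
    """Rebuild a :class:`SimulationDesign` from a written design index
    (sim_type/requested_counts columns), e.g. between CLI stages."""
    df = index.df
    novel = dict(
        zip(
            df.loc[df["sim_type"] == "novel", "transcript_id"],
            df.loc[df["sim_type"] == "novel", "potential_category"],
        )
    )
    known = df.loc[df["sim_type"] == "known", "transcript_id"].tolist()
    design = SimulationDesign(
        novel=novel,
        known=known,
        annotation=annotation,
        reduced=annotation.remove(novel),
        index=index,
    )
    counts = pd.Series(
        df["requested_counts"].to_numpy(), index=df["transcript_id"], dtype=int
    )
    if counts.sum() > 0:
        design.counts = counts
        design.tpm = pd.Series(
            df["requested_tpm"].to_numpy(), index=df["transcript_id"], dtype=float
        )
        design.expressed = set(counts.index[counts > 0]) & set(design.simulated_ids)
    return design


def build_reduced_annotation(design: SimulationDesign, gtf_path=None) -> AnnotationSet:
    """The input annotation minus the novel set; optionally written to GTF
    (genes emptied by deletion are dropped)."""
    reduced = design.annotation.remove(design.novel)
    design.reduced = reduced
    if gtf_path is not None:
        from .annotation_io import write_gtf

        write_gtf(reduced, gtf_path)
    return reduced


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    quota = w / w.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
    return base


def _weighted_order(is_known: np.ndarray, diff_exp: float, rng) -> np.ndarray:
    """Order in which transcripts receive the descending-sorted expression
    values: a weighted sample without replacement (Efraimidis-Spirakis keys)
    with weight exp(diff_exp) for known and 1 for novel transcripts."""
    w = np.where(is_known, math.exp(diff_exp), 1.0)
    u = rng.random(len(w))
    keys = np.power(u, 1.0 / w)
    return np.argsort(-keys, kind="stable")


def assign_expression(
    design: SimulationDesign, config: ExpressionConfig, seed: int = 0
) -> pd.Series:
    """Per-transcript read counts summing exactly to ``long_count``."""
    rng = np.random.default_rng(seed)
    ids = design.expressed_ids()
    n = len(ids)
    if n == 0:
        raise ValueError("no transcripts selected for expression")
    if config.long_count < n:
        log.warning(
            "long_count %d < %d transcripts: some will get 0 reads",
            config.long_count,
            n,
        )
    is_known = np.array([tid in set(design.known) for tid in ids])

    if config.mode == "equal":
        values = np.ones(n)
    elif config.mode == "custom":
        size_k, mu_k = config.nb_known
        size_n, mu_n = config.nb_novel
        values = np.empty(n)
        nk = int(is_known.sum())
        values[is_known] = rng.negative_binomial(size_k, size_k / (size_k + mu_k), nk)
        values[~is_known] = rng.negative_binomial(
            size_n, size_n / (size_n + mu_n), n - nk
        )
        values = values + 1e-9  # keep zero-count draws allocatable
    else:  # sample: inverse-transform from the empirical ECDF
        table = np.sort(np.asarray(config.sample_counts, dtype=float))
        u = rng.random(n)
        values = table[np.minimum((u * len(table)).astype(int), len(table) - 1)]

    if config.diff_exp > 0 and config.mode != "equal":
        order = _weighted_order(is_known, config.diff_exp, rng)
        sorted_vals = np.sort(values)[::-1]
        out = np.empty(n)
        out[order] = sorted_vals
        values = out
    counts = _largest_remainder(values, config.long_count)

    series = pd.Series(0, index=design.index.df["transcript_id"], dtype=int)
    series.loc[ids] = counts
    design.counts = series

    lengths = pd.Series(
        design.index.df["spliced_length"].values,
        index=design.index.df["transcript_id"],
    ).astype(float)
    rate = series / lengths
    total_rate = rate.sum()
    design.tpm = rate / total_rate * 1e6 if total_rate > 0 else rate * 0.0

    df = design.index.df
    df["requested_counts"] = series.loc[df["transcript_id"]].values
    df["requested_tpm"] = design.tpm.loc[df["transcript_id"]].values
    return series


def match_isoform_complexity(
    design: SimulationDesign,
    isoform_count_dist: np.ndarray,
    seed: int = 0,
) -> set[str]:
    """Restrict the expressed set so per-gene expressed-isoform counts follow
    an empirical distribution. Novel transcripts always stay expressed;
    surplus known isoforms are dropped (they will receive zero reads)."""
    rng = np.random.default_rng(seed)
    dist = np.sort(np.asarray(isoform_count_dist, dtype=int))
    if len(dist) == 0:
        raise ValueError("empty isoform-count distribution")
    by_gene: dict[str, dict[str, list[str]]] = {}
    novel_set = set(design.novel)
    for tid in design.simulated_ids:
        gid = design.annotation.transcripts[tid].gene_id
        slot = by_gene.setdefault(gid, {"novel": [], "known": []})
        slot["novel" if tid in novel_set else "known"].append(tid)
    expressed: set[str] = set()
    for gid, slot in by_gene.items():
        u = rng.random()
        k = int(dist[min(int(u * len(dist)), len(dist) - 1)])
        avail = len(slot["novel"]) + len(slot["known"])
        k = min(max(k, len(slot["novel"])), avail)
        expressed.update(slot["novel"])
        n_known = k - len(slot["novel"])
        if n_known > 0:
            ks = sorted(slot["known"])
            pick = rng.permutation(len(ks))[:n_known]
            expressed.update(ks[i] for i in pick)
    design.expressed = expressed
    return expressed
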