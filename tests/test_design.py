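"""Novelty selection, reduced annotation, and expression assignment."""

import logging

import numpy as np
import pytest
from scipy import stats

from isosim import (
    ExpressionConfig,
    NoveltyRequest,
    assign_expression,
    classify_query,
    classify_reference,
    match_isoform_complexity,
    select_novel_set,
)
from isosim.classify import ISM, NNC, NOVEL_CATEGORIES
from isosim.design import _largest_remainder

from conftest import make_annotation, make_transcript

from hypothesis import given, settings
from hypothesis import strategies as st


def toy_ism_annotation():
    """One gene: two full-length isoforms (FSM pair) + one truncated (ISM)."""
    full = [(100, 200), (300, 400), (500, 600), (700, 800)]
    return make_annotation(
        make_transcript("full_a", "g1", "chr1", "+", full),
        make_transcript("full_b", "g1", "chr1", "+", [(140, 200)] + full[1:]),
        make_transcript("trunc", "g1", "chr1", "+", full[1:]),
    )


class TestSelection:
    def test_single_candidate_forced(self):
        ann = toy_ism_annotation()
        index = classify_reference(ann)
        design = select_novel_set(
            index, ann, NoveltyRequest(counts={ISM: 1}, seed=0)
        )
        assert design.novel == {"trunc": ISM}
        # its associated full-length isoform was retained
        assert "full_a" in design.reduced.transcripts

    def test_insufficient_candidates_warns(self, caplog):
        ann = toy_ism_annotation()
        index = classify_reference(ann)
        with caplog.at_level(logging.WARNING):
            design = select_novel_set(
                index, ann, NoveltyRequest(counts={ISM: 5}, seed=0)
            )
        assert sum(1 for c in design.novel.values() if c == ISM) == 1
        assert any("requested" in r.message for r in caplog.records)

    def test_delete_and_reclassify_audit_holds(self, small_fixture, small_design):
        """Every selected novel transcript keeps its assigned category when
        re-classified against the reduced annotation."""
        ann = small_fixture.annotation
        for tid, cat in small_design.novel.items():
            call = classify_query(ann.transcripts[tid], small_design.reduced)
            assert call.category == cat

    def test_min_length_rule(self, small_design, small_fixture):
        for tid in small_design.novel:
            assert small_fixture.annotation.transcripts[tid].spliced_length >= 200

    def test_partition_and_reduction(self, small_fixture, small_design):
        ann = small_fixture.annotation
        novel = set(small_design.novel)
        assert novel.isdisjoint(small_design.known)
        assert set(small_design.reduced.transcripts) == set(ann.transcripts) - novel

    def test_empty_request_is_identity(self, small_fixture, small_index):
        design = select_novel_set(
            small_index, small_fixture.annotation, NoveltyRequest(counts={}, seed=0)
        )
        assert design.novel == {}
        assert len(design.reduced) == len(small_fixture.annotation)

    def test_seeded_determinism(self, small_fixture, small_index):
        req = NoveltyRequest(counts={c: 4 for c in NOVEL_CATEGORIES}, n_known=30, seed=99)
        d1 = select_novel_set(small_index, small_fixture.annotation, req)
        d2 = select_novel_set(small_index, small_fixture.annotation, req)
        assert d1.novel == d2.novel
        assert d1.known == d2.known


class TestExpression:
    def test_equal_mode_splits_evenly(self, small_fixture, small_index):
        ann = small_fixture.annotation
        design = select_novel_set(
            small_index, ann, NoveltyRequest(counts={}, n_known=10, seed=1)
        )
        counts = assign_expression(
            design, ExpressionConfig(mode="equal", long_count=1000), seed=0
        )
        assert (counts.loc[design.known] == 100).all()

    @pytest.mark.parametrize("mode", ["equal", "custom", "sample"])
    def test_reads_sum_to_long_count(self, small_fixture, small_index, mode):
        design = select_novel_set(
            small_index,
            small_fixture.annotation,
            NoveltyRequest(counts={c: 5 for c in NOVEL_CATEGORIES}, n_known=60, seed=2),
        )
        cfg = ExpressionConfig(
            mode=mode,
            long_count=12_345,
            sample_counts=small_fixture.count_table if mode == "sample" else None,
        )
        counts = assign_expression(design, cfg, seed=5)
        assert counts.sum() == 12_345

    def test_diff_exp_biases_known_over_novel(self, small_design):
        counts = small_design.counts
        known_mean = counts.loc[small_design.known].mean()
        novel_mean = counts.loc[list(small_design.novel)].mean()
        assert known_mean > novel_mean

    def test_diff_exp_monotone_in_expectation(self, small_fixture, small_index):
        design = select_novel_set(
            small_index,
            small_fixture.annotation,
            NoveltyRequest(counts={c: 6 for c in NOVEL_CATEGORIES}, n_known=60, seed=3),
        )
        means = []
        for diff_exp in (0.0, 1.0, 3.0):
            novel_means = []
            for seed in range(5):
                cfg = ExpressionConfig(
                    mode="sample",
                    long_count=50_000,
                    sample_counts=small_fixture.count_table,
                    diff_exp=diff_exp,
                )
                counts = assign_expression(design, cfg, seed=seed)
                novel_means.append(counts.loc[list(design.novel)].mean())
            means.append(np.mean(novel_means))
        assert means[0] > means[1] > means[2]

    def test_sample_mode_reproduces_source_ecdf(self, small_fixture, small_index):
        """Inverse-transform oracle: a table of 90% ones / 10% hundreds
        yields ~90% low counts."""
        design = select_novel_set(
            small_index,
            small_fixture.annotation,
            NoveltyRequest(counts={}, n_known=200, seed=4),
        )
        table = np.array([1.0] * 90 + [100.0] * 10)
        cfg = ExpressionConfig(mode="sample", long_count=100_000, sample_counts=table)
        counts = assign_expression(design, cfg, seed=6)
        vals = counts.loc[design.known].to_numpy()
        # counts are rescaled to long_count, so the two-point shape survives
        # as a low/high split at half the maximum
        frac_low = (vals < vals.max() / 2).mean()
        assert 0.80 < frac_low < 0.97

    def test_invalid_nb_params_rejected(self):
        with pytest.raises(ValueError):
            ExpressionConfig(mode="custom", nb_known=(-1.0, 10.0))

    def test_sample_mode_requires_table(self):
        with pytest.raises(ValueError):
            ExpressionConfig(mode="sample", sample_counts=None)

    def test_tpm_normalization(self, small_design):
        tpm = small_design.tpm
        assert tpm is not None
        assert np.isclose(tpm.sum(), 1e6)


class TestIsoformComplexity:
    def test_degenerate_distribution_one_isoform_per_gene(
        self, small_fixture, small_index
    ):
        design = select_novel_set(
            small_index,
            small_fixture.annotation,
            NoveltyRequest(counts={ISM: 4, NNC: 4}, n_known=120, seed=5),
        )
        expressed = match_isoform_complexity(design, np.array([1]), seed=1)
        novel = set(design.novel)
        by_gene = {}
        for tid in expressed:
            gid = small_fixture.annotation.transcripts[tid].gene_id
            by_gene.setdefault(gid, []).append(tid)
        for gid, members in by_gene.items():
            n_novel = sum(1 for t in members if t in novel)
            assert len(members) == max(1, n_novel)
        assert novel <= expressed  # novel transcripts always stay expressed

    def test_disabled_flag_keeps_all(self, small_design):
        assert small_design.expressed is None
        assert set(small_design.expressed_ids()) == set(small_design.simulated_ids)

    def test_distribution_reproduced(self, small_fixture, small_index):
        """Chi-square GOF non-rejection for the per-gene isoform counts."""
        design = select_novel_set(
            small_index,
            small_fixture.annotation,
            NoveltyRequest(counts={}, n_known=len(small_index), seed=6),
        )
        dist = np.array([1] * 50 + [2] * 30 + [3] * 20)
        expressed = match_isoform_complexity(design, dist, seed=2)
        by_gene = {}
        for tid in expressed:
            gid = small_fixture.annotation.transcripts[tid].gene_id
            by_gene[gid] = by_gene.get(gid, 0) + 1
        # only genes with >=3 available isoforms can realize every draw
        ann = small_fixture.annotation
        counts = np.array(
            [k for g, k in by_gene.items() if len(ann.genes[g]) >= 3]
        )
        if len(counts) >= 30:
            obs = np.array([(counts == k).sum() for k in (1, 2, 3)])
            exp = np.array([0.5, 0.3, 0.2]) * obs.sum()
            p = stats.chisquare(obs, exp).pvalue
            assert p > 0.01


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    weights=st.lists(st.floats(0.0, 1e6, allow_nan=False), min_size=1, max_size=40),
    total=st.integers(0, 10_000),
)
def test_largest_remainder_conserves_total(weights, total):
    alloc = _largest_remainder(np.array(weights), total)
    assert alloc.sum() == total
    assert (alloc >= 0).all()
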