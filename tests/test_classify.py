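"""Structural-category classification: cascade rules, index, oracle."""

import numpy as np
import pandas as pd
import pytest

from isosim import (
    ClassificationIndex,
    classify_query,
    classify_reference,
)
from isosim.classify import (
    ANTISENSE,
    FSM,
    FUSION,
    GENIC,
    INTERGENIC,
    ISM,
    NIC,
    NNC,
)

from conftest import make_annotation, make_transcript

# a 3-exon reference: exons 100-200, 300-400, 500-600 -> junctions
# (201,299), (401,499)
REF = make_transcript("ref", "g1", "chr1", "+", [(100, 200), (300, 400), (500, 600)])


def q(exons, strand="+", tid="q", gid="gq"):
    return make_transcript(tid, gid, "chr1", strand, exons)


class TestCascadeRules:
    def test_identical_chain_is_fsm(self):
        ann = make_annotation(REF)
        call = classify_query(q([(120, 200), (300, 400), (500, 580)]), ann)
        assert call.category == FSM
        assert call.associated_transcript == "ref"

    def test_missing_terminal_junction_is_ism(self):
        ann = make_annotation(REF)
        call = classify_query(q([(320, 400), (500, 600)]), ann)
        assert call.category == ISM
        assert call.associated_transcript == "ref"

    def test_unannotated_donor_is_nnc(self):
        ann = make_annotation(REF)
        # donor shifted from 201 to 191
        call = classify_query(q([(100, 190), (300, 400), (500, 600)]), ann)
        assert call.category == NNC

    def test_known_sites_novel_combination_is_nic(self):
        ann = make_annotation(REF)
        # skip middle exon: donor of junction 1 + acceptor of junction 2
        call = classify_query(q([(100, 200), (500, 600)]), ann)
        assert call.category == NIC

    def test_antisense_mono_exon(self):
        ann = make_annotation(REF)
        call = classify_query(q([(150, 450)], strand="-"), ann)
        assert call.category == ANTISENSE
        assert call.associated_gene == "g1"

    def test_intergenic_far_away(self):
        ann = make_annotation(REF)
        assert classify_query(q([(5000, 5400)]), ann).category == INTERGENIC

    def test_empty_annotation_is_intergenic(self):
        assert classify_query(q([(100, 400)]), make_annotation()).category == INTERGENIC

    def test_mono_exon_in_intron_is_genic(self):
        ann = make_annotation(REF)
        assert classify_query(q([(210, 290)]), ann).category == GENIC

    def test_mono_exon_within_exon_is_ism(self):
        ann = make_annotation(REF)
        assert classify_query(q([(310, 390)]), ann).category == ISM

    def test_mono_exon_matching_mono_reference_is_fsm(self):
        mono_ref = make_transcript("m", "g2", "chr1", "+", [(1000, 1500)])
        ann = make_annotation(mono_ref)
        assert classify_query(q([(1100, 1400)]), ann).category == FSM

    def test_fusion_spans_two_genes(self):
        gene_b = make_transcript(
            "refB", "g2", "chr1", "+", [(2000, 2100), (2300, 2400)]
        )
        ann = make_annotation(REF, gene_b)
        # bridges exons of g1 and g2
        call = classify_query(q([(100, 200), (300, 400), (2000, 2100), (2300, 2400)]), ann)
        assert call.category == FUSION
        assert call.associated_gene == "g1_g2"

    def test_exclusion_removes_reference(self):
        ann = make_annotation(REF)
        copy = q([(100, 200), (300, 400), (500, 600)])
        assert classify_query(copy, ann).category == FSM
        assert classify_query(copy, ann, exclude_ids={"ref"}).category == INTERGENIC


class TestClassifyReference:
    def test_shared_chain_gives_mutual_fsm(self):
        t1 = make_transcript("a", "g", "chr1", "+", [(100, 200), (300, 400)])
        t2 = make_transcript("b", "g", "chr1", "+", [(130, 200), (300, 380)])
        index = classify_reference(make_annotation(t1, t2))
        assert set(index.df["potential_category"]) == {FSM}

    def test_row_per_transcript_and_no_self_fsm(self, small_fixture, small_index):
        ann = small_fixture.annotation
        assert len(small_index) == len(ann)
        # delete-and-reclassify oracle: the index entry equals classify_query
        # with the transcript itself excluded
        rng = np.random.default_rng(0)
        ids = list(ann.transcripts)
        for tid in rng.choice(ids, size=60, replace=False):
            call = classify_query(ann.transcripts[tid], ann, exclude_ids={tid})
            assert call.category == small_index.category_of(tid)

    def test_determinism_under_insertion_order(self, small_fixture):
        ann = small_fixture.annotation
        shuffled = make_annotation(
            *[ann.transcripts[t] for t in sorted(ann.transcripts, reverse=True)]
        )
        a = classify_reference(ann).df
        b = classify_reference(shuffled).df
        pd.testing.assert_frame_equal(a, b)


class TestIndexIO:
    def test_round_trip(self, small_index, tmp_path):
        p = tmp_path / "index.tsv"
        small_index.write(p)
        again = ClassificationIndex.read(p)
        pd.testing.assert_frame_equal(
            small_index.df, again.df, check_dtype=False
        )

    def test_unknown_category_rejected(self, small_index, tmp_path):
        p = tmp_path / "bad.tsv"
        df = small_index.df.copy()
        df.loc[0, "potential_category"] = "bogus"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="category"):
            ClassificationIndex.read(p)

    def test_missing_column_rejected(self, small_index, tmp_path):
        p = tmp_path / "bad2.tsv"
        small_index.df.drop(columns=["strand"]).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing"):
            ClassificationIndex.read(p)

    def test_empty_index_is_header_only(self, tmp_path):
        from isosim.classify import INDEX_COLUMNS

        idx = ClassificationIndex(pd.DataFrame(columns=INDEX_COLUMNS))
        p = tmp_path / "empty.tsv"
        idx.write(p)
        assert p.read_text().strip() == "\t".join(INDEX_COLUMNS)


# ---------------------------------------------------------------------------
# brute-force oracle: an independent re-statement of the category rules that
# scans every reference transcript with no interval index and enumerates all
# contiguous sub-chains explicitly.
# ---------------------------------------------------------------------------


def brute_force_classify(query, transcripts, exclude=frozenset()):
    refs = [
        t
        for t in transcripts
        if t.transcript_id not in exclude
        and t.chrom == query.chrom
        and t.start <= query.end
        and query.start <= t.end
    ]
    same = [t for t in refs if t.strand == query.strand]
    opposite = [t for t in refs if t.strand != query.strand]

    def exonic_overlap(a, b):
        return any(
            max(s1, s2) <= min(e1, e2)
            for s1, e1 in a.exons
            for s2, e2 in b.exons
        )

    if query.is_mono_exon:
        if any(t.is_mono_exon for t in same):
            return FSM
        if any(
            s <= query.start and query.end <= e
            for t in same
            if not t.is_mono_exon
            for s, e in t.exons
        ):
            return ISM
        if same:
            return GENIC
        return ANTISENSE if opposite else INTERGENIC

    chain = tuple(query.junctions)
    chains = [tuple(t.junctions) for t in same if not t.is_mono_exon]
    if any(c == chain for c in chains):
        return FSM
    subchains = {
        c[i : i + k]
        for c in chains
        for k in range(1, len(c) + 1)
        for i in range(len(c) - k + 1)
    }
    if chain in subchains:
        return ISM
    # fusion: gene spans over overlapping transcripts, >=2 disjoint groups hit
    spans = {}
    for t in same:
        s, e = spans.get(t.gene_id, (t.start, t.end))
        spans[t.gene_id] = (min(s, t.start), max(e, t.end))
    genes = sorted(spans.items(), key=lambda kv: kv[1])
    groups, cur_end = [], None
    for gid, (s, e) in genes:
        if cur_end is not None and s <= cur_end:
            groups[-1].append(gid)
            cur_end = max(cur_end, e)
        else:
            groups.append([gid])
            cur_end = e
    hit = [
        g
        for g in groups
        if any(exonic_overlap(query, t) for t in same if t.gene_id in g)
    ]
    if len(hit) >= 2:
        return FUSION
    if same:
        donors = {d for t in same for d in t.donors()}
        acceptors = {a for t in same for a in t.acceptors()}
        if query.donors() <= donors and query.acceptors() <= acceptors:
            return NIC
        return NNC
    return ANTISENSE if opposite else INTERGENIC


def random_toy_annotation(seed):
    """Random small annotation: base genes plus mutated variants."""
    rng = np.random.default_rng(seed)
    transcripts = []
    pos = 100
    n_genes = int(rng.integers(3, 8))
    for g in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 5))
        exons = []
        p = pos
        for _ in range(n_ex):
            el = int(rng.integers(30, 120))
            exons.append((p, p + el - 1))
            p += el + int(rng.integers(60, 250))
        gid = f"g{g}"
        transcripts.append(
            make_transcript(f"g{g}t0", gid, "chr1", strand, exons)
        )
        for v in range(int(rng.integers(0, 3))):
            mut = [list(e) for e in exons]
            kind = rng.integers(0, 3)
            if kind == 0 and len(mut) > 2:  # drop a terminal exon
                mut = mut[1:] if rng.random() < 0.5 else mut[:-1]
            elif kind == 1 and len(mut) > 2:  # skip an internal exon
                del mut[int(rng.integers(1, len(mut) - 1))]
            else:  # shift a boundary
                i = int(rng.integers(0, len(mut)))
                mut[i][1] = max(mut[i][1] - int(rng.integers(1, 15)), mut[i][0] + 5)
            try:
                transcripts.append(
                    make_transcript(
                        f"g{g}t{v + 1}", gid, "chr1", strand,
                        [tuple(e) for e in mut],
                    )
                )
            except ValueError:
                pass
        pos = max(pos, transcripts[-1].end) + int(rng.integers(-200, 600))
        pos = max(pos, 100)
    return transcripts


@pytest.mark.parametrize("seed", range(20))
def test_classifier_agrees_with_brute_force_oracle(seed):
    transcripts = random_toy_annotation(seed)
    ann = make_annotation(*transcripts)
    for t in transcripts:
        expected = brute_force_classify(t, transcripts, exclude={t.transcript_id})
        got = classify_query(t, ann, exclude_ids={t.transcript_id})
        assert got.category == expected, (
            f"seed {seed}, {t.transcript_id}: {got.category} != {expected}"
        )
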