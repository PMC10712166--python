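import numpy as np
import pytest

from isosim import (
    AnnotationSet,
    ExpressionConfig,
    FixtureSpec,
    NoveltyRequest,
    TranscriptModel,
    assign_expression,
    classify_reference,
    generate_fixture,
    select_novel_set,
)
from isosim.classify import NOVEL_CATEGORIES


def make_transcript(tid, gid, chrom, strand, exons):
    return TranscriptModel(tid, gid, chrom, strand, exons)


def make_annotation(*transcripts):
    ann = AnnotationSet()
    for t in transcripts:
        ann.add(t)
    return ann


@pytest.fixture(scope="session")
def small_fixture():
    """Synthetic genome + annotation with ~8 candidates per novel category."""
    spec = FixtureSpec(
        n_known_genes=40,
        novel_candidates={c: 8 for c in NOVEL_CATEGORIES},
        seed=20240915,
    )
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def small_index(small_fixture):
    return classify_reference(small_fixture.annotation)


@pytest.fixture(scope="session")
def small_design(small_fixture, small_index):
    """A selected + expressed design over the small fixture (sample mode)."""
    request = NoveltyRequest(
        counts={c: 6 for c in NOVEL_CATEGORIES}, n_known=80, seed=7
    )
    design = select_novel_set(small_index, small_fixture.annotation, request)
    config = ExpressionConfig(
        mode="sample",
        long_count=30_000,
        sample_counts=small_fixture.count_table,
        diff_exp=1.0,
    )
    assign_expression(design, config, seed=3)
    return design


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
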