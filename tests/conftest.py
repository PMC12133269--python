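import pytest

from sssviz.annotations import AnnotationSet, DomainMatch
from sssviz.layout import CanvasSpec
from sssviz.sss_model import HitRecord, HSPRecord, SSSRun


def make_hsp(qs=1, qe=50, hs=1, he=50, bits=100.0, evalue=1e-20,
             identity=60.0, similarity=75.0) -> HSPRecord:
    return HSPRecord(
        query_start=qs, query_end=qe, hit_start=hs, hit_end=he,
        bit_score=bits, evalue=evalue,
        identity_percent=identity, similarity_percent=similarity,
    )


def make_hit(ident="HIT_1", length=200, hsps=None, url=None) -> HitRecord:
    return HitRecord(
        hit_identifier=ident, source_database="uniprotkb",
        description="a test hit", hit_length=length, link_url=url,
        hsps=tuple(hsps or [make_hsp()]),
    )


def make_run(hits=None, query_length=100) -> SSSRun:
    return SSSRun(
        tool_name="ncbiblast", tool_version="2.17.0+",
        database_name="uniprotkb_swissprot", query_identifier="Q1",
        query_length=query_length, program_type="protein",
        start_time="2025-01-01T00:00:00Z", end_time="2025-01-01T00:01:00Z",
        hits=tuple(hits if hits is not None else [make_hit()]),
    )


@pytest.fixture
def simple_run() -> SSSRun:
    return make_run([
        make_hit("HIT_A", 200, [make_hsp(1, 50, 11, 60, bits=120, evalue=1e-30),
                                make_hsp(60, 90, 70, 100, bits=40, evalue=1e-5)],
                 url="https://example.org/HIT_A"),
        make_hit("HIT_B", 150, [make_hsp(5, 80, 1, 76, bits=80, evalue=1e-15)]),
    ])


@pytest.fixture
def simple_annotations() -> AnnotationSet:
    return AnnotationSet.from_matches([
        DomainMatch(hit_identifier="HIT_A", source_name="Pfam",
                    accession="PF00001", name="kinase domain", start=20, end=55),
        DomainMatch(hit_identifier="HIT_A", source_name="SUPERFAMILY",
                    accession="SSF1234", name="barrel", start=40, end=90),
        DomainMatch(hit_identifier="HIT_B", source_name="Pfam",
                    accession="PF00002", name="SH3", start=10, end=60),
    ])


@pytest.fixture
def canvas() -> CanvasSpec:
    return CanvasSpec()
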