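"""Seeded synthetic sequence-search results and domain annotations.

Stands in for live search and annotation services in all tests and
examples.  The generator aims for *statistical* realism, not biological
sequence content:

* alignment lengths are uniform on ``[20, query_length]``;
* identity % is uniform on a configurable range and similarity % is
  identity plus a uniform [0, 15] bump, capped at 100 (identity can
  never exceed similarity, as in real substitution-matrix scoring);
* the bit score follows a simple heuristic, ``0.5 * aln_len *
  (identity/100) * 4.3`` bits — roughly two matched residues per
  alignment position scoring ~2 bits each at full identity;
* the E-value follows the standard Karlin–Altschul relation for a
  normalised bit score, ``E = m * n * 2**(-S')`` with query length *m*
  and effective database size *n*, so a higher bit score always means a
  strictly lower E-value within a run.

Hits are emitted pre-sorted by best E-value, the way search tools print
them.  All draws come from one ``numpy`` generator seeded from
``FixtureParams.seed``, so equal parameters give byte-identical outputs.
"""
from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .annotations import AnnotationSet, DomainMatch
from .sss_model import HitRecord, HSPRecord, SSSRun, rank_hits

__all__ = ["FixtureParams", "generate_sss_result", "generate_domain_annotations"]

#: URL templates keyed by the fixture's source-database namespaces.
URL_TEMPLATES = {
    "uniprotkb": "https://www.uniprot.org/uniprotkb/{id}",
    "pdbe": "https://www.ebi.ac.uk/pdbe/entry/pdb/{id}",
}

_SOURCE_ACCESSION_PREFIX = {
    "Pfam": "PF",
    "SUPERFAMILY": "SSF",
    "PROSITE": "PS",
    "CDD": "cd",
    "PANTHER": "PTHR",
    "Gene3D": "G3DSA:",
    "SMART": "SM",
    "PRINTS": "PR",
}

_DOMAIN_WORDS = (
    "kinase", "helicase", "zinc-finger", "SH3", "WD40", "EF-hand",
    "immunoglobulin", "transferase", "barrel", "coiled-coil",
)


class FixtureParams(BaseModel):
    """Knobs for the synthetic result generator."""

    model_config = ConfigDict(frozen=True)

    n_hits: int = Field(default=50, ge=0)
    max_hsps_per_hit: int = Field(default=10, ge=1)
    query_length: int = Field(default=400, ge=10)
    database_size: float = Field(default=5e8, gt=0)  # effective residues
    identity_range: tuple[float, float] = (25.0, 98.0)
    seed: int = 0

    @model_validator(mode="after")
    def _identity_ok(self) -> "FixtureParams":
        lo, hi = self.identity_range
        if not (0 <= lo <= hi <= 100):
            raise ValueError("identity_range must satisfy 0 <= low <= high <= 100")
        return self


def _make_hsp(rng: np.random.Generator, params: FixtureParams,
              hit_length: int) -> HSPRecord:
    L = params.query_length
    aln_min = min(20, L)
    aln_len = int(rng.integers(aln_min, L + 1))
    lo, hi = params.identity_range
    identity = float(rng.uniform(lo, hi))
    similarity = min(100.0, identity + float(rng.uniform(0.0, 15.0)))
    bit_score = 0.5 * aln_len * (identity / 100.0) * 4.3
    evalue = float(L * params.database_size * 2.0 ** (-bit_score))
    qstart = int(rng.integers(1, L - aln_len + 2))
    hstart = int(rng.integers(1, hit_length - aln_len + 2))
    return HSPRecord(
        query_start=qstart,
        query_end=qstart + aln_len - 1,
        hit_start=hstart,
        hit_end=hstart + aln_len - 1,
        bit_score=round(bit_score, 1),
        evalue=evalue,
        identity_percent=round(identity, 1),
        similarity_percent=round(similarity, 1),
    )


def generate_sss_result(params: FixtureParams | None = None, **kwargs) -> SSSRun:
    """Generate a synthetic, validated :class:`SSSRun`.

    Accepts either a :class:`FixtureParams` or its fields as keyword
    arguments (``generate_sss_result(n_hits=3, seed=1)``).  Deterministic
    given the seed.
    """
    if params is None:
        params = FixtureParams(**kwargs)
    elif kwargs:
        params = params.model_copy(update=kwargs)
    rng = np.random.default_rng(params.seed)
    L = params.query_length

    hits = []
    for i in range(params.n_hits):
        # hit at least as long as the query so any alignment length fits
        hit_length = int(rng.integers(L, int(1.6 * L) + 1))
        n_hsps = int(rng.integers(1, params.max_hsps_per_hit + 1))
        hsps = tuple(_make_hsp(rng, params, hit_length) for _ in range(n_hsps))
        if rng.random() < 0.8:
            source, ident = "uniprotkb", f"SP:Q{rng.integers(0, 100000):05d}"
        else:
            source, ident = "pdbe", f"PDB:{rng.integers(1, 10)}{_rand_pdb(rng)}"
        hits.append(HitRecord(
            hit_identifier=ident,
            source_database=source,
            description=f"synthetic hit protein {i + 1}",
            hit_length=hit_length,
            link_url=URL_TEMPLATES[source].format(id=ident.split(":", 1)[1]),
            hsps=hsps,
        ))

    run = SSSRun(
        tool_name="ncbiblast",
        tool_version="2.17.0+",
        database_name="uniprotkb_swissprot",
        query_identifier="QUERY_1",
        query_description="synthetic query sequence",
        query_length=L,
        program_type="protein",
        start_time="2025-01-15T10:00:00Z",
        end_time="2025-01-15T10:02:30Z",
        hits=tuple(hits),
    )
    # emit pre-sorted best-E-value-first, as search tools do
    return run.model_copy(update={"hits": tuple(rank_hits(run))})


def _rand_pdb(rng: np.random.Generator) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz0123456789"
    return "".join(letters[int(rng.integers(0, len(letters)))] for _ in range(3))


DEFAULT_SOURCES: tuple[str, ...] = ("Pfam", "SUPERFAMILY", "PROSITE", "CDD")


def generate_domain_annotations(
    run: SSSRun,
    sources: tuple[str, ...] = DEFAULT_SOURCES,
    mean_domains_per_hit: float = 2.0,
    seed: int = 0,
) -> AnnotationSet:
    """Poisson(``mean_domains_per_hit``) domains per hit, each with a
    uniformly drawn source and in-bounds coordinates (length >= 10 where
    the hit allows it); overlaps are permitted.  Deterministic given the
    seed."""
    if not sources:
        raise ValueError("sources must be non-empty")
    if mean_domains_per_hit < 0:
        raise ValueError("mean_domains_per_hit must be >= 0")
    rng = np.random.default_rng(seed)
    matches = []
    for hit in run.hits:
        n = int(rng.poisson(mean_domains_per_hit))
        for _ in range(n):
            src = sources[int(rng.integers(0, len(sources)))]
            # typical domain: 10 residues up to ~40% of the hit sequence
            upper = max(min(10, hit.hit_length), int(hit.hit_length * 0.4))
            dlen = int(rng.integers(min(10, hit.hit_length), upper + 1))
            start = int(rng.integers(1, hit.hit_length - dlen + 2))
            acc_no = int(rng.integers(1, 99999))
            prefix = _SOURCE_ACCESSION_PREFIX.get(src, src[:2].upper())
            word = _DOMAIN_WORDS[int(rng.integers(0, len(_DOMAIN_WORDS)))]
            matches.append(DomainMatch(
                hit_identifier=hit.hit_identifier,
                source_name=src,
                accession=f"{prefix}{acc_no:05d}",
                name=f"{word} domain",
                start=start,
                end=start + dlen - 1,
            ))
    return AnnotationSet.from_matches(matches)
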