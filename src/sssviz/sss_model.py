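"""Data model for sequence-similarity-search (SSS) results.

A run of a search tool (BLAST+, FASTA, ...) is modelled as an
:class:`SSSRun`: tool/database/query metadata plus an ordered list of
:class:`HitRecord` objects, each carrying one or more scored local
alignments (:class:`HSPRecord`, high-scoring segment pairs).

The on-disk format is a flat JSON dialect (UTF-8, no comments) with the
following keys::

    top level: program, version, db, query_id, query_def, query_len,
               program_type, start_time, end_time, hits[]
    hit:       id, source, description, length, url, hsps[]
    hsp:       qstart, qend, hstart, hend, bitscore, evalue,
               identity, similarity

Unknown extra fields are ignored on read.  Coordinates are 1-based
inclusive throughout, the convention of BLAST-style reports.
"""
from __future__ import annotations

import enum
import json
import warnings
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ScoreKind",
    "HSPRecord",
    "HitRecord",
    "SSSRun",
    "parse_sss_json",
    "write_sss_json",
    "rank_hits",
    "cap_display",
]


class ScoreKind(str, enum.Enum):
    """A selectable per-HSP score."""

    EVALUE = "evalue"
    BITSCORE = "bitscore"
    IDENTITY = "identity"
    SIMILARITY = "similarity"


class HSPRecord(BaseModel):
    """One local alignment between query and hit (a high-scoring segment pair)."""

    model_config = ConfigDict(frozen=True)

    query_start: int = Field(ge=1)
    query_end: int = Field(ge=1)
    hit_start: int = Field(ge=1)
    hit_end: int = Field(ge=1)
    bit_score: float = Field(ge=0.0)
    evalue: float = Field(ge=0.0)
    identity_percent: float = Field(ge=0.0, le=100.0)
    similarity_percent: float = Field(ge=0.0, le=100.0)

    @model_validator(mode="after")
    def _ordered(self) -> "HSPRecord":
        if self.query_start > self.query_end:
            raise ValueError(
                f"query_start {self.query_start} > query_end {self.query_end}"
            )
        if self.hit_start > self.hit_end:
            raise ValueError(f"hit_start {self.hit_start} > hit_end {self.hit_end}")
        return self

    def score(self, kind: ScoreKind) -> float:
        kind = ScoreKind(kind)
        if kind is ScoreKind.EVALUE:
            return self.evalue
        if kind is ScoreKind.BITSCORE:
            return self.bit_score
        if kind is ScoreKind.IDENTITY:
            return self.identity_percent
        return self.similarity_percent


class HitRecord(BaseModel):
    """A matched database sequence and its HSPs."""

    model_config = ConfigDict(frozen=True)

    hit_identifier: str
    source_database: str = ""
    description: str = ""
    hit_length: int = Field(ge=1)
    link_url: Optional[str] = None
    hsps: tuple[HSPRecord, ...]

    @model_validator(mode="after")
    def _non_empty(self) -> "HitRecord":
        if len(self.hsps) == 0:
            raise ValueError(f"hit {self.hit_identifier!r} has no HSPs")
        for i, h in enumerate(self.hsps):
            if h.hit_end > self.hit_length:
                raise ValueError(
                    f"hit {self.hit_identifier!r} HSP {i}: hit_end {h.hit_end} "
                    f"exceeds hit_length {self.hit_length}"
                )
        return self

    def best_score(self, kind: ScoreKind) -> float:
        """Best HSP score: minimum for E-value, maximum otherwise."""
        kind = ScoreKind(kind)
        vals = [h.score(kind) for h in self.hsps]
        return min(vals) if kind is ScoreKind.EVALUE else max(vals)

    def best_hsp(self, kind: ScoreKind = ScoreKind.EVALUE) -> HSPRecord:
        kind = ScoreKind(kind)
        if kind is ScoreKind.EVALUE:
            return min(self.hsps, key=lambda h: (h.evalue, -h.bit_score))
        return max(self.hsps, key=lambda h: (h.score(kind), h.bit_score))


class SSSRun(BaseModel):
    """One sequence-similarity-search execution."""

    model_config = ConfigDict(frozen=True)

    tool_name: str
    tool_version: str = ""
    database_name: str = ""
    query_identifier: str = ""
    query_description: str = ""
    query_length: int = Field(ge=1)
    program_type: str = "protein"  # "protein" | "nucleotide"
    start_time: str = ""
    end_time: str = ""
    hits: tuple[HitRecord, ...] = ()

    @model_validator(mode="after")
    def _bounds(self) -> "SSSRun":
        if self.program_type not in ("protein", "nucleotide"):
            raise ValueError(f"program_type must be protein|nucleotide, got {self.program_type!r}")
        for hit in self.hits:
            for i, h in enumerate(hit.hsps):
                if h.query_end > self.query_length:
                    raise ValueError(
                        f"hit {hit.hit_identifier!r} HSP {i}: query_end "
                        f"{h.query_end} exceeds query_length {self.query_length}"
                    )
        return self


# --- JSON dialect -----------------------------------------------------------

_HSP_KEYS = {
    "qstart": "query_start",
    "qend": "query_end",
    "hstart": "hit_start",
    "hend": "hit_end",
    "bitscore": "bit_score",
    "evalue": "evalue",
    "identity": "identity_percent",
    "similarity": "similarity_percent",
}
_HIT_KEYS = {
    "id": "hit_identifier",
    "source": "source_database",
    "description": "description",
    "length": "hit_length",
    "url": "link_url",
}
_RUN_KEYS = {
    "program": "tool_name",
    "version": "tool_version",
    "db": "database_name",
    "query_id": "query_identifier",
    "query_def": "query_description",
    "query_len": "query_length",
    "program_type": "program_type",
    "start_time": "start_time",
    "end_time": "end_time",
}

_REQUIRED_TOP = ("program", "query_len")
_REQUIRED_HIT = ("id", "length", "hsps")
_REQUIRED_HSP = ("qstart", "qend", "hstart", "hend", "bitscore", "evalue")


def _pick(obj: dict, mapping: dict[str, str]) -> dict:
    return {field: obj[key] for key, field in mapping.items() if key in obj}


def parse_sss_json(document: str | dict | list) -> SSSRun:
    """Parse an SSS-JSON document into a validated :class:`SSSRun`.

    ``document`` may be raw JSON text or an already-decoded object.  A
    top-level list is treated as a multi-query result: the first query
    is parsed and a warning is emitted for the rest.

    Raises ``ValueError`` naming the missing field or the offending
    hit/HSP when validation fails.
    """
    if isinstance(document, (str, bytes)):
        obj = json.loads(document)
    else:
        obj = document
    if isinstance(obj, list):
        if not obj:
            raise ValueError("empty result list")
        if len(obj) > 1:
            warnings.warn(
                f"multi-query result: using the first query, ignoring {len(obj) - 1} more",
                stacklevel=2,
            )
        obj = obj[0]
    if not isinstance(obj, dict):
        raise ValueError("top-level SSS-JSON value must be an object")

    for key in _REQUIRED_TOP:
        if key not in obj:
            raise ValueError(f"missing required field: {key}")

    hits = []
    for hi, hobj in enumerate(obj.get("hits", []) or []):
        for key in _REQUIRED_HIT:
            if key not in hobj:
                raise ValueError(f"hits[{hi}]: missing required field: {key}")
        hsps = []
        for si, sobj in enumerate(hobj["hsps"] or []):
            for key in _REQUIRED_HSP:
                if key not in sobj:
                    raise ValueError(f"hits[{hi}].hsps[{si}]: missing required field: {key}")
            fields = _pick(sobj, _HSP_KEYS)
            fields.setdefault("identity_percent", 0.0)
            fields.setdefault("similarity_percent", 0.0)
            hsps.append(HSPRecord(**fields))
        hits.append(HitRecord(**_pick(hobj, _HIT_KEYS), hsps=tuple(hsps)))

    return SSSRun(**_pick(obj, _RUN_KEYS), hits=tuple(hits))


def write_sss_json(run: SSSRun) -> str:
    """Serialize a run to canonical SSS-JSON text.

    Keys are emitted in a fixed order so equal runs produce
    byte-identical text (required for golden-file tests).
    """
    doc = {
        "program": run.tool_name,
        "version": run.tool_version,
        "db": run.database_name,
        "query_id": run.query_identifier,
        "query_def": run.query_description,
        "query_len": run.query_length,
        "program_type": run.program_type,
        "start_time": run.start_time,
        "end_time": run.end_time,
        "hits": [
            {
                "id": hit.hit_identifier,
                "source": hit.source_database,
                "description": hit.description,
                "length": hit.hit_length,
                "url": hit.link_url,
                "hsps": [
                    {
                        "qstart": h.query_start,
                        "qend": h.query_end,
                        "hstart": h.hit_start,
                        "hend": h.hit_end,
                        "bitscore": h.bit_score,
                        "evalue": h.evalue,
                        "identity": h.identity_percent,
                        "similarity": h.similarity_percent,
                    }
                    for h in hit.hsps
                ],
            }
            for hit in run.hits
        ],
    }
    return json.dumps(doc, indent=1, ensure_ascii=False) + "\n"


def rank_hits(run: SSSRun, score_kind: ScoreKind = ScoreKind.EVALUE) -> list[HitRecord]:
    """Order hits best-first by their best HSP score.

    Best is the minimum for E-value and the maximum for the other score
    kinds.  Ties are broken by best bit score descending, then by input
    order (stable).
    """
    score_kind = ScoreKind(score_kind)
    sign = 1.0 if score_kind is ScoreKind.EVALUE else -1.0
    return sorted(
        run.hits,
        key=lambda hit: (
            sign * hit.best_score(score_kind),
            -hit.best_score(ScoreKind.BITSCORE),
        ),
    )


def cap_display(
    run: SSSRun,
    max_hits: int,
    max_hsps: int,
    score_kind: ScoreKind = ScoreKind.EVALUE,
) -> SSSRun:
    """Return a copy retaining the first ``max_hits`` hits and, per hit,
    its best ``max_hsps`` HSPs under ``score_kind`` (input order preserved
    within the hit).

    The run is assumed already ranked (see :func:`rank_hits`).
    """
    if max_hits < 1 or max_hsps < 1:
        raise ValueError("max_hits and max_hsps must be >= 1")
    score_kind = ScoreKind(score_kind)
    sign = 1.0 if score_kind is ScoreKind.EVALUE else -1.0

    capped_hits = []
    for hit in run.hits[:max_hits]:
        if len(hit.hsps) <= max_hsps:
            capped_hits.append(hit)
            continue
        order = sorted(
            range(len(hit.hsps)),
            key=lambda i: (sign * hit.hsps[i].score(score_kind), -hit.hsps[i].bit_score),
        )
        keep = sorted(order[:max_hsps])
        capped_hits.append(
            hit.model_copy(update={"hsps": tuple(hit.hsps[i] for i in keep)})
        )
    return run.model_copy(update={"hits": tuple(capped_hits)})
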