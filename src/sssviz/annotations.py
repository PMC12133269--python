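"""Per-hit domain annotations (InterPro-style member-database matches).

Each :class:`DomainMatch` locates a predicted domain on a hit sequence
and names the resource that predicted it (Pfam, SUPERFAMILY, PROSITE,
CDD, PANTHER, Gene3D, ...).  The on-disk format is a flat JSON list of
objects ``{hit_id, source, accession, name, start, end}`` — a
deliberately simpler shape than the live annotation API's nested
payload; see docs/methods.md for the mapping between the two.
"""
from __future__ import annotations

import json
import logging
from typing import Iterable, Mapping

from pydantic import BaseModel, ConfigDict, model_validator

from .sss_model import SSSRun

logger = logging.getLogger(__name__)

__all__ = [
    "DomainMatch",
    "AnnotationSet",
    "parse_annotations",
    "write_annotations",
    "available_sources",
    "filter_sources",
    "clip_matches",
]


class DomainMatch(BaseModel):
    """One domain prediction on a hit sequence (1-based inclusive coordinates).

    Coordinates outside ``[1, hit_length]`` are tolerated at construction —
    sequence-version mismatches between the annotation payload and the
    search result produce them — and reconciled by :func:`clip_matches`.
    """

    model_config = ConfigDict(frozen=True)

    hit_identifier: str
    source_name: str
    accession: str = ""
    name: str = ""
    start: int
    end: int

    @model_validator(mode="after")
    def _ordered(self) -> "DomainMatch":
        if self.start > self.end:
            raise ValueError(
                f"domain {self.accession or self.name!r} on hit "
                f"{self.hit_identifier!r}: start {self.start} > end {self.end}"
            )
        return self


class AnnotationSet(BaseModel):
    """Domain matches grouped by hit identifier.

    ``sources_present`` is always the union of ``source_name`` over all
    matches (recomputed by the constructor helpers below).
    """

    model_config = ConfigDict(frozen=True)

    matches: Mapping[str, tuple[DomainMatch, ...]] = {}

    @property
    def sources_present(self) -> frozenset[str]:
        return frozenset(
            m.source_name for ms in self.matches.values() for m in ms
        )

    def all_matches(self) -> list[DomainMatch]:
        return [m for ms in self.matches.values() for m in ms]

    @classmethod
    def from_matches(cls, matches: Iterable[DomainMatch]) -> "AnnotationSet":
        grouped: dict[str, list[DomainMatch]] = {}
        for m in matches:
            grouped.setdefault(m.hit_identifier, []).append(m)
        return cls(matches={k: tuple(v) for k, v in grouped.items()})


def parse_annotations(document: str | list) -> AnnotationSet:
    """Parse an annotation JSON document (a flat list of match objects).

    Matches for hit identifiers absent from any particular run are kept;
    joining against a run happens at layout time.  A match with
    ``start > end`` raises a validation error naming the match.
    """
    obj = json.loads(document) if isinstance(document, (str, bytes)) else document
    if not isinstance(obj, list):
        raise ValueError("annotation document must be a JSON list of match objects")
    matches = []
    for i, rec in enumerate(obj):
        for key in ("hit_id", "source", "start", "end"):
            if key not in rec:
                raise ValueError(f"match[{i}]: missing required field: {key}")
        matches.append(
            DomainMatch(
                hit_identifier=rec["hit_id"],
                source_name=rec["source"],
                accession=rec.get("accession", ""),
                name=rec.get("name", ""),
                start=rec["start"],
                end=rec["end"],
            )
        )
    return AnnotationSet.from_matches(matches)


def write_annotations(ann: AnnotationSet) -> str:
    """Serialize to the flat-list annotation dialect (canonical key order)."""
    records = [
        {
            "hit_id": m.hit_identifier,
            "source": m.source_name,
            "accession": m.accession,
            "name": m.name,
            "start": m.start,
            "end": m.end,
        }
        for hit_id in sorted(ann.matches)
        for m in ann.matches[hit_id]
    ]
    return json.dumps(records, indent=1, ensure_ascii=False) + "\n"


def available_sources(ann: AnnotationSet, run: SSSRun) -> frozenset[str]:
    """Sources with at least one match on a hit present in the (capped) run."""
    displayed = {hit.hit_identifier for hit in run.hits}
    return frozenset(
        m.source_name
        for hit_id, ms in ann.matches.items()
        if hit_id in displayed
        for m in ms
    )


def filter_sources(ann: AnnotationSet, enabled: Iterable[str]) -> AnnotationSet:
    """Retain only matches whose source is in ``enabled``."""
    enabled = set(enabled)
    return AnnotationSet.from_matches(
        m for m in ann.all_matches() if m.source_name in enabled
    )


def clip_matches(ann: AnnotationSet, run: SSSRun) -> AnnotationSet:
    """Clamp match coordinates to ``[1, hit_length]`` of the owning hit.

    Matches with no overlap at all are dropped with a logged warning —
    annotation payloads and search hits can disagree on sequence
    versions, so out-of-range coordinates are not treated as fatal.
    Matches on hits unknown to the run pass through unchanged.
    """
    lengths = {hit.hit_identifier: hit.hit_length for hit in run.hits}
    kept: list[DomainMatch] = []
    for m in ann.all_matches():
        length = lengths.get(m.hit_identifier)
        if length is None:
            kept.append(m)
            continue
        if m.end < 1 or m.start > length:
            logger.warning(
                "dropping domain %s [%d, %d] outside hit %s (length %d)",
                m.accession or m.name, m.start, m.end, m.hit_identifier, length,
            )
            continue
        start = max(1, m.start)
        end = min(length, m.end)
        if (start, end) != (m.start, m.end):
            logger.warning(
                "clipping domain %s [%d, %d] to [%d, %d] on hit %s",
                m.accession or m.name, m.start, m.end, start, end, m.hit_identifier,
            )
            m = m.model_copy(update={"start": start, "end": end})
        kept.append(m)
    return AnnotationSet.from_matches(kept)
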