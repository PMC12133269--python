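"""Deterministic layout: a capped run (+ optional annotations) becomes a
positioned, backend-independent render tree.

The tree is an ordered list of primitives (rectangles, lines, text) in
painter's order — later primitives draw over earlier ones.  Primitives
carry an optional ``tag`` (rendered as an SVG class) so tests and
downstream tooling can count rows, bars and labels structurally, an
optional embedded ``title`` (the static analogue of an interactive
tooltip) and an optional hyperlink.

Two composite layouts are provided:

* :func:`layout_visual_output` — the hit-coverage view: one row per hit,
  one score-coloured bar per HSP positioned on the query axis.
* :func:`layout_functional_predictions` — per hit, a single
  score-coloured background bar spanning its aggregate HSP range, with
  domain-annotation bars overlaid in source colours, plus a source
  legend.

Domain coordinates live on the *hit* sequence; they are projected onto
the query axis through the hit's best HSP assuming a gap-free linear
offset (``query_start - hit_start``), clipping to the HSP's hit range.
This is an approximation — real alignments gap — and is documented as
such in the methods note.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, model_validator

from .annotations import AnnotationSet, available_sources, filter_sources
from .colors import (
    Palette,
    ScaleSpec,
    build_gradient,
    color_for,
    inverse_transform,
    rgb_to_hex,
    source_color,
)
from .sss_model import HitRecord, ScoreKind, SSSRun

__all__ = [
    "CanvasSpec",
    "Rect",
    "Line",
    "Text",
    "RenderTree",
    "seq_to_px",
    "layout_header",
    "layout_scale_bar",
    "layout_visual_output",
    "layout_functional_predictions",
    "DEFAULT_SOURCE_PRIORITY",
]

#: Legend order (and overlay paint priority) for annotation sources.
DEFAULT_SOURCE_PRIORITY: tuple[str, ...] = (
    "Pfam", "SUPERFAMILY", "PROSITE", "CDD", "PANTHER", "Gene3D", "SMART", "PRINTS",
)

GRADIENT_STEPS = 50  # cosmetic: rectangles in the scale-bar strip
N_TICKS = 5          # cosmetic: tick labels under the strip


class CanvasSpec(BaseModel):
    """Canvas geometry and typography (pixels; font size in points)."""

    model_config = ConfigDict(frozen=True)

    width: float = 1000.0
    margin_top: float = 10.0
    margin_bottom: float = 10.0
    margin_left: float = 10.0
    margin_right: float = 10.0
    label_panel_width: float = 170.0
    row_height: float = 24.0
    hsp_bar_height: float = 12.0
    domain_bar_height: float = 8.0
    font_family: str = "Helvetica, Arial, sans-serif"
    font_size: float = 11.0

    @model_validator(mode="after")
    def _positive_content(self) -> "CanvasSpec":
        if self.content_width <= 0:
            raise ValueError("canvas too narrow: content width must be positive")
        return self

    @property
    def content_width(self) -> float:
        return (
            self.width
            - self.margin_left
            - self.margin_right
            - self.label_panel_width
        )

    @property
    def content_x0(self) -> float:
        return self.margin_left + self.label_panel_width


@dataclasses.dataclass(frozen=True)
class Rect:
    x: float
    y: float
    w: float
    h: float
    fill: str
    stroke: Optional[str] = None
    title: Optional[str] = None
    href: Optional[str] = None
    tag: Optional[str] = None


@dataclasses.dataclass(frozen=True)
class Line:
    x1: float
    y1: float
    x2: float
    y2: float
    stroke: str = "#000000"
    tag: Optional[str] = None


@dataclasses.dataclass(frozen=True)
class Text:
    x: float
    y: float  # baseline
    content: str
    font_size: float
    anchor: str = "start"  # start | middle | end
    fill: str = "#000000"
    bold: bool = False
    href: Optional[str] = None
    tag: Optional[str] = None


Primitive = Union[Rect, Line, Text]


@dataclasses.dataclass(frozen=True)
class RenderTree:
    """Positioned primitives in painter's order plus the canvas extent."""

    primitives: tuple[Primitive, ...]
    width: float
    height: float


def seq_to_px(pos: int, seq_length: int, x0: float, span: float) -> float:
    """Left pixel edge of residue ``pos`` on a track of ``span`` pixels.

    A bar covering residues [s, e] runs from the left edge of s to the
    *right* edge of e, so its width is ``(e - s + 1) / L * span``.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if not 1 <= pos <= seq_length:
        raise ValueError(f"position {pos} outside [1, {seq_length}]")
    return x0 + (pos - 1) / seq_length * span


def _bar_geometry(s: int, e: int, L: int, x0: float, span: float) -> tuple[float, float]:
    x = seq_to_px(s, L, x0, span)
    w = (e - s + 1) / L * span
    return x, w


HEADER_LINE = 15.0


def layout_header(run: SSSRun, canvas: CanvasSpec, y0: Optional[float] = None) -> list[Primitive]:
    """Header block: tool+version, database, query id/description and
    length on the left; start/end timestamps right-aligned."""
    y = canvas.margin_top + HEADER_LINE if y0 is None else y0 + HEADER_LINE
    x = canvas.margin_left
    xr = canvas.width - canvas.margin_right
    fs = canvas.font_size
    prims: list[Primitive] = []

    tool = run.tool_name + (f" {run.tool_version}" if run.tool_version else "")
    prims.append(Text(x, y, tool, fs + 2, bold=True, tag="header-tool"))
    if run.start_time or run.end_time:
        stamp = f"{run.start_time} → {run.end_time}".strip(" → ")
        prims.append(Text(xr, y, stamp, fs - 1, anchor="end", tag="header-timestamps"))
    y += HEADER_LINE
    if run.database_name:
        prims.append(Text(x, y, f"Database: {run.database_name}", fs, tag="header-db"))
        y += HEADER_LINE
    query = f"Query: {run.query_identifier}"
    if run.query_description:
        query += f" — {run.query_description}"
    prims.append(Text(x, y, query, fs, tag="header-query"))
    y += HEADER_LINE
    unit = "residues" if run.program_type == "protein" else "bases"
    prims.append(Text(x, y, f"Length: {run.query_length} {unit}", fs, tag="header-length"))
    return prims


def _header_height(run: SSSRun) -> float:
    lines = 3 + (1 if run.database_name else 0)
    return lines * HEADER_LINE + 6


def _fmt_tick(t: float, score_kind: ScoreKind) -> str:
    v = inverse_transform(t, score_kind)
    if ScoreKind(score_kind) is ScoreKind.EVALUE:
        return f"{v:.1e}"
    if abs(v - round(v)) < 1e-9:
        return str(int(round(v)))
    return f"{v:g}"


SCALEBAR_STRIP_H = 12.0
SCALEBAR_HEIGHT = 48.0  # caption + strip + tick labels


def layout_scale_bar(
    scale: ScaleSpec,
    palette: Palette,
    canvas: CanvasSpec,
    y0: float = 0.0,
) -> list[Primitive]:
    """Scale bar: a caption naming the active score/scale/palette, then a
    50-step gradient strip with 5 equally spaced tick labels showing
    untransformed scores (scientific notation for E-values).  The binned
    palette gets a discrete legend of bin ranges instead of a strip."""
    prims: list[Primitive] = []
    fs = canvas.font_size
    x0 = canvas.content_x0
    span = canvas.content_width
    caption = (
        f"score: {scale.score_kind.value} | scale: {scale.kind.value}"
        f" | palette: {palette.name}"
    )
    prims.append(Text(x0, y0 + fs, caption, fs - 1, fill="#555555", tag="scale-caption"))
    strip_y = y0 + fs + 6

    if palette.is_binned:
        labels = []
        prev = None
        for edge, _ in palette.bins:
            if prev is None:
                labels.append(f"< {edge:g}")
            elif edge == float("inf"):
                labels.append(f">= {prev:g}")
            else:
                labels.append(f"{prev:g} - {edge:g}")
            prev = edge
        sw = span / len(palette.bins)
        for i, ((_, color), label) in enumerate(zip(palette.bins, labels)):
            x = x0 + i * sw
            prims.append(Rect(x, strip_y, 14, SCALEBAR_STRIP_H, rgb_to_hex(color),
                              stroke="#333333", tag="bin-swatch"))
            prims.append(Text(x + 18, strip_y + SCALEBAR_STRIP_H - 2, label, fs - 1,
                              tag="bin-label"))
        return prims

    colors = build_gradient(palette, GRADIENT_STEPS)
    step_w = span / GRADIENT_STEPS
    for i, color in enumerate(colors):
        prims.append(Rect(x0 + i * step_w, strip_y, step_w, SCALEBAR_STRIP_H,
                          rgb_to_hex(color), tag="gradient-step"))
    tick_y = strip_y + SCALEBAR_STRIP_H
    for i in range(N_TICKS):
        f = i / (N_TICKS - 1)
        tx = x0 + f * span
        t = scale.domain_min + f * (scale.domain_max - scale.domain_min)
        prims.append(Line(tx, tick_y, tx, tick_y + 3, stroke="#333333", tag="tick-mark"))
        anchor = "start" if i == 0 else ("end" if i == N_TICKS - 1 else "middle")
        prims.append(Text(tx, tick_y + 3 + fs, _fmt_tick(t, scale.score_kind),
                          fs - 1, anchor=anchor, tag="tick-label"))
    return prims


def _truncate(s: str, limit: int = 26) -> str:
    return s if len(s) <= limit else s[: limit - 1] + "…"


def _hsp_title(hit: HitRecord, h) -> str:
    return (
        f"{hit.hit_identifier} | query {h.query_start}-{h.query_end}"
        f" | hit {h.hit_start}-{h.hit_end}"
        f" | E-value {h.evalue:.3g} | bit score {h.bit_score:.1f}"
        f" | identity {h.identity_percent:.1f}%"
        f" | similarity {h.similarity_percent:.1f}%"
    )


def _hit_label(hit: HitRecord, row_y: float, canvas: CanvasSpec) -> Text:
    return Text(
        canvas.margin_left,
        row_y + canvas.row_height / 2 + canvas.font_size / 2 - 1,
        _truncate(hit.hit_identifier),
        canvas.font_size,
        fill="#0645ad" if hit.link_url else "#000000",
        href=hit.link_url,
        tag="hit-label",
    )


def _query_bar_row(run: SSSRun, canvas: CanvasSpec, y: float) -> list[Primitive]:
    prims: list[Primitive] = [
        Text(canvas.margin_left, y + canvas.row_height / 2 + canvas.font_size / 2 - 1,
             "Query", canvas.font_size, bold=True, tag="query-label")
    ]
    bar_y = y + (canvas.row_height - canvas.hsp_bar_height) / 2
    prims.append(Rect(canvas.content_x0, bar_y, canvas.content_width,
                      canvas.hsp_bar_height, "#707070",
                      title=f"query {run.query_identifier} 1-{run.query_length}",
                      tag="query-bar"))
    return prims


def layout_visual_output(
    run: SSSRun,
    scale: ScaleSpec,
    palette: Palette,
    canvas: CanvasSpec,
) -> RenderTree:
    """Hit-coverage view of a capped, ranked run.

    Header; scale bar; a full-width query reference bar; then one row per
    hit with its identifier in the left panel (hyperlinked when a URL is
    known) and one coloured bar per HSP, positioned by query coordinates
    and filled by the selected score's colour.  Each bar embeds a title
    listing the identifier, coordinates and all four scores.
    """
    header_h = _header_height(run)
    rows = len(run.hits)
    height = (
        canvas.margin_top + header_h + SCALEBAR_HEIGHT
        + (rows + 1) * canvas.row_height
        + (0 if rows else canvas.row_height)  # room for the no-hits notice
        + canvas.margin_bottom
    )
    prims: list[Primitive] = []
    prims += layout_header(run, canvas)
    y = canvas.margin_top + header_h
    prims += layout_scale_bar(scale, palette, canvas, y0=y)
    y += SCALEBAR_HEIGHT
    prims += _query_bar_row(run, canvas, y)
    y += canvas.row_height

    if not run.hits:
        prims.append(Text(canvas.content_x0, y + canvas.font_size + 4,
                          "no hits found", canvas.font_size, fill="#777777",
                          tag="no-hits"))

    x0, span = canvas.content_x0, canvas.content_width
    for rank, hit in enumerate(run.hits):
        prims.append(_hit_label(hit, y, canvas))
        prims.append(Line(x0, y + canvas.row_height / 2, x0 + span,
                          y + canvas.row_height / 2, stroke="#dddddd", tag="row-guide"))
        bar_y = y + (canvas.row_height - canvas.hsp_bar_height) / 2
        for h in hit.hsps:
            bx, bw = _bar_geometry(h.query_start, h.query_end, run.query_length, x0, span)
            fill = rgb_to_hex(color_for(h.score(scale.score_kind), scale, palette, rank=rank))
            prims.append(Rect(bx, bar_y, bw, canvas.hsp_bar_height, fill,
                              stroke="#333333", title=_hsp_title(hit, h),
                              href=hit.link_url, tag="hsp-bar"))
        y += canvas.row_height

    return RenderTree(tuple(prims), canvas.width, height)


def _project_domain(
    match_start: int, match_end: int, hsp, query_length: int
) -> Optional[tuple[int, int]]:
    """Project hit-space coordinates onto the query through one HSP.

    Gap-free linear offset; the domain is first clipped to the HSP's hit
    range (None if no overlap), and the projection is clamped to the
    query bounds (the hit-side span of a gapped HSP can exceed its
    query-side span).
    """
    s = max(match_start, hsp.hit_start)
    e = min(match_end, hsp.hit_end)
    if s > e:
        return None
    offset = hsp.query_start - hsp.hit_start
    qs = max(1, s + offset)
    qe = min(query_length, e + offset)
    if qs > qe:
        return None
    return qs, qe


LEGEND_ROW_H = 18.0


def layout_functional_predictions(
    run: SSSRun,
    ann: AnnotationSet,
    scale: ScaleSpec,
    palette: Palette,
    canvas: CanvasSpec,
    enabled_sources: Optional[Sequence[str]] = None,
    source_priority: Sequence[str] = DEFAULT_SOURCE_PRIORITY,
    stack_domains: bool = False,
) -> RenderTree:
    """Domain-overlay view: per hit, one score-coloured background bar
    spanning its aggregate HSP query range, with domain bars (source
    colours) painted on top, and a source legend marking sources without
    annotations as disabled.

    ``ann`` should already be clipped (see
    :func:`sssviz.annotations.clip_matches`).  When ``stack_domains`` is
    true, overlapping domain bars are laid on sub-rows instead of fully
    overlaying each other.
    """
    avail = available_sources(ann, run)
    if enabled_sources is not None:
        ann = filter_sources(ann, enabled_sources)

    known = list(source_priority) + sorted(
        s for s in ann.sources_present | avail if s not in source_priority
    )
    priority = {name: i for i, name in enumerate(known)}

    header_h = _header_height(run)
    rows = len(run.hits)
    legend_h = (len(known) + 1) * LEGEND_ROW_H
    height = (
        canvas.margin_top + header_h + SCALEBAR_HEIGHT
        + (rows + 1) * canvas.row_height
        + (0 if rows else canvas.row_height)
        + legend_h
        + canvas.margin_bottom
    )
    prims: list[Primitive] = []
    prims += layout_header(run, canvas)
    y = canvas.margin_top + header_h
    prims += layout_scale_bar(scale, palette, canvas, y0=y)
    y += SCALEBAR_HEIGHT
    prims += _query_bar_row(run, canvas, y)
    y += canvas.row_height

    if not run.hits:
        prims.append(Text(canvas.content_x0, y + canvas.font_size + 4,
                          "no hits found", canvas.font_size, fill="#777777",
                          tag="no-hits"))
        y += canvas.row_height

    x0, span = canvas.content_x0, canvas.content_width
    for rank, hit in enumerate(run.hits):
        prims.append(_hit_label(hit, y, canvas))
        prims.append(Line(x0, y + canvas.row_height / 2, x0 + span,
                          y + canvas.row_height / 2, stroke="#dddddd", tag="row-guide"))
        # background bar: aggregate HSP query range, coloured by best score
        qs = min(h.query_start for h in hit.hsps)
        qe = max(h.query_end for h in hit.hsps)
        bx, bw = _bar_geometry(qs, qe, run.query_length, x0, span)
        best = hit.best_score(scale.score_kind)
        fill = rgb_to_hex(color_for(best, scale, palette, rank=rank))
        bar_y = y + (canvas.row_height - canvas.hsp_bar_height) / 2
        prims.append(Rect(bx, bar_y, bw, canvas.hsp_bar_height, fill,
                          stroke="#333333", title=_hsp_title(hit, hit.best_hsp()),
                          href=hit.link_url, tag="bg-bar"))
        # domain overlays through the best HSP's linear offset
        best_hsp = hit.best_hsp()
        matches = sorted(
            ann.matches.get(hit.hit_identifier, ()),
            key=lambda m: (priority.get(m.source_name, len(priority)), m.start),
        )
        lanes: list[int] = []  # per placed domain: its lane end (query coord)
        max_lanes = max(1, int((canvas.row_height - 4) // (canvas.domain_bar_height + 1)))
        for m in matches:
            proj = _project_domain(m.start, m.end, best_hsp, run.query_length)
            if proj is None:
                continue
            ds, de = proj
            dx, dw = _bar_geometry(ds, de, run.query_length, x0, span)
            dy = y + (canvas.row_height - canvas.domain_bar_height) / 2
            if stack_domains:
                lane = 0
                while lane < len(lanes) and lanes[lane] >= ds:
                    lane += 1
                lane = min(lane, max_lanes - 1)
                if lane == len(lanes):
                    lanes.append(de)
                else:
                    lanes[lane] = max(lanes[lane], de) if lane < len(lanes) else de
                dy = y + 2 + lane * (canvas.domain_bar_height + 1)
            title = (
                f"{m.accession} {m.name}".strip()
                + f" ({m.source_name}) | hit {m.start}-{m.end}"
            )
            prims.append(Rect(dx, dy, dw, canvas.domain_bar_height,
                              rgb_to_hex(source_color(m.source_name)),
                              stroke="#222222", title=title, tag="domain-bar"))
        y += canvas.row_height

    # source legend
    prims.append(Text(canvas.margin_left, y + canvas.font_size + 2,
                      "Annotation sources", canvas.font_size, bold=True,
                      tag="legend-title"))
    y += LEGEND_ROW_H
    enabled = set(enabled_sources) if enabled_sources is not None else set(known)
    for name in known:
        active = name in avail and name in enabled
        swatch = rgb_to_hex(source_color(name)) if active else "#cccccc"
        label = name if active else f"{name} (no data)" if name not in avail else f"{name} (hidden)"
        tag = "legend-source" if active else "legend-source-disabled"
        prims.append(Rect(canvas.margin_left, y + 4, 12, 10, swatch,
                          stroke="#333333", tag=tag + "-swatch"))
        prims.append(Text(canvas.margin_left + 18, y + 4 + canvas.font_size - 1,
                          label, canvas.font_size - 1,
                          fill="#000000" if active else "#999999", tag=tag))
        y += LEGEND_ROW_H

    return RenderTree(tuple(prims), canvas.width, height)
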