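"""Serialize render trees to SVG text, rasterize SVG to PNG, and export
per-HSP details as a tab-separated table.

SVG is the source of truth: PNG output is produced by rasterizing the
SVG text, so there is exactly one rendering path to test.  The SVG
writer emits numeric attributes rounded to 2 decimal places and keys in
a fixed order, making output byte-identical across calls for equal
inputs.

The rasterizer handles the subset of SVG 1.1 this library emits (rect,
line, text, ``<a>`` wrappers, ``<title>`` children) by walking the XML
with lxml and drawing onto a Pillow image.  It is not a general SVG
engine; text metrics are approximate.
"""
from __future__ import annotations

import io
from xml.sax.saxutils import escape, quoteattr

from lxml import etree
from PIL import Image, ImageDraw

from .layout import Line, Rect, RenderTree, Text
from .sss_model import SSSRun

__all__ = ["render_svg", "render_png", "export_hit_table", "SVG_NS"]

SVG_NS = "http://www.w3.org/2000/svg"
XLINK_NS = "http://www.w3.org/1999/xlink"


def _n(v: float) -> str:
    """Fixed 2-decimal formatting for byte-stable attribute output."""
    s = f"{v:.2f}"
    return "0.00" if s == "-0.00" else s


def _rect_svg(p: Rect) -> str:
    attrs = [
        f'x="{_n(p.x)}"', f'y="{_n(p.y)}"',
        f'width="{_n(p.w)}"', f'height="{_n(p.h)}"',
        f'fill="{p.fill}"',
    ]
    if p.stroke:
        attrs.append(f'stroke="{p.stroke}" stroke-width="0.5"')
    if p.tag:
        attrs.append(f"class={quoteattr(p.tag)}")
    body = f"<title>{escape(p.title)}</title>" if p.title else ""
    elem = f'<rect {" ".join(attrs)}>{body}</rect>' if body else f'<rect {" ".join(attrs)}/>'
    if p.href:
        return f"<a xlink:href={quoteattr(p.href)}>{elem}</a>"
    return elem


def _line_svg(p: Line) -> str:
    attrs = (
        f'x1="{_n(p.x1)}" y1="{_n(p.y1)}" x2="{_n(p.x2)}" y2="{_n(p.y2)}" '
        f'stroke="{p.stroke}" stroke-width="1"'
    )
    if p.tag:
        attrs += f" class={quoteattr(p.tag)}"
    return f"<line {attrs}/>"


_ANCHORS = {"start": "start", "middle": "middle", "end": "end"}


def _text_svg(p: Text, font_family: str) -> str:
    attrs = [
        f'x="{_n(p.x)}"', f'y="{_n(p.y)}"',
        f"font-family={quoteattr(font_family)}",
        f'font-size="{_n(p.font_size)}"',
        f'fill="{p.fill}"',
    ]
    if p.anchor != "start":
        attrs.append(f'text-anchor="{_ANCHORS[p.anchor]}"')
    if p.bold:
        attrs.append('font-weight="bold"')
    if p.tag:
        attrs.append(f"class={quoteattr(p.tag)}")
    elem = f'<text {" ".join(attrs)}>{escape(p.content)}</text>'
    if p.href:
        return f"<a xlink:href={quoteattr(p.href)}>{elem}</a>"
    return elem


def render_svg(tree: RenderTree, font_family: str = "Helvetica, Arial, sans-serif") -> str:
    """Serialize a render tree to a standalone SVG 1.1 document.

    Embedded titles become ``<title>`` children (native tooltips in
    browsers); hyperlinks become ``<a xlink:href>`` wrappers.  Output is
    byte-identical across calls for equal inputs.
    """
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="{SVG_NS}" xmlns:xlink="{XLINK_NS}" version="1.1" '
        f'width="{_n(tree.width)}" height="{_n(tree.height)}" '
        f'viewBox="0 0 {_n(tree.width)} {_n(tree.height)}">',
        f'<rect x="0.00" y="0.00" width="{_n(tree.width)}" '
        f'height="{_n(tree.height)}" fill="#ffffff" class="background"/>',
    ]
    for p in tree.primitives:
        if isinstance(p, Rect):
            parts.append(_rect_svg(p))
        elif isinstance(p, Line):
            parts.append(_line_svg(p))
        elif isinstance(p, Text):
            parts.append(_text_svg(p, font_family))
        else:  # pragma: no cover - the tree is a closed union
            raise TypeError(f"unknown primitive {type(p).__name__}")
    parts.append("</svg>\n")
    return "\n".join(parts)


def _f(elem, attr: str, default: float = 0.0) -> float:
    v = elem.get(attr)
    return float(v) if v is not None else default


def render_png(svg_text: str, pixel_scale: float = 1.0) -> bytes:
    """Rasterize SVG text (this library's dialect) to PNG bytes.

    The image is ``round(width * pixel_scale) x round(height *
    pixel_scale)`` pixels on a white background.
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    try:
        root = etree.fromstring(svg_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed SVG: {exc}") from exc
    if etree.QName(root).localname != "svg":
        raise ValueError("not an SVG document")

    width = _f(root, "width")
    height = _f(root, "height")
    if width <= 0 or height <= 0:
        raise ValueError("SVG must declare positive width and height")
    k = pixel_scale
    img = Image.new("RGB", (round(width * k), round(height * k)), "#ffffff")
    draw = ImageDraw.Draw(img)

    def walk(elem) -> None:
        for child in elem:
            name = etree.QName(child).localname
            if name == "a" or name == "g":
                walk(child)
            elif name == "rect":
                x, y = _f(child, "x") * k, _f(child, "y") * k
                w, h = _f(child, "width") * k, _f(child, "height") * k
                draw.rectangle(
                    [x, y, max(x, x + w - 1), max(y, y + h - 1)],
                    fill=child.get("fill", "#000000"),
                    outline=child.get("stroke"),
                )
            elif name == "line":
                draw.line(
                    [_f(child, "x1") * k, _f(child, "y1") * k,
                     _f(child, "x2") * k, _f(child, "y2") * k],
                    fill=child.get("stroke", "#000000"),
                )
            elif name == "text":
                size = max(6, round(_f(child, "font-size", 11.0) * k))
                content = child.text or ""
                x, y = _f(child, "x") * k, _f(child, "y") * k
                anchor = child.get("text-anchor", "start")
                pil_anchor = {"start": "ls", "middle": "ms", "end": "rs"}[anchor]
                try:
                    from PIL import ImageFont

                    font = ImageFont.load_default(size=size)
                except (ImportError, AttributeError):  # very old Pillow
                    font = None
                draw.text((x, y), content, fill=child.get("fill", "#000000"),
                          font=font, anchor=pil_anchor)
            # <title> and unknown elements are not visual: skip

    walk(root)
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()


TABLE_COLUMNS = (
    "hit_id", "rank", "qstart", "qend", "hstart", "hend",
    "evalue", "bitscore", "identity", "similarity",
)


def export_hit_table(run: SSSRun) -> str:
    """One tab-separated row per displayed HSP (header row first).

    ``rank`` is the hit's 1-based display rank.  This is the scriptable
    analogue of the per-bar tooltip: every score shown in an embedded
    title is recoverable from the table.
    """
    lines = ["\t".join(TABLE_COLUMNS)]
    for rank, hit in enumerate(run.hits, start=1):
        for h in hit.hsps:
            lines.append("\t".join(map(str, (
                hit.hit_identifier, rank,
                h.query_start, h.query_end, h.hit_start, h.hit_end,
                h.evalue, h.bit_score, h.identity_percent, h.similarity_percent,
            ))))
    return "\n".join(lines) + "\n"
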