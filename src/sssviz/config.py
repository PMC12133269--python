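"""Optional TOML configuration: canvas geometry, palette overrides and
annotation-source priority/colours.

Precedence is CLI flags > config file > built-in defaults.  Example::

    [canvas]
    width = 1200
    label_panel_width = 200
    font_size = 12

    [palettes.heatmap]
    anchors = ["#0000ff", "#00ff00", "#ffff00", "#ff0000"]

    [palettes.my-bins]
    bins = [[40, "#000000"], [200, "#0000ff"], ["inf", "#ff0000"]]

    [sources]
    priority = ["Pfam", "SUPERFAMILY"]
    colors = { Pfam = "#6287b1" }
"""
from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .colors import RGB, Palette, hex_to_rgb
from .layout import DEFAULT_SOURCE_PRIORITY, CanvasSpec

__all__ = ["VizConfig", "load_config"]


@dataclass
class VizConfig:
    canvas: CanvasSpec = field(default_factory=CanvasSpec)
    palette_overrides: dict[str, Palette] = field(default_factory=dict)
    source_priority: tuple[str, ...] = DEFAULT_SOURCE_PRIORITY
    source_colors: dict[str, RGB] = field(default_factory=dict)


def _parse_palette(name: str, spec: dict) -> Palette:
    if "bins" in spec:
        bins = tuple(
            (math.inf if edge == "inf" else float(edge), hex_to_rgb(color))
            for edge, color in spec["bins"]
        )
        return Palette(name=name, bins=bins)
    anchors = tuple(hex_to_rgb(c) for c in spec["anchors"])
    return Palette(name=name, anchors=anchors, reversed=spec.get("reversed", False))


def load_config(path: str | Path | None) -> VizConfig:
    """Load a TOML config file; ``None`` yields all defaults."""
    if path is None:
        return VizConfig()
    data = tomllib.loads(Path(path).read_text(encoding="utf-8"))

    canvas = CanvasSpec(**data.get("canvas", {}))
    palettes = {
        name: _parse_palette(name, spec)
        for name, spec in data.get("palettes", {}).items()
    }
    src = data.get("sources", {})
    priority = tuple(src.get("priority", DEFAULT_SOURCE_PRIORITY))
    colors = {name: hex_to_rgb(c) for name, c in src.get("colors", {}).items()}
    return VizConfig(
        canvas=canvas,
        palette_overrides=palettes,
        source_priority=priority,
        source_colors=colors,
    )
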