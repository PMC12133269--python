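"""Score transforms, colour scales, palettes and gradients.

A selected per-HSP score (E-value, bit score, identity % or similarity %)
is mapped to a colour in three steps:

1. **transform** — E-values are mapped to ``-log10(max(E, 1e-200))`` so
   that larger transformed values mean more significant matches; the
   other scores pass through unchanged.
2. **normalize** — the transformed value is placed on a scale, either
   *dynamic* (the observed min/max of the data) or *fixed* (a preset
   score-dependent range, e.g. [0, 100] for identity), yielding a
   fraction in [0, 1] where 1 is the most significant end.
3. **colour lookup** — continuous palettes interpolate linearly (per RGB
   channel) between equally spaced anchor colours; the ``ncbi-bins``
   palette instead bins the *raw* bit score into the conventional
   NCBI BLAST+ graphic-summary ranges.

Six built-in palettes: heatmap (default), greyscale, blues, divergent,
qualitative (8 contrasting hues cycled by hit rank, ignoring the score),
and ncbi-bins.
"""
from __future__ import annotations

import enum
import math
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .sss_model import HSPRecord, ScoreKind

__all__ = [
    "EVALUE_FLOOR",
    "ScaleKind",
    "ScaleSpec",
    "Palette",
    "DEFAULT_PALETTES",
    "get_palette",
    "transform_score",
    "inverse_transform",
    "build_scale",
    "normalize",
    "color_for",
    "build_gradient",
    "hex_to_rgb",
    "rgb_to_hex",
]

#: E-values of exactly 0 are reported by search tools; floor before log10.
EVALUE_FLOOR = 1e-200

RGB = tuple[int, int, int]


def hex_to_rgb(s: str) -> RGB:
    s = s.lstrip("#")
    return (int(s[0:2], 16), int(s[2:4], 16), int(s[4:6], 16))


def rgb_to_hex(c: RGB) -> str:
    return "#{:02x}{:02x}{:02x}".format(*c)


class ScaleKind(str, enum.Enum):
    DYNAMIC = "dynamic"
    FIXED = "fixed"


class ScaleSpec(BaseModel):
    """How a selected score maps onto [0, 1].

    ``domain_min``/``domain_max`` are in *transformed* units (i.e.
    -log10 E for E-values).
    """

    model_config = ConfigDict(frozen=True)

    kind: ScaleKind
    score_kind: ScoreKind
    transform: str  # "identity" | "neglog10"
    domain_min: float
    domain_max: float

    @model_validator(mode="after")
    def _check(self) -> "ScaleSpec":
        needs_log = self.score_kind is ScoreKind.EVALUE
        if (self.transform == "neglog10") != needs_log:
            raise ValueError("transform is neglog10 iff score_kind is evalue")
        if not self.domain_min < self.domain_max:
            raise ValueError(
                f"domain_min {self.domain_min} must be < domain_max {self.domain_max}"
            )
        return self


class Palette(BaseModel):
    """Anchor colours for continuous palettes, or bin edges for ncbi-bins.

    ``bins`` is an ordered list of ``(upper_edge, colour)`` pairs with
    strictly increasing edges; the last bin is open-ended (edge is
    ``inf``).  ``reversed`` flips the anchor order of continuous
    palettes.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    anchors: tuple[RGB, ...] = ()
    bins: tuple[tuple[float, RGB], ...] = ()
    reversed: bool = False

    @model_validator(mode="after")
    def _check(self) -> "Palette":
        if self.bins:
            edges = [e for e, _ in self.bins]
            if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
                raise ValueError("bins need >= 2 strictly increasing edges")
        elif len(self.anchors) < 2:
            raise ValueError("continuous palettes need >= 2 anchors")
        return self

    @property
    def is_binned(self) -> bool:
        return bool(self.bins)

    def effective_anchors(self) -> tuple[RGB, ...]:
        return tuple(reversed(self.anchors)) if self.reversed else self.anchors


def _hx(*colors: str) -> tuple[RGB, ...]:
    return tuple(hex_to_rgb(c) for c in colors)


#: Qualitative hues cycled by hit rank (a contrasting 8-colour cycle).
QUALITATIVE_HUES: tuple[RGB, ...] = _hx(
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3",
    "#ff7f00", "#a65628", "#f781bf", "#17becf",
)

#: Conventional NCBI BLAST+ graphic-summary bit-score bins.
NCBI_BINS: tuple[tuple[float, RGB], ...] = (
    (40.0, hex_to_rgb("#000000")),   # < 40
    (50.0, hex_to_rgb("#0000ff")),   # 40-50
    (80.0, hex_to_rgb("#00a651")),   # 50-80
    (200.0, hex_to_rgb("#ff00ff")),  # 80-200
    (math.inf, hex_to_rgb("#ff0000")),  # >= 200
)

# Anchors run from the least to the most significant end of the scale,
# so the heatmap paints the most significant matches red.
DEFAULT_PALETTES: dict[str, Palette] = {
    "heatmap": Palette(name="heatmap",
                       anchors=_hx("#0000ff", "#00ff00", "#ffff00", "#ff0000")),
    "greyscale": Palette(name="greyscale", anchors=_hx("#f0f0f0", "#101010")),
    "blues": Palette(name="blues", anchors=_hx("#deebf7", "#08306b")),
    "divergent": Palette(name="divergent",
                         anchors=_hx("#d73027", "#ffffff", "#1a9850")),
    "qualitative": Palette(name="qualitative", anchors=QUALITATIVE_HUES),
    "ncbi-bins": Palette(name="ncbi-bins", bins=NCBI_BINS),
}


def get_palette(name: str, overrides: Optional[dict[str, Palette]] = None) -> Palette:
    table = dict(DEFAULT_PALETTES)
    if overrides:
        table.update(overrides)
    try:
        return table[name]
    except KeyError:
        raise ValueError(
            f"unknown palette {name!r}; available: {', '.join(sorted(table))}"
        ) from None


def transform_score(value: float, score_kind: ScoreKind) -> float:
    """Transformed score: ``-log10(max(E, 1e-200))`` for E-values,
    identity for the rest.  Monotone non-increasing in the E-value."""
    if value < 0:
        raise ValueError(f"scores must be non-negative, got {value}")
    if ScoreKind(score_kind) is ScoreKind.EVALUE:
        return -math.log10(max(value, EVALUE_FLOOR))
    return float(value)


def inverse_transform(t: float, score_kind: ScoreKind) -> float:
    """Untransformed score for a transformed value (used for tick labels)."""
    if ScoreKind(score_kind) is ScoreKind.EVALUE:
        return 10.0 ** (-t)
    return float(t)


#: Fixed-scale endpoints in transformed units per score kind.
#: identity/similarity span their natural 0-100%; bit scores span the
#: conventional 0-200-bit bin range; E-values span 10 down to 1e-100.
FIXED_DOMAINS: dict[ScoreKind, tuple[float, float]] = {
    ScoreKind.IDENTITY: (0.0, 100.0),
    ScoreKind.SIMILARITY: (0.0, 100.0),
    ScoreKind.BITSCORE: (0.0, 200.0),
    ScoreKind.EVALUE: (-1.0, 100.0),
}


def build_scale(
    hsps: Sequence[HSPRecord],
    kind: ScaleKind,
    score_kind: ScoreKind,
) -> ScaleSpec:
    """Build a dynamic (data min/max) or fixed (preset) colour scale.

    A degenerate dynamic range (all scores equal) is widened to
    ``[m - 0.5, m + 0.5]``.
    """
    kind = ScaleKind(kind)
    score_kind = ScoreKind(score_kind)
    transform = "neglog10" if score_kind is ScoreKind.EVALUE else "identity"
    if kind is ScaleKind.FIXED:
        lo, hi = FIXED_DOMAINS[score_kind]
    else:
        if not hsps:
            raise ValueError("dynamic scale requires at least one HSP")
        ts = [transform_score(h.score(score_kind), score_kind) for h in hsps]
        lo, hi = min(ts), max(ts)
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
    return ScaleSpec(
        kind=kind, score_kind=score_kind, transform=transform,
        domain_min=lo, domain_max=hi,
    )


def normalize(value: float, scale: ScaleSpec) -> float:
    """Fraction in [0, 1] of the transformed value on the scale's domain.

    For E-values, 1 means the most significant (smallest) E.
    """
    t = transform_score(value, scale.score_kind)
    f = (t - scale.domain_min) / (scale.domain_max - scale.domain_min)
    return min(1.0, max(0.0, f))


def _interpolate(anchors: Sequence[RGB], fraction: float) -> RGB:
    """Piecewise-linear interpolation between equally spaced anchors."""
    f = min(1.0, max(0.0, fraction))
    n = len(anchors)
    pos = f * (n - 1)
    i = min(int(pos), n - 2)
    local = pos - i
    a, b = anchors[i], anchors[i + 1]
    return tuple(round(a[c] + (b[c] - a[c]) * local) for c in range(3))  # type: ignore[return-value]


def color_for(
    value: float,
    scale: ScaleSpec,
    palette: Palette,
    rank: Optional[int] = None,
) -> RGB:
    """Colour for one score.

    Continuous palettes interpolate at ``normalize(value)``.  The
    qualitative palette ignores the value and cycles its hues by
    ``rank``.  ``ncbi-bins`` looks the *raw* bit score up in its bin
    table (first bin whose upper edge exceeds the score; the last bin is
    open-ended) and therefore requires ``score_kind = bitscore``.
    """
    if palette.is_binned:
        if scale.score_kind is not ScoreKind.BITSCORE:
            raise ValueError("the ncbi-bins palette requires the bitscore score kind")
        for edge, color in palette.bins:
            if value < edge:
                return color
        return palette.bins[-1][1]
    if palette.name == "qualitative":
        anchors = palette.effective_anchors()
        return anchors[(rank or 0) % len(anchors)]
    return _interpolate(palette.effective_anchors(), normalize(value, scale))


#: Display colours for well-known annotation sources; unknown sources fall
#: back deterministically onto the qualitative hue cycle (hash of the name).
SOURCE_COLORS: dict[str, RGB] = {
    "Pfam": hex_to_rgb("#6287b1"),
    "SUPERFAMILY": hex_to_rgb("#84c3a3"),
    "PROSITE": hex_to_rgb("#f7a35c"),
    "CDD": hex_to_rgb("#b381b3"),
    "PANTHER": hex_to_rgb("#d05c5c"),
    "Gene3D": hex_to_rgb("#8a9a5b"),
    "SMART": hex_to_rgb("#d4a31f"),
    "PRINTS": hex_to_rgb("#5cb8d0"),
}


def source_color(name: str, overrides: Optional[dict[str, RGB]] = None) -> RGB:
    if overrides and name in overrides:
        return overrides[name]
    if name in SOURCE_COLORS:
        return SOURCE_COLORS[name]
    import hashlib

    digest = hashlib.sha1(name.encode("utf-8")).digest()
    return QUALITATIVE_HUES[digest[0] % len(QUALITATIVE_HUES)]


def build_gradient(palette: Palette, n_steps: int) -> list[RGB]:
    """Colours at fractions ``i/(n_steps-1)`` — used to paint the scale bar."""
    if palette.is_binned:
        return [color for _, color in palette.bins]
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    anchors = palette.effective_anchors()
    return [_interpolate(anchors, i / (n_steps - 1)) for i in range(n_steps)]
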