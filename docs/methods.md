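# Methods

This note records the conventions, defaults and approximations behind
sssviz's two visualizations, and what the synthetic fixtures do and do
not emulate.

## Data model and input dialects

A search execution is an `SSSRun`: tool, version, database, query
metadata (identifier, description, length, protein/nucleotide), start
and end timestamps, and an ordered list of hits. Each `HitRecord`
carries its identifier, source namespace (e.g. a protein knowledgebase
or structure archive), length, an optional link URL and one or more
`HSPRecord`s; each HSP carries 1-based inclusive query and hit
coordinates plus four scores (E-value, bit score, % identity,
% similarity). Coordinates are validated against the owning sequence
lengths at parse time; a hit with zero HSPs is rejected rather than
silently dropped. Multi-query documents are handled by taking the first
query and warning about the rest.

The result dialect is a flat JSON object (`program, version, db,
query_id, query_def, query_len, program_type, start_time, end_time,
hits[]`, with `hit = {id, source, description, length, url, hsps[]}` and
`hsp = {qstart, qend, hstart, hend, bitscore, evalue, identity,
similarity}`). Serialization uses a fixed key order so equal runs
produce byte-identical text.

Domain annotations use a deliberately flat dialect: a JSON list of
`{hit_id, source, accession, name, start, end}` records on hit
coordinates. This is a simplification of nested web-API payloads, which
group matches by entry and carry per-location fragments; mapping from
such a payload means emitting one record per match location with the
member-database name as `source`. Matches whose coordinates disagree
with the hit length (a sequence-version mismatch) are clamped to
`[1, hit_length]` when they partially overlap and dropped with a logged
warning when they do not; they are never fatal.

## Ranking and display caps

Hits are ranked by their best HSP — minimum E-value (the default score)
or maximum of the selected score — with ties broken by best bit score
descending, then stable input order, so layouts are reproducible.
Display caps default to 100 hits × 10 HSPs for the coverage view and 30
hits for the domain view; within a hit the best HSPs under the active
score are kept in their original order. How the original web views rank
hits or choose surviving HSPs is not documented anywhere we know of;
these rules are this package's own, chosen for determinism.

## Colour model

Scores are transformed (E-values to `−log10 max(E, 1e-200)`; the floor
handles tool-reported E = 0 without infinities), normalized onto a scale
domain, and looked up in a palette. Dynamic scales span the observed
transformed scores, widened to ±0.5 when all scores are equal. Fixed
scales use preset per-score domains: 0–100 for identity and similarity,
0–200 bits for bit scores (the top edge of the conventional NCBI bin
scheme), and E-values from 10 down to 1e-100 (transformed −1 to 100),
which brackets typically reported significance.

Continuous palettes interpolate linearly per RGB channel between equally
spaced anchors — simple and deterministic, not perceptually uniform.
Anchors are stored from the least to the most significant end, so the
default heatmap (blue → green → yellow → red) paints the most
significant matches red. The qualitative palette ignores the score and
cycles 8 contrasting hues by hit rank. The `ncbi-bins` palette bins the
raw bit score at edges 40/50/80/200 with the conventional
black/blue/green/magenta/red colours and therefore only combines with
the bit-score score kind. Annotation sources have a fixed colour table
with a deterministic fallback (SHA-1 of the source name into the
qualitative hues) for unknown sources. All palettes, source colours and
priorities are overridable in a TOML config file.

## Geometry

Residue *pos* on a track starting at `x0` with pixel span *S* has left
edge `x0 + (pos−1)/L·S`; a bar for `[s, e]` extends to the right edge of
*e*, so its width is exactly `(e−s+1)/L·S` — width is linear in
alignment length and a full-length alignment spans the whole track. Row
height, bar heights, margins, label-panel width, fonts and canvas width
(default 1000 px) live in `CanvasSpec`; total height is affine in the
row count. The scale bar uses 50 gradient steps and 5 ticks (cosmetic
constants, held in config), with E-value ticks printed in scientific
notation on the untransformed scale.

In the domain view the background bar spans the hit's aggregate HSP
query range (min start to max end). Domain bars are projected from hit
space to query space through the hit's best HSP under a **gap-free
linear offset** (`query_start − hit_start`), after clipping to that
HSP's hit range; projections are clamped to the query bounds. Real
alignments contain gaps, so projected domain positions are approximate —
this is a rendering convention, not an alignment. Overlapping domains
overlay fully in a fixed source-priority order by default; an optional
stacking mode lays them on sub-rows (lanes assigned greedily, capped to
the row height).

## Rendering

SVG is the source of truth; PNG is produced by rasterizing the SVG, so
there is one rendering path to test. Numeric SVG attributes are fixed to
2 decimals for byte-stable output; embedded titles become `<title>`
children (native browser tooltips) and identifiers with URLs become
`<a xlink:href>` links. The rasterizer walks the library's own SVG
subset (rect/line/text/a/title) with lxml and draws via Pillow; it is
not a general SVG engine and its text metrics are approximate, but
geometry and fills are exact up to pixel rounding. The per-HSP TSV
export carries every score shown in a tooltip, so no information is
locked inside the images.

## Synthetic fixtures

The generator emulates the statistical shape of real search output, not
sequences: alignment lengths uniform on `[20, query_length]`; identity
uniform on a configurable range (default 25–98%); similarity = identity
plus uniform [0, 15], capped at 100 (identity can never exceed
similarity, as under substitution-matrix scoring); bit score
`0.5·aln_len·(identity/100)·4.3` bits; and E-value from the standard
Karlin–Altschul form `E = m·n·2^(−S′)` with query length *m* and an
effective database size *n* (default 5e8 residues), so higher bit scores
imply strictly lower E-values. Hit lengths are 1–1.6× the query length
and coordinates are placed uniformly within bounds; hits are emitted
best-E-value first, as search tools print them. Domain annotations are
Poisson-distributed per hit (default mean 2) with uniformly drawn
sources and lengths of 10 residues up to ~40% of the hit.

Because the generator and the validator agree by construction, passing
tests demonstrate the pipeline's correctness on well-formed inputs with
realistic score coupling; they do not probe gapped-alignment coordinate
effects, biased score distributions, database-specific identifier
conventions, or malformed third-party files beyond the explicit error
tests. The pinned demonstration fixture used by the golden-file test is
seed 42 with 25 hits — small enough to keep the committed reference SVG
readable in review — while cap behaviour is exercised on 250-hit runs
generated at test time.

## Degenerate inputs and numerical choices

Zero-hit runs render (header, scale bar, query bar, a "no hits found"
notice); an empty run falls back from a dynamic to the fixed scale since
there is no data range. Equal-score ties everywhere resolve to input
order. E-value 0 maps to the 1e-200 floor. All randomness flows through
seeded numpy generators; two calls with equal inputs produce
byte-identical JSON, SVG and PNG.

## Out of scope

Parsing native BLAST+/FASTA text, XML or tabular output; live retrieval
from web APIs; nested annotation entry hierarchies; pixel parity with
any web rendering; PDF export and font embedding.
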