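# sssviz

Static, scriptable visualizations of **sequence similarity search (SSS)
results** — the output of tools such as NCBI BLAST+ and FASTA — rendered
as SVG or PNG, with optional InterPro-style domain-annotation overlays.

It is aimed at bioinformaticians who want publication-quality or
pipeline-embeddable graphics of search results without a browser: every
interactive toggle of a typical web result page (selected score, colour
scale, palette, annotation-source filter) is a command-line flag, so any
interactive state is a renderable static image.

## What it draws

**Visual output** (hit coverage). Each database hit is one row; each of
its high-scoring segment pairs (HSPs) is a bar positioned by its query
coordinates, so a bar from query position *s* to *e* on a query of
length *L* occupies the fraction `(e − s + 1)/L` of the track. Bars are
coloured by a selectable score: E-value (transformed as
`−log10 max(E, 1e-200)`), bit score, % identity or % similarity. The
colour scale is either *dynamic* (spanning the observed scores) or
*fixed* (a preset range per score, e.g. 0–100 for identity). Six
palettes are built in, including a qualitative scheme keyed to the
conventional NCBI BLAST+ bit-score bins (<40, 40–50, 50–80, 80–200,
≥200). Hits are ranked by their best HSP (minimum E-value; ties broken
by bit score), and display is capped at 100 hits × 10 HSPs per hit by
default.

**Functional predictions** (domain overlay). Each hit becomes a single
score-coloured background bar spanning its aggregate HSP range, with
domain predictions (Pfam, SUPERFAMILY, PROSITE, CDD, ...) overlaid as
source-coloured bars; domain coordinates are projected from hit space
into query space through the hit's best HSP. A legend lists the
annotation sources and marks those without matches as disabled. The
default display cap here is 30 hits.

Inputs are a flat JSON dialect for search results (and a flat JSON list
for domain matches) documented in `sssviz/sss_model.py` and
`sssviz/annotations.py`. A seeded fixture generator replaces live
search/annotation services for testing and demos.

## Worked example

Generate a synthetic 50-hit search result plus domain annotations, then
render both views:

```sh
sssviz fixtures --hits 50 --seed 7 -o result.json --domains-out domains.json
sssviz visual-output result.json --max-hits 5 -o coverage.svg --table-out hits.tsv -v
sssviz functional-predictions result.json --domains domains.json -o domains.svg -v
```

which prints

```
wrote result.json
wrote domains.json
5 hits displayed (35 HSPs)
wrote coverage.svg
wrote hits.tsv
30 hits displayed, 102 domain matches
wrote domains.svg
```

`coverage.svg` shows the 5 best hits (by E-value) as heatmap-coloured
HSP bars under a dynamic scale bar; `domains.svg` shows the top 30 hits
as background bars with 102 domain matches overlaid. `hits.tsv` is the
tabular analogue of the per-bar tooltips — one row per displayed HSP:

```
hit_id      rank  qstart  qend  hstart  hend  evalue        bitscore  identity  similarity
SP:Q23010   1     321     352   40      71    1.74e-08      63.3      92.0      100.0
SP:Q23010   1     111     317   182     388   8.66e-68      260.3     58.5      67.0
SP:Q23010   1     61      360   52      351   3.74e-134     480.8     74.5      89.5
...
```

Rank 1 is the best hit; its strongest HSP covers query residues 61–360
at 74.5% identity with an E-value of 3.7e-134. PNG output is selected by
the file extension (`-o coverage.png --png-scale 2` doubles the pixel
resolution); a fixed identity scale with a greyscale palette is
`--score identity --scale fixed --palette greyscale`.

The same operations are available as a library; see the package
docstring (`python -c "import sssviz; help(sssviz)"`) and
`docs/methods.md` for the model and its conventions.

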