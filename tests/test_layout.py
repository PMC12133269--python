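"""Geometry and render-tree construction for both visualizations."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_hit, make_hsp, make_run
from sssviz.annotations import AnnotationSet, clip_matches
from sssviz.colors import build_scale, get_palette
from sssviz.fixtures import generate_domain_annotations, generate_sss_result
from sssviz.layout import (
    CanvasSpec,
    Line,
    Rect,
    Text,
    layout_functional_predictions,
    layout_header,
    layout_scale_bar,
    layout_visual_output,
    seq_to_px,
)
from sssviz.sss_model import cap_display

HEAT = get_palette("heatmap")
EV_FIXED = build_scale([], "fixed", "evalue")
ID_FIXED = build_scale([], "fixed", "identity")


def tagged(tree, tag):
    return [p for p in tree.primitives if getattr(p, "tag", None) == tag]


class TestSeqToPx:
    def test_first_residue_at_track_origin(self):
        assert seq_to_px(1, 100, 0.0, 500.0) == 0.0

    def test_full_and_half_coverage_widths(self):
        L, span = 100, 500.0
        x1 = seq_to_px(1, L, 0.0, span)
        assert (100 - 1 + 1) / L * span == 500.0 and x1 == 0.0
        x51 = seq_to_px(51, L, 0.0, span)
        assert x51 == 250.0
        assert (100 - 51 + 1) / L * span == 250.0

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            seq_to_px(0, 100, 0.0, 500.0)
        with pytest.raises(ValueError):
            seq_to_px(101, 100, 0.0, 500.0)

    @settings(max_examples=100, deadline=None)
    @given(data=st.data(), L=st.integers(2, 5000), span=st.floats(10, 2000))
    def test_bar_width_is_linear_in_alignment_span(self, data, L, span):
        s = data.draw(st.integers(1, L))
        e = data.draw(st.integers(s, L))
        width = (e - s + 1) / L * span
        lhs = seq_to_px(s, L, 0.0, span)
        assert lhs + width <= span + 1e-9
        assert width == pytest.approx((e - s + 1) / L * span, abs=1e-9)
        # doubling the alignment span doubles the width
        if e - s + 1 <= L // 2 and (s + 2 * (e - s + 1) - 1) <= L:
            e2 = s + 2 * (e - s + 1) - 1
            w2 = (e2 - s + 1) / L * span
            assert w2 == pytest.approx(2 * width, abs=1e-9)


class TestHeader:
    def test_header_text_matches_run_fields(self, simple_run, canvas):
        prims = layout_header(simple_run, canvas)
        contents = [p.content for p in prims if isinstance(p, Text)]
        assert "ncbiblast 2.17.0+" in contents
        assert "Database: uniprotkb_swissprot" in contents
        assert any("Q1" in c for c in contents)
        assert any("100 residues" in c for c in contents)
        stamps = [p for p in prims if p.tag == "header-timestamps"]
        assert stamps and stamps[0].anchor == "end"

    def test_empty_description_leaves_no_gap(self, canvas):
        run = make_run()
        prims = layout_header(run, canvas)
        q = next(p for p in prims if p.tag == "header-query")
        assert q.content == "Query: Q1"

    def test_trees_differ_only_in_the_changed_field(self, simple_run, canvas):
        other = simple_run.model_copy(update={"database_name": "pdb"})
        a = layout_header(simple_run, canvas)
        b = layout_header(other, canvas)
        diffs = [(x, y) for x, y in zip(a, b) if x != y]
        assert len(diffs) == 1
        assert diffs[0][1].content == "Database: pdb"


class TestScaleBar:
    def test_fixed_identity_ticks(self, canvas):
        prims = layout_scale_bar(ID_FIXED, HEAT, canvas)
        labels = [p.content for p in prims if getattr(p, "tag", "") == "tick-label"]
        assert labels == ["0", "25", "50", "75", "100"]

    def test_fixed_evalue_leftmost_tick_is_10(self, canvas):
        prims = layout_scale_bar(EV_FIXED, HEAT, canvas)
        labels = [p.content for p in prims if getattr(p, "tag", "") == "tick-label"]
        assert labels[0] == "1.0e+01"

    def test_gradient_strip_has_50_steps(self, canvas):
        prims = layout_scale_bar(ID_FIXED, HEAT, canvas)
        assert len([p for p in prims if getattr(p, "tag", "") == "gradient-step"]) == 50

    def test_binned_palette_gets_swatches_not_a_strip(self, canvas):
        bits = build_scale([], "fixed", "bitscore")
        prims = layout_scale_bar(bits, get_palette("ncbi-bins"), canvas)
        assert len([p for p in prims if getattr(p, "tag", "") == "bin-swatch"]) == 5
        assert not [p for p in prims if getattr(p, "tag", "") == "gradient-step"]

    def test_caption_names_active_selection(self, canvas):
        prims = layout_scale_bar(ID_FIXED, HEAT, canvas)
        caption = next(p for p in prims if p.tag == "scale-caption")
        assert "identity" in caption.content and "heatmap" in caption.content


class TestVisualOutput:
    def test_empty_run_still_renders_with_notice(self, canvas):
        run = make_run([])
        tree = layout_visual_output(run, EV_FIXED, HEAT, canvas)
        assert tagged(tree, "no-hits")
        assert tagged(tree, "query-bar")
        assert not tagged(tree, "hit-label")

    def test_one_label_per_hit_and_one_bar_per_hsp(self, simple_run, canvas):
        tree = layout_visual_output(simple_run, EV_FIXED, HEAT, canvas)
        assert len(tagged(tree, "hit-label")) == 2
        assert len(tagged(tree, "hsp-bar")) == 3  # 2 + 1 HSPs

    def test_three_hsp_hit_gives_three_bars(self, canvas):
        hit = make_hit("h3", 300, [make_hsp(1, 20, 1, 20),
                                   make_hsp(30, 60, 30, 60),
                                   make_hsp(70, 99, 70, 99)])
        tree = layout_visual_output(make_run([hit], 100), EV_FIXED, HEAT, canvas)
        assert len(tagged(tree, "hsp-bar")) == 3

    def test_hyperlinked_identifier(self, simple_run, canvas):
        tree = layout_visual_output(simple_run, EV_FIXED, HEAT, canvas)
        labels = tagged(tree, "hit-label")
        assert labels[0].href == "https://example.org/HIT_A"
        assert labels[1].href is None

    def test_bars_carry_score_titles(self, simple_run, canvas):
        tree = layout_visual_output(simple_run, EV_FIXED, HEAT, canvas)
        bar = tagged(tree, "hsp-bar")[0]
        for token in ("HIT_A", "query 1-50", "hit 11-60", "E-value", "bit score",
                      "identity", "similarity"):
            assert token in bar.title

    def test_layout_is_a_pure_function(self, simple_run, canvas):
        a = layout_visual_output(simple_run, EV_FIXED, HEAT, canvas)
        b = layout_visual_output(simple_run, EV_FIXED, HEAT, canvas)
        assert a == b

    def test_height_grows_affinely_with_row_count(self, canvas):
        runs = [generate_sss_result(n_hits=n, seed=1, query_length=150)
                for n in (2, 5, 8)]
        trees = [layout_visual_output(r, EV_FIXED, HEAT, canvas) for r in runs]
        h2, h5, h8 = (t.height for t in trees)
        assert h5 - h2 == pytest.approx(3 * canvas.row_height)
        assert h8 - h5 == pytest.approx(3 * canvas.row_height)

    @pytest.mark.parametrize("seed", range(6))
    def test_all_primitives_within_canvas_bounds(self, seed, canvas):
        run = generate_sss_result(n_hits=seed * 7, seed=seed, query_length=80 + seed * 90)
        capped = cap_display(run, 100, 10) if run.hits else run
        hsps = [h for hit in capped.hits for h in hit.hsps]
        scale = build_scale(hsps, "dynamic", "evalue") if hsps else EV_FIXED
        tree = layout_visual_output(capped, scale, HEAT, canvas)
        _assert_in_bounds(tree)


def _assert_in_bounds(tree):
    eps = 1e-6
    for p in tree.primitives:
        if isinstance(p, Rect):
            xs, ys = (p.x, p.x + p.w), (p.y, p.y + p.h)
        elif isinstance(p, Line):
            xs, ys = (p.x1, p.x2), (p.y1, p.y2)
        else:
            xs, ys = (p.x,), (p.y,)
        for x in xs:
            assert -eps <= x <= tree.width + eps, (p, tree.width)
        for y in ys:
            assert -eps <= y <= tree.height + eps, (p, tree.height)


class TestFunctionalPredictions:
    def _tree(self, run, ann, **kw):
        hsps = [h for hit in run.hits for h in hit.hsps]
        scale = build_scale(hsps, "dynamic", "evalue") if hsps else EV_FIXED
        return layout_functional_predictions(
            run, ann, scale, HEAT, CanvasSpec(), **kw)

    def test_empty_annotations_give_background_bars_and_disabled_legend(
            self, simple_run):
        tree = self._tree(simple_run, AnnotationSet())
        assert len(tagged(tree, "bg-bar")) == 2
        assert not tagged(tree, "domain-bar")
        assert not tagged(tree, "legend-source")
        assert tagged(tree, "legend-source-disabled")

    def test_one_domain_paints_after_its_background_bar(self, simple_run,
                                                        simple_annotations):
        ann = clip_matches(simple_annotations, simple_run)
        tree = self._tree(simple_run, ann)
        prims = list(tree.primitives)
        for d in tagged(tree, "domain-bar"):
            bg = [prims.index(b) for b in tagged(tree, "bg-bar")
                  if b.y < d.y + 1 and d.y < b.y + b.h + 1]
            assert bg and all(prims.index(d) > i for i in bg)

    def test_source_filter_removes_bars(self, simple_run, simple_annotations):
        ann = clip_matches(simple_annotations, simple_run)
        everything = self._tree(simple_run, ann)
        only_pfam = self._tree(simple_run, ann, enabled_sources=["Pfam"])
        n_pfam = sum(1 for m in simple_annotations.all_matches()
                     if m.source_name == "Pfam")
        assert len(tagged(only_pfam, "domain-bar")) <= n_pfam
        assert len(tagged(only_pfam, "domain-bar")) < len(
            tagged(everything, "domain-bar"))

    def test_background_bar_spans_aggregate_hsp_range(self, simple_run):
        tree = self._tree(simple_run, AnnotationSet())
        canvas = CanvasSpec()
        bg = tagged(tree, "bg-bar")[0]  # HIT_A: HSPs [1,50] and [60,90]
        x0, span = canvas.content_x0, canvas.content_width
        assert bg.x == pytest.approx(x0)
        assert bg.w == pytest.approx(90 / 100 * span)

    def test_unavailable_sources_marked_disabled(self, simple_run,
                                                 simple_annotations):
        ann = clip_matches(simple_annotations, simple_run)
        tree = self._tree(simple_run, ann)
        active = {p.content for p in tagged(tree, "legend-source")}
        disabled = {p.content for p in tagged(tree, "legend-source-disabled")}
        assert active == {"Pfam", "SUPERFAMILY"}
        assert any(lbl.endswith("(no data)") for lbl in disabled)

    def test_domain_titles_carry_id_name_and_source(self, simple_run,
                                                    simple_annotations):
        ann = clip_matches(simple_annotations, simple_run)
        tree = self._tree(simple_run, ann)
        titles = [d.title for d in tagged(tree, "domain-bar")]
        assert any("PF00001" in t and "kinase domain" in t and "Pfam" in t
                   for t in titles)

    def test_stacked_domains_do_not_escape_the_canvas(self):
        run = generate_sss_result(n_hits=10, seed=21)
        run = cap_display(run, 30, 10)
        ann = clip_matches(
            generate_domain_annotations(run, mean_domains_per_hit=5, seed=22), run)
        tree = self._tree(run, ann, stack_domains=True)
        _assert_in_bounds(tree)

    @pytest.mark.parametrize("seed", range(4))
    def test_bounds_fuzz(self, seed):
        run = generate_sss_result(n_hits=3 + seed * 11, seed=seed)
        run = cap_display(run, 30, 10)
        ann = clip_matches(generate_domain_annotations(run, seed=seed + 1), run)
        tree = self._tree(run, ann)
        _assert_in_bounds(tree)
        # purity
        assert tree == self._tree(run, ann)
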