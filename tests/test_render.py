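"""Panels, brackets, legends, composition, and deterministic export."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bubbleheatmap.align import align_results
from bubbleheatmap.render import (BracketSpec, Circle, Polyline, StyleOptions,
                                  Text, add_bracket, compose_figure,
                                  metab_figure, render_bubble_grid,
                                  render_legends, to_svg, write_figure)
from bubbleheatmap.scales import make_scales

from conftest import build_catalog
from test_align import _res


def _panel(cells, results, **scale_kw):
    cat = build_catalog({"g": cells})
    aligned, _ = align_results(cat, results)
    ests = [r.estimate for r in results]
    scos = [r.score() for r in results if r.score() is not None]
    scales = make_scales(ests, scos, **scale_kw)
    return render_bubble_grid(aligned[0], scales), aligned[0], scales


def _circles(panel_or_fig):
    return [p for p in panel_or_fig.primitives if isinstance(p, Circle)]


def test_one_circle_per_unmasked_cell():
    cells = [["a", "b", "c"], ["d", "e", "f"]]
    panel, _, _ = _panel(cells, [_res(v) for v in "abcdef"])
    assert len(_circles(panel)) == 6


def test_masked_cells_draw_no_circle():
    cells = [["a", "b", "c"], ["d", "e", "f"]]
    panel, _, _ = _panel(cells, [_res(v) for v in "abcd"])  # e, f unfilled
    assert len(_circles(panel)) == 4


def test_zero_score_cell_still_visible_at_rmin():
    panel, _, scales = _panel([["a"]], [_res("a", p=1.0)])
    (c,) = _circles(panel)
    assert c.r == pytest.approx(scales.size.rmin)


def test_primitives_stay_inside_declared_bbox():
    cells = [["a", "b"], ["c", None]]
    panel, _, _ = _panel(cells, [_res(v) for v in "abc"])
    x0, y0, x1, y1 = panel.bbox
    for c in _circles(panel):
        assert x0 <= c.cx - c.r and c.cx + c.r <= x1
        assert y0 <= c.cy - c.r and c.cy + c.r <= y1


def test_zero_dimension_grid_rejected():
    cat = build_catalog({"g": [["a"]]})
    aligned, _ = align_results(cat, [_res("a")])
    aligned[0].grid.row_labels = []
    aligned[0].grid.cells = []
    scales = make_scales([0.1], [2.0])
    with pytest.raises(ValueError, match="zero size"):
        render_bubble_grid(aligned[0], scales)


def test_pitch_smaller_than_bubble_diameter_rejected():
    cat = build_catalog({"g": [["a"]]})
    aligned, _ = align_results(cat, [_res("a")])
    scales = make_scales([0.1], [2.0], rmin=0.3, rmax=0.6)
    with pytest.raises(ValueError, match="pitch"):
        render_bubble_grid(aligned[0], scales, StyleOptions(pitch=1.0))


@given(st.integers(min_value=1, max_value=6), st.integers(min_value=1, max_value=8),
       st.integers(min_value=0, max_value=47))
@settings(derandomize=True, max_examples=40)
def test_circle_count_equals_unmasked_count_on_random_grids(nr, nc, nmask):
    ids = [[f"v{i}_{j}" for j in range(nc)] for i in range(nr)]
    cat = build_catalog({"g": ids})
    flat = [v for row in ids for v in row]
    keep = flat[: max(1, len(flat) - (nmask % len(flat)))]
    aligned, _ = align_results(cat, [_res(v) for v in keep])
    scales = make_scales([0.1, -0.2], [1.0, 9.0])
    panel = render_bubble_grid(aligned[0], scales)
    assert len(_circles(panel)) == aligned[0].n_unmasked == len(keep)


def test_missing_dot_option_marks_masked_cells():
    cells = [["a", "b"]]
    cat = build_catalog({"g": cells})
    aligned, _ = align_results(cat, [_res("a")])
    scales = make_scales([0.1], [2.0])
    panel = render_bubble_grid(aligned[0], scales, StyleOptions(missing_dot=True))
    assert len(_circles(panel)) == 2  # one bubble + one gray dot
    grays = [c for c in _circles(panel) if c.fill == "#999999"]
    assert len(grays) == 1


# ---------------------------------------------------------------------------
# brackets


def _bracket_fixture():
    cells = [[f"v{i}{j}" for j in range(5)] for i in range(4)]
    return _panel(cells, [_res(v) for row in cells for v in row])


def test_bracket_adds_polyline_and_label():
    panel, _, _ = _bracket_fixture()
    n0 = len(panel.primitives)
    out = add_bracket(panel, BracketSpec("cols", 0, 4, "CETP GS", side="top"))
    polys = [p for p in out.primitives[n0:] if isinstance(p, Polyline)]
    texts = [p for p in out.primitives[n0:] if isinstance(p, Text)]
    assert len(polys) == 1 and len(texts) == 1
    assert texts[0].s == "CETP GS"
    assert out.primitives[:n0] == panel.primitives  # originals untouched


def test_left_bracket_label_sits_left_of_row_labels():
    panel, _, _ = _bracket_fixture()
    out = add_bracket(panel, BracketSpec("rows", 2, 3, "block", side="left"))
    label = [p for p in out.primitives if isinstance(p, Text) and p.s == "block"][0]
    row_label_xs = [p.x for p in panel.primitives
                    if isinstance(p, Text) and p.anchor == "end"]
    assert label.x < min(row_label_xs)


def test_bracket_out_of_range_rejected():
    panel, _, _ = _bracket_fixture()
    with pytest.raises(ValueError, match="outside"):
        add_bracket(panel, BracketSpec("cols", 0, 99, "too wide"))


def test_bracket_requires_grid_geometry():
    legends = render_legends(make_scales([1.0], [5.0], cap=35.0))
    with pytest.raises(ValueError, match="geometry"):
        add_bracket(legends, BracketSpec("cols", 0, 1, "x"))


# ---------------------------------------------------------------------------
# legends


def test_legend_largest_reference_bubble_is_labeled_with_the_cap():
    panel = render_legends(make_scales([1.0], [5.0, 50.0], cap=35.0))
    labels = [p.s for p in panel.primitives if isinstance(p, Text)]
    assert "35 (capped)" in labels


def test_legend_color_midpoint_swatch_labeled_zero():
    panel = render_legends(make_scales([-2.0, 2.0], [5.0], cap=10.0))
    labels = [p.s for p in panel.primitives if isinstance(p, Text)]
    assert "0" in labels and "-2" in labels and "2" in labels


def test_legend_without_cap_spans_observed_max():
    panel = render_legends(make_scales([1.0], [2.0, 7.3]))
    labels = [p.s for p in panel.primitives if isinstance(p, Text)]
    assert "7.3" in labels
    assert not any("capped" in s for s in labels)


# ---------------------------------------------------------------------------
# composition


def test_compose_rejects_overlapping_regions():
    panel, _, _ = _panel([["a"]], [_res("a")])
    with pytest.raises(ValueError, match="overlap"):
        compose_figure([(panel, (0, 0, 5, 5)), (panel, (4, 4, 5, 5))])


def test_compose_single_panel_identity_layout():
    panel, _, _ = _panel([["a", "b"]], [_res("a"), _res("b")])
    fig = compose_figure([(panel, (0, 0, panel.width, panel.height))])
    assert fig.size[0] >= panel.width
    assert len(_circles(fig)) == 2


def test_compose_translates_without_rescaling():
    panel, _, _ = _panel([["a"]], [_res("a")])
    (c0,) = _circles(panel)
    fig = compose_figure([(panel, (10.0, 20.0, panel.width, panel.height))])
    (c1,) = _circles(fig)
    assert c1.r == c0.r  # radius untouched by placement
    assert c1.cx == pytest.approx(c0.cx - panel.bbox[0] + 10.0)
    assert c1.cy == pytest.approx(c0.cy - panel.bbox[1] + 20.0)


def test_metab_figure_has_ten_grid_panels_plus_legend(results225, nh225):
    fig = metab_figure(results225, "nh225")
    assert len(_circles(fig)) == 225 + 4  # bubbles + legend reference circles
    titles = {p.s for p in fig.primitives if isinstance(p, Text) and p.bold}
    grid_titles = {pl.title for pl in nh225.layout.placements}
    assert grid_titles <= titles
    assert len(grid_titles) == 10


def test_metab_figure_emits_fatty_acid_footnote(results225):
    fig = metab_figure(results225, "nh225")
    texts = [p.s for p in fig.primitives if isinstance(p, Text)]
    assert any(s.startswith("*Ratios are to total fatty acids") for s in texts)


def test_one_step_equals_four_step_pipeline(results225, nh225):
    """The single-call figure must be byte-identical to the staged pipeline."""
    from bubbleheatmap.catalog import Placement
    from bubbleheatmap.render import FOOTNOTE_TEXT
    from dataclasses import replace

    one = to_svg(metab_figure(results225, "nh225"))

    aligned, _ = align_results(nh225, results225)
    ests = [r.estimate for r in results225]
    scos = [r.score() for r in results225 if r.score() is not None]
    scales = make_scales(ests, scos)
    style = StyleOptions()
    by_name = {a.grid.name: a for a in aligned}
    placed = [(render_bubble_grid(by_name[pl.grid_name], scales,
                                  replace(style, title=pl.title)), pl)
              for pl in nh225.layout.placements]
    placed.append((render_legends(scales, style),
                   Placement("__legend__", nh225.layout.legend_region)))
    four = to_svg(compose_figure(placed, nh225.layout, footnote=FOOTNOTE_TEXT))
    assert one == four


def test_empty_results_propagate_error_from_align():
    with pytest.raises(ValueError):
        metab_figure([], "nh225")


# ---------------------------------------------------------------------------
# export


def test_svg_output_is_deterministic(tmp_path, results225):
    fig = metab_figure(results225, "nh225")
    p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
    write_figure(fig, p1)
    write_figure(metab_figure(results225, "nh225"), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_unknown_format_rejected(tmp_path, results225):
    fig = metab_figure(results225, "nh225")
    with pytest.raises(ValueError, match="tiff"):
        write_figure(fig, tmp_path / "f.tiff")


def test_png_pixel_dimensions_double_with_dpi(tmp_path):
    panel, _, _ = _panel([["a", "b"]], [_res("a"), _res("b")])
    fig = compose_figure([(panel, (0, 0, panel.width, panel.height))])
    from PIL import Image

    write_figure(fig, tmp_path / "lo.png", dpi=72)
    write_figure(fig, tmp_path / "hi.png", dpi=144)
    lo = Image.open(tmp_path / "lo.png").size
    hi = Image.open(tmp_path / "hi.png").size
    assert hi == (2 * lo[0], 2 * lo[1])


def test_pdf_export_writes_a_pdf(tmp_path):
    panel, _, _ = _panel([["a"]], [_res("a")])
    fig = compose_figure([(panel, (0, 0, panel.width, panel.height))])
    out = write_figure(fig, tmp_path / "f.pdf")
    assert out.read_bytes()[:5] == b"%PDF-"
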