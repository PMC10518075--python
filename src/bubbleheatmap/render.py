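"""Vector rendering: bubble-grid panels, brackets, legends, figure composition.

Panels are lists of drawing primitives (circles, text, polylines, rects) in an
abstract unit coordinate frame with a top-left origin and y growing downward.
Figures are composed by *translating* panels into layout regions — never
rescaling them anisotropically — then serialized:

* SVG through a native writer with a deterministic dialect: no timestamps or
  generated ids, floats formatted at 3 decimals, primitives emitted in
  insertion order. Identical inputs give byte-identical files, which makes
  golden-file regression tests meaningful.
* PDF/PNG by replaying the same primitives onto a matplotlib canvas.

The one-step :func:`metab_figure` is exactly the four-step pipeline
(align → scales → panels/legends → compose) and is tested to be
byte-equivalent to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .align import AlignedGridData, AssociationResult, align_results
from .catalog import FigureLayout, Placement, VariableCatalog, load_template
from .scales import ScalePair, legend_ticks, map_color, map_radius

# ---------------------------------------------------------------------------
# Primitives

FMT = "%.3f"  # fixed float formatting for the deterministic SVG dialect


@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    r: float
    fill: str


@dataclass(frozen=True)
class Text:
    x: float
    y: float
    s: str
    size: float = 0.38
    anchor: str = "middle"  # start | middle | end
    rotation: float = 0.0   # degrees, about (x, y)
    bold: bool = False


@dataclass(frozen=True)
class Polyline:
    points: tuple[tuple[float, float], ...]
    stroke: str = "#000000"
    width: float = 0.04


@dataclass(frozen=True)
class Rect:
    x: float
    y: float
    w: float
    h: float
    fill: str = "none"
    stroke: str = "none"
    stroke_width: float = 0.04


Primitive = Circle | Text | Polyline | Rect


@dataclass(frozen=True)
class GridGeometry:
    """Where the cell lattice sits inside a panel, for brackets to target."""

    origin: tuple[float, float]  # top-left of cell (0, 0)
    pitch: float
    nrows: int
    ncols: int

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (j + 0.5) * self.pitch, y0 + (i + 0.5) * self.pitch)


@dataclass
class Panel:
    primitives: list[Primitive] = field(default_factory=list)
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)  # x0,y0,x1,y1
    geometry: GridGeometry | None = None

    @property
    def width(self) -> float:
        return self.bbox[2] - self.bbox[0]

    @property
    def height(self) -> float:
        return self.bbox[3] - self.bbox[1]

    def translated(self, dx: float, dy: float) -> "Panel":
        prims = [_translate(p, dx, dy) for p in self.primitives]
        x0, y0, x1, y1 = self.bbox
        geom = None
        if self.geometry:
            ox, oy = self.geometry.origin
            geom = replace(self.geometry, origin=(ox + dx, oy + dy))
        return Panel(prims, (x0 + dx, y0 + dy, x1 + dx, y1 + dy), geom)


@dataclass
class Figure:
    primitives: list[Primitive]
    size: tuple[float, float]  # (width, height) in abstract units


def _translate(p: Primitive, dx: float, dy: float) -> Primitive:
    if isinstance(p, Circle):
        return replace(p, cx=p.cx + dx, cy=p.cy + dy)
    if isinstance(p, Text):
        return replace(p, x=p.x + dx, y=p.y + dy)
    if isinstance(p, Polyline):
        return replace(p, points=tuple((x + dx, y + dy) for x, y in p.points))
    return replace(p, x=p.x + dx, y=p.y + dy)


# ---------------------------------------------------------------------------
# Style


@dataclass(frozen=True)
class StyleOptions:
    """Presentation knobs shared by all panels of a figure.

    All lengths are in abstract canvas units (one cell pitch = ``pitch``
    units). ``pitch`` must be at least twice the size scale's maximum radius
    so bubbles never overlap neighboring cells.
    """

    pitch: float = 1.0
    font_size: float = 0.34
    title_size: float = 0.42
    label_rotation: float = 60.0  # column labels, degrees counterclockwise
    max_label_chars: int = 22     # longer labels are ellipsized
    margins: float = 0.4
    title: str = ""
    footnote: str = ""
    missing_dot: bool = False     # draw a small gray dot in masked cells
    unit_px: float = 22.0         # SVG export: pixels per abstract unit
    background: str = "#ffffff"


CHAR_W = 0.58  # crude text-width estimate, em per character


def _ellipsize(s: str, limit: int) -> str:
    return s if len(s) <= limit else s[: max(1, limit - 1)] + "…"


def _text_w(s: str, size: float) -> float:
    return CHAR_W * size * len(s)


# ---------------------------------------------------------------------------
# Panels


def render_bubble_grid(data: AlignedGridData, scales: ScalePair,
                       style: StyleOptions = StyleOptions()) -> Panel:
    """Render one aligned grid as a bubble panel.

    One filled circle per unmasked cell, centered on the cell, radius from the
    size scale and fill from the color scale; row labels on the left, column
    labels (rotated) on top. Output is a pure function of the inputs.
    """
    nr, nc = data.grid.shape
    if nr == 0 or nc == 0:
        raise ValueError(f"grid {data.grid.name!r} has zero size {nr}x{nc}")
    if style.pitch < 2 * scales.size.rmax:
        raise ValueError("cell pitch must be >= twice the maximum bubble "
                         f"radius (pitch={style.pitch}, rmax={scales.size.rmax})")
    p = style.pitch
    row_texts = [_ellipsize(s, style.max_label_chars) for s in data.grid.row_labels]
    col_texts = [_ellipsize(s, style.max_label_chars) for s in data.grid.col_labels]
    gut_left = max((_text_w(s, style.font_size) for s in row_texts), default=0) + 0.25
    rot = math.radians(style.label_rotation)
    col_len = max((_text_w(s, style.font_size) for s in col_texts), default=0)
    gut_top = col_len * abs(math.sin(rot)) + 0.35
    if style.title:
        gut_top += style.title_size * 1.6

    x0, y0 = gut_left, gut_top  # top-left of the cell lattice
    prims: list[Primitive] = []
    if style.title:
        prims.append(Text(x0 + nc * p / 2, style.title_size, style.title,
                          size=style.title_size, anchor="middle", bold=True))
    for j, s in enumerate(col_texts):
        cx = x0 + (j + 0.5) * p
        prims.append(Text(cx, y0 - 0.18, s, size=style.font_size,
                          anchor="start" if style.label_rotation else "middle",
                          rotation=style.label_rotation))
    for i, s in enumerate(row_texts):
        cy = y0 + (i + 0.5) * p
        prims.append(Text(x0 - 0.22, cy + style.font_size * 0.35, s,
                          size=style.font_size, anchor="end"))
    geom = GridGeometry(origin=(x0, y0), pitch=p, nrows=nr, ncols=nc)
    for i in range(nr):
        for j in range(nc):
            cx, cy = geom.cell_center(i, j)
            if data.mask[i, j]:
                if style.missing_dot and data.grid.cells[i][j] is not None:
                    prims.append(Circle(cx, cy, 0.05, "#999999"))
                continue
            r = map_radius(scales.size, float(data.size_values[i, j]))
            fill = map_color(scales.color, float(data.color_values[i, j]))
            prims.append(Circle(cx, cy, r, fill))
    bbox = (0.0, 0.0, x0 + nc * p + style.margins, y0 + nr * p + style.margins)
    return Panel(prims, bbox, geom)


@dataclass(frozen=True)
class BracketSpec:
    """A labeled bracket spanning a row- or column-range of a grid panel.

    ``axis='cols'`` with ``side`` top/bottom, or ``axis='rows'`` with side
    left/right; ``start``/``stop`` are inclusive 0-based indices.
    """

    axis: str            # 'rows' | 'cols'
    start: int
    stop: int
    label: str
    side: str = "top"    # top | bottom | left | right

    def __post_init__(self):
        if self.axis not in ("rows", "cols"):
            raise ValueError(f"axis must be 'rows' or 'cols', got {self.axis!r}")
        if self.side not in ("top", "bottom", "left", "right"):
            raise ValueError(f"bad side {self.side!r}")


def add_bracket(panel: Panel, spec: BracketSpec,
                style: StyleOptions = StyleOptions()) -> Panel:
    """Return a new panel with a bracket polyline + centered label added
    outside the data region; the original primitives are untouched."""
    geom = panel.geometry
    if geom is None:
        raise ValueError("panel has no grid geometry; brackets target grids")
    n = geom.ncols if spec.axis == "cols" else geom.nrows
    if not (0 <= spec.start <= spec.stop < n):
        raise ValueError(f"bracket range {spec.start}..{spec.stop} outside "
                         f"0..{n - 1} for axis {spec.axis!r}")
    x0, y0 = geom.origin
    p = geom.pitch
    tick = 0.18
    off = 0.25
    bx0, by0, bx1, by1 = panel.bbox
    if spec.axis == "cols":
        xa = x0 + spec.start * p + 0.08
        xb = x0 + (spec.stop + 1) * p - 0.08
        if spec.side == "top":
            yb = by0 + 0.1 + tick  # bar y; ticks point down toward the grid
            pts = ((xa, yb + tick), (xa, yb), (xb, yb), (xb, yb + tick))
            label_xy = ((xa + xb) / 2, yb - 0.12)
            new_bbox = (bx0, by0 - style.font_size * 1.6 - tick, bx1, by1)
        else:
            yb = by1 - 0.1 - tick
            pts = ((xa, yb - tick), (xa, yb), (xb, yb), (xb, yb - tick))
            label_xy = ((xa + xb) / 2, yb + style.font_size * 1.2)
            new_bbox = (bx0, by0, bx1, by1 + style.font_size * 1.6 + tick)
        label = Text(*label_xy, spec.label, size=style.font_size, anchor="middle")
    else:
        ya = y0 + spec.start * p + 0.08
        yb_ = y0 + (spec.stop + 1) * p - 0.08
        if spec.side == "left":
            xb = bx0 + 0.1 + tick
            pts = ((xb + tick, ya), (xb, ya), (xb, yb_), (xb + tick, yb_))
            label = Text(xb - 0.12, (ya + yb_) / 2, spec.label,
                         size=style.font_size, anchor="middle", rotation=90.0)
            new_bbox = (bx0 - style.font_size * 1.6 - tick, by0, bx1, by1)
        else:
            xb = bx1 - 0.1 - tick
            pts = ((xb - tick, ya), (xb, ya), (xb, yb_), (xb - tick, yb_))
            label = Text(xb + 0.12 + style.font_size, (ya + yb_) / 2, spec.label,
                         size=style.font_size, anchor="middle", rotation=-90.0)
            new_bbox = (bx0, by0, bx1 + style.font_size * 1.6 + tick, by1)
    prims = list(panel.primitives) + [Polyline(pts, width=0.05), label]
    return Panel(prims, new_bbox, geom)


def render_legends(scales: ScalePair,
                   style: StyleOptions = StyleOptions()) -> Panel:
    """Color-ramp swatches with tick labels plus a row of reference bubbles.

    Reference bubbles sit at :func:`legend_ticks` of the size scale, each
    labeled with its -log10 p value; when capping is active the cap tick is
    annotated "(capped)". With no explicit cap the bubbles span the observed
    score range instead.
    """
    prims: list[Primitive] = []
    fs = style.font_size
    # --- color ramp: discrete swatches
    cticks = legend_ticks(scales.color, 5)
    n_sw = 48
    sw_w, sw_h = 6.0 / n_sw, 0.5
    y = fs * 1.8
    prims.append(Text(0.0, y - fs * 0.8, "Estimate", size=fs, anchor="start",
                      bold=True))
    vmin, vmax = scales.color.vmin, scales.color.vmax
    for k in range(n_sw):
        v = vmin + (k + 0.5) / n_sw * (vmax - vmin)
        prims.append(Rect(k * sw_w, y, sw_w * 1.02, sw_h,
                          fill=map_color(scales.color, v)))
    for t in cticks:
        tx = (t - vmin) / (vmax - vmin) * (n_sw * sw_w)
        prims.append(Polyline(((tx, y + sw_h), (tx, y + sw_h + 0.12))))
        prims.append(Text(tx, y + sw_h + 0.12 + fs, _fmt_tick(t), size=fs))
    # --- size key: reference bubbles
    y2 = y + sw_h + fs * 2.2 + 0.55
    prims.append(Text(0.0, y2 - 0.1, "-log10 P", size=fs, anchor="start",
                      bold=True))
    sticks = legend_ticks(scales.size, 4)
    rmax = scales.size.rmax
    x = 0.2
    yc = y2 + rmax + 0.25
    for t in sticks:
        x += rmax + 0.35
        r = map_radius(scales.size, t)
        prims.append(Circle(x, yc, r, map_color(scales.color, vmax * 0.6)))
        lab = _fmt_tick(t)
        if scales.capped and t == sticks[-1]:
            lab += " (capped)"
        prims.append(Text(x, yc + rmax + fs * 1.3, lab, size=fs))
        x += rmax + _text_w(lab, fs) / 2
    w = max(n_sw * sw_w, x) + style.margins
    h = yc + rmax + fs * 2.0 + style.margins
    return Panel(prims, (0.0, 0.0, w, h), None)


def _fmt_tick(t: float) -> str:
    if t == int(t):
        return str(int(t))
    return (FMT % t).rstrip("0").rstrip(".")


# ---------------------------------------------------------------------------
# Composition


def compose_figure(placed_panels: list[tuple[Panel, tuple[float, float, float, float] | Placement]],
                   layout: FigureLayout | None = None,
                   footnote: str = "",
                   style: StyleOptions = StyleOptions()) -> Figure:
    """Compose panels onto one canvas.

    Each entry pairs a panel with its region ``(x, y, w, h)`` (or a layout
    :class:`~bubbleheatmap.catalog.Placement`); the panel is translated so its
    bounding-box origin lands on the region origin. Overlapping regions are an
    error naming the colliding pair; regions must stay on the canvas.
    """
    if not placed_panels:
        raise ValueError("no panels to compose")
    regions = []
    for k, (_, reg) in enumerate(placed_panels):
        r = reg.region if isinstance(reg, Placement) else tuple(reg)
        regions.append(r)
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            if _region_overlap(regions[a], regions[b]):
                raise ValueError(f"panel placements overlap: region {a} "
                                 f"{regions[a]} and region {b} {regions[b]}")
    if layout is not None:
        W, H = layout.canvas_size
    else:
        W = max(r[0] + r[2] for r in regions) + style.margins
        H = max(r[1] + r[3] for r in regions) + style.margins
    prims: list[Primitive] = []
    for (panel, _), r in zip(placed_panels, regions):
        if r[0] < -1e-9 or r[1] < -1e-9 or r[0] + r[2] > W + 1e-9 \
                or r[1] + r[3] > H + 1e-9:
            raise ValueError(f"placement {r} leaves the {W}x{H} canvas")
        moved = panel.translated(r[0] - panel.bbox[0], r[1] - panel.bbox[1])
        prims.extend(moved.primitives)
    if footnote:
        prims.append(Text(0.3, H - 0.25, footnote, size=style.font_size,
                          anchor="start"))
    return Figure(prims, (W, H))


def _region_overlap(r1, r2) -> bool:
    x1, y1, w1, h1 = r1
    x2, y2, w2, h2 = r2
    return (x1 < x2 + w2 and x2 < x1 + w1 and y1 < y2 + h2 and y2 < y1 + h1)


FOOTNOTE_TEXT = "*Ratios are to total fatty acids except where specified"


def metab_figure(results: list[AssociationResult], template: str | VariableCatalog,
                 *, keyspace: str = "nh_name", keymap=None,
                 cap: float | None = None, vmax: float | None = None,
                 style: StyleOptions = StyleOptions(),
                 scale_options: dict | None = None,
                 return_report: bool = False):
    """One-step NH metabolomics figure.

    Equivalent to, and byte-identical with, the explicit pipeline::

        cat = load_template(template)
        aligned, report = align_results(cat, results, keyspace)
        scales = make_scales(...)
        panels = [render_bubble_grid(a, scales, ...) for a in aligned]
        fig = compose_figure([... placements ...] + legend, cat.layout)

    With ``return_report=True`` returns ``(figure, UnmatchedReport)``.
    """
    from .scales import make_scales  # local to keep module import cheap

    cat = template if isinstance(template, VariableCatalog) else load_template(template)
    aligned, report = align_results(cat, results, keyspace, keymap=keymap)
    opts = dict(scale_options or {})
    if cap is not None:
        opts["cap"] = cap
    if vmax is not None:
        opts["vmax"] = vmax
    ests = [r.estimate for r in results]
    scos = [r.score() for r in results if r.score() is not None]
    scales = make_scales(ests, scos, **opts)

    by_name = {a.grid.name: a for a in aligned}
    placed: list[tuple[Panel, Placement]] = []
    for pl in cat.layout.placements:
        a = by_name[pl.grid_name]
        pstyle = replace(style, title=pl.title or a.grid.name)
        placed.append((render_bubble_grid(a, scales, pstyle), pl))
    if cat.layout.legend_region is not None:
        placed.append((render_legends(scales, style),
                       Placement("__legend__", cat.layout.legend_region)))
    footnote = style.footnote
    if not footnote and any(v.footnote for v in cat.variables):
        footnote = FOOTNOTE_TEXT
    fig = compose_figure(placed, cat.layout, footnote=footnote, style=style)
    if return_report:
        return fig, report
    return fig


# ---------------------------------------------------------------------------
# Serialization


def _f(v: float) -> str:
    s = FMT % v
    return "0.000" if s == "-0.000" else s


def to_svg(fig: Figure, style: StyleOptions = StyleOptions()) -> str:
    """Serialize a figure to the deterministic SVG dialect (a pure function
    of the figure: fixed float formatting, no ids, no timestamps)."""
    u = style.unit_px
    W, H = fig.size
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(W * u)}" height="{_f(H * u)}" '
        f'viewBox="0 0 {_f(W * u)} {_f(H * u)}">',
        f'<rect x="0" y="0" width="{_f(W * u)}" height="{_f(H * u)}" '
        f'fill="{style.background}"/>',
    ]
    for p in fig.primitives:
        if isinstance(p, Circle):
            out.append(f'<circle cx="{_f(p.cx * u)}" cy="{_f(p.cy * u)}" '
                       f'r="{_f(p.r * u)}" fill="{p.fill}"/>')
        elif isinstance(p, Rect):
            attrs = (f'x="{_f(p.x * u)}" y="{_f(p.y * u)}" '
                     f'width="{_f(p.w * u)}" height="{_f(p.h * u)}" '
                     f'fill="{p.fill}"')
            if p.stroke != "none":
                attrs += f' stroke="{p.stroke}" stroke-width="{_f(p.stroke_width * u)}"'
            out.append(f"<rect {attrs}/>")
        elif isinstance(p, Polyline):
            pts = " ".join(f"{_f(x * u)},{_f(y * u)}" for x, y in p.points)
            out.append(f'<polyline points="{pts}" fill="none" '
                       f'stroke="{p.stroke}" stroke-width="{_f(p.width * u)}"/>')
        elif isinstance(p, Text):
            attrs = (f'x="{_f(p.x * u)}" y="{_f(p.y * u)}" '
                     f'font-family="Helvetica,Arial,sans-serif" '
                     f'font-size="{_f(p.size * u)}" text-anchor="{p.anchor}"')
            if p.bold:
                attrs += ' font-weight="bold"'
            if p.rotation:
                attrs += (f' transform="rotate({_f(-p.rotation)} '
                          f'{_f(p.x * u)} {_f(p.y * u)})"')
            out.append(f"<text {attrs}>{_escape(p.s)}</text>")
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _escape(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))


def _draw_mpl(fig: Figure, style: StyleOptions):
    """Replay primitives on a matplotlib canvas (for PDF/PNG export)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import patches, transforms

    W, H = fig.size
    inches_per_unit = style.unit_px / 96.0
    # snap to whole points so pixel dimensions scale exactly with dpi
    fw = round(W * inches_per_unit * 72.0) / 72.0
    fh = round(H * inches_per_unit * 72.0) / 72.0
    mfig = plt.figure(figsize=(fw, fh))
    ax = mfig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, W)
    ax.set_ylim(H, 0)  # y grows downward, like the SVG frame
    ax.axis("off")
    ax.add_patch(patches.Rectangle((0, 0), W, H, facecolor=style.background,
                                   edgecolor="none"))
    anchor_ha = {"start": "left", "middle": "center", "end": "right"}
    for p in fig.primitives:
        if isinstance(p, Circle):
            ax.add_patch(patches.Circle((p.cx, p.cy), p.r, facecolor=p.fill,
                                        edgecolor="none"))
        elif isinstance(p, Rect):
            ax.add_patch(patches.Rectangle(
                (p.x, p.y), p.w, p.h, facecolor=p.fill,
                edgecolor=None if p.stroke == "none" else p.stroke))
        elif isinstance(p, Polyline):
            xs, ys = zip(*p.points)
            ax.plot(xs, ys, color=p.stroke, linewidth=p.width * style.unit_px,
                    solid_capstyle="butt")
        elif isinstance(p, Text):
            ax.text(p.x, p.y, p.s, fontsize=p.size * style.unit_px * 0.75,
                    ha=anchor_ha[p.anchor], va="baseline",
                    rotation=p.rotation, rotation_mode="anchor",
                    fontweight="bold" if p.bold else "normal")
    return mfig


def write_figure(fig: Figure, path, format: str | None = None,
                 dpi: int = 96, style: StyleOptions = StyleOptions()):
    """Write a figure as SVG, PDF, or PNG.

    SVG bytes are deterministic; PNG pixel dimensions scale with ``dpi``.
    Returns the output path.
    """
    from pathlib import Path as _P

    path = _P(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "svg":
        path.write_text(to_svg(fig, style), encoding="utf-8")
    elif fmt in ("pdf", "png"):
        mfig = _draw_mpl(fig, style)
        try:
            mfig.savefig(path, format=fmt, dpi=dpi)
        finally:
            import matplotlib.pyplot as plt
            plt.close(mfig)
    else:
        raise ValueError(f"unknown output format {fmt!r}; use svg, pdf or png")
    return path
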