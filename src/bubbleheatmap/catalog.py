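"""Variable catalogs: packaged Nightingale Health (NH) templates and user-defined grids.

A catalog describes *where every variable lives* in a composed figure: the set
of variable entries, the rectangular grids they occupy (with display row and
column labels), the figure layout (panel placements on an abstract canvas) and
the keyspaces used to translate external identifiers (e.g. biobank field IDs)
into canonical variable ids.

Packaged templates
------------------
``nh251``
    The current 251-biomarker NH panel: a 14-subclass x 12-measure lipoprotein
    main block (168 cells) plus 83 further measures in 9 smaller grids.
``nh249``
    The 249-variable variant, represented as the nh251 layout with the two
    optional-flagged variables removed; their cells render empty.
``nh225``
    The legacy 225-variable panel: the same 168-cell main block plus 57
    further measures in 9 grids.

The partition of non-subclass variables into the smaller grids, and the
synthetic ``ukb_field`` keyspace, are illustrative authored data (see
``docs/methods.md``); structural invariants (counts, shapes, uniqueness) are
the contract, biochemical naming is not.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

logger = logging.getLogger("bubbleheatmap")

PACKAGED_TEMPLATES = ("nh251", "nh249", "nh225")

#: grid name of the lipoprotein-subclass main block in the packaged templates
MAIN_BLOCK = "Lipoprotein Subclasses"

IDENTITY_KEYSPACE = "nh_name"


class CatalogError(Exception):
    """Base class for catalog loading/validation failures."""


class TemplateNotFoundError(CatalogError, KeyError):
    """Unknown packaged template name and no such file on disk."""


class CatalogValidationError(CatalogError, ValueError):
    """A user catalog violates structural invariants; carries the report."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__(str(report))


class KeyspaceError(CatalogError, KeyError):
    """Unknown keyspace; message names the available ones."""


@dataclass(frozen=True)
class VariableEntry:
    """One catalog variable: canonical id, display label, block membership."""

    variable_id: str
    display_name: str
    group: str
    footnote: bool = False
    optional: bool = False


@dataclass
class TemplateGrid:
    """One rectangular panel: ordered labels plus a row-major cell matrix.

    ``cells[i][j]`` holds the variable id occupying row *i*, column *j*, or
    ``None`` for an empty cell (empty cells are legal: the 249-variable data
    render into the 251 layout with two blanks).
    """

    name: str
    row_labels: list[str]
    col_labels: list[str]
    cells: list[list[str | None]]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_labels), len(self.col_labels))

    @property
    def n_cells(self) -> int:
        return len(self.row_labels) * len(self.col_labels)

    def filled_ids(self) -> list[str]:
        return [v for r in self.cells for v in r if v is not None]

    def iter_cells(self):
        """Yield ``(i, j, variable_id_or_None)`` in row-major order."""
        for i, r in enumerate(self.cells):
            for j, v in enumerate(r):
                yield i, j, v


@dataclass(frozen=True)
class Placement:
    grid_name: str
    region: tuple[float, float, float, float]  # (x, y, w, h), y grows downward
    title: str = ""


@dataclass
class FigureLayout:
    """Panel placements on an abstract unit canvas (top-left origin)."""

    canvas_size: tuple[float, float]
    placements: list[Placement]
    legend_region: tuple[float, float, float, float] | None = None


@dataclass
class VariableCatalog:
    name: str
    variables: list[VariableEntry]
    grids: list[TemplateGrid]
    layout: FigureLayout
    keyspaces: dict[str, dict[str, str]] = field(default_factory=dict)
    main_block: str | None = None

    def __post_init__(self):
        if IDENTITY_KEYSPACE not in self.keyspaces:
            self.keyspaces[IDENTITY_KEYSPACE] = {
                v.variable_id: v.variable_id for v in self.variables
            }

    @property
    def variable_ids(self) -> list[str]:
        return [v.variable_id for v in self.variables]

    def grid(self, name: str) -> TemplateGrid:
        for g in self.grids:
            if g.name == name:
                return g
        raise KeyError(name)

    @property
    def n_variables(self) -> int:
        return len(self.variables)


@dataclass(frozen=True)
class Violation:
    code: str
    message: str
    ids: tuple[str, ...] = ()


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, code: str, message: str, ids=()):
        self.violations.append(Violation(code, message, tuple(ids)))

    def __str__(self) -> str:
        if self.ok:
            return "catalog valid"
        return "\n".join(f"[{v.code}] {v.message}" for v in self.violations)


# ---------------------------------------------------------------------------
# Loading


def _data_path(filename: str):
    return resources.files("bubbleheatmap").joinpath("data", filename)


def _read_variable_rows(fh) -> list[dict]:
    reader = csv.DictReader(fh)
    required = {"variable_id", "group", "grid_name", "row_label", "col_label"}
    missing = required - set(reader.fieldnames or ())
    if missing:
        raise CatalogValidationError(
            _report_of("missing-columns",
                       f"catalog file lacks columns: {sorted(missing)}")
        )
    return list(reader)


def _report_of(code, message, ids=()):
    rep = ValidationReport()
    rep.add(code, message, ids)
    return rep


def _truthy(s) -> bool:
    return str(s or "").strip().lower() in {"1", "true", "yes", "y"}


def _build_catalog(name: str, rows: list[dict], layout_doc: dict,
                   drop_optional: bool) -> VariableCatalog:
    # optional-flagged variables leave the entry list but keep their grid
    # cells (blanked), so legacy data render into the full layout with gaps
    dropped: set[str] = set()
    if drop_optional:
        dropped = {r["variable_id"] for r in rows if _truthy(r.get("optional_flag"))}
    variables = [
        VariableEntry(
            variable_id=r["variable_id"],
            display_name=r.get("display_name") or r["variable_id"],
            group=r["group"],
            footnote=_truthy(r.get("footnote_flag")),
            optional=_truthy(r.get("optional_flag")),
        )
        for r in rows
        if r["variable_id"] not in dropped
    ]

    # grid skeletons: label order = first appearance in the file
    grid_rows: dict[str, list[str]] = {}
    grid_cols: dict[str, list[str]] = {}
    for r in rows:
        g = r["grid_name"]
        grid_rows.setdefault(g, [])
        grid_cols.setdefault(g, [])
        if r["row_label"] not in grid_rows[g]:
            grid_rows[g].append(r["row_label"])
        if r["col_label"] not in grid_cols[g]:
            grid_cols[g].append(r["col_label"])

    grids = []
    for g in grid_rows:
        nr, nc = len(grid_rows[g]), len(grid_cols[g])
        cells: list[list[str | None]] = [[None] * nc for _ in range(nr)]
        grids.append(TemplateGrid(g, grid_rows[g], grid_cols[g], cells))
    by_name = {g.name: g for g in grids}
    for r in rows:
        if r["variable_id"] in dropped:
            continue
        g = by_name[r["grid_name"]]
        i = g.row_labels.index(r["row_label"])
        j = g.col_labels.index(r["col_label"])
        if g.cells[i][j] is not None:
            raise CatalogValidationError(_report_of(
                "cell-collision",
                f"grid {g.name!r} cell ({r['row_label']!r}, {r['col_label']!r}) "
                f"assigned to both {g.cells[i][j]!r} and {r['variable_id']!r}",
                (g.cells[i][j], r["variable_id"]),
            ))
        g.cells[i][j] = r["variable_id"]

    placements = [
        Placement(p["grid"], tuple(p["region"]), p.get("title", ""))
        for p in layout_doc.get("placements", [])
    ]
    layout = FigureLayout(
        canvas_size=tuple(layout_doc.get("canvas_size", (40.0, 40.0))),
        placements=placements,
        legend_region=(tuple(layout_doc["legend_region"])
                       if layout_doc.get("legend_region") else None),
    )
    return VariableCatalog(
        name=name,
        variables=variables,
        grids=grids,
        layout=layout,
        main_block=layout_doc.get("main_block"),
    )


def _default_layout(grids: list[TemplateGrid]) -> dict:
    """Stack grids vertically: the fallback for user catalogs with no layout."""
    placements = []
    y = 1.0
    width = max(g.shape[1] for g in grids) + 8.0
    for g in grids:
        h = g.shape[0] + 4.0
        placements.append({"grid": g.name,
                           "region": [0.0, y, width, h],
                           "title": g.name})
        y += h + 1.0
    return {"canvas_size": [width + 2.0, y + 8.0],
            "legend_region": [0.0, y, width, 7.0],
            "placements": placements}


def _load_ukb_keyspace(catalog: VariableCatalog) -> None:
    """Attach the packaged synthetic ukb_field keyspace (illustrative ids only)."""
    with _data_path("ukb_field_synthetic.csv").open(encoding="utf-8") as fh:
        mapping = dict(load_keymap(fh))
    known = set(catalog.variable_ids)
    catalog.keyspaces["ukb_field"] = {
        k: v for k, v in mapping.items() if v in known
    }


def load_keymap(source) -> dict[str, str]:
    """Read a two-column merge-key CSV ``(external_id, variable_id)``.

    Header row is required; extra columns are ignored.
    """
    close = False
    if isinstance(source, (str, Path)):
        source = open(source, newline="", encoding="utf-8")
        close = True
    try:
        reader = csv.reader(source)
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise CatalogValidationError(_report_of(
                "keymap-format", "merge-key file needs a header and 2 columns"))
        return {row[0]: row[1] for row in reader if len(row) >= 2 and row[0]}
    finally:
        if close:
            source.close()


def load_catalog(variables_csv, layout_json=None, name: str | None = None,
                 drop_optional: bool = False) -> VariableCatalog:
    """Load a catalog from a variables CSV plus an optional layout JSON.

    If ``layout_json`` is omitted, a file named ``*_layout.json`` next to the
    CSV is used when present, else a simple stacked layout is synthesized.
    The loaded catalog is validated; violations raise
    :class:`CatalogValidationError`.
    """
    variables_csv = Path(variables_csv)
    with open(variables_csv, newline="", encoding="utf-8") as fh:
        rows = _read_variable_rows(fh)
    if not rows:
        raise CatalogValidationError(_report_of("empty", "catalog has no variables"))
    if layout_json is None:
        guess = variables_csv.with_name(
            variables_csv.stem.replace("_variables", "") + "_layout.json")
        layout_json = guess if guess.exists() else None
    if layout_json is not None:
        layout_doc = json.loads(Path(layout_json).read_text(encoding="utf-8"))
    else:
        layout_doc = None
    cat = _build_catalog(name or variables_csv.stem, rows,
                         layout_doc or {}, drop_optional)
    if layout_doc is None:
        doc = _default_layout(cat.grids)
        cat.layout = FigureLayout(
            canvas_size=tuple(doc["canvas_size"]),
            placements=[Placement(p["grid"], tuple(p["region"]), p["title"])
                        for p in doc["placements"]],
            legend_region=tuple(doc["legend_region"]),
        )
    report = validate_catalog(cat)
    if not report.ok:
        raise CatalogValidationError(report)
    return cat


def load_template(name: str) -> VariableCatalog:
    """Load a packaged NH template (``nh251``/``nh249``/``nh225``) or a user
    catalog given as a path to its variables CSV.

    Loading is side-effect-free and repeatable; each call returns a fresh
    catalog object.
    """
    if name in PACKAGED_TEMPLATES:
        base = "nh251" if name == "nh249" else name
        with _data_path(f"{base}_variables.csv").open(encoding="utf-8") as fh:
            rows = _read_variable_rows(fh)
        layout_doc = json.loads(
            _data_path(f"{base}_layout.json").read_text(encoding="utf-8"))
        cat = _build_catalog(name, rows, layout_doc,
                             drop_optional=(name == "nh249"))
        _load_ukb_keyspace(cat)
        report = validate_catalog(cat)
        if not report.ok:  # pragma: no cover - packaged data is validated in tests
            raise CatalogValidationError(report)
        return cat
    if Path(name).exists():
        return load_catalog(name)
    raise TemplateNotFoundError(
        f"unknown template {name!r}; packaged templates: "
        f"{', '.join(PACKAGED_TEMPLATES)} (or pass a catalog CSV path)")


# ---------------------------------------------------------------------------
# Validation


def validate_catalog(cat: VariableCatalog) -> ValidationReport:
    """Check every structural invariant; returns a report, never raises.

    Checked: unique variable ids and grid names; matrix dimensions consistent
    with labels; every variable placed in exactly one cell; every cell id
    known; non-empty groups; layout placements reference existing grids, stay
    on canvas and do not overlap; packaged-template counts (251/249/225
    variables, 10 grids, 14x12 main block).
    """
    rep = ValidationReport()
    ids = [v.variable_id for v in cat.variables]
    seen: set[str] = set()
    dups = {i for i in ids if i in seen or seen.add(i)}
    if dups:
        rep.add("duplicate-variable", f"duplicate variable ids: {sorted(dups)}",
                sorted(dups))
    for v in cat.variables:
        if not v.group:
            rep.add("empty-group", f"variable {v.variable_id!r} has empty group",
                    (v.variable_id,))

    gnames = [g.name for g in cat.grids]
    if len(set(gnames)) != len(gnames):
        dupg = sorted({n for n in gnames if gnames.count(n) > 1})
        rep.add("duplicate-grid", f"duplicate grid names: {dupg}", dupg)

    placed: dict[str, list[str]] = {}
    for g in cat.grids:
        nr, nc = g.shape
        if len(g.cells) != nr or any(len(r) != nc for r in g.cells):
            rep.add("dimension-mismatch",
                    f"grid {g.name!r}: cells matrix is "
                    f"{len(g.cells)}x{len(g.cells[0]) if g.cells else 0} but labels "
                    f"imply {nr}x{nc}", (g.name,))
            continue
        for _, _, vid in g.iter_cells():
            if vid is not None:
                placed.setdefault(vid, []).append(g.name)

    known = set(ids)
    for vid, where in placed.items():
        if len(where) > 1:
            rep.add("multiple-placement",
                    f"variable {vid!r} placed in {len(where)} grids: {where}",
                    (vid,))
        if vid not in known:
            rep.add("unknown-cell-id",
                    f"cell references unknown variable {vid!r}", (vid,))
    unplaced = sorted(known - set(placed))
    if unplaced:
        rep.add("unplaced-variable",
                f"variables not placed in any grid: {unplaced}", unplaced)

    # layout checks
    known_grids = set(gnames)
    regions = []
    W, H = cat.layout.canvas_size
    for p in cat.layout.placements:
        if p.grid_name not in known_grids:
            rep.add("layout-unknown-grid",
                    f"layout places unknown grid {p.grid_name!r}", (p.grid_name,))
            continue
        x, y, w, h = p.region
        if x < 0 or y < 0 or x + w > W + 1e-9 or y + h > H + 1e-9:
            rep.add("layout-off-canvas",
                    f"placement of {p.grid_name!r} leaves the canvas", (p.grid_name,))
        regions.append((p.grid_name, p.region))
    for a in range(len(regions)):
        for b in range(a + 1, len(regions)):
            if _overlaps(regions[a][1], regions[b][1]):
                rep.add("layout-overlap",
                        f"placements overlap: {regions[a][0]!r} and {regions[b][0]!r}",
                        (regions[a][0], regions[b][0]))

    if cat.name in PACKAGED_TEMPLATES:
        expected = int(cat.name[2:])
        if len(cat.variables) != expected:
            rep.add("count", f"{cat.name} must have {expected} variables, "
                    f"found {len(cat.variables)}")
        if len(cat.grids) != 10:
            rep.add("grid-count", f"{cat.name} must define 10 grids, "
                    f"found {len(cat.grids)}")
        if cat.main_block:
            mb = next((g for g in cat.grids if g.name == cat.main_block), None)
            if mb is None or mb.shape != (14, 12):
                rep.add("main-block",
                        f"main block must be 14x12, found "
                        f"{mb.shape if mb else 'missing'}")
    return rep


def _overlaps(r1, r2) -> bool:
    x1, y1, w1, h1 = r1
    x2, y2, w2, h2 = r2
    return (x1 < x2 + w2 and x2 < x1 + w1 and y1 < y2 + h2 and y2 < y1 + h1)


# ---------------------------------------------------------------------------
# Identifier resolution


def resolve_ids(cat: VariableCatalog, ids, keyspace: str = IDENTITY_KEYSPACE,
                keymap: dict[str, str] | None = None):
    """Translate external ids to canonical variable ids.

    Returns ``(resolved, unresolved)`` where ``resolved`` maps each input id
    to at most one variable id and ``unresolved`` lists, in input order, every
    id that could not be translated (or translates to a variable absent from
    the catalog). The two outputs partition the input exactly; nothing is
    dropped silently.

    A user-supplied ``keymap`` (e.g. from :func:`load_keymap`) overrides the
    catalog keyspace of the same name.
    """
    if keymap is not None:
        mapping = keymap
    else:
        try:
            mapping = cat.keyspaces[keyspace]
        except KeyError:
            raise KeyspaceError(
                f"unknown keyspace {keyspace!r}; available: "
                f"{sorted(cat.keyspaces)}") from None
    known = set(cat.variable_ids)
    resolved: dict[str, str] = {}
    unresolved: list[str] = []
    for ext in ids:
        vid = mapping.get(ext)
        if vid is None or vid not in known:
            unresolved.append(ext)
        else:
            resolved[ext] = vid
    return resolved, unresolved
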