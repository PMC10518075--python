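"""Read association-results tables and populate template grids.

One row per metabolite: an identifier, a signed effect estimate, optionally a
standard error, and a p-value and/or -log10 p. Alignment places each matched
result in its catalog cell and reports — never silently drops — every
unmatched input and every unfilled template variable, since partial/legacy
result sets are an expected use (e.g. 249-variable data in the 251 layout).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import TemplateGrid, VariableCatalog, resolve_ids
from .scales import neglog10

logger = logging.getLogger("bubbleheatmap")

#: default results-file column names (what the fixture generator writes)
DEFAULT_COLUMN_MAP = {
    "id": "id",
    "estimate": "estimate",
    "se": "se",
    "p": "p",
    "neglogp": "neglogp",
}

#: tolerated |neglog10(p) - neglogp| before a consistency warning
NEGLOGP_WARN_TOL = 0.01


class SchemaError(ValueError):
    """Results file lacks a mandatory column."""


class DuplicateInputError(ValueError):
    """Two result rows map to the same catalog variable."""

    def __init__(self, ids):
        self.ids = list(ids)
        super().__init__(
            f"duplicate result rows for variable(s): {sorted(self.ids)}")


@dataclass(frozen=True)
class AssociationResult:
    """One metabolite's association statistics.

    At least one of ``p`` / ``neglogp`` should be present; when both are, the
    supplied ``neglogp`` wins at alignment time (it may encode p-values below
    the smallest representable float) and a discrepancy beyond
    ``NEGLOGP_WARN_TOL`` logs a warning.
    """

    external_id: str
    estimate: float
    se: float | None = None
    p: float | None = None
    neglogp: float | None = None

    def score(self) -> float | None:
        """The -log10 p value to size the bubble by, uncapped."""
        if self.neglogp is not None and not math.isnan(self.neglogp):
            return self.neglogp
        if self.p is not None and not math.isnan(self.p):
            return neglog10(self.p)
        return None


@dataclass
class AlignedGridData:
    """A template grid populated with per-cell (color, size) values.

    Matrices share the grid's shape; ``mask`` is True where no bubble should
    be drawn (no result matched, or its values were missing/unparseable).
    """

    grid: TemplateGrid
    color_values: np.ndarray
    size_values: np.ndarray
    mask: np.ndarray

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())


@dataclass
class UnmatchedReport:
    """Reconciliation of one alignment: what matched, what did not."""

    n_matched: int = 0
    unmatched_inputs: list[str] = field(default_factory=list)
    unfilled_template: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_matched": self.n_matched,
            "unmatched_inputs": list(self.unmatched_inputs),
            "unfilled_template": list(self.unfilled_template),
        }


def read_results(path, column_map: dict | None = None,
                 delimiter: str | None = None) -> list[AssociationResult]:
    """Read a CSV/TSV results table into :class:`AssociationResult` records.

    ``column_map`` maps the logical names ``id``/``estimate``/``se``/``p``/
    ``neglogp`` to the file's column names; unmapped optional columns are
    skipped. The delimiter is sniffed from the extension (``.tsv`` → tab)
    unless given explicitly. Rows whose numeric fields fail to parse are kept
    with those fields missing, and a warning is logged — they are never
    dropped silently.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update({k: v for k, v in column_map.items() if v is not None})
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str)

    missing = [cmap[k] for k in ("id", "estimate") if cmap[k] not in df.columns]
    have_p = cmap["p"] in df.columns
    have_nlp = cmap["neglogp"] in df.columns
    if not (have_p or have_nlp):
        missing.append(f"{cmap['p']} (or {cmap['neglogp']})")
    if missing:
        raise SchemaError(f"results file {path} lacks mandatory column(s): "
                          f"{missing}; available: {list(df.columns)}")

    numeric_cols = {k: cmap[k] for k in ("estimate", "se", "p", "neglogp")
                    if cmap[k] in df.columns}
    parsed = {}
    for key, col in numeric_cols.items():
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() & df[col].notna() & (df[col].str.strip() != "")
        nastr = df[col].str.upper().isin(["NA", "NAN", "NULL", ""])
        truly_bad = bad & ~nastr
        if truly_bad.any():
            logger.warning("%d unparseable value(s) in column %r treated as "
                           "missing (rows %s)", truly_bad.sum(), col,
                           list(df.index[truly_bad][:5]))
        parsed[key] = num

    out = []
    for i, ext in enumerate(df[cmap["id"]].astype(str)):
        out.append(AssociationResult(
            external_id=ext,
            estimate=_get_num(parsed, "estimate", i),
            se=_get_num(parsed, "se", i),
            p=_get_num(parsed, "p", i),
            neglogp=_get_num(parsed, "neglogp", i),
        ))
    return out


def _get_num(parsed, key, i):
    if key not in parsed:
        return None
    v = parsed[key].iloc[i]
    return None if pd.isna(v) else float(v)


def align_results(cat: VariableCatalog, results: list[AssociationResult],
                  keyspace: str = "nh_name",
                  keymap: dict[str, str] | None = None,
                  ) -> tuple[list[AlignedGridData], UnmatchedReport]:
    """Place results into the catalog's grids.

    Returns one :class:`AlignedGridData` per catalog grid (in catalog order)
    and an :class:`UnmatchedReport`. Conservation laws hold exactly:
    ``n_matched + len(unmatched_inputs) == len(results)`` and
    ``n_matched + len(unfilled_template) == catalog size``. Two input rows
    resolving to the same variable raise :class:`DuplicateInputError`.

    Size values are stored *uncapped*; capping belongs to the scales so one
    aligned dataset can render under different caps.
    """
    if not results:
        raise ValueError("no association results supplied")
    for r in results:
        if r.p is not None and r.neglogp is not None and not math.isnan(r.p):
            if abs(neglog10(r.p) - r.neglogp) > NEGLOGP_WARN_TOL:
                logger.warning("p and neglogp disagree for %r: "
                               "-log10(p)=%.4f vs neglogp=%.4f",
                               r.external_id, neglog10(r.p), r.neglogp)

    resolved, unresolved = resolve_ids(
        cat, [r.external_id for r in results], keyspace, keymap=keymap)
    by_var: dict[str, AssociationResult] = {}
    dups = []
    for r in results:
        vid = resolved.get(r.external_id)
        if vid is None:
            continue
        if vid in by_var:
            dups.append(vid)
        by_var[vid] = r
    if dups:
        raise DuplicateInputError(dups)

    aligned = []
    filled = set()
    for g in cat.grids:
        nr, nc = g.shape
        color = np.full((nr, nc), np.nan)
        size = np.full((nr, nc), np.nan)
        mask = np.ones((nr, nc), dtype=bool)
        for i, j, vid in g.iter_cells():
            if vid is None or vid not in by_var:
                continue
            r = by_var[vid]
            filled.add(vid)
            est, sco = r.estimate, r.score()
            if est is None or sco is None or math.isnan(est):
                continue  # recorded as matched but stays masked
            color[i, j] = est
            size[i, j] = sco
            mask[i, j] = False
        aligned.append(AlignedGridData(g, color, size, mask))

    matched = set(by_var)
    report = UnmatchedReport(
        n_matched=len(matched),
        unmatched_inputs=list(unresolved),
        unfilled_template=[v for v in cat.variable_ids if v not in matched],
    )
    if report.unmatched_inputs or report.unfilled_template:
        logger.warning("alignment against %s: %d matched, %d unmatched inputs, "
                       "%d unfilled template variables", cat.name,
                       report.n_matched, len(report.unmatched_inputs),
                       len(report.unfilled_template))
    return aligned, report


def matched_table(aligned: list[AlignedGridData]) -> pd.DataFrame:
    """Export matched cells as a flat table (id, estimate, neglogp).

    Re-aligning this table against the same catalog reproduces the aligned
    data exactly (idempotence).
    """
    rows = []
    for ag in aligned:
        for i, j, vid in ag.grid.iter_cells():
            if vid is not None and not ag.mask[i, j]:
                rows.append({"id": vid,
                             "estimate": ag.color_values[i, j],
                             "neglogp": ag.size_values[i, j]})
    return pd.DataFrame(rows, columns=["id", "estimate", "neglogp"])
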