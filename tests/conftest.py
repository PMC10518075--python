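import csv
from pathlib import Path

import pytest

from bubbleheatmap.catalog import (FigureLayout, Placement, TemplateGrid,
                                   VariableCatalog, VariableEntry,
                                   load_template)
from bubbleheatmap.fixtures import generate_results


@pytest.fixture(scope="session")
def nh251():
    return load_template("nh251")


@pytest.fixture(scope="session")
def nh249():
    return load_template("nh249")


@pytest.fixture(scope="session")
def nh225():
    return load_template("nh225")


@pytest.fixture(scope="session")
def results225():
    return generate_results("nh225", seed=1)


def build_catalog(grids: dict[str, list[list[str | None]]],
                  name: str = "toy") -> VariableCatalog:
    """Construct a small in-memory catalog from {grid_name: cell matrix}."""
    tgrids, variables, placements = [], [], []
    y = 0.0
    for gname, cells in grids.items():
        nr, nc = len(cells), len(cells[0])
        tgrids.append(TemplateGrid(
            gname,
            [f"r{i}" for i in range(nr)],
            [f"c{j}" for j in range(nc)],
            [list(row) for row in cells],
        ))
        for row in cells:
            for v in row:
                if v is not None:
                    variables.append(VariableEntry(v, v, "toy"))
        h = nr + 4.0
        placements.append(Placement(gname, (0.0, y, nc + 8.0, h), gname))
        y += h + 1.0
    layout = FigureLayout((max(g.shape[1] for g in tgrids) + 10.0, y + 2.0),
                          placements)
    return VariableCatalog(name, variables, tgrids, layout)


def write_catalog_csv(path: Path, rows: list[dict]) -> Path:
    """Write a user-catalog variables CSV from row dicts."""
    fields = ["variable_id", "display_name", "group", "grid_name",
              "row_label", "col_label", "footnote_flag", "optional_flag"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        for r in rows:
            w.writerow({**{k: "" for k in fields}, **r})
    return path
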