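"""Seeded synthetic association results shaped like the CETP genetic-score
demo data: one signed estimate + p-value per template variable.

The generator emulates the qualitative structure of associations between a
genetic score raising HDL cholesterol and the NH metabolomics panel: VLDL
measures trend negative and HDL measures positive, with a smooth gradient
across the 14 lipoprotein-subclass rows ordered from the largest VLDL to the
smallest HDL particles. Non-subclass blocks get per-group base effects.
Magnitudes are arbitrary defaults (the source analyses are not reproduced);
only the shape and sign structure matter for testing and demonstration.

p-values are the two-sided normal tail of ``estimate / se``, so the four
reported fields (estimate, se, p, -log10 p) are internally consistent.
Randomness uses numpy's ``default_rng`` (PCG64), so one seed gives identical
tables on every platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AssociationResult
from .catalog import VariableCatalog, load_template

#: |z| beyond which p-values would underflow; keeps generated p in (0, 1]
_Z_LIMIT = 36.0

DEFAULT_GROUP_EFFECTS = {
    "Lipoprotein Lipids": 0.15,
    "Cholesterol": 0.25,
    "Lipoprotein Size": 0.30,
    "Apolipoproteins": 0.20,
    "Fatty Acids": -0.10,
    "Other Lipids": 0.10,
    "Glycolysis": -0.05,
    "Ketones": 0.04,
    "Fluid Balance": 0.02,
    "Inflammation": -0.08,
    "Amino Acids": 0.03,
}


@dataclass(frozen=True)
class EffectProfile:
    """Parameters of the synthetic effect structure.

    ``subclass_gradient`` is the per-row step of the main-block estimate: row
    *i* of the 14 subclass rows gets base effect ``gradient * (i - 6.5)``,
    i.e. about -0.52 for the largest VLDL and +0.52 for the smallest HDL at
    the default 0.08 — opposite signs at the two ends, smooth in between.
    ``significance_scale`` divides the standard error, steering how extreme
    the p-values get.
    """

    group_effects: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    subclass_gradient: float = 0.08
    noise_sd: float = 0.05
    se: float = 0.05
    significance_scale: float = 1.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.se <= 0 or self.significance_scale <= 0:
            raise ValueError("se and significance_scale must be > 0")


def generate_results(template: str | VariableCatalog, seed: int,
                     profile: EffectProfile | None = None,
                     ) -> list[AssociationResult]:
    """Generate exactly one synthetic record per catalog variable.

    Reproducible per seed; covering every template variable, so aligning the
    output against its own template leaves nothing unmatched or unfilled.
    """
    profile = profile or EffectProfile()
    cat = template if isinstance(template, VariableCatalog) else load_template(template)
    rng = np.random.default_rng(seed)
    se = profile.se / profile.significance_scale

    main = cat.main_block
    row_of: dict[str, int] = {}
    if main is not None:
        g = cat.grid(main)
        for i, _, vid in g.iter_cells():
            if vid is not None:
                row_of[vid] = i
    group_of = {v.variable_id: v.group for v in cat.variables}

    out = []
    for v in cat.variables:
        vid = v.variable_id
        if vid in row_of:
            base = profile.subclass_gradient * (row_of[vid] - 6.5)
        else:
            base = profile.group_effects.get(group_of[vid], 0.0)
        est = base + (rng.normal(0.0, profile.noise_sd)
                      if profile.noise_sd > 0 else 0.0)
        z = min(abs(est) / se, _Z_LIMIT)
        p = 2.0 * _norm_sf(z)
        out.append(AssociationResult(
            external_id=vid, estimate=float(est), se=float(se),
            p=float(p), neglogp=float(-math.log10(p)),
        ))
    return out


def _norm_sf(z: float) -> float:
    """Standard-normal upper tail via erfc (stable far into the tail)."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def write_fixture(results: list[AssociationResult], path):
    """Write results as a CSV in the default input schema.

    Floats are formatted with 17 significant digits, so the table round-trips
    through :func:`bubbleheatmap.align.read_results` losslessly.
    """
    df = pd.DataFrame([{
        "id": r.external_id,
        "estimate": r.estimate,
        "se": r.se,
        "p": r.p,
        "neglogp": r.neglogp,
    } for r in results], columns=["id", "estimate", "se", "p", "neglogp"])
    df.to_csv(path, index=False, float_format="%.17g")
    return path
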