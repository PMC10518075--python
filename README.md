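# bubbleheatmap

Bubble-heatmap figures for high-dimensional association results, built for
the Nightingale Health (NH) ¹H-NMR metabolomics panels.

## The problem

Analyses against NH metabolomics profiles produce one signed effect estimate
and one p-value for each of 251 (current) or 225/249 (legacy) blood
biomarkers. Roughly 75% of those variables are 12 lipid measures repeated
across 14 lipoprotein subclasses, and the scientific signal often lives in
how associations change *across* subclasses (rows) and *within* each subclass
(columns). Forest plots cannot show all of this in one figure; a bubble
heatmap can. Each cell of a rectangular grid is drawn as a circle:

* **fill color** encodes the signed effect estimate β on a symmetric
  diverging scale (blue–white–red, 0 at the midpoint, range ±max|β| by
  default);
* **size** encodes significance as −log₁₀ p, optionally capped (e.g. at 35,
  i.e. p = 10⁻³⁵) so a few extreme associations do not flatten the rest.
  By default the circle *area* is linear in the capped score.

The package ships variable-catalog templates that lay the full 251/249/225
NH profiles out as 10 grids composed into a single figure, aligns a flat
results table onto them (via canonical NH names or user-supplied merge
keys), and renders deterministic SVG (plus PDF/PNG). User-defined catalogs
get the same treatment, so any variables × analyses grid — e.g. genetic
variants × clinical outcomes — can be drawn the same way.

## Worked example

Generate the seeded synthetic demo fixture (emulating associations of an
HDL-cholesterol-raising genetic score with the 225-variable legacy panel),
then render the composed figure:

```python
import bubbleheatmap as bh

results = bh.generate_results("nh225", seed=1)   # 225 records
print(results[0])
# AssociationResult(external_id='XXL_VLDL_P', estimate=-0.5027207903967608,
#                   se=0.05, p=8.784086712540562e-24, neglogp=23.056303385713655)

fig, report = bh.metab_figure(results, "nh225", return_report=True)
print(report.n_matched, len(report.unmatched_inputs), len(report.unfilled_template))
# 225 0 0
bh.write_figure(fig, "fig.svg")
```

The first record says: the largest-VLDL particle concentration falls by
0.503 units per score unit, 10 standard errors from zero (p ≈ 8.8 × 10⁻²⁴,
−log₁₀ p ≈ 23.1) — the generator's built-in VLDL-negative/HDL-positive
gradient. The figure contains one bubble per matched variable, ten titled
panels (the 14 × 12 lipoprotein main block plus nine smaller grids), a color
ramp and reference-bubble legend, and the fatty-acid ratio footnote.

The same run from the shell:

```sh
bubbleheatmap generate --template nh225 --seed 1 --out fixture.csv
bubbleheatmap metabfigure --in fixture.csv --template nh225 \
    --out fig.svg --report report.json
# wrote fig.svg (225 matched, 0 unmatched, 0 unfilled)
```

Aligning a 249-variable table against the 251-variable layout exits 0 and
reports exactly 2 unfilled template cells — partial/legacy inputs are
warnings, never failures. `bubbleheatmap render --catalog my_variables.csv`
draws user-defined grids; `--cap 25` caps the significance scale at
p = 10⁻²⁵; `bubbleheatmap validate` checks any catalog file.

## Layout of the package

| module | role |
|---|---|
| `bubbleheatmap.catalog` | packaged/user variable catalogs, validation, merge-key resolution |
| `bubbleheatmap.scales` | diverging color scale, cappable size scale, legend ticks |
| `bubbleheatmap.align` | results-table reading and template alignment with full reconciliation |
| `bubbleheatmap.render` | panels, brackets, legends, composition, SVG/PDF/PNG export |
| `bubbleheatmap.fixtures` | seeded synthetic demo-data generator |
| `bubbleheatmap.cli` / `config` | `bubbleheatmap` console script, YAML config |

See `docs/methods.md` for the encoding model, defaults, and limitations.
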