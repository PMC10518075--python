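# Methods

## The encoding model

A bubble heatmap displays two numbers per cell of a categorical 2-D grid:

* **Color** — the signed effect estimate β, mapped through a diverging ramp
  that is symmetric about zero: the scale domain is [−vmax, +vmax] with
  vmax = max|β| over non-missing values unless overridden, so β = 0 always
  lands on the ramp midpoint and a given hue means the same magnitude in
  either direction. Values beyond the domain are clamped, not errors: one
  outlier must not break a figure. The default palette is matplotlib's
  `RdBu_r` (a colorblind-safe blue–white–red ramp); the palette is
  configuration, not contract — tests assert ramp *positions*
  (pos(v) + pos(−v) = 1), never specific hues.
* **Size** — significance as s = −log₁₀ p, saturated at a configurable cap
  c (`cap_score(s, c) = min(s, c)`). The radius map is, by default,
  **area-linear**: r(s) = √(rmin² + (rmax² − rmin²)·min(s, c)/c), so
  perceived ink is proportional to the capped score; a radius-linear
  variant is available (`size.transform: radius`). r(0) = rmin > 0 keeps
  p = 1 cells visible; r(s ≥ c) = rmax. With no cap configured, the
  observed score maximum becomes the effective cap for that figure and the
  legend omits the "(capped)" annotation. p = 0 maps to a hard score
  ceiling of 300 — finite, yet far beyond any cap anyone would set
  (published NH figures use caps of 35 and 25).

Both scales are built once per figure and shared by every panel, so bubbles
are comparable across grids.

## Catalogs and alignment

A catalog is data, not code: a CSV of variables (id, display name, group,
grid, row/column label, footnote and optional flags) plus a JSON layout
(placements of named grids on an abstract-unit canvas). The packaged NH
templates encode the 14-subclass × 12-measure lipoprotein main block
(168 cells — about 75% of the 225-variable panel) plus the remaining
variables in nine smaller grids, ten grids per template. The subclass and
measure nomenclature follows NH's public documentation; the partition of
non-subclass variables into the nine smaller grids, and the specific pair
of variables distinguishing the 251- from the 249-variable panel, are
illustrative authored choices — structural invariants (counts, shapes,
uniqueness, placement) are the tested contract, biochemical naming is not.
`nh249` is the `nh251` catalog with its two optional-flagged variables
removed from the entry list but their cells kept (blank), so 249-variable
results render into the full 251 layout with two gaps.

Alignment is deliberately lenient: unmatched inputs and unfilled template
variables are warnings plus a machine-readable report (the two lists
partition the inputs and the catalog exactly), because partial and legacy
result sets are a normal use. Only two rows resolving to the *same*
variable are a hard error — silently keeping one would misrepresent the
input. When a table supplies both p and −log₁₀ p, the latter wins (it can
encode p-values below float underflow); a discrepancy > 0.01 logs a
warning. Size values are stored uncapped so one aligned dataset can render
under different caps.

Merge keys: the `nh_name` identity keyspace always exists; a two-column CSV
(`external_id,variable_id`) can supply any other mapping. The packaged
`ukb_field` keyspace is a synthetic illustrative mapping (the file is named
`ukb_field_synthetic.csv`): nothing is ever downloaded at build or test
time.

## Rendering and determinism

Panels are lists of geometric primitives (circles, text, polylines, rects)
in an abstract unit frame, composed onto the canvas by pure translation —
so a panel looks identical wherever it is placed. SVG is written natively
in a deterministic dialect: fixed 3-decimal float formatting, no ids, no
timestamps, primitives in insertion order. Figure bytes are therefore a
pure function of (catalog, results, options), which is what makes the
one-step/four-step equivalence and golden-file regression tests exact
(byte equality, not approximate comparison). PDF/PNG export replays the
same primitives onto a matplotlib canvas; the figure size is snapped to
whole points so PNG pixel dimensions scale exactly with dpi. Text widths
are estimated as 0.58 em per character (labels are ellipsized beyond a
configurable length rather than shrinking the cell pitch); the estimate
affects gutter sizes only, never data geometry. Cell pitch must be at
least 2·rmax, so bubbles can never invade neighboring cells. Masked
(missing) cells draw nothing by default; `style.missing_dot` draws a small
gray dot instead.

## The synthetic demo generator

`generate_results` emulates the *shape* of the packaged demo data — one
signed estimate, standard error, p and −log₁₀ p per template variable, as
produced by regressing NH measures on an HDL-cholesterol-raising genetic
score — without reproducing any published numbers. Main-block variables in
subclass row i (of 14, ordered largest VLDL → smallest HDL) get base
effect g·(i − 6.5) with g = 0.08: about −0.52 at the VLDL end, +0.52 at
the HDL end, opposite signs with a smooth gradient between. Non-subclass
blocks get fixed per-group base effects (±0.02…0.30). Gaussian noise
(sd 0.05) is added; se = 0.05/significance_scale; p is the two-sided
normal tail of estimate/se computed via `erfc` (|z| limited to 36 so p
stays in (0, 1]), and −log₁₀ p is derived from that same p, making the
four fields exactly consistent. Randomness uses NumPy's `default_rng`
(PCG64), so a seed fixes the table across platforms. These magnitudes are
arbitrary defaults chosen once for a realistic-looking figure (|z| up to
~12, −log₁₀ p up to ~33).

What passing tests show — and do not. The generator covers every template
variable with clean numerics, so tests exercise alignment, scaling,
rendering and reporting exactly. Real result files additionally bring
messy ids, missing values, and effect/SE distributions the generator does
not model; the reading/alignment layer handles those paths (tested with
hand-built tables), but no claim is made that the synthetic effect sizes
resemble any real analysis.

## Numerical and design choices

* Problem sizes: tests and the acceptance script run the full 225/249/251
  templates — figure assembly is milliseconds, so nothing needed scaling
  down; property tests sample up to 10⁴ scores and a few dozen random
  grids.
* Legend ticks: linspace endpoints kept exact, interior ticks rounded to a
  tidy multiple of the step's leading digit, falling back to exact spacing
  if rounding breaks strict monotonicity; degenerate domains yield a
  single tick.
* Exit codes: 0 success (warnings included), 1 validation/configuration,
  2 I/O. Warnings never change the exit code.
* Config files are YAML validated by a pydantic model (the equivalent JSON
  Schema ships in `data/config.schema.json`); CLI flags override config
  values.

## Known limitations

* Text metrics are estimated, not measured; extreme fonts could make
  gutters tight (data geometry is unaffected).
* The SVG determinism guarantee covers bytes this package writes; PDF/PNG
  go through matplotlib and are not byte-stable across matplotlib
  versions.
* No interactive/HTML output, no font embedding, no perceptual-uniformity
  optimization of palettes.
* The packaged layout's panel aspect ratios and margins are this package's
  own; goldens are self-referential regression anchors.
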