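"""Per-figure encodings: diverging color scale for signed effects, cappable
size scale for -log10 p-values.

The color scale is symmetric about zero (vmin = -vmax) so that the palette
midpoint always means "no effect"; the size scale saturates at a configurable
cap so a handful of extreme p-values cannot flatten the rest of the figure
(published NH figures cap at 1e-35 or 1e-25 depending on the analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib import colors as mcolors
from matplotlib import pyplot as plt

#: -log10 p returned for p == 0: finite, beyond any plausible cap
NEGLOG10_CEILING = 300.0

DEFAULT_PALETTE = "RdBu_r"  # colorblind-safe blue-white-red diverging ramp
DEFAULT_NA_COLOR = "#bfbfbf"


def neglog10(p: float, ceiling: float = NEGLOG10_CEILING) -> float:
    """-log10 of a p-value; ``p == 0`` returns the finite ``ceiling``."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value must lie in [0, 1], got {p!r}")
    if p == 0.0:
        return ceiling
    return min(-math.log10(p), ceiling)


def cap_score(s: float, cap: float | None) -> float:
    """Saturate a -log10 p score at ``cap`` (identity when cap is None)."""
    if s < 0:
        raise ValueError(f"score must be nonnegative, got {s!r}")
    if cap is None:
        return s
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap!r}")
    return min(s, cap)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class ColorScale:
    """Symmetric diverging map from signed effect to color.

    ``vmax`` is the magnitude at which the ramp saturates; values are clamped
    into [-vmax, vmax] rather than erroring, so a single outlier cannot break
    a figure. Value 0 maps to the ramp midpoint.
    """

    vmax: float
    palette: str = DEFAULT_PALETTE
    na_color: str = DEFAULT_NA_COLOR

    def __post_init__(self):
        if not (self.vmax > 0):
            raise ValueError(f"vmax must be positive, got {self.vmax!r}")

    @property
    def vmin(self) -> float:
        return -self.vmax

    def position(self, v: float) -> float:
        """Clamped position of *v* on the unit ramp; 0.5 at v = 0."""
        t = (v + self.vmax) / (2.0 * self.vmax)
        return min(1.0, max(0.0, t))


@dataclass(frozen=True)
class SizeScale:
    """Monotone map from (capped) -log10 p to bubble radius.

    ``transform='area'`` makes circle *area* linear in the capped score (the
    default: perceived ink scales with significance); ``'radius'`` makes the
    radius itself linear. A score of 0 still draws at ``rmin`` so p = 1 cells
    remain visible.
    """

    cap: float | None
    rmin: float = 0.08
    rmax: float = 0.42
    transform: str = "area"

    def __post_init__(self):
        if not (0 < self.rmin < self.rmax):
            raise ValueError("require 0 < rmin < rmax, got "
                             f"rmin={self.rmin!r} rmax={self.rmax!r}")
        if self.transform not in ("area", "radius"):
            raise ValueError(f"transform must be 'area' or 'radius', "
                             f"got {self.transform!r}")
        if self.cap is not None and self.cap <= 0:
            raise ValueError(f"cap must be positive or None, got {self.cap!r}")

    @property
    def domain_max(self) -> float:
        if self.cap is None:
            raise ValueError("size scale has no cap and no observed maximum; "
                             "resolve with with_effective_cap() before use")
        return self.cap

    def with_effective_cap(self, observed_max: float) -> "SizeScale":
        """For uncapped scales: use the observed score maximum for this figure."""
        if self.cap is not None:
            return self
        eff = observed_max if observed_max > 0 else 1.0
        return SizeScale(cap=eff, rmin=self.rmin, rmax=self.rmax,
                         transform=self.transform)


@dataclass(frozen=True)
class ScalePair:
    color: ColorScale
    size: SizeScale
    capped: bool = True  #: False when size.cap fell back to the observed max


def make_scales(estimates, scores, *, vmax: float | None = None,
                cap: float | None = None, palette: str = DEFAULT_PALETTE,
                rmin: float = 0.08, rmax: float = 0.42,
                transform: str = "area",
                na_color: str = DEFAULT_NA_COLOR) -> ScalePair:
    """Build the shared color/size scales for one figure.

    The color range defaults to +/- max|estimate| over non-missing values;
    the size cap defaults to None, in which case the observed score maximum
    becomes the effective cap (and legends omit the "capped" annotation).
    """
    est = np.asarray([e for e in estimates if not _is_missing(e)], dtype=float)
    sco = np.asarray([s for s in scores if not _is_missing(s)], dtype=float)
    est = est[np.isfinite(est)]
    sco = sco[np.isfinite(sco)]
    if vmax is None:
        if est.size == 0:
            raise ValueError("all estimates missing: pass an explicit vmax")
        vmax = float(np.max(np.abs(est)))
        if vmax == 0.0:
            vmax = 1.0
    color = ColorScale(vmax=vmax, palette=palette, na_color=na_color)
    size = SizeScale(cap=cap, rmin=rmin, rmax=rmax, transform=transform)
    capped = cap is not None
    if cap is None:
        if sco.size == 0:
            raise ValueError("all scores missing: pass an explicit cap")
        size = size.with_effective_cap(float(np.max(sco)))
    return ScalePair(color=color, size=size, capped=capped)


def map_color(scale: ColorScale, v) -> str:
    """Hex color for a signed value; missing values get the NA color."""
    if _is_missing(v):
        return scale.na_color
    cmap = plt.get_cmap(scale.palette)
    return mcolors.to_hex(cmap(scale.position(float(v))))


def map_radius(scale: SizeScale, s: float) -> float:
    """Bubble radius for a -log10 p score (applied after capping).

    Area-linear: ``r(s) = sqrt(rmin^2 + (rmax^2 - rmin^2) * t)`` with
    ``t = min(s, cap)/cap``; radius-linear: ``r(s) = rmin + (rmax-rmin) * t``.
    Monotone non-decreasing, ``r(0) = rmin``, ``r(cap) = rmax``.
    """
    if s < 0:
        raise ValueError(f"score must be nonnegative, got {s!r}")
    cap = scale.domain_max
    t = min(s, cap) / cap
    if scale.transform == "area":
        return math.sqrt(scale.rmin ** 2 + (scale.rmax ** 2 - scale.rmin ** 2) * t)
    return scale.rmin + (scale.rmax - scale.rmin) * t


def legend_ticks(scale, n: int = 4) -> list[float]:
    """Round, strictly increasing tick values spanning the scale domain,
    endpoints included; a degenerate domain yields a single tick."""
    if n < 2:
        raise ValueError("need at least 2 ticks")
    if isinstance(scale, SizeScale):
        lo, hi = 0.0, scale.domain_max
    else:
        lo, hi = scale.vmin, scale.vmax
    if hi == lo:
        return [lo]
    raw = np.linspace(lo, hi, n)
    step = (hi - lo) / (n - 1)
    # round interior ticks to a tidy multiple of the step's leading digit
    mag = 10.0 ** math.floor(math.log10(step))
    ticks = [lo] + [round(round(t / mag) * mag, 10) for t in raw[1:-1]] + [hi]
    if all(a < b for a, b in zip(ticks, ticks[1:])):
        return [float(t) for t in ticks]
    return [float(t) for t in raw]  # fall back to exact spacing
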