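"""Calibration, inverse prediction, detection limit and risk classification.

Replicate strip measurements at known neutrophil-elastase (NE) concentrations
are reduced to per-concentration means and standard deviations, and an
unweighted least-squares quadratic

    r(c) = a2*c^2 + a1*c + a0

is fitted to the mean ratio. The ratio falls roughly linearly with
concentration over the working range (default 0-600 ng/ml) and plateaus above
it, so the curve is only inverted inside the working range; fits that are not
strictly decreasing there are rejected. Unknown samples are quantified by
solving the quadratic for c, with censoring instead of extrapolation: ratios
brighter than the blank end of the curve are reported as
``below_working_range`` and ratios darker than the saturated end as
``saturated``, each clamped to the nearest range endpoint.

The limit of detection is operationalised as the smallest grid concentration
whose noise-free ratio separates from the blank by more than ``k`` replicate
standard deviations (default k=2, sigma_r=0.07) — a concrete version of the
usual "error bars no longer overlap the blank" reading of assay sensitivity.

Clinically, sputum NE above 250 ng/ml flags a high risk of respiratory
exacerbation; that threshold (inclusive) drives the risk label. The coarser
visual bands (negative / low / high) follow the semi-quantitative groups a
reader of the bare strip would assign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .detect import StripMeasurement
from .errors import CalibrationError

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "QuantResult",
    "replicate_stats",
    "fit_calibration",
    "estimate_concentration",
    "lod_estimate",
    "classify_risk",
    "DEFAULT_WORKING_RANGE",
    "DEFAULT_HIGH_RISK_THRESHOLD",
    "DEFAULT_BAND_BOUNDS",
    "DEFAULT_LOD_GRID",
]

DEFAULT_WORKING_RANGE = (0.0, 600.0)  # ng/ml; ratio ~linear in c up to 600
DEFAULT_HIGH_RISK_THRESHOLD = 250.0  # ng/ml, inclusive
#: Midpoints of the gaps between the visual concentration groups
#: (negative up to 87, low 131-296, high 444+): invented interpolation.
DEFAULT_BAND_BOUNDS = (109.0, 370.0)
DEFAULT_LOD_GRID = (0.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0)


@dataclass(frozen=True)
class CalibrationPoint:
    """Replicate summary at one known concentration."""

    concentration: float  # ng/ml
    mean_ratio: float
    sd_ratio: float
    n_replicates: int


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted quadratic concentration -> ratio map with its working range."""

    coeffs: tuple[float, float, float]  # (a2, a1, a0)
    working_lo: float
    working_hi: float
    residual_rmse: float
    ratio_kind: str

    def __call__(self, concentration: float) -> float:
        a2, a1, a0 = self.coeffs
        return a2 * concentration**2 + a1 * concentration + a0

    def is_monotone_decreasing(self) -> bool:
        """Strictly decreasing on the working range (derivative is linear,
        so checking both endpoints suffices)."""
        a2, a1, _ = self.coeffs
        d_lo = 2 * a2 * self.working_lo + a1
        d_hi = 2 * a2 * self.working_hi + a1
        return d_lo < 0 and d_hi < 0


@dataclass(frozen=True)
class QuantResult:
    """Inverse prediction for one measured ratio."""

    estimated_concentration: float  # ng/ml
    censoring: str  # "none" | "below_working_range" | "saturated"
    risk_label: str  # "negative" | "low" | "high_risk"
    band_label: str  # "negative" | "low" | "high"


def replicate_stats(
    measurements: Sequence[StripMeasurement],
    concentrations: Sequence[float],
    ratio_kind: str = "ratio_tb",
) -> list[CalibrationPoint]:
    """Group measurements by concentration label; per-group mean and sample sd.

    The sd uses the n-1 denominator and is 0 for singleton groups. Points are
    returned sorted by concentration.
    """
    if len(measurements) != len(concentrations):
        raise ValueError("one concentration label per measurement is required")
    if len(measurements) == 0:
        raise ValueError("no measurements to summarise")
    groups: dict[float, list[float]] = {}
    for m, c in zip(measurements, concentrations):
        groups.setdefault(float(c), []).append(m.ratio(ratio_kind))
    points = []
    for c in sorted(groups):
        vals = np.asarray(groups[c])
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        points.append(
            CalibrationPoint(
                concentration=c,
                mean_ratio=float(vals.mean()),
                sd_ratio=sd,
                n_replicates=int(vals.size),
            )
        )
    return points


def fit_calibration(
    points: Sequence[CalibrationPoint],
    ratio_kind: str = "ratio_tb",
    working_range: tuple[float, float] = DEFAULT_WORKING_RANGE,
    weighted: bool = False,
    clip_range_to_vertex: bool = True,
) -> CalibrationCurve:
    """Least-squares quadratic of mean ratio on concentration.

    Only points whose concentration lies inside the working range enter the
    fit: the curve is never evaluated outside that range, and including the
    saturated tail would bias the inversion everywhere else. Unweighted by
    default (the curve is fitted to the group means); ``weighted=True``
    weights each point by ``sqrt(n)/sd``. Requires at least 3 distinct
    in-range concentrations.

    The curve must be strictly decreasing on the working range. A quadratic
    fitted through a saturating response typically turns upward just before
    the requested upper limit; with ``clip_range_to_vertex`` (default) the
    working range is truncated to 1 ng/ml below the parabola's vertex, which
    keeps the monotone-inversion invariant while preserving as much range as
    the fit supports. A fit that is not decreasing at ``working_lo`` (or whose
    truncated range collapses) is rejected as ``non_monotone_calibration``.
    """
    lo, hi = working_range
    if not hi > lo >= 0:
        raise CalibrationError(f"invalid working range [{lo}, {hi}]")
    in_range = [p for p in points if lo <= p.concentration <= hi]
    conc = np.asarray([p.concentration for p in in_range], dtype=float)
    ratio = np.asarray([p.mean_ratio for p in in_range], dtype=float)
    if len(np.unique(conc)) < 3:
        raise CalibrationError(
            "need >= 3 distinct concentrations inside the working range, "
            f"got {len(np.unique(conc))}"
        )
    if weighted:
        w = np.asarray(
            [math.sqrt(p.n_replicates) / max(p.sd_ratio, 1e-6) for p in in_range]
        )
        coeffs = np.polyfit(conc, ratio, 2, w=w)
    else:
        coeffs = np.polyfit(conc, ratio, 2)
    a2, a1 = float(coeffs[0]), float(coeffs[1])
    if 2 * a2 * lo + a1 >= 0:
        raise CalibrationError("non_monotone_calibration")
    if 2 * a2 * hi + a1 >= 0:  # parabola turns inside the requested range
        if not clip_range_to_vertex:
            raise CalibrationError("non_monotone_calibration")
        hi = -a1 / (2 * a2) - 1.0
        if hi <= lo:
            raise CalibrationError("non_monotone_calibration")
    resid = ratio - np.polyval(coeffs, conc)
    curve = CalibrationCurve(
        coeffs=(a2, a1, float(coeffs[2])),
        working_lo=float(lo),
        working_hi=float(hi),
        residual_rmse=float(np.sqrt(np.mean(resid**2))),
        ratio_kind=ratio_kind,
    )
    assert curve.is_monotone_decreasing()
    return curve


def estimate_concentration(curve: CalibrationCurve, ratio: float) -> QuantResult:
    """Invert the calibration curve for one measured ratio.

    Inside the working range the unique root of ``curve(c) = ratio`` is
    returned. Ratios brighter than the blank end are censored
    ``below_working_range`` (estimate clamped to ``working_lo``); ratios
    darker than the saturated end are censored ``saturated`` (clamped to
    ``working_hi``). Every input maps to a result; nothing is extrapolated.
    """
    if not curve.is_monotone_decreasing():
        raise CalibrationError("curve is not monotone on its working range")
    r_blank = curve(curve.working_lo)
    r_sat = curve(curve.working_hi)
    if ratio >= r_blank:
        c, censoring = curve.working_lo, "below_working_range"
    elif ratio <= r_sat:
        c, censoring = curve.working_hi, "saturated"
    else:
        a2, a1, a0 = curve.coeffs
        if a2 == 0:
            c = (ratio - a0) / a1
        else:
            roots = np.roots([a2, a1, a0 - ratio])
            real = roots[np.abs(roots.imag) < 1e-9].real
            tol = 1e-6 * max(1.0, curve.working_hi)
            inside = real[
                (real >= curve.working_lo - tol) & (real <= curve.working_hi + tol)
            ]
            if inside.size == 0:  # numerically impossible for a monotone curve
                raise CalibrationError("no root inside the working range")
            c = float(np.clip(inside[0], curve.working_lo, curve.working_hi))
        censoring = "none"
    risk_label, band_label = classify_risk(c)
    return QuantResult(
        estimated_concentration=float(c),
        censoring=censoring,
        risk_label=risk_label,
        band_label=band_label,
    )


def lod_estimate(
    ratio_fn: Callable[[float], float],
    sigma_r: float = 0.07,
    k: float = 2.0,
    grid: Sequence[float] = DEFAULT_LOD_GRID,
) -> float | None:
    """Detection limit: smallest grid concentration separated from the blank.

    ``ratio_fn`` maps concentration to a (noise-free) ratio — a fitted
    :class:`CalibrationCurve` works, as does a function that renders and
    analyses a noise-free phantom. Returns the smallest grid concentration c
    with ``ratio_fn(0) - ratio_fn(c) > k * sigma_r``, or ``None`` if no grid
    point separates ("not reached"). ``sigma_r`` is the assumed replicate sd
    of the ratio and ``k`` the separation multiplier.
    """
    if sigma_r <= 0:
        raise ValueError(f"sigma_r must be > 0, got {sigma_r}")
    grid = sorted(float(g) for g in grid)
    if 0.0 not in grid:
        raise ValueError("LOD grid must include the blank (0 ng/ml)")
    r_blank = ratio_fn(0.0)
    for c in grid:
        if c == 0.0:
            continue
        if r_blank - ratio_fn(c) > k * sigma_r:
            return c
    return None


def classify_risk(
    concentration: float,
    high_threshold: float = DEFAULT_HIGH_RISK_THRESHOLD,
    band_bounds: tuple[float, float] = DEFAULT_BAND_BOUNDS,
) -> tuple[str, str]:
    """Exacerbation-risk label and semi-quantitative visual band.

    ``risk_label`` is ``high_risk`` iff concentration >= ``high_threshold``
    (inclusive, default 250 ng/ml); below that it is ``negative`` under the
    first band boundary and ``low`` otherwise. ``band_label`` follows the
    visual bands: negative < ``band_bounds[0]`` <= low < ``band_bounds[1]``
    <= high.
    """
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    b_neg, b_high = band_bounds
    if concentration >= high_threshold:
        risk = "high_risk"
    elif concentration < b_neg:
        risk = "negative"
    else:
        risk = "low"
    if concentration < b_neg:
        band = "negative"
    elif concentration < b_high:
        band = "low"
    else:
        band = "high"
    return risk, band
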