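"""Line detection and ratio metrics on averaged intensity profiles.

The detection logic mirrors how a fixed-geometry strip reader locates its
bands. The control line must always develop on a valid strip, so it is found
first: the minimum of the averaged profile inside a configurable downstream
search band. The search is *restricted* rather than global because at high
analyte concentrations the test band becomes darker than the control band and
a global minimum scan would lock onto the wrong line; the strip sits in a
mechanically fixed position, so a search band is justified. The test line is
then found as the minimum inside a small window placed a known offset upstream
of the detected control line. The region strictly between the two lines
(minus an exclusion margin around each) estimates the unstained membrane
background.

Three normalised darkness metrics are reported:

    ratio_tb = test_value / background_mean     (test-background)
    ratio_cb = control_value / background_mean  (control-background)
    ratio_tc = ratio_tb / ratio_cb              (test-control)

Dividing by the background cancels common multiplicative factors (lighting,
exposure): scaling every pixel by a constant leaves all three ratios
unchanged. Visible lines give ratios below 1, decreasing with concentration;
ratio_tc crosses 1 where the test band is as dark as the control band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BackgroundTooSmallError,
    NoControlLineError,
    PipelineStageError,
    TestWindowError,
)
from .image import (
    IntensityProfile,
    RoiRect,
    StripImage,
    average_profile,
    crop_roi,
    smooth_profile,
    to_grayscale,
)

__all__ = [
    "DetectionConfig",
    "StripMeasurement",
    "detect_control",
    "detect_test",
    "background_stats",
    "compute_ratios",
    "analyze_strip",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the windowed line search.

    ``control_search_lo/hi`` bound the control-line search band as fractions
    of the profile length; ``expected_offset`` is how far upstream (smaller
    positions) the test-line center is expected relative to the control line;
    the test line is searched within ``+- test_window_halfwidth`` pixels of
    that point. ``line_exclusion_margin`` pixels around each detected line are
    excluded from the background region, which must retain at least
    ``min_background_px`` positions. ``smooth_window`` is the moving-average
    width applied to the profile before any detection (1 disables it).
    """

    control_search_lo: float = 0.55
    control_search_hi: float = 0.95
    expected_offset: int = 60
    test_window_halfwidth: int = 15
    line_exclusion_margin: int = 18
    min_background_px: int = 5
    smooth_window: int = 5
    flow_axis: str = "width"

    def __post_init__(self):
        if not 0 <= self.control_search_lo < self.control_search_hi <= 1:
            raise ValueError("need 0 <= control_search_lo < control_search_hi <= 1")
        if self.test_window_halfwidth < 1:
            raise ValueError("test_window_halfwidth must be >= 1")
        if self.line_exclusion_margin < 0:
            raise ValueError("line_exclusion_margin must be >= 0")


@dataclass(frozen=True)
class StripMeasurement:
    """Detected line positions/values, background statistics and the ratios."""

    control_pos: int
    control_value: float
    test_pos: int
    test_value: float
    background_mean: float
    background_sd: float
    ratio_tb: float
    ratio_cb: float
    ratio_tc: float
    flags: frozenset[str] = frozenset()
    audit: dict | None = field(default=None, compare=False)

    def ratio(self, kind: str) -> float:
        """Look up one of the three ratios by name ('ratio_tb', ...)."""
        if kind not in ("ratio_tb", "ratio_cb", "ratio_tc"):
            raise ValueError(f"unknown ratio kind {kind!r}")
        return getattr(self, kind)


def _index_of(p: IntensityProfile, position: int) -> int:
    return int(position - p.positions[0])


def detect_control(p: IntensityProfile, cfg: DetectionConfig) -> tuple[int, float]:
    """Locate the control line: profile minimum inside the search band.

    Returns ``(position, value)``; ties on equal minima break to the smallest
    position. A flat profile inside the band means no control line developed
    and the strip is invalid.
    """
    n = len(p)
    if n < 10:
        raise ValueError(f"profile too short for detection ({n} < 10 positions)")
    i0 = int(math.floor(cfg.control_search_lo * n))
    i1 = int(math.floor(cfg.control_search_hi * n))
    seg = p.values[i0:i1]
    if seg.size == 0:
        raise NoControlLineError("control search band is empty")
    if np.ptp(seg) == 0:
        raise NoControlLineError(
            "profile is flat in the control search band; no control line"
        )
    k = i0 + int(np.argmin(seg))  # argmin returns the first (leftmost) minimum
    return int(p.positions[k]), float(p.values[k])


def detect_test(
    p: IntensityProfile, control_pos: int, cfg: DetectionConfig
) -> tuple[int, float]:
    """Locate the test line: minimum inside a window upstream of the control.

    The window is ``control_pos - expected_offset +- test_window_halfwidth``,
    clipped to the profile; ties break to the smallest position.
    """
    center = _index_of(p, control_pos) - cfg.expected_offset
    lo = max(center - cfg.test_window_halfwidth, 0)
    hi = min(center + cfg.test_window_halfwidth + 1, len(p))
    if lo >= hi:
        raise TestWindowError(
            f"test window [{center - cfg.test_window_halfwidth}, "
            f"{center + cfg.test_window_halfwidth}] lies outside the profile"
        )
    seg = p.values[lo:hi]
    k = lo + int(np.argmin(seg))
    return int(p.positions[k]), float(p.values[k])


def background_stats(
    p: IntensityProfile, test_pos: int, control_pos: int, cfg: DetectionConfig
) -> tuple[float, float]:
    """Mean and sample sd of the background between the two lines.

    Uses positions strictly between ``test_pos`` and ``control_pos`` further
    than ``line_exclusion_margin`` pixels from either line; at least
    ``min_background_px`` positions must remain.
    """
    if not test_pos < control_pos:
        raise ValueError("test line must lie upstream of the control line")
    lo = _index_of(p, test_pos) + cfg.line_exclusion_margin + 1
    hi = _index_of(p, control_pos) - cfg.line_exclusion_margin  # exclusive
    seg = p.values[max(lo, 0) : max(hi, 0)]
    if seg.size < cfg.min_background_px:
        raise BackgroundTooSmallError(
            f"only {seg.size} background positions remain "
            f"(need >= {cfg.min_background_px})"
        )
    mean = float(seg.mean())
    sd = float(seg.std(ddof=1)) if seg.size > 1 else 0.0
    return mean, sd


def compute_ratios(
    test_value: float, control_value: float, background_mean: float
) -> tuple[float, float, float]:
    """The three normalised line-darkness ratios.

    ``ratio_tc`` is computed as ``ratio_tb / ratio_cb``, which equals
    ``test_value / control_value`` and keeps the identity between the three
    ratios exact in floating point.
    """
    if background_mean <= 0:
        raise ValueError(f"background mean must be > 0, got {background_mean}")
    if control_value <= 0:
        raise ValueError(f"control value must be > 0, got {control_value}")
    ratio_tb = test_value / background_mean
    ratio_cb = control_value / background_mean
    ratio_tc = ratio_tb / ratio_cb
    return ratio_tb, ratio_cb, ratio_tc


def analyze_strip(
    img: StripImage,
    roi: RoiRect,
    cfg: DetectionConfig | None = None,
    keep_audit: bool = True,
) -> StripMeasurement:
    """Full single-strip analysis: image in, three ratios out.

    Composes grayscale conversion, RoI crop, transverse averaging, smoothing,
    control- and test-line detection, background statistics and the ratio
    computation. Any stage failure is re-raised as
    :class:`PipelineStageError` naming the stage. When ``keep_audit`` is true
    the returned measurement carries every intermediate (raw and smoothed
    profiles, window bounds) for inspection.
    """
    cfg = cfg or DetectionConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    gray = stage("to_grayscale", to_grayscale, img)
    cropped = stage("crop_roi", crop_roi, gray, roi)
    raw = stage("average_profile", average_profile, cropped, cfg.flow_axis)
    prof = stage("smooth_profile", smooth_profile, raw, cfg.smooth_window)
    control_pos, control_value = stage("detect_control", detect_control, prof, cfg)
    test_pos, test_value = stage("detect_test", detect_test, prof, control_pos, cfg)
    bg_mean, bg_sd = stage(
        "background_stats", background_stats, prof, test_pos, control_pos, cfg
    )
    ratio_tb, ratio_cb, ratio_tc = stage(
        "compute_ratios", compute_ratios, test_value, control_value, bg_mean
    )

    audit = None
    if keep_audit:
        audit = {
            "roi": roi,
            "raw_profile": raw,
            "smoothed_profile": prof,
            "smooth_window": cfg.smooth_window,
            "control_search_band": (
                int(math.floor(cfg.control_search_lo * len(prof))),
                int(math.floor(cfg.control_search_hi * len(prof))),
            ),
            "test_window_center": control_pos - cfg.expected_offset,
        }
    return StripMeasurement(
        control_pos=control_pos,
        control_value=control_value,
        test_pos=test_pos,
        test_value=test_value,
        background_mean=bg_mean,
        background_sd=bg_sd,
        ratio_tb=ratio_tb,
        ratio_cb=ratio_cb,
        ratio_tc=ratio_tc,
        flags=frozenset(),
        audit=audit,
    )
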